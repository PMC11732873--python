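"""Synthetic PET/CT phantoms and simulated cohorts with known ground truth.

Because clinical PET/CT data with MACE follow-up cannot be shared, every
pipeline stage here is exercised on synthetic inputs:

* **Phantoms** — a tubular "aorta" (soft-tissue lumen on CT, blood-pool
  uptake on PET) running axially next to a high-attenuation,
  high-uptake "vertebral column", with calcified lesions of specified
  pixel footprint and HU inside the aortic wall and focal PET hotspots
  of specified SUV. Bone uptake spills into a halo around the column
  (exponential decay, truncated below the 10 mm exclusion distance), so
  the spill-over correction is testable. With zero noise, the total
  Agatston score and cSUVmax of a phantom follow in closed form from
  the spec (:class:`PhantomTruth`), which is what the pipeline is
  checked against.

* **Cohorts** — per-patient biomarker values drawn from correlated
  log-normal distributions calibrated to the observed cohort scale
  (cSUVmax median 0.64 with tertiles near 0.50/0.77; Agatston median
  2893 with tertiles near 1403/7153, heavy right tail), age from a
  truncated normal (61 +/- 17 y, range 7-92), exponential event times
  whose hazard depends on the biomarker tertile, and administrative
  censoring spread over 0.5-7.3 years (median ~3.9 y of follow-up).
  Defaults target the observed scale of ~12 events among 216 patients
  with the excess hazard concentrated in the high tertile.

All randomness is governed by a single integer seed per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .imaging import BinaryMask, ImageVolume
from .masks import SphereVOI
from .calcium import DEFAULT_MIN_AREA_MM2, DEFAULT_THRESHOLD_HU, density_weight
from .survival import tertile_stratify

__all__ = [
    "LesionSpec",
    "HotspotSpec",
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "random_phantom_spec",
    "CohortSpec",
    "make_cohort",
    "baseline_for_expected_events",
]


class PhantomSpecError(ValueError):
    """Raised when a phantom spec cannot yield exact closed-form truth."""


@dataclass(frozen=True)
class LesionSpec:
    """A rectangular calcified patch on one axial slice (uniform HU)."""

    slice_index: int
    i0: int
    j0: int
    ni: int
    nj: int
    hu: float

    @property
    def pixel_count(self) -> int:
        return self.ni * self.nj


@dataclass(frozen=True)
class HotspotSpec:
    """A single-voxel PET hotspot."""

    slice_index: int
    i: int
    j: int
    suv: float


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (48, 48, 28)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    # aorta: tube along z between slice_lo..slice_hi (inclusive)
    aorta_center_mm: tuple[float, float] = (24.0, 32.0)
    aorta_radius_mm: float = 13.0
    slice_lo: int = 2
    slice_hi: int = 23
    # vertebral column: axis-aligned cuboid over the same slice range
    vertebra_x_mm: tuple[float, float] | None = (16.0, 32.0)
    vertebra_y_mm: tuple[float, float] | None = (0.0, 12.0)
    vertebra_hu: float = 700.0
    vertebra_suv: float = 10.0
    # spill-over halo around bone on PET: amp * exp(-d / tau) for d <= reach
    spill_amplitude: float = 3.0
    spill_tau_mm: float = 2.0
    spill_reach_mm: float = 9.0
    # tissue values
    background_hu: float = -50.0
    lumen_hu: float = 40.0
    blood_pool_suv: float = 1.0
    lesions: list[LesionSpec] = field(default_factory=list)
    hotspots: list[HotspotSpec] = field(default_factory=list)
    sphere_centers_mm: tuple[tuple[float, float, float], ...] = (
        (18.0, 30.0, 78.0),
        (30.0, 30.0, 78.0),
        (24.0, 38.0, 78.0),
    )
    noise_sigma_ct: float = 0.0
    noise_sigma_pet: float = 0.0
    # margin the generator enforces between lesions/hotspots and bone so
    # that the spill-over exclusion provably cannot remove them
    exclusion_margin_mm: float = 13.0


@dataclass
class PhantomTruth:
    """Closed-form ground truth of a zero-noise phantom."""

    total_agatston: float
    csuvmax: float
    average_suvmax: float
    blood_pool_suvmean: float
    lesion_inventory: list[dict]
    n_slices: int


def _aorta_cross_section(spec: PhantomSpec) -> np.ndarray:
    nx, ny, _ = spec.shape
    dx, dy, _ = spec.spacing
    x = np.arange(nx) * dx
    y = np.arange(ny) * dy
    cx, cy = spec.aorta_center_mm
    return (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2 <= spec.aorta_radius_mm**2


def _vertebra_mask(spec: PhantomSpec) -> np.ndarray:
    mask = np.zeros(spec.shape, dtype=bool)
    if spec.vertebra_x_mm is None or spec.vertebra_y_mm is None:
        return mask
    nx, ny, _ = spec.shape
    dx, dy, _ = spec.spacing
    x = np.arange(nx) * dx
    y = np.arange(ny) * dy
    xi = (x >= spec.vertebra_x_mm[0]) & (x <= spec.vertebra_x_mm[1])
    yi = (y >= spec.vertebra_y_mm[0]) & (y <= spec.vertebra_y_mm[1])
    cross = xi[:, None] & yi[None, :]
    mask[:, :, spec.slice_lo : spec.slice_hi + 1] = cross[:, :, None]
    return mask


def phantom_truth(
    spec: PhantomSpec,
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
) -> PhantomTruth:
    """Ground truth by closed form, independent of any image processing."""
    dx, dy, _ = spec.spacing
    inventory = []
    total = 0.0
    for les in spec.lesions:
        area = les.pixel_count * dx * dy
        counted = les.hu >= threshold_hu and area > min_area_mm2
        w = density_weight(les.hu) if les.hu >= threshold_hu else 0
        score = area * w if counted else 0.0
        inventory.append(
            {
                "slice_index": les.slice_index,
                "pixel_count": les.pixel_count,
                "area_mm2": area,
                "peak_hu": les.hu,
                "weight": w if counted else 0,
                "score": score,
                "counted": counted,
            }
        )
        total += score
    slices = range(spec.slice_lo, spec.slice_hi + 1)
    per_slice_max = {k: spec.blood_pool_suv for k in slices}
    for h in spec.hotspots:
        per_slice_max[h.slice_index] = max(per_slice_max[h.slice_index], h.suv)
    avg = float(np.mean(list(per_slice_max.values())))
    return PhantomTruth(
        total_agatston=total,
        csuvmax=avg - spec.blood_pool_suv,
        average_suvmax=avg,
        blood_pool_suvmean=spec.blood_pool_suv,
        lesion_inventory=inventory,
        n_slices=len(per_slice_max),
    )


def _validate_spec(spec: PhantomSpec, aorta_cross, vert_mask) -> None:
    nx, ny, nz = spec.shape
    if not (0 <= spec.slice_lo <= spec.slice_hi < nz):
        raise PhantomSpecError("aorta slice range outside the volume")
    if spec.spill_reach_mm >= 10.0:
        raise PhantomSpecError(
            "spill reach must stay below the 10 mm exclusion distance "
            "for the closed-form truth to hold"
        )
    # lesions: inside the aorta, inside the slice range, mutually separated
    by_slice: dict[int, list[LesionSpec]] = {}
    for les in spec.lesions:
        if not (spec.slice_lo <= les.slice_index <= spec.slice_hi):
            raise PhantomSpecError(f"lesion on slice {les.slice_index} outside aorta")
        if les.i0 < 0 or les.j0 < 0 or les.i0 + les.ni > nx or les.j0 + les.nj > ny:
            raise PhantomSpecError("lesion footprint outside the grid")
        foot = aorta_cross[les.i0 : les.i0 + les.ni, les.j0 : les.j0 + les.nj]
        if not foot.all():
            raise PhantomSpecError(
                f"lesion at slice {les.slice_index}, ({les.i0},{les.j0}) "
                "extends outside the aorta"
            )
        by_slice.setdefault(les.slice_index, []).append(les)
    for k, group in by_slice.items():
        for a in range(len(group)):
            for b in range(a + 1, len(group)):
                la, lb = group[a], group[b]
                gap_i = max(la.i0 - (lb.i0 + lb.ni), lb.i0 - (la.i0 + la.ni))
                gap_j = max(la.j0 - (lb.j0 + lb.nj), lb.j0 - (la.j0 + la.nj))
                if gap_i < 1 and gap_j < 1:
                    raise PhantomSpecError(
                        f"lesions on slice {k} touch under 8-connectivity"
                    )
    seen = set()
    for h in spec.hotspots:
        if not (spec.slice_lo <= h.slice_index <= spec.slice_hi):
            raise PhantomSpecError(f"hotspot on slice {h.slice_index} outside aorta")
        if not (0 <= h.i < nx and 0 <= h.j < ny):
            raise PhantomSpecError("hotspot outside the grid")
        if not aorta_cross[h.i, h.j]:
            raise PhantomSpecError(f"hotspot at ({h.i},{h.j}) outside the aorta")
        key = (h.slice_index, h.i, h.j)
        if key in seen:
            raise PhantomSpecError(f"duplicate hotspot voxel {key}")
        seen.add(key)

    if vert_mask.any():
        dist = ndimage.distance_transform_edt(~vert_mask, sampling=spec.spacing)
        margin = spec.exclusion_margin_mm
        for les in spec.lesions:
            d = dist[les.i0 : les.i0 + les.ni, les.j0 : les.j0 + les.nj, les.slice_index]
            if (d <= margin).any():
                raise PhantomSpecError(
                    f"lesion on slice {les.slice_index} within {margin} mm of "
                    "bone: the spill-over exclusion could remove it"
                )
        for h in spec.hotspots:
            if dist[h.i, h.j, h.slice_index] <= margin:
                raise PhantomSpecError(
                    f"hotspot on slice {h.slice_index} within {margin} mm of bone"
                )
        # every aortic slice must keep voxels beyond the exclusion zone
        far = dist[:, :, spec.slice_lo] > margin
        if not (aorta_cross & far).any():
            raise PhantomSpecError("aorta fully inside the exclusion zone")
        # blood-pool spheres must sit in uniform background
        radius = SphereVOI((0, 0, 0)).radius_mm
        dxs = np.arange(nx) * spec.spacing[0]
        dys = np.arange(ny) * spec.spacing[1]
        dzs = np.arange(nz) * spec.spacing[2]
        hot_keys = {(h.i, h.j, h.slice_index) for h in spec.hotspots}
        for c in spec.sphere_centers_mm:
            d2 = (
                (dxs - c[0])[:, None, None] ** 2
                + (dys - c[1])[None, :, None] ** 2
                + (dzs - c[2])[None, None, :] ** 2
            )
            inside = d2 <= radius**2
            if (dist[inside] <= spec.spill_reach_mm).any() or vert_mask[inside].any():
                raise PhantomSpecError(
                    f"blood-pool sphere at {c} touches bone or its spill halo"
                )
            ii, jj, kk = np.nonzero(inside)
            for a, b, cix in zip(ii, jj, kk):
                if (a, b, cix) in hot_keys:
                    raise PhantomSpecError(
                        f"blood-pool sphere at {c} contains a hotspot voxel"
                    )


def make_phantom(spec: PhantomSpec, seed: int = 0):
    """Build CT, PET, masks, blood-pool VOIs and closed-form truth.

    Returns ``(ct, pet, aorta_mask, vertebra_mask, sphere_vois, truth)``.
    The truth is computed from the spec alone and is exact when both
    noise sigmas are zero; noise never changes the reported truth.
    """
    aorta_cross = _aorta_cross_section(spec)
    vert = _vertebra_mask(spec)
    _validate_spec(spec, aorta_cross, vert)
    nx, ny, nz = spec.shape

    aorta = np.zeros(spec.shape, dtype=bool)
    aorta[:, :, spec.slice_lo : spec.slice_hi + 1] = aorta_cross[:, :, None]

    ct = np.full(spec.shape, spec.background_hu, dtype=float)
    ct[aorta] = spec.lumen_hu
    ct[vert] = spec.vertebra_hu
    for les in spec.lesions:
        ct[les.i0 : les.i0 + les.ni, les.j0 : les.j0 + les.nj, les.slice_index] = les.hu

    pet = np.full(spec.shape, spec.blood_pool_suv, dtype=float)
    if vert.any():
        dist = ndimage.distance_transform_edt(~vert, sampling=spec.spacing)
        halo = (dist > 0) & (dist <= spec.spill_reach_mm)
        pet[halo] += spec.spill_amplitude * np.exp(-dist[halo] / spec.spill_tau_mm)
        pet[vert] = spec.vertebra_suv
    for h in spec.hotspots:
        pet[h.i, h.j, h.slice_index] = h.suv

    rng = np.random.default_rng(seed)
    if spec.noise_sigma_ct > 0:
        ct = ct + rng.normal(0.0, spec.noise_sigma_ct, size=spec.shape)
    if spec.noise_sigma_pet > 0:
        pet = pet + rng.normal(0.0, spec.noise_sigma_pet, size=spec.shape)

    ct_vol = ImageVolume(ct, spec.spacing, unit="HU")
    pet_vol = ImageVolume(pet, spec.spacing, unit="SUV")
    aorta_mask = BinaryMask(aorta, spec.spacing)
    vert_mask = BinaryMask(vert, spec.spacing)
    vois = [SphereVOI(c, 1.0) for c in spec.sphere_centers_mm]
    return ct_vol, pet_vol, aorta_mask, vert_mask, vois, phantom_truth(spec)


# candidate in-aorta sites kept > exclusion_margin from the default column
_LESION_SITES = [(18, 28), (26, 28), (22, 36), (30, 36)]
_HOTSPOT_SITES = [(22, 40), (28, 40)]


def random_phantom_spec(
    seed: int,
    max_lesions: int = 20,
    max_hotspots: int = 10,
    noise_sigma_ct: float = 0.0,
    noise_sigma_pet: float = 0.0,
) -> PhantomSpec:
    """Random valid phantom: 0..max lesions (including sub-threshold and
    sub-area distractors) and 0..max single-voxel hotspots."""
    rng = np.random.default_rng(seed)
    spec = PhantomSpec(noise_sigma_ct=noise_sigma_ct, noise_sigma_pet=noise_sigma_pet)
    slices = list(range(spec.slice_lo, spec.slice_hi + 1))

    n_lesions = int(rng.integers(0, max_lesions + 1))
    slots = [(k, s) for k in slices for s in range(len(_LESION_SITES))]
    rng.shuffle(slots)
    lesions = []
    for k, s in slots[:n_lesions]:
        i0, j0 = _LESION_SITES[s]
        ni = int(rng.integers(1, 4))
        nj = int(rng.integers(1, 4))
        kind = rng.random()
        if kind < 0.15:  # sub-threshold distractor
            hu = float(rng.uniform(60, 129))
        else:
            hu = float(rng.uniform(130, 1000))
        lesions.append(LesionSpec(k, i0, j0, ni, nj, hu))

    n_hot = int(rng.integers(0, max_hotspots + 1))
    hslots = [(k, s) for k in slices for s in range(len(_HOTSPOT_SITES))]
    rng.shuffle(hslots)
    hotspots = [
        HotspotSpec(k, *_HOTSPOT_SITES[s], suv=float(rng.uniform(1.5, 5.0)))
        for k, s in hslots[:n_hot]
    ]
    return replace(spec, lesions=lesions, hotspots=hotspots)


# ---------------------------------------------------------------------------
# simulated cohorts


@dataclass
class CohortSpec:
    """Generative model for a survival cohort at the observed scale."""

    n: int = 216
    csuvmax_log_mu: float = float(np.log(0.64))
    csuvmax_log_sigma: float = 0.57
    agatston_log_mu: float = float(np.log(2893.0))
    agatston_log_sigma: float = 1.9
    metric_correlation: float = 0.5
    age_mean: float = 61.0
    age_sd: float = 17.0
    age_range: tuple[float, float] = (7.0, 92.0)
    hazard_ratios: tuple[float, float, float] = (1.0, 1.0, 5.0)
    baseline_hazard: float | None = None  # per year; None -> solve for events
    expected_events: float = 12.0
    censor_low_years: float = 0.5
    censor_high_years: float = 7.3
    hazard_metric: str = "csuvmax"

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("cohort needs n >= 3")
        if any(h <= 0 for h in self.hazard_ratios):
            raise ValueError("hazard ratios must be positive")
        if self.baseline_hazard is not None and self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")


def _mean_exp_neg_hC(h: float, a: float, b: float) -> float:
    """E[exp(-h C)] for C ~ Uniform(a, b)."""
    if h == 0:
        return 1.0
    return (np.exp(-h * a) - np.exp(-h * b)) / (h * (b - a))


def baseline_for_expected_events(spec: CohortSpec) -> float:
    """Baseline hazard (per year) giving the spec's expected event count
    under equal tertile sizes and uniform administrative censoring."""
    a, b = spec.censor_low_years, spec.censor_high_years
    n_g = spec.n / 3.0

    def expected(lam):
        return sum(
            n_g * (1.0 - _mean_exp_neg_hC(lam * hr, a, b))
            for hr in spec.hazard_ratios
        )

    # a cohort of n subjects cannot expect more than n events; cap the
    # target so tiny cohorts remain generable
    target = min(spec.expected_events, 0.9 * spec.n)
    return float(optimize.brentq(lambda lam: expected(lam) - target, 1e-8, 50.0))


def make_cohort(spec: CohortSpec, seed: int = 0) -> pd.DataFrame:
    """Simulate a cohort table (id, age, metrics, follow-up, event).

    Biomarkers are correlated log-normals; the event hazard is
    ``baseline * HR(tertile of the hazard metric)`` with exponential
    event times and uniform administrative censoring.
    """
    rng = np.random.default_rng(seed)
    n = spec.n
    rho = spec.metric_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    csuv = np.exp(spec.csuvmax_log_mu + spec.csuvmax_log_sigma * z[:, 0])
    agat = np.exp(spec.agatston_log_mu + spec.agatston_log_sigma * z[:, 1])
    age = np.clip(
        rng.normal(spec.age_mean, spec.age_sd, size=n), *spec.age_range
    )

    metric = csuv if spec.hazard_metric == "csuvmax" else agat
    labels, _ = tertile_stratify(metric)
    hr = np.array(
        [spec.hazard_ratios[("low", "medium", "high").index(g)] for g in labels]
    )
    lam0 = (
        spec.baseline_hazard
        if spec.baseline_hazard is not None
        else baseline_for_expected_events(spec)
    )
    t_event = rng.exponential(1.0 / (lam0 * hr))
    t_censor = rng.uniform(spec.censor_low_years, spec.censor_high_years, size=n)
    event = t_event <= t_censor
    followup = np.where(event, t_event, t_censor)
    return pd.DataFrame(
        {
            "id": [f"P{i:04d}" for i in range(n)],
            "age_years": age,
            "csuvmax": csuv,
            "agatston": agat,
            "followup_years": followup,
            "event": event.astype(bool),
        }
    )
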