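"""End-to-end orchestration: images -> per-patient metrics ("quantify")
and cohort table -> survival results ("associate")."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calcium import CalciumResult, agatston_total
from .imaging import (
    BinaryMask,
    ImageVolume,
    assert_same_geometry,
    read_mask,
    read_volume,
)
from .masks import SphereVOI, rasterize_spheres, spill_over_corrected_aorta
from .survival import (
    cohen_kappa,
    concordance_percent,
    cox_fit,
    km_estimate,
    logrank_test,
    tertile_stratify,
)
from .uptake import UptakeResult, csuvmax

__all__ = [
    "PipelineConfig",
    "QuantifyResult",
    "run_quantify",
    "run_quantify_paths",
    "run_associate",
    "load_spheres_json",
]

log = logging.getLogger(__name__)

COHORT_COLUMNS = ["id", "age_years", "csuvmax", "agatston", "followup_years", "event"]


@dataclass
class PipelineConfig:
    """Quantification parameters; defaults follow the published protocol
    (130 HU threshold, lesions > 1 mm^2, 10 mm spill-over dilation)."""

    threshold_hu: float = 130.0
    min_area_mm2: float = 1.0
    dilate_mm: float = 10.0
    close_radius_mm: float = 3.0
    connectivity: int = 8
    blood_pool_convention: str = "mean-of-means"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class QuantifyResult:
    calcium: CalciumResult
    uptake: UptakeResult
    n_aorta_voxels: int
    n_corrected_voxels: int

    def metrics_row(self, patient_id: str = "phantom") -> dict:
        return {
            "patient_id": patient_id,
            "csuvmax": self.uptake.csuvmax,
            "average_suvmax": self.uptake.average_suvmax,
            "blood_pool_suvmean": self.uptake.blood_pool_suvmean,
            "n_slices": self.uptake.n_slices,
            "total_agatston": self.calcium.total_agatston,
            "n_lesions": self.calcium.n_lesions,
        }


def run_quantify(
    ct: ImageVolume,
    pet: ImageVolume,
    aorta: BinaryMask,
    vertebrae: BinaryMask,
    spheres: list[SphereVOI],
    config: PipelineConfig | None = None,
) -> QuantifyResult:
    """Spill-over correction, Agatston scoring and cSUVmax in one pass."""
    config = config or PipelineConfig()
    for other in (pet, aorta, vertebrae):
        assert_same_geometry(ct, other)
    corrected = spill_over_corrected_aorta(
        aorta, vertebrae, config.close_radius_mm, config.dilate_mm
    )
    n_raw, n_corr = aorta.count(), corrected.count()
    log.info(
        "spill-over correction removed %d of %d aortic voxels", n_raw - n_corr, n_raw
    )
    if corrected.is_empty():
        raise ValueError("empty aortic mask after spill-over correction")
    calcium = agatston_total(
        ct,
        corrected,
        threshold_hu=config.threshold_hu,
        min_area_mm2=config.min_area_mm2,
        connectivity=config.connectivity,
    )
    _, sphere_idx = rasterize_spheres(pet, spheres)
    uptake = csuvmax(pet, corrected, sphere_idx, config.blood_pool_convention)
    return QuantifyResult(
        calcium=calcium,
        uptake=uptake,
        n_aorta_voxels=n_raw,
        n_corrected_voxels=n_corr,
    )


def load_spheres_json(path: str | Path) -> list[SphereVOI]:
    """Sphere VOIs from a JSON list of {"center_mm": [x,y,z], "volume_ml": v}."""
    with open(path) as fh:
        raw = json.load(fh)
    return [
        SphereVOI(tuple(d["center_mm"]), float(d.get("volume_ml", 1.0))) for d in raw
    ]


def run_quantify_paths(
    ct_path, pet_path, aorta_path, vertebra_path, spheres_path, config=None
) -> QuantifyResult:
    ct = read_volume(ct_path, unit="HU")
    pet = read_volume(pet_path, unit="SUV")
    aorta = read_mask(aorta_path)
    vertebrae = read_mask(vertebra_path)
    spheres = load_spheres_json(spheres_path)
    return run_quantify(ct, pet, aorta, vertebrae, spheres, config)


def _km_frame(df: pd.DataFrame, labels: np.ndarray, metric: str) -> pd.DataFrame:
    rows = []
    for g in ("low", "medium", "high"):
        sel = labels == g
        if not sel.any():
            continue
        curve = km_estimate(df.loc[sel, "followup_years"], df.loc[sel, "event"])
        for t, n, d, s in zip(
            curve.event_times, curve.at_risk, curve.events, curve.survival
        ):
            rows.append(
                {
                    "metric": metric,
                    "group": g,
                    "time_years": t,
                    "at_risk": int(n),
                    "events": int(d),
                    "survival": s,
                }
            )
    return pd.DataFrame(rows)


def run_associate(cohort: pd.DataFrame, config: PipelineConfig | None = None) -> dict:
    """Tertile stratification + survival/agreement analysis of a cohort.

    Returns a dict with, per metric (csuvmax, agatston): tertile
    boundaries, per-group KM curves (as DataFrame), overall and pairwise
    log-rank tests, and an age-adjusted Cox fit of the continuous
    metric; plus kappa and concordance between the two stratifications.
    """
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    df = cohort.copy()
    df["event"] = df["event"].astype(bool)
    times = df["followup_years"].to_numpy(float)
    events = df["event"].to_numpy(bool)
    if (times <= 0).any():
        raise ValueError("column followup_years must be strictly positive")

    out: dict = {"n": int(len(df)), "n_events": int(events.sum()), "metrics": {}}
    labels_by_metric = {}
    for metric in ("csuvmax", "agatston"):
        values = df[metric].to_numpy(float)
        labels, (t1, t2) = tertile_stratify(values)
        labels_by_metric[metric] = labels
        lr = logrank_test(labels, times, events)
        X = np.column_stack([values, df["age_years"].to_numpy(float)])
        cox = cox_fit(X, times, events, names=[metric, "age_years"])
        out["metrics"][metric] = {
            "tertile_boundaries": (t1, t2),
            "group_sizes": {g: int((labels == g).sum()) for g in ("low", "medium", "high")},
            "events_per_group": {
                g: int(events[labels == g].sum()) for g in ("low", "medium", "high")
            },
            "logrank": {
                "chi2": lr.chi2,
                "df": lr.df,
                "p": lr.p,
                "pairwise": {
                    f"{a}_vs_{b}": {"chi2": c, "p": p}
                    for (a, b), (c, p) in lr.pairwise.items()
                },
            },
            "cox_age_adjusted": {
                "coef": dict(zip(cox.names, cox.coefficients.tolist())),
                "hr": dict(zip(cox.names, cox.hazard_ratios().tolist())),
                "se": dict(zip(cox.names, cox.standard_errors.tolist())),
                "wald_z": dict(zip(cox.names, cox.wald_z.tolist())),
                "wald_p": dict(zip(cox.names, cox.wald_p.tolist())),
                "lrt_statistic": cox.lrt_statistic,
                "lrt_p": cox.lrt_p,
            },
            "km_curves": _km_frame(df, labels, metric),
        }

    la, lb = labels_by_metric["csuvmax"], labels_by_metric["agatston"]
    order = ("low", "medium", "high")
    table = np.array(
        [[int(((la == a) & (lb == b)).sum()) for b in order] for a in order]
    )
    kap = cohen_kappa(table)
    overall, per_group = concordance_percent(la, lb)
    out["agreement"] = {
        "crosstab": table.tolist(),
        "kappa": kap.kappa,
        "kappa_se": kap.se,
        "kappa_ci95": list(kap.ci95),
        "concordance_percent": overall,
        "concordance_per_group": per_group,
    }
    return out


def write_associate_outputs(results: dict, out_dir: str | Path) -> None:
    """Persist run_associate output as JSON + per-group KM curve CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    serializable = json.loads(
        json.dumps(
            {
                **results,
                "metrics": {
                    m: {k: v for k, v in d.items() if k != "km_curves"}
                    for m, d in results["metrics"].items()
                },
            },
            default=float,
        )
    )
    with open(out_dir / "survival_results.json", "w") as fh:
        json.dump(serializable, fh, indent=2)
    frames = [d["km_curves"] for d in results["metrics"].values()]
    pd.concat(frames, ignore_index=True).to_csv(
        out_dir / "km_curves.csv", index=False
    )
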