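"""Tertile stratification and survival/agreement statistics.

The cohort half of the pipeline: patients are split into low/medium/high
groups at the first and second tertiles of a biomarker (cSUVmax or total
Agatston score), MACE-free survival is estimated per group with the
Kaplan-Meier product-limit estimator, groups are compared with the
log-rank test (overall and pairwise, unadjusted), and the association of
the continuous biomarker with the hazard is quantified with an
age-adjusted Cox proportional-hazards model (Efron tie handling, Newton
optimization; likelihood-ratio test for the model, Wald tests per
covariate). Agreement between the two biomarker stratifications is
summarized with Cohen's kappa and raw concordance percentages.

Conventions, pinned for reproducibility:

* tertile boundaries use linear-interpolation percentiles (33.33 / 66.67);
  a value equal to a boundary goes to the lower group;
* at a tied time, events precede censorings (censored subjects remain in
  the risk set for events at their censoring time);
* pairwise log-rank p-values are reported without multiplicity adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "KMCurve",
    "CoxFit",
    "KappaResult",
    "LogrankResult",
    "tertile_stratify",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cohen_kappa",
    "concordance_percent",
]

GROUP_LABELS = ("low", "medium", "high")


# ---------------------------------------------------------------------------
# stratification


def tertile_stratify(values) -> tuple[np.ndarray, tuple[float, float]]:
    """Split values into low/medium/high at the first and second tertiles.

    Boundaries are the 33.33rd and 66.67th percentiles under the
    linear-interpolation convention; assignment is ``low`` if
    ``v <= t1``, ``medium`` if ``t1 < v <= t2``, else ``high``.

    Returns ``(labels, (t1, t2))`` where labels is an object array of
    group names aligned with the input.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("need at least 3 values to form tertiles")
    if not np.isfinite(v).all():
        raise ValueError("tertile stratification requires finite values")
    t1, t2 = np.percentile(v, [100 / 3, 200 / 3], method="linear")
    if t1 == t2:
        raise ValueError("degenerate tertiles: boundaries coincide")
    labels = np.where(v <= t1, "low", np.where(v <= t2, "medium", "high"))
    return labels.astype(object), (float(t1), float(t2))


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    """Product-limit survival estimate at the distinct event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_surv_input(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("times and events must have the same length")
    if (t <= 0).any():
        raise ValueError("follow-up times must be strictly positive")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimator with right censoring (events-first ties)."""
    t, e = _check_surv_input(times, events)
    ev_times = np.unique(t[e])
    at_risk = np.array([(t >= u).sum() for u in ev_times], dtype=int)
    d = np.array([((t == u) & e).sum() for u in ev_times], dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(event_times=ev_times, at_risk=at_risk, events=d, survival=surv)


# ---------------------------------------------------------------------------
# log-rank


@dataclass
class LogrankResult:
    chi2: float
    df: int
    p: float
    pairwise: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    """(chi2, p) per unordered group pair, unadjusted."""


def _logrank_chi2(t, e, g, groups) -> tuple[float, int]:
    """k-sample log-rank chi-square via the grouped O-E / covariance form."""
    k = len(groups)
    gidx = {lab: i for i, lab in enumerate(groups)}
    gi = np.array([gidx[x] for x in g])
    ev_times = np.unique(t[e])
    OmE = np.zeros(k)
    V = np.zeros((k, k))
    for u in ev_times:
        at_risk = t >= u
        n = at_risk.sum()
        d = ((t == u) & e).sum()
        if n <= 1:
            continue
        ng = np.bincount(gi[at_risk], minlength=k).astype(float)
        dg = np.bincount(gi[(t == u) & e], minlength=k).astype(float)
        frac = ng / n
        OmE += dg - d * frac
        mult = d * (n - d) / (n - 1)
        V += mult * (np.diag(frac) - np.outer(frac, frac))
    sub = slice(0, k - 1)
    v = V[sub, sub]
    o = OmE[sub]
    try:
        chi2 = float(o @ np.linalg.solve(v, o))
    except np.linalg.LinAlgError:
        chi2 = float(o @ np.linalg.pinv(v) @ o)
    return max(chi2, 0.0), k - 1


def logrank_test(group_labels, times, events) -> LogrankResult:
    """Log-rank comparison of survival across >= 2 groups.

    Returns the overall chi-square test (df = groups - 1) plus all
    pairwise two-group tests, unadjusted for multiplicity.
    """
    t, e = _check_surv_input(times, events)
    g = np.asarray(group_labels, dtype=object)
    if g.shape != t.shape:
        raise ValueError("group labels must align with times")
    groups = [lab for lab in GROUP_LABELS if lab in g] or sorted(
        set(g), key=str
    )
    present = set(g)
    groups = [lab for lab in groups if lab in present]
    if len(groups) < 2:
        raise ValueError("log-rank test requires >= 2 nonempty groups")
    chi2, df = _logrank_chi2(t, e, g, groups)
    p = float(stats.chi2.sf(chi2, df))
    pairwise: dict[tuple[str, str], tuple[float, float]] = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            sel = (g == groups[i]) | (g == groups[j])
            c2, _ = _logrank_chi2(t[sel], e[sel], g[sel], [groups[i], groups[j]])
            pairwise[(groups[i], groups[j])] = (c2, float(stats.chi2.sf(c2, 1)))
    return LogrankResult(chi2=chi2, df=df, p=p, pairwise=pairwise)


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    wald_z: np.ndarray
    wald_p: np.ndarray
    lrt_statistic: float
    lrt_p: float
    log_likelihood: float
    null_log_likelihood: float
    n_iter: int
    converged: bool
    separation_flag: bool = False

    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)


def _cox_loglik_grad_hess(beta, X, t, e, ties: str = "efron"):
    """Partial log-likelihood, gradient and Hessian (Efron or Breslow ties).

    Subjects sorted by time descending so risk sets are cumulative sums.
    With no tied event times the two tie methods coincide exactly.
    """
    n, p = X.shape
    order = np.argsort(-t, kind="stable")
    Xs, ts, es = X[order], t[order], e[order]
    eta = Xs @ beta
    eta -= eta.max()  # overflow guard; partial likelihood is shift-invariant
    w = np.exp(eta)
    wx = w[:, None] * Xs
    wxx = wx[:, :, None] * Xs[:, None, :]

    cw = np.cumsum(w)
    cwx = np.cumsum(wx, axis=0)
    cwxx = np.cumsum(wxx, axis=0)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        # subjects i..j share this time; risk set = everyone up to j
        ev = np.arange(i, j + 1)[es[i : j + 1]]
        d = ev.size
        if d > 0:
            R_w, R_wx, R_wxx = cw[j], cwx[j], cwxx[j]
            tie_w = w[ev].sum()
            tie_wx = wx[ev].sum(axis=0)
            tie_wxx = wxx[ev].sum(axis=0)
            ll += eta[ev].sum()
            grad += Xs[ev].sum(axis=0)
            for r in range(d):
                f = r / d if ties == "efron" else 0.0
                denom = R_w - f * tie_w
                num = R_wx - f * tie_wx
                num2 = R_wxx - f * tie_wxx
                ll -= np.log(denom)
                grad -= num / denom
                hess -= num2 / denom - np.outer(num, num) / denom**2
        i = j + 1
    return ll, grad, hess


def cox_fit(
    covariates,
    times,
    events,
    names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    ties: str = "efron",
) -> CoxFit:
    """Cox proportional-hazards fit via Newton iteration.

    ``covariates`` is an (n, p) array (or (n,) for a single covariate).
    ``ties`` selects Efron (default, more accurate) or Breslow handling
    of tied event times. Convergence requires gradient max-norm <
    ``tol``. Standard errors come from the inverse observed information;
    the likelihood-ratio test compares against the null (no-covariate)
    model.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    t, e = _check_surv_input(times, events)
    if X.shape[0] != t.size:
        raise ValueError("covariate rows must align with times")
    if e.sum() < 1:
        raise ValueError("Cox fit requires at least one event")
    stds = X.std(axis=0)
    if (stds == 0).any():
        bad = int(np.flatnonzero(stds == 0)[0])
        raise ValueError(f"covariate {bad} is constant")
    p = X.shape[1]
    names = names or [f"x{i}" for i in range(p)]

    # center and scale for conditioning; back-transform at the end
    mu, sd = X.mean(axis=0), stds
    Z = (X - mu) / sd

    beta = np.zeros(p)
    ll0, _, _ = _cox_loglik_grad_hess(beta, Z, t, e, ties)
    ll = ll0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, grad, hess = _cox_loglik_grad_hess(beta, Z, t, e, ties)
        if np.abs(grad).max() < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"singular information matrix: {exc}") from exc
        # Newton step with halving if the likelihood does not improve;
        # the acceptance slack is relative to |ll| so that float-level
        # wiggle near the optimum cannot stall the iteration
        scale = 1.0
        slack = 1e-10 * max(1.0, abs(ll))
        for _ in range(30):
            cand = beta - scale * step
            ll_new, _, _ = _cox_loglik_grad_hess(cand, Z, t, e, ties)
            if ll_new >= ll - slack:
                break
            scale /= 2.0
        beta = beta - scale * step
    else:
        raise RuntimeError(
            f"Cox Newton iteration failed to converge in {max_iter} iterations "
            f"(|grad| = {np.abs(grad).max():.3g}, beta = {beta})"
        )
    ll, grad, hess = _cox_loglik_grad_hess(beta, Z, t, e, ties)

    separation = bool(np.abs(beta).max() > 10.0)  # on standardized scale
    info_inv = np.linalg.inv(-hess)
    se_z = np.sqrt(np.diag(info_inv))
    coef = beta / sd
    se = se_z / sd
    z = coef / se
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    lrt = max(2.0 * (ll - ll0), 0.0)
    lrt_p = float(stats.chi2.sf(lrt, p))
    return CoxFit(
        names=list(names),
        coefficients=coef,
        standard_errors=se,
        wald_z=z,
        wald_p=wald_p,
        lrt_statistic=float(lrt),
        lrt_p=lrt_p,
        log_likelihood=float(ll),
        null_log_likelihood=float(ll0),
        n_iter=it,
        converged=converged,
        separation_flag=separation,
    )


# ---------------------------------------------------------------------------
# agreement


@dataclass
class KappaResult:
    kappa: float
    se: float
    ci95: tuple[float, float]


def cohen_kappa(table) -> KappaResult:
    """Cohen's kappa for a square cross-classification table.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from marginal products;
    the 95% CI is kappa +/- 1.96 * SE with the large-sample
    SE = sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)).
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] != tab.shape[1]:
        raise ValueError("kappa requires a square table")
    n = tab.sum()
    if n < 1:
        raise ValueError("kappa requires at least one observation")
    po = np.trace(tab) / n
    row = tab.sum(axis=1) / n
    col = tab.sum(axis=0) / n
    pe = float(row @ col)
    if pe >= 1.0:
        raise ValueError("expected agreement is 1: kappa undefined")
    kappa = (po - pe) / (1.0 - pe)
    se = float(np.sqrt(po * (1.0 - po) / (n * (1.0 - pe) ** 2)))
    return KappaResult(
        kappa=float(kappa), se=se, ci95=(float(kappa - 1.96 * se), float(kappa + 1.96 * se))
    )


def concordance_percent(labels_a, labels_b) -> tuple[float, dict[str, float]]:
    """Percentage of identically classified subjects, overall and per group.

    Per-group denominators are the subjects with ``labels_a == g`` (the
    first labelling defines the groups).
    """
    a = np.asarray(labels_a, dtype=object)
    b = np.asarray(labels_b, dtype=object)
    if a.size == 0:
        raise ValueError("empty label lists")
    if a.shape != b.shape:
        raise ValueError("label lists must have equal length")
    match = a == b
    overall = 100.0 * match.mean()
    per_group: dict[str, float] = {}
    order = [g for g in GROUP_LABELS if g in a] or sorted(set(a), key=str)
    for g in order:
        sel = a == g
        per_group[g] = 100.0 * match[sel].mean()
    return float(overall), per_group
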