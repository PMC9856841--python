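"""Survival stratification: Kaplan-Meier, log-rank, maximally selected rank
statistics, and univariate Cox hazard ratios.

The optimal-cutpoint search follows the maximally-selected-rank-statistic
construction: for every candidate cutpoint mu of a continuous score whose
induced low/high split leaves at least a fraction ``eps`` of subjects on each
side, the standardized two-group log-rank statistic is evaluated, and the mu
maximizing its absolute value is selected.  Because the maximum over many
correlated splits is anti-conservative, the reported p-value is adjusted
either by the Miller-Siegmund improved-Bonferroni approximation for the
maximum of the standardized process over the candidate interval, or by a
seeded permutation null that re-runs the full maximization on score-permuted
data.

The hazard ratio between the resulting groups comes from a univariate Cox
proportional-hazards fit on the binary high-vs-low indicator, solved by
Newton-Raphson on the partial likelihood with Breslow tie handling (Efron
optional); lifelines backs the Kaplan-Meier curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .errors import NumericalError, ValidationError

__all__ = [
    "CutpointResult",
    "SurvivalFit",
    "km_estimate",
    "logrank",
    "maxstat_cutpoint",
    "dichotomize",
    "cox_hr",
    "fit_survival",
]

#: cap applied to the Cox coefficient under a monotone partial likelihood
_BETA_CAP = 15.0


def _as_surv_arrays(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.shape != event.shape:
        raise ValidationError("time and event must have equal length")
    if (time <= 0).any() or not np.isfinite(time).all():
        raise ValidationError("survival times must be positive and finite")
    if not np.isin(event, [0, 1]).all():
        raise ValidationError("event indicators must be 0 or 1")
    return time, event.astype(int)


def _logrank_components(
    time: np.ndarray, event: np.ndarray, low_mask: np.ndarray
) -> tuple[float, float, float]:
    """Observed events, expected events and hypergeometric variance for the
    'low' group, tabulated over distinct event times."""
    ev_times = np.unique(time[event == 1])
    o1 = e1 = v1 = 0.0
    for t in ev_times:
        at_risk = time >= t
        n_tot = at_risk.sum()
        n_low = (at_risk & low_mask).sum()
        d = int(((time == t) & (event == 1)).sum())
        d_low = int(((time == t) & (event == 1) & low_mask).sum())
        o1 += d_low
        e1 += d * n_low / n_tot
        if n_tot > 1:
            frac = n_low / n_tot
            v1 += d * (n_tot - d) / (n_tot - 1) * frac * (1 - frac)
    return o1, e1, v1


def logrank(time, event, labels) -> tuple[float, float]:
    """Two-group log-rank test.

    Returns the chi-square statistic (1 df) and its p-value.  Requires two
    non-empty groups and at least one event.
    """
    time, event = _as_surv_arrays(time, event)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValidationError(f"log-rank needs exactly two groups, got {list(uniq)}")
    low_mask = labels == uniq[0]
    if low_mask.all() or not low_mask.any():
        raise ValidationError("one group is empty")
    if event.sum() == 0:
        raise ValidationError("log-rank is undefined with zero events")
    o1, e1, v1 = _logrank_components(time, event, low_mask)
    if v1 <= 0:
        return 0.0, 1.0
    chisq = (o1 - e1) ** 2 / v1
    return float(chisq), float(stats.chi2.sf(chisq, df=1))


class _SplitScan:
    """Vectorized standardized log-rank statistics over all cutpoint splits.

    Subjects are taken in a given order; split k puts the first k subjects
    in the 'low' group.  Precomputes per-subject at-risk rows over the
    distinct event times so that a full scan is a cumulative sum, which
    makes permutation re-runs cheap.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray):
        self.n = len(time)
        ev_times = np.unique(time[event == 1])
        self.at_risk_rows = (time[:, None] >= ev_times[None, :]).astype(float)
        n_at_risk = self.at_risk_rows.sum(axis=0)
        d = np.array(
            [((time == t) & (event == 1)).sum() for t in ev_times], dtype=float
        )
        self.event = event.astype(float)
        self.exp_coef = d / n_at_risk
        with np.errstate(divide="ignore", invalid="ignore"):
            var_coef = d * (n_at_risk - d) / np.maximum(n_at_risk - 1.0, 1.0)
        self.var_coef = var_coef
        self.n_at_risk = n_at_risk

    def zstats(self, order: np.ndarray) -> np.ndarray:
        """Signed standardized statistic for every split k = 1..n-1, indexed
        by k-1 (low group = first k subjects of ``order``)."""
        n1 = np.cumsum(self.at_risk_rows[order], axis=0)[:-1]
        o1 = np.cumsum(self.event[order])[:-1]
        e1 = n1 @ self.exp_coef
        frac = n1 / self.n_at_risk
        v1 = (frac * (1.0 - frac)) @ self.var_coef
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (o1 - e1) / np.sqrt(v1)
        z[~np.isfinite(z)] = 0.0
        return z


@dataclass
class CutpointResult:
    """Outcome of the maximally-selected-rank-statistic cutpoint search."""

    cutpoint: float
    statistic: float  # max |standardized log-rank| over admissible splits
    p_adjusted: float
    p_unadjusted: float
    method: str
    candidate_range: tuple[float, float]
    n_low: int
    n_high: int


def _miller_siegmund(b: float, t1: float, t2: float) -> float:
    """Improved-Bonferroni tail bound for the maximum of the standardized
    two-sample process over the quantile interval (t1, t2)."""
    if b <= 0:
        return 1.0
    phi = stats.norm.pdf(b)
    p = 4.0 * phi / b + phi * (b - 1.0 / b) * np.log(
        (t2 * (1.0 - t1)) / ((1.0 - t2) * t1)
    )
    return float(min(1.0, p))


def maxstat_cutpoint(
    time,
    event,
    scores,
    eps: float = 0.1,
    method: str = "approximation",
    n_perm: int = 1000,
    seed: int | None = None,
) -> CutpointResult:
    """Optimal survival cutpoint by maximally selected rank statistics.

    Evaluates the standardized two-group log-rank statistic at every distinct
    score value whose split leaves at least ``eps`` of subjects on each side
    (low group: score <= mu), and returns the maximizing mu (smallest on
    ties).  ``method='approximation'`` adjusts the p-value with the
    Miller-Siegmund bound, clamped below by the unadjusted p of the selected
    split; ``method='permutation'`` re-runs the full maximization on
    ``n_perm`` score permutations under the given seed.
    """
    time, event = _as_surv_arrays(time, event)
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if len(time) != n:
        raise ValidationError("scores and survival data must have equal length")
    if n < 10:
        raise ValidationError("cutpoint search needs >= 10 subjects")
    if np.unique(scores).size < 2:
        raise ValidationError("all scores identical; no cutpoint exists")
    if event.sum() == 0:
        raise ValidationError("cutpoint search needs >= 1 event")
    if not (0.0 < eps < 0.5):
        raise ValidationError("eps must lie in (0, 0.5)")
    if method not in ("approximation", "permutation"):
        raise ValidationError(f"unknown method {method!r}")

    order = np.argsort(scores, kind="stable")
    sorted_scores = scores[order]
    k_min = int(np.ceil(eps * n - 1e-12))
    k_max = n - k_min
    ks = np.arange(1, n)  # split k: low = first k sorted subjects
    distinct = sorted_scores[:-1] < sorted_scores[1:]
    admissible = (ks >= k_min) & (ks <= k_max) & distinct
    if not admissible.any():
        raise ValidationError(f"no admissible cutpoint with eps={eps}")

    scan = _SplitScan(time, event)
    z = scan.zstats(order)
    abs_z = np.where(admissible, np.abs(z), -np.inf)
    best = int(np.argmax(abs_z))  # argmax takes the first (smallest mu) tie
    m_stat = float(abs_z[best])
    k_best = best + 1
    cutpoint = float(sorted_scores[best])

    p_unadj = float(stats.chi2.sf(m_stat**2, df=1))
    if method == "approximation":
        p_adj = max(_miller_siegmund(m_stat, eps, 1.0 - eps), p_unadj)
    else:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            # subject i receives score scores[perm[i]]; order subjects by it
            p_order = np.argsort(scores[perm], kind="stable")
            z_p = scan.zstats(p_order)
            m_p = np.max(np.where(admissible, np.abs(z_p), -np.inf))
            if m_p >= m_stat - 1e-12:
                exceed += 1
        p_adj = (1.0 + exceed) / (1.0 + n_perm)

    return CutpointResult(
        cutpoint=cutpoint,
        statistic=m_stat,
        p_adjusted=float(min(1.0, p_adj)),
        p_unadjusted=p_unadj,
        method=method,
        candidate_range=(eps, 1.0 - eps),
        n_low=k_best,
        n_high=n - k_best,
    )


def dichotomize(
    scores,
    method: str = "optimal",
    time=None,
    event=None,
    eps: float = 0.1,
    maxstat_method: str = "approximation",
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[pd.Series, float, CutpointResult | None]:
    """Split scores into 'low'/'high' groups at the median or optimal cutoff.

    Subjects with score <= cutpoint are 'low' (ties go low).  Returns the
    labels, the cutpoint, and the :class:`CutpointResult` when
    ``method='optimal'``.
    """
    index = scores.index if isinstance(scores, pd.Series) else None
    values = np.asarray(scores, dtype=float)
    if np.unique(values).size < 2:
        raise ValidationError("cannot dichotomize constant scores")
    result = None
    if method == "median":
        cut = float(np.median(values))
    elif method == "optimal":
        if time is None or event is None:
            raise ValidationError("optimal cutoff requires survival data")
        result = maxstat_cutpoint(
            time, event, values, eps=eps, method=maxstat_method,
            n_perm=n_perm, seed=seed,
        )
        cut = result.cutpoint
    else:
        raise ValidationError(f"unknown cutoff method {method!r}")
    low = values <= cut
    if low.all() or not low.any():
        raise ValidationError(f"cutpoint {cut:g} leaves one group empty")
    labels = pd.Series(np.where(low, "low", "high"), index=index, name="group")
    return labels, cut, result


def km_estimate(time, event, labels) -> pd.DataFrame:
    """Kaplan-Meier product-limit curves per group.

    Returns a long table (group, time, survival, at_risk) with one row per
    observed time per group, starting from S=1 at time 0.
    """
    time, event = _as_surv_arrays(time, event)
    labels = np.asarray(labels)
    frames = []
    for g in np.unique(labels):
        mask = labels == g
        if not mask.any():
            raise ValidationError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        surv = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(surv.index)
        frames.append(
            pd.DataFrame(
                {
                    "group": g,
                    "time": surv.index.to_numpy(dtype=float),
                    "survival": surv.to_numpy(dtype=float),
                    "at_risk": at_risk.to_numpy(dtype=float),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _cox_binary_nr(
    time: np.ndarray, event: np.ndarray, x: np.ndarray, ties: str,
    max_iter: int = 50, tol: float = 1e-10,
) -> tuple[float, float, int]:
    """Newton-Raphson on the univariate Cox partial likelihood for a binary
    covariate.  Returns (beta, se, n_iter)."""
    order = np.argsort(time, kind="stable")
    time, event, x = time[order], event[order], x[order]
    ev_times = np.unique(time[event == 1])

    beta = 0.0
    for it in range(1, max_iter + 1):
        w = np.exp(beta * x)
        score = 0.0
        info = 0.0
        for t in ev_times:
            risk = time >= t
            ev_here = (time == t) & (event == 1)
            d = int(ev_here.sum())
            s1_obs = float(x[ev_here].sum())
            s0 = float(w[risk].sum())
            s1 = float((w * x)[risk].sum())
            if ties == "breslow" or d == 1:
                score += s1_obs - d * s1 / s0
                info += d * (s1 / s0 - (s1 / s0) ** 2)
            else:  # efron
                s0e = float(w[ev_here].sum())
                s1e = float((w * x)[ev_here].sum())
                for ell in range(d):
                    f = ell / d
                    s0l = s0 - f * s0e
                    s1l = s1 - f * s1e
                    score += s1_obs / d - s1l / s0l
                    info += s1l / s0l - (s1l / s0l) ** 2
        if info <= 0:
            raise NumericalError("singular information in Cox fit")
        step = score / info
        beta_new = beta + step
        if abs(beta_new) > _BETA_CAP:
            warnings.warn(
                "monotone partial likelihood (complete separation); "
                f"coefficient capped at +/-{_BETA_CAP}", stacklevel=3
            )
            beta = float(np.sign(beta_new) * _BETA_CAP)
            break
        beta = beta_new
        if abs(step) < tol:
            break
    else:
        raise NumericalError(f"Cox fit did not converge in {max_iter} iterations")

    # recompute information at the solution for the standard error
    w = np.exp(beta * x)
    info = 0.0
    for t in ev_times:
        risk = time >= t
        ev_here = (time == t) & (event == 1)
        d = int(ev_here.sum())
        s0 = float(w[risk].sum())
        s1 = float((w * x)[risk].sum())
        if ties == "breslow" or d == 1:
            info += d * (s1 / s0 - (s1 / s0) ** 2)
        else:
            s0e = float(w[ev_here].sum())
            s1e = float((w * x)[ev_here].sum())
            for ell in range(d):
                f = ell / d
                s0l = s0 - f * s0e
                s1l = s1 - f * s1e
                info += s1l / s0l - (s1l / s0l) ** 2
    if info <= 0:
        raise NumericalError("singular information in Cox fit")
    return beta, float(1.0 / np.sqrt(info)), it


def cox_hr(
    time, event, labels, ties: str = "breslow"
) -> tuple[float, tuple[float, float], float]:
    """Univariate Cox hazard ratio of 'high' vs 'low'.

    Returns (HR, (ci_low, ci_high), wald_p) with HR = exp(beta) for the
    binary high-group indicator, 95% CI = exp(beta +/- 1.96 se), and the
    Wald p from beta/se against the standard normal.  Requires at least one
    event in each group.
    """
    time, event = _as_surv_arrays(time, event)
    labels = np.asarray(labels)
    uniq = set(np.unique(labels))
    if uniq != {"low", "high"}:
        raise ValidationError(f"labels must be 'low'/'high', got {sorted(uniq)}")
    if ties not in ("breslow", "efron"):
        raise ValidationError(f"unknown tie method {ties!r}")
    x = (labels == "high").astype(float)
    for g, mask in (("low", x == 0), ("high", x == 1)):
        if event[mask].sum() == 0:
            raise ValidationError(f"no events in the {g} group")
    beta, se, _ = _cox_binary_nr(time, event, x, ties)
    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
    wald_p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return hr, ci, wald_p


@dataclass
class SurvivalFit:
    """One stratified survival analysis: KM curves plus the Cox contrast."""

    km: pd.DataFrame
    hazard_ratio: float
    ci95: tuple[float, float]
    wald_p: float
    logrank_p: float
    cutoff_method: str
    cutpoint: float
    n_low: int
    n_high: int
    cutpoint_result: CutpointResult | None = None


def fit_survival(
    time,
    event,
    scores,
    cutoff_method: str = "optimal",
    eps: float = 0.1,
    maxstat_method: str = "approximation",
    n_perm: int = 1000,
    seed: int | None = None,
    ties: str = "breslow",
) -> SurvivalFit:
    """Dichotomize scores, then estimate KM curves, log-rank p and the Cox
    hazard ratio of high vs low."""
    labels, cut, cp = dichotomize(
        scores, cutoff_method, time=time, event=event, eps=eps,
        maxstat_method=maxstat_method, n_perm=n_perm, seed=seed,
    )
    lab = labels.to_numpy()
    hr, ci, wald_p = cox_hr(time, event, lab, ties=ties)
    _, lr_p = logrank(time, event, lab)
    return SurvivalFit(
        km=km_estimate(time, event, lab),
        hazard_ratio=hr,
        ci95=ci,
        wald_p=wald_p,
        logrank_p=lr_p,
        cutoff_method=cutoff_method,
        cutpoint=cut,
        n_low=int((lab == "low").sum()),
        n_high=int((lab == "high").sum()),
        cutpoint_result=cp,
    )
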