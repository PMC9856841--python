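"""Multi-cohort evaluation: forest tables of hazard ratios and race tests.

Each cohort is analyzed independently — map the signature, score, rescale
within the cohort, dichotomize by each requested cutoff method, and fit the
Cox contrast — with no cross-cohort pooling or renormalization.  The race
comparison is a two-sided Wilcoxon rank-sum test on scaled scores (a t-test
is available as an option), with per-group medians and IQRs for box plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .errors import ValidationError
from .signature import GeneSignature, module_score, rescale_scores
from .survival import fit_survival

__all__ = [
    "CohortResult",
    "RaceComparison",
    "evaluate_signature_on_cohort",
    "forest_table",
    "race_difference",
]

MIN_OVERLAP = 20

FOREST_COLUMNS = [
    "dataset", "variant", "cutoff_method", "hr", "ci_low", "ci_high",
    "wald_p", "logrank_p", "cutpoint", "n", "n_events",
]


@dataclass
class CohortResult:
    """One (cohort, signature variant, cutoff method) hazard-ratio row."""

    dataset: str
    variant: str
    cutoff_method: str
    hr: float
    ci95: tuple[float, float]
    wald_p: float
    logrank_p: float
    cutpoint: float
    n: int
    n_events: int

    def __post_init__(self) -> None:
        if self.n_events > self.n:
            raise ValidationError("n_events cannot exceed n")
        if self.hr <= 0:
            raise ValidationError("hazard ratio must be positive")


@dataclass
class RaceComparison:
    """Score comparison between two race groups."""

    variant: str
    groups: tuple[str, str]
    n: tuple[int, int]
    median: tuple[float, float]
    iqr: tuple[float, float]
    statistic: float
    p_value: float
    test: str


def evaluate_signature_on_cohort(
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    signatures: GeneSignature | dict[str, GeneSignature],
    cutoff_methods: tuple[str, ...] = ("optimal", "median"),
    dataset: str | None = None,
    eps: float = 0.1,
    maxstat_method: str = "approximation",
    n_perm: int = 1000,
    seed: int | None = None,
) -> list[CohortResult]:
    """Score a cohort with one or more signatures and fit survival per
    cutoff method.

    ``clinical`` needs columns sample, time, event (optional dataset).
    Samples are intersected with the matrix columns; fewer than 20 in common
    is an error.  Returns one :class:`CohortResult` per (variant, method).
    """
    for col in ("sample", "time", "event"):
        if col not in clinical.columns:
            raise ValidationError(f"clinical table lacks column {col!r}")
    if isinstance(signatures, GeneSignature):
        signatures = {signatures.variant: signatures}
    common = clinical["sample"][clinical["sample"].isin(expr.samples)]
    if len(common) < MIN_OVERLAP:
        raise ValidationError(
            f"only {len(common)} samples shared between expression and "
            f"clinical tables (need >= {MIN_OVERLAP})"
        )
    clin = clinical.set_index("sample").loc[common]
    sub = expr.subset_samples(common)
    if dataset is None:
        dataset = (
            str(clin["dataset"].iloc[0]) if "dataset" in clin.columns else "cohort"
        )

    results = []
    for variant, sig in signatures.items():
        scores = rescale_scores(module_score(sub, sig))
        for method in cutoff_methods:
            fit = fit_survival(
                clin["time"].to_numpy(),
                clin["event"].to_numpy(),
                scores.scaled,
                cutoff_method=method,
                eps=eps,
                maxstat_method=maxstat_method,
                n_perm=n_perm,
                seed=seed,
            )
            results.append(
                CohortResult(
                    dataset=dataset,
                    variant=variant,
                    cutoff_method=method,
                    hr=fit.hazard_ratio,
                    ci95=fit.ci95,
                    wald_p=fit.wald_p,
                    logrank_p=fit.logrank_p,
                    cutpoint=fit.cutpoint,
                    n=len(clin),
                    n_events=int(clin["event"].sum()),
                )
            )
    return results


def forest_table(results: list[CohortResult]) -> pd.DataFrame:
    """Assemble per-cohort results into a forest-plot table.

    One row per (dataset, variant, cutoff method), ordered by dataset then
    variant then method; no aggregation across cohorts.
    """
    if not results:
        raise ValidationError("no cohort results to tabulate")
    rows = [
        {
            "dataset": r.dataset,
            "variant": r.variant,
            "cutoff_method": r.cutoff_method,
            "hr": r.hr,
            "ci_low": r.ci95[0],
            "ci_high": r.ci95[1],
            "wald_p": r.wald_p,
            "logrank_p": r.logrank_p,
            "cutpoint": r.cutpoint,
            "n": r.n,
            "n_events": r.n_events,
        }
        for r in results
    ]
    return (
        pd.DataFrame(rows, columns=FOREST_COLUMNS)
        .sort_values(["dataset", "variant", "cutoff_method"], kind="stable")
        .reset_index(drop=True)
    )


def race_difference(
    scores, race_labels, variant: str = "Sig", test: str = "wilcoxon"
) -> RaceComparison:
    """Two-sided test of score difference between exactly two race groups.

    Default is the Wilcoxon rank-sum (Mann-Whitney U) test on scaled scores;
    ``test='ttest'`` switches to Welch's t-test.  Each group needs n >= 2.
    """
    scores = np.asarray(scores, dtype=float)
    race = np.asarray(race_labels)
    if len(scores) != len(race):
        raise ValidationError("scores and race labels must have equal length")
    groups = sorted(np.unique(race).tolist())
    if len(groups) != 2:
        raise ValidationError(f"need exactly two race groups, got {groups}")
    g1 = scores[race == groups[0]]
    g2 = scores[race == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError("each race group needs n >= 2")
    if test == "wilcoxon":
        stat, p = stats.mannwhitneyu(g1, g2, alternative="two-sided")
    elif test == "ttest":
        stat, p = stats.ttest_ind(g1, g2, equal_var=False)
    else:
        raise ValidationError(f"unknown test {test!r}")
    iqr = lambda v: float(np.quantile(v, 0.75) - np.quantile(v, 0.25))  # noqa: E731
    return RaceComparison(
        variant=variant,
        groups=(groups[0], groups[1]),
        n=(len(g1), len(g2)),
        median=(float(np.median(g1)), float(np.median(g2))),
        iqr=(iqr(g1), iqr(g2)),
        statistic=float(stat),
        p_value=float(p),
        test=test,
    )
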