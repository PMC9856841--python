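"""Per-gene two-group testing, fold changes, the signature filter and PCA QC.

Testing is a two-sided Student t-test with pooled variance per gene (Welch is
available as a switch).  Fold change is computed from the difference of
group means on the log2 scale, ``fc_linear = 2**log2fc``, treated
symmetrically in the filter: a gene passes at threshold f when its linear
fold change is >= f or <= 1/f.  The signature filter keeps genes with
(p < 0.05 and fold change beyond 2) or fold change beyond 4 regardless of p.
No multiple-testing correction enters the filter; a Benjamini-Hochberg
q-value column is emitted for reference only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .containers import ExpressionMatrix
from .errors import ValidationError

__all__ = [
    "ttest_per_gene",
    "filter_signature_genes",
    "volcano_table",
    "pca_qc",
    "PcaResult",
]


def ttest_per_gene(
    matrix: ExpressionMatrix,
    groups: pd.Series | dict,
    treatment: str | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sided t-test of every gene between the two arms.

    Parameters
    ----------
    groups
        Mapping sample -> arm label; exactly two labels, each with >= 2
        samples.
    treatment
        The arm treated as group B (log2fc = mean_b - mean_a). Defaults to
        the lexicographically larger label (e.g. ``LV`` over ``EV``).
    equal_var
        Pooled-variance Student test when True (default), Welch otherwise.

    Returns a DE table with one row per gene: symbol, entrez, mean_a,
    mean_b, log2fc, fc_linear, p_value, q_value (BH, reference only),
    direction. Genes constant in both groups get p = 1 with a warning.
    """
    groups = pd.Series(groups)
    groups = groups.loc[groups.index.intersection(matrix.samples)]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValidationError(f"need exactly two groups, got {labels}")
    if treatment is None:
        treatment = labels[1]
    if treatment not in labels:
        raise ValidationError(f"treatment {treatment!r} not among groups {labels}")
    control = labels[0] if labels[1] == treatment else labels[1]
    a_samples = groups.index[groups == control]
    b_samples = groups.index[groups == treatment]
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValidationError(
            f"each group needs >= 2 samples "
            f"(got {len(a_samples)} vs {len(b_samples)})"
        )

    xa = matrix.values.loc[:, a_samples].to_numpy()
    xb = matrix.values.loc[:, b_samples].to_numpy()
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p = stats.ttest_ind(xb, xa, axis=1, equal_var=equal_var)
    p = np.asarray(p)

    # a gene flat in both groups has an undefined statistic; call it null
    flat = (xa.std(axis=1) == 0) & (xb.std(axis=1) == 0) & (mean_a == mean_b)
    degenerate = ~np.isfinite(p)
    if (flat | degenerate).any():
        warnings.warn(
            f"{int((flat | degenerate).sum())} constant gene(s): p set to 1",
            stacklevel=2,
        )
        p = np.where(flat | degenerate, 1.0, p)

    log2fc = mean_b - mean_a
    q = stats.false_discovery_control(np.clip(p, 0.0, 1.0))
    de = pd.DataFrame(
        {
            "symbol": matrix.genes,
            "entrez": (
                matrix.entrez.reindex(matrix.genes).to_numpy()
                if matrix.entrez is not None
                else pd.NA
            ),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "fc_linear": 2.0 ** log2fc,
            "p_value": p,
            "q_value": q,
            "direction": np.where(log2fc > 0, "up", "down"),
        }
    ).reset_index(drop=True)
    return de


def _filter_mask(
    de: pd.DataFrame, p_thresh: float, fc_thresh: float, rescue_fc: float
) -> np.ndarray:
    fc = de["fc_linear"].to_numpy()
    p = de["p_value"].to_numpy()
    beyond = lambda f: (fc >= f) | (fc <= 1.0 / f)  # noqa: E731
    return ((p < p_thresh) & beyond(fc_thresh)) | beyond(rescue_fc)


def filter_signature_genes(
    de: pd.DataFrame,
    p_thresh: float = 0.05,
    fc_thresh: float = 2.0,
    rescue_fc: float = 4.0,
) -> pd.DataFrame:
    """Shortlist signature genes from a DE table.

    A gene is kept when (p < p_thresh and fold change beyond fc_thresh in
    either direction) or its fold change is beyond rescue_fc in either
    direction regardless of p.
    """
    if de is None or len(de) == 0:
        raise ValidationError("DE table is empty")
    if min(p_thresh, fc_thresh, rescue_fc) <= 0:
        raise ValidationError("thresholds must be positive")
    return de.loc[_filter_mask(de, p_thresh, fc_thresh, rescue_fc)].reset_index(
        drop=True
    )


def volcano_table(
    de: pd.DataFrame,
    p_thresh: float = 0.05,
    fc_thresh: float = 2.0,
    rescue_fc: float = 4.0,
    neg_log10_cap: float = 300.0,
) -> pd.DataFrame:
    """Volcano-plot coordinates: log2fc vs -log10 p with a significance flag.

    The flag reproduces :func:`filter_signature_genes` membership exactly;
    -log10 p is capped at ``neg_log10_cap`` for p = 0.
    """
    p = de["p_value"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        neg_log10 = np.minimum(-np.log10(p), neg_log10_cap)
    return pd.DataFrame(
        {
            "symbol": de["symbol"],
            "log2fc": de["log2fc"],
            "neg_log10_p": neg_log10,
            "significant": _filter_mask(de, p_thresh, fc_thresh, rescue_fc),
        }
    )


class PcaResult:
    """Sample coordinates and variance fractions of a PCA on samples."""

    def __init__(self, coordinates: pd.DataFrame, variance_fraction: np.ndarray):
        self.coordinates = coordinates
        self.variance_fraction = np.asarray(variance_fraction, dtype=float)


def pca_qc(matrix: ExpressionMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of samples on gene-centered expression, for quality control.

    Components are ordered by variance explained; the coordinate frame
    carries columns ``PC1..PCk``.
    """
    if matrix.n_samples < 3:
        raise ValidationError("PCA QC needs at least 3 samples")
    x = matrix.values.to_numpy().T  # samples x genes; PCA centers columns
    k = min(matrix.n_samples - 1, matrix.n_genes)
    if n_components is not None:
        k = min(k, n_components)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        pd.DataFrame(coords, index=matrix.samples, columns=cols),
        pca.explained_variance_ratio_,
    )
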