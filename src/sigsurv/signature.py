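"""Signed-weight gene signatures and quantile-rescaled module scores.

A signature is a list of genes with weights W_i in {+1, -1}. The per-sample
module score is the weighted average

    s = sum_i W_i * X_i / sum_i |W_i|

over the signature genes present in the matrix, where X_i is log2 expression.
Raw scores are then rescaled affinely so that the cohort's empirical 2.5% and
97.5% quantiles map to -1 and +1; values beyond the anchors are retained
unclipped.  Four variants are built from a filtered differential-expression
table: ``Sig`` (all genes, weight = sign of log2 fold change), ``NoDir``
(all genes, weight +1), ``Up`` (upregulated genes, +1) and ``Dn``
(downregulated genes, +1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .errors import ValidationError

__all__ = [
    "VARIANTS",
    "GeneSignature",
    "ScoreVector",
    "MappingReport",
    "build_signatures",
    "map_genes",
    "module_score",
    "rescale_scores",
]

VARIANTS = ("Sig", "NoDir", "Up", "Dn")

#: default quantile anchors for rescaling
DEFAULT_ANCHORS = (0.025, 0.975)


@dataclass
class GeneSignature:
    """A gene list with signed unit weights.

    ``members`` columns: symbol, entrez (nullable), weight (+1/-1), log2fc
    (the source log2 fold change; NaN when unknown).
    """

    variant: str
    members: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"symbol", "weight"}
        if not req.issubset(self.members.columns):
            raise ValidationError(f"signature members need columns {sorted(req)}")
        m = self.members
        if "entrez" not in m.columns:
            m = m.assign(entrez=pd.NA)
        if "log2fc" not in m.columns:
            m = m.assign(log2fc=np.nan)
        self.members = m.reset_index(drop=True)
        if len(self.members) == 0:
            raise ValidationError(f"signature {self.variant!r} has no members")
        w = self.members["weight"].to_numpy()
        if not np.isin(w, [-1, 1]).all():
            raise ValidationError("signature weights must be +1 or -1")
        if self.members["symbol"].duplicated().any():
            d = self.members.loc[self.members["symbol"].duplicated(), "symbol"]
            raise ValidationError(f"duplicate signature genes: {d.tolist()}")
        if self.variant in ("NoDir", "Up", "Dn") and (w != 1).any():
            raise ValidationError(f"variant {self.variant} requires all +1 weights")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def symbols(self) -> pd.Series:
        return self.members["symbol"]

    def with_weights(self, weights) -> "GeneSignature":
        """Return a copy with replaced weights (variant forced to 'Sig')."""
        m = self.members.assign(weight=np.asarray(weights, dtype=int))
        return GeneSignature("Sig", m)


@dataclass
class MappingReport:
    n_matched: int
    n_missing: int
    matched_by_entrez: int
    matched_by_symbol: int

    @property
    def coverage(self) -> float:
        total = self.n_matched + self.n_missing
        return self.n_matched / total if total else 0.0


@dataclass
class ScoreVector:
    """Per-sample module scores, raw and (after rescaling) scaled."""

    raw: pd.Series
    scaled: pd.Series | None = None
    q_low: float | None = None
    q_high: float | None = None
    n_genes_used: int = 0
    n_genes_missing: int = 0
    anchors: tuple[float, float] = DEFAULT_ANCHORS


def build_signatures(filtered: pd.DataFrame) -> dict[str, GeneSignature]:
    """Build the four signature variants from a filtered DE table.

    ``filtered`` must carry columns symbol, log2fc, direction (and optionally
    entrez). Variants with no members (e.g. ``Dn`` when every gene is up) are
    omitted with a warning rather than constructed empty.
    """
    if filtered is None or len(filtered) == 0:
        raise ValidationError("cannot build signatures from an empty table")
    for col in ("symbol", "log2fc", "direction"):
        if col not in filtered.columns:
            raise ValidationError(f"filtered DE table lacks column {col!r}")
    base = filtered.loc[:, ["symbol", "log2fc"]].copy()
    base["entrez"] = filtered["entrez"] if "entrez" in filtered.columns else pd.NA
    up_mask = (filtered["direction"] == "up").to_numpy()

    out: dict[str, GeneSignature] = {}
    sig_w = np.where(up_mask, 1, -1)
    out["Sig"] = GeneSignature("Sig", base.assign(weight=sig_w))
    out["NoDir"] = GeneSignature("NoDir", base.assign(weight=1))
    for name, mask in (("Up", up_mask), ("Dn", ~up_mask)):
        if mask.any():
            out[name] = GeneSignature(name, base.loc[mask].assign(weight=1))
        else:
            warnings.warn(f"no {'up' if name == 'Up' else 'down'}-regulated genes; "
                          f"variant {name} omitted", stacklevel=2)
    return out


def map_genes(
    sig: GeneSignature, matrix: ExpressionMatrix
) -> tuple[GeneSignature, MappingReport]:
    """Match signature members to matrix genes, by Entrez ID then symbol.

    A member matches by Entrez when both the member and some matrix gene
    carry the same Entrez ID; otherwise by symbol.  Unmatched members are
    dropped and counted; a warning is raised when coverage falls below 50%,
    and an error when nothing matches.  The returned signature's symbols are
    matrix row names.
    """
    entrez_to_gene: dict = {}
    if matrix.entrez is not None:
        for symbol, eid in matrix.entrez.dropna().items():
            entrez_to_gene.setdefault(int(eid), symbol)
    gene_set = set(matrix.genes)

    rows, by_entrez, by_symbol = [], 0, 0
    for rec in sig.members.itertuples(index=False):
        target = None
        if pd.notna(rec.entrez) and int(rec.entrez) in entrez_to_gene:
            target = entrez_to_gene[int(rec.entrez)]
            by_entrez += 1
        elif rec.symbol in gene_set:
            target = rec.symbol
            by_symbol += 1
        if target is not None:
            rows.append((target, rec.entrez, rec.weight, rec.log2fc))
    n_missing = len(sig) - len(rows)
    report = MappingReport(len(rows), n_missing, by_entrez, by_symbol)
    if not rows:
        raise ValidationError(
            f"no signature genes of {sig.variant!r} found in the matrix"
        )
    if report.coverage < 0.5:
        warnings.warn(
            f"signature {sig.variant!r}: only {report.n_matched}/{len(sig)} "
            f"genes mapped ({report.coverage:.0%})", stacklevel=2
        )
    members = pd.DataFrame(rows, columns=["symbol", "entrez", "weight", "log2fc"])
    # the same matrix gene can be hit once via entrez and once via symbol
    members = members.drop_duplicates(subset="symbol")
    mapped = GeneSignature(sig.variant, members)
    return mapped, report


def module_score(matrix: ExpressionMatrix, sig: GeneSignature) -> ScoreVector:
    """Raw module score per sample: sum(W_i X_i) / sum(|W_i|)."""
    mapped, report = map_genes(sig, matrix)
    expr = matrix.values.loc[mapped.members["symbol"]].to_numpy()
    w = mapped.members["weight"].to_numpy(dtype=float)
    raw = (w @ expr) / np.abs(w).sum()
    return ScoreVector(
        raw=pd.Series(raw, index=matrix.samples, name="raw_score"),
        n_genes_used=report.n_matched,
        n_genes_missing=report.n_missing,
    )


def rescale_scores(
    scores: ScoreVector, anchors: tuple[float, float] = DEFAULT_ANCHORS
) -> ScoreVector:
    """Affinely rescale raw scores so the anchor quantiles map to -1/+1.

    Quantiles use linear interpolation (numpy default, Hyndman–Fan type 7).
    Scores outside [-1, 1] are kept as-is.  Near-constant raw scores (equal
    anchor quantiles) are an error.
    """
    lo_f, hi_f = anchors
    if not (0.0 < lo_f < hi_f < 1.0):
        raise ValidationError(f"anchors must satisfy 0 < low < high < 1, got {anchors}")
    raw = scores.raw.to_numpy(dtype=float)
    if np.unique(raw).size < 2:
        raise ValidationError("cannot rescale a constant score vector")
    q_low, q_high = np.quantile(raw, [lo_f, hi_f])
    if q_high <= q_low:
        raise ValidationError(
            f"degenerate quantile anchors (q_low={q_low:g} >= q_high={q_high:g})"
        )
    scaled = 2.0 * (raw - q_low) / (q_high - q_low) - 1.0
    return replace(
        scores,
        scaled=pd.Series(scaled, index=scores.raw.index, name="scaled_score"),
        q_low=float(q_low),
        q_high=float(q_high),
        anchors=anchors,
    )
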