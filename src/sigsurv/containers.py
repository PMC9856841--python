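"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2-scale expression values.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol, one column per sample, values on
        the log2 scale (already normalized; no count normalization happens
        here).
    entrez
        Optional Series mapping gene symbol -> Entrez Gene ID for the subset
        of genes that have one.

    Duplicate gene rows are collapsed by mean on construction (with a
    warning), so every downstream consumer sees a unique gene index.
    """

    values: pd.DataFrame
    entrez: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise ValidationError("expression values must be a pandas DataFrame")
        if self.values.shape[0] < 1 or self.values.shape[1] < 2:
            raise ValidationError(
                f"expression matrix needs >=1 gene and >=2 samples, "
                f"got shape {self.values.shape}"
            )
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample IDs: {dupes}")
        if self.values.index.duplicated().any():
            n_dup = int(self.values.index.duplicated().sum())
            warnings.warn(
                f"collapsed {n_dup} duplicate gene row(s) by mean", stacklevel=3
            )
            self.values = self.values.groupby(level=0, sort=False).mean()
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite expression value at gene "
                f"{self.values.index[bad[0]]!r}, sample "
                f"{self.values.columns[bad[1]]!r}"
            )
        if self.entrez is not None:
            self.entrez = self.entrez[self.entrez.index.isin(self.values.index)]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[1])

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(samples)], self.entrez)
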