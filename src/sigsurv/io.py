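"""Readers and writers for the package's tabular interchange formats.

Everything is plain TSV/CSV.  Writers emit a comment header (package
version, config hash, seeds) that readers skip; column order is fixed so
files are byte-reproducible for a fixed configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ExpressionMatrix
from .errors import ValidationError
from .signature import GeneSignature, ScoreVector

__all__ = [
    "RunConfig",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_signatures",
    "write_signatures",
    "read_scores",
    "write_scores",
    "config_hash",
]


@dataclasses.dataclass
class RunConfig:
    """Pipeline-wide settings, mergeable from YAML and CLI flags."""

    p_thresh: float = 0.05
    fc_thresh: float = 2.0
    rescue_fc: float = 4.0
    anchor_low: float = 0.025
    anchor_high: float = 0.975
    eps: float = 0.1
    maxstat_method: str = "approximation"
    n_perm: int = 1000
    cutoff_methods: tuple[str, ...] = ("optimal", "median")
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if not (0.0 < self.anchor_low < self.anchor_high < 1.0):
            raise ValidationError("quantile anchors must satisfy 0 < low < high < 1")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        merged = {k: v for k, v in raw.items() if k in known}
        merged.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**merged)


def config_hash(config) -> str:
    """Short stable hash of a configuration object or mapping."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(config=None, seed=None) -> str:
    parts = [f"# sigsurv v{__version__}"]
    if config is not None:
        parts.append(f"# config_hash={config_hash(config)}")
    if seed is not None:
        parts.append(f"# seed={seed}")
    return "\n".join(parts) + "\n"


def _write_table(df: pd.DataFrame, path, config=None, seed=None, sep="\t",
                 index=False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(config, seed))
        df.to_csv(fh, sep=sep, index=index)


def read_expression(path) -> ExpressionMatrix:
    """Read a gene x sample TSV: first column gene symbol, optional second
    column ``entrez``, remaining columns samples (log2 values)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected symbol + sample columns")
    if df.columns.duplicated().any():
        raise ValidationError(f"{path}: duplicate sample IDs in header")
    sym_col = df.columns[0]
    df = df.set_index(sym_col)
    entrez = None
    if len(df.columns) and str(df.columns[0]).lower() == "entrez":
        entrez = pd.to_numeric(df.iloc[:, 0], errors="coerce").dropna().astype(int)
        df = df.iloc[:, 1:]
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric value at gene {df.index[gi]!r}, "
            f"sample {df.columns[si]!r}"
        )
    if numeric.isna().to_numpy().any():
        gi, si = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: missing value at gene {df.index[gi]!r}, "
            f"sample {df.columns[si]!r}"
        )
    return ExpressionMatrix(numeric, entrez)


def write_expression(matrix: ExpressionMatrix, path, config=None, seed=None) -> None:
    df = matrix.values.copy()
    if matrix.entrez is not None:
        df.insert(0, "entrez", matrix.entrez.reindex(df.index).astype("Int64"))
    df.index.name = "symbol"
    _write_table(df, path, config, seed, index=True)


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV (sample, time, event, optional race/dataset/...).

    Validates positive times, binary events and unique sample IDs; unknown
    columns are preserved as annotations.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValidationError(f"{path}: duplicate sample ID {dup!r}")
    bad_t = ~(pd.to_numeric(df["time"], errors="coerce") > 0)
    if bad_t.any():
        row = int(np.argwhere(bad_t.to_numpy())[0][0])
        raise ValidationError(
            f"{path}: non-positive or invalid time in row {row + 1} "
            f"(sample {df['sample'].iloc[row]!r})"
        )
    if not df["event"].isin([0, 1]).all():
        row = int(np.argwhere(~df["event"].isin([0, 1]).to_numpy())[0][0])
        raise ValidationError(
            f"{path}: event must be 0 or 1 in row {row + 1} "
            f"(sample {df['sample'].iloc[row]!r})"
        )
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    return df


def write_clinical(df: pd.DataFrame, path, config=None, seed=None) -> None:
    _write_table(df, path, config, seed)


def write_signatures(
    signatures: GeneSignature | dict[str, GeneSignature], path,
    config=None, seed=None,
) -> None:
    """Write one or more signatures to CSV (variant, symbol, entrez, weight,
    log2fc)."""
    if isinstance(signatures, GeneSignature):
        signatures = {signatures.variant: signatures}
    frames = [
        sig.members.assign(variant=name)[
            ["variant", "symbol", "entrez", "weight", "log2fc"]
        ]
        for name, sig in signatures.items()
    ]
    _write_table(pd.concat(frames, ignore_index=True), path, config, seed, sep=",")


def read_signatures(path) -> dict[str, GeneSignature]:
    df = pd.read_csv(path, comment="#")
    for col in ("variant", "symbol", "weight"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    out = {}
    for variant, grp in df.groupby("variant", sort=False):
        out[str(variant)] = GeneSignature(
            str(variant), grp.drop(columns="variant").reset_index(drop=True)
        )
    if not out:
        raise ValidationError(f"{path}: no signatures found")
    return out


def write_scores(scores: ScoreVector, path, config=None, seed=None) -> None:
    df = pd.DataFrame({"sample": scores.raw.index, "raw_score": scores.raw.values})
    if scores.scaled is not None:
        df["scaled_score"] = scores.scaled.values
    _write_table(df, path, config, seed)


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("sample", "raw_score"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return df
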