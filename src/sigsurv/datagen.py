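"""Synthetic data generators and small assay formulas.

Two generators back the test surface of the pipeline:

* :func:`simulate_xenograft` emulates a small two-arm (control vs
  overexpression) bulk RNA-seq experiment, three samples per arm by default,
  with a planted fraction of up/down-regulated genes. Values are drawn
  directly on the log2 scale with Gaussian per-gene noise, the scale the
  downstream t-test / fold-change machinery operates on.
* :func:`simulate_cohort` emulates a human cohort in which a latent
  per-patient factor drives both the signature-gene expression and survival:
  event times are exponential with rate ``baseline_hazard *
  exp(beta * scaled_score)`` under independent exponential censoring, and an
  optional race label shifts the score distribution of one group.

Two bench formulas used alongside the simulations are also housed here:
caliper tumor volume ``(W^2 * L) / 2`` with W the smaller diameter, and
relative qPCR quantification by ``2^(-ddCt)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .errors import ConfigurationError, ValidationError
from .signature import GeneSignature, module_score, rescale_scores

__all__ = [
    "XenoSimConfig",
    "CohortSimConfig",
    "QpcrRecord",
    "simulate_xenograft",
    "simulate_cohort",
    "tumor_volume",
    "ddct_fold",
]


@dataclass
class XenoSimConfig:
    """Configuration for the two-arm expression simulation.

    ``frac_de`` of the genes receive a mean shift in the treatment arm;
    ``frac_up_of_de`` of those are shifted up, the rest down. Planted
    |log2FC| magnitudes are gamma-distributed with mean ``log2fc_effect``.
    """

    n_genes: int = 10_000
    n_per_arm: int = 3
    frac_de: float = 0.1
    frac_up_of_de: float = 0.42
    log2fc_effect: float = 2.0
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ConfigurationError("n_per_arm must be >= 2")
        if not (0.0 <= self.frac_de <= 1.0 and 0.0 <= self.frac_up_of_de <= 1.0):
            raise ConfigurationError("fractions must lie in [0, 1]")
        if self.noise_sd <= 0 or self.log2fc_effect <= 0:
            raise ConfigurationError("noise_sd and log2fc_effect must be positive")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")


@dataclass
class CohortSimConfig:
    """Configuration for the survival-cohort simulation.

    ``beta`` is the log hazard ratio per unit of the scaled true module
    score; ``censor_rate`` is the rate of the independent exponential
    censoring clock (0 disables censoring). ``race_score_shift`` moves the
    module score of ``shifted_race`` by that amount, applied to each
    signature gene along its weight direction.
    """

    n_patients: int = 300
    signature_truth: GeneSignature | None = None
    beta: float = 0.0
    baseline_hazard: float = 0.1
    censor_rate: float = 0.05
    race_fractions: dict = field(default_factory=lambda: {"white": 0.7, "black": 0.3})
    race_score_shift: float = 0.0
    shifted_race: str | None = None
    expr_noise_sd: float = 0.5
    n_background_genes: int = 60
    baseline_mean: float = 8.0
    dataset_label: str = "SimCohort"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 20:
            raise ConfigurationError("n_patients must be >= 20")
        if self.signature_truth is None or len(self.signature_truth) == 0:
            raise ConfigurationError("signature_truth must be a non-empty signature")
        if self.censor_rate < 0 or self.baseline_hazard <= 0:
            raise ConfigurationError(
                "censor_rate must be >= 0 and baseline_hazard > 0"
            )
        if self.expr_noise_sd <= 0:
            raise ConfigurationError("expr_noise_sd must be positive")
        total = sum(self.race_fractions.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ConfigurationError(f"race fractions must sum to 1, got {total}")
        if self.shifted_race is None:
            self.shifted_race = list(self.race_fractions)[-1]
        if self.shifted_race not in self.race_fractions:
            raise ConfigurationError(
                f"shifted_race {self.shifted_race!r} not in race_fractions"
            )


def simulate_xenograft(
    config: XenoSimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a two-arm expression matrix with planted effects.

    Returns the matrix (arms labeled ``EV``/``LV``, the latter carrying the
    planted shifts) and a truth table with columns symbol, entrez, is_de,
    direction, true_log2fc. Exactly ``round(n_genes * frac_de)`` genes are
    flagged. Deterministic for a fixed seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    symbols = [f"GENE{i:05d}" for i in range(cfg.n_genes)]
    entrez = pd.Series(np.arange(cfg.n_genes) + 1000, index=symbols, name="entrez")

    n_de = round(cfg.n_genes * cfg.frac_de)
    n_up = round(n_de * cfg.frac_up_of_de)
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
    up_idx = de_idx[:n_up]

    true_log2fc = np.zeros(cfg.n_genes)
    if n_de:
        magnitudes = rng.gamma(shape=4.0, scale=cfg.log2fc_effect / 4.0, size=n_de)
        signs = np.full(n_de, -1.0)
        signs[:n_up] = 1.0
        true_log2fc[de_idx] = signs * magnitudes

    baselines = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    n = cfg.n_per_arm
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, 2 * n))
    expr = baselines[:, None] + noise
    expr[:, n:] += true_log2fc[:, None]  # treatment arm carries the shift

    samples = [f"EV_{i + 1}" for i in range(n)] + [f"LV_{i + 1}" for i in range(n)]
    matrix = ExpressionMatrix(
        pd.DataFrame(expr, index=symbols, columns=samples), entrez
    )
    is_de = np.zeros(cfg.n_genes, dtype=bool)
    is_de[de_idx] = True
    truth = pd.DataFrame(
        {
            "symbol": symbols,
            "entrez": entrez.to_numpy(),
            "is_de": is_de,
            "direction": np.where(true_log2fc > 0, "up", "down"),
            "true_log2fc": true_log2fc,
        }
    )
    truth.loc[~truth["is_de"], "direction"] = "none"
    return matrix, truth


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a cohort whose survival depends on its true module score.

    A standard-normal latent factor u_i moves every signature gene along its
    weight direction, so the true raw score tracks u_i.  The true score is
    quantile-rescaled within the cohort and sets the exponential event rate
    ``baseline_hazard * exp(beta * scaled)``.  Censoring is an independent
    exponential clock.  Returns the matrix and a clinical table with columns
    sample, time, event, race, dataset.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sig = cfg.signature_truth
    n = cfg.n_patients
    samples = [f"P{i + 1:04d}" for i in range(n)]

    u = rng.normal(0.0, 1.0, size=n)
    races = rng.choice(
        list(cfg.race_fractions), size=n, p=list(cfg.race_fractions.values())
    )
    shifted = races == cfg.shifted_race

    sig_syms = sig.members["symbol"].tolist()
    w = sig.members["weight"].to_numpy(dtype=float)
    mu = rng.normal(cfg.baseline_mean, 1.0, size=len(sig_syms))
    expr_sig = (
        mu[:, None]
        + w[:, None] * u[None, :]
        + rng.normal(0.0, cfg.expr_noise_sd, size=(len(sig_syms), n))
    )
    # race effect: shift each signature gene along its weight direction so
    # the module score of the shifted group moves by exactly race_score_shift
    if cfg.race_score_shift:
        expr_sig += cfg.race_score_shift * w[:, None] * shifted[None, :]

    bg_syms = [f"BG{i:04d}" for i in range(cfg.n_background_genes)]
    bg_mu = rng.normal(cfg.baseline_mean, 1.0, size=cfg.n_background_genes)
    expr_bg = bg_mu[:, None] + rng.normal(
        0.0, cfg.expr_noise_sd, size=(cfg.n_background_genes, n)
    )

    values = pd.DataFrame(
        np.vstack([expr_sig, expr_bg]), index=sig_syms + bg_syms, columns=samples
    )
    entrez_vals = {}
    for rec in sig.members.itertuples(index=False):
        if pd.notna(rec.entrez):
            entrez_vals[rec.symbol] = int(rec.entrez)
    entrez = pd.Series(entrez_vals, name="entrez") if entrez_vals else None
    matrix = ExpressionMatrix(values, entrez)

    truth_scores = rescale_scores(module_score(matrix, sig))
    z = truth_scores.scaled.to_numpy()
    rate = cfg.baseline_hazard * np.exp(cfg.beta * z)
    t_event = rng.exponential(1.0 / rate)
    if cfg.censor_rate > 0:
        t_censor = rng.exponential(1.0 / cfg.censor_rate, size=n)
    else:
        t_censor = np.full(n, np.inf)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    clinical = pd.DataFrame(
        {
            "sample": samples,
            "time": time,
            "event": event,
            "race": races,
            "dataset": cfg.dataset_label,
        }
    )
    return matrix, clinical


def tumor_volume(width_mm: float, length_mm: float) -> float:
    """Caliper tumor volume in mm^3: (W^2 * L) / 2, W the smaller diameter.

    The two diameters are swapped if given in the wrong order, so the result
    is orientation-invariant.
    """
    if not (np.isfinite(width_mm) and np.isfinite(length_mm)):
        raise ValidationError("tumor dimensions must be finite")
    if width_mm <= 0 or length_mm <= 0:
        raise ValidationError(
            f"tumor dimensions must be positive, got ({width_mm}, {length_mm})"
        )
    w, length = min(width_mm, length_mm), max(width_mm, length_mm)
    return (w * w * length) / 2.0


def ddct_fold(
    cq_target_test: float,
    cq_ref_test: float,
    cq_target_ctrl: float,
    cq_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^(-ddCt) method.

    ddCt = (Cq_target - Cq_ref)_test - (Cq_target - Cq_ref)_control.
    """
    cqs = (cq_target_test, cq_ref_test, cq_target_ctrl, cq_ref_ctrl)
    if not all(np.isfinite(c) for c in cqs):
        raise ValidationError(f"Cq values must be finite, got {cqs}")
    ddct = (cq_target_test - cq_ref_test) - (cq_target_ctrl - cq_ref_ctrl)
    return float(2.0 ** (-ddct))


@dataclass
class QpcrRecord:
    """One qPCR quantification: four Cq values and the derived fold change."""

    cq_target_test: float
    cq_ref_test: float
    cq_target_ctrl: float
    cq_ref_ctrl: float

    @property
    def fold(self) -> float:
        return ddct_fold(
            self.cq_target_test, self.cq_ref_test,
            self.cq_target_ctrl, self.cq_ref_ctrl,
        )
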