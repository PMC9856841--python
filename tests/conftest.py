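import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sigsurv import datagen
from sigsurv.signature import GeneSignature

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def xeno():
    """Small planted-effect two-arm simulation shared across tests."""
    cfg = datagen.XenoSimConfig(
        n_genes=800, n_per_arm=3, frac_de=0.12, frac_up_of_de=0.45,
        log2fc_effect=2.0, noise_sd=0.5, seed=11,
    )
    return datagen.simulate_xenograft(cfg)


@pytest.fixture(scope="session")
def xeno_groups(xeno):
    matrix, _ = xeno
    return pd.Series(
        [s.split("_")[0] for s in matrix.samples], index=matrix.samples
    )


@pytest.fixture(scope="session")
def toy_signature():
    """Hand-built 20-gene signature, 12 up / 8 down, with Entrez IDs."""
    n_up, n_dn = 12, 8
    syms = [f"SIG{i:03d}" for i in range(n_up + n_dn)]
    weights = [1] * n_up + [-1] * n_dn
    return GeneSignature(
        "Sig",
        pd.DataFrame(
            {
                "symbol": syms,
                "entrez": np.arange(len(syms)) + 5000,
                "weight": weights,
                "log2fc": [2.0] * n_up + [-2.0] * n_dn,
            }
        ),
    )


@pytest.fixture(scope="session")
def protective_cohort(toy_signature):
    """Cohort where a high signature score halves the hazard."""
    cfg = datagen.CohortSimConfig(
        n_patients=300, signature_truth=toy_signature, beta=np.log(0.5),
        baseline_hazard=0.1, censor_rate=0.05, seed=7,
    )
    return datagen.simulate_cohort(cfg)


@pytest.fixture
def handmade_de_table():
    """Ten genes spanning every branch of the signature filter.

    Kept set under (p < 0.05 and FC beyond 2) or FC beyond 4:
    G01 (both), G02 (rescue up), G05 (p + FC down), G06 (rescue down),
    G09 (both).
    """
    fc = np.array([3.0, 5.0, 1.5, 3.0, 0.3, 0.2, 0.6, 2.5, 10.0, 1.0])
    p = np.array([0.01, 0.20, 0.01, 0.20, 0.04, 0.50, 0.03, 0.06, 0.001, 0.9])
    log2fc = np.log2(fc)
    return pd.DataFrame(
        {
            "symbol": [f"G{i + 1:02d}" for i in range(10)],
            "entrez": np.arange(10) + 100,
            "mean_a": 8.0,
            "mean_b": 8.0 + log2fc,
            "log2fc": log2fc,
            "fc_linear": fc,
            "p_value": p,
            "direction": np.where(log2fc > 0, "up", "down"),
        }
    )


HANDMADE_KEPT = ["G01", "G02", "G05", "G06", "G09"]
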