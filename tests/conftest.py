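import numpy as np
import pandas as pd
import pytest
from scipy import stats

import backtrans as bt


def make_sumstats(z, chrom=None, pos=None, spacing=1_000_000, beta=None, se=None):
    """Summary-statistic frame from a Z vector (SE=0.05, a realistic
    per-allele standard error for a quantitative GWAS, unless given)."""
    z = np.asarray(z, dtype=float)
    n = len(z)
    se = np.full(n, 0.05) if se is None else np.asarray(se, float)
    beta = z * se if beta is None else np.asarray(beta, float)
    chrom = np.array(["1"] * n) if chrom is None else np.asarray(chrom, str)
    pos = (np.arange(n, dtype=np.int64) * spacing + 1) if pos is None else np.asarray(pos, np.int64)
    return pd.DataFrame({
        "CHR": chrom, "POS": pos,
        "ID": [f"{c}_{p}_G_A" for c, p in zip(chrom, pos)],
        "EA": "A", "OA": "G", "EAF": 0.3,
        "BETA": beta, "SE": se, "Z": z,
        "P": np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-320, 1.0),
        "N": 1000, "FLAG": "",
    })


def survival_frame(rng, n, n_cov=1, beta=None, censor_frac=0.3):
    """Small tie-free survival fixture: covariates X, times, events."""
    x = rng.standard_normal((n, n_cov))
    lp = x @ (np.zeros(n_cov) if beta is None else np.asarray(beta, float))
    t_event = rng.exponential(np.exp(-lp))
    t_cens = rng.exponential(3.0, size=n) if censor_frac > 0 else np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = time + rng.uniform(0, 1e-9, size=n)  # break any accidental ties
    return x, time, event


def toy_cohort(n=60, n_biomarkers=3, seed=0, coefs=None, censoring=0.5):
    cfg = bt.SimulationConfig(n_subjects=n, n_biomarkers=n_biomarkers,
                              censoring_target=censoring, seed=seed)
    truth = bt.SimulationTruth(true_coefficients=coefs or {}, seed=seed)
    return bt.gen_cohort(cfg, truth, seed=seed)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def fitted_score():
    """A score fitted once on a mid-size trial cohort, reused across tests."""
    cfg = bt.SimulationConfig(n_subjects=2000, n_biomarkers=5, seed=11)
    truth = bt.SimulationTruth(true_coefficients={"bm0": 0.8, "bm1": -0.6}, seed=11)
    cohort = bt.gen_cohort(cfg, truth, seed=11)
    results = bt.RiskScoreModel(cohort, include_age_sex=False).fit()
    return cfg, truth, cohort, results
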