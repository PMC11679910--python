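import numpy as np
import pandas as pd
import pytest

import migrisk as mg


@pytest.fixture(scope="session")
def small_cohort():
    """1000-sample cohort with one planted main effect (log-OR = ln 2)."""
    spec = mg.SimCohortSpec(
        n_samples=1000,
        n_snps=12,
        maf_range=(0.2, 0.5),
        missing_rate=0.02,
        intercept=-1.0,
        main_effects={"rs000003": float(np.log(2.0))},
        seed=11,
    )
    geno = mg.simulate_genotypes(spec)
    cohort = mg.simulate_phenotypes(geno, spec)
    return geno, cohort


@pytest.fixture(scope="session")
def epistatic_cohort():
    """Cohort with a pure 2-SNP interaction and no main effects."""
    spec = mg.SimCohortSpec(
        n_samples=2000,
        n_snps=8,
        maf_range=(0.3, 0.5),
        missing_rate=0.0,
        intercept=0.0,
        interaction_effects={("rs000002", "rs000005"): 1.0},
        seed=5,
    )
    geno = mg.simulate_genotypes(spec)
    cohort = mg.simulate_phenotypes(geno, spec)
    return geno, cohort


def make_prs_cohort(
    rng: np.random.Generator,
    n: int = 2000,
    beta_medium: float = 0.0,
    beta_high: float = 0.0,
    interaction: float = 0.0,
    factor_coef: float = 0.0,
    intercept: float = -1.0,
) -> pd.DataFrame:
    """Minimal cohort with a PRS category, one continuous factor, outcome."""
    cat = rng.choice(["low", "medium", "high"], size=n, p=[0.25, 0.5, 0.25])
    trend = pd.Series(cat).map({"low": 0, "medium": 1, "high": 2}).to_numpy(float)
    factor = rng.normal(15.0, 6.0, n)
    factor_high = (factor > 15.0).astype(float)
    eta = (
        intercept
        + beta_medium * (trend == 1)
        + beta_high * (trend == 2)
        + factor_coef * factor_high
        + interaction * trend * factor_high
    )
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return pd.DataFrame(
        {"mi": y, "category": cat, "fat_en_pct": factor}
    )
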