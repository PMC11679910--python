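"""Generator correctness: HWE conformity, planted effects, reproducibility."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import chisquare

import migrisk as mg


# ---------------------------------------------------------------------------
# genotypes


def test_heterozygote_fraction_at_maf_half():
    spec = mg.SimCohortSpec(
        n_samples=20_000, n_snps=2, maf_range=(0.5, 0.5), missing_rate=0.0, seed=0
    )
    geno = mg.simulate_genotypes(spec)
    het = geno.het_fraction()
    assert np.allclose(het, 0.5, atol=0.02)


def test_invalid_specs_raise():
    with pytest.raises(mg.InvalidSpecError):
        mg.SimCohortSpec(n_samples=100, n_snps=10, maf_range=(0.0, 0.3))
    with pytest.raises(mg.InvalidSpecError):
        mg.SimCohortSpec(n_samples=0, n_snps=10)
    with pytest.raises(mg.InvalidSpecError):
        mg.SimSumstatsSpec(n_snps=100, rg_true=1.5)
    with pytest.raises(mg.InvalidSpecError):
        mg.SimLocusSpec(n_snps=10, ld_block_size=20, causal_config="H3")
    with pytest.raises(mg.InvalidSpecError):
        mg.SimLocusSpec(n_snps=100, causal_config="H7")


def test_hwe_goodness_of_fit_across_seeds():
    """Chi-square GoF against HWE proportions at m=0.3, n=10,000 per seed."""
    failures = 0
    n_seeds = 50
    for seed in range(n_seeds):
        spec = mg.SimCohortSpec(
            n_samples=10_000, n_snps=1, maf_range=(0.3, 0.3), missing_rate=0.0,
            seed=seed,
        )
        geno = mg.simulate_genotypes(spec)
        nAA, nAa, naa = geno.genotype_counts(geno.rsids[0])
        exp = 10_000 * np.array([0.49, 0.42, 0.09])
        p = chisquare([nAA, nAa, naa], exp).pvalue
        failures += p <= 0.001
    assert failures <= max(1, int(0.01 * n_seeds))


# ---------------------------------------------------------------------------
# phenotypes


def test_null_intercept_zero_gives_half_cases():
    spec = mg.SimCohortSpec(n_samples=20_000, n_snps=5, intercept=0.0, seed=2)
    geno = mg.simulate_genotypes(spec)
    cohort = mg.simulate_phenotypes(geno, spec)
    assert abs(cohort["mi"].mean() - 0.5) < 0.02


def test_logistic_refit_recovers_planted_or():
    spec = mg.SimCohortSpec(
        n_samples=20_000, n_snps=4, maf_range=(0.3, 0.5), missing_rate=0.0,
        intercept=-1.0, main_effects={"rs000001": float(np.log(2.0))}, seed=3,
    )
    geno = mg.simulate_genotypes(spec)
    cohort = mg.simulate_phenotypes(geno, spec)
    X = sm.add_constant(geno.dosages["rs000001"].to_numpy())
    fit = sm.Logit(cohort["mi"].to_numpy(), X).fit(disp=False)
    assert 1.8 <= np.exp(fit.params[1]) <= 2.2


def test_unknown_effect_rsid_raises(small_cohort):
    geno, _ = small_cohort
    spec = mg.SimCohortSpec(
        n_samples=geno.n_samples, n_snps=geno.n_snps,
        main_effects={"rs_nonexistent": 0.5}, seed=0,
    )
    with pytest.raises(mg.ConfigurationError):
        mg.simulate_phenotypes(geno, spec)


def test_null_phenotypes_independent_of_genotype():
    """With all effects zero the outcome is independent of every SNP."""
    spec = mg.SimCohortSpec(n_samples=4000, n_snps=20, missing_rate=0.0, seed=9)
    geno = mg.simulate_genotypes(spec)
    cohort = mg.simulate_phenotypes(geno, spec)
    from scipy.stats import chi2_contingency

    ps = []
    for rsid in geno.rsids:
        tab = pd.crosstab(geno.dosages[rsid], cohort["mi"])
        ps.append(chi2_contingency(tab).pvalue)
    # uniform p-values: none should be extreme after 20 tests
    assert min(ps) > 0.05 / 20 / 10


# ---------------------------------------------------------------------------
# sumstats pair


def test_sumstats_null_rg_flat_product_regression():
    spec = mg.SimSumstatsSpec(n_snps=10_000, rg_true=0.0, seed=4)
    s1, s2 = mg.simulate_sumstats_pair(spec)
    X = sm.add_constant(s1["ldscore"].to_numpy())
    fit = sm.OLS((s1["z"] * s2["z"]).to_numpy(), X).fit(cov_type="HC1")
    assert abs(fit.params[1]) < 3 * fit.bse[1]


def test_sumstats_moment_check_recovers_slope():
    """Regression of z1·z2 on ℓ matches √(N1N2)·rg·√(h²1h²2)/M within jackknife SE."""
    spec = mg.SimSumstatsSpec(
        n_snps=20_000, h2_1=0.4, h2_2=0.4, rg_true=0.6, N1=50_000, N2=50_000, seed=6
    )
    s1, s2 = mg.simulate_sumstats_pair(spec)
    ell = s1["ldscore"].to_numpy()
    y = (s1["z"] * s2["z"]).to_numpy()
    expected = np.sqrt(50_000 * 50_000) * 0.6 * 0.4 / 20_000
    X = sm.add_constant(ell)
    fit = sm.OLS(y, X).fit(cov_type="HC1")
    assert abs(fit.params[1] - expected) < 3 * fit.bse[1]


def test_sumstats_degenerate_rg_one():
    spec = mg.SimSumstatsSpec(
        n_snps=2000, h2_1=0.5, h2_2=0.5, rg_true=1.0, N1=10**6, N2=10**6, seed=7
    )
    s1, s2 = mg.simulate_sumstats_pair(spec)
    # signal dominates noise at huge N: z1 ≈ z2
    corr = np.corrcoef(s1["z"], s2["z"])[0, 1]
    assert corr > 0.99


# ---------------------------------------------------------------------------
# coloc loci


def test_h0_locus_max_z_is_null_scale():
    exceed = 0
    for seed in range(30):
        l1, l2 = mg.simulate_coloc_locus(
            mg.SimLocusSpec(n_snps=500, causal_config="H0", seed=seed)
        )
        exceed += max(np.abs(l1["z"]).max(), np.abs(l2["z"]).max()) >= 4.0
    assert exceed <= 4  # max of ~500 correlated null z-scores rarely reaches 4


def test_h4_top_snp_is_planted():
    """Both traits' argmax |z| hits the planted causal in most seeds.

    With ρ=0.9 LD, each immediate neighbour beats the causal SNP with
    probability Φ(−(1−ρ)ζ/√(2(1−ρ))) ≈ 3.7%, giving ≈ 0.91 per trait and
    ≈ 0.83 for both jointly; 80% over 40 seeds leaves sampling margin.
    """
    hits = 0
    for seed in range(40):
        spec = mg.SimLocusSpec(
            n_snps=500, ld_block_size=20, causal_config="H4", causal_z=8.0, seed=seed
        )
        l1, l2 = mg.simulate_coloc_locus(spec)
        i1 = int(np.abs(l1["z"]).to_numpy().argmax())
        i2 = int(np.abs(l2["z"]).to_numpy().argmax())
        # recover planted index: strongest mean signal position
        planted = int((np.abs(l1["z"]) + np.abs(l2["z"])).to_numpy().argmax())
        hits += (i1 == planted) and (i2 == planted)
    assert hits >= 32


def test_h3_causals_in_distinct_blocks():
    for seed in range(10):
        spec = mg.SimLocusSpec(
            n_snps=200, ld_block_size=20, causal_config="H3", causal_z=10.0, seed=seed
        )
        l1, l2 = mg.simulate_coloc_locus(spec)
        b1 = int(np.abs(l1["z"]).to_numpy().argmax()) // 20
        b2 = int(np.abs(l2["z"]).to_numpy().argmax()) // 20
        assert b1 != b2


# ---------------------------------------------------------------------------
# expression


def test_marker_elevation_ranks_assigned_type():
    wins = 0
    for seed in range(20):
        spec = mg.SimExpressionSpec(
            n_cells=300, n_genes=50, cell_types={"A": 0.5, "B": 0.5},
            marker_map={"A": {"G00007": 10.0}}, seed=seed,
        )
        adata, _ = mg.simulate_expression(spec)
        expr = np.asarray(adata[:, "G00007"].X).ravel()
        ct = adata.obs["cell_type"].to_numpy()
        wins += expr[ct == "A"].mean() > expr[ct == "B"].mean()
    assert wins >= 19


def test_fold_one_means_equal_across_types():
    spec = mg.SimExpressionSpec(
        n_cells=4000, n_genes=10, cell_types={"A": 0.5, "B": 0.5},
        marker_map={"A": {"G00001": 1.0}}, baseline_mean=2.0, seed=1,
    )
    adata, _ = mg.simulate_expression(spec)
    expr = np.asarray(adata[:, "G00001"].X).ravel()
    ct = adata.obs["cell_type"].to_numpy()
    assert abs(expr[ct == "A"].mean() - expr[ct == "B"].mean()) < 0.2


def test_marker_outside_universe_raises():
    spec = mg.SimExpressionSpec(
        n_cells=10, n_genes=5, cell_types={"A": 1.0},
        marker_map={"A": {"NOPE": 2.0}},
    )
    with pytest.raises(mg.ConfigurationError):
        mg.simulate_expression(spec)


# ---------------------------------------------------------------------------
# reproducibility across all five generators


@pytest.mark.parametrize("which", ["cohort", "sumstats", "locus", "expression"])
def test_same_seed_identical_output(which):
    if which == "cohort":
        spec = mg.SimCohortSpec(n_samples=200, n_snps=10, seed=42)
        g1, g2 = mg.simulate_genotypes(spec), mg.simulate_genotypes(spec)
        pd.testing.assert_frame_equal(g1.dosages, g2.dosages)
        c1 = mg.simulate_phenotypes(g1, spec)
        c2 = mg.simulate_phenotypes(g2, spec)
        pd.testing.assert_frame_equal(c1, c2)
    elif which == "sumstats":
        spec = mg.SimSumstatsSpec(n_snps=500, rg_true=0.4, seed=42)
        a1, b1 = mg.simulate_sumstats_pair(spec)
        a2, b2 = mg.simulate_sumstats_pair(spec)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)
    elif which == "locus":
        spec = mg.SimLocusSpec(n_snps=100, causal_config="H4", seed=42)
        a1, b1 = mg.simulate_coloc_locus(spec)
        a2, b2 = mg.simulate_coloc_locus(spec)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)
    else:
        spec = mg.SimExpressionSpec(n_cells=50, n_genes=20, seed=42)
        x1, w1 = mg.simulate_expression(spec)
        x2, w2 = mg.simulate_expression(spec)
        assert np.array_equal(np.asarray(x1.X), np.asarray(x2.X))
        pd.testing.assert_frame_equal(w1, w2)
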