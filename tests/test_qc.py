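"""SNP QC filters, exact HWE test, association scan, hotspot binning."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln
from scipy.stats import kstest

import migrisk as mg
from migrisk.qc import QCThresholds, hwe_chisq_test


def hwe_enumeration_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Independent exact HWE p via direct log-gamma evaluation of
    P(h | n, allele counts) = n!/(nAA! h! naa!) · nA! na! / (2n)! · 2^h."""
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    rare = min(nA, na)

    def logprob(h):
        aa = (rare - h) // 2
        AA = n - aa - h
        return (
            gammaln(n + 1) - gammaln(AA + 1) - gammaln(h + 1) - gammaln(aa + 1)
            + gammaln(nA + 1) + gammaln(na + 1) - gammaln(2 * n + 1)
            + h * np.log(2.0)
        )

    hs = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    if len(hs) == 0:
        return 1.0
    lp = np.array([logprob(h) for h in hs])
    probs = np.exp(lp - lp.max())
    probs /= probs.sum()
    p_obs = probs[list(hs).index(n_Aa)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert mg.hwe_exact_test(50, 0, 0) == 1.0
        assert mg.hwe_exact_test(0, 0, 31) == 1.0

    def test_balanced_matches_enumeration(self):
        assert mg.hwe_exact_test(25, 50, 25) == pytest.approx(
            hwe_enumeration_oracle(25, 50, 25), rel=1e-10
        )

    def test_extreme_het_deficit_tiny_p(self):
        assert mg.hwe_exact_test(10, 0, 10) < 1e-5

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            mg.hwe_exact_test(0, 0, 0)

    def test_agrees_with_enumeration_sampled_totals(self):
        """Spot-check against the oracle on a grid of configurations;
        the exhaustive all-totals-≤200 sweep lives in the acceptance suite."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 120))
            rare = int(rng.integers(0, n + 1))
            h = int(rng.choice(np.arange(rare % 2, rare + 1, 2))) if rare else 0
            aa = (rare - h) // 2
            AA = n - aa - h
            assert mg.hwe_exact_test(AA, h, aa) == pytest.approx(
                hwe_enumeration_oracle(AA, h, aa), rel=1e-9
            )

    def test_chisq_variant_agrees_roughly(self):
        p_exact = mg.hwe_exact_test(400, 420, 180)
        p_chi = hwe_chisq_test(400, 420, 180)
        assert abs(p_exact - p_chi) < 0.05


class TestSnpQc:
    def _make(self, dosage_cols: dict) -> mg.GenotypeMatrix:
        dos = pd.DataFrame(dosage_cols, dtype=float)
        snps = pd.DataFrame(
            {
                "chr": 1,
                "pos": np.arange(len(dosage_cols)) * 1000 + 1,
                "minor": "A",
                "major": "G",
                "maf": 0.3,
            },
            index=pd.Index(list(dosage_cols), name="rsid"),
        )
        return mg.GenotypeMatrix(dos, snps)

    def test_boundary_missing_four_percent_excluded(self):
        col = [np.nan] * 4 + [1.0] * 96  # exactly 4% missing
        hwe_ok = [0.0] * 44 + [1.0] * 42 + [2.0] * 14
        geno = self._make({"rs_bad": col, "rs_ok": hwe_ok})
        _, report = mg.snp_qc(geno, QCThresholds(max_het=1.0, hwe_alpha=0.0))
        assert not report.table.loc["rs_bad", "kept"]
        assert "missing" in report.table.loc["rs_bad", "reasons"]
        assert report.table.loc["rs_ok", "kept"]

    def test_low_maf_excluded(self):
        # 1000 calls, 9 minor alleles → MAF 0.0045 < 1%
        col = [1.0] * 9 + [0.0] * 991
        geno = self._make({"rs_rare": col})
        _, report = mg.snp_qc(geno, QCThresholds(max_het=1.0, hwe_alpha=0.0))
        assert "maf" in report.table.loc["rs_rare", "reasons"]

    def test_monomorphic_excluded_for_maf(self):
        geno = self._make({"rs_mono": [0.0] * 50})
        _, report = mg.snp_qc(geno)
        assert "maf" in report.table.loc["rs_mono", "reasons"]

    def test_excess_heterozygosity_excluded(self):
        geno = self._make({"rs_het": [1.0] * 40 + [0.0] * 60})
        _, report = mg.snp_qc(geno, QCThresholds(hwe_alpha=0.0, min_maf=0.0))
        assert "heterozygosity" in report.table.loc["rs_het", "reasons"]

    def test_counts_balance_and_idempotence(self):
        spec = mg.SimCohortSpec(n_samples=500, n_snps=40, missing_rate=0.03, seed=8)
        geno = mg.simulate_genotypes(spec)
        kept, report = mg.snp_qc(geno)
        assert report.n_kept + report.n_excluded == geno.n_snps
        excluded = report.table[~report.table["kept"]]
        assert (excluded["reasons"].str.len() > 0).all()
        if kept.n_snps:
            kept2, report2 = mg.snp_qc(kept)
            assert kept2.rsids == kept.rsids


class TestAssociationScan:
    def test_bonferroni_threshold(self, small_cohort):
        geno, cohort = small_cohort
        stats = mg.association_scan(geno, cohort)
        assert stats.attrs["bonferroni_threshold"] == pytest.approx(0.05 / geno.n_snps)

    def test_planted_effect_detected(self, small_cohort):
        geno, cohort = small_cohort
        stats = mg.association_scan(geno, cohort, ["age", "sex"]).set_index("rsid")
        assert stats.loc["rs000003", "p"] < 1e-4
        assert 1.5 < stats.loc["rs000003", "or_"] < 2.7

    def test_two_by_two_collapse_matches_cross_product(self):
        """Binary-collapsed no-covariate fit equals the 2×2 cross-product OR."""
        rng = np.random.default_rng(12)
        n = 400
        dose = rng.integers(0, 2, n).astype(float)  # binary dosage 0/1
        y = (rng.random(n) < np.where(dose > 0, 0.4, 0.2)).astype(int)
        dos = pd.DataFrame({"rs1": dose})
        snps = pd.DataFrame(
            {"chr": [1], "pos": [1], "minor": ["A"], "major": ["G"], "maf": [0.5]},
            index=pd.Index(["rs1"], name="rsid"),
        )
        stats = mg.association_scan(mg.GenotypeMatrix(dos, snps), pd.DataFrame({"mi": y}))
        a = np.sum((dose == 1) & (y == 1))
        b = np.sum((dose == 1) & (y == 0))
        c = np.sum((dose == 0) & (y == 1))
        d = np.sum((dose == 0) & (y == 0))
        assert stats.loc[0, "or_"] == pytest.approx(a * d / (b * c), abs=1e-6)

    def test_null_scan_pvalues_uniform_and_type_i_error(self):
        """2000 null SNPs: KS uniformity and α=0.05 rejection in [0.04, 0.06]."""
        spec = mg.SimCohortSpec(
            n_samples=300, n_snps=2000, maf_range=(0.2, 0.5), missing_rate=0.0,
            intercept=0.0, seed=13,
        )
        geno = mg.simulate_genotypes(spec)
        cohort = mg.simulate_phenotypes(geno, spec)
        stats = mg.association_scan(geno, cohort)
        p = stats.loc[stats["converged"], "p"].to_numpy()
        assert len(p) > 1900
        assert kstest(p, "uniform").pvalue > 0.01
        assert 0.04 <= np.mean(p < 0.05) <= 0.06


class TestDensityHotspots:
    def _stats(self, positions, ps, chrom=1):
        return pd.DataFrame(
            {"rsid": [f"rs{i}" for i in range(len(positions))],
             "chr": chrom, "pos": positions, "p": ps}
        )

    @pytest.mark.parametrize("n_sig,tier", [(50, "hotspot"), (49, "intermediate")])
    def test_hotspot_boundary(self, n_sig, tier):
        pos = list(range(1, n_sig * 1000, 1000))[:n_sig]
        stats = self._stats(pos, [1e-6] * n_sig)
        hs = mg.density_hotspots(stats)
        assert len(hs) == 1
        assert hs.loc[0, "n_significant"] == n_sig
        assert hs.loc[0, "tier"] == tier

    def test_no_significant_snps_empty(self):
        stats = self._stats([1, 2, 3], [0.5, 0.9, 0.2])
        assert mg.density_hotspots(stats).empty

    def test_windows_are_fixed_one_based(self):
        # pos 1_000_000 belongs to the first window [1, 1_000_001)
        stats = self._stats([1_000_000, 1_000_001], [1e-9, 1e-9])
        hs = mg.density_hotspots(stats)
        assert list(hs["window_start"]) == [1, 1_000_001]

    def test_missing_positions_raise(self):
        stats = self._stats([1, None], [1e-9, 1e-9])
        with pytest.raises(mg.MigriskError):
            mg.density_hotspots(stats)
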