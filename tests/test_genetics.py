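"""HWE, QC cascade, association engine, permutation adjustment, q-values."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from mirherit import (
    AnalysisConfig,
    TraitAssociation,
    adjust_permutation,
    hwe_chisq,
    qc_filter,
    qt_association,
    qvalue,
)
from mirherit.containers import GenotypeMatrix
from mirherit.exceptions import EmptyResultError, ParameterError
from mirherit.genetics import snp_vs_many_traits


def _geno(codes: np.ndarray, samples=None) -> GenotypeMatrix:
    m, n = codes.shape
    samples = samples or [f"s{i}" for i in range(n)]
    snps = [f"snp{i}" for i in range(m)]
    meta = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, m + 1) * 100, "ref": "A", "alt": "G"},
        index=snps,
    )
    return GenotypeMatrix(pd.DataFrame(codes, index=snps, columns=samples), meta)


def oracle_hwe(n_AA, n_Aa, n_aa):
    """Direct Pearson formula from multinomial expected counts."""
    n = n_AA + n_Aa + n_aa
    q = (2 * n_aa + n_Aa) / (2 * n)
    exp = [n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q**2]
    obs = [n_AA, n_Aa, n_aa]
    chi2 = sum((o - e) ** 2 / e for o, e in zip(obs, exp) if e > 0)
    return chi2


class TestHWE:
    def test_worked_example(self):
        chi2, p = hwe_chisq(50, 30, 20)
        assert chi2 == pytest.approx(11.60, abs=0.01)
        assert p == pytest.approx(6.6e-4, rel=0.02)

    def test_exact_proportions_give_p_one(self):
        chi2, p = hwe_chisq(25, 50, 25)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_monomorphic_p_one(self):
        assert hwe_chisq(100, 0, 0) == (0.0, 1.0)
        assert hwe_chisq(0, 0, 77) == (0.0, 1.0)

    def test_exhaustive_small_totals_match_oracle(self):
        """All genotype-count triples with total <= 30."""
        for total in range(1, 31):
            for n_AA in range(total + 1):
                for n_Aa in range(total - n_AA + 1):
                    n_aa = total - n_AA - n_Aa
                    chi2, p = hwe_chisq(n_AA, n_Aa, n_aa)
                    q = (2 * n_aa + n_Aa) / (2 * total)
                    if q in (0.0, 1.0):
                        assert (chi2, p) == (0.0, 1.0)
                    else:
                        assert chi2 == pytest.approx(oracle_hwe(n_AA, n_Aa, n_aa), abs=1e-9)


class TestQCFilter:
    def test_mac_boundary(self):
        """4 minor-allele copies removed, 5 retained."""
        rng = np.random.default_rng(0)
        n = 40
        base = rng.binomial(2, 0.4, size=(5, n)).astype(float)
        four = np.zeros(n); four[:4] = 1.0
        five = np.zeros(n); five[:5] = 1.0
        codes = np.vstack([base, four, five])
        cfg = AnalysisConfig(ibs_markers=5)
        filtered, report = qc_filter(_geno(codes), cfg, seed=1)
        assert "snp5" not in filtered.snp_ids  # 4 copies
        assert "snp6" in filtered.snp_ids  # exactly 5 copies
        assert report.n_failed_mac >= 1

    def test_duplicated_sample_removed_by_ibs(self):
        rng = np.random.default_rng(1)
        codes = rng.binomial(2, 0.3, size=(50, 10)).astype(float)
        codes[:, 9] = codes[:, 0]  # identical twin pair
        cfg = AnalysisConfig(ibs_markers=50)
        filtered, report = qc_filter(_geno(codes), cfg, seed=2)
        assert report.n_removed_samples_ibs == 1
        assert filtered.n_samples == 9

    def test_low_callrate_snp_and_sample_removed(self):
        rng = np.random.default_rng(2)
        codes = rng.binomial(2, 0.4, size=(40, 20)).astype(float)
        codes[0, :10] = np.nan  # SNP with 50% call rate
        codes[1:40:2, 5] = np.nan  # sample 5 loses half its genotypes
        cfg = AnalysisConfig(ibs_markers=10)
        filtered, report = qc_filter(_geno(codes), cfg, seed=3)
        assert report.n_removed_samples_callrate == 1
        assert "snp0" not in filtered.snp_ids

    def test_saturated_missingness_empties_panel(self):
        rng = np.random.default_rng(3)
        codes = rng.binomial(2, 0.4, size=(20, 20)).astype(float)
        mask = rng.random(codes.shape) < 0.5
        codes[mask] = np.nan
        with pytest.raises(EmptyResultError):
            qc_filter(_geno(codes), AnalysisConfig(ibs_markers=5), seed=4)

    def test_clean_hwe_data_rarely_fails_hwe(self):
        rng = np.random.default_rng(4)
        codes = rng.binomial(2, 0.3, size=(200, 100)).astype(float)
        _, report = qc_filter(_geno(codes), AnalysisConfig(ibs_markers=50), seed=5)
        assert report.n_failed_hwe <= 2

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        codes = rng.binomial(2, 0.35, size=(80, 30)).astype(float)
        codes[rng.random(codes.shape) < 0.02] = np.nan
        cfg = AnalysisConfig(ibs_markers=40)
        once, _ = qc_filter(_geno(codes), cfg, seed=6)
        twice, rep2 = qc_filter(once, cfg, seed=6)
        assert list(twice.snp_ids) == list(once.snp_ids)
        assert list(twice.sample_ids) == list(once.sample_ids)


class TestAssociation:
    def test_exact_linear_trait_recovers_slope(self):
        codes = np.tile(np.array([0.0, 1.0, 2.0]), 10)[None, :]
        geno = _geno(codes)
        trait = pd.Series(3.5 * codes[0] + 1.0, index=geno.sample_ids)
        res = qt_association(trait, geno)
        assert res.loc["snp0", "beta"] == pytest.approx(3.5)
        assert res.loc["snp0", "p"] < 1e-12

    def test_matches_statsmodels_ols(self):
        """Independent cross-check of the closed-form engine."""
        rng = np.random.default_rng(6)
        codes = rng.binomial(2, 0.4, size=(10, 50)).astype(float)
        codes[rng.random(codes.shape) < 0.05] = np.nan
        geno = _geno(codes)
        trait = pd.Series(rng.normal(size=50), index=geno.sample_ids)
        res = qt_association(trait, geno)
        for snp in res.index:
            x = geno.codes.loc[snp]
            ok = x.notna()
            sm_fit = sm.OLS(trait[ok], sm.add_constant(x[ok])).fit()
            assert res.loc[snp, "beta"] == pytest.approx(sm_fit.params[snp], rel=1e-9)
            assert res.loc[snp, "p"] == pytest.approx(sm_fit.pvalues[snp], rel=1e-9)

    def test_monomorphic_snp_omitted(self):
        codes = np.vstack([np.zeros(20), np.tile([0.0, 1.0], 10)])
        geno = _geno(codes)
        trait = pd.Series(np.random.default_rng(7).normal(size=20), index=geno.sample_ids)
        res = qt_association(trait, geno)
        assert "snp0" not in res.index and "snp1" in res.index

    def test_null_trait_p_uniform(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(30):
            codes = rng.binomial(2, 0.4, size=(20, 60)).astype(float)
            geno = _geno(codes)
            trait = pd.Series(rng.normal(size=60), index=geno.sample_ids)
            ps.extend(qt_association(trait, geno)["p"].tolist())
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_snp_vs_many_traits_matches_per_trait_ols(self):
        rng = np.random.default_rng(9)
        g = pd.Series(rng.binomial(2, 0.4, 40).astype(float),
                      index=[f"s{i}" for i in range(40)])
        traits = pd.DataFrame(rng.normal(size=(5, 40)), columns=g.index)
        res = snp_vs_many_traits(g, traits)
        for t in traits.index:
            fit = sm.OLS(traits.loc[t], sm.add_constant(g.rename("g"))).fit()
            assert res.loc[t, "p"] == pytest.approx(fit.pvalues["g"], rel=1e-9)


class TestPermutationAdjustment:
    def test_single_snp_panel_reduces_to_per_test(self):
        rng = np.random.default_rng(10)
        codes = rng.binomial(2, 0.4, size=(1, 80)).astype(float)
        geno = _geno(codes)
        trait = pd.Series(0.3 * codes[0] + rng.normal(size=80), index=geno.sample_ids)
        raw = qt_association(trait, geno)
        adj = adjust_permutation(trait, geno, raw, n_perm=4000, seed=11)
        assert adj.iloc[0] == pytest.approx(raw["p"].iloc[0], abs=0.02)

    def test_family_wise_dominates_per_snp(self):
        rng = np.random.default_rng(12)
        codes = rng.binomial(2, 0.4, size=(30, 60)).astype(float)
        geno = _geno(codes)
        trait = pd.Series(rng.normal(size=60), index=geno.sample_ids)
        raw = qt_association(trait, geno)
        fw = adjust_permutation(trait, geno, raw, n_perm=300, seed=13, mode="family-wise")
        ps = adjust_permutation(trait, geno, raw, n_perm=300, seed=13, mode="per-snp")
        assert (fw >= ps - 1e-12).all()

    def test_permutation_close_to_bonferroni_for_independent_snps(self):
        """On an LD-free panel maxT adjusted p approximately tracks, and
        does not exceed by much, the Bonferroni bound."""
        rng = np.random.default_rng(14)
        codes = rng.binomial(2, 0.4, size=(40, 80)).astype(float)
        geno = _geno(codes)
        trait = pd.Series(0.5 * codes[3] + rng.normal(size=80), index=geno.sample_ids)
        res = TraitAssociation(trait, geno).fit(n_perm=2000, seed=15)
        top = res.table.iloc[0]
        assert top["permutation_p"] <= top["bonferroni_p"] + 0.05

    def test_invalid_nperm_and_mode(self):
        codes = np.tile([0.0, 1.0, 2.0], 5)[None, :]
        geno = _geno(codes)
        trait = pd.Series(np.arange(15.0), index=geno.sample_ids)
        raw = qt_association(trait, geno)
        with pytest.raises(ParameterError):
            adjust_permutation(trait, geno, raw, n_perm=0, seed=0)
        with pytest.raises(ParameterError):
            adjust_permutation(trait, geno, raw, n_perm=10, seed=0, mode="bogus")


class TestQValues:
    def test_all_ones_stay_one(self):
        assert (qvalue(np.ones(50)) == 1.0).all()

    def test_bh_reduction_when_pi0_forced_one(self):
        """10 small + 90 large p-values: q equals the BH adjusted value."""
        ps = np.array([0.001] * 10 + [0.5] * 90)
        q = qvalue(ps, pi0=1.0)
        from statsmodels.stats.multitest import multipletests

        bh = multipletests(ps, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, rtol=1e-9)

    def test_monotone_in_p_order(self):
        rng = np.random.default_rng(16)
        ps = rng.uniform(size=200)
        q = qvalue(ps)
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_range_and_floor_bounds(self):
        rng = np.random.default_rng(17)
        ps = np.concatenate([rng.uniform(size=150), rng.uniform(0, 1e-3, size=50)])
        q = qvalue(ps)
        assert ((q >= 0) & (q <= 1)).all()
        # with pi0 estimated, q is bounded below by pi0 * p (BH scaled by pi0)
        from mirherit.genetics import estimate_pi0

        pi0 = min(1.0, max(estimate_pi0(ps), 0.0))
        assert (q >= pi0 * ps - 1e-12).all()
        # under pi0 = 1 the raw-p floor holds exactly
        q_bh = qvalue(ps, pi0=1.0)
        assert (q_bh >= ps - 1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ParameterError):
            qvalue([0.5, 1.5])


class TestTraitAssociationModel:
    def test_fit_produces_all_adjustment_columns(self, small_dataset):
        from mirherit import re_matrix

        scores = re_matrix(small_dataset.expression, small_dataset.targets, min_targets=1)
        trait = scores.mean_re.loc[small_dataset.unrelated_samples]
        res = TraitAssociation(trait, small_dataset.genotypes).fit(n_perm=200, seed=3)
        t = res.table
        assert {"beta", "p", "bonferroni_p", "q_value", "permutation_p", "n"} <= set(t.columns)
        m = len(t)
        np.testing.assert_allclose(
            t["bonferroni_p"], np.minimum(1.0, m * t["p"]), rtol=1e-12
        )
        assert (t["q_value"] >= t["p"] - 1e-12).all()
        assert "Quantitative-trait association" in res.summary()

    def test_causal_snp_tops_small_panel(self, small_dataset):
        from mirherit import re_matrix

        scores = re_matrix(small_dataset.expression, small_dataset.targets, min_targets=1)
        trait = scores.mean_re.loc[small_dataset.unrelated_samples]
        res = TraitAssociation(trait, small_dataset.genotypes).fit()
        assert res.top_snp == small_dataset.causal_snp_id

    def test_score_test_agrees_with_t_test_asymptotically(self, small_dataset):
        from mirherit import re_matrix

        scores = re_matrix(small_dataset.expression, small_dataset.targets, min_targets=1)
        trait = scores.mean_re.loc[small_dataset.unrelated_samples]
        t_res = TraitAssociation(trait, small_dataset.genotypes).fit()
        s_res = TraitAssociation(trait, small_dataset.genotypes).fit(score_test=True)
        shared = t_res.table.index.intersection(s_res.table.index)
        lt = -np.log10(t_res.table.loc[shared, "p"].astype(float) + 1e-300)
        ls = -np.log10(s_res.table.loc[shared, "p"].astype(float) + 1e-300)
        assert np.corrcoef(lt, ls)[0, 1] > 0.99
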