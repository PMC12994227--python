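import numpy as np
import pandas as pd
import pytest
from scipy import stats

import backtrans as bt
from backtrans.gwas import loci_table, read_sumstats, write_sumstats
from backtrans.simulate import GenotypeMatrix

from _oracles import ols_closed_form
from conftest import make_sumstats


def _geno_from_matrix(g):
    n, p = g.shape
    pos = np.arange(p, dtype=np.int64) * 1_000_000 + 1
    return GenotypeMatrix(
        matrix=g.astype(np.int8), variant_ids=[f"1_{q}_G_A" for q in pos],
        chrom=np.array(["1"] * p), pos=pos,
        ea=np.array(["A"] * p), oa=np.array(["G"] * p),
        maf=g.mean(axis=0) / 2.0)


class TestVariantAssociation:
    def test_matches_closed_form_ols_on_toy(self):
        g = np.array([[0], [1], [2], [0], [1], [2]])
        y = np.array([0.1, 0.5, 1.2, -0.2, 0.7, 0.9])
        ss = bt.run_variant_association(y, _geno_from_matrix(g))
        beta, se = ols_closed_form(y, g[:, 0])
        assert ss["BETA"].iloc[0] == pytest.approx(beta, rel=1e-12)
        assert ss["SE"].iloc[0] == pytest.approx(se, rel=1e-12)
        z = beta / se
        assert ss["P"].iloc[0] == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-12)

    def test_monomorphic_variant_flagged_with_p_one(self):
        g = np.column_stack([np.zeros(6, int), [0, 1, 2, 0, 1, 2]])
        y = np.arange(6, dtype=float)
        ss = bt.run_variant_association(y, _geno_from_matrix(g))
        assert ss["FLAG"].iloc[0] == "monomorphic"
        assert ss["P"].iloc[0] == 1.0
        assert ss["FLAG"].iloc[1] == ""

    def test_null_type_one_error_calibrated(self, rng):
        n, p = 2000, 1000
        g = rng.binomial(2, 0.3, size=(n, p))
        y = rng.standard_normal(n)
        ss = bt.run_variant_association(y, _geno_from_matrix(g))
        frac = (ss["P"] < 0.05).mean()
        # binomial 99% envelope around 0.05 with 1000 trials
        assert 0.032 <= frac <= 0.068

    def test_covariate_adjustment_removes_confounding(self, rng):
        n = 3000
        conf = rng.standard_normal(n)
        g = rng.binomial(2, np.clip(0.3 + 0.1 * np.tanh(conf), 0.05, 0.95))
        y = conf + 0.02 * rng.standard_normal(n)
        geno = _geno_from_matrix(g[:, None])
        unadj = bt.run_variant_association(y, geno)
        adj = bt.run_variant_association(y, geno, covariates=conf[:, None])
        assert unadj["P"].iloc[0] < 1e-6      # confounded signal
        assert adj["P"].iloc[0] > 1e-3        # gone after adjustment


class TestLocusDefinition:
    def test_worked_three_variant_case(self):
        ss = make_sumstats(z=[6.0, 6.5, 6.2],
                           pos=[1_000_000, 1_050_000, 2_000_000])
        loci = bt.define_loci(ss)
        assert [(l.start, l.end) for l in loci] == [(900_000, 1_150_000),
                                                    (1_900_000, 2_100_000)]
        assert loci[0].lead_id == ss["ID"].iloc[1]  # smallest p in the pair
        assert loci[0].n_sig == 2

    def test_no_significant_variants_gives_empty_list(self):
        ss = make_sumstats(z=[1.0, 2.0, 3.0])
        assert bt.define_loci(ss) == []

    def test_default_threshold_is_genome_wide(self):
        z_edge = stats.norm.isf(5e-8 / 2)
        ss = make_sumstats(z=[z_edge * 0.999, z_edge * 1.001],
                           pos=[1_000_000, 5_000_000])
        loci = bt.define_loci(ss)
        assert len(loci) == 1
        assert loci[0].members == [ss["ID"].iloc[1]]

    def test_flank_clipped_at_position_one(self):
        ss = make_sumstats(z=[7.0], pos=[50_000])
        locus = bt.define_loci(ss)[0]
        assert locus.start == 1

    def test_overlapping_flanks_merge_to_disjoint_loci(self):
        # gap of 150 kb: separate chains, but flanked intervals overlap
        ss = make_sumstats(z=[6.0, 7.0], pos=[1_000_000, 1_150_000])
        loci = bt.define_loci(ss)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (900_000, 1_250_000)
        assert loci[0].lead_id == ss["ID"].iloc[1]

    def test_every_significant_variant_in_exactly_one_locus(self, rng):
        z = rng.choice([0.5, 6.0, 8.0], size=200, p=[0.8, 0.1, 0.1])
        pos = np.sort(rng.choice(np.arange(1, 30_000_001, 10_000), 200, replace=False))
        ss = make_sumstats(z=z, pos=pos)
        loci = bt.define_loci(ss)
        sig_ids = set(ss.loc[ss["P"] < 5e-8, "ID"])
        member_ids = [m for l in loci for m in l.members]
        assert len(member_ids) == len(set(member_ids))
        assert set(member_ids) == sig_ids
        for a, b in zip(loci, loci[1:]):
            if a.chrom == b.chrom:
                assert a.end < b.start


class TestInflation:
    def _null_grid(self, m=20001):
        q = (np.arange(m) + 0.5) / m
        return make_sumstats(z=np.sqrt(stats.chi2.ppf(q, df=1)),
                             pos=np.arange(m) * 1000 + 1)

    def test_chi_square_grid_gives_lambda_one(self):
        adj = bt.inflation_factor(self._null_grid(), loci=[])
        assert adj.lambda_ == pytest.approx(1.0, abs=0.01)
        assert not adj.applied

    def test_doubling_z_quadruples_lambda(self):
        ss = self._null_grid()
        lam1 = bt.inflation_factor(ss, loci=[]).lambda_
        ss2 = ss.copy()
        ss2["Z"] *= 2.0
        lam2 = bt.inflation_factor(ss2, loci=[]).lambda_
        assert lam2 == pytest.approx(4.0 * lam1, rel=1e-12)

    def test_locus_variants_excluded_from_lambda(self):
        ss = self._null_grid(m=5001)
        spiked = ss.copy()
        inside = spiked["POS"] <= 1_000_000
        spiked.loc[inside, "Z"] = 10.0
        locus = bt.Locus(chrom="1", start=1, end=1_000_000, lead_id="x", lead_p=1e-20)
        lam_excl = bt.inflation_factor(spiked, loci=[locus]).lambda_
        lam_incl = bt.inflation_factor(spiked, loci=[]).lambda_
        assert lam_excl < lam_incl
        assert lam_excl == pytest.approx(
            bt.inflation_factor(ss.loc[~inside], loci=[]).lambda_, rel=1e-9)

    def test_too_few_outside_variants_rejected(self):
        ss = make_sumstats(z=np.ones(50))
        with pytest.raises(ValueError):
            bt.inflation_factor(ss, loci=[])


class TestAdjustment:
    def test_lambda_leq_one_is_identity(self):
        ss = make_sumstats(z=[1.0, 2.0, 5.0])
        adj = bt.InflationAdjustment(lambda_=0.97, quantile=0.99, n_variants=1000)
        out = bt.adjust_zscores(ss, adj)
        pd.testing.assert_frame_equal(out, ss)

    def test_closed_form_deflation(self):
        # beta 0.5, se 0.1 -> z = 5; lambda 1.25 -> z* = 4, p* = 2 Phi(-4)
        ss = make_sumstats(z=[5.0], beta=[0.5], se=[0.1])
        adj = bt.InflationAdjustment(lambda_=1.25, quantile=0.99, n_variants=1000)
        out = bt.adjust_zscores(ss, adj)
        assert out["Z"].iloc[0] == pytest.approx(4.0, rel=1e-12)
        assert out["P"].iloc[0] == pytest.approx(2 * stats.norm.cdf(-4.0), rel=1e-9)
        assert out["P"].iloc[0] == pytest.approx(6.334e-5, rel=1e-3)

    def test_sqrt_lambda_mode(self):
        ss = make_sumstats(z=[4.0])
        adj = bt.InflationAdjustment(lambda_=4.0, quantile=0.99, n_variants=1000)
        out = bt.adjust_zscores(ss, adj, gc_mode="z_over_sqrt_lambda")
        assert out["Z"].iloc[0] == pytest.approx(2.0)

    def test_adjustment_is_monotone_and_rank_preserving(self, rng):
        ss = make_sumstats(z=rng.standard_normal(500) * 2)
        adj = bt.InflationAdjustment(lambda_=1.3, quantile=0.99, n_variants=500)
        out = bt.adjust_zscores(ss, adj)
        assert (out["P"].to_numpy() >= ss["P"].to_numpy() - 1e-15).all()
        assert (np.argsort(-np.abs(out["Z"])) == np.argsort(-np.abs(ss["Z"]))).all()

    def test_boundary_variant_drops_out_after_adjustment(self):
        z_edge = stats.norm.isf(5e-8 / 2)  # just significant before adjustment
        ss = make_sumstats(z=[z_edge * 1.001, 9.0], pos=[1_000_000, 50_000_000])
        assert len(bt.define_loci(ss)) == 2
        adj = bt.InflationAdjustment(lambda_=1.1, quantile=0.99, n_variants=1000)
        loci = bt.redefine_loci_after_adjustment(bt.adjust_zscores(ss, adj))
        assert len(loci) == 1
        assert loci[0].members == [ss["ID"].iloc[1]]


def test_sumstats_tsv_round_trip(tmp_path, rng):
    ss = make_sumstats(z=rng.standard_normal(20))
    path = tmp_path / "ss.tsv"
    write_sumstats(ss, path)
    back = read_sumstats(path)
    assert np.allclose(back["Z"], ss["Z"])
    assert list(back["FLAG"]) == list(ss["FLAG"])
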