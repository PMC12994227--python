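import numpy as np
import pandas as pd
import pytest

import backtrans as bt
from backtrans.burden import (CollapseResult, DEFAULT_MASKS, MaskDefinition,
                              gene_summary, results_table)
from backtrans.simulate import GenotypeMatrix

from _oracles import ols_closed_form


def _rare(matrix, genes, classes, mafs=None):
    matrix = np.asarray(matrix, dtype=np.int8)
    n, p = matrix.shape
    mafs = matrix.mean(axis=0) / 2.0 if mafs is None else np.asarray(mafs)
    ids = [f"rv{i}" for i in range(p)]
    ann = pd.DataFrame({"variant_id": ids, "chrom": "23",
                        "pos": np.arange(1, p + 1) * 100, "gene": genes,
                        "class": classes, "maf": mafs})
    geno = GenotypeMatrix(matrix=matrix, variant_ids=ids,
                          chrom=np.array(["23"] * p),
                          pos=np.arange(1, p + 1) * 100,
                          ea=np.array(["T"] * p), oa=np.array(["C"] * p),
                          maf=mafs)
    return geno, ann


LOF_MASK = MaskDefinition("lof", ("LOF",), maf_ceiling=0.5)


class TestCollapse:
    def test_toy_carrier_enumeration(self):
        geno, ann = _rare([[0, 1], [1, 0], [0, 0], [1, 1]],
                          genes=["G1", "G1"], classes=["LOF", "LOF"])
        res = bt.collapse_gene(geno, ann, "G1", LOF_MASK)
        assert list(res.carrier) == [1, 1, 0, 1]
        assert res.n_carriers == 3
        assert res.n_variants == 2

    def test_mask_excluding_all_classes_gives_empty(self):
        geno, ann = _rare([[1], [0]], genes=["G1"], classes=["missense-benign"])
        res = bt.collapse_gene(geno, ann, "G1", LOF_MASK)
        assert res.n_variants == 0
        assert not res.carrier.any()

    def test_maf_ceiling_below_all_variants_flagged_empty(self):
        geno, ann = _rare([[1], [1]], genes=["G1"], classes=["LOF"], mafs=[0.25])
        mask = MaskDefinition("tight", ("LOF",), maf_ceiling=0.01)
        res = bt.collapse_gene(geno, ann, "G1", mask)
        assert res.n_variants == 0

    def test_singleton_mask_keeps_single_allele_variants_only(self):
        geno, ann = _rare([[1, 1], [0, 1], [0, 0]],
                          genes=["G1", "G1"], classes=["LOF", "LOF"])
        mask = MaskDefinition("single", ("LOF",), singleton_only=True)
        res = bt.collapse_gene(geno, ann, "G1", mask)
        assert res.n_variants == 1          # only the first variant is a singleton
        assert list(res.carrier) == [1, 0, 0]

    def test_homozygous_counts_as_carrier_but_not_het(self):
        geno, ann = _rare([[2], [1], [0]], genes=["G1"], classes=["LOF"])
        res = bt.collapse_gene(geno, ann, "G1", LOF_MASK)
        assert res.n_carriers == 2
        assert res.n_het_carriers == 1

    def test_collapsing_order_independent(self, rng):
        g = rng.binomial(1, 0.05, size=(30, 6))
        geno, ann = _rare(g, genes=["G1"] * 6, classes=["LOF"] * 6)
        perm = rng.permutation(6)
        geno2, ann2 = _rare(g[:, perm], genes=["G1"] * 6, classes=["LOF"] * 6)
        r1 = bt.collapse_gene(geno, ann, "G1", LOF_MASK)
        r2 = bt.collapse_gene(geno2, ann2, "G1", LOF_MASK)
        assert np.array_equal(r1.carrier, r2.carrier)

    def test_absent_gene_raises(self):
        geno, ann = _rare([[1]], genes=["G1"], classes=["LOF"])
        with pytest.raises(KeyError):
            bt.collapse_gene(geno, ann, "NOPE", LOF_MASK)


class TestBurdenTest:
    def test_matches_closed_form_ols(self):
        carrier = np.array([1, 0, 1, 0, 0, 1], dtype=np.int8)
        y = np.array([1.2, 0.1, 0.9, -0.3, 0.2, 1.5])
        res = bt.burden_test(
            CollapseResult("G1", "lof", carrier, 3, 3, 2), y)
        beta, se = ols_closed_form(y, carrier.astype(float))
        assert res.beta == pytest.approx(beta, rel=1e-12)
        assert res.se == pytest.approx(se, rel=1e-12)

    def test_degenerate_carrier_vector_flagged(self):
        res = bt.burden_test(
            CollapseResult("G1", "lof", np.zeros(5, np.int8), 0, 0, 0),
            np.arange(5.0))
        assert res.p == 1.0
        assert "degenerate_carrier_vector" in res.filter_reasons


class TestFilters:
    def _result(self, p, het=50, mask="lof"):
        return bt.BurdenResult("G1", mask, het + 1, het, 3, 0.5, 0.1, p)

    def test_bonferroni_threshold_reproduction(self):
        # alpha 0.05 over 17,857 genes x 1 phenotype -> 2.8e-6
        thr = 0.05 / (17857 * 1)
        assert thr == pytest.approx(2.8e-6, rel=1e-3)
        hit = bt.filter_hits([self._result(2.7e-6)], n_genes=17857)[0]
        miss = bt.filter_hits([self._result(2.9e-6)], n_genes=17857)[0]
        assert hit.hit and not miss.hit

    def test_exactly_twenty_het_carriers_removed(self):
        res = bt.filter_hits([self._result(1e-10, het=20)], n_genes=100)[0]
        assert not res.hit
        assert any("het_carriers" in r for r in res.filter_reasons)
        res21 = bt.filter_hits([self._result(1e-10, het=21)], n_genes=100)[0]
        assert res21.hit

    def test_singleton_mask_hit_removed_regardless_of_p(self):
        masks = DEFAULT_MASKS
        res = bt.filter_hits([self._result(1e-10, mask="singleton_lof")],
                             n_genes=100, masks=masks)[0]
        assert not res.hit
        assert "ultra_rare_mask" in res.filter_reasons

    def test_ultra_rare_maf_ceiling_mask_removed(self):
        res = bt.filter_hits([self._result(1e-10, mask="lof_pathogenic_rare")],
                             n_genes=100)[0]
        assert not res.hit
        assert "ultra_rare_mask" in res.filter_reasons

    def test_no_silent_drops(self):
        results = [self._result(1e-10), self._result(0.5),
                   self._result(1e-10, het=5)]
        out = bt.filter_hits(results, n_genes=100)
        assert len(out) == len(results)
        for r in out:
            assert r.hit or r.filter_reasons

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            bt.filter_hits([], n_genes=0)

    def test_gene_summary_keeps_smallest_corrected_p(self):
        a = bt.BurdenResult("G1", "lof", 40, 40, 3, 0.5, 0.1, 1e-8,
                            p_corrected=1e-6, hit=True)
        b = bt.BurdenResult("G1", "lof_pathogenic", 60, 60, 5, 0.5, 0.1, 1e-10,
                            p_corrected=1e-8, hit=True)
        summ = gene_summary([a, b])
        assert len(summ) == 1
        assert summ["p_corrected"].iloc[0] == 1e-8


def test_planted_gene_effect_survives_and_small_carrier_count_filtered(rng):
    n = 2000
    # gene A: ~60 carriers, gene B: 10 carriers; both shifted by +1 SD
    gA = rng.binomial(1, 0.015, size=(n, 2))
    gB = np.zeros((n, 1), np.int8)
    gB[rng.choice(n, 10, replace=False), 0] = 1
    geno, ann = _rare(np.column_stack([gA, gB]),
                      genes=["GA", "GA", "GB"], classes=["LOF"] * 3)
    y = rng.standard_normal(n)
    y += (np.column_stack([gA, gB]).sum(axis=1) > 0) * 0.0
    carrierA = gA.sum(axis=1) > 0
    carrierB = gB[:, 0] > 0
    y = y + 1.0 * carrierA + 1.0 * carrierB
    res = bt.filter_hits(
        [bt.burden_test(bt.collapse_gene(geno, ann, g, LOF_MASK), y)
         for g in ("GA", "GB")],
        n_genes=17857, masks=[LOF_MASK])
    byg = {r.gene: r for r in res}
    assert byg["GA"].hit
    assert not byg["GB"].hit  # 10 carriers: below the support filter
    assert results_table(res).shape[0] == 2
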