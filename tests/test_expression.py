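"""RPKM, expressed filter, BH, the NB differential test, bound classification
and subfamily enrichment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from teomics.expression import (
    CountMatrix,
    benjamini_hochberg,
    classify_bound,
    compute_rpkm,
    differential_test,
    family_enrichment,
    filter_expressed,
)
from teomics.genome import GenomicInterval, Peak, TEElement


def make_cm(counts: np.ndarray, lengths=None, conditions=("Ctrl", "Ctrl", "KO", "KO")):
    n, m = counts.shape
    cols = [f"{c}_{i}" for i, c in enumerate(conditions)]
    idx = pd.Index([f"f{i}" for i in range(n)], name="feature_id")
    return CountMatrix(
        counts=pd.DataFrame(counts, index=idx, columns=cols),
        lengths=pd.Series(lengths if lengths is not None else 1000, index=idx),
        samples=pd.DataFrame(
            {"condition": list(conditions), "state": "primed"}, index=pd.Index(cols)
        ),
    )


class TestRpkm:
    def test_unit_definition(self):
        cm = make_cm(np.array([[10], [999_990]]), lengths=[1000, 1000], conditions=("Ctrl",))
        rpkm = compute_rpkm(cm)
        assert rpkm.iloc[0, 0] == pytest.approx(10.0)

    def test_zero_count_gives_zero(self):
        cm = make_cm(np.array([[0], [50]]), conditions=("Ctrl",))
        assert compute_rpkm(cm).iloc[0, 0] == 0.0

    def test_matches_scalar_loop(self, rng):
        counts = rng.integers(0, 500, size=(50, 4))
        lengths = rng.integers(200, 5000, size=50)
        cm = make_cm(counts, lengths=lengths)
        rpkm = compute_rpkm(cm)
        lib = counts.sum(axis=0)
        for i in range(50):
            for j in range(4):
                expect = counts[i, j] / (lengths[i] / 1e3) / (lib[j] / 1e6)
                assert rpkm.iloc[i, j] == pytest.approx(expect)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            compute_rpkm(make_cm(np.array([[0], [0]]), conditions=("Ctrl",)))


class TestFilterExpressed:
    def test_strictly_greater_than_threshold(self):
        # feature maxima {0, 5, 10, 11, 100, 10}: only 11 and 100 pass
        maxima = [0, 5, 10, 11, 100, 10]
        counts = np.zeros((6, 4), dtype=int)
        counts[:, 2] = maxima
        kept = filter_expressed(make_cm(counts), threshold=10)
        assert list(kept) == ["f3", "f4"]

    def test_all_zero_feature_excluded(self):
        kept = filter_expressed(make_cm(np.zeros((3, 4), dtype=int)))
        assert len(kept) == 0


class TestBenjaminiHochberg:
    def test_single_pvalue_unchanged(self):
        assert benjamini_hochberg([0.04])[0] == pytest.approx(0.04)

    def test_hand_stepup(self):
        got = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_matches_formula_oracle_and_statsmodels(self, rng):
        p = rng.random(1000)
        got = benjamini_hochberg(p)
        m = len(p)
        order = np.argsort(p)
        # direct formula: adj_i = min_{k: p_k >= p_i rank} (m p_(k) / k)
        sorted_p = p[order]
        oracle_sorted = np.array(
            [np.min(m * sorted_p[i:] / np.arange(i + 1, m + 1)) for i in range(m)]
        )
        oracle = np.empty(m)
        oracle[order] = np.minimum(oracle_sorted, 1.0)
        assert np.allclose(got, oracle)
        from statsmodels.stats.multitest import multipletests

        assert np.allclose(got, multipletests(p, method="fdr_bh")[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


def nb_counts(mean, disp, rng):
    r = 1.0 / disp
    return rng.negative_binomial(r, r / (r + mean))


def null_matrix(n, mu, disp, seed, floor=None):
    rng = np.random.default_rng(seed)
    base = mu * rng.lognormal(-0.18, 0.6, size=n)
    if floor is not None:
        base = np.maximum(base, floor)
    return base, np.stack([nb_counts(base, disp, rng) for _ in range(4)], axis=1), rng


class TestDifferentialTest:
    def test_identical_groups_all_unchanged(self):
        counts = np.tile(np.array([[20], [100], [400]]), (1, 4))
        res = differential_test(make_cm(counts))
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["status"] == "unchanged").all()

    def test_invariant_to_column_order_and_global_scaling(self):
        _, counts, _ = null_matrix(300, 50, 0.1, seed=5)
        cm = make_cm(counts)
        res = differential_test(cm)

        shuffled = cm.counts[["KO_3", "Ctrl_0", "KO_2", "Ctrl_1"]]
        cm2 = CountMatrix(counts=shuffled, lengths=cm.lengths, samples=cm.samples)
        res2 = differential_test(cm2)
        assert np.allclose(res["log2fc"], res2["log2fc"])
        assert np.allclose(res["pvalue"], res2["pvalue"])

        # global scaling: compare on all features so the expressed filter
        # (which sees larger raw counts) does not change the tested set;
        # the zero-safety pseudocount leaves an O(pc/mean) wobble in log2fc
        cm3 = make_cm(counts * 3)
        res3 = differential_test(cm3, dispersion=0.1, expressed_threshold=None)
        res1d = differential_test(cm, dispersion=0.1, expressed_threshold=None)
        assert np.allclose(res1d["log2fc"], res3["log2fc"], atol=0.05)
        assert (res1d["status"] == res3["status"]).all()

    def test_status_partition_exhaustive_and_consistent(self):
        _, counts, rng = null_matrix(500, 50, 0.05, seed=9)
        counts[:40, 2:] *= 8
        res = differential_test(make_cm(counts))
        assert set(res["status"]) <= {"up", "down", "unchanged"}
        up = (res["log2fc"] >= 1) & (res["fdr"] < 0.05)
        down = (res["log2fc"] <= -1) & (res["fdr"] < 0.05)
        assert ((res["status"] == "up") == up).all()
        assert ((res["status"] == "down") == down).all()

    def test_missing_condition_rejected(self):
        cm = make_cm(np.ones((5, 2), dtype=int), conditions=("Ctrl", "Ctrl"))
        with pytest.raises(ValueError):
            differential_test(cm)

    def test_null_type_i_error_within_band(self):
        """Raw p < 0.05 fraction in [0.03, 0.07] on 2,000 null NB features."""
        _, counts, _ = null_matrix(2000, 50, 0.1, seed=11)
        res = differential_test(make_cm(counts))
        frac = float((res["pvalue"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_planted_fold_recovery(self):
        """>= 90 of 100 planted 4-fold features at mean >= 50 called up."""
        base, counts, rng = null_matrix(2000, 50, 0.04, seed=12, floor=50)
        ko = nb_counts(np.where(np.arange(2000) < 100, base * 4, base), 0.04, rng)
        counts[:, 2] = ko
        counts[:, 3] = nb_counts(
            np.where(np.arange(2000) < 100, base * 4, base), 0.04, rng
        )
        res = differential_test(make_cm(counts))
        recovered = (res["status"].iloc[:100] == "up").sum()
        assert recovered >= 90


def te(eid, start, end, family="HERVH", subfamily="HERVH-int", chrom="chr1"):
    return TEElement(
        interval=GenomicInterval(chrom, start, end, "+"),
        subfamily=subfamily, family=family, class_="LTR", element_id=eid,
    )


class TestClassifyBound:
    def test_no_peaks_nothing_bound(self):
        flags = classify_bound([te("a", 0, 100)], [], expressed={"a"})
        assert not flags.any()

    def test_unexpressed_element_not_bound(self):
        peaks = [Peak(interval=GenomicInterval("chr1", 50, 80))]
        flags = classify_bound([te("a", 0, 100)], peaks, expressed=set())
        assert not flags["a"]

    def test_generator_planted_bound_hervh_recovered_exactly(self, default_ds):
        """All 81 planted TRIM28-bound HERVH of 1,400 expressed recovered."""
        ds = default_ds
        expressed = filter_expressed(ds.rna, 10)
        flags = classify_bound(ds.annotation.tes, ds.chip_peaks, expressed)
        hervh = [t.element_id for t in ds.annotation.tes if t.family == "HERVH"]
        assert len(hervh) == 1400
        got = {eid for eid in hervh if flags[eid]}
        assert got == set(ds.truth.bound_te_ids["HERVH"])
        assert len(got) == 81


class TestFamilyEnrichment:
    def make_inputs(self):
        tes = [te(f"A.{i}", 1000 * i + 10, 1000 * i + 500, subfamily="A") for i in range(5)]
        tes += [te(f"B.{i}", 100_000 + 1000 * i, 100_000 + 1000 * i + 500, subfamily="B")
                for i in range(15)]
        ids = [t.element_id for t in tes]
        detes = [f"A.{i}" for i in range(4)] + [f"B.{i}" for i in range(6)]
        diff = pd.DataFrame(
            {
                "log2fc": 1.5,
                "status": ["up" if i in detes else "unchanged" for i in ids],
            },
            index=pd.Index(ids, name="feature_id"),
        )
        rpkm = pd.DataFrame(
            {"Ctrl_1": 10.0, "Ctrl_2": 10.0, "KO_1": 40.0, "KO_2": 40.0}, index=diff.index
        )
        samples = pd.DataFrame(
            {"condition": ["Ctrl", "Ctrl", "KO", "KO"], "state": "primed"},
            index=pd.Index(rpkm.columns),
        )
        return diff, tes, rpkm, samples

    def test_hypergeometric_matches_enumeration(self):
        """4 of 10 DETEs in a 5-member subfamily of a 20-element universe."""
        diff, tes, rpkm, samples = self.make_inputs()
        enr = family_enrichment(diff, tes, rpkm, samples)
        # exhaustive: P(X >= 4), X hypergeom(M=20, K=5, n=10)
        from math import comb

        expect = sum(
            comb(5, k) * comb(15, 10 - k) for k in range(4, 6)
        ) / comb(20, 10)
        assert enr.loc["A", "representation_p"] == pytest.approx(expect)
        assert enr.loc["A", "n_dete"] == 4 and enr.loc["A", "n_total"] == 5

    def test_equal_means_give_zero_fold(self):
        diff, tes, rpkm, samples = self.make_inputs()
        rpkm[:] = 7.0
        enr = family_enrichment(diff, tes, rpkm, samples)
        assert enr["expr_fold"].abs().max() == pytest.approx(0.0)

    def test_primed_generator_ranks_hervh_sva_above_hervk(self, default_ds, default_diff):
        ds = default_ds
        rpkm = compute_rpkm(ds.rna)
        enr = family_enrichment(default_diff, ds.annotation.tes, rpkm, ds.rna.samples)
        assert enr.loc["HERVH-int", "expr_fold"] > 1.0
        assert enr.loc["SVA_D", "expr_fold"] > 1.0
        if "HERVK-int" in enr.index:
            assert enr.loc["HERVK-int", "expr_fold"] < min(
                enr.loc["HERVH-int", "expr_fold"], enr.loc["SVA_D", "expr_fold"]
            )


class TestBoundGroupFoldChanges:
    def test_bound_hervk_null_while_hervh_sva_derepressed(self, default_ds, default_diff):
        """Planted primed-state pattern: bound HERVK ~0, HERVH/SVA > +1."""
        ds, diff = default_ds, default_diff
        for family, low, high in (("HERVK", -0.2, 0.2), ("HERVH", 1.0, 10), ("SVA", 1.0, 10)):
            ids = [i for i in ds.truth.bound_te_ids[family] if i in diff.index]
            mean_lfc = diff.loc[ids, "log2fc"].mean()
            assert low < mean_lfc < high, family
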