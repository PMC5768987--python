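"""Metaprofiles, differential accessibility, peak turnover, overlap partition
and promoter switches."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from teomics.accessibility import (
    accessibility_methylation_correlation,
    binding_overlap_partition,
    differential_accessibility,
    metaprofile,
    peak_turnover,
    promoter_switch,
)
from teomics.expression import CountMatrix
from teomics.genome import GenomicInterval, Peak, TEElement
from teomics.methylation import CpGIndex, pool_replicates, region_methylation
from teomics.signal import SignalTrack


def te(eid, start, end, strand="+", family="HERVH", chrom="chr1"):
    return TEElement(
        interval=GenomicInterval(chrom, start, end, strand),
        subfamily=f"{family}-int", family=family, class_="LTR", element_id=eid,
    )


def peak(start, end, chrom="chr1", name=None):
    return Peak(interval=GenomicInterval(chrom, start, end), score=1.0, name=name)


class TestMetaprofile:
    def test_uniform_track_gives_flat_profile(self):
        track = SignalTrack.from_intervals([("chr1", 0, 1_000_000, 3.0)])
        prof = metaprofile([te("a", 100_000, 105_000), te("b", 200_000, 201_000, "-")], track)
        assert np.allclose(prof.mean_signal, 3.0)
        assert prof.n_elements == 2

    def test_hand_built_bins_single_element(self):
        track = SignalTrack.from_intervals(
            [("chr1", 95_000, 100_000, 2.0), ("chr1", 100_000, 101_000, 6.0)]
        )
        prof = metaprofile(
            [te("a", 100_000, 101_000)], track, flank_bp=5000, body_bins=10, flank_bins=5
        )
        assert np.allclose(prof.mean_signal[:5], 2.0)   # upstream flank
        assert np.allclose(prof.mean_signal[5:15], 6.0)  # body
        assert np.allclose(prof.mean_signal[15:], 0.0)   # downstream uncovered

    def test_linearity_in_the_track(self, default_ds):
        ds = default_ds
        members = [
            t for t in ds.annotation.tes
            if t.element_id in ds.truth.bound_te_ids["HERVH"]
        ][:30]
        t1, t2 = ds.atac_tracks["Ctrl"], ds.atac_tracks["KO"]
        p1 = metaprofile(members, t1)
        p2 = metaprofile(members, t2)
        psum = metaprofile(members, t1 + t2)
        assert np.allclose(psum.mean_signal, p1.mean_signal + p2.mean_signal)

    def test_minus_strand_orientation(self):
        # signal only upstream (genomic right) of a minus-strand element
        track = SignalTrack.from_intervals([("chr1", 201_000, 206_000, 5.0)])
        prof = metaprofile(
            [te("a", 200_000, 201_000, strand="-")], track, 5000, 10, 5
        )
        assert np.allclose(prof.mean_signal[:5], 5.0)  # biological upstream
        assert np.allclose(prof.mean_signal[5:], 0.0)

    def test_empty_element_set_rejected(self):
        track = SignalTrack.from_intervals([("chr1", 0, 1000, 1.0)])
        with pytest.raises(ValueError):
            metaprofile([], track)

    def test_planted_atac_gain_offset_recovered(self, default_ds):
        """KO-minus-Ctrl profile peaks in the flank bin holding -2 kb."""
        ds = default_ds
        gained = {g["te_id"] for g in ds.truth.gained_te}
        members = [t for t in ds.annotation.tes if t.element_id in gained]
        prof_c = metaprofile(members, ds.atac_tracks["Ctrl"])
        prof_k = metaprofile(members, ds.atac_tracks["KO"])
        delta = prof_k.mean_signal - prof_c.mean_signal
        argmax = int(np.argmax(delta[: prof_c.flank_bins]))  # upstream flank
        offsets = prof_c.upstream_bin_offsets()
        expected_bin = int(np.argmin(np.abs(offsets + 2000)))
        assert abs(argmax - expected_bin) <= 1
        assert int(np.argmax(delta)) == argmax  # global max is in the flank


def atac_cm(ctrl_means, ko_means, disp, seed):
    rng = np.random.default_rng(seed)
    r = 1.0 / disp
    def draw(m):
        return rng.negative_binomial(r, r / (r + m))
    idx = pd.Index([f"r{i}" for i in range(len(ctrl_means))], name="feature_id")
    counts = pd.DataFrame(
        {
            "Ctrl_1": draw(ctrl_means), "Ctrl_2": draw(ctrl_means),
            "KO_1": draw(ko_means), "KO_2": draw(ko_means),
        },
        index=idx,
    )
    return CountMatrix(
        counts=counts,
        lengths=pd.Series(500, index=idx),
        samples=pd.DataFrame(
            {"condition": ["Ctrl", "Ctrl", "KO", "KO"], "state": "primed"},
            index=pd.Index(counts.columns),
        ),
    )


class TestDifferentialAccessibility:
    def test_identical_columns_nothing_significant(self):
        means = np.full(200, 80.0)
        cm = atac_cm(means, means, 0.05, seed=3)
        cm.counts["KO_1"] = cm.counts["Ctrl_1"]
        cm.counts["KO_2"] = cm.counts["Ctrl_2"]
        res = differential_accessibility(cm)
        assert not res["significant"].any()

    def test_double_threshold_semantics(self):
        means = np.full(400, 100.0)
        ko = means.copy()
        ko[:50] = 100.0 * 16
        res = differential_accessibility(atac_cm(means, ko, 0.05, seed=4))
        lfc_cut = np.log2(8.0)
        expect = (res["log2fc_atac"].abs() >= lfc_cut) & (res["pvalue"] < 0.05)
        assert (res["significant"] == expect).all()
        # a 7.9-fold region fails the >= 8 threshold no matter how small its p
        below = res[(res["log2fc_atac"].abs() < lfc_cut) & (res["pvalue"] < 0.001)]
        assert not below["significant"].any()

    def test_planted_fold16_recovery(self):
        """>= 45 of 50 planted 16-fold regions recovered, <= 5% false calls."""
        means = np.full(1050, 100.0)
        ko = means.copy()
        ko[:50] = 1600.0
        res = differential_accessibility(atac_cm(means, ko, 0.05, seed=5))
        gained = res["significant"] & (res["log2fc_atac"] > 0)
        assert int(gained.iloc[:50].sum()) >= 45
        assert float(res["significant"].iloc[50:].mean()) <= 0.05


class TestPeakTurnover:
    def test_identical_sets_all_stable(self):
        peaks = [peak(0, 100), peak(500, 700)]
        t = peak_turnover(peaks, peaks)
        assert (t["turnover_class"] == "stable").all()

    def test_disjoint_sets_counted_by_definition(self):
        ctrl = [peak(i * 1000, i * 1000 + 100) for i in range(3)]
        ko = [peak(50_000 + i * 1000, 50_000 + i * 1000 + 100) for i in range(4)]
        t = peak_turnover(ctrl, ko)
        assert (t["turnover_class"] == "gained").sum() == 4
        assert (t["turnover_class"] == "lost").sum() == 3

    def test_unmerged_input_rejected(self):
        with pytest.raises(ValueError, match="merge"):
            peak_turnover([peak(0, 100), peak(50, 150)], [])

    def test_matches_bruteforce_on_random_sets(self, rng):
        def random_merged(n, offset):
            starts = np.sort(rng.choice(np.arange(0, 500_000, 400), n, replace=False))
            return [peak(int(s) + offset, int(s) + offset + 300) for s in starts]

        ctrl, ko = random_merged(300, 0), random_merged(300, 150)
        t = peak_turnover(ctrl, ko)
        ko_rows = t[t["peak_set"] == "KO"].reset_index(drop=True)
        for i, p in enumerate(ko):
            expect = (
                "stable"
                if any(p.interval.overlap_bp(c.interval) >= 1 for c in ctrl)
                else "gained"
            )
            assert ko_rows.loc[i, "turnover_class"] == expect

    def test_accounting_identity(self):
        ctrl = [peak(0, 100), peak(1000, 1100), peak(5000, 5100)]
        ko = [peak(50, 160), peak(7000, 7100)]
        t = peak_turnover(ctrl, ko)
        n = len(t)
        assert n == len(ctrl) + len(ko)
        counts = t["turnover_class"].value_counts()
        assert counts.get("gained", 0) + counts.get("lost", 0) + counts.get("stable", 0) == n


class TestOverlapPartition:
    def test_paper_worked_example_rounds_to_6(self):
        """477 of 7,885 bound regions gained -> 6% after rounding."""
        sites = [peak(i * 2000, i * 2000 + 500) for i in range(7885)]
        gained = [GenomicInterval("chr1", i * 2000 + 100, i * 2000 + 300) for i in range(477)]
        part = binding_overlap_partition(sites, gained)
        assert (part.n_bound_total, part.n_bound_gained) == (7885, 477)
        assert part.percent_display == 6

    def test_disjoint_sets_zero_bound_gained(self):
        sites = [peak(0, 100)]
        part = binding_overlap_partition(sites, [GenomicInterval("chr1", 5000, 5100)])
        assert part.n_bound_gained == 0
        assert part.n_gained_unbound == 1

    def test_hand_fixture_partition(self):
        """20 sites / 10 gains with 4 planted overlaps -> (4, 6), 20%."""
        sites = [peak(i * 10_000, i * 10_000 + 500) for i in range(20)]
        gains = [GenomicInterval("chr1", i * 10_000 + 200, i * 10_000 + 400) for i in range(4)]
        gains += [GenomicInterval("chr2", i * 1000, i * 1000 + 100) for i in range(6)]
        part = binding_overlap_partition(sites, gains)
        assert (part.n_bound_gained, part.n_gained_unbound) == (4, 6)
        assert part.percent_display == 20

    def test_percent_scale_free_under_duplication(self):
        sites = [peak(i * 10_000, i * 10_000 + 500) for i in range(20)]
        gains = [GenomicInterval("chr1", i * 10_000 + 200, i * 10_000 + 400) for i in range(4)]
        p1 = binding_overlap_partition(sites, gains)
        # duplicate the geometry on another chromosome with the same overlaps
        sites2 = sites + [
            Peak(interval=GenomicInterval("chr2", pk.interval.start, pk.interval.end))
            for pk in sites
        ]
        gains2 = gains + [GenomicInterval("chr2", g.start, g.end) for g in gains]
        p2 = binding_overlap_partition(sites2, gains2)
        assert p2.percent_bound_gained == pytest.approx(p1.percent_bound_gained)


class TestPromoterSwitch:
    def test_accessible_in_both_is_unchanged(self):
        prom = {"g1": GenomicInterval("chr1", 0, 2500)}
        pk = [peak(100, 300)]
        table, _ = promoter_switch(prom, pk, pk, {"g1": 10.0}, {"g1": 12.0})
        assert table.iloc[0]["class"] == "unchanged"

    def test_uncovered_promoters_excluded(self):
        prom = {"g1": GenomicInterval("chr1", 0, 2500)}
        table, _ = promoter_switch(prom, [], [], {"g1": float("nan")}, {"g1": 50.0})
        assert len(table) == 0

    def test_planted_closed_promoter_methylation_shift(self, default_ds):
        """Closed promoters move ~10% -> ~80% methylation (within 5 points)."""
        ds = default_ds
        meth = {
            "Ctrl": pool_replicates([ds.methylomes["Ctrl_1"], ds.methylomes["Ctrl_2"]]),
            "KO": pool_replicates([ds.methylomes["KO_1"], ds.methylomes["KO_2"]]),
        }
        proms = {g.gene_id: g.promoter for g in ds.annotation.genes}
        idx_c, idx_k = CpGIndex(meth["Ctrl"]), CpGIndex(meth["KO"])
        mc = {g: region_methylation(idx_c, r, 3).percent for g, r in proms.items()}
        mk = {g: region_methylation(idx_k, r, 3).percent for g, r in proms.items()}
        table, summary = promoter_switch(
            proms, ds.atac_ctrl_peaks, ds.atac_ko_peaks, mc, mk
        )
        closed = summary[summary["class"] == "closed"].iloc[0]
        assert abs(closed["mean_meth_ctrl"] - 10.0) <= 5.0
        assert abs(closed["mean_meth_ko"] - 80.0) <= 5.0
        # planted closed genes really classify as closed
        got_closed = set(table.loc[table["class"] == "closed", "gene_id"])
        assert set(ds.truth.closed_promoter_genes) <= got_closed

    def test_accessibility_inversely_correlated_with_methylation(self, default_ds):
        ds = default_ds
        meth = {
            "Ctrl": pool_replicates([ds.methylomes["Ctrl_1"], ds.methylomes["Ctrl_2"]]),
            "KO": pool_replicates([ds.methylomes["KO_1"], ds.methylomes["KO_2"]]),
        }
        proms = {g.gene_id: g.promoter for g in ds.annotation.genes}
        idx_c, idx_k = CpGIndex(meth["Ctrl"]), CpGIndex(meth["KO"])
        mc = {g: region_methylation(idx_c, r, 3).percent for g, r in proms.items()}
        mk = {g: region_methylation(idx_k, r, 3).percent for g, r in proms.items()}
        table, _ = promoter_switch(proms, ds.atac_ctrl_peaks, ds.atac_ko_peaks, mc, mk)
        assert accessibility_methylation_correlation(table) < 0
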