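"""TE-anchored metaprofiles, differential accessibility, and peak turnover.

Metaprofiles average signal over strand-oriented anchor bins (fixed-width
flanks, scaled element body) with an unweighted per-element mean.  The
differential-accessibility test reuses the NB machinery on peak-region
counts with the double threshold fold change >= 8 and p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import CountMatrix, differential_test
from .genome import GenomicInterval, IntervalIndex, Peak, TEElement, anchor_bins
from .signal import SignalTrack

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 5000
DEFAULT_BODY_BINS = 50
DEFAULT_FLANK_BINS = 25
DEFAULT_ATAC_FC = 8.0
DEFAULT_ATAC_P = 0.05


@dataclass(frozen=True)
class MetaProfile:
    """Mean signal per anchor bin over a set of elements.

    Bins 0..F-1 are the upstream flank, F..F+B-1 the scaled body,
    F+B..F+2B-1 the downstream flank; the anchors (element 5' and 3'
    ends) sit at bin indices F and F+B.
    """

    bin_labels: tuple[str, ...]
    mean_signal: np.ndarray
    n_elements: int
    flank_bins: int
    body_bins: int
    flank_bp: int

    @property
    def anchor_positions(self) -> tuple[int, int]:
        return self.flank_bins, self.flank_bins + self.body_bins

    def upstream_bin_offsets(self) -> np.ndarray:
        """Genomic offset (bp, negative) of each upstream-flank bin center."""
        w = self.flank_bp / self.flank_bins
        return -self.flank_bp + w * (np.arange(self.flank_bins) + 0.5)


def _bin_labels(flank_bins: int, body_bins: int, flank_bp: int) -> tuple[str, ...]:
    w = flank_bp / flank_bins
    up = [f"up{-flank_bp + w * (i + 0.5):.0f}" for i in range(flank_bins)]
    body = [f"body{i}" for i in range(body_bins)]
    down = [f"down{w * (i + 0.5):.0f}" for i in range(flank_bins)]
    return tuple(up + body + down)


def metaprofile(
    elements,
    track: SignalTrack,
    flank_bp: int = DEFAULT_FLANK_BP,
    body_bins: int = DEFAULT_BODY_BINS,
    flank_bins: int = DEFAULT_FLANK_BINS,
    *,
    chroms: set[str] | None = None,
) -> MetaProfile:
    """Unweighted per-element mean profile over anchor bins.

    Elements shorter than ``body_bins`` bp are excluded (logged); pass
    ``chroms`` to restrict to placed chromosomes.
    """
    total = np.zeros(2 * flank_bins + body_bins)
    n = 0
    skipped = 0
    for el in elements:
        iv = el.interval if isinstance(el, TEElement) else el
        if chroms is not None and iv.chrom not in chroms:
            continue
        if iv.length < body_bins:
            skipped += 1
            continue
        ab = anchor_bins(el, flank_bp, body_bins, flank_bins)
        total += [track.mean(ab.chrom, s, e) for s, e in ab.bins]
        n += 1
    if skipped:
        logger.info("metaprofile: skipped %d elements shorter than %d bp", skipped, body_bins)
    if n == 0:
        raise ValueError("no usable elements for metaprofile")
    return MetaProfile(
        bin_labels=_bin_labels(flank_bins, body_bins, flank_bp),
        mean_signal=total / n,
        n_elements=n,
        flank_bins=flank_bins,
        body_bins=body_bins,
        flank_bp=flank_bp,
    )


def metaprofile_table(profiles: dict[str, MetaProfile]) -> pd.DataFrame:
    """Combine named profiles into one tidy table (bin index, label, means)."""
    first = next(iter(profiles.values()))
    df = pd.DataFrame({"bin": range(len(first.bin_labels)), "label": first.bin_labels})
    for name, prof in profiles.items():
        df[f"mean_{name}"] = prof.mean_signal
        df[f"n_{name}"] = prof.n_elements
    return df


def differential_accessibility(
    atac_counts: CountMatrix,
    regions: dict[str, GenomicInterval] | None = None,
    *,
    fc_threshold: float = DEFAULT_ATAC_FC,
    p_threshold: float = DEFAULT_ATAC_P,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-region NB test with the double threshold |FC| >= 8 and p < 0.05.

    Significance uses the raw p-value (not FDR) per the double-threshold
    convention; ``turnover_class`` from the sign of significant changes.
    """
    res = differential_test(
        atac_counts,
        expressed_threshold=None,
        dispersion=dispersion,
        fc_threshold=fc_threshold,
        fdr_threshold=1.1,  # status column unused here
    )
    lfc_cut = np.log2(fc_threshold)
    res = res.rename(columns={"log2fc": "log2fc_atac"})
    res["significant"] = (res["log2fc_atac"].abs() >= lfc_cut) & (
        res["pvalue"] < p_threshold
    )
    res["turnover_class"] = np.where(
        res["significant"] & (res["log2fc_atac"] > 0),
        "gained",
        np.where(res["significant"], "lost", "stable"),
    )
    res = res.drop(columns=["status"])
    if regions:
        res["chrom"] = [regions[f].chrom if f in regions else "." for f in res.index]
        res["start"] = [regions[f].start if f in regions else -1 for f in res.index]
        res["end"] = [regions[f].end if f in regions else -1 for f in res.index]
    return res


def _check_merged(peaks: list[Peak], label: str) -> None:
    by: dict[str, list[Peak]] = {}
    for p in peaks:
        by.setdefault(p.interval.chrom, []).append(p)
    for chrom, ps in by.items():
        ps.sort(key=lambda p: p.interval.start)
        for a, b in zip(ps, ps[1:]):
            if b.interval.start < a.interval.end:
                raise ValueError(
                    f"{label}: overlapping peaks within one set on {chrom}; merge first"
                )


def peak_turnover(
    ctrl_peaks: list[Peak], ko_peaks: list[Peak], min_bp: int = 1
) -> pd.DataFrame:
    """Classify peaks as gained (KO-only), lost (Ctrl-only) or stable.

    Both input sets must be internally non-overlapping (pre-merged).
    Returns one row per input peak with columns chrom/start/end/set/class.
    """
    _check_merged(ctrl_peaks, "ctrl_peaks")
    _check_merged(ko_peaks, "ko_peaks")
    ctrl_idx = IntervalIndex([p.interval for p in ctrl_peaks])
    ko_idx = IntervalIndex([p.interval for p in ko_peaks])
    rows = []
    for p in ko_peaks:
        cls = "stable" if ctrl_idx.any_overlap(p.interval, min_bp) else "gained"
        rows.append((p.interval.chrom, p.interval.start, p.interval.end, "KO", cls))
    for p in ctrl_peaks:
        cls = "stable" if ko_idx.any_overlap(p.interval, min_bp) else "lost"
        rows.append((p.interval.chrom, p.interval.start, p.interval.end, "Ctrl", cls))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_set", "turnover_class"])


@dataclass(frozen=True)
class OverlapPartition:
    """Venn partition of binding sites against gained-accessibility regions."""

    n_bound_total: int
    n_bound_gained: int
    n_gained_unbound: int

    @property
    def percent_bound_gained(self) -> float:
        if self.n_bound_total == 0:
            return float("nan")
        return 100.0 * self.n_bound_gained / self.n_bound_total

    @property
    def percent_display(self) -> int:
        """Nearest-integer percentage for report display."""
        return int(round(self.percent_bound_gained))


def binding_overlap_partition(
    binding_sites: list[Peak],
    gained_regions: list[GenomicInterval],
    min_bp: int = 1,
) -> OverlapPartition:
    """Partition gained regions by overlap with binding sites (Venn counts)."""
    gained_idx = IntervalIndex(gained_regions)
    n_bound_gained = sum(
        1 for p in binding_sites if gained_idx.any_overlap(p.interval, min_bp)
    )
    site_idx = IntervalIndex([p.interval for p in binding_sites])
    n_gained_unbound = sum(
        1 for r in gained_regions if not site_idx.any_overlap(r, min_bp)
    )
    return OverlapPartition(
        n_bound_total=len(binding_sites),
        n_bound_gained=n_bound_gained,
        n_gained_unbound=n_gained_unbound,
    )


def promoter_switch(
    promoters: dict[str, GenomicInterval],
    ctrl_peaks: list[Peak],
    ko_peaks: list[Peak],
    meth_ctrl: dict[str, float],
    meth_ko: dict[str, float],
    min_bp: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Promoter accessibility switches with per-class mean methylation.

    A promoter is accessible in a condition iff it overlaps >= 1 peak of
    that condition; classes: opened (inaccessible -> accessible in KO),
    closed, unchanged.  Promoters without covered CpGs (NaN methylation)
    are excluded and logged.  Returns (per-promoter table, per-class
    mean-methylation summary).
    """
    ctrl_idx = IntervalIndex([p.interval for p in ctrl_peaks])
    ko_idx = IntervalIndex([p.interval for p in ko_peaks])
    rows = []
    n_excluded = 0
    for gene_id, region in promoters.items():
        mc = meth_ctrl.get(gene_id, float("nan"))
        mk = meth_ko.get(gene_id, float("nan"))
        if np.isnan(mc) or np.isnan(mk):
            n_excluded += 1
            continue
        acc_c = ctrl_idx.any_overlap(region, min_bp)
        acc_k = ko_idx.any_overlap(region, min_bp)
        if acc_c and not acc_k:
            cls = "closed"
        elif acc_k and not acc_c:
            cls = "opened"
        else:
            cls = "unchanged"
        rows.append(
            {
                "gene_id": gene_id,
                "accessible_ctrl": acc_c,
                "accessible_ko": acc_k,
                "meth_ctrl": mc,
                "meth_ko": mk,
                "class": cls,
            }
        )
    if n_excluded:
        logger.info("promoter_switch: excluded %d promoters with no covered CpGs", n_excluded)
    columns = [
        "gene_id", "accessible_ctrl", "accessible_ko", "meth_ctrl", "meth_ko", "class",
    ]
    table = pd.DataFrame(rows, columns=columns)
    summary = (
        table.groupby("class")[["meth_ctrl", "meth_ko"]]
        .agg(["mean", "count"])
        .reset_index()
    )
    summary.columns = ["class", "mean_meth_ctrl", "n_ctrl", "mean_meth_ko", "n_ko"]
    return table, summary


def accessibility_methylation_correlation(table: pd.DataFrame) -> float:
    """Spearman correlation between accessibility and methylation per condition.

    Pools (accessible indicator, methylation) pairs from both conditions;
    expected negative when open promoters are unmethylated.
    """
    acc = np.concatenate(
        [table["accessible_ctrl"].astype(float), table["accessible_ko"].astype(float)]
    )
    meth = np.concatenate([table["meth_ctrl"], table["meth_ko"]])
    rho, _ = stats.spearmanr(acc, meth)
    return float(rho)
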