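"""CpG methylation: common-CpG pairing, region/global levels, DMRs, ICRs.

Methylation percentages are coverage-weighted throughout:
percent = 100 * sum(meth) / sum(meth + unmeth) over the contributing CpGs.
DMRs are called on fixed genome-wide windows with pooled per-condition
counts, a two-sided Fisher exact test, BH correction, and a minimum
methylation difference; adjacent same-direction windows are merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomicInterval

DEFAULT_MIN_COV = 5
DEFAULT_DMR_WINDOW = 1000
DEFAULT_DMR_MIN_CPGS = 4
DEFAULT_DMR_MIN_DELTA = 20.0
DEFAULT_DMR_ALPHA = 0.05
DEFAULT_ICR_LOSS_THRESHOLD = 30.0


@dataclass(frozen=True)
class ICRPanelEntry:
    """An imprinting control region with its parent-of-origin label."""

    name: str
    region: GenomicInterval
    parent: str

    def __post_init__(self) -> None:
        if self.parent not in ("maternal", "paternal"):
            raise ValueError(f"{self.name}: parent must be maternal or paternal")


@dataclass(frozen=True)
class RegionMethylation:
    region: GenomicInterval
    percent: float  # NaN when n_cpgs < min_cpgs
    n_cpgs: int
    total_coverage: int


def _require_sorted(cpgs: pd.DataFrame, label: str) -> None:
    key = cpgs[["chrom", "pos"]]
    if not (
        key.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        .equals(key.reset_index(drop=True))
    ):
        raise ValueError(f"{label}: CpG records must be sorted by (chrom, pos)")


def pool_replicates(replicates: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum methylated/unmethylated counts across replicate CpG tables."""
    merged = pd.concat(replicates, ignore_index=True)
    out = (
        merged.groupby(["chrom", "pos", "strand"], as_index=False)[["meth", "unmeth"]]
        .sum()
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )
    return out


def common_cpgs(
    a: pd.DataFrame, b: pd.DataFrame, min_cov: int = DEFAULT_MIN_COV
) -> pd.DataFrame:
    """CpG positions present in both samples with coverage >= min_cov in each.

    Returns a frame with chrom, pos, strand, meth_a, unmeth_a, meth_b,
    unmeth_b, sorted by (chrom, pos).  Symmetric up to column naming.
    """
    _require_sorted(a, "a")
    _require_sorted(b, "b")
    merged = a.merge(b, on=["chrom", "pos", "strand"], suffixes=("_a", "_b"))
    cov_a = merged["meth_a"] + merged["unmeth_a"]
    cov_b = merged["meth_b"] + merged["unmeth_b"]
    out = merged[(cov_a >= min_cov) & (cov_b >= min_cov)].reset_index(drop=True)
    return out


class CpGIndex:
    """O(log n) coverage-weighted region sums over a sorted CpG table."""

    def __init__(self, cpgs: pd.DataFrame):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in cpgs.groupby("chrom", sort=False):
            pos = grp["pos"].values.astype(np.int64)
            order = np.argsort(pos, kind="stable")
            pos = pos[order]
            meth = grp["meth"].values.astype(np.int64)[order]
            cov = meth + grp["unmeth"].values.astype(np.int64)[order]
            self._by_chrom[chrom] = (
                pos,
                np.concatenate([[0], np.cumsum(meth)]),
                np.concatenate([[0], np.cumsum(cov)]),
            )

    def region_sums(self, region: GenomicInterval) -> tuple[int, int, int]:
        """(n_cpgs, sum_meth, sum_coverage) of CpGs inside [start, end)."""
        if region.chrom not in self._by_chrom:
            return 0, 0, 0
        pos, cum_meth, cum_cov = self._by_chrom[region.chrom]
        lo = int(np.searchsorted(pos, region.start, side="left"))
        hi = int(np.searchsorted(pos, region.end, side="left"))
        return hi - lo, int(cum_meth[hi] - cum_meth[lo]), int(cum_cov[hi] - cum_cov[lo])


def region_methylation(
    cpgs: pd.DataFrame | CpGIndex,
    region: GenomicInterval,
    min_cpgs: int = 1,
) -> RegionMethylation:
    """Weighted percent methylation over a region; NaN below min_cpgs CpGs."""
    index = cpgs if isinstance(cpgs, CpGIndex) else CpGIndex(cpgs)
    n, meth, cov = index.region_sums(region)
    if n < min_cpgs or cov == 0:
        return RegionMethylation(region, float("nan"), n, cov)
    return RegionMethylation(region, 100.0 * meth / cov, n, cov)


def global_methylation(pairs: pd.DataFrame) -> tuple[float, float]:
    """Weighted percent methylation per sample over the common-CpG pairing."""
    if len(pairs) == 0:
        raise ValueError("empty common-CpG pairing")
    pct_a = 100.0 * pairs["meth_a"].sum() / (pairs["meth_a"] + pairs["unmeth_a"]).sum()
    pct_b = 100.0 * pairs["meth_b"].sum() / (pairs["meth_b"] + pairs["unmeth_b"]).sum()
    return float(pct_a), float(pct_b)


def call_dmrs(
    pairs: pd.DataFrame,
    *,
    window_bp: int = DEFAULT_DMR_WINDOW,
    min_cpgs: int = DEFAULT_DMR_MIN_CPGS,
    min_delta: float = DEFAULT_DMR_MIN_DELTA,
    alpha: float = DEFAULT_DMR_ALPHA,
) -> pd.DataFrame:
    """Fixed-window DMRs between the two pooled conditions in ``pairs``.

    Per window the (meth, unmeth) counts of each condition are pooled into
    a 2x2 table tested with a two-sided Fisher exact test; windows with
    BH FDR < alpha and |delta| >= min_delta (percentage points, B - A) are
    DMRs, and adjacent same-direction DMR windows are merged.  Direction
    is hyper (in B) iff delta > 0.
    """
    rows = []
    for chrom, grp in pairs.groupby("chrom", sort=True):
        win = grp["pos"].values // window_bp
        agg = grp.groupby(win)[["meth_a", "unmeth_a", "meth_b", "unmeth_b"]].sum()
        n = grp.groupby(win).size()
        agg = agg[n >= min_cpgs]
        n = n[n >= min_cpgs]
        for w, r in agg.iterrows():
            rows.append(
                (
                    chrom,
                    int(w) * window_bp,
                    (int(w) + 1) * window_bp,
                    int(n.loc[w]),
                    int(r["meth_a"]),
                    int(r["unmeth_a"]),
                    int(r["meth_b"]),
                    int(r["unmeth_b"]),
                )
            )
    if not rows:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_cpgs", "delta", "pvalue", "fdr", "direction"]
        )
    tab = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_cpgs", "meth_a", "unmeth_a", "meth_b", "unmeth_b"],
    )
    pct_a = 100.0 * tab["meth_a"] / (tab["meth_a"] + tab["unmeth_a"])
    pct_b = 100.0 * tab["meth_b"] / (tab["meth_b"] + tab["unmeth_b"])
    tab["delta"] = pct_b - pct_a
    pvals = np.ones(len(tab))
    for i, r in enumerate(tab.itertuples()):
        pvals[i] = stats.fisher_exact(
            [[r.meth_a, r.unmeth_a], [r.meth_b, r.unmeth_b]], alternative="two-sided"
        )[1]
    tab["pvalue"] = pvals
    tab["fdr"] = _bh(pvals)
    sig = tab[(tab["fdr"] < alpha) & (tab["delta"].abs() >= min_delta)].copy()
    sig["direction"] = np.where(sig["delta"] > 0, "hyper", "hypo")
    return _merge_adjacent(sig)


def _bh(p: np.ndarray) -> np.ndarray:
    from .expression import benjamini_hochberg

    return benjamini_hochberg(p)


def _merge_adjacent(windows: pd.DataFrame) -> pd.DataFrame:
    """Merge touching same-chromosome, same-direction DMR windows."""
    out = []
    cur = None
    for r in windows.sort_values(["chrom", "start"]).itertuples():
        if (
            cur is not None
            and r.chrom == cur["chrom"]
            and r.start == cur["end"]
            and r.direction == cur["direction"]
        ):
            w_old = cur["end"] - cur["start"]
            w_new = r.end - r.start
            cur["delta"] = (cur["delta"] * cur["n_cpgs"] + r.delta * r.n_cpgs) / (
                cur["n_cpgs"] + r.n_cpgs
            )
            cur["n_cpgs"] += r.n_cpgs
            cur["end"] = r.end
            cur["pvalue"] = min(cur["pvalue"], r.pvalue)
            cur["fdr"] = min(cur["fdr"], r.fdr)
        else:
            if cur is not None:
                out.append(cur)
            cur = {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_cpgs": r.n_cpgs,
                "delta": r.delta,
                "pvalue": r.pvalue,
                "fdr": r.fdr,
                "direction": r.direction,
            }
    if cur is not None:
        out.append(cur)
    return pd.DataFrame(
        out,
        columns=["chrom", "start", "end", "n_cpgs", "delta", "pvalue", "fdr", "direction"],
    )


def icr_report(
    panel: list[ICRPanelEntry],
    cpg_sets: dict[str, pd.DataFrame],
    *,
    min_cpgs: int = 1,
    ctrl: str = "Ctrl",
    ko: str = "KO",
    loss_threshold: float = DEFAULT_ICR_LOSS_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ICR percent methylation per sample with parent-group means.

    Returns (per_icr, summary).  ``per_icr`` has one row per panel entry
    with percent columns per sample, the KO - Ctrl delta, and a
    ``meth_lost`` flag set when the delta is below -loss_threshold
    (paternal-demethylation detection).  ``summary`` holds the
    maternal/paternal group means per sample.
    """
    if not panel:
        raise ValueError("empty ICR panel")
    indexes = {name: CpGIndex(df) for name, df in cpg_sets.items()}
    rows = []
    for entry in panel:
        row: dict = {"name": entry.name, "parent": entry.parent,
                     "chrom": entry.region.chrom, "start": entry.region.start,
                     "end": entry.region.end}
        for sample, idx in indexes.items():
            rm = region_methylation(idx, entry.region, min_cpgs)
            row[f"percent_{sample}"] = rm.percent
            row[f"n_cpgs_{sample}"] = rm.n_cpgs
        rows.append(row)
    per_icr = pd.DataFrame(rows)
    if f"percent_{ctrl}" in per_icr and f"percent_{ko}" in per_icr:
        per_icr["delta"] = per_icr[f"percent_{ko}"] - per_icr[f"percent_{ctrl}"]
        per_icr["meth_lost"] = per_icr["delta"] < -loss_threshold
    summary = (
        per_icr.groupby("parent")[[c for c in per_icr.columns if c.startswith("percent_")]]
        .mean()
        .reset_index()
    )
    return per_icr, summary
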