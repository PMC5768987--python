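"""Cross-omic analyses: DETE-neighbor-gene correlation and ZNF 3'-exon enrichment.

Each differentially expressed TE is paired with its single nearest
differentially expressed gene within a distance window (one pair per TE,
deterministic tie-break), and the Pearson correlation of the signed log2
fold changes is reported per window and TE-class subset.  The ZNF test
compares mean ChIP signal over the 3'-most exons of differentially
expressed zinc-finger genes against size-matched draws from expression-
stable ZNFs (|log2fc| < 0.1) with an add-one permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneModel, GenomicInterval, IntervalIndex
from .signal import SignalTrack

DEFAULT_WINDOWS = (5000, 10000, 20000)
CONTROL_LFC_MAX = 0.1
MIN_PAIRS = 3


def neighbor_pairs(
    te_table: pd.DataFrame,
    gene_table: pd.DataFrame,
    window_bp: int,
) -> pd.DataFrame:
    """One nearest-DEG pair per DETE within ``window_bp``.

    Both tables need columns feature_id, chrom, start, end, log2fc.
    Distance is the gap in bp (0 when overlapping).
    """
    gene_ivs = [
        GenomicInterval(r.chrom, r.start, r.end) for r in gene_table.itertuples()
    ]
    idx = IntervalIndex(gene_ivs, ids=list(gene_table["feature_id"]))
    rows = []
    for r in te_table.itertuples():
        hit = idx.nearest(GenomicInterval(r.chrom, r.start, r.end), window_bp)
        if hit is None:
            continue
        gi, dist = hit
        rows.append(
            {
                "te_id": r.feature_id,
                "gene_id": gene_table["feature_id"].iloc[gi],
                "distance": dist,
                "te_log2fc": r.log2fc,
                "gene_log2fc": gene_table["log2fc"].iloc[gi],
            }
        )
    return pd.DataFrame(
        rows, columns=["te_id", "gene_id", "distance", "te_log2fc", "gene_log2fc"]
    )


def neighbor_correlation(
    te_table: pd.DataFrame,
    gene_table: pd.DataFrame,
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
    subsets: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Pearson r of (TE, nearest-gene) log2 fold changes per window/subset.

    ``subsets`` maps a label to a boolean mask over te_table rows (e.g.
    all-LTR, HERV-only); the full set is always reported as 'all'.
    Results with fewer than 3 pairs are NA.
    """
    masks: dict[str, pd.Series] = {"all": pd.Series(True, index=te_table.index)}
    if subsets:
        masks.update(subsets)
    rows = []
    for window in windows:
        for label, mask in masks.items():
            pairs = neighbor_pairs(te_table[mask], gene_table, window)
            if len(pairs) >= MIN_PAIRS:
                r, _ = stats.pearsonr(pairs["te_log2fc"], pairs["gene_log2fc"])
                r = float(r)
            else:
                r = float("nan")
            rows.append(
                {"window_bp": window, "subset": label, "r": r, "n_pairs": len(pairs)}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ZNFEnrichment:
    gene_set_label: str
    observed_mean_signal: float
    null_means: np.ndarray
    n_permutations: int

    @property
    def p_perm(self) -> float:
        """Add-one permutation p-value; never exactly 0."""
        return (1 + int(np.sum(self.null_means >= self.observed_mean_signal))) / (
            self.n_permutations + 1
        )


def znf_enrichment(
    znf_genes: list[GeneModel],
    chip_track: SignalTrack,
    de_set: set[str],
    lfc: dict[str, float],
    *,
    n_permutations: int = 999,
    control_lfc_max: float = CONTROL_LFC_MAX,
    rng: np.random.Generator | None = None,
    label: str = "DE-ZNF",
) -> ZNFEnrichment:
    """Permutation test of ChIP signal on 3'-most exons of DE ZNFs.

    Observed statistic: mean signal over each DE gene's 3'-most exon.
    Null: the same statistic on size-matched random draws from ZNFs whose
    |log2fc| < control_lfc_max (expression-stable controls).
    """
    if len(znf_genes) < 10:
        raise ValueError("need >= 10 genes in the ZNF universe")
    rng = rng or np.random.default_rng()
    signal = {}
    for g in znf_genes:
        ex = g.three_prime_exon()
        signal[g.gene_id] = chip_track.mean(ex.chrom, ex.start, ex.end)
    de_ids = [g.gene_id for g in znf_genes if g.gene_id in de_set]
    control_ids = [
        g.gene_id
        for g in znf_genes
        if g.gene_id not in de_set and abs(lfc.get(g.gene_id, 0.0)) < control_lfc_max
    ]
    if len(control_ids) < len(de_ids):
        raise ValueError(
            f"control pool ({len(control_ids)}) smaller than DE set ({len(de_ids)})"
        )
    observed = float(np.mean([signal[g] for g in de_ids]))
    ctrl_vals = np.array([signal[g] for g in control_ids])
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = ctrl_vals[rng.choice(len(ctrl_vals), size=len(de_ids), replace=False)].mean()
    return ZNFEnrichment(
        gene_set_label=label,
        observed_mean_signal=observed,
        null_means=null,
        n_permutations=n_permutations,
    )
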