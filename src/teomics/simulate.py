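"""Synthetic multi-omic data with planted ground truth.

Generates every input the pipeline consumes — TE/gene/ICR annotation, TRIM28
ChIP peaks and signal, RNA counts, ATAC peaks/counts/signal, and per-CpG
bisulfite methylomes — with the statistical structure the analysis assumes:

* NB RNA counts with planted fold changes on TRIM28-bound HERVH/SVA in the
  primed state (bound HERVK null) and on HERVK/SVA/LTR7 in the naive state;
* family-specific ChIP geometry (HERVH 5'-biased, HERVK both ends, SVA
  body-wide) and TRIM28 enrichment at paternal but not maternal ICRs;
* KO-gained ATAC peaks whose accessibility bump is centred 2 kb upstream of
  the bound TE's 5' anchor, plus promoter accessibility switches coupled to
  methylation switches;
* beta-binomial methylomes with a per-state global target (primed ~80%,
  naive ~42%), hemimethylated (~50%) maternal ICRs, KO-demethylated paternal
  ICRs, and planted 40-point hypomethylated windows at bound TEs;
* neighbour genes whose fold changes couple to nearby planted TEs with a
  distance-decaying strength.

Every output is deterministic for a given :class:`SimulationConfig` (each
stage derives its own `numpy` generator from the seed), and the planted
effects are returned as a :class:`GroundTruth` for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .expression import CountMatrix
from .genome import GeneModel, GenomicInterval, Peak, TEElement, promoter_of
from .methylation import ICRPanelEntry
from .signal import SignalTrack


@dataclass(frozen=True)
class SubfamilySpec:
    subfamily: str
    family: str
    class_: str
    n: int
    min_len: int
    max_len: int


DEFAULT_SUBFAMILIES = (
    SubfamilySpec("HERVH-int", "HERVH", "LTR", 1400, 2000, 5000),
    SubfamilySpec("HERVK-int", "HERVK", "LTR", 500, 1500, 4000),
    SubfamilySpec("SVA_D", "SVA", "Retroposon", 700, 800, 2500),
    SubfamilySpec("LTR7", "LTR7", "LTR", 300, 400, 500),
    SubfamilySpec("L1HS", "L1", "LINE", 600, 500, 4000),
    SubfamilySpec("AluY", "Alu", "SINE", 500, 280, 320),
)

# study-anchored bound counts: 81 of 1,400 expressed HERVH, 169 HERVK, 293 SVA
DEFAULT_BOUND_FRACTION = {
    "HERVH": 81 / 1400,
    "HERVK": 169 / 500,
    "SVA": 293 / 700,
    "LTR7": 0.4,
    "L1": 0.05,
    "Alu": 0.0,
}

PRIMED_EFFECTS = {"HERVH": 2.0, "SVA": 2.0, "LTR7": 1.5, "HERVK": 0.0}
NAIVE_EFFECTS = {"HERVK": 2.0, "SVA": 2.0, "LTR7": 2.0, "HERVH": 0.0}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic multi-omic dataset."""

    seed: int
    genome: dict[str, int] = field(
        default_factory=lambda: {"chr1": 12_000_000, "chr2": 12_000_000}
    )
    mode: str = "primed"  # primed | naive
    subfamilies: tuple[SubfamilySpec, ...] = DEFAULT_SUBFAMILIES
    bound_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BOUND_FRACTION)
    )
    effect_log2fc: dict[str, float] | None = None  # per family; mode default if None
    effect_sd: float = 0.75  # per-element spread of planted log2fc (truncated >= 1)
    n_replicates: int = 2
    mean_count: float = 50.0  # TE baseline NB mean
    gene_mean_count: float = 100.0
    baseline_sigma: float = 0.6  # lognormal spread of per-feature baselines
    baseline_floor: float = 30.0  # floor for HERVH/HERVK/SVA/LTR7 (keeps them expressed)
    low_expression_scale: dict[str, float] = field(
        default_factory=lambda: {"L1": 0.5, "Alu": 0.3}
    )
    nb_dispersion: float = 0.04
    n_genes: int = 1100
    gene_min_len: int = 3000
    gene_max_len: int = 8000
    n_znf: int = 400
    n_znf_de: int = 50
    znf_chip_fold: float = 2.0
    # methylome
    n_cpgs: int = 180_000
    coverage_mean: float = 15.0
    meth_bb_rho: float = 0.05
    meth_global_target: dict[str, float] | None = None  # per condition; mode default
    n_icr_maternal: int = 29
    icr_len: int = 2000
    maternal_icr_level: float = 0.5
    paternal_icr_ctrl: float = 0.8
    paternal_icr_ko: float = 0.2
    n_dmr: int = 30
    dmr_window_bp: int = 1000
    dmr_min_sites: int = 6
    dmr_ctrl_level: float = 0.8
    dmr_ko_level: float = 0.4
    # ATAC
    n_background_peaks: int = 2000
    background_peak_len: int = 500
    n_gained_te: int = 50
    n_gained_background: int = 150
    n_lost_background: int = 50
    n_closed_promoters: int = 121
    n_opened_promoters: int = 40
    atac_gain_offset_bp: int = 2000
    atac_gain_width: int = 400
    atac_background_mean: float = 100.0
    atac_fold: float = 16.0
    atac_dispersion: float = 0.05
    closed_prom_meth: tuple[float, float] = (0.10, 0.80)  # Ctrl, KO
    opened_prom_meth: tuple[float, float] = (0.80, 0.10)
    # neighbour-gene coupling
    coupling_decay: float = 7000.0
    coupling_noise_sd: float = 0.3
    coupling_max_dist: int = 20_000
    min_feature_gap: int = 400

    def __post_init__(self) -> None:
        if self.mode not in ("primed", "naive"):
            raise ValueError("mode must be primed or naive")
        self.subfamilies = tuple(
            s
            if isinstance(s, SubfamilySpec)
            else SubfamilySpec(**s)
            if isinstance(s, dict)
            else SubfamilySpec(*s)
            for s in self.subfamilies
        )
        if isinstance(self.closed_prom_meth, list):
            self.closed_prom_meth = tuple(self.closed_prom_meth)
        if isinstance(self.opened_prom_meth, list):
            self.opened_prom_meth = tuple(self.opened_prom_meth)
        if self.effect_log2fc is None:
            self.effect_log2fc = dict(
                PRIMED_EFFECTS if self.mode == "primed" else NAIVE_EFFECTS
            )
        if self.meth_global_target is None:
            self.meth_global_target = (
                {"Ctrl": 0.80, "KO": 0.80}
                if self.mode == "primed"
                else {"Ctrl": 0.42, "KO": 0.50}
            )
        for frac in self.bound_fraction.values():
            if not 0.0 <= frac <= 1.0:
                raise ValueError("bound fractions must lie in [0, 1]")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass
class Annotation:
    genome: dict[str, int]
    tes: list[TEElement]
    genes: list[GeneModel]
    icrs: list[ICRPanelEntry]
    cpg_sites: dict[str, np.ndarray] = field(default_factory=dict)

    def te_by_id(self) -> dict[str, TEElement]:
        return {t.element_id: t for t in self.tes}

    def gene_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}


@dataclass
class GroundTruth:
    """Planted effects; the oracle for all recovery tests."""

    bound_te_ids: dict[str, list[str]] = field(default_factory=dict)  # family -> ids
    planted_te_log2fc: dict[str, float] = field(default_factory=dict)  # nonzero only
    coupled_gene_log2fc: dict[str, float] = field(default_factory=dict)
    coupled_gene_distance: dict[str, float] = field(default_factory=dict)
    znf_ids: list[str] = field(default_factory=list)
    znf_de_ids: list[str] = field(default_factory=list)
    planted_dmr_regions: list[tuple[GenomicInterval, float]] = field(default_factory=list)
    imprint_state: dict[str, dict[str, float]] = field(default_factory=dict)
    closed_promoter_genes: list[str] = field(default_factory=list)
    opened_promoter_genes: list[str] = field(default_factory=list)
    gained_te: list[dict] = field(default_factory=list)  # te_id, center, anchor, strand
    gained_background: list[GenomicInterval] = field(default_factory=list)
    lost_background: list[GenomicInterval] = field(default_factory=list)

    def all_bound_ids(self) -> list[str]:
        return [i for ids in self.bound_te_ids.values() for i in ids]

    def planted_dete_ids(self) -> list[str]:
        return sorted(self.planted_te_log2fc)

    def hypo_meth_regions(self) -> list[GenomicInterval]:
        """All regions planted to lose methylation in the KO."""
        return [r for r, _ in self.planted_dmr_regions]


# ------------------------------------------------------------------ annotation


def _place_features(
    lengths: list[int], genome: dict[str, int], gap: int, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Non-overlapping placement with >= gap bp between features."""
    order = rng.permutation(len(lengths))
    chroms = list(genome)
    totals = np.array([genome[c] for c in chroms], dtype=float)
    # greedily assign shuffled features to chromosomes proportional to size
    budgets = {c: genome[c] * 0.92 for c in chroms}
    assigned: dict[str, list[int]] = {c: [] for c in chroms}
    used = {c: 0.0 for c in chroms}
    for i in order:
        probs = np.array([max(budgets[c] - used[c], 0.0) for c in chroms])
        if probs.sum() <= 0:
            raise ValueError("genome too small to place requested features")
        c = chroms[int(rng.choice(len(chroms), p=probs / probs.sum()))]
        assigned[c].append(int(i))
        used[c] += lengths[i] + gap
    out: list[tuple[str, int, int] | None] = [None] * len(lengths)
    for c in chroms:
        idxs = assigned[c]
        total_len = sum(lengths[i] for i in idxs)
        free = genome[c] - total_len - gap * (len(idxs) + 1)
        if free < 0:
            raise ValueError("genome too small to place requested features")
        cuts = np.sort(rng.random(len(idxs) + 1))
        extra = np.diff(np.concatenate([[0.0], cuts / cuts[-1]])) * free if len(idxs) else []
        pos = 0
        for k, i in enumerate(idxs):
            pos += gap + int(extra[k])
            out[i] = (c, pos, pos + lengths[i])
            pos += lengths[i]
    return out  # type: ignore[return-value]


def _make_exons(
    iv: GenomicInterval, rng: np.random.Generator
) -> tuple[GenomicInterval, ...]:
    n_exons = int(rng.integers(2, 7))
    # 2*n_exons - 1 alternating exon/intron blocks spanning the gene
    cuts = np.sort(rng.choice(np.arange(1, iv.length), size=2 * n_exons - 2, replace=False))
    bounds = np.concatenate([[0], cuts, [iv.length]])
    exons = []
    for k in range(0, len(bounds) - 1, 2):
        s, e = int(bounds[k]), int(bounds[k + 1])
        if e > s:
            exons.append(GenomicInterval(iv.chrom, iv.start + s, iv.start + e, iv.strand))
    return tuple(exons)


def simulate_annotation(config: SimulationConfig) -> tuple[Annotation, GroundTruth]:
    """Place TEs, genes and ICRs; choose every planted effect deterministically."""
    rng = config.rng(1)
    te_specs: list[SubfamilySpec] = []
    te_lengths: list[int] = []
    for spec in config.subfamilies:
        for _ in range(spec.n):
            te_specs.append(spec)
            te_lengths.append(int(rng.integers(spec.min_len, spec.max_len + 1)))
    gene_lengths = [
        int(rng.integers(config.gene_min_len, config.gene_max_len + 1))
        for _ in range(config.n_genes)
    ]
    icr_names = [f"mICR{i + 1:02d}" for i in range(config.n_icr_maternal)] + [
        "IG-DMR",
        "H19-ICR",
    ]
    icr_lengths = [config.icr_len] * len(icr_names)

    placed = _place_features(
        te_lengths + gene_lengths + icr_lengths,
        config.genome,
        config.min_feature_gap,
        rng,
    )
    n_te, n_gene = len(te_lengths), len(gene_lengths)

    tes: list[TEElement] = []
    counters: dict[str, int] = {}
    for spec, (chrom, start, end) in zip(te_specs, placed[:n_te]):
        strand = "+" if rng.random() < 0.5 else "-"
        k = counters.get(spec.subfamily, 0)
        counters[spec.subfamily] = k + 1
        tes.append(
            TEElement(
                interval=GenomicInterval(chrom, start, end, strand),
                subfamily=spec.subfamily,
                family=spec.family,
                class_=spec.class_,
                element_id=f"{spec.subfamily}.{k}",
            )
        )
    tes.sort(key=lambda t: (t.interval.chrom, t.interval.start))

    genes: list[GeneModel] = []
    znf_slots = set(
        rng.choice(n_gene, size=min(config.n_znf, n_gene), replace=False).tolist()
    )
    n_znf_seen = 0
    for j, (chrom, start, end) in enumerate(placed[n_te : n_te + n_gene]):
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval(chrom, start, end, strand)
        if j in znf_slots:
            n_znf_seen += 1
            gid = f"ZNF{n_znf_seen:03d}"
        else:
            gid = f"GENE{j + 1:04d}"
        genes.append(GeneModel(gene_id=gid, interval=iv, exons=_make_exons(iv, rng)))
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start))

    icrs = [
        ICRPanelEntry(
            name=name,
            region=GenomicInterval(chrom, start, end),
            parent="paternal" if name in ("IG-DMR", "H19-ICR") else "maternal",
        )
        for name, (chrom, start, end) in zip(icr_names, placed[n_te + n_gene :])
    ]

    # CpG sites are fixed at annotation time and shared by every sample
    chroms = sorted(config.genome)
    weights = np.array([config.genome[c] for c in chroms], dtype=float)
    n_per = rng.multinomial(config.n_cpgs, weights / weights.sum())
    cpg_sites = {
        c: np.sort(rng.choice(config.genome[c], size=n, replace=False))
        for c, n in zip(chroms, n_per)
    }
    ann = Annotation(
        genome=dict(config.genome), tes=tes, genes=genes, icrs=icrs, cpg_sites=cpg_sites
    )
    truth = GroundTruth()
    _plan_effects(config, ann, truth, config.rng(2))
    return ann, truth


def _plan_effects(
    config: SimulationConfig,
    ann: Annotation,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> None:
    # bound TEs per family (exact planted counts)
    by_family: dict[str, list[TEElement]] = {}
    for te in ann.tes:
        by_family.setdefault(te.family, []).append(te)
    for family, members in sorted(by_family.items()):
        frac = config.bound_fraction.get(family, 0.0)
        n_bound = int(round(frac * len(members)))
        if n_bound == 0:
            continue
        chosen = rng.choice(len(members), size=n_bound, replace=False)
        truth.bound_te_ids[family] = sorted(members[i].element_id for i in chosen)

    # planted expression effects on bound elements of affected families
    for family, ids in truth.bound_te_ids.items():
        effect = config.effect_log2fc.get(family, 0.0)
        if effect == 0.0:
            continue
        for eid in ids:
            lfc = effect + config.effect_sd * rng.standard_normal()
            truth.planted_te_log2fc[eid] = float(max(lfc, 1.0))

    # neighbour-gene coupling with distance decay
    te_by_id = ann.te_by_id()
    planted = [(eid, te_by_id[eid]) for eid in sorted(truth.planted_te_log2fc)]
    for gene in ann.genes:
        if gene.gene_id.startswith("ZNF"):
            continue
        best: tuple[float, str] | None = None
        for eid, te in planted:
            gap = gene.interval.gap_to(te.interval)
            if gap is None or gap > config.coupling_max_dist:
                continue
            if best is None or gap < best[0]:
                best = (gap, eid)
        if best is None:
            continue
        gap, eid = best
        lfc = truth.planted_te_log2fc[eid] * float(
            np.exp(-gap / config.coupling_decay)
        ) + config.coupling_noise_sd * rng.standard_normal()
        truth.coupled_gene_log2fc[gene.gene_id] = float(lfc)
        truth.coupled_gene_distance[gene.gene_id] = float(gap)

    # ZNF DE set with planted upregulation (kept out of the coupled set)
    truth.znf_ids = sorted(g.gene_id for g in ann.genes if g.gene_id.startswith("ZNF"))
    eligible = [g for g in truth.znf_ids if g not in truth.coupled_gene_log2fc]
    n_de = min(config.n_znf_de, len(eligible))
    chosen = rng.choice(len(eligible), size=n_de, replace=False)
    truth.znf_de_ids = sorted(eligible[i] for i in chosen)
    for gid in truth.znf_de_ids:
        truth.coupled_gene_log2fc[gid] = float(max(2.0 + 0.5 * rng.standard_normal(), 1.2))

    # imprint states
    for icr in ann.icrs:
        if icr.parent == "maternal":
            truth.imprint_state[icr.name] = {
                "Ctrl": config.maternal_icr_level,
                "KO": config.maternal_icr_level,
            }
        else:
            truth.imprint_state[icr.name] = {
                "Ctrl": config.paternal_icr_ctrl,
                "KO": config.paternal_icr_ko,
            }

    # planted hypomethylated DMR windows at bound TEs (window-grid aligned)
    delta = 100.0 * (config.dmr_ko_level - config.dmr_ctrl_level)
    dmr_pool_families = ["HERVK"] if config.mode == "primed" else ["SVA", "HERVK"]
    candidates = []
    for fam in dmr_pool_families:
        candidates.extend(truth.bound_te_ids.get(fam, []))
    w = config.dmr_window_bp
    for eid in candidates:
        iv = te_by_id[eid].interval
        win_start = ((iv.start + w - 1) // w) * w
        if win_start + w <= iv.end:
            sites = ann.cpg_sites.get(iv.chrom, np.array([]))
            n_sites = int(
                np.searchsorted(sites, win_start + w) - np.searchsorted(sites, win_start)
            )
            if n_sites >= config.dmr_min_sites:
                truth.planted_dmr_regions.append(
                    (GenomicInterval(iv.chrom, win_start, win_start + w), delta)
                )
        if len(truth.planted_dmr_regions) >= config.n_dmr:
            break

    # promoter accessibility/methylation switches on non-coupled ordinary
    # genes; switch promoters must not touch each other or any ICR, so the
    # methylation overrides they imply never collide with the imprint model
    gene_by_id = ann.gene_by_id()
    pool = [
        g.gene_id
        for g in ann.genes
        if g.gene_id not in truth.coupled_gene_log2fc and g.gene_id.startswith("GENE")
    ]
    taken: dict[str, list[tuple[int, int]]] = {}
    for icr in ann.icrs:
        taken.setdefault(icr.region.chrom, []).append((icr.region.start, icr.region.end))
    # keep switch promoters clear of prospective KO-gained ATAC regions around
    # bound TEs of the planted-effect families (gain bump + shoulder + slop)
    margin = config.atac_gain_offset_bp + config.atac_gain_width // 2 + 300
    for family, ids in truth.bound_te_ids.items():
        if config.effect_log2fc.get(family, 0.0) <= 0:
            continue
        for eid in ids:
            iv = te_by_id[eid].interval
            taken.setdefault(iv.chrom, []).append((iv.start - margin, iv.end + margin))
    switch: list[str] = []
    n_switch = config.n_closed_promoters + config.n_opened_promoters
    for i in rng.permutation(len(pool)):
        prom = gene_by_id[pool[i]].promoter
        spans = taken.setdefault(prom.chrom, [])
        if any(prom.start < e and s < prom.end for s, e in spans):
            continue
        spans.append((prom.start, prom.end))
        switch.append(pool[i])
        if len(switch) >= n_switch:
            break
    truth.closed_promoter_genes = sorted(switch[: config.n_closed_promoters])
    truth.opened_promoter_genes = sorted(switch[config.n_closed_promoters :])


# ------------------------------------------------------------------------ ChIP


def _te_anchor(te: TEElement) -> tuple[int, int]:
    """(5' anchor, 3' anchor) genomic positions, strand aware."""
    iv = te.interval
    return (iv.start, iv.end) if iv.strand != "-" else (iv.end, iv.start)


def simulate_chip(
    ann: Annotation, truth: GroundTruth, config: SimulationConfig
) -> tuple[list[Peak], SignalTrack]:
    """TRIM28 peaks with family-specific geometry plus a signal track.

    HERVH-type: one 5'-biased peak; HERVK-type: peaks at both ends;
    SVA/LTR7: body-wide; paternal ICRs only (maternal ICRs unbound).
    """
    te_by_id = ann.te_by_id()
    peaks: list[Peak] = []
    half = 300
    for family, ids in sorted(truth.bound_te_ids.items()):
        for eid in ids:
            te = te_by_id[eid]
            iv = te.interval
            a5, a3 = _te_anchor(te)
            if family in ("HERVH", "L1"):
                regions = [(a5 - half, a5 + half)]
            elif family == "HERVK":
                regions = [(a5 - half, a5 + half), (a3 - half, a3 + half)]
            else:  # SVA, LTR7, other body-binders
                regions = [(iv.start, iv.end)]
            for s, e in regions:
                peaks.append(
                    Peak(
                        interval=GenomicInterval(iv.chrom, max(0, s), e, iv.strand),
                        score=5.0,
                        name=f"T28_{eid}",
                    )
                )
    for icr in ann.icrs:
        if icr.parent == "paternal":
            peaks.append(Peak(interval=icr.region, score=5.0, name=f"T28_{icr.name}"))
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))

    baseline = SignalTrack.from_intervals(
        (c, 0, length, 0.2) for c, length in ann.genome.items()
    )
    bumps = [(p.interval.chrom, p.interval.start, p.interval.end, 1.0) for p in peaks]
    # planted 3'-exon enrichment on DE ZNFs (znf_chip_fold x the exon baseline)
    gene_by_id = ann.gene_by_id()
    for gid in truth.znf_de_ids:
        ex = gene_by_id[gid].three_prime_exon()
        bumps.append((ex.chrom, ex.start, ex.end, 0.2 * (config.znf_chip_fold - 1.0)))
    track = baseline + _accumulate(bumps)
    return peaks, track


def _accumulate(rects: list[tuple[str, int, int, float]]) -> SignalTrack:
    """Sum possibly-overlapping rectangles into one step function."""
    by: dict[str, list[tuple[int, float]]] = {}
    for chrom, s, e, v in rects:
        by.setdefault(chrom, []).append((s, v))
        by[chrom].append((e, -v))
    data = {}
    for chrom, events in by.items():
        events.sort()
        pos = np.array([p for p, _ in events])
        delta = np.array([d for _, d in events])
        bounds = np.unique(pos)
        level = np.zeros(len(bounds))
        np.add.at(level, np.searchsorted(bounds, pos), delta)
        level = np.cumsum(level)
        s, e, v = bounds[:-1], bounds[1:], level[:-1]
        keep = np.abs(v) > 1e-12
        if keep.any():
            data[chrom] = (s[keep], e[keep], v[keep])
    return SignalTrack(data)


# ------------------------------------------------------------------- RNA counts


def _nb_draw(mean: np.ndarray, disp: float, rng: np.random.Generator) -> np.ndarray:
    r = 1.0 / disp
    return rng.negative_binomial(r, r / (r + np.maximum(mean, 1e-9)))


def simulate_counts(
    ann: Annotation, truth: GroundTruth, config: SimulationConfig
) -> CountMatrix:
    """NB RNA counts (TEs + genes), n_replicates per condition."""
    rng = config.rng(3)
    floored = {"HERVH", "HERVK", "SVA", "LTR7"}
    feature_ids: list[str] = []
    lengths: list[int] = []
    base: list[float] = []
    lfc: list[float] = []
    for te in ann.tes:
        scale = config.low_expression_scale.get(te.family, 1.0)
        mu = (
            config.mean_count
            * scale
            * rng.lognormal(-config.baseline_sigma**2 / 2, config.baseline_sigma)
        )
        if te.family in floored:
            mu = max(mu, config.baseline_floor)
        feature_ids.append(te.element_id)
        lengths.append(te.interval.length)
        base.append(mu)
        lfc.append(truth.planted_te_log2fc.get(te.element_id, 0.0))
    for gene in ann.genes:
        mu = config.gene_mean_count * rng.lognormal(
            -config.baseline_sigma**2 / 2, config.baseline_sigma
        )
        mu = max(mu, config.baseline_floor)
        feature_ids.append(gene.gene_id)
        lengths.append(sum(ex.length for ex in gene.exons))
        base.append(mu)
        lfc.append(truth.coupled_gene_log2fc.get(gene.gene_id, 0.0))

    base_arr = np.asarray(base)
    ko_arr = base_arr * 2.0 ** np.asarray(lfc)
    cols = {}
    for r in range(config.n_replicates):
        cols[f"Ctrl_{r + 1}"] = _nb_draw(base_arr, config.nb_dispersion, rng)
    for r in range(config.n_replicates):
        cols[f"KO_{r + 1}"] = _nb_draw(ko_arr, config.nb_dispersion, rng)
    counts = pd.DataFrame(cols, index=pd.Index(feature_ids, name="feature_id"))
    samples = pd.DataFrame(
        {
            "condition": [c.split("_")[0] for c in counts.columns],
            "state": config.mode,
        },
        index=pd.Index(counts.columns, name="sample_id"),
    )
    return CountMatrix(
        counts=counts,
        lengths=pd.Series(lengths, index=counts.index, name="length"),
        samples=samples,
    )


# -------------------------------------------------------------------- methylome


def simulate_methylome(
    ann: Annotation, truth: GroundTruth, config: SimulationConfig
) -> dict[str, pd.DataFrame]:
    """Beta-binomial per-CpG methylomes, one table per replicate sample.

    CpG sites are shared across samples; coverage is Poisson (zero-coverage
    sites omitted); region overrides implement the imprint model, planted
    DMR windows and promoter methylation switches.
    """
    rng = config.rng(4)
    chroms = sorted(ann.cpg_sites)
    pos_all = np.concatenate([ann.cpg_sites[c] for c in chroms])
    chrom_all = np.concatenate(
        [np.full(len(ann.cpg_sites[c]), c) for c in chroms]
    )

    target = {
        cond: np.full(len(pos_all), config.meth_global_target[cond])
        for cond in ("Ctrl", "KO")
    }
    overridden = {cond: np.zeros(len(pos_all), dtype=bool) for cond in ("Ctrl", "KO")}

    gene_by_id = ann.gene_by_id()

    def override(region: GenomicInterval, cond: str, level: float) -> None:
        mask = (chrom_all == region.chrom) & (pos_all >= region.start) & (
            pos_all < region.end
        )
        target[cond][mask] = level
        overridden[cond][mask] = True

    for icr in ann.icrs:
        state = truth.imprint_state[icr.name]
        override(icr.region, "Ctrl", state["Ctrl"])
        override(icr.region, "KO", state["KO"])
    for region, _ in truth.planted_dmr_regions:
        override(region, "Ctrl", config.dmr_ctrl_level)
        override(region, "KO", config.dmr_ko_level)
    for gid in truth.closed_promoter_genes:
        prom = gene_by_id[gid].promoter
        override(prom, "Ctrl", config.closed_prom_meth[0])
        override(prom, "KO", config.closed_prom_meth[1])
    for gid in truth.opened_promoter_genes:
        prom = gene_by_id[gid].promoter
        override(prom, "Ctrl", config.opened_prom_meth[0])
        override(prom, "KO", config.opened_prom_meth[1])

    # solve the background level so the genome-wide expectation equals the
    # stated global target despite the planted region overrides
    for cond in ("Ctrl", "KO"):
        g = config.meth_global_target[cond]
        free = ~overridden[cond]
        if free.any():
            base = (g * len(pos_all) - target[cond][~free].sum()) / free.sum()
            target[cond][free] = np.clip(base, 0.02, 0.98)

    rho = config.meth_bb_rho
    a_scale = (1 - rho) / rho
    out: dict[str, pd.DataFrame] = {}
    for cond in ("Ctrl", "KO"):
        mu = np.clip(target[cond], 1e-4, 1 - 1e-4)
        for r in range(config.n_replicates):
            cov = rng.poisson(config.coverage_mean, size=len(pos_all))
            p = rng.beta(mu * a_scale, (1 - mu) * a_scale)
            meth = rng.binomial(cov, p)
            keep = cov > 0
            df = pd.DataFrame(
                {
                    "chrom": chrom_all[keep],
                    "pos": pos_all[keep],
                    "strand": "+",
                    "meth": meth[keep],
                    "unmeth": (cov - meth)[keep],
                }
            )
            out[f"{cond}_{r + 1}"] = df.sort_values(
                ["chrom", "pos"], kind="stable"
            ).reset_index(drop=True)
    return out


# ------------------------------------------------------------------------- ATAC


def simulate_atac(
    ann: Annotation, truth: GroundTruth, config: SimulationConfig
) -> tuple[list[Peak], list[Peak], CountMatrix, dict[str, SignalTrack]]:
    """ATAC peaks, peak-region counts and tracks for both conditions.

    KO-gained peaks at a subset of bound TEs carry an accessibility bump
    centred ``atac_gain_offset_bp`` upstream of the TE 5' anchor (strand
    aware) with a low shoulder reaching into the element, so the gained
    region overlaps the TRIM28 site while the signal maximum sits at the
    planted offset.  Ctrl-only (lost) peaks sit at planted closed
    promoters; KO-only peaks at opened promoters.
    """
    rng = config.rng(5)
    te_by_id = ann.te_by_id()
    gene_by_id = ann.gene_by_id()
    half_w = config.atac_gain_width // 2
    off = config.atac_gain_offset_bp

    # pick gained TEs among bound elements of the planted-effect families
    gain_pool = []
    for family, ids in sorted(truth.bound_te_ids.items()):
        if config.effect_log2fc.get(family, 0.0) > 0:
            gain_pool.extend(ids)
    n_gain = min(config.n_gained_te, len(gain_pool))
    chosen = sorted(
        np.array(gain_pool)[rng.choice(len(gain_pool), size=n_gain, replace=False)]
    )
    gained_te_regions: list[tuple[str, GenomicInterval, GenomicInterval]] = []
    for eid in chosen:
        te = te_by_id[eid]
        iv = te.interval
        a5, _ = _te_anchor(te)
        if iv.strand == "-":
            bump = GenomicInterval(iv.chrom, a5 + off - half_w, a5 + off + half_w)
            region = GenomicInterval(iv.chrom, a5 - 300, a5 + off + half_w)
        else:
            bump = GenomicInterval(iv.chrom, max(0, a5 - off - half_w), a5 - off + half_w)
            region = GenomicInterval(iv.chrom, max(0, a5 - off - half_w), a5 + 300)
        gained_te_regions.append((eid, region, bump))
        truth.gained_te.append(
            {
                "te_id": eid,
                "center": (bump.start + bump.end) / 2.0,
                "anchor": a5,
                "strand": iv.strand,
            }
        )

    closed_proms = [
        (gid, promoter_of(gene_by_id[gid].interval))
        for gid in truth.closed_promoter_genes
    ]
    opened_proms = [
        (gid, promoter_of(gene_by_id[gid].interval))
        for gid in truth.opened_promoter_genes
    ]

    # random background locations, avoiding planted regions and each other
    blocked: dict[str, list[tuple[int, int]]] = {c: [] for c in ann.genome}
    for _, region, _ in gained_te_regions:
        blocked[region.chrom].append((region.start, region.end))
    for _, prom in closed_proms + opened_proms:
        blocked[prom.chrom].append((prom.start, prom.end))

    def conflicts(chrom: str, s: int, e: int) -> bool:
        return any(s < be and bs < e for bs, be in blocked[chrom])

    chroms = sorted(ann.genome)
    weights = np.array([ann.genome[c] for c in chroms], dtype=float)
    bg_len = config.background_peak_len

    def sample_regions(n: int) -> list[GenomicInterval]:
        regions = []
        attempts = 0
        while len(regions) < n and attempts < 50 * n:
            attempts += 1
            c = chroms[int(rng.choice(len(chroms), p=weights / weights.sum()))]
            s = int(rng.integers(0, ann.genome[c] - bg_len))
            if conflicts(c, s - bg_len, s + 2 * bg_len):
                continue
            blocked[c].append((s, s + bg_len))
            regions.append(GenomicInterval(c, s, s + bg_len))
        if len(regions) < n:
            raise ValueError("genome too crowded for requested background peaks")
        return regions

    shared = sample_regions(config.n_background_peaks)
    bg_gain = sample_regions(config.n_gained_background)
    bg_lost = sample_regions(config.n_lost_background)
    truth.gained_background = bg_gain
    truth.lost_background = bg_lost

    def dedupe(named_regions: list[tuple[str, GenomicInterval]]):
        """Greedy keep in priority order, dropping collisions within the set."""
        kept: list[tuple[str, GenomicInterval]] = []
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for name, r in named_regions:
            spans = by_chrom.setdefault(r.chrom, [])
            if any(r.start < e and s < r.end for s, e in spans):
                continue
            spans.append((r.start, r.end))
            kept.append((name, r))
        return kept

    ctrl_named = dedupe(
        [(f"shared_{i}", r) for i, r in enumerate(shared)]
        + [(f"closedprom_{gid}", r) for gid, r in closed_proms]
        + [(f"bglost_{i}", r) for i, r in enumerate(bg_lost)]
    )
    ko_named = dedupe(
        [(f"shared_{i}", r) for i, r in enumerate(shared)]
        + [(f"tegain_{eid}", r) for eid, r, _ in gained_te_regions]
        + [(f"bggain_{i}", r) for i, r in enumerate(bg_gain)]
        + [(f"openedprom_{gid}", r) for gid, r in opened_proms]
    )
    kept_names = {n for n, _ in ctrl_named} | {n for n, _ in ko_named}

    # sync ground truth with what was actually planted after collision drops
    gained_te_regions = [
        (eid, r, bump) for eid, r, bump in gained_te_regions
        if f"tegain_{eid}" in kept_names
    ]
    truth.gained_te = [
        g for g in truth.gained_te
        if f"tegain_{g['te_id']}" in kept_names
    ]
    closed_proms = [(g, r) for g, r in closed_proms if f"closedprom_{g}" in kept_names]
    opened_proms = [(g, r) for g, r in opened_proms if f"openedprom_{g}" in kept_names]
    truth.closed_promoter_genes = [g for g, _ in closed_proms]
    truth.opened_promoter_genes = [g for g, _ in opened_proms]
    bg_gain_named = [
        (f"bggain_{i}", r) for i, r in enumerate(bg_gain) if f"bggain_{i}" in kept_names
    ]
    bg_lost_named = [
        (f"bglost_{i}", r) for i, r in enumerate(bg_lost) if f"bglost_{i}" in kept_names
    ]
    truth.gained_background = [r for _, r in bg_gain_named]
    truth.lost_background = [r for _, r in bg_lost_named]

    def mk(named_regions) -> list[Peak]:
        return [Peak(interval=r, score=1.0, name=n) for n, r in named_regions]

    ctrl_peaks = mk(ctrl_named)
    ko_peaks = mk(ko_named)
    ctrl_peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    ko_peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))

    # peak-region counts over the union region set
    regions: list[tuple[str, GenomicInterval, float, float]] = []
    b = config.atac_background_mean
    lo = b / config.atac_fold
    for i, r in enumerate(shared):
        regions.append((f"shared_{i}", r, b, b))
    for eid, r, _ in gained_te_regions:
        regions.append((f"tegain_{eid}", r, lo, b))
    for name, r in bg_gain_named:
        regions.append((name, r, lo, b))
    for name, r in bg_lost_named:
        regions.append((name, r, b, lo))
    for gid, r in closed_proms:
        regions.append((f"closedprom_{gid}", r, b, lo))
    for gid, r in opened_proms:
        regions.append((f"openedprom_{gid}", r, lo, b))

    ids = [rid for rid, _, _, _ in regions]
    mc = np.array([m for _, _, m, _ in regions])
    mk_ = np.array([m for _, _, _, m in regions])
    cols = {}
    for r in range(config.n_replicates):
        cols[f"Ctrl_{r + 1}"] = _nb_draw(mc, config.atac_dispersion, rng)
    for r in range(config.n_replicates):
        cols[f"KO_{r + 1}"] = _nb_draw(mk_, config.atac_dispersion, rng)
    counts = pd.DataFrame(cols, index=pd.Index(ids, name="feature_id"))
    atac_cm = CountMatrix(
        counts=counts,
        lengths=pd.Series(
            [rg.length for _, rg, _, _ in regions], index=counts.index, name="length"
        ),
        samples=pd.DataFrame(
            {
                "condition": [c.split("_")[0] for c in counts.columns],
                "state": config.mode,
            },
            index=pd.Index(counts.columns, name="sample_id"),
        ),
    )

    # signal tracks: baseline 1.0 plus peak rectangles; the TE-gain bump is
    # high (value 4) over the planted offset with a 1.5 shoulder to the anchor
    baseline = SignalTrack.from_intervals(
        (c, 0, length, 1.0) for c, length in ann.genome.items()
    )
    ctrl_rects = [
        (p.interval.chrom, p.interval.start, p.interval.end, 4.0) for p in ctrl_peaks
    ]
    ko_rects = []
    for p in ko_peaks:
        if p.name and p.name.startswith("tegain"):
            continue
        ko_rects.append((p.interval.chrom, p.interval.start, p.interval.end, 4.0))
    for _, region, bump in gained_te_regions:
        ko_rects.append((bump.chrom, bump.start, bump.end, 4.0))
        shoulder = (
            (region.chrom, region.start, bump.start, 1.5)
            if bump.start > region.start
            else (region.chrom, bump.end, region.end, 1.5)
        )
        if shoulder[2] > shoulder[1]:
            ko_rects.append(shoulder)
    tracks = {
        "Ctrl": baseline + _accumulate(ctrl_rects),
        "KO": baseline + _accumulate(ko_rects),
    }
    regions_by_id = {rid: rg for rid, rg, _, _ in regions}
    atac_cm.regions = regions_by_id  # type: ignore[attr-defined]
    return ctrl_peaks, ko_peaks, atac_cm, tracks


# --------------------------------------------------------------------- run dirs


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: Annotation
    truth: GroundTruth
    chip_peaks: list[Peak]
    chip_track: SignalTrack
    rna: CountMatrix
    methylomes: dict[str, pd.DataFrame]
    atac_ctrl_peaks: list[Peak]
    atac_ko_peaks: list[Peak]
    atac_counts: CountMatrix
    atac_tracks: dict[str, SignalTrack]


def simulate_all(config: SimulationConfig) -> SimulatedDataset:
    ann, truth = simulate_annotation(config)
    chip_peaks, chip_track = simulate_chip(ann, truth, config)
    rna = simulate_counts(ann, truth, config)
    # ATAC before the methylome: collision drops during peak placement sync
    # the planted promoter-switch lists that the methylome overrides use
    ctrl_pk, ko_pk, atac_cm, tracks = simulate_atac(ann, truth, config)
    methylomes = simulate_methylome(ann, truth, config)
    return SimulatedDataset(
        config=config,
        annotation=ann,
        truth=truth,
        chip_peaks=chip_peaks,
        chip_track=chip_track,
        rna=rna,
        methylomes=methylomes,
        atac_ctrl_peaks=ctrl_pk,
        atac_ko_peaks=ko_pk,
        atac_counts=atac_cm,
        atac_tracks=tracks,
    )


def write_run_inputs(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every pipeline input (and ground-truth tables) to a run directory."""
    outdir = Path(outdir)
    inputs = outdir / "inputs"
    gt = outdir / "ground_truth"
    inputs.mkdir(parents=True, exist_ok=True)
    gt.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["te_bed"] = inputs / "te_annotation.bed"
    tio.write_te_bed(ds.annotation.tes, paths["te_bed"])
    paths["gtf"] = inputs / "genes.gtf"
    tio.write_gtf(ds.annotation.genes, paths["gtf"])
    paths["icr_bed"] = inputs / "icr_panel.bed"
    tio.write_icr_panel(ds.annotation.icrs, paths["icr_bed"])
    paths["chip_bed"] = inputs / "trim28_peaks.bed"
    tio.write_peaks_bed(ds.chip_peaks, paths["chip_bed"])
    paths["chip_bedgraph"] = inputs / "trim28_signal.bedgraph"
    tio.write_bedgraph(ds.chip_track, paths["chip_bedgraph"])
    paths["rna_counts"] = inputs / "rna_counts.tsv"
    tio.write_counts(ds.rna.counts, ds.rna.lengths, paths["rna_counts"])
    paths["sample_sheet"] = inputs / "samples.tsv"
    ds.rna.samples.to_csv(paths["sample_sheet"], sep="\t", index_label="sample_id")
    for sample, df in ds.methylomes.items():
        p = inputs / f"cpg_{sample}.tsv"
        tio.write_cpg_table(df, p)
        paths[f"cpg_{sample}"] = p
    paths["atac_ctrl_bed"] = inputs / "atac_peaks_Ctrl.bed"
    tio.write_peaks_bed(ds.atac_ctrl_peaks, paths["atac_ctrl_bed"])
    paths["atac_ko_bed"] = inputs / "atac_peaks_KO.bed"
    tio.write_peaks_bed(ds.atac_ko_peaks, paths["atac_ko_bed"])
    paths["atac_counts"] = inputs / "atac_counts.tsv"
    tio.write_counts(ds.atac_counts.counts, ds.atac_counts.lengths, paths["atac_counts"])
    for cond, track in ds.atac_tracks.items():
        p = inputs / f"atac_signal_{cond}.bedgraph"
        tio.write_bedgraph(track, p)
        paths[f"atac_track_{cond}"] = p

    truth = ds.truth
    pd.DataFrame(
        [(fam, eid) for fam, ids in sorted(truth.bound_te_ids.items()) for eid in ids],
        columns=["family", "element_id"],
    ).to_csv(gt / "bound_te.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.planted_te_log2fc.items()), columns=["element_id", "true_log2fc"]
    ).to_csv(gt / "planted_dete.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (gid, truth.coupled_gene_log2fc[gid], truth.coupled_gene_distance.get(gid, np.nan))
            for gid in sorted(truth.coupled_gene_log2fc)
        ],
        columns=["gene_id", "true_log2fc", "distance"],
    ).to_csv(gt / "coupled_genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(r.chrom, r.start, r.end, d) for r, d in truth.planted_dmr_regions],
        columns=["chrom", "start", "end", "true_delta"],
    ).to_csv(gt / "planted_dmrs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (name, st["Ctrl"], st["KO"])
            for name, st in sorted(truth.imprint_state.items())
        ],
        columns=["icr", "ctrl_level", "ko_level"],
    ).to_csv(gt / "imprint_state.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_id": truth.closed_promoter_genes}).to_csv(
        gt / "closed_promoters.tsv", sep="\t", index=False
    )
    pd.DataFrame({"gene_id": truth.opened_promoter_genes}).to_csv(
        gt / "opened_promoters.tsv", sep="\t", index=False
    )
    pd.DataFrame(truth.gained_te).to_csv(gt / "gained_te_peaks.tsv", sep="\t", index=False)
    pd.DataFrame({"znf_de": truth.znf_de_ids}).to_csv(
        gt / "znf_de.tsv", sep="\t", index=False
    )
    return paths
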