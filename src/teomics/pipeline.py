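"""End-to-end orchestration: simulate -> expression -> chromatin -> methylome
-> integration, with a fixed run-directory layout and a machine-readable
summary.  Re-running with an identical config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as tio
from .accessibility import (
    accessibility_methylation_correlation,
    binding_overlap_partition,
    differential_accessibility,
    metaprofile,
    metaprofile_table,
    peak_turnover,
    promoter_switch,
)
from .expression import (
    CountMatrix,
    classify_bound,
    compute_rpkm,
    differential_test,
    family_enrichment,
    filter_expressed,
)
from .genome import GenomicInterval
from .integration import neighbor_correlation, znf_enrichment
from .methylation import (
    CpGIndex,
    call_dmrs,
    common_cpgs,
    global_methylation,
    icr_report,
    pool_replicates,
    region_methylation,
)
from .simulate import SimulationConfig, simulate_all, write_run_inputs

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "expressed_min_reads": 10,
    "de_fc": 2.0,
    "de_fdr": 0.05,
    "atac_fc": 8.0,
    "atac_p": 0.05,
    "dmr_window": 1000,
    "dmr_min_cpgs": 4,
    "dmr_min_delta": 20.0,
    "dmr_alpha": 0.05,
    "min_bp": 1,
    "min_cov": 5,
    "windows": [5000, 10000, 20000],
    "promoter_min_cpgs": 3,
    "icr_loss_threshold": 30.0,
}


@dataclasses.dataclass
class RunConfig:
    seed: int
    outdir: Path
    mode: str = "primed"
    thresholds: dict = dataclasses.field(default_factory=dict)
    simulate: dict | None = None  # SimulationConfig overrides; None = use inputs
    inputs: dict | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        for key, value in self.thresholds.items():
            if key != "windows" and not isinstance(value, (int, float)):
                raise ValueError(f"threshold {key} must be numeric")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        raw.update(overrides)
        return cls(
            seed=raw["seed"],
            outdir=Path(raw.get("outdir", "teomics_run")),
            mode=raw.get("mode", "primed"),
            thresholds=raw.get("thresholds", {}),
            simulate=raw.get("simulate"),
            inputs=raw.get("inputs"),
            log_level=raw.get("log_level", "INFO"),
        )

    def simulation_config(self) -> SimulationConfig:
        kwargs = dict(self.simulate or {})
        kwargs.setdefault("seed", self.seed)
        kwargs.setdefault("mode", self.mode)
        return SimulationConfig(**kwargs)


class PipelineRun:
    """A run directory with staged inputs and outputs."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = config.outdir
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.paths: dict[str, Path] = {}
        self._setup_logging()

    def _setup_logging(self) -> None:
        handler = logging.FileHandler(self.outdir / "run.log", mode="a")
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        root = logging.getLogger("teomics")
        root.addHandler(handler)
        root.setLevel(getattr(logging, self.config.log_level.upper(), logging.INFO))
        logger.info("teomics %s seed=%s mode=%s", __version__, self.config.seed, self.config.mode)
        logger.info("thresholds: %s", self.config.thresholds)

    # ------------------------------------------------------------------ inputs

    def stage_simulate(self) -> dict:
        ds = simulate_all(self.config.simulation_config())
        self.paths = write_run_inputs(ds, self.outdir)
        logger.info("simulated inputs written to %s", self.outdir / "inputs")
        return {
            "n_te": len(ds.annotation.tes),
            "n_genes": len(ds.annotation.genes),
            "n_icrs": len(ds.annotation.icrs),
            "n_cpg_sites": int(sum(len(v) for v in ds.annotation.cpg_sites.values())),
            "n_planted_dete": len(ds.truth.planted_te_log2fc),
            "n_planted_dmr": len(ds.truth.planted_dmr_regions),
        }

    def resolve_inputs(self) -> dict[str, Path]:
        if self.paths:
            return self.paths
        if self.config.inputs:
            self.paths = {k: Path(v) for k, v in self.config.inputs.items()}
            missing = [str(p) for p in self.paths.values() if not p.exists()]
            if missing:
                raise FileNotFoundError(f"missing inputs: {missing}")
            return self.paths
        inputs = self.outdir / "inputs"
        if not inputs.exists():
            raise FileNotFoundError("no inputs: run simulate first or give [inputs]")
        self.paths = {"dir": inputs}
        p = {
            "te_bed": inputs / "te_annotation.bed",
            "gtf": inputs / "genes.gtf",
            "icr_bed": inputs / "icr_panel.bed",
            "chip_bed": inputs / "trim28_peaks.bed",
            "chip_bedgraph": inputs / "trim28_signal.bedgraph",
            "rna_counts": inputs / "rna_counts.tsv",
            "sample_sheet": inputs / "samples.tsv",
            "atac_ctrl_bed": inputs / "atac_peaks_Ctrl.bed",
            "atac_ko_bed": inputs / "atac_peaks_KO.bed",
            "atac_counts": inputs / "atac_counts.tsv",
            "atac_track_Ctrl": inputs / "atac_signal_Ctrl.bedgraph",
            "atac_track_KO": inputs / "atac_signal_KO.bedgraph",
        }
        for f in sorted(inputs.glob("cpg_*.tsv")):
            p[f.stem] = f
        self.paths = p
        return p

    # ------------------------------------------------------------- expression

    def stage_expression(self) -> dict:
        p = self.resolve_inputs()
        th = self.config.thresholds
        tes = tio.read_repeatmasker(p["te_bed"])
        counts, lengths = tio.read_counts(p["rna_counts"])
        samples = tio.read_sample_sheet(p["sample_sheet"])
        chip = tio.read_peaks_bed(p["chip_bed"])
        cm = CountMatrix(counts=counts, lengths=lengths, samples=samples)

        te_ids = {t.element_id for t in tes}
        classes = pd.Series(
            ["te" if f in te_ids else "gene" for f in counts.index], index=counts.index
        )
        diff = differential_test(
            cm,
            expressed_threshold=int(th["expressed_min_reads"]),
            fc_threshold=float(th["de_fc"]),
            fdr_threshold=float(th["de_fdr"]),
            feature_classes=classes,
        )
        expressed = filter_expressed(cm, int(th["expressed_min_reads"]))
        bound = classify_bound(tes, chip, expressed, min_bp=int(th["min_bp"]))
        rpkm = compute_rpkm(cm)

        te_meta = pd.DataFrame(
            {
                "family": {t.element_id: t.family for t in tes},
                "subfamily": {t.element_id: t.subfamily for t in tes},
            }
        )
        diff_te = diff.loc[diff.index.intersection(te_meta.index)].join(te_meta)
        diff_te["bound"] = bound.reindex(diff_te.index).fillna(False)
        diff_te.index.name = "feature_id"
        diff_gene = diff.loc[diff.index.difference(te_meta.index)]
        diff_gene.index.name = "feature_id"
        if (diff_te["status"] != "unchanged").any():
            enrich = family_enrichment(diff, tes, rpkm, samples)
        else:  # degenerate thresholds can leave no DETEs to enrich
            logger.info("expression: no DETEs; enrichment table empty")
            enrich = pd.DataFrame(
                columns=["n_dete", "n_total", "expr_fold",
                         "representation_p", "representation_fdr"],
                index=pd.Index([], name="subfamily"),
            )

        tio.write_table(diff_te.reset_index(), self.outdir / "differential_te.tsv")
        tio.write_table(
            diff_gene.reset_index().rename(columns={"index": "feature_id"}),
            self.outdir / "differential_genes.tsv",
        )
        tio.write_table(enrich.reset_index(), self.outdir / "te_enrichment.tsv")
        n_dete = int((diff_te["status"] != "unchanged").sum())
        n_deg = int((diff_gene["status"] != "unchanged").sum())
        logger.info("expression: %d DETEs, %d DEGs", n_dete, n_deg)
        return {
            "n_dete": n_dete,
            "n_deg": n_deg,
            "n_expressed": len(expressed),
            "n_bound": int(bound.sum()),
        }

    # -------------------------------------------------------------- chromatin

    def stage_chromatin(self) -> dict:
        p = self.resolve_inputs()
        th = self.config.thresholds
        tes = tio.read_repeatmasker(p["te_bed"])
        genes = tio.read_gtf(p["gtf"])
        chip_peaks = tio.read_peaks_bed(p["chip_bed"])
        chip_track = tio.read_bedgraph(p["chip_bedgraph"])
        ctrl_peaks = tio.read_peaks_bed(p["atac_ctrl_bed"])
        ko_peaks = tio.read_peaks_bed(p["atac_ko_bed"])
        tracks = {
            "Ctrl": tio.read_bedgraph(p["atac_track_Ctrl"]),
            "KO": tio.read_bedgraph(p["atac_track_KO"]),
        }
        counts, lengths = tio.read_counts(p["atac_counts"])
        samples = tio.read_sample_sheet(p["sample_sheet"])
        atac_cm = CountMatrix(counts=counts, lengths=lengths, samples=samples)

        # bound-TE metaprofiles per family
        expressed_counts, _ = tio.read_counts(p["rna_counts"])
        chip_idx = classify_bound(
            tes,
            chip_peaks,
            {t.element_id for t in tes},  # binding only; expression handled upstream
            min_bp=int(th["min_bp"]),
        )
        profiles = {}
        for family in ("HERVH", "HERVK", "SVA"):
            members = [t for t in tes if t.family == family and chip_idx[t.element_id]]
            if not members:
                continue
            for name, track in [
                ("atac_Ctrl", tracks["Ctrl"]),
                ("atac_KO", tracks["KO"]),
                ("chip", chip_track),
            ]:
                profiles[f"{family}_{name}"] = metaprofile(members, track)
        tio.write_table(metaprofile_table(profiles), self.outdir / "metaprofiles.tsv")

        diff_atac = differential_accessibility(
            atac_cm,
            fc_threshold=float(th["atac_fc"]),
            p_threshold=float(th["atac_p"]),
        )
        tio.write_table(
            diff_atac.reset_index(), self.outdir / "differential_accessibility.tsv"
        )

        turnover = peak_turnover(ctrl_peaks, ko_peaks, min_bp=int(th["min_bp"]))
        tio.write_table(turnover, self.outdir / "peak_turnover.tsv")

        # fold-change-significant gained regions intersected with binding sites
        region_ids = diff_atac.index[
            diff_atac["significant"] & (diff_atac["log2fc_atac"] > 0)
        ]
        id_to_region = _atac_region_map(ctrl_peaks, ko_peaks, counts.index)
        gained_regions = [id_to_region[r] for r in region_ids if r in id_to_region]
        partition = binding_overlap_partition(
            chip_peaks, gained_regions, min_bp=int(th["min_bp"])
        )
        part_df = pd.DataFrame(
            [
                {
                    "n_bound_total": partition.n_bound_total,
                    "n_bound_gained": partition.n_bound_gained,
                    "n_gained_unbound": partition.n_gained_unbound,
                    "percent_bound_gained": partition.percent_bound_gained,
                    "percent_display": partition.percent_display,
                }
            ]
        )
        tio.write_table(part_df, self.outdir / "binding_overlap_partition.tsv")

        # promoter switches with methylation
        meth = self._pooled_methylomes()
        prom = {g.gene_id: g.promoter for g in genes}
        idx_c, idx_k = CpGIndex(meth["Ctrl"]), CpGIndex(meth["KO"])
        mc = {
            gid: region_methylation(idx_c, r, int(th["promoter_min_cpgs"])).percent
            for gid, r in prom.items()
        }
        mk = {
            gid: region_methylation(idx_k, r, int(th["promoter_min_cpgs"])).percent
            for gid, r in prom.items()
        }
        switch_table, switch_summary = promoter_switch(
            prom, ctrl_peaks, ko_peaks, mc, mk, min_bp=int(th["min_bp"])
        )
        tio.write_table(switch_table, self.outdir / "promoter_switch.tsv")
        tio.write_table(switch_summary, self.outdir / "promoter_switch_summary.tsv")
        rho = accessibility_methylation_correlation(switch_table)

        n_gained = int((turnover["turnover_class"] == "gained").sum())
        n_lost = int((turnover["turnover_class"] == "lost").sum())
        logger.info(
            "chromatin: %d gained, %d lost, partition %d/%d (%d%%)",
            n_gained, n_lost, partition.n_bound_gained, partition.n_bound_total,
            partition.percent_display,
        )
        return {
            "n_gained_peaks": n_gained,
            "n_lost_peaks": n_lost,
            "n_sig_accessibility": int(diff_atac["significant"].sum()),
            "n_bound_gained": partition.n_bound_gained,
            "n_bound_total": partition.n_bound_total,
            "percent_bound_gained": partition.percent_display,
            "n_closed_promoters": int((switch_table["class"] == "closed").sum()),
            "n_opened_promoters": int((switch_table["class"] == "opened").sum()),
            "accessibility_methylation_rho": rho,
        }

    def _pooled_methylomes(self) -> dict[str, pd.DataFrame]:
        p = self.resolve_inputs()
        reps: dict[str, list[pd.DataFrame]] = {"Ctrl": [], "KO": []}
        for key, path in sorted(p.items()):
            if key.startswith("cpg_"):
                cond = key.split("_")[1]
                reps[cond].append(tio.read_cpg_table(path))
        if not reps["Ctrl"] or not reps["KO"]:
            raise FileNotFoundError("need cpg_Ctrl_* and cpg_KO_* methylomes")
        return {cond: pool_replicates(dfs) for cond, dfs in reps.items()}

    # -------------------------------------------------------------- methylome

    def stage_methylome(self) -> dict:
        p = self.resolve_inputs()
        th = self.config.thresholds
        meth = self._pooled_methylomes()
        pairs = common_cpgs(meth["Ctrl"], meth["KO"], min_cov=int(th["min_cov"]))
        g_ctrl, g_ko = global_methylation(pairs)
        dmrs = call_dmrs(
            pairs,
            window_bp=int(th["dmr_window"]),
            min_cpgs=int(th["dmr_min_cpgs"]),
            min_delta=float(th["dmr_min_delta"]),
            alpha=float(th["dmr_alpha"]),
        )
        tio.write_table(dmrs, self.outdir / "dmrs.tsv")
        panel = tio.read_icr_panel(p["icr_bed"])
        per_icr, summary = icr_report(
            panel,
            meth,
            loss_threshold=float(th["icr_loss_threshold"]),
        )
        tio.write_table(per_icr, self.outdir / "icr_report.tsv")
        tio.write_table(summary, self.outdir / "icr_summary.tsv")
        glob_df = pd.DataFrame(
            [{"sample": "Ctrl", "global_percent": g_ctrl, "n_cpgs": len(pairs)},
             {"sample": "KO", "global_percent": g_ko, "n_cpgs": len(pairs)}]
        )
        tio.write_table(glob_df, self.outdir / "global_methylation.tsv")
        n_hyper = int((dmrs["direction"] == "hyper").sum())
        n_hypo = int((dmrs["direction"] == "hypo").sum())
        logger.info(
            "methylome: %d common CpGs, global %.1f/%.1f, %d hyper / %d hypo DMRs",
            len(pairs), g_ctrl, g_ko, n_hyper, n_hypo,
        )
        maternal = summary[summary["parent"] == "maternal"]
        return {
            "n_common_cpgs": len(pairs),
            "global_ctrl": g_ctrl,
            "global_ko": g_ko,
            "n_hyper_dmr": n_hyper,
            "n_hypo_dmr": n_hypo,
            "maternal_icr_mean_ctrl": float(maternal["percent_Ctrl"].iloc[0]),
            "maternal_icr_mean_ko": float(maternal["percent_KO"].iloc[0]),
            "n_paternal_meth_lost": int(
                per_icr.loc[per_icr["parent"] == "paternal", "meth_lost"].sum()
            ),
        }

    # ------------------------------------------------------------ integration

    def stage_integrate(self) -> dict:
        p = self.resolve_inputs()
        th = self.config.thresholds
        diff_te = pd.read_csv(self.outdir / "differential_te.tsv", sep="\t")
        diff_gene = pd.read_csv(self.outdir / "differential_genes.tsv", sep="\t")
        tes = {t.element_id: t for t in tio.read_repeatmasker(p["te_bed"])}
        genes = tio.read_gtf(p["gtf"])
        gene_iv = {g.gene_id: g.interval for g in genes}

        dete = diff_te[diff_te["status"] != "unchanged"].copy()
        deg = diff_gene[diff_gene["status"] != "unchanged"].copy()
        for df, ivs in ((dete, {k: v.interval for k, v in tes.items()}), (deg, gene_iv)):
            df["chrom"] = [ivs[f].chrom for f in df["feature_id"]]
            df["start"] = [ivs[f].start for f in df["feature_id"]]
            df["end"] = [ivs[f].end for f in df["feature_id"]]
        subsets = {
            "LTR": pd.Series(
                [tes[f].class_ == "LTR" for f in dete["feature_id"]], index=dete.index
            ),
            "HERV": pd.Series(
                [tes[f].family in ("HERVH", "HERVK") for f in dete["feature_id"]],
                index=dete.index,
            ),
        }
        corr = neighbor_correlation(
            dete, deg, windows=tuple(int(w) for w in th["windows"]), subsets=subsets
        )
        tio.write_table(corr, self.outdir / "neighbor_correlation.tsv")

        chip_track = tio.read_bedgraph(p["chip_bedgraph"])
        znfs = [g for g in genes if g.gene_id.startswith("ZNF")]
        lfc = dict(zip(diff_gene["feature_id"], diff_gene["log2fc"]))
        de_set = set(deg["feature_id"])
        result = {}
        if znfs and de_set & {g.gene_id for g in znfs}:
            enr = znf_enrichment(
                znfs,
                chip_track,
                de_set,
                lfc,
                rng=np.random.default_rng([self.config.seed, 99]),
            )
            enr_df = pd.DataFrame(
                [
                    {
                        "gene_set": enr.gene_set_label,
                        "observed_mean_signal": enr.observed_mean_signal,
                        "null_mean": float(enr.null_means.mean()),
                        "p_perm": enr.p_perm,
                        "n_permutations": enr.n_permutations,
                        "seed": self.config.seed,
                    }
                ]
            )
            tio.write_table(enr_df, self.outdir / "znf_enrichment.tsv")
            result["znf_p_perm"] = enr.p_perm
        all5 = corr[(corr["subset"] == "all")].set_index("window_bp")["r"]
        for w in th["windows"]:
            result[f"neighbor_r_{int(w) // 1000}kb"] = float(all5.get(int(w), float("nan")))
        logger.info("integration: %s", result)
        return result

    # ------------------------------------------------------------------- runner

    def run_all(self) -> dict:
        summary: dict[str, object] = {}
        stages = [
            ("expression", self.stage_expression),
            ("chromatin", self.stage_chromatin),
            ("methylome", self.stage_methylome),
            ("integration", self.stage_integrate),
        ]
        if self.config.simulate is not None:
            stages.insert(0, ("simulate", self.stage_simulate))
        for name, fn in stages:
            try:
                result = fn() or {}
            except Exception as exc:
                (self.outdir / "FAILED").write_text(f"{name}: {exc}\n")
                logger.exception("stage %s failed", name)
                raise RuntimeError(f"stage {name} failed: {exc}") from exc
            for key, value in result.items():
                summary[f"{name}.{key}"] = value
        rows = [{"key": k, "value": v} for k, v in summary.items()]
        tio.write_table(pd.DataFrame(rows), self.outdir / "summary.tsv")
        (self.outdir / "resolved_config.toml").write_text(self._config_toml())
        return summary

    def _config_toml(self) -> str:
        th = "\n".join(
            f"{k} = {list(v) if isinstance(v, list) else v}"
            for k, v in sorted(self.config.thresholds.items())
        )
        sim = ""
        if self.config.simulate is not None:
            sim_cfg = self.config.simulation_config()
            sim = f"\n[simulate]\nseed = {sim_cfg.seed}\nmode = \"{sim_cfg.mode}\"\n"
        return (
            f'# teomics {__version__} resolved configuration\n'
            f'seed = {self.config.seed}\nmode = "{self.config.mode}"\n'
            f"\n[thresholds]\n{th}\n{sim}"
        )


def _atac_region_map(ctrl_peaks, ko_peaks, ids) -> dict[str, GenomicInterval]:
    """Map ATAC count-table region ids back to intervals via peak names."""
    by_name: dict[str, GenomicInterval] = {}
    for pk in list(ctrl_peaks) + list(ko_peaks):
        if pk.name:
            by_name.setdefault(pk.name, pk.interval)
    return {rid: by_name[rid] for rid in ids if rid in by_name}


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the summary mapping."""
    return PipelineRun(config).run_all()
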