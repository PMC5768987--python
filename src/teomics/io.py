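"""Readers and writers for the annotation and signal formats the pipeline uses.

Supported inputs: RepeatMasker ``.out``, BED6(+) element/peak sets, minimal
GTF (gene/exon features), 4-column bedGraph, per-CpG methylation tables,
ICR panel BED, count tables with sample sheets.  All tables are written as
TSV with header; element and peak sets round-trip exactly through BED.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomicInterval, Peak, TEElement
from .signal import SignalTrack


class ParseError(ValueError):
    pass


def _open(path):
    return open(path, "rt", encoding="utf-8")


# ---------------------------------------------------------------- TE annotation

_RM_STRAND = {"+": "+", "C": "-", "-": "-"}


def read_repeatmasker(path: str | Path) -> list[TEElement]:
    """Parse a RepeatMasker ``.out`` file or a BED6+ TE annotation.

    RepeatMasker coordinates (1-based inclusive) are converted to 0-based
    half-open; strand symbol ``C`` maps to ``-``.  The BED dialect carries
    labels in the name field as ``subfamily:family:class[:element_id]``.
    """
    path = Path(path)
    with _open(path) as fh:
        text = fh.read()
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    fields = first.split()
    is_bed = (
        len(fields) >= 6
        and fields[1].isdigit()
        and fields[2].isdigit()
        and ":" in fields[3]
    )
    if is_bed:
        return _read_te_bed(text, path)
    return _read_rm_out(text, path)


def _read_rm_out(text: str, path: Path) -> list[TEElement]:
    elements: list[TEElement] = []
    counter: dict[str, int] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if not fields[0].replace(".", "").isdigit():
            if lineno <= 3:  # the two header lines (+ blank)
                continue
            raise ParseError(f"{path}:{lineno}: malformed RepeatMasker record")
        if len(fields) < 11:
            raise ParseError(f"{path}:{lineno}: too few fields ({len(fields)})")
        try:
            chrom = fields[4]
            begin = int(fields[5])
            end = int(fields[6])
            strand_sym = fields[8]
            subfamily = fields[9]
            cls_fam = fields[10]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if strand_sym not in _RM_STRAND:
            raise ParseError(f"{path}:{lineno}: unknown strand symbol {strand_sym!r}")
        if "/" in cls_fam:
            class_, family = cls_fam.split("/", 1)
        else:
            class_ = family = cls_fam
        n = counter.get(subfamily, 0)
        counter[subfamily] = n + 1
        try:
            elements.append(
                TEElement(
                    interval=GenomicInterval(chrom, begin - 1, end, _RM_STRAND[strand_sym]),
                    subfamily=subfamily,
                    family=family,
                    class_=class_,
                    element_id=f"{subfamily}.{n}",
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return elements


def _read_te_bed(text: str, path: Path) -> list[TEElement]:
    elements: list[TEElement] = []
    seen: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 6:
            raise ParseError(f"{path}:{lineno}: BED6 requires 6 columns")
        name_parts = fields[3].split(":")
        if len(name_parts) < 3:
            raise ParseError(
                f"{path}:{lineno}: name field must be subfamily:family:class[:id]"
            )
        subfamily, family, class_ = name_parts[:3]
        element_id = name_parts[3] if len(name_parts) > 3 else f"{path.stem}.{lineno}"
        if element_id in seen:
            raise ParseError(f"{path}:{lineno}: duplicate element_id {element_id!r}")
        seen.add(element_id)
        try:
            elements.append(
                TEElement(
                    interval=GenomicInterval(
                        fields[0], int(fields[1]), int(fields[2]), fields[5]
                    ),
                    subfamily=subfamily,
                    family=family,
                    class_=class_,
                    element_id=element_id,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return elements


def write_te_bed(elements: Iterable[TEElement], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for el in elements:
            iv = el.interval
            name = f"{el.subfamily}:{el.family}:{el.class_}:{el.element_id}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ------------------------------------------------------------------------ peaks

def read_peaks_bed(path: str | Path) -> list[Peak]:
    peaks: list[Peak] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED requires >= 3 columns")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = float(fields[4]) if len(fields) > 4 else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            try:
                peaks.append(
                    Peak(
                        interval=GenomicInterval(
                            fields[0], int(fields[1]), int(fields[2]), strand
                        ),
                        score=score,
                        name=name,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return peaks


def write_peaks_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for pk in peaks:
            iv = pk.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{pk.name or '.'}"
                f"\t{pk.score:g}\t{iv.strand}\n"
            )


# -------------------------------------------------------------------------- GTF

def read_gtf(path: str | Path) -> list[GeneModel]:
    """Minimal GTF reader: gene and exon features with gene_id attributes."""
    genes: dict[str, dict] = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ParseError(f"{path}:{lineno}: GTF requires 9 columns")
            chrom, _, feature, start, end, _, strand, _, attrs = f[:9]
            gid = None
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("gene_id"):
                    gid = part.split(None, 1)[1].strip().strip('"')
                    break
            if gid is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            rec = genes.setdefault(gid, {"exons": []})
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            if feature == "gene":
                rec["interval"] = iv
            elif feature == "exon":
                rec["exons"].append(iv)
    out = []
    for gid, rec in genes.items():
        exons = tuple(sorted(rec["exons"], key=lambda e: e.start))
        iv = rec.get("interval")
        if iv is None:
            iv = GenomicInterval(
                exons[0].chrom, exons[0].start, exons[-1].end, exons[0].strand
            )
        out.append(GeneModel(gene_id=gid, interval=iv, exons=exons))
    out.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    return out


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for g in genes:
            iv = g.interval
            attr = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{iv.chrom}\tteomics\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attr}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{ex.chrom}\tteomics\texon\t{ex.start + 1}\t{ex.end}\t.\t{iv.strand}\t.\t{attr}\n"
                )


# --------------------------------------------------------------------- bedGraph

def read_bedgraph(path: str | Path) -> SignalTrack:
    """4-column bedGraph; overlapping intervals are a dialect violation."""
    rows = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                raise ParseError(f"{path}:{lineno}: bedGraph requires 4 columns")
            rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
    try:
        return SignalTrack.from_intervals(rows)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for chrom, start, end, value in track.intervals():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ------------------------------------------------------------------ count tables

def read_counts(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Counts TSV: feature_id, length, then one integer column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "length" not in df.columns:
        raise ParseError(f"{path}: missing 'length' column")
    lengths = df["length"]
    counts = df.drop(columns=["length"])
    return counts, lengths


def write_counts(counts: pd.DataFrame, lengths: pd.Series, path: str | Path) -> None:
    out = counts.copy()
    out.insert(0, "length", lengths)
    out.to_csv(path, sep="\t", index_label="feature_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, condition (Ctrl/KO), state (primed/naive)."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    for col in ("condition", "state"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing '{col}' column")
    return df


# -------------------------------------------------------------------- methylome

CPG_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth"]


def read_cpg_table(path: str | Path) -> pd.DataFrame:
    """Per-CpG calls: chrom, pos (0-based), strand, meth_count, unmeth_count."""
    df = pd.read_csv(path, sep="\t", header=0)
    df.columns = CPG_COLUMNS[: len(df.columns)]
    if list(df.columns) != CPG_COLUMNS:
        raise ParseError(f"{path}: expected columns {CPG_COLUMNS}")
    if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
        raise ParseError(f"{path}: negative counts")
    return df


def write_cpg_table(cpgs: pd.DataFrame, path: str | Path) -> None:
    cpgs.to_csv(path, sep="\t", index=False)


def read_icr_panel(path: str | Path):
    """ICR panel BED with name field ``ICRname:maternal|paternal``."""
    from .methylation import ICRPanelEntry

    entries = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4 or ":" not in f[3]:
                raise ParseError(f"{path}:{lineno}: need name field ICRname:parent")
            name, parent = f[3].rsplit(":", 1)
            entries.append(
                ICRPanelEntry(
                    name=name,
                    region=GenomicInterval(f[0], int(f[1]), int(f[2])),
                    parent=parent,
                )
            )
    return entries


def write_icr_panel(entries, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for e in entries:
            fh.write(
                f"{e.region.chrom}\t{e.region.start}\t{e.region.end}"
                f"\t{e.name}:{e.parent}\n"
            )


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table as TSV with stable float formatting."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
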