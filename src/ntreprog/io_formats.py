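"""Readers and writers for every external representation the pipeline touches.

All genomic intervals inside the package are 0-based, half-open.  GTF input
(1-based, inclusive) is converted here, at the boundary, and nowhere else.
"""
from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


_VALID_BASES = set("ACGTN")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene with exon structure on a single chromosome.

    Coordinates are 0-based half-open.  The TSS is the strand-aware 5' base
    (``start`` on + genes, ``end - 1`` on - genes); the TTS is the 3' base.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"unknown strand {self.strand!r} for gene {self.gene_id}")
        if not self.end > self.start:
            raise FormatError(f"gene {self.gene_id}: end must exceed start")
        prev_end = None
        for (s, e) in self.exons:
            if not (self.start <= s < e <= self.end):
                raise FormatError(f"gene {self.gene_id}: exon ({s},{e}) outside gene body")
            if prev_end is not None and s < prev_end:
                raise FormatError(f"gene {self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer counts with a sample design.

    ``library_size`` defaults to the column sum; an explicitly supplied value
    must be positive and at least the column sum.
    """

    counts: pd.DataFrame
    condition: pd.Series
    replicate: pd.Series
    library_size: pd.Series
    _explicit_libsize: bool = field(default=False, repr=False)

    @classmethod
    def from_frame(
        cls,
        counts: pd.DataFrame,
        condition: Mapping[str, str],
        replicate: Mapping[str, int],
        library_size: Mapping[str, int] | None = None,
    ) -> "CountMatrix":
        counts = counts.copy()
        if counts.index.duplicated().any():
            raise FormatError("duplicate gene ids")
        if counts.columns.duplicated().any():
            raise FormatError("duplicate sample ids")
        if any(g == "" for g in counts.index):
            raise FormatError("empty gene id")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric counts")
        if np.any(arr != np.floor(arr)) or np.any(arr < 0):
            raise FormatError("counts must be non-negative integers")
        counts = counts.astype(np.int64)
        missing = [s for s in counts.columns if s not in condition or s not in replicate]
        if missing:
            raise FormatError(f"samples missing from design: {missing}")
        cond = pd.Series({s: condition[s] for s in counts.columns}, name="condition")
        rep = pd.Series({s: int(replicate[s]) for s in counts.columns}, name="replicate")
        colsum = counts.sum(axis=0)
        if library_size is None:
            lib = colsum.astype(np.int64)
            explicit = False
        else:
            lib = pd.Series({s: int(library_size[s]) for s in counts.columns})
            if (lib <= 0).any():
                raise FormatError("library sizes must be positive")
            if (lib < colsum).any():
                raise FormatError("explicit library size below column sum")
            explicit = True
        return cls(counts, cond, rep, lib, explicit)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, condition: str) -> list[str]:
        sel = [s for s in self.sample_ids if self.condition[s] == condition]
        if not sel:
            raise ValueError(f"condition {condition!r} absent from design")
        return sel


@dataclass(frozen=True)
class PeakRecord:
    """An interval of B4-over-H3 enrichment (0-based half-open)."""

    chrom: str
    start: int
    end: int
    fold_enrichment: float
    p_value: float
    fdr: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("peak end must exceed start")
        for name, v in (("p_value", self.p_value), ("fdr", self.fdr)):
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> uppercased sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(f"sequence {rec.id!r} contains invalid characters {sorted(bad)}")
        out[rec.id] = seq
    if not out:
        raise FormatError(f"no FASTA records in {path}")
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# gene annotation (BED12 / minimal GTF)
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path, dialect: str) -> list[GeneModel]:
    """Read gene models from BED12 or a minimal GTF (gene/exon features only)."""
    if dialect == "bed12":
        return _read_bed12(path)
    if dialect == "minimal_gtf":
        return _read_minimal_gtf(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _read_bed12(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{ln}: BED12 needs 12 columns, got {len(f)}")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}:{ln}: block count mismatch")
            exons = tuple((start + bs, start + bs + sz) for bs, sz in zip(starts, sizes))
            genes.append(GeneModel(name, chrom, strand, start, end, exons))
    return genes


def _read_minimal_gtf(path: str | Path) -> list[GeneModel]:
    bodies: dict[str, tuple[str, str, int, int]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}:{ln}: GTF needs 9 columns")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = f[:9]
            if feature not in ("gene", "exon"):
                raise FormatError(f"{path}:{ln}: unsupported feature {feature!r} (minimal GTF allows gene/exon)")
            gid = _gtf_gene_id(attrs, path, ln)
            start, end = int(start1) - 1, int(end1)  # 1-based inclusive -> 0-based half-open
            if feature == "gene":
                if gid in bodies:
                    raise FormatError(f"{path}:{ln}: duplicate gene {gid!r}")
                bodies[gid] = (chrom, strand, start, end)
                order.append(gid)
            else:
                exons.setdefault(gid, []).append((start, end))
    genes = []
    for gid in order:
        chrom, strand, start, end = bodies[gid]
        ex = tuple(sorted(exons.get(gid, [(start, end)])))
        genes.append(GeneModel(gid, chrom, strand, start, end, ex))
    stray = set(exons) - set(bodies)
    if stray:
        raise FormatError(f"exons without a gene feature: {sorted(stray)}")
    return genes


def _gtf_gene_id(attrs: str, path, ln: int) -> str:
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if chunk.startswith("gene_id"):
            return chunk.split(None, 1)[1].strip().strip('"')
    raise FormatError(f"{path}:{ln}: missing gene_id attribute")


def write_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# count tables and sample designs
# ---------------------------------------------------------------------------

def read_count_table(
    path: str | Path, design: Mapping[str, tuple[str, int]]
) -> CountMatrix:
    """Read a TSV count table (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.isna().any() or any(g in ("", "nan") for g in df.index):
        raise FormatError("empty gene id in count table")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or np.any(arr != np.floor(arr)):
        raise FormatError("count table contains non-integer cells")
    missing = [s for s in df.columns if s not in design]
    if missing:
        raise FormatError(f"samples missing from design: {missing}")
    cond = {s: design[s][0] for s in df.columns}
    rep = {s: design[s][1] for s in df.columns}
    return CountMatrix.from_frame(df, cond, rep)


def write_count_table(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_design_table(path: str | Path) -> dict[str, tuple[str, int]]:
    """Read a sample design TSV with columns sample, condition, replicate."""
    df = pd.read_csv(path, sep="\t")
    need = {"sample", "condition", "replicate"}
    if not need <= set(df.columns):
        raise FormatError(f"design table needs columns {sorted(need)}")
    return {r["sample"]: (r["condition"], int(r["replicate"])) for _, r in df.iterrows()}


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

_PEAK_HEADER = "#chrom\tstart\tend\tname\tfold_enrichment\tstrand\tp_value\tfdr"


def write_peaks_bed(peaks: Sequence[PeakRecord], path: str | Path) -> None:
    """Write peaks as BED6 + p/fdr columns.  Input must be (chrom, start) sorted."""
    keys = [(p.chrom, p.start) for p in peaks]
    if keys != sorted(keys):
        raise ValueError("peaks must be sorted by (chrom, start) before writing")
    with open(path, "w") as fh:
        fh.write(_PEAK_HEADER + "\n")
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i + 1}\t{p.fold_enrichment:.6g}\t.\t"
                f"{p.p_value:.6g}\t{p.fdr:.6g}\n"
            )


def read_peaks_bed(path: str | Path) -> list[PeakRecord]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            peaks.append(
                PeakRecord(f[0], int(f[1]), int(f[2]), float(f[4]), float(f[6]), float(f[7]))
            )
    return peaks


# ---------------------------------------------------------------------------
# ortholog maps, gene sets, time courses
# ---------------------------------------------------------------------------

def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    """Two-column TSV: host_gene_id, oocyte_gene_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["host_gene_id", "oocyte_gene_id"]:
        raise FormatError("ortholog map needs columns host_gene_id, oocyte_gene_id")
    return df[["host_gene_id", "oocyte_gene_id"]]


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """GMT-style file: set name, description, then member gene ids (tab-separated)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{ln}: GMT line needs name, description, members")
            if f[0] in sets:
                raise FormatError(f"{path}:{ln}: duplicate set name {f[0]!r}")
            sets[f[0]] = set(f[2:])
    return sets


TIMECOURSE_COLUMNS = ["time_h", "n_scored", "pos_B4", "pos_PolIIA", "pos_Ser5P", "pos_Ser2P"]


def read_timecourse_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != TIMECOURSE_COLUMNS:
        raise FormatError(f"time course table needs columns {TIMECOURSE_COLUMNS}")
    return df


def write_timecourse_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
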