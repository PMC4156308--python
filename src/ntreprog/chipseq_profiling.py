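"""Dual-genome ChIP read partitioning, B4/H3 peak calling, and TSS profiling.

Reads from a ChIP of transplanted (host) chromatin inside recipient oocytes
are a mixture of the two genomes.  Assignment uses exact k-mer membership
against both genomes (both strands): a read belongs to the host iff at least
one of its k-mers occurs in the host index and none in the recipient index,
and symmetrically; hits in both give "ambiguous", in neither "unmapped".

B4-over-H3 enrichment is called per fixed genomic window with an exact
binomial test against the library-size null, BH-corrected, fold-filtered and
gap-merged.  Metaprofiles aggregate strand-oriented read counts around TSSs
in reads-per-billion-per-gene units; peak densities per megabase are compared
across genomic feature classes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneModel, PeakRecord
from .synthetic_data import GenomeBundle, reverse_complement

ASSIGNMENTS = ("host", "recipient", "ambiguous", "unmapped")


@dataclass
class PartitionReport:
    """Read partition between genomes, with both denominators reported.

    Published mapping fractions may or may not exclude ambiguous/unmapped
    reads, so fractions are given both over all reads and over assigned
    (host + recipient) reads.
    """

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def assigned(self) -> int:
        return self.counts["host"] + self.counts["recipient"]

    def fraction_of_all(self, which: str) -> float:
        return self.counts[which] / self.total if self.total else np.nan

    def fraction_of_assigned(self, which: str) -> float:
        return self.counts[which] / self.assigned if self.assigned else np.nan

    def to_frame(self) -> pd.DataFrame:
        rows = {
            a: (self.counts[a], self.fraction_of_all(a),
                self.fraction_of_assigned(a) if a in ("host", "recipient") else np.nan)
            for a in ASSIGNMENTS
        }
        return pd.DataFrame(rows, index=["count", "fraction_of_all", "fraction_of_assigned"]).T


@dataclass
class WindowTrack:
    """Read counts per fixed-width window tiling each chromosome (last window partial)."""

    window: int
    chrom_lengths: dict[str, int]
    counts: dict[str, np.ndarray]

    @property
    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def same_grid(self, other: "WindowTrack") -> bool:
        return self.window == other.window and self.chrom_lengths == other.chrom_lengths


@dataclass
class MetaProfile:
    """Binned, normalized signal around TSSs (reads per billion per gene per bin)."""

    bin_offsets: np.ndarray  # bin centers relative to TSS, upstream negative
    values: np.ndarray
    n_genes: int
    n_genes_dropped: int
    total_reads: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.bin_offsets, "value": self.values})


@dataclass
class FeatureDensityReport:
    """Peaks per megabase in genomic feature classes vs the whole-genome average."""

    table: pd.DataFrame  # per class: length_mb, n_peaks, density, p_value, stars
    genome_average: float


# ---------------------------------------------------------------------------
# read assignment
# ---------------------------------------------------------------------------

def _kmer_index(bundle: GenomeBundle, k: int) -> set[str]:
    idx: set[str] = set()
    for seq in bundle.sequences.values():
        for s in (seq, reverse_complement(seq)):
            idx.update(s[i : i + k] for i in range(len(s) - k + 1))
    return idx


def assign_reads_dual_genome(
    reads: pd.DataFrame,
    host: GenomeBundle,
    recipient: GenomeBundle,
    k: int = 25,
) -> tuple[pd.DataFrame, PartitionReport]:
    """Assign each read to host, recipient, ambiguous or unmapped by k-mer membership.

    ``reads`` needs a ``sequence`` column; a copy with an ``assignment`` column
    is returned together with the partition report.
    """
    seqs = reads["sequence"]
    if (seqs.str.len() < k).any():
        raise ValueError(f"k = {k} exceeds the length of some reads")
    host_idx = _kmer_index(host, k)
    rec_idx = _kmer_index(recipient, k)
    out = []
    for seq in seqs:
        in_host = in_rec = False
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if not in_host and kmer in host_idx:
                in_host = True
            if not in_rec and kmer in rec_idx:
                in_rec = True
            if in_host and in_rec:
                break
        if in_host and in_rec:
            out.append("ambiguous")
        elif in_host:
            out.append("host")
        elif in_rec:
            out.append("recipient")
        else:
            out.append("unmapped")
    tagged = reads.copy()
    tagged["assignment"] = out
    counts = {a: int((tagged["assignment"] == a).sum()) for a in ASSIGNMENTS}
    return tagged, PartitionReport(counts)


# ---------------------------------------------------------------------------
# window counts and peak calling
# ---------------------------------------------------------------------------

def window_counts(
    intervals: pd.DataFrame, chrom_lengths: Mapping[str, int], window: int = 1000
) -> WindowTrack:
    """Count reads per window by their leftmost base (read strand ignored).

    ``intervals`` needs ``chrom`` and ``start`` columns; every read falls in
    exactly one window, so the track total equals the read count.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    counts = {}
    for chrom, length in chrom_lengths.items():
        n_win = (length + window - 1) // window
        sel = intervals[intervals["chrom"] == chrom]
        idx = (sel["start"].to_numpy() // window).astype(int)
        if len(idx) and (idx.min() < 0 or idx.max() >= n_win):
            raise ValueError(f"read outside chromosome {chrom}")
        counts[chrom] = np.bincount(idx, minlength=n_win).astype(np.int64)
    return WindowTrack(window, dict(chrom_lengths), counts)


def call_b4_peaks(
    b4: WindowTrack,
    h3: WindowTrack,
    alpha_fdr: float = 0.05,
    min_fold: float = 1.5,
    merge_gap: int = 1,
) -> list[PeakRecord]:
    """Call windows of significant B4-over-H3 enrichment and merge them into peaks.

    Per window, a two-sided exact binomial test of the B4 count out of the
    B4 + H3 total against the track-total null probability; a window is
    significant iff its BH FDR < ``alpha_fdr`` and the library-normalized fold
    (with a 0.5-read pseudocount per track, used for the fold only) is at
    least ``min_fold``.  Significant windows separated by at most ``merge_gap``
    non-significant windows are merged; each peak reports its best window p
    and fold.
    """
    if not b4.same_grid(h3):
        raise ValueError("window grids differ between tracks")
    nb, nh = b4.total, h3.total
    if nb == 0 or nh == 0:
        raise ValueError("both tracks need at least one read")
    pi0 = nb / (nb + nh)

    chroms = list(b4.counts)
    flat_b = np.concatenate([b4.counts[c] for c in chroms])
    flat_h = np.concatenate([h3.counts[c] for c in chroms])
    t = flat_b + flat_h
    p = np.ones(len(t))
    for i in np.nonzero(t > 0)[0]:
        p[i] = stats.binomtest(int(flat_b[i]), int(t[i]), pi0).pvalue
    fdr = np.ones(len(t))
    nz = t > 0
    if nz.any():
        fdr[nz] = multipletests(p[nz], method="fdr_bh")[1]
    fold = ((flat_b + 0.5) / nb) / ((flat_h + 0.5) / nh)
    sig = (fdr < alpha_fdr) & (fold >= min_fold)

    peaks: list[PeakRecord] = []
    offset = 0
    for chrom in chroms:
        n_win = len(b4.counts[chrom])
        sl = slice(offset, offset + n_win)
        idx = np.nonzero(sig[sl])[0]
        offset += n_win
        if len(idx) == 0:
            continue
        groups: list[list[int]] = [[int(idx[0])]]
        for i in idx[1:]:
            if i - groups[-1][-1] <= merge_gap + 1:
                groups[-1].append(int(i))
            else:
                groups.append([int(i)])
        for g in groups:
            start = g[0] * b4.window
            end = min((g[-1] + 1) * b4.window, b4.chrom_lengths[chrom])
            widx = [sl.start + i for i in g]
            peaks.append(
                PeakRecord(
                    chrom,
                    start,
                    end,
                    float(fold[widx].max()),
                    float(p[widx].min()),
                    float(fdr[widx].min()),
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# TSS metaprofiles
# ---------------------------------------------------------------------------

def gene_bin_counts(
    intervals: pd.DataFrame,
    genes: Sequence[GeneModel],
    chrom_lengths: Mapping[str, int],
    flank: int = 20_000,
    bin_size: int = 200,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene strand-oriented read counts in bins spanning TSS +/- flank.

    Genes whose TSS lies closer than ``flank`` to a chromosome edge are
    dropped (their names returned).  Reads are assigned by their leftmost base
    to the bin containing their strand-oriented offset from the TSS
    (upstream negative).
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin size")
    n_bins = 2 * flank // bin_size
    starts_by_chrom = {
        c: np.sort(intervals.loc[intervals["chrom"] == c, "start"].to_numpy())
        for c in intervals["chrom"].unique()
    }
    rows, kept, dropped = [], [], []
    for g in genes:
        if g.tss < flank or g.tss + flank > chrom_lengths[g.chrom]:
            dropped.append(g.gene_id)
            continue
        starts = starts_by_chrom.get(g.chrom, np.empty(0, dtype=int))
        lo, hi = np.searchsorted(starts, [g.tss - flank, g.tss + flank])
        offs = starts[lo:hi] - g.tss
        if g.strand == "-":
            offs = -offs
        idx = (offs + flank) // bin_size
        idx = idx[(idx >= 0) & (idx < n_bins)]
        rows.append(np.bincount(idx.astype(int), minlength=n_bins))
        kept.append(g.gene_id)
    if not kept:
        raise ValueError("no genes left after edge filtering")
    return pd.DataFrame(rows, index=kept), dropped


def bin_centers(flank: int, bin_size: int) -> np.ndarray:
    n_bins = 2 * flank // bin_size
    return -flank + bin_size * (np.arange(n_bins) + 0.5)


def tss_metaplot(
    intervals: pd.DataFrame,
    genes: Sequence[GeneModel],
    chrom_lengths: Mapping[str, int],
    flank: int = 20_000,
    bin_size: int = 200,
    subset: set[str] | None = None,
    total_reads: int | None = None,
) -> MetaProfile:
    """Aggregate TSS-centered signal over genes in reads per billion per gene.

    value[b] = (sum over genes of the bin-b count) / total_reads * 1e9 /
    n_genes_used, where total_reads defaults to the full size of the supplied
    read set (not just reads near genes), making the profile invariant to
    uniform read duplication.
    """
    if subset is not None:
        genes = [g for g in genes if g.gene_id in subset]
    per_gene, dropped = gene_bin_counts(intervals, genes, chrom_lengths, flank, bin_size)
    total = total_reads if total_reads is not None else len(intervals)
    values = per_gene.sum(axis=0).to_numpy() / total * 1e9 / per_gene.shape[0]
    return MetaProfile(bin_centers(flank, bin_size), values, per_gene.shape[0], len(dropped), total)


def metaplot_class_contrast(
    per_gene_counts: pd.DataFrame,
    expressed: set[str],
    not_expressed: set[str],
    flank: int = 20_000,
    bin_size: int = 200,
    core: int = 2000,
    total_reads: int | None = None,
) -> dict:
    """Contrast TSS-core depletion between expressed and non-expressed genes.

    The per-gene depletion statistic is the mean signal in TSS +/- core
    divided by the mean signal in the remaining flanks, with a pseudocount of
    half the global per-bin mean protecting genes with empty flanks; the
    classes are compared by a Welch t test on the log2 statistic.
    """
    if expressed & not_expressed:
        raise ValueError("gene classes overlap")
    for name, s in (("expressed", expressed), ("not_expressed", not_expressed)):
        if len(s & set(per_gene_counts.index)) < 20:
            raise ValueError(f"class {name!r} has fewer than 20 profiled genes")
    centers = bin_centers(flank, bin_size)
    core_mask = np.abs(centers) <= core
    pseudo = per_gene_counts.to_numpy().mean() / 2.0

    def stat(rows: pd.DataFrame) -> np.ndarray:
        arr = rows.to_numpy(dtype=float)
        num = arr[:, core_mask].mean(axis=1) + pseudo
        den = arr[:, ~core_mask].mean(axis=1) + pseudo
        return num / den

    def profile(names: set[str]) -> MetaProfile:
        rows = per_gene_counts.loc[sorted(names & set(per_gene_counts.index))]
        total = total_reads if total_reads is not None else int(per_gene_counts.to_numpy().sum())
        values = rows.sum(axis=0).to_numpy() / total * 1e9 / rows.shape[0]
        return MetaProfile(centers, values, rows.shape[0], 0, total)

    s_expr = stat(per_gene_counts.loc[sorted(expressed & set(per_gene_counts.index))])
    s_not = stat(per_gene_counts.loc[sorted(not_expressed & set(per_gene_counts.index))])
    t, p = stats.ttest_ind(np.log2(s_expr), np.log2(s_not), equal_var=False)
    return {
        "profiles": {"expressed": profile(expressed), "not_expressed": profile(not_expressed)},
        "depletion_stat": {"expressed": s_expr, "not_expressed": s_not},
        "t": float(t),
        "p": float(p),
    }


# ---------------------------------------------------------------------------
# peak density across genomic features
# ---------------------------------------------------------------------------

def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    iv = sorted((s, e) for s, e in iv if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in iv:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _feature_intervals(
    genes: Sequence[GeneModel], chrom_lengths: Mapping[str, int], f: int
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    feats: dict[str, dict[str, list[tuple[int, int]]]] = {
        name: {c: [] for c in chrom_lengths} for name in ("tss", "tts", "exon", "intron", "intergenic")
    }
    bodies: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for g in genes:
        length = chrom_lengths[g.chrom]
        feats["tss"][g.chrom].append((max(0, g.tss - f), min(length, g.tss + f)))
        feats["tts"][g.chrom].append((max(0, g.tts - f), min(length, g.tts + f)))
        feats["exon"][g.chrom].extend(g.exons)
        bodies[g.chrom].append((g.start, g.end))
    for c, length in chrom_lengths.items():
        exon_m = _merge_intervals(feats["exon"][c])
        body_m = _merge_intervals(bodies[c])
        feats["intron"][c] = _subtract(body_m, exon_m)
        feats["intergenic"][c] = _subtract([(0, length)], body_m)
    for name in feats:
        for c in feats[name]:
            feats[name][c] = _merge_intervals(feats[name][c])
    return feats


def _subtract(base: list[tuple[int, int]], cut: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for s, e in base:
        pos = s
        for cs, ce in cut:
            if ce <= pos or cs >= e:
                continue
            if cs > pos:
                out.append((pos, cs))
            pos = max(pos, ce)
            if pos >= e:
                break
        if pos < e:
            out.append((pos, e))
    return out


def _midpoint_in(iv: list[tuple[int, int]], point: int) -> bool:
    if not iv:
        return False
    starts = np.array([s for s, _ in iv])
    i = int(np.searchsorted(starts, point, side="right")) - 1
    return i >= 0 and point < iv[i][1]


_STAR_THRESHOLDS = ((1e-4, "***"), (1e-3, "**"), (1e-2, "*"))


def peak_feature_density(
    peaks: Sequence[PeakRecord],
    genes: Sequence[GeneModel],
    chrom_lengths: Mapping[str, int],
    f: int = 1000,
) -> FeatureDensityReport:
    """Peaks per megabase in TSS/TTS flanks, exons, introns and intergenic space.

    A peak is attributed to a feature class iff its midpoint lies in the
    class's (merged) interval set; classes are evaluated independently, so a
    peak may count toward several.  Significance per class: one-sample t test
    of per-chromosome densities against the whole-genome average (needs at
    least two chromosomes for a defined p).  Stars at p < 0.01 / 0.001 /
    0.0001.
    """
    feats = _feature_intervals(genes, chrom_lengths, f)
    genome_mb = sum(chrom_lengths.values()) / 1e6
    genome_avg = len(peaks) / genome_mb
    mid_by_chrom: dict[str, list[int]] = {c: [] for c in chrom_lengths}
    for p in peaks:
        mid_by_chrom[p.chrom].append((p.start + p.end) // 2)

    rows = []
    for name, per_chrom in feats.items():
        lengths_mb, counts = [], []
        for c in chrom_lengths:
            iv = per_chrom[c]
            lengths_mb.append(sum(e - s for s, e in iv) / 1e6)
            counts.append(sum(_midpoint_in(iv, m) for m in mid_by_chrom[c]))
        total_mb = sum(lengths_mb)
        if total_mb == 0:
            rows.append((name, 0.0, 0, np.nan, np.nan, ""))
            continue
        density = sum(counts) / total_mb
        chrom_dens = [cnt / lm for cnt, lm in zip(counts, lengths_mb) if lm > 0]
        if len(chrom_dens) >= 2 and np.std(chrom_dens) > 0:
            _, p_val = stats.ttest_1samp(chrom_dens, genome_avg)
        else:
            p_val = np.nan
        stars = next((s for thr, s in _STAR_THRESHOLDS if p_val < thr), "") if np.isfinite(p_val) else ""
        rows.append((name, total_mb, int(sum(counts)), density, p_val, stars))
    table = pd.DataFrame(
        rows, columns=["feature", "length_mb", "n_peaks", "density_per_mb", "p_value", "stars"]
    ).set_index("feature")
    return FeatureDensityReport(table, genome_avg)
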