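"""Synthetic fixtures with the statistical structure the analysis assumes.

Every downstream stage of the pipeline is testable without external data:
negative-binomial nascent counts in four gene classes with triplicates,
two-genome ChIP read mixtures with antibody-specific host fractions, B4
depletion / H3 enrichment around TSSs, and sequential four-marker acquisition
kinetics.  All generators are deterministic under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .hierarchy_model import MARKERS, TimeCourse
from .io_formats import CountMatrix, GeneModel

CLASSES = ("reprogrammed", "maintained", "downregulated", "silent")

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# parameter bundles
# ---------------------------------------------------------------------------

@dataclass
class SimDesign:
    """Design of a donor-vs-NT nascent count simulation.

    Class calibration: "below detection" genes have expected CPM ``low_cpm``
    (0.2), expressed genes have expected CPM at least ``high_cpm`` (20), so the
    all-replicates CPM > 1 detection rule separates the classes sharply.  The
    expressed-side mean of up/down classes is max(high_cpm, low_cpm * 2**log2fc).
    """

    n_genes: int = 2000
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            # expressed classes in the proportions 1749:1544:917 with 30% silent
            "reprogrammed": 0.2908,
            "maintained": 0.2567,
            "downregulated": 0.1525,
            "silent": 0.3000,
        }
    )
    n_replicates: int = 3
    log2fc: float = 4.0
    dispersion: float = 0.05
    libsize_range: tuple[int, int] = (800_000, 1_200_000)
    low_cpm: float = 0.2
    high_cpm: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.get(c, 0.0) for c in CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per condition")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class ChipSimParams:
    """Two-genome ChIP read mixture with TSS-shaped host intensity.

    ``host_fraction`` gives, per antibody, the probability a read originates
    from the host (transplanted) genome rather than the recipient genome — the
    B4 antibody is nearly host-exclusive while H3 pulls down both chromatins.
    Host-read positions follow a uniform baseline modulated by an exponential
    TSS depletion dip (depth ``tss_depletion_depth``, half-width
    ``tss_depletion_halfwidth``) and exon enrichment for B4, and by a TSS bump
    for H3.
    """

    host_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"B4": 0.97, "H3": 0.73}
    )
    n_reads: int = 100_000
    read_length: int = 75
    tss_depletion_depth: float = 0.8
    tss_depletion_halfwidth: float = 1000.0
    h3_tss_enrichment: float = 1.0
    exon_enrichment: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for ab, f in self.host_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"host fraction for {ab} outside [0, 1]")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0.0 <= self.tss_depletion_depth <= 1.0:
            raise ValueError("depletion depth outside [0, 1]")
        if self.exon_enrichment < 1.0:
            raise ValueError("exon enrichment must be >= 1")


@dataclass
class KineticsParams:
    """Sequential-stage rates and observation design for the marker time course.

    Default rates correspond to stage half-lives of 6, 12, 24, and 48 h for
    B4, Pol IIA, Ser5P and Ser2P — with these, over 90% of nuclei are B4+
    by 24 h.
    """

    rates: tuple[float, float, float, float] = (
        np.log(2) / 6.0,
        np.log(2) / 12.0,
        np.log(2) / 24.0,
        np.log(2) / 48.0,
    )
    times: tuple[float, ...] = (1.0, 6.0, 24.0, 48.0)
    nuclei_per_time: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.rates):
            raise ValueError("rates must be positive")
        t = np.asarray(self.times, dtype=float)
        if np.any(t < 0) or np.any(np.diff(t) < 0):
            raise ValueError("times must be non-negative and sorted")


@dataclass
class GenomeBundle:
    """A toy genome: chromosome sequences plus gene models."""

    name: str
    sequences: dict[str, str]
    genes: list[GeneModel]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


# ---------------------------------------------------------------------------
# toy genomes
# ---------------------------------------------------------------------------

def _random_genes(
    rng: np.random.Generator, chrom: str, chrom_length: int, n_genes: int, prefix: str
) -> list[GeneModel]:
    # one gene per equal-width slot; slot width >= 10 kb guaranteed by caller
    slot = chrom_length // n_genes
    genes = []
    for i in range(n_genes):
        lo = i * slot
        glen = int(rng.integers(2000, 6001))
        start = int(rng.integers(lo + 200, lo + slot - glen - 200))
        end = start + glen
        n_exons = int(rng.integers(2, 5))
        cuts = np.sort(rng.choice(np.arange(start + 100, end - 100), size=2 * n_exons, replace=False))
        exons = tuple((int(cuts[2 * j]), int(cuts[2 * j + 1])) for j in range(n_exons))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"{prefix}_g{i + 1:04d}", chrom, strand, start, end, exons))
    return genes


def build_toy_genomes(
    n_chroms: int = 1,
    chrom_length: int = 200_000,
    n_genes: int = 20,
    seed: int = 0,
) -> tuple[GenomeBundle, GenomeBundle]:
    """Generate divergent host and recipient toy genomes with annotated genes.

    Sequences are generated independently for the two genomes, so shared
    k-mers at the read-assignment default k are vanishingly improbable (use
    :func:`shared_kmer_count` to quantify on a built pair).  Each chromosome
    must offer at least 10 kb per gene placed; genes get 2-4 exons each.
    """
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0) for i in range(n_chroms)]
    for ng in per_chrom:
        if ng > 0 and chrom_length < 10_000 * ng:
            raise ValueError(
                f"chromosome of {chrom_length} bp cannot host {ng} genes (needs >= 10 kb per gene)"
            )
    rng = np.random.default_rng(seed)
    bundles = []
    for name in ("host", "recipient"):
        seqs: dict[str, str] = {}
        genes: list[GeneModel] = []
        for i, ng in enumerate(per_chrom):
            chrom = f"{name}_chr{i + 1}"
            seqs[chrom] = "".join(rng.choice(_BASES, size=chrom_length))
            if ng > 0:
                genes.extend(_random_genes(rng, chrom, chrom_length, ng, chrom))
        bundles.append(GenomeBundle(name, seqs, genes))
    return bundles[0], bundles[1]


def shared_kmer_count(a: GenomeBundle, b: GenomeBundle, k: int = 25) -> int:
    """Number of k-mers (both strands) common to two genome bundles."""
    def kmers(bundle: GenomeBundle) -> set[str]:
        out: set[str] = set()
        for seq in bundle.sequences.values():
            for s in (seq, reverse_complement(seq)):
                out.update(s[i : i + k] for i in range(len(s) - k + 1))
        return out

    return len(kmers(a) & kmers(b))


# ---------------------------------------------------------------------------
# nascent counts
# ---------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Counts with mean m and variance m + dispersion * m**2 (Poisson at 0)."""
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_nascent_counts(design: SimDesign) -> tuple[CountMatrix, pd.Series]:
    """Simulate donor and NT nascent counts for four gene classes.

    Returns the count matrix (samples donor_1.. and NT_1..) and the true
    per-gene class labels.  Reprogrammed genes sit below detection in the donor
    and above in NT; downregulated genes the converse; maintained genes are
    expressed equally in both; silent genes are below detection everywhere.
    """
    rng = np.random.default_rng(design.seed)
    fracs = np.array([design.class_fractions.get(c, 0.0) for c in CLASSES])
    n_per = np.floor(fracs * design.n_genes).astype(int)
    n_per[0] += design.n_genes - n_per.sum()  # remainder to the first class
    labels = np.repeat(CLASSES, n_per)
    gene_ids = [f"gene_{i + 1:05d}" for i in range(design.n_genes)]

    hi = max(design.high_cpm, design.low_cpm * 2.0 ** design.log2fc)
    mean_cpm = {
        "reprogrammed": (design.low_cpm, hi),
        "maintained": (design.high_cpm, design.high_cpm),
        "downregulated": (hi, design.low_cpm),
        "silent": (design.low_cpm, design.low_cpm),
    }
    donor_cpm = np.array([mean_cpm[c][0] for c in labels])
    nt_cpm = np.array([mean_cpm[c][1] for c in labels])

    counts: dict[str, np.ndarray] = {}
    design_map: dict[str, tuple[str, int]] = {}
    libsizes: dict[str, int] = {}
    lib_lo, lib_hi = design.libsize_range
    for cond, cpm in (("donor", donor_cpm), ("NT", nt_cpm)):
        for r in range(1, design.n_replicates + 1):
            lib = int(rng.integers(lib_lo, lib_hi + 1))
            mean = cpm * lib / 1e6
            sample = f"{cond}_{r}"
            counts[sample] = _nb_sample(rng, mean, design.dispersion)
            design_map[sample] = (cond, r)
            libsizes[sample] = lib
    df = pd.DataFrame(counts, index=gene_ids)
    # the drawn depth is the library size (the simulated universe covers only
    # part of the transcriptome, so column sums understate sequencing depth)
    cm = CountMatrix.from_frame(
        df,
        {s: c for s, (c, _) in design_map.items()},
        {s: r for s, (_, r) in design_map.items()},
        library_size=libsizes,
    )
    truth = pd.Series(labels, index=gene_ids, name="true_class")
    return cm, truth


# ---------------------------------------------------------------------------
# ChIP reads
# ---------------------------------------------------------------------------

def _host_weights(bundle: GenomeBundle, params: ChipSimParams, antibody: str) -> dict[str, np.ndarray]:
    """Per-base sampling intensity for read start positions on each chromosome."""
    d = params.tss_depletion_depth
    w = params.tss_depletion_halfwidth
    weights = {}
    for chrom, seq in bundle.sequences.items():
        arr = np.ones(len(seq))
        for g in bundle.genes:
            if g.chrom != chrom:
                continue
            span = int(min(8 * w, len(seq)))
            lo = max(0, g.tss - span)
            hi = min(len(seq), g.tss + span)
            dist = np.abs(np.arange(lo, hi) - g.tss)
            if antibody == "B4":
                arr[lo:hi] *= 1.0 - d * np.exp(-dist / w)
            else:
                arr[lo:hi] *= 1.0 + params.h3_tss_enrichment * np.exp(-dist / w)
            if antibody == "B4" and params.exon_enrichment > 1.0:
                for s, e in g.exons:
                    arr[s:e] *= params.exon_enrichment
        weights[chrom] = arr
    return weights


def simulate_chip_reads(
    host: GenomeBundle,
    recipient: GenomeBundle,
    params: ChipSimParams,
    antibody: str,
) -> pd.DataFrame:
    """Simulate a tagged ChIP read set for one antibody.

    Each read is a verbatim subsequence (either strand) of its true genome of
    origin; origin is Bernoulli(host_fraction[antibody]).  Recipient reads are
    uniform; host reads follow the antibody-specific TSS/exon intensity.
    Returns a data frame with columns read_id, sequence, true_genome,
    true_chrom, true_start, true_end, true_strand.
    """
    if antibody not in params.host_fraction:
        raise ValueError(f"no host fraction declared for antibody {antibody!r}")
    rng = np.random.default_rng(params.seed)
    rl = params.read_length
    for bundle in (host, recipient):
        if any(rl > len(s) for s in bundle.sequences.values()):
            raise ValueError("read_length exceeds a chromosome length")

    origins = rng.random(params.n_reads) < params.host_fraction[antibody]
    host_w = _host_weights(host, params, antibody)

    rows = []
    for origin_is_host, bundle in ((True, host), (False, recipient)):
        n = int(origins.sum()) if origin_is_host else int((~origins).sum())
        if n == 0:
            continue
        chroms = list(bundle.sequences)
        lengths = np.array([len(bundle.sequences[c]) for c in chroms], dtype=float)
        chrom_idx = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
        for ci in range(len(chroms)):
            m = int((chrom_idx == ci).sum())
            if m == 0:
                continue
            chrom = chroms[ci]
            seq = bundle.sequences[chrom]
            n_starts = len(seq) - rl + 1
            if origin_is_host:
                w = host_w[chrom][:n_starts].copy()
                starts = rng.choice(n_starts, size=m, p=w / w.sum())
            else:
                starts = rng.integers(0, n_starts, size=m)
            strands = rng.random(m) < 0.5
            for s, minus in zip(starts, strands):
                frag = seq[s : s + rl]
                rows.append(
                    (
                        frag if not minus else reverse_complement(frag),
                        bundle.name,
                        chrom,
                        int(s),
                        int(s) + rl,
                        "-" if minus else "+",
                    )
                )
    reads = pd.DataFrame(
        rows, columns=["sequence", "true_genome", "true_chrom", "true_start", "true_end", "true_strand"]
    )
    # shuffle so host/recipient reads are interleaved, then assign stable ids
    reads = reads.sample(frac=1.0, random_state=np.random.RandomState(params.seed)).reset_index(drop=True)
    reads.insert(0, "read_id", [f"{antibody}_r{i + 1:06d}" for i in range(len(reads))])
    return reads


# ---------------------------------------------------------------------------
# marker time course
# ---------------------------------------------------------------------------

def simulate_timecourse(params: KineticsParams) -> TimeCourse:
    """Simulate cross-sectional marker scoring of transplanted nuclei.

    Each nucleus advances through stages 1..4 with independent exponential
    sojourns; marker j is positive iff stage j has been reached by the
    observation time.  Truth therefore satisfies the containment chain
    Ser2P+ within Ser5P+ within PolIIA+ within B4+ exactly.
    """
    rng = np.random.default_rng(params.seed)
    rates = np.asarray(params.rates, dtype=float)
    times = np.asarray(params.times, dtype=float)
    n = params.nuclei_per_time
    per_nucleus: dict[float, pd.DataFrame] = {}
    pos_rows = []
    for t in times:
        sojourn = rng.exponential(1.0 / rates, size=(n, len(rates)))
        arrival = np.cumsum(sojourn, axis=1)
        positive = (arrival <= t).astype(int)
        df = pd.DataFrame(positive, columns=list(MARKERS))
        per_nucleus[float(t)] = df
        pos_rows.append(df.sum(axis=0).to_numpy())
    positives = pd.DataFrame(pos_rows, columns=list(MARKERS))
    return TimeCourse(times, np.full(len(times), n), positives, per_nucleus)
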