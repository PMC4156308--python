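# Methods

This note describes the statistical methods, the synthetic-data generators,
and the numerical and design choices behind `ntreprog`.

## Nascent RNA-seq analysis

### Normalization and detection

CPM is `count / library_size * 1e6`; RPKM additionally divides by the exonic
gene length in kilobases. Library sizes default to column sums but may be
supplied explicitly (they must be at least the column sum) — important when a
count table covers only part of the transcriptome, in which case column sums
understate sequencing depth and induce composition bias between conditions.

A gene is *expressed* in a condition iff its CPM exceeds the threshold
(default 1.0, strict inequality) in **every** replicate of that condition.
Requiring all replicates makes detection robust to single-replicate noise and
matches the conservative detection rule used for the published 4,210-gene
expressed universe.

### Exact conditional binomial differential test

For each gene, replicate counts are pooled within condition: `A` reads in
condition a (total depth `L_a`) and `B` in condition b (depth `L_b`).
Conditional on the total `T = A + B`, under the null of equal concentration
`A ~ Binomial(T, π₀)` with `π₀ = L_a / (L_a + L_b)`. The two-sided p-value is
the exact minimum-likelihood tail sum (`scipy.stats.binomtest`, method
"minlike"). Genes with `T = 0` carry no information and get `p = 1`.
BH correction (`statsmodels.stats.multitest.multipletests`) is applied over
genes with `T > 0`. The fold change is
`log2((B/L_b + c) / (A/L_a + c))` with a 0.5-count-per-mean-depth pseudocount.

The exact test conditions away the library sizes but assumes Poisson
(within-condition) variation. Under negative-binomial overdispersion it
becomes anticonservative; the default generator dispersion (φ = 0.05,
variance `m + φ m²`) is in the regime where the test is well calibrated
(measured null significant fraction ≈ 0.017 at FDR 0.05). For noisier data,
`de_nb_quasi_test` implements a quasi-binomial z-test whose variance is
inflated by the moment-estimated common dispersion
(`estimate_common_dispersion`, median method-of-moments over well-expressed
genes); it controls the FDR even at φ = 0.1.

### Gene classification

With expression flags `expr_donor`, `expr_NT` and the DE result (`up` means
higher in NT):

- **reprogrammed**: expressed in NT and (not expressed in donor, or
  significantly up) — oocyte-type activation;
- **downregulated**: expressed in donor and (not expressed in NT, or
  significantly down), unless already reprogrammed;
- **silent**: expressed in neither condition;
- **maintained**: everything else that is expressed in both.

The rules guarantee a partition. Percentages are reported over the expressed
universe (genes expressed in either condition). Note that in simulations
containing many strong true positives, BH's adaptive threshold admits more
borderline calls than under a global null; the FDR among discoveries stays at
the nominal level, but class percentages can drift a few points from the
generating fractions. This is a property of BH, not a bug in the
classification.

### Ortholog contrast, clustering, enrichment

The ortholog contrast splits oocyte genes into high/low expression (terciles
by default) and compares the NT expression of their host orthologs by Welch's
t-test on `log2(RPKM + 1)`. Hierarchical clustering uses 1 − Spearman
correlation distance with average linkage (`scipy.cluster.hierarchy`),
serialized to Newick. Gene-set enrichment is the one-sided hypergeometric
tail (`hypergeom.sf(k − 1, M, n, N)`) with BH correction; sets that are empty
after intersection with the universe are flagged and given `p = 1`.

## Dual-genome ChIP-seq

### Read assignment

Reads from transplanted nuclei may originate from either genome. Each read is
scanned for exact 25-mers (default `k = 25`; both strands indexed): a read is
assigned *host* iff at least one of its k-mers occurs in the host index and
none in the recipient index (symmetrically for *recipient*); reads matching
both are *ambiguous*, reads matching neither *unmapped*. On the divergent toy
genomes the classifier agrees with the simulation truth for >99% of reads.
Exact membership (no mismatch tolerance) is deliberate: it is conservative —
sequencing errors push reads to *unmapped*, never to the wrong genome — and
partition fractions are reported both over all reads and over assigned reads.

### Peak calling

Host-assigned reads are binned into fixed windows (default 1 kb) by their
leftmost base. For each window the B4 count out of the B4 + H3 total is
tested against the library-ratio null `π₀ = N_B4 / (N_B4 + N_H3)` by an exact
two-sided binomial test; BH correction is genome-wide over non-empty windows.
A window is significant iff FDR < 0.05 **and** its library-normalized fold
(0.5-read pseudocount, used only for the fold) is at least 1.5. Significant
windows separated by at most `merge_gap` (default 1) non-significant windows
merge into peaks, which report their best window statistics. Using the H3
track as the control normalizes nucleosome density, so B4/H3 peaks reflect
linker-histone enrichment rather than open chromatin.

### TSS metaprofiles and feature densities

Per gene, reads within ±20 kb of the TSS are counted in 200-bp bins by their
strand-oriented offset (upstream negative); genes whose flank would leave the
chromosome are dropped and counted. The aggregated profile is in reads per
billion per gene, with the denominator equal to the **full** read-set size so
the profile is invariant to uniform read duplication. The central-depletion
summary is the mean of the two central bins divided by the median of the
outer-half flank bins — on depletion-structured simulations this ratio is
≈0.28, and on uniform simulations the profile is flat to Poisson tolerance.
The expressed-vs-silent contrast compares per-gene core/flank ratios (core
±2 kb; pseudocount of half the global per-bin mean to protect empty flanks)
by Welch's t-test on the log2 ratio.

Peak feature densities attribute each peak by its midpoint to merged interval
sets (TSS ±1 kb, TTS ±1 kb, exon, intron = gene body minus exons,
intergenic); classes are evaluated independently, so a peak may count toward
several. Densities are peaks per megabase; significance is a one-sample
t-test of per-chromosome densities against the whole-genome average (the
chromosome is the replication unit; at least two chromosomes required).

## Sequential marker kinetics

Nuclei acquire B4 → Pol IIA → Ser5P → Ser2P irreversibly, with independent
exponential sojourn times (rates k₁..k₄ per hour). The probability of having
reached stage j by time t is the hypoexponential CDF of the first j sojourns:
for distinct rates the closed form
`P_j(t) = 1 − Σᵢ wᵢ e^(−kᵢ t)` with `wᵢ = Π_{m≠i} k_m/(k_m − kᵢ)`;
when any two rates are within 10⁻⁶ relative of each other the closed form is
numerically unsafe (catastrophic cancellation in the weights) and a matrix
exponential of the bidiagonal generator is used instead. The two branches
agree to 10⁻¹⁰ on separated rates.

Each observation time scores an independent cross-section of nuclei, so the
likelihood is a product of binomials `positives_j(t) ~ Bin(n_t, P_j(t))`.
Rates are fit by L-BFGS-B on log-rates with multistart (8 starts around
ln 2 / median-time); data with no partially-positive count (all-zero or
saturated) are non-identifiable and flagged with infinite CIs. 95% confidence
intervals are profile-likelihood intervals: the profile NLL is bracketed
outward from the MLE and the χ²(1)/2 cutoff crossing found by Brent's method;
unbracketed directions give ±∞. Measured coverage over simulated replicates
is ≈95%.

The *containment matrix* `C[x, y]` is the fraction of x-positive nuclei that
are also y-positive; under the sequential model every entry with y upstream
of x is exactly 1. The *hierarchy violation score* is the fraction of nuclei
whose marker pattern is not a prefix (0000, 1000, 1100, 1110, 1111) of the
stage order.

## Synthetic-data generators

The generators define the study conditions; analysis code never sees the
truth labels.

- **Toy genomes**: independent random host/recipient sequences (so they share
  no 25-mers), with non-overlapping multi-exon genes (2–6 kb, 2–4 exons)
  placed in randomly chosen slots.
- **Nascent counts**: gamma-Poisson (negative binomial, variance `m + φ m²`,
  default φ = 0.05) draws around class-defined mean CPMs: low = 0.2 (below
  the detection threshold), high = 20, with the expressed side of changing
  classes at `max(20, 0.2 · 2^log2fc)` so that a requested |log2FC| is never
  collapsed by the detection band. Default class fractions are the published
  proportions (29.1% reprogrammed / 25.7% maintained / 15.3% downregulated /
  30% silent); drawn sequencing depths are passed as explicit library sizes
  to avoid composition bias (the simulated universe covers only part of a
  transcriptome).
- **ChIP reads**: each read is host-origin with the antibody's host fraction
  (defaults 0.97 for B4, 0.73 for H3 — the study mapping fractions);
  recipient reads are uniform; host reads are drawn from a per-base intensity
  with a multiplicative exponential dip at TSSs for B4
  (depth 0.8, half-width 1 kb), optional TSS enrichment for H3, and exon
  enrichment (×2) that gives peak calling structure to find. Reads come from
  both strands with recorded true coordinates.
- **Time courses**: per nucleus, cumulative exponential sojourns at the
  default rates ln 2 / (6, 12, 24, 48) h⁻¹, thresholded at each observation
  time — half-lives spanning the observed dynamics (most nuclei B4-positive
  within a day, Ser2P accumulating over two days).

## Pipeline determinism

`run_pipeline` derives four stage seeds from the run seed via
`numpy.random.SeedSequence.spawn` (reduced mod 2³¹), writes every table with
fixed formatting, and records SHA-256 checksums of all outputs in
`summary.json` (sorted keys, floats rounded to 10 decimals). Two runs with
identical config and seed are byte-identical, which the acceptance suite
verifies file-by-file.

## Parameter defaults

| parameter | default | rationale |
| --- | --- | --- |
| CPM detection threshold | 1.0, all replicates | published expressed-universe rule |
| DE / peak FDR | 0.05 | published significance level |
| NB dispersion φ | 0.05 | regime where the exact test is calibrated |
| simulated \|log2FC\| | 4 | well above the test's resolution at these depths |
| k-mer size | 25 | specific at genome scale, robust within 75-bp reads |
| window / merge gap | 1 kb / 1 | peak resolution vs fragmentation trade-off |
| metaplot flank / bin | 20 kb / 200 bp | resolves the ~1 kb TSS dip with stable bins |
| host fractions B4 / H3 | 0.97 / 0.73 | study mapping fractions |
| acquisition half-lives | 6/12/24/48 h | consistent with observed marker uptake |
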