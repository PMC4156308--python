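# ntreprog

Analysis toolkit for transcriptional reprogramming of somatic nuclei
transplanted into amphibian oocytes, with a matching synthetic-data generator
for end-to-end validation.

## Scientific background

When mouse somatic nuclei are injected into the germinal vesicle of a
*Xenopus* oocyte, the oocyte reprograms them towards an oocyte-like
transcriptional state without cell division. Three experimental readouts
characterize this process, and this package implements the analysis for each:

1. **Nascent RNA-seq (BrUTP labeling).** Only transcripts made *after*
   transfer are sequenced, so donor-vs-NT (nuclear transfer) comparisons
   reflect new transcription. Genes fall into three classes relative to the
   donor cell: *reprogrammed* (oocyte-type genes activated after transfer),
   *maintained* (somatic genes still transcribed), and *downregulated*
   (somatic genes switched off). Detection uses a CPM threshold in every
   replicate; differential calls use an exact conditional binomial test on
   pooled counts with Benjamini–Hochberg correction.
2. **Dual-genome ChIP-seq.** Chromatin from transplanted mouse nuclei sits
   inside a frog cell, so reads must first be assigned to the host (mouse) or
   recipient (*Xenopus*) genome; we use an exact k-mer membership classifier.
   Host-genome tracks are then profiled: windowed B4-over-H3 enrichment peaks
   (binomial test against the library-ratio null), strand-aware TSS
   metaprofiles showing the characteristic depletion of the oocyte linker
   histone B4 at active transcription start sites, and peaks-per-megabase
   densities across TSS/TTS/exon/intron/intergenic feature classes.
3. **Single-nucleus marker kinetics.** Nuclei acquire four markers in a fixed
   order — B4, hypophosphorylated Pol II (Pol IIA), Ser5-phosphorylated
   Pol II, Ser2-phosphorylated Pol II. We model this as an irreversible
   sequential chain of exponential sojourns: stage-occupancy probabilities are
   hypoexponential CDFs, rates are fit by maximum likelihood to
   cross-sectional binomial counts, and the hierarchy is checked empirically
   with a containment matrix (every downstream-marker-positive nucleus should
   carry all upstream markers).

Because the original sequencing data are not shipped with the package, a
synthetic-data module generates fixtures under the study conditions
(negative-binomial nascent counts with the published class structure,
dual-genome ChIP reads with 97%/73% host fractions for B4/H3, TSS-depleted B4
coverage, and sequential marker time courses). Every analysis is validated
against these generators by property-based tests.

## Running the tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests, property-based tests (hypothesis), and an
acceptance module (`tests/test_acceptance.py`) checking published worked
examples and statistical guarantees (FDR control, label recovery, partition
accuracy, metaplot shape, null peak rates, CI coverage, determinism).

## Worked example

A single config-driven command simulates fixtures and runs every analysis:

```bash
cat > example.yaml <<'YAML'
seed: 7
n_genes: 1000
chip_n_reads: 20000
kin_nuclei_per_time: 200
outdir: example_run
YAML
ntreprog run --config example.yaml
```

Output (verbatim):

```
{
  "chip": {
    "host_fraction_of_all_B4": 0.97195,
    "host_fraction_of_all_H3": 0.7266,
    "host_fraction_of_assigned_B4": 0.97195,
    "host_fraction_of_assigned_H3": 0.7266,
    "n_peaks": 19,
    "tss_depletion_ratio": 0.279809221
  },
  "classification": {
    "counts": {
      "downregulated": 164,
      "maintained": 232,
      "reprogrammed": 304,
      "silent": 300
    },
    "expressed_universe": 700,
    "percent_of_universe": {
      "downregulated": 23.4285714286,
      "maintained": 33.1428571429,
      "reprogrammed": 43.4285714286
    },
    "reprogrammed_percent_of_nt_expressed": 56.7164179104
  },
  "fixtures": {
    "n_genes": 1000,
    "n_nuclei_per_time": 200,
    "n_toy_genes": 20
  },
  "kinetics": {
    "containment_B4_PolIIA": 0.1764705882,
    "containment_time_h": 6.0,
    "converged": true,
    "hierarchy_violation_score": 0.0,
    "rates_per_h": [
      0.1135018164,
      0.0628279943,
      0.0306251315,
      0.0136263708
    ]
  }
}
summary written to example_run/summary.json
```

Reading the output: the k-mer classifier recovers the simulated 97% (B4) and
73% (H3) host-read fractions; the B4 TSS metaprofile's central bins carry
~0.28× the flank signal (the active-TSS depletion); the fitted acquisition
rates are close to the generating half-lives of 6/12/24/48 h
(ln 2/6 ≈ 0.116, ln 2/12 ≈ 0.058, ln 2/24 ≈ 0.029, ln 2/48 ≈ 0.014 per hour);
and no nucleus violates the sequential marker hierarchy.

The `example_run/` directory contains every intermediate table (count matrix,
DE table, classification, partition reports, peak BED, metaprofile, feature
densities, rate estimates with profile CIs, containment matrix) plus
`summary.json` with SHA-256 checksums of all outputs. Re-running with the
same config and seed reproduces every file byte-for-byte.

Individual analyses are also exposed as subcommands
(`ntreprog classify`, `chip-assign`, `chip-peaks`, `chip-metaplot`,
`chip-density`, `kinetics-fit`, `kinetics-containment`, `cluster`,
`enrich`, `orthocompare`); see `ntreprog --help`.

## Package layout

| module | contents |
| --- | --- |
| `ntreprog.io_formats` | FASTA / BED12 / minimal-GTF / count-table / peak-BED / time-course readers and writers, core domain types |
| `ntreprog.synthetic_data` | toy genome pair, NB nascent counts, dual-genome ChIP reads, marker time courses |
| `ntreprog.nascent_rnaseq` | CPM/RPKM, detection, exact binomial DE test, gene classification, ortholog contrast, clustering, gene-set enrichment |
| `ntreprog.chipseq_profiling` | k-mer read assignment, window tracks, B4/H3 peak calling, TSS metaprofiles, feature densities |
| `ntreprog.hierarchy_model` | hypoexponential stage model, ML rate fitting with profile CIs, containment diagnostics |
| `ntreprog.pipeline` / `ntreprog.cli` | config-driven orchestration and the `ntreprog` command |

See `docs/methods.md` for the statistical methods and modeling choices.
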