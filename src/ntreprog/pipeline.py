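"""Config-driven orchestration: fixtures -> classification -> ChIP -> kinetics.

A single flat YAML config (all keys optional, unknown keys rejected) fully
determines a run; the machine-readable summary lists every output file with a
checksum, so identical config + seed reproduce byte-identical summaries.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import chipseq_profiling as chip
from . import hierarchy_model as hm
from . import io_formats as iof
from . import nascent_rnaseq as nr
from . import synthetic_data as sd


@dataclass
class RunConfig:
    """Fully resolved run parameters (defaults carry the published thresholds:
    detection at CPM > 1, significance at FDR < 0.05)."""

    seed: int = 0
    outdir: str = "ntreprog_run"
    # nascent RNA-seq fixture
    n_genes: int = 2000
    frac_reprogrammed: float = 0.2908
    frac_maintained: float = 0.2567
    frac_downregulated: float = 0.1525
    frac_silent: float = 0.3000
    n_replicates: int = 3
    log2fc: float = 4.0
    dispersion: float = 0.05
    libsize_min: int = 800_000
    libsize_max: int = 1_200_000
    # classification
    de_alpha: float = 0.05
    cpm_threshold: float = 1.0
    # toy genomes / ChIP
    n_chroms: int = 1
    chrom_length: int = 200_000
    n_toy_genes: int = 20
    chip_n_reads: int = 100_000
    chip_read_length: int = 75
    chip_k: int = 25
    host_fraction_b4: float = 0.97
    host_fraction_h3: float = 0.73
    tss_depletion_depth: float = 0.8
    tss_depletion_halfwidth: float = 1000.0
    h3_tss_enrichment: float = 1.0
    exon_enrichment: float = 2.0
    chip_window: int = 1000
    peak_min_fold: float = 1.5
    peak_merge_gap: int = 1
    metaplot_flank: int = 20_000
    metaplot_bin: int = 200
    feature_flank: int = 1000
    # kinetics
    kin_k1: float = float(np.log(2) / 6.0)
    kin_k2: float = float(np.log(2) / 12.0)
    kin_k3: float = float(np.log(2) / 24.0)
    kin_k4: float = float(np.log(2) / 48.0)
    kin_times: tuple[float, ...] = (1.0, 6.0, 24.0, 48.0)
    kin_nuclei_per_time: int = 100


def validate_config(source: str | Path | dict | None) -> RunConfig:
    """Build a RunConfig from a YAML file or dict; unknown keys are rejected."""
    if source is None:
        raw: dict[str, Any] = {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    if "kin_times" in raw:
        raw["kin_times"] = tuple(float(t) for t in raw["kin_times"])
    cfg = RunConfig(**raw)
    if not 0.0 < cfg.de_alpha < 1.0:
        raise ValueError(f"de_alpha must lie in (0, 1), got {cfg.de_alpha}")
    if cfg.cpm_threshold < 0:
        raise ValueError("cpm_threshold must be non-negative")
    if cfg.libsize_min <= 0 or cfg.libsize_max < cfg.libsize_min:
        raise ValueError("invalid library size range")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _round(x: float, nd: int = 10) -> float:
    return float(np.round(float(x), nd))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full synthetic pipeline and return the run summary.

    Stages: fixture generation, donor-vs-NT gene classification, dual-genome
    ChIP partitioning / peak calling / TSS metaplot, and kinetic rate fitting
    with containment diagnostics.  Every stage derives its RNG stream from the
    run seed, so the summary is deterministic.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(cfg.seed).spawn(4)]
    summary: dict[str, Any] = {"config": dataclasses.asdict(cfg), "stage_seeds": seeds, "stages": {}}
    files: dict[str, str] = {}

    try:
        # ---------------- fixtures ----------------
        host, recip = sd.build_toy_genomes(cfg.n_chroms, cfg.chrom_length, cfg.n_toy_genes, seeds[0])
        iof.write_fasta(host.sequences, out / "host.fa")
        iof.write_fasta(recip.sequences, out / "recipient.fa")
        iof.write_bed12(host.genes, out / "host_genes.bed12")
        design = sd.SimDesign(
            n_genes=cfg.n_genes,
            class_fractions={
                "reprogrammed": cfg.frac_reprogrammed,
                "maintained": cfg.frac_maintained,
                "downregulated": cfg.frac_downregulated,
                "silent": cfg.frac_silent,
            },
            n_replicates=cfg.n_replicates,
            log2fc=cfg.log2fc,
            dispersion=cfg.dispersion,
            libsize_range=(cfg.libsize_min, cfg.libsize_max),
            seed=seeds[0],
        )
        cm, truth = sd.simulate_nascent_counts(design)
        iof.write_count_table(cm, out / "nascent_counts.tsv")
        truth.to_csv(out / "nascent_truth.tsv", sep="\t", header=True)
        kin = sd.KineticsParams(
            rates=(cfg.kin_k1, cfg.kin_k2, cfg.kin_k3, cfg.kin_k4),
            times=cfg.kin_times,
            nuclei_per_time=cfg.kin_nuclei_per_time,
            seed=seeds[0],
        )
        tc = sd.simulate_timecourse(kin)
        iof.write_timecourse_table(tc.to_frame(), out / "timecourse.tsv")
        summary["stages"]["fixtures"] = {
            "n_genes": cfg.n_genes,
            "n_toy_genes": len(host.genes),
            "n_nuclei_per_time": cfg.kin_nuclei_per_time,
        }
    except Exception as e:  # pragma: no cover - abort path
        raise RuntimeError(f"stage 'fixtures' failed: {e}") from e

    try:
        # ---------------- classification ----------------
        cpm = nr.compute_cpm(cm)
        expr_d = nr.detect_expressed(cpm, cm, "donor", cfg.cpm_threshold)
        expr_n = nr.detect_expressed(cpm, cm, "NT", cfg.cpm_threshold)
        de = nr.de_exact_test(cm, "donor", "NT")
        cls = nr.classify_genes(expr_d, expr_n, de, cfg.de_alpha)
        de.table.to_csv(out / "de_table.tsv", sep="\t", index_label="gene_id")
        cls.table.to_csv(out / "classification.tsv", sep="\t", index_label="gene_id")
        pct = nr.class_percentages(cls)
        summary["stages"]["classification"] = {
            "counts": cls.counts(),
            "expressed_universe": int(pct.attrs["universe"]),
            "percent_of_universe": {
                c: _round(pct.loc[c, "percent_of_universe"]) for c in pct.index
            },
            "reprogrammed_percent_of_nt_expressed": _round(
                pct.attrs["reprogrammed_percent_of_nt_expressed"]
            ),
        }
    except Exception as e:
        raise RuntimeError(f"stage 'classification' failed: {e}") from e

    try:
        # ---------------- ChIP profiling ----------------
        chip_stage: dict[str, Any] = {}
        tracks = {}
        for i, antibody in enumerate(("B4", "H3")):
            params = sd.ChipSimParams(
                host_fraction={"B4": cfg.host_fraction_b4, "H3": cfg.host_fraction_h3},
                n_reads=cfg.chip_n_reads,
                read_length=cfg.chip_read_length,
                tss_depletion_depth=cfg.tss_depletion_depth,
                tss_depletion_halfwidth=cfg.tss_depletion_halfwidth,
                h3_tss_enrichment=cfg.h3_tss_enrichment,
                exon_enrichment=cfg.exon_enrichment,
                seed=seeds[1] + i,
            )
            reads = sd.simulate_chip_reads(host, recip, params, antibody)
            tagged, report = chip.assign_reads_dual_genome(reads, host, recip, cfg.chip_k)
            report.to_frame().to_csv(out / f"partition_{antibody}.tsv", sep="\t")
            host_reads = tagged[(tagged["assignment"] == "host") & (tagged["true_genome"] == "host")]
            intervals = host_reads.rename(columns={"true_chrom": "chrom", "true_start": "start"})
            tracks[antibody] = chip.window_counts(intervals, host.chrom_lengths, cfg.chip_window)
            chip_stage[f"host_fraction_of_assigned_{antibody}"] = _round(
                report.fraction_of_assigned("host")
            )
            chip_stage[f"host_fraction_of_all_{antibody}"] = _round(report.fraction_of_all("host"))
            if antibody == "B4":
                b4_intervals = intervals
        peaks = chip.call_b4_peaks(
            tracks["B4"], tracks["H3"], cfg.de_alpha, cfg.peak_min_fold, cfg.peak_merge_gap
        )
        peaks_sorted = sorted(peaks, key=lambda p: (p.chrom, p.start))
        iof.write_peaks_bed(peaks_sorted, out / "b4_h3_peaks.bed")
        profile = chip.tss_metaplot(
            b4_intervals, host.genes, host.chrom_lengths, cfg.metaplot_flank, cfg.metaplot_bin
        )
        profile.to_frame().to_csv(out / "b4_tss_metaprofile.tsv", sep="\t", index=False)
        density = chip.peak_feature_density(
            peaks_sorted, host.genes, host.chrom_lengths, cfg.feature_flank
        )
        density.table.to_csv(out / "peak_feature_density.tsv", sep="\t")
        central = np.abs(profile.bin_offsets) <= cfg.metaplot_bin
        far = np.abs(profile.bin_offsets) >= cfg.metaplot_flank / 2
        chip_stage["n_peaks"] = len(peaks_sorted)
        chip_stage["tss_depletion_ratio"] = _round(
            profile.values[central].mean() / np.median(profile.values[far])
        )
        summary["stages"]["chip"] = chip_stage
    except Exception as e:
        raise RuntimeError(f"stage 'chip' failed: {e}") from e

    try:
        # ---------------- kinetics ----------------
        est = hm.fit_rates(tc, seed=seeds[2])
        rates_df = pd.DataFrame(
            {
                "marker": list(hm.MARKERS),
                "rate_per_h": est.rates,
                "ci_lower": est.ci_lower,
                "ci_upper": est.ci_upper,
            }
        )
        rates_df.to_csv(out / "rate_estimates.tsv", sep="\t", index=False)
        t_ref = 6.0 if 6.0 in tc.times else float(tc.times[-1])
        per_nuc = tc.per_nucleus[t_ref]
        cmat, denoms = hm.containment_matrix(per_nuc)
        cmat.to_csv(out / "containment_matrix.tsv", sep="\t")
        all_nuc = pd.concat(tc.per_nucleus.values(), ignore_index=True)
        score, _ = hm.hierarchy_violation_score(all_nuc)
        summary["stages"]["kinetics"] = {
            "rates_per_h": [_round(k) for k in est.rates],
            "converged": bool(est.converged),
            "containment_time_h": t_ref,
            "containment_B4_PolIIA": _round(cmat.loc["B4", "PolIIA"])
            if np.isfinite(cmat.loc["B4", "PolIIA"])
            else None,
            "hierarchy_violation_score": _round(score),
        }
    except Exception as e:
        raise RuntimeError(f"stage 'kinetics' failed: {e}") from e

    for path in sorted(out.iterdir()):
        if path.name != "summary.json" and path.is_file():
            files[path.name] = _sha256(path)
    summary["files"] = files
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
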