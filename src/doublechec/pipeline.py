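"""End-to-end orchestration: coverage -> smoothing -> baseline -> maxima ->
NB enrichment vs control -> doublet pairing, with a run manifest recording
the peak-count funnel at each stage."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import __version__
from .cleavage_profile import (
    CleavageProfile,
    cpm_normalize,
    extract_cleavage,
    mean_track,
)
from .doublets import HighConfidenceSite, adjacent_distances, call_doublets
from .io_formats import BedInterval, GenomeIndex, read_chrom_sizes, write_bed
from .nb_enrichment import (
    CountMatrix,
    EnrichmentResult,
    NbTestConfig,
    estimate_dispersion,
    size_factors,
    wald_test,
)
from .peak_core import LocalMaxSet, filter_and_find_maxima, genome_baseline, smooth

logger = logging.getLogger("doublechec")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "call_sites_from_profiles"]


@dataclass
class RunConfig:
    """All stage parameters, at their standard defaults."""

    chrom_sizes: str = ""
    tf_bams: list[str] = field(default_factory=list)
    control_bams: list[str] = field(default_factory=list)
    out_dir: str = "doublechec_out"
    mapq_min: int = 10
    window: int = 3
    step: int = 2
    baseline_multiplier: float = 3.0
    lfc_min: float = 1.7
    alpha: float = 1e-4
    d_min: int = 15
    d_max: int = 50
    upstream: int = 700
    flank: int = 10
    size_factor_method: str = "library"   # or "median-of-ratios"
    plateau: str = "drop"
    chain_merge: bool = True
    genes: str = ""
    catalog: str = ""
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    genome: GenomeIndex
    maxima: LocalMaxSet
    enrichment: list[EnrichmentResult]
    retained_peaks: dict[str, np.ndarray]       # contig -> sorted retained centers
    retained_scores: dict[str, np.ndarray]      # matching adjusted p
    sites: list[HighConfidenceSite]
    funnel: dict[str, int]

    def site_midpoints(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for s in self.sites:
            out.setdefault(s.contig, []).append(s.midpoint)
        return out


def call_sites_from_profiles(
    tf_profiles: Sequence[CleavageProfile],
    control_profiles: Sequence[CleavageProfile],
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the analysis stages on in-memory cleavage profiles.

    This is the engine behind the CLI `run` command and the simulator
    round-trip tests.
    """
    config = config or RunConfig()
    if not tf_profiles:
        raise ValueError("no TF samples")
    if not control_profiles:
        raise ValueError("no control samples")
    genome = tf_profiles[0].genome

    tf_mean = mean_track([cpm_normalize(p) for p in tf_profiles])
    threshold = genome_baseline(tf_mean, config.baseline_multiplier)
    all_profiles = list(tf_profiles) + list(control_profiles)
    smoothed = smooth(tf_mean, all_profiles, w=config.window, s=config.step)
    maxima = filter_and_find_maxima(smoothed, threshold, plateau=config.plateau)
    n_maxima = maxima.n_peaks()
    logger.info("local maxima above baseline %.4g: %d", threshold, n_maxima)

    conditions = tuple(
        ["tf"] * len(tf_profiles) + ["control"] * len(control_profiles)
    )
    retained_peaks: dict[str, np.ndarray] = {}
    retained_scores: dict[str, np.ndarray] = {}
    enrichment: list[EnrichmentResult] = []
    if n_maxima > 0:
        row_ids = []
        rows = []
        for contig in maxima.centers:
            for center, sums in zip(maxima.centers[contig], maxima.raw_sums[contig]):
                row_ids.append((contig, int(center)))
                rows.append(sums)
        matrix = CountMatrix(
            row_ids,
            np.asarray(rows),
            conditions,
            tuple(p.label or f"s{i}" for i, p in enumerate(all_profiles)),
        )
        nb_config = NbTestConfig(lfc_min=config.lfc_min, alpha=config.alpha)
        if config.size_factor_method == "library":
            libs = np.asarray([p.library_size for p in all_profiles], dtype=float)
            factors = libs / np.exp(np.mean(np.log(libs)))
        elif config.size_factor_method == "median-of-ratios":
            factors = size_factors(matrix)
        else:
            raise ValueError(f"unknown size_factor_method {config.size_factor_method!r}")
        dispersions = estimate_dispersion(matrix, factors, nb_config)
        enrichment = wald_test(matrix, factors, dispersions, nb_config)
        for contig in maxima.centers:
            keep = [
                (r.row_id[1], r.adjusted_p)
                for r in enrichment
                if r.retained and r.row_id[0] == contig
            ]
            keep.sort()
            retained_peaks[contig] = np.asarray([c for c, _ in keep], dtype=np.int64)
            retained_scores[contig] = np.asarray([p for _, p in keep])
    n_enriched = int(sum(v.size for v in retained_peaks.values()))
    logger.info("peaks enriched over control: %d", n_enriched)

    sites = call_doublets(
        retained_peaks,
        d_min=config.d_min,
        d_max=config.d_max,
        scores=retained_scores,
        chain_merge=config.chain_merge,
    )
    logger.info("merged doublet sites: %d", len(sites))
    funnel = {
        "local_maxima": n_maxima,
        "enriched_peaks": n_enriched,
        "doublet_sites": len(sites),
    }
    assert funnel["local_maxima"] >= funnel["enriched_peaks"] >= funnel["doublet_sites"]
    return PipelineResult(
        genome, maxima, enrichment, retained_peaks, retained_scores, sites, funnel
    )


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-level pipeline: read alignments, call sites, write artifacts.

    Writes maxima.tsv, enriched.tsv, sites.bed, distances.tsv and a JSON
    run manifest with parameters, input checksums and the funnel counts.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if not config.tf_bams:
        raise ValueError("no TF samples in design")
    if not config.control_bams:
        raise ValueError("no control samples in design")
    genome = read_chrom_sizes(config.chrom_sizes)
    tf_profiles = [
        extract_cleavage(p, genome, config.mapq_min, label=f"tf_{i+1}")
        for i, p in enumerate(config.tf_bams)
    ]
    control_profiles = [
        extract_cleavage(p, genome, config.mapq_min, label=f"control_{i+1}")
        for i, p in enumerate(config.control_bams)
    ]
    result = call_sites_from_profiles(tf_profiles, control_profiles, config)

    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)

    with open(out("maxima.tsv"), "w") as handle:
        labels = "\t".join(result.maxima.sample_labels)
        handle.write(f"contig\tcenter\twindow_start\twindow_end\tmean_cpmn\t{labels}\n")
        half = config.window // 2
        for contig in result.maxima.centers:
            for center, cpm, sums in zip(
                result.maxima.centers[contig],
                result.maxima.mean_cpm[contig],
                result.maxima.raw_sums[contig],
            ):
                counts = "\t".join(str(int(x)) for x in sums)
                handle.write(
                    f"{contig}\t{center}\t{center - half}\t{center + half + 1}\t{cpm:.6g}\t{counts}\n"
                )

    with open(out("enriched.tsv"), "w") as handle:
        handle.write(
            "contig\tcenter\tmean_tf\tmean_control\tlog2_fold_change\tp_value\tadjusted_p\tretained\n"
        )
        for r in result.enrichment:
            handle.write(
                f"{r.row_id[0]}\t{r.row_id[1]}\t{r.base_mean_tf:.6g}\t{r.base_mean_control:.6g}"
                f"\t{r.log2_fold_change:.6g}\t{r.p_value:.6g}\t{r.adjusted_p:.6g}\t{int(r.retained)}\n"
            )

    hist = adjacent_distances(
        {c: list(v) for c, v in result.retained_peaks.items() if v.size}
    )
    edges, counts = hist.counts
    with open(out("distances.tsv"), "w") as handle:
        handle.write("distance_bin_start\tcount\n")
        for e, c in zip(edges, counts):
            handle.write(f"{int(e)}\t{int(c)}\n")

    intervals = [
        BedInterval(
            s.contig,
            s.start,
            s.end,
            f"doublet_{i + 1}",
            min(1000.0, -np.log10(max(s.score, 1e-300))) if np.isfinite(s.score) else 0.0,
            ".",
        )
        for i, s in enumerate(result.sites)
    ]
    write_bed(intervals, out("sites.bed"), genome)

    manifest = {
        "version": __version__,
        "parameters": asdict(config),
        "inputs": {
            path: _sha256(path)
            for path in [config.chrom_sizes, *config.tf_bams, *config.control_bams]
        },
        "funnel": result.funnel,
    }
    with open(out("manifest.json"), "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return result
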