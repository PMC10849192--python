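"""Synthetic cleavage-track generator with planted doublet sites.

Control replicates draw NB counts from a smooth shared accessibility
landscape; TF replicates add NB spikes at the two positions flanking each
planted protected site.  Accessibility is suppressed to 10% inside each
protected gap in every library, mimicking binding-site protection.  All
randomness derives from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cleavage_profile import CleavageProfile, profile_from_arrays
from .io_formats import GenomeIndex

__all__ = [
    "SimConfig",
    "PlantedSite",
    "SimTruth",
    "simulate_tracks",
    "score_recovery",
    "write_sam",
]

PROTECTION_FACTOR = 0.1  # accessibility retained inside a protected gap


@dataclass
class SimConfig:
    genome_length: int = 200_000
    n_contigs: int = 1
    n_sites: int = 40
    gap_range: tuple[int, int] = (8, 12)            # protected gap g, inclusive
    spacing_range: tuple[int, int] = (15, 50)       # doublet spacing d, inclusive
    occupancy: float = 50.0                         # expected TF reads per spike
    background_depth: float = 0.5                   # expected reads per bp
    dispersion: float = 0.1
    n_tf_replicates: int = 3
    n_control_replicates: int = 3
    roughness: float = 0.3                          # lognormal sigma of accessibility
    smoothing_bp: int = 200                         # accessibility correlation length
    jitter: bool = False                            # +/-1 bp spike jitter
    min_site_separation: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be > 0")
        if self.n_sites < 0 or self.n_contigs < 1:
            raise ValueError("bad site/contig counts")
        if self.n_sites * (self.spacing_range[1] + 2) >= self.genome_length:
            raise ValueError("too many sites for genome length")
        for rate in (self.occupancy, self.background_depth, self.dispersion):
            if rate < 0:
                raise ValueError("rates must be >= 0")

    def genome(self) -> GenomeIndex:
        base = self.genome_length // self.n_contigs
        lengths = [base] * self.n_contigs
        lengths[-1] += self.genome_length - base * self.n_contigs
        names = tuple(f"sim_{i + 1}" for i in range(self.n_contigs))
        return GenomeIndex(names, tuple(lengths))


@dataclass(frozen=True)
class PlantedSite:
    contig: str
    left: int              # left spike position
    right: int             # right spike position
    spacing: int           # right - left
    gap: int               # protected gap width
    occupancy: float

    @property
    def midpoint(self) -> int:
        return (self.left + self.right) // 2


@dataclass
class SimTruth:
    sites: list[PlantedSite]
    config: SimConfig

    def midpoints(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for s in self.sites:
            out.setdefault(s.contig, []).append(s.midpoint)
        return out


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB2 draws: var = mu + dispersion * mu^2; Poisson when dispersion = 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mean, 1e-300))
    out = np.zeros(mean.shape, dtype=np.int64)
    nz = mean > 0
    out[nz] = rng.negative_binomial(r, p[nz])
    return out


def _accessibility(rng: np.random.Generator, length: int, sigma: float, smooth_bp: int) -> np.ndarray:
    """Smooth positive landscape: exp(sigma * smoothed standard normal), mean 1."""
    z = rng.standard_normal(length)
    if smooth_bp > 1 and length > 1:
        kernel = np.exp(-0.5 * (np.arange(-3 * smooth_bp, 3 * smooth_bp + 1) / smooth_bp) ** 2)
        kernel /= kernel.sum()
        z = np.convolve(z, kernel, mode="same")
        sd = z.std()
        if sd > 0:
            z = z / sd
    acc = np.exp(sigma * z)
    return acc / acc.mean()


def _place_sites(
    rng: np.random.Generator, config: SimConfig, genome: GenomeIndex
) -> list[PlantedSite]:
    placed: dict[str, list[tuple[int, int]]] = {name: [] for name in genome.names}
    sites: list[PlantedSite] = []
    lengths = np.asarray(genome.lengths, dtype=float)
    weights = lengths / lengths.sum()
    sep = config.min_site_separation
    max_tries = 200 * max(config.n_sites, 1)
    tries = 0
    while len(sites) < config.n_sites:
        if tries > max_tries:
            raise RuntimeError(
                "could not place sites without overlap; reduce n_sites or "
                "min_site_separation"
            )
        tries += 1
        ci = rng.choice(len(genome.names), p=weights)
        contig, length = genome.names[ci], genome.lengths[ci]
        d = int(rng.integers(config.spacing_range[0], config.spacing_range[1] + 1))
        g = int(rng.integers(config.gap_range[0], config.gap_range[1] + 1))
        g = min(g, d - 2) if d > 2 else 0  # gap must fit between the spikes
        margin = sep
        if length < d + 2 * margin + 2:
            continue
        left = int(rng.integers(margin, length - d - margin))
        right = left + d
        if any(left - sep < e and right + sep > s for s, e in placed[contig]):
            continue
        placed[contig].append((left, right))
        sites.append(PlantedSite(contig, left, right, d, g, config.occupancy))
    sites.sort(key=lambda s: (s.contig, s.left))
    return sites


def simulate_tracks(
    config: SimConfig,
) -> tuple[list[CleavageProfile], list[CleavageProfile], SimTruth]:
    """Generate TF and control cleavage profiles plus the planted truth."""
    rng = np.random.default_rng(config.seed)
    genome = config.genome()
    acc = {
        name: _accessibility(rng, length, config.roughness, config.smoothing_bp)
        for name, length in genome
    }
    sites = _place_sites(rng, config, genome)
    # suppress accessibility inside each protected gap (shared by all libraries)
    for site in sites:
        mid = site.midpoint
        gap_start = mid - site.gap // 2
        gap_end = gap_start + site.gap
        acc[site.contig][gap_start:gap_end] *= PROTECTION_FACTOR

    depth = config.background_depth

    def background_draw() -> dict[str, np.ndarray]:
        return {
            name: _nb_draw(rng, depth * acc[name], config.dispersion)
            for name, _ in genome
        }

    controls = [
        profile_from_arrays(genome, background_draw(), label=f"control_{i + 1}", replicate=str(i + 1))
        for i in range(config.n_control_replicates)
    ]
    tfs: list[CleavageProfile] = []
    for i in range(config.n_tf_replicates):
        counts = background_draw()
        for site in sites:
            for pos in (site.left, site.right):
                n_reads = int(_nb_draw(rng, np.array([config.occupancy]), config.dispersion)[0])
                if n_reads == 0:
                    continue
                if config.jitter:
                    shifts = rng.choice([-1, 0, 1], size=n_reads)
                    for shift in shifts:
                        p = min(max(pos + shift, 0), genome.length_of(site.contig) - 1)
                        counts[site.contig][p] += 1
                else:
                    counts[site.contig][pos] += n_reads
        tfs.append(profile_from_arrays(genome, counts, label=f"tf_{i + 1}", replicate=str(i + 1)))
    return tfs, controls, SimTruth(sites, config)


def score_recovery(
    called_midpoints: dict[str, Sequence[int]],
    truth: SimTruth,
    tolerance: int = 10,
) -> tuple[float, float]:
    """(sensitivity, false-discovery proportion) by greedy nearest matching.

    Each truth site matches at most one call within ``tolerance`` bp.
    With no calls at all, FDP is reported as 0.0 (undefined-by-convention).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    truth_mids = truth.midpoints()
    n_truth = sum(len(v) for v in truth_mids.values())
    n_calls = sum(len(v) for v in called_midpoints.values())
    if n_truth == 0:
        return (1.0, 0.0 if n_calls == 0 else 1.0)
    if n_calls == 0:
        return (0.0, 0.0)
    matched_truth = 0
    matched_calls = 0
    for contig, calls in called_midpoints.items():
        truths = truth_mids.get(contig, [])
        pairs = [
            (abs(c - t), ci, ti)
            for ci, c in enumerate(calls)
            for ti, t in enumerate(truths)
            if abs(c - t) <= tolerance
        ]
        pairs.sort()
        used_c: set[int] = set()
        used_t: set[int] = set()
        for _, ci, ti in pairs:
            if ci in used_c or ti in used_t:
                continue
            used_c.add(ci)
            used_t.add(ti)
        matched_truth += len(used_t)
        matched_calls += len(used_c)
    sensitivity = matched_truth / n_truth
    fdp = (n_calls - matched_calls) / n_calls
    return (sensitivity, fdp)


def write_sam(profile: CleavageProfile, path, read_length: int = 50, seed: int = 0) -> None:
    """Emit the profile as minimal single-end SAM alignments.

    Each cleavage event becomes one MAPQ-60 read whose 5'-most aligned
    base is the event position; strand is drawn at random (forward forced
    when a reverse alignment would run off the contig start).
    """
    import pysam

    rng = np.random.default_rng(seed)
    genome = profile.genome
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in genome],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for tid, (contig, length) in enumerate(genome):
            positions = np.repeat(
                np.arange(length), profile.counts[contig]
            )
            for i, pos in enumerate(positions):
                pos = int(pos)
                reverse = bool(rng.integers(2)) and pos - read_length + 1 >= 0
                if reverse:
                    start = pos - read_length + 1
                    span = pos - start + 1
                else:
                    start = pos
                    span = min(read_length, length - pos)
                a = pysam.AlignedSegment()
                a.query_name = f"{contig}_{pos}_{i}"
                a.query_sequence = "A" * span
                a.query_qualities = pysam.qualitystring_to_array("I" * span)
                a.reference_id = tid
                a.reference_start = start
                a.cigarstring = f"{span}M"
                a.mapping_quality = 60
                a.flag = 16 if reverse else 0
                out.write(a)
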