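"""Sliding-window smoothing, baseline filtering and local-maxima detection.

Windows are w bases wide (default 3), centered every s bases (default 2)
starting at the first full window (center = w//2); partial edge windows
are dropped.  A center is a local maximum iff its window mean passes the
baseline threshold and strictly exceeds both genomic-neighbor windows
(missing neighbors at contig edges compare as -infinity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cleavage_profile import CleavageProfile, MeanCpmTrack
from .io_formats import GenomeIndex

__all__ = [
    "SmoothedTrack",
    "LocalMaxSet",
    "smooth",
    "genome_baseline",
    "filter_and_find_maxima",
]


@dataclass
class SmoothedTrack:
    """Window centers (per contig) with mean CPMn and per-sample raw sums."""

    genome: GenomeIndex
    centers: dict[str, np.ndarray]          # window center positions, step s
    mean_cpm: dict[str, np.ndarray]         # window-mean averaged CPMn
    raw_sums: dict[str, np.ndarray]         # (n_windows, n_samples) int window sums
    sample_labels: tuple[str, ...]
    window: int = 3
    step: int = 2

    def n_windows(self) -> int:
        return int(sum(c.size for c in self.centers.values()))


@dataclass
class LocalMaxSet:
    """Centers flagged as baseline-passing local maxima."""

    genome: GenomeIndex
    centers: dict[str, np.ndarray]          # subset of SmoothedTrack centers
    mean_cpm: dict[str, np.ndarray]
    raw_sums: dict[str, np.ndarray]
    sample_labels: tuple[str, ...]
    threshold: float = 0.0
    window: int = 3
    step: int = 2

    def n_peaks(self) -> int:
        return int(sum(c.size for c in self.centers.values()))


def _window_view(vec: np.ndarray, w: int, s: int) -> np.ndarray:
    """(n_windows, w) strided view of full windows starting at 0, step s."""
    n = (vec.size - w) // s + 1
    if n <= 0:
        return np.empty((0, w), dtype=vec.dtype)
    return np.lib.stride_tricks.sliding_window_view(vec, w)[:: s][:n]


def smooth(
    mean_cpm: MeanCpmTrack,
    raw_profiles: Sequence[CleavageProfile] = (),
    w: int = 3,
    s: int = 2,
) -> SmoothedTrack:
    """Smooth the averaged CPMn track and window-sum the raw counts.

    Returns window means of ``mean_cpm`` and, for each profile in
    ``raw_profiles``, the integer sum of the w covered base counts, at
    centers ``w//2, w//2 + s, ...``.  Contigs shorter than w are skipped
    with a warning.
    """
    if w % 2 != 1:
        raise ValueError("window width must be odd")
    if s < 1:
        raise ValueError("step must be >= 1")
    genome = mean_cpm.genome
    centers: dict[str, np.ndarray] = {}
    means: dict[str, np.ndarray] = {}
    sums: dict[str, np.ndarray] = {}
    labels = tuple(
        p.label or p.replicate or f"sample_{i}" for i, p in enumerate(raw_profiles)
    )
    half = w // 2
    for contig, length in genome:
        if length < w:
            warnings.warn(f"contig {contig!r} shorter than window ({length} < {w}); skipped")
            continue
        view = _window_view(mean_cpm.values[contig], w, s)
        centers[contig] = np.arange(view.shape[0], dtype=np.int64) * s + half
        means[contig] = view.mean(axis=1)
        if raw_profiles:
            per_sample = [
                _window_view(p.counts[contig], w, s).sum(axis=1) for p in raw_profiles
            ]
            sums[contig] = np.stack(per_sample, axis=1).astype(np.int64)
        else:
            sums[contig] = np.zeros((view.shape[0], 0), dtype=np.int64)
    return SmoothedTrack(genome, centers, means, sums, labels, window=w, step=s)


def genome_baseline(track: MeanCpmTrack, multiplier: float = 3.0) -> float:
    """``multiplier`` times the genome-wide mean per-base value of the track.

    For a CPM-normalized averaged track this is multiplier * 1e6 / L, but
    the actual track sum is used so unequal-depth averaging is handled.
    """
    length = track.genome.total_length
    return multiplier * track.genome_sum() / length


def filter_and_find_maxima(
    smoothed: SmoothedTrack,
    threshold: float,
    plateau: str = "drop",
) -> LocalMaxSet:
    """Keep centers passing ``threshold`` that strictly exceed both neighbors.

    Neighbor comparison uses the genomic-neighbor windows at c +/- step
    regardless of whether those neighbors passed the filter; missing
    neighbors at contig ends compare as -infinity, so edge windows can be
    maxima.  Plateaus (exact ties) yield no maximum unless
    ``plateau='keep-left'``, which keeps the leftmost window of each
    strictly-rising-then-flat-then-strictly-falling run.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if plateau not in ("drop", "keep-left"):
        raise ValueError("plateau must be 'drop' or 'keep-left'")
    centers: dict[str, np.ndarray] = {}
    means: dict[str, np.ndarray] = {}
    sums: dict[str, np.ndarray] = {}
    for contig in smoothed.centers:
        m = smoothed.mean_cpm[contig]
        padded = np.concatenate(([-np.inf], m, [-np.inf]))
        left, right = padded[:-2], padded[2:]
        if plateau == "drop":
            is_max = (m > left) & (m > right)
        else:
            rising = m > left
            falling = m > right
            # keep-left: first window of a plateau bounded by rises/falls
            is_max = np.zeros(m.size, dtype=bool)
            i = 0
            while i < m.size:
                j = i
                while j + 1 < m.size and m[j + 1] == m[i]:
                    j += 1
                if rising[i] and falling[j]:
                    is_max[i] = True
                i = j + 1
        is_max &= m >= threshold
        idx = np.flatnonzero(is_max)
        centers[contig] = smoothed.centers[contig][idx]
        means[contig] = m[idx]
        sums[contig] = smoothed.raw_sums[contig][idx]
    return LocalMaxSet(
        smoothed.genome,
        centers,
        means,
        sums,
        smoothed.sample_labels,
        threshold=threshold,
        window=smoothed.window,
        step=smoothed.step,
    )
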