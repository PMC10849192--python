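"""Doublet pairing: adjacent enriched peaks flanking a protected site.

Distances are measured center-to-center between consecutive retained
peaks within a contig.  Consecutive pairs with distance in [d_min, d_max]
found a doublet; chains sharing a peak are merged transitively into one
site spanning the chain's extreme centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from pyfaidx import Fasta

__all__ = [
    "HighConfidenceSite",
    "DistanceHistogram",
    "adjacent_distances",
    "call_doublets",
    "expand_sites",
    "merge_intervals",
    "extract_site_sequences",
]


@dataclass
class HighConfidenceSite:
    """A merged doublet: interval from left member center to right center."""

    contig: str
    start: int                      # leftmost member center
    end: int                        # rightmost member center + 1 (half-open)
    member_centers: tuple[int, ...]
    score: float = np.nan           # min member adjusted p

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty site interval")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end - 1) // 2


@dataclass
class DistanceHistogram:
    """Center-to-center distances of adjacent retained peaks, 2 bp bins."""

    distances: np.ndarray
    bin_width: int = 2

    @property
    def counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(bin_left_edges, counts) at the configured bin width."""
        if self.distances.size == 0:
            return np.array([]), np.array([])
        hi = int(self.distances.max()) + self.bin_width
        edges = np.arange(0, hi + self.bin_width, self.bin_width)
        counts, _ = np.histogram(self.distances, bins=edges)
        return edges[:-1], counts

    @property
    def total(self) -> int:
        return int(self.distances.size)


def adjacent_distances(peaks: Mapping[str, Sequence[int]], bin_width: int = 2) -> DistanceHistogram:
    """Distances between consecutive peak centers per contig (no cross-contig)."""
    dists: list[np.ndarray] = []
    for contig, centers in peaks.items():
        c = np.asarray(centers, dtype=np.int64)
        if c.size and (np.diff(c) <= 0).any():
            raise ValueError(f"peak centers not sorted/unique on {contig!r}")
        if c.size >= 2:
            dists.append(np.diff(c))
    all_d = np.concatenate(dists) if dists else np.array([], dtype=np.int64)
    return DistanceHistogram(all_d, bin_width=bin_width)


def call_doublets(
    peaks: Mapping[str, Sequence[int]],
    d_min: int = 15,
    d_max: int = 50,
    scores: Mapping[str, Sequence[float]] | None = None,
    chain_merge: bool = True,
) -> list[HighConfidenceSite]:
    """Pair consecutive peaks d_min..d_max bp apart; merge chains into sites.

    ``peaks`` maps contig -> sorted unique retained peak centers; optional
    ``scores`` carries a per-peak adjusted p (site score = min of members).
    With ``chain_merge=False`` each qualifying consecutive pair becomes its
    own (possibly overlapping) site.
    """
    sites: list[HighConfidenceSite] = []
    for contig, centers in peaks.items():
        c = np.asarray(centers, dtype=np.int64)
        if c.size and (np.diff(c) <= 0).any():
            raise ValueError(f"peak centers not sorted/unique on {contig!r}")
        sc = None if scores is None else np.asarray(scores[contig], dtype=float)
        if c.size < 2:
            continue
        gaps = np.diff(c)
        ok = (gaps >= d_min) & (gaps <= d_max)
        if chain_merge:
            # runs of consecutive qualifying gaps -> one site per run
            i = 0
            while i < ok.size:
                if not ok[i]:
                    i += 1
                    continue
                j = i
                while j + 1 < ok.size and ok[j + 1]:
                    j += 1
                members = tuple(int(x) for x in c[i : j + 2])
                score = float(np.min(sc[i : j + 2])) if sc is not None else np.nan
                sites.append(
                    HighConfidenceSite(contig, members[0], members[-1] + 1, members, score)
                )
                i = j + 1
        else:
            for i in np.flatnonzero(ok):
                members = (int(c[i]), int(c[i + 1]))
                score = float(np.min(sc[i : i + 2])) if sc is not None else np.nan
                sites.append(
                    HighConfidenceSite(contig, members[0], members[1] + 1, members, score)
                )
    return sites


def merge_intervals(intervals: Iterable[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Merge overlapping/adjacent half-open intervals per contig."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for contig, start, end in intervals:
        if contig not in by_contig:
            by_contig[contig] = []
            order.append(contig)
        by_contig[contig].append((start, end))
    out: list[tuple[str, int, int]] = []
    for contig in order:
        ivs = sorted(by_contig[contig])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((contig, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((contig, cur_s, cur_e))
    return out


def expand_sites(
    sites: Sequence[HighConfidenceSite],
    flank: int,
    contig_lengths: Mapping[str, int] | None = None,
) -> list[tuple[str, int, int]]:
    """Expand each site to midpoint +/- flank, clip to contig, merge overlaps."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    raw = []
    for site in sites:
        mid = site.midpoint
        start = mid - flank
        end = mid + flank + 1
        if contig_lengths is not None:
            start = max(0, start)
            end = min(contig_lengths[site.contig], end)
        else:
            start = max(0, start)
        raw.append((site.contig, start, end))
    return merge_intervals(raw)


def extract_site_sequences(
    intervals: Sequence[tuple[str, int, int]],
    fasta_path,
) -> list[tuple[str, str]]:
    """Fetch + strand, uppercase sequences; record ids are contig:start-end."""
    records: list[tuple[str, str]] = []
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    try:
        for contig, start, end in intervals:
            if contig not in fasta:
                raise KeyError(f"contig {contig!r} not in FASTA")
            if not (0 <= start < end <= len(fasta[contig])):
                raise ValueError(f"interval [{start},{end}) outside contig {contig!r}")
            seq = str(fasta[contig][start:end])
            records.append((f"{contig}:{start}-{end}", seq))
    finally:
        fasta.close()
    return records


def write_fasta(records: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n{seq}\n")
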