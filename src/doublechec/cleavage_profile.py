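"""Single-base cleavage tracks from aligned reads.

Each retained read contributes one cleavage event at the 5'-most genomic
base of its alignment: the leftmost aligned base for + strand alignments
and the rightmost for - strand alignments.  Soft-clipped bases are ignored
(the aligned span defines the position).  For paired-end input only read 1
is used; duplicates are retained unless ``drop_duplicates`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pysam

from .io_formats import GenomeIndex

__all__ = [
    "CleavageProfile",
    "CpmTrack",
    "MeanCpmTrack",
    "extract_cleavage",
    "profile_from_arrays",
    "cpm_normalize",
    "mean_track",
]


class EmptyLibraryError(ValueError):
    """No reads survived filtering."""


@dataclass
class CleavageProfile:
    """Per-contig integer vectors of cleavage-event counts for one library."""

    genome: GenomeIndex
    counts: dict[str, np.ndarray]
    label: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        for name, length in self.genome:
            vec = self.counts.get(name)
            if vec is None:
                self.counts[name] = np.zeros(length, dtype=np.int64)
                continue
            vec = np.asarray(vec)
            if vec.shape != (length,):
                raise ValueError(f"count vector for {name!r} has wrong length")
            if np.issubdtype(vec.dtype, np.floating):
                if not np.allclose(vec, np.round(vec)):
                    raise ValueError("counts must be integers")
                vec = np.round(vec).astype(np.int64)
            if (vec < 0).any():
                raise ValueError("negative counts")
            self.counts[name] = vec.astype(np.int64, copy=False)

    @property
    def library_size(self) -> int:
        """Total retained reads N."""
        return int(sum(int(v.sum()) for v in self.counts.values()))


@dataclass
class CpmTrack:
    """Counts-per-million normalized per-base values; sums to 1e6 genome-wide."""

    genome: GenomeIndex
    values: dict[str, np.ndarray]
    label: str = ""


@dataclass
class MeanCpmTrack:
    """Elementwise mean of one or more CPM tracks."""

    genome: GenomeIndex
    values: dict[str, np.ndarray]
    n_replicates: int = 1

    def genome_sum(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))


def extract_cleavage(
    alignment_path,
    genome: GenomeIndex,
    mapq_min: int = 10,
    *,
    drop_duplicates: bool = False,
    label: str = "",
    replicate: str = "",
) -> CleavageProfile:
    """Tally one cleavage event per retained read from a BAM/SAM file.

    Unmapped, secondary and supplementary reads, reads with MAPQ below
    ``mapq_min`` (default 10) and mates other than read 1 are excluded.
    Raises :class:`EmptyLibraryError` if nothing survives, and ``KeyError``
    if an alignment references a contig absent from ``genome``.
    """
    counts = {name: np.zeros(length, dtype=np.int64) for name, length in genome}
    n = 0
    mode = "r" if str(alignment_path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(alignment_path), mode, check_sq=False) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < mapq_min:
                continue
            if read.is_paired and read.is_read2:
                continue
            if drop_duplicates and read.is_duplicate:
                continue
            contig = read.reference_name
            if contig not in genome:
                raise KeyError(f"alignment contig {contig!r} absent from genome index")
            pos = read.reference_end - 1 if read.is_reverse else read.reference_start
            if not (0 <= pos < genome.length_of(contig)):
                continue  # defensive: malformed alignment past contig end
            counts[contig][pos] += 1
            n += 1
    if n == 0:
        raise EmptyLibraryError(f"empty library: no reads retained from {alignment_path}")
    return CleavageProfile(genome, counts, label=label, replicate=replicate)


def profile_from_arrays(
    genome: GenomeIndex,
    counts: Mapping[str, np.ndarray],
    label: str = "",
    replicate: str = "",
) -> CleavageProfile:
    """Build a profile directly from per-contig count vectors (simulator path)."""
    return CleavageProfile(genome, dict(counts), label=label, replicate=replicate)


def cpm_normalize(profile: CleavageProfile) -> CpmTrack:
    """Scale counts to counts-per-million: value[i] = count[i] * 1e6 / N."""
    n = profile.library_size
    if n == 0:
        raise EmptyLibraryError("cannot CPM-normalize an empty library")
    values = {name: vec * (1e6 / n) for name, vec in profile.counts.items()}
    return CpmTrack(profile.genome, values, label=profile.label)


def mean_track(tracks: Sequence[CpmTrack]) -> MeanCpmTrack:
    """Elementwise arithmetic mean of CPM tracks sharing one genome index."""
    if not tracks:
        raise ValueError("need at least one track")
    genome = tracks[0].genome
    for t in tracks[1:]:
        if t.genome.names != genome.names or t.genome.lengths != genome.lengths:
            raise ValueError("tracks have mismatched genome indexes")
    values = {
        name: np.mean([t.values[name] for t in tracks], axis=0) for name, _ in genome
    }
    return MeanCpmTrack(genome, values, n_replicates=len(tracks))
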