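"""Motif-site scanning and strand-oriented average cleavage (metaplots).

Offsets are anchored at the motif's 5' end on the motif strand: offset 0
is the first motif base, negative offsets are upstream of it.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from pyfaidx import Fasta

from .cleavage_profile import MeanCpmTrack

__all__ = [
    "MotifSiteSet",
    "Metaplot",
    "scan_iupac",
    "metaplot",
    "protection_width",
    "IUPAC_CODES",
]

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(pattern: str) -> str:
    return pattern.translate(_COMPLEMENT)[::-1]


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for letter in pattern:
        try:
            bases = IUPAC_CODES[letter]
        except KeyError:
            raise ValueError(f"invalid IUPAC letter {letter!r} in pattern") from None
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead enables overlapping matches
    return re.compile(f"(?=({''.join(parts)}))")


@dataclass
class MotifSiteSet:
    """Motif instances as (contig, start, end, strand), all on + coordinates."""

    pattern: str
    sites: list[tuple[str, int, int, str]]

    def __post_init__(self) -> None:
        plen = len(self.pattern)
        for contig, start, end, strand in self.sites:
            if end - start != plen:
                raise ValueError(f"site [{start},{end}) length != pattern length {plen}")
            if strand not in ("+", "-"):
                raise ValueError(f"bad strand {strand!r}")

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class Metaplot:
    """Mean signal per offset relative to the oriented site start."""

    offsets: np.ndarray                 # -flank .. site_len + flank - 1
    mean_signal: np.ndarray
    n_sites: int
    site_length: int

    def __post_init__(self) -> None:
        if self.offsets.shape != self.mean_signal.shape:
            raise ValueError("offsets/signal shape mismatch")
        if not np.isfinite(self.mean_signal).all():
            raise ValueError("non-finite metaplot values")


def scan_iupac(fasta_path, pattern: str) -> MotifSiteSet:
    """Find all instances of an IUPAC pattern on both strands of a genome.

    Minus-strand matches are recorded at the + strand coordinates of
    their reverse complement with strand='-'.  Overlapping matches are
    all reported.  Palindromic hits are reported once per strand.
    """
    pattern = pattern.upper()
    fwd = _iupac_regex(pattern)
    rev = _iupac_regex(_revcomp(pattern))
    plen = len(pattern)
    sites: list[tuple[str, int, int, str]] = []
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    try:
        for contig in fasta.keys():
            seq = str(fasta[contig][:])
            for m in fwd.finditer(seq):
                sites.append((contig, m.start(), m.start() + plen, "+"))
            for m in rev.finditer(seq):
                sites.append((contig, m.start(), m.start() + plen, "-"))
    finally:
        fasta.close()
    sites.sort(key=lambda s: (s[0], s[1], s[3]))
    return MotifSiteSet(pattern, sites)


def metaplot(
    track: MeanCpmTrack,
    sites: MotifSiteSet | Sequence[tuple[str, int, int, str]],
    flank: int = 100,
    orient: bool = True,
) -> Metaplot:
    """Average the track over all sites, oriented by site strand.

    For + sites the window [start - flank, end + flank) is taken as-is;
    for - sites the same window is reversed so offsets run 5'->3' on the
    motif strand.  Sites whose flanked window leaves the contig are
    dropped with a warning; an empty usable site set is an error.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    site_list = sites.sites if isinstance(sites, MotifSiteSet) else list(sites)
    if not site_list:
        raise ValueError("empty site set")
    site_len = site_list[0][2] - site_list[0][1]
    width = site_len + 2 * flank
    total = np.zeros(width)
    n_used = 0
    n_dropped = 0
    for contig, start, end, strand in site_list:
        if end - start != site_len:
            raise ValueError("sites of unequal length in one metaplot")
        vec = track.values.get(contig)
        if vec is None:
            n_dropped += 1
            continue
        lo, hi = start - flank, end + flank
        if lo < 0 or hi > vec.size:
            n_dropped += 1
            continue
        window = vec[lo:hi]
        if orient and strand == "-":
            window = window[::-1]
        total += window
        n_used += 1
    if n_dropped:
        warnings.warn(f"{n_dropped} site(s) dropped (out of bounds after flanking)")
    if n_used == 0:
        raise ValueError("empty site set (all sites out of bounds)")
    offsets = np.arange(-flank, site_len + flank)
    return Metaplot(offsets, total / n_used, n_sites=n_used, site_length=site_len)


def protection_width(meta: Metaplot, flank_reference: int) -> int:
    """Longest run of site-body offsets below 50% of the far-flank mean.

    The reference level is the mean signal at offsets more than
    ``flank_reference`` bp outside the site body (so near-site peaks are
    excluded from the reference).  Returns 0 for a flat metaplot or when
    no reference offsets exist.
    """
    if flank_reference < 0:
        raise ValueError("flank_reference must be >= 0")
    body = meta.site_length
    in_flank = (meta.offsets < -flank_reference) | (meta.offsets >= body + flank_reference)
    if not in_flank.any():
        return 0
    ref = float(meta.mean_signal[in_flank].mean())
    if ref <= 0:
        return 0
    in_body = (meta.offsets >= 0) & (meta.offsets < body)
    below = meta.mean_signal[in_body] < 0.5 * ref
    best = run = 0
    for flag in below:
        run = run + 1 if flag else 0
        best = max(best, run)
    return best
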