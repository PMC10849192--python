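"""Readers and writers for the standard genomic text formats the pipeline touches.

All internal coordinates are 0-based, half-open.  BED and bedGraph outputs
follow their respective standards; GFF3/GTF inputs (1-based, closed) are
converted on read.  Contig order is always the chrom.sizes file order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeIndex",
    "GeneRecord",
    "TargetSetCatalog",
    "read_chrom_sizes",
    "read_gene_annotation",
    "read_target_catalog",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered contig names and lengths.

    Parameters
    ----------
    names : sequence of str
        Contig names, unique, in the order they should appear in outputs.
    lengths : sequence of int
        Contig lengths in bp, all >= 1.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(self.names) == 0:
            raise FormatError("no contigs")
        if len(set(self.names)) != len(self.names):
            raise FormatError("duplicate contig names")
        for name, length in zip(self.names, self.lengths):
            if int(length) < 1:
                raise FormatError(f"non-positive length for contig {name!r}")

    @property
    def total_length(self) -> int:
        """Total genome length L in bp."""
        return int(sum(self.lengths))

    def length_of(self, contig: str) -> int:
        try:
            return self.lengths[self.names.index(contig)]
        except ValueError:
            raise KeyError(f"unknown contig {contig!r}") from None

    def __contains__(self, contig: str) -> bool:
        return contig in self.names

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(zip(self.names, self.lengths))

    def rank(self, contig: str) -> int:
        """Sort key for contig-order sorting."""
        return self.names.index(contig)


@dataclass(frozen=True)
class GeneRecord:
    """A gene anchor: id, contig, 0-based start-codon position and strand."""

    gene_id: str
    contig: str
    position: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.position < 0:
            raise ValueError("negative position")


@dataclass
class TargetSetCatalog:
    """Map of TF name -> set of reported target gene ids."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tf, genes in self.sets.items():
            if not tf:
                raise ValueError("empty TF name")
            if any(not g for g in genes):
                raise ValueError(f"empty gene id in target set for {tf!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def read_chrom_sizes(path) -> GenomeIndex:
    """Read a UCSC-style chrom.sizes file (name<TAB>length per line).

    Blank lines are ignored.  Raises :class:`FormatError` on malformed
    lines, duplicate contigs, non-positive lengths or an empty file.
    """
    names: list[str] = []
    lengths: list[int] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"line {lineno}: expected name<TAB>length, got {line!r}")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise FormatError(f"line {lineno}: length {fields[1]!r} is not an integer") from None
            if length <= 0:
                raise FormatError(f"line {lineno}: non-positive length for contig {name!r}")
            if name in names:
                raise FormatError(f"line {lineno}: duplicate contig {name!r}")
            names.append(name)
            lengths.append(length)
    if not names:
        raise FormatError("no contigs")
    return GenomeIndex(tuple(names), tuple(lengths))


def _parse_gff_attributes(text: str) -> dict[str, str]:
    """Parse GFF3 (`key=value;`) or GTF (`key "value";`) attribute strings."""
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:  # GFF3
            key, _, value = chunk.partition("=")
            attrs[key.strip()] = value.strip()
        else:  # GTF
            parts = chunk.split(None, 1)
            if len(parts) == 2:
                attrs[parts[0]] = parts[1].strip().strip('"')
    return attrs


_GFF_ID_KEYS = ("ID", "gene_id", "Name", "gene", "locus_tag", "Parent")


def read_gene_annotation(
    path,
    genome: GenomeIndex | None = None,
    feature_type: str = "gene",
) -> list[GeneRecord]:
    """Read gene anchors from GFF3/GTF or BED (4+ columns with strand).

    For GFF3/GTF, records with the requested ``feature_type`` (``"gene"``
    or ``"CDS"`` — the convention flag for the start-codon source) are
    kept; the anchor is the leftmost coordinate for + strand features and
    the rightmost for - strand, converted to 0-based.  BED input is
    0-based half-open already; the name column supplies the gene id.

    Records on contigs absent from ``genome`` (when given) are skipped
    with a warning.  Missing strand is an error.
    """
    records: list[GeneRecord] = []
    seen_ids: set[str] = set()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) >= 8 and fields[6] in ("+", "-", ".", "?") and fields[3].isdigit():
                # GFF3/GTF
                contig, _, ftype, start, end, _, strand = fields[:7]
                if ftype != feature_type:
                    continue
                if strand not in ("+", "-"):
                    raise FormatError(f"line {lineno}: missing strand for feature")
                attrs = _parse_gff_attributes(fields[8]) if len(fields) > 8 else {}
                gene_id = next((attrs[k] for k in _GFF_ID_KEYS if k in attrs), None)
                if gene_id is None:
                    gene_id = f"feature_{lineno}"
                start0 = int(start) - 1  # 1-based closed -> 0-based
                end0 = int(end)
                position = start0 if strand == "+" else end0 - 1
            elif len(fields) >= 6:
                # BED6+
                contig, start, end, gene_id = fields[:4]
                strand = fields[5]
                if strand not in ("+", "-"):
                    raise FormatError(f"line {lineno}: missing strand in BED record")
                position = int(start) if strand == "+" else int(end) - 1
            else:
                raise FormatError(
                    f"line {lineno}: not a recognizable GFF3/GTF or stranded BED record"
                )
            if genome is not None and contig not in genome:
                warnings.warn(f"line {lineno}: contig {contig!r} not in genome index; skipped")
                continue
            if genome is not None and not (0 <= position < genome.length_of(contig)):
                raise FormatError(f"line {lineno}: position {position} outside contig {contig!r}")
            if gene_id in seen_ids:
                continue  # first record wins (GTF repeats gene_id per feature)
            seen_ids.add(gene_id)
            records.append(GeneRecord(gene_id, contig, position, strand))
    return records


def read_target_catalog(path) -> TargetSetCatalog:
    """Read a TSV of ``tf_name<TAB>gene_id`` rows into a catalog.

    A header line whose first field is ``tf_name`` is skipped.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"line {lineno}: expected tf_name<TAB>gene_id")
            tf, gene = fields[0].strip(), fields[1].strip()
            if lineno == 1 and tf.lower() == "tf_name":
                continue
            if not tf or not gene:
                raise FormatError(f"line {lineno}: empty field")
            sets.setdefault(tf, set()).add(gene)
    return TargetSetCatalog({tf: frozenset(genes) for tf, genes in sets.items()})


@dataclass(frozen=True)
class BedInterval:
    contig: str
    start: int
    end: int
    name: str = "."
    score: float | str = "."
    strand: str = "."


def write_bed(intervals: Iterable[BedInterval], path, genome: GenomeIndex | None = None) -> None:
    """Write BED6, sorted by contig order (genome order if given) then start.

    Raises on out-of-bounds intervals.  An empty list yields an empty file.
    """
    items = list(intervals)
    for iv in items:
        if not (0 <= iv.start < iv.end):
            raise ValueError(f"invalid interval [{iv.start},{iv.end}) on {iv.contig}")
        if genome is not None:
            if iv.contig not in genome:
                raise ValueError(f"unknown contig {iv.contig!r}")
            if iv.end > genome.length_of(iv.contig):
                raise ValueError(f"interval [{iv.start},{iv.end}) out of bounds on {iv.contig}")
    if genome is not None:
        items.sort(key=lambda iv: (genome.rank(iv.contig), iv.start, iv.end))
    else:
        items.sort(key=lambda iv: (iv.contig, iv.start, iv.end))
    with open(path, "w") as handle:
        for iv in items:
            score = iv.score if isinstance(iv.score, str) else format(iv.score, "g")
            handle.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


def read_bed(path) -> list[BedInterval]:
    """Read BED3/BED6 into intervals (missing columns filled with defaults)."""
    out: list[BedInterval] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: BED needs >= 3 columns")
            name = fields[3] if len(fields) > 3 else "."
            score: float | str = fields[4] if len(fields) > 4 else "."
            strand = fields[5] if len(fields) > 5 else "."
            out.append(BedInterval(fields[0], int(fields[1]), int(fields[2]), name, score, strand))
    return out


def write_bedgraph(values: Mapping[str, np.ndarray], path, genome: GenomeIndex | None = None) -> None:
    """Write per-base vectors as bedGraph, collapsing runs and omitting zeros.

    ``values`` maps contig name -> per-base float vector.  NaN anywhere is
    an error.  Contigs are emitted in genome order when given, else in
    mapping order.
    """
    if genome is not None:
        order = [name for name in genome.names if name in values]
    else:
        order = list(values)
    with open(path, "w") as handle:
        for contig in order:
            vec = np.asarray(values[contig], dtype=float)
            if vec.size == 0:
                continue
            if np.isnan(vec).any():
                raise ValueError(f"NaN value in track for contig {contig!r}")
            # run-length boundaries
            change = np.flatnonzero(np.diff(vec) != 0)
            starts = np.concatenate(([0], change + 1))
            ends = np.concatenate((change + 1, [vec.size]))
            for s, e in zip(starts, ends):
                v = vec[s]
                if v == 0:
                    continue
                handle.write(f"{contig}\t{s}\t{e}\t{format(v, 'g')}\n")


def read_bedgraph(path, genome: GenomeIndex) -> dict[str, np.ndarray]:
    """Expand a bedGraph back into dense per-base vectors over ``genome``."""
    out = {name: np.zeros(length, dtype=float) for name, length in genome}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"line {lineno}: bedGraph needs 4 columns")
            contig, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if contig not in out:
                raise FormatError(f"line {lineno}: unknown contig {contig!r}")
            out[contig][start:end] = value
    return out
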