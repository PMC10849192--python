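import numpy as np
import pytest

from doublechec.io_formats import GenomeIndex
from doublechec.cleavage_profile import CleavageProfile, profile_from_arrays


@pytest.fixture
def genome():
    return GenomeIndex(("chrI", "chrII"), (1000, 600))


@pytest.fixture
def single_contig_genome():
    return GenomeIndex(("chrI",), (1000,))


@pytest.fixture
def make_profile():
    """Factory: per-contig count dict -> CleavageProfile over a matching genome."""

    def _make(counts: dict[str, list[int]], label: str = "p") -> CleavageProfile:
        genome = GenomeIndex(
            tuple(counts), tuple(len(v) for v in counts.values())
        )
        arrays = {k: np.asarray(v, dtype=np.int64) for k, v in counts.items()}
        return profile_from_arrays(genome, arrays, label=label)

    return _make


SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chrI\tLN:1000\n@SQ\tSN:chrII\tLN:600\n"


def sam_line(name, flag, contig, pos1, mapq, cigar, seq_len=None):
    if seq_len is None:
        seq_len = sum(
            int(n) for n, op in _cigar_ops(cigar) if op in "MIS=X"
        )
    seq = "A" * seq_len
    qual = "I" * seq_len
    return f"{name}\t{flag}\t{contig}\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{qual}\n"


def _cigar_ops(cigar):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""


@pytest.fixture
def write_sam(tmp_path):
    """Factory: list of sam_line strings -> path to a SAM file."""

    def _write(lines, name="reads.sam", header=SAM_HEADER):
        path = tmp_path / name
        path.write_text(header + "".join(lines))
        return str(path)

    return _write
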