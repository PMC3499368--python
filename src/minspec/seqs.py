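"""Protein alignment container and FASTA I/O."""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from os import PathLike

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .evomodel import ALPHABET

__all__ = ["Alignment", "read_alignment", "write_alignment", "aligned_difference_count"]


class AlignmentFormatError(ValueError):
    pass


@dataclass
class Alignment:
    """A protein multiple sequence alignment.

    ``site_flags[j]`` is True when column ``j`` contains a gap in any row
    (an indel-containing site); such sites are excluded from mean posterior
    probability summaries downstream. ``site_subsets`` holds named 0-based
    column index sets, e.g. the ligand-contacting positions.
    """

    names: list[str]
    rows: list[str]
    site_subsets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise AlignmentFormatError("names and rows differ in count")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise AlignmentFormatError(f"duplicate sequence names: {dupes}")
        if not self.rows:
            raise AlignmentFormatError("empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            bad = [n for n, r in zip(self.names, self.rows) if len(r) != len(self.rows[0])]
            raise AlignmentFormatError(f"unequal sequence lengths; offending records: {bad}")
        for name, subset in self.site_subsets.items():
            subset = np.asarray(subset, dtype=int)
            if subset.size and (subset.min() < 0 or subset.max() >= self.n_sites):
                raise AlignmentFormatError(f"site subset {name!r} out of range")
            self.site_subsets[name] = subset

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    @property
    def site_flags(self) -> np.ndarray:
        """Boolean mask of indel-containing columns."""
        flags = np.zeros(self.n_sites, dtype=bool)
        for row in self.rows:
            flags |= np.frombuffer(row.encode(), dtype=np.uint8) == ord("-")
        return flags

    @property
    def encoded(self) -> np.ndarray:
        """Integer-encoded matrix (n_sequences, n_sites); -1 marks missing data."""
        return np.vstack([ALPHABET.encode(r) for r in self.rows])

    def empirical_frequencies(self, pseudocount: float = 0.0) -> np.ndarray:
        """Observed amino-acid frequencies across the alignment (+F)."""
        enc = self.encoded
        counts = np.bincount(enc[enc >= 0].ravel(), minlength=20).astype(float)
        counts += pseudocount
        if counts.sum() == 0:
            raise AlignmentFormatError("alignment contains no residue characters")
        return counts / counts.sum()

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]


def read_alignment(path: str | PathLike | io.TextIOBase) -> Alignment:
    """Read a FASTA protein alignment.

    Gaps are preserved; characters outside the 20-state alphabet are kept
    in the rows and treated as missing data by the likelihood machinery.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise AlignmentFormatError(f"no FASTA records found in {path}")
    names = [r.id for r in records]
    rows = [str(r.seq).upper() for r in records]
    return Alignment(names=names, rows=rows)


def write_alignment(alignment: Alignment, path: str | PathLike) -> None:
    records = [
        SeqRecord(Seq(row), id=name, description="")
        for name, row in zip(alignment.names, alignment.rows)
    ]
    SeqIO.write(records, path, "fasta-2line")


def aligned_difference_count(seq_a: str, seq_b: str) -> int:
    """Number of differing residues between two sequences after global
    pairwise alignment (BLOSUM62, affine gaps); gapped columns are counted
    as differences only when one sequence has a residue there.

    For pre-aligned equal-length sequences the gap penalties never engage
    and this reduces to a positionwise mismatch count.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    a = seq_a.replace("-", "").upper()
    b = seq_b.replace("-", "").upper()
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    return sum(1 for x, y in zip(sa, sb) if x != y)
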