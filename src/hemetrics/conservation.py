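"""Pairwise percent identity, alignment-column conservation and motif search.

Identity is computed from a global (Needleman-Wunsch) alignment under
BLOSUM62 with affine gaps (open 10, extend 0.5), via Biopython's
``PairwiseAligner``.  The denominator excludes terminal-gap columns but
counts internal gaps as mismatches; this convention is configurable since
published percent-identity figures rarely state theirs.

Conservation is tallied over a user-supplied multiple sequence alignment
(FASTA or Stockholm): a column is *fully conserved* only when every
sequence carries the same residue and none is gapped.  Residue positions
in reports are 1-based, matching the way structural papers label residues.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from Bio import AlignIO, SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

GAP_CHARS = "-."

_AA = set("ACDEFGHIKLMNPQRSTVWYBZX*")


@dataclass(frozen=True)
class AlignedSet:
    """A multiple sequence alignment: unique ids and equal-length gapped rows."""

    ids: tuple
    sequences: tuple

    def __post_init__(self):
        if len(self.ids) != len(self.sequences) or not self.ids:
            raise ValueError("need one id per sequence")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        object.__setattr__(self, "sequences",
                           tuple(s.upper().replace(".", "-")
                                 for s in self.sequences))

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def row(self, seq_id: str) -> str:
        return self.sequences[self.ids.index(seq_id)]

    @classmethod
    def from_file(cls, path, fmt: str = "auto") -> "AlignedSet":
        path = Path(path)
        if fmt == "auto":
            fmt = ("stockholm" if path.suffix.lower() in (".sto", ".stk",
                                                          ".stockholm")
                   else "fasta")
        aln = AlignIO.read(str(path), fmt)
        return cls(ids=tuple(rec.id for rec in aln),
                   sequences=tuple(str(rec.seq) for rec in aln))


def read_sequence(path, fmt: str = "fasta") -> str:
    """First sequence of a FASTA file as a plain string."""
    rec = next(SeqIO.parse(str(path), fmt))
    return str(rec.seq).upper()


def _check_protein(seq: str, name: str) -> str:
    seq = seq.upper().replace(" ", "")
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"{name}: non-amino-acid symbols {sorted(bad)}")
    return seq


def pairwise_identity(seq_a: str, seq_b: str, *,
                      matrix: str = "BLOSUM62",
                      gap_open: float = 10.0, gap_extend: float = 0.5,
                      count_internal_gaps: bool = True) -> float:
    """Percent identity from a global pairwise alignment.

    Identity = identical aligned pairs / aligned columns excluding
    terminal-gap columns, x100.  Internal gap columns count in the
    denominator unless ``count_internal_gaps`` is False.  The function is
    exactly symmetric in its arguments (the pair is canonically ordered
    before aligning).
    """
    a = _check_protein(seq_a, "seq_a")
    b = _check_protein(seq_b, "seq_b")
    if b < a:
        a, b = b, a

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])

    lead = max(len(ga) - len(ga.lstrip("-")), len(gb) - len(gb.lstrip("-")))
    trail = max(len(ga) - len(ga.rstrip("-")), len(gb) - len(gb.rstrip("-")))
    end = len(ga) - trail
    matches = columns = 0
    for x, y in zip(ga[lead:end], gb[lead:end]):
        gap = x == "-" or y == "-"
        if gap and not count_internal_gaps:
            continue
        columns += 1
        if not gap and x == y:
            matches += 1
    if columns == 0:
        raise ValueError("alignment has no comparable columns")
    return round(100.0 * matches / columns, 1)


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column conservation of an alignment.

    ``consensus[i]`` is the most frequent residue of column i (ties broken
    alphabetically; ``None`` for all-gap columns), ``counts[i]`` how many
    sequences carry it, ``fractions[i] = counts[i] / n``.
    ``fully_conserved`` lists 0-based columns where all n sequences agree
    and none is gapped.
    """

    msa: AlignedSet
    consensus: tuple
    counts: np.ndarray
    fractions: np.ndarray
    fully_conserved: tuple

    def column(self, i: int) -> str:
        return "".join(s[i] for s in self.msa.sequences)

    def occupancy(self, column: int, residue: str) -> int:
        """Number of sequences carrying ``residue`` at a 0-based column."""
        return self.column(column).count(residue.upper())

    def column_for_ref_position(self, ref_id: str, pos: int) -> int:
        """0-based alignment column of 1-based residue ``pos`` of a
        reference sequence."""
        row = self.msa.row(ref_id)
        n = 0
        for col, ch in enumerate(row):
            if ch not in GAP_CHARS:
                n += 1
                if n == pos:
                    return col
        raise IndexError(f"{ref_id} has only {n} residues (asked for {pos})")

    def ref_position_for_column(self, ref_id: str, column: int) -> int | None:
        """1-based residue number of the reference at a 0-based column
        (``None`` if the reference is gapped there)."""
        row = self.msa.row(ref_id)
        if row[column] in GAP_CHARS:
            return None
        return sum(1 for ch in row[:column + 1] if ch not in GAP_CHARS)

    def occupancy_at_ref(self, ref_id: str, pos: int,
                         residue: str | None = None) -> int:
        """How many sequences carry ``residue`` (default: the reference's
        own residue) at the column aligned to reference position ``pos``."""
        col = self.column_for_ref_position(ref_id, pos)
        if residue is None:
            residue = self.msa.row(ref_id)[col]
        return self.occupancy(col, residue)


def conservation_profile(msa: AlignedSet) -> ConservationProfile:
    """Column-wise consensus, counts and fully conserved columns."""
    n = msa.n_sequences
    consensus, counts, full = [], [], []
    for i in range(msa.n_columns):
        col = [s[i] for s in msa.sequences]
        residues = [c for c in col if c not in GAP_CHARS]
        if not residues:
            consensus.append(None)
            counts.append(0)
            continue
        uniq = sorted(set(residues))
        # highest count wins; alphabetical tie-break keeps this deterministic
        best = sorted(uniq, key=lambda r: (-residues.count(r), r))[0]
        consensus.append(best)
        counts.append(residues.count(best))
        if len(residues) == n and len(uniq) == 1:
            full.append(i)
    counts = np.asarray(counts)
    return ConservationProfile(
        msa=msa, consensus=tuple(consensus), counts=counts,
        fractions=counts / n, fully_conserved=tuple(full))


def find_motif(seq: str, motif: str) -> list[tuple[int, int, str]]:
    """Non-overlapping matches of a literal+wildcard motif, left to right.

    The pattern language is amino-acid letters plus ``X`` as a wildcard
    (e.g. ``CXXCH`` for the c-heme attachment motif).  Returns 1-based
    inclusive (start, end, matched_text) tuples.
    """
    if not motif:
        raise ValueError("empty motif pattern")
    motif = motif.upper()
    if not set(motif) <= set("ABCDEFGHIJKLMNOPQRSTUVWXYZ"):
        raise ValueError(f"invalid motif {motif!r}: letters and X only")
    seq = seq.upper()
    pattern = "".join("." if ch == "X" else re.escape(ch) for ch in motif)
    return [(m.start() + 1, m.end(), m.group())
            for m in re.finditer(pattern, seq)]
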