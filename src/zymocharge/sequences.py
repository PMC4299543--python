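"""Protein sequences, global alignment and mutation handling.

The central object is :class:`ProteinSequence`, a one-letter residue string
with a *canonical numbering offset* so that positions can be reported in the
conventional precursor numbering of the protein family (e.g. the famous
R122 position of human cationic trypsinogen) regardless of which chain
fragment is actually held in memory.

Alignment is global (Needleman-Wunsch) with affine gap costs computed by the
Gotoh recursion; a gap of length ``L`` costs ``gap_open + (L - 1) *
gap_extend``.  Substitution matrices are looked up by name from biotite's
matrix collection (BLOSUM62 by default).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import biotite.sequence as _bseq
import biotite.sequence.align as _balign

from .tables import AMINO_ACIDS, charge_of

__all__ = [
    "GAP",
    "ProteinSequence",
    "PairwiseAlignment",
    "ChargeDiffSite",
    "Mutation",
    "global_align",
    "percent_identity",
    "charge_diff_sites",
    "apply_mutations",
    "reverse_mutations",
    "parse_mutations",
    "format_mutations",
    "read_fasta",
    "write_fasta",
]

#: Sentinel marking a gap in an alignment column.
GAP = None


class AlignmentError(ValueError):
    """Raised for invalid alignment inputs (unknown matrix, bad residues)."""


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence with a canonical numbering offset.

    Parameters
    ----------
    id
        Free-text label (FASTA record id).
    residues
        Non-empty string over the 20 standard one-letter codes.
    first_residue_number
        Canonical number of the first residue; residue ``i`` (0-based
        internal index) has canonical number ``first_residue_number + i``.
    """

    id: str
    residues: str
    first_residue_number: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("sequence must be non-empty")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-standard residue codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def last_residue_number(self) -> int:
        return self.first_residue_number + len(self.residues) - 1

    def index_of(self, canonical_position: int) -> int:
        """Internal 0-based index of a canonical residue number."""
        i = canonical_position - self.first_residue_number
        if not 0 <= i < len(self.residues):
            raise IndexError(
                f"canonical position {canonical_position} outside "
                f"[{self.first_residue_number}, {self.last_residue_number}]"
            )
        return i

    def residue_at(self, canonical_position: int) -> str:
        return self.residues[self.index_of(canonical_position)]

    def canonical_numbers(self) -> range:
        return range(self.first_residue_number, self.last_residue_number + 1)

    def subsequence(self, start: int, end: int) -> "ProteinSequence":
        """Slice by canonical numbers, both ends inclusive."""
        i, j = self.index_of(start), self.index_of(end)
        if j < i:
            raise ValueError("end before start")
        return ProteinSequence(self.id, self.residues[i : j + 1], start)


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment of sequences ``a`` and ``b``.

    ``columns`` is an ordered tuple of ``(index_a, index_b)`` pairs of
    0-based internal indices, with :data:`GAP` (``None``) marking a gap.
    """

    a: ProteinSequence
    b: ProteinSequence
    columns: tuple
    score: float
    matrix_name: str
    gap_open: float
    gap_extend: float

    def __post_init__(self) -> None:
        for seq, side in ((self.a, 0), (self.b, 1)):
            idx = [c[side] for c in self.columns if c[side] is not GAP]
            if idx != list(range(len(seq))):
                raise ValueError(
                    "alignment columns must cover each sequence exactly once "
                    "in increasing order"
                )
        if any(c == (GAP, GAP) for c in self.columns):
            raise ValueError("alignment contains an all-gap column")

    def paired_columns(self):
        """Columns where both sequences contribute a residue."""
        return [(i, j) for i, j in self.columns if i is not GAP and j is not GAP]


@dataclass(frozen=True)
class ChargeDiffSite:
    """An aligned position whose formal charge class differs between the
    target (sequence ``a``) and the homolog (sequence ``b``)."""

    canonical_position: int
    target_residue: str
    homolog_residue: str
    target_charge: int
    homolog_charge: int

    def __post_init__(self) -> None:
        if self.target_charge == self.homolog_charge:
            raise ValueError("not a charge difference")

    @property
    def delta_charge(self) -> int:
        return self.homolog_charge - self.target_charge


@dataclass(frozen=True)
class Mutation:
    """A point substitution in canonical numbering, e.g. E79K."""

    canonical_position: int
    from_residue: str
    to_residue: str

    def __post_init__(self) -> None:
        for r in (self.from_residue, self.to_residue):
            if r not in AMINO_ACIDS:
                raise ValueError(f"invalid residue code {r!r}")
        if self.from_residue == self.to_residue:
            raise ValueError("mutation must change the residue")

    def __str__(self) -> str:
        return f"{self.from_residue}{self.canonical_position}{self.to_residue}"

    @property
    def delta_charge(self) -> int:
        return charge_of(self.to_residue) - charge_of(self.from_residue)

    def reversed(self) -> "Mutation":
        return Mutation(self.canonical_position, self.to_residue, self.from_residue)


_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_mutations(text: str) -> list[Mutation]:
    """Parse comma- or whitespace-separated mutation tokens like ``E79K``."""
    muts = []
    for token in re.split(r"[,\s]+", text.strip()):
        if not token:
            continue
        m = _MUTATION_RE.match(token)
        if m is None:
            raise ValueError(f"malformed mutation token {token!r}")
        muts.append(Mutation(int(m.group(2)), m.group(1), m.group(3)))
    _check_unique_positions(muts)
    return muts


def format_mutations(muts: Iterable[Mutation]) -> str:
    return ", ".join(str(m) for m in muts)


def _check_unique_positions(muts: Sequence[Mutation]) -> None:
    positions = [m.canonical_position for m in muts]
    if len(positions) != len(set(positions)):
        raise ValueError("duplicate positions in mutation set")


def apply_mutations(seq: ProteinSequence, muts: Sequence[Mutation]) -> ProteinSequence:
    """Return a new sequence with every mutation applied.

    Each mutation's ``from_residue`` must match the sequence at its canonical
    position; a mismatch usually signals a numbering-offset error and is
    reported as such.
    """
    _check_unique_positions(muts)
    residues = list(seq.residues)
    for m in muts:
        i = seq.index_of(m.canonical_position)
        if residues[i] != m.from_residue:
            raise ValueError(
                f"mutation {m}: sequence has {residues[i]} at canonical "
                f"position {m.canonical_position} (numbering offset error?)"
            )
        residues[i] = m.to_residue
    return replace(seq, residues="".join(residues))


def reverse_mutations(muts: Sequence[Mutation]) -> list[Mutation]:
    return [m.reversed() for m in muts]


# --------------------------------------------------------------------------
# Global alignment (Gotoh affine-gap dynamic programming)
# --------------------------------------------------------------------------

def _load_matrix(name: str) -> tuple[np.ndarray, dict[str, int]]:
    """Score matrix by name from biotite's collection, as a dense array
    indexed by our own residue encoding."""
    alph = _bseq.ProteinSequence.alphabet
    try:
        mat = _balign.SubstitutionMatrix(alph, alph, name.upper())
    except Exception as exc:  # unknown matrix name
        raise AlignmentError(f"unknown substitution matrix {name!r}") from exc
    scores = mat.score_matrix()
    encode = {sym: alph.encode(sym) for sym in AMINO_ACIDS}
    return scores, encode


def global_align(
    a: ProteinSequence,
    b: ProteinSequence,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignment:
    """Optimal global alignment with affine gap costs.

    The score is the sum of substitution scores over residue-residue columns
    minus ``gap_open + (L - 1) * gap_extend`` for every gap of length ``L``
    (terminal gaps included).  Among equally optimal alignments the traceback
    deterministically prefers substitution columns, then gaps in ``b``, then
    gaps in ``a`` (high-road convention: residues are matched as early as
    possible).
    """
    if gap_open < 0 or gap_extend < 0:
        raise ValueError("gap penalties must be non-negative")
    scores, encode = _load_matrix(matrix)
    try:
        ea = np.array([encode[r] for r in a.residues])
        eb = np.array([encode[r] for r in b.residues])
    except KeyError as exc:
        raise AlignmentError(f"residue {exc} not covered by matrix") from exc
    S = scores[np.ix_(ea, eb)].astype(float)

    n, m = len(a), len(b)
    NEG = -np.inf
    # M: a_i aligned to b_j; X: gap in b (a consumed); Y: gap in a.
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        # M and X rows can be vectorised against the previous row;
        # Y needs the left neighbour and stays scalar.
        M[i, 1:] = np.maximum(np.maximum(Mi1[:-1], Xi1[:-1]), Yi1[:-1]) + S[i - 1]
        X[i, :] = np.maximum(
            np.maximum(Mi1, Yi1) - gap_open, Xi1 - gap_extend
        )
        X[i, 0] = -gap_open - (i - 1) * gap_extend
        Yi = Y[i]
        Mi = M[i]
        Xi = X[i]
        for j in range(1, m + 1):
            Yi[j] = max(Mi[j - 1] - gap_open, Yi[j - 1] - gap_extend,
                        Xi[j - 1] - gap_open)

    score = max(M[n, m], X[n, m], Y[n, m])
    # Traceback, tie-break priority M > X > Y.
    columns: list[tuple] = []
    i, j = n, m
    state = max(
        (("M", M[n, m]), ("X", X[n, m]), ("Y", Y[n, m])),
        key=lambda t: (t[1], {"M": 2, "X": 1, "Y": 0}[t[0]]),
    )[0]
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            columns.append((i - 1, j - 1))
            prev = M[i - 1, j - 1] + S[i - 1, j - 1]
            for cand, val in (("M", M[i - 1, j - 1]), ("X", X[i - 1, j - 1]),
                              ("Y", Y[i - 1, j - 1])):
                if abs(val + S[i - 1, j - 1] - M[i, j]) <= tol:
                    state = cand
                    break
            i, j = i - 1, j - 1
        elif state == "X":
            columns.append((i - 1, GAP))
            if abs(M[i - 1, j] - gap_open - X[i, j]) <= tol:
                state = "M"
            elif abs(X[i - 1, j] - gap_extend - X[i, j]) <= tol:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:  # Y
            columns.append((GAP, j - 1))
            if abs(M[i, j - 1] - gap_open - Y[i, j]) <= tol:
                state = "M"
            elif abs(Y[i, j - 1] - gap_extend - Y[i, j]) <= tol:
                state = "Y"
            else:
                state = "X"
            j -= 1
    columns.reverse()
    return PairwiseAlignment(
        a=a, b=b, columns=tuple(columns), score=float(score),
        matrix_name=matrix.upper(), gap_open=gap_open, gap_extend=gap_extend,
    )


def percent_identity(aln: PairwiseAlignment, denominator: str = "paired") -> float:
    """Fraction of identical residues in an alignment, in [0, 1].

    ``denominator`` selects the convention:

    - ``"paired"`` (default): columns where both sequences have a residue,
    - ``"shorter"``: length of the shorter sequence,
    - ``"columns"``: total number of alignment columns.
    """
    paired = aln.paired_columns()
    if not paired:
        raise ValueError("alignment has no residue-residue columns")
    n_identical = sum(
        aln.a.residues[i] == aln.b.residues[j] for i, j in paired
    )
    if denominator == "paired":
        denom = len(paired)
    elif denominator == "shorter":
        denom = min(len(aln.a), len(aln.b))
    elif denominator == "columns":
        denom = len(aln.columns)
    else:
        raise ValueError(f"unknown identity denominator {denominator!r}")
    return n_identical / denom


def charge_diff_sites(aln: PairwiseAlignment) -> list[ChargeDiffSite]:
    """Aligned positions whose formal charge class differs between target
    (``a``) and homolog (``b``), in ascending target canonical numbering."""
    sites = []
    for i, j in aln.paired_columns():
        ra = aln.a.residues[i]
        rb = aln.b.residues[j]
        ca, cb = charge_of(ra), charge_of(rb)
        if ca != cb:
            sites.append(
                ChargeDiffSite(
                    canonical_position=aln.a.first_residue_number + i,
                    target_residue=ra,
                    homolog_residue=rb,
                    target_charge=ca,
                    homolog_charge=cb,
                )
            )
    return sites


# --------------------------------------------------------------------------
# FASTA I/O
# --------------------------------------------------------------------------

_START_RE = re.compile(r"\bstart=(-?\d+)\b")


def read_fasta(path) -> list[ProteinSequence]:
    """Read a multi-record FASTA file.

    A ``start=N`` token in the description sets the canonical number of the
    first residue (default 1).
    """
    seqs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _START_RE.search(rec.description)
        first = int(m.group(1)) if m else 1
        seqs.append(ProteinSequence(rec.id, str(rec.seq).upper(), first))
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs: Iterable[ProteinSequence], path) -> None:
    """Write sequences as FASTA, 60 columns per line, annotating non-default
    numbering offsets as ``start=N``."""
    records = []
    for s in seqs:
        desc = f"start={s.first_residue_number}" if s.first_residue_number != 1 else ""
        records.append(SeqRecord(Seq(s.residues), id=s.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)
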