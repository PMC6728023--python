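"""Alignment-based organism distances.

Pairwise global (Needleman-Wunsch) alignment with an affine gap penalty
produces an optimal score S; dividing by the maximum attainable score M
(the score of a mismatch-free, gap-free alignment) gives the dimensionless
distance

    P = 1 - S / M.

P is 0 for identical sequences and can exceed 1 when gaps and mismatches
subtract more than matches add.  Scoring defaults follow the nucleotide
scheme +5 match / -4 mismatch with gap open 10 and gap extension 0.5;
amino-acid sequences are scored with standard BLOSUM/PAM matrices.

Three organism-level constructions turn P into distance matrices:

* ``DRIBO``  — P over the 16S-like ``RIBO`` marker sequences;
* ``DENZS``  — mean of the per-enzyme-family distances over every EC number
  common to all organisms in the set;
* ``D1ENZ``  — the distance for a single common EC number drawn at random.

When an organism carries multiple copies of a marker, each sequence of the
organism with fewer copies is matched to its best-scoring partner in the
other organism (many-to-one allowed) and the P values are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .dendro import DistanceMatrix
from .io_formats import Alphabet, Dataset, SequenceRecord, RIBO_MARKER

__all__ = [
    "SubstitutionMatrix",
    "GapPenalty",
    "AlignmentScore",
    "GENE_METHODS",
    "load_matrix",
    "available_matrices",
    "nw_score",
    "max_score",
    "p_distance",
    "organism_pair_distance",
    "common_markers",
    "distance_matrix_gene",
]

GENE_METHODS = ("DRIBO", "DENZS", "D1ENZ")

#: nucleotide scheme: +5 for a match, -4 for a mismatch
NUC_MATCH = 5.0
NUC_MISMATCH = -4.0

NEG_INF = -1e30  # safe -infinity for DP cells (avoids inf-inf warnings)


class SubstitutionMatrix:
    """Symmetric substitution score table over one alphabet.

    ``NUC`` is the built-in +5/-4 nucleotide scheme; every other name is
    resolved through the standard BLOSUM/PAM tables (amino-acid alphabet,
    including the B/Z/X/* ambiguity codes those tables score).
    """

    def __init__(self, name: str, alphabet: Alphabet, symbols: str, table: np.ndarray):
        self.name = name
        self.alphabet = alphabet
        self.symbols = symbols
        self._index = {c: i for i, c in enumerate(symbols)}
        self.table = np.asarray(table, dtype=float)
        if not np.allclose(self.table, self.table.T):
            raise ValueError(f"substitution matrix {name} is not symmetric")

    def score(self, x: str, y: str) -> float:
        try:
            return float(self.table[self._index[x], self._index[y]])
        except KeyError as exc:
            raise ValueError(f"symbol {exc.args[0]!r} not scored by matrix {self.name}") from exc

    def encode(self, residues: str) -> np.ndarray:
        try:
            return np.fromiter((self._index[c] for c in residues), dtype=np.intp)
        except KeyError as exc:
            raise ValueError(f"symbol {exc.args[0]!r} not scored by matrix {self.name}") from exc


def available_matrices() -> list[str]:
    return ["NUC"] + [
        n for n in substitution_matrices.load() if n.startswith(("BLOSUM", "PAM"))
    ]


@lru_cache(maxsize=None)
def load_matrix(name: str) -> SubstitutionMatrix:
    """Load ``NUC`` or a named BLOSUM/PAM table."""
    if name == "NUC":
        symbols = "ACGTU"
        n = len(symbols)
        table = np.full((n, n), NUC_MISMATCH)
        np.fill_diagonal(table, NUC_MATCH)
        return SubstitutionMatrix("NUC", Alphabet.NUCLEOTIDE, symbols, table)
    try:
        arr = substitution_matrices.load(name)
    except FileNotFoundError as exc:
        raise ValueError(
            f"unknown substitution matrix {name!r}; available: {available_matrices()}"
        ) from exc
    symbols = "".join(arr.alphabet)
    return SubstitutionMatrix(name, Alphabet.AMINO_ACID, symbols, np.asarray(arr))


@dataclass(frozen=True)
class GapPenalty:
    """Affine gap cost: a gap of length L subtracts open_cost + L * extend_cost."""

    open_cost: float = 10.0
    extend_cost: float = 0.5

    def __post_init__(self) -> None:
        if self.open_cost < 0 or self.extend_cost < 0:
            raise ValueError("gap costs must be non-negative")


@dataclass(frozen=True)
class AlignmentScore:
    """Raw optimal score S, maximum possible score M, and P = 1 - S/M."""

    S: float
    M: float
    P: float


def _check_pair(a: SequenceRecord, b: SequenceRecord, m: SubstitutionMatrix) -> None:
    if a.alphabet is not b.alphabet:
        raise ValueError(
            f"alphabet mismatch: {a.organism_id}|{a.marker_id} is {a.alphabet.value}, "
            f"{b.organism_id}|{b.marker_id} is {b.alphabet.value}"
        )
    if a.alphabet is not m.alphabet:
        raise ValueError(
            f"matrix {m.name} is {m.alphabet.value} but sequences are {a.alphabet.value}"
        )


def nw_score(
    a: SequenceRecord,
    b: SequenceRecord,
    m: SubstitutionMatrix,
    g: GapPenalty = GapPenalty(),
) -> float:
    """Optimal global alignment score under affine gap costs (Gotoh DP).

    Three states per cell: a substitution (diagonal), a gap in ``b``
    (vertical) and a gap in ``a`` (horizontal).  Rows are computed with numpy;
    the within-row dependency of the horizontal-gap state is resolved with a
    running prefix maximum, since the best horizontal gap ending at column j
    is ``max_k (best[k] - open - (j - k) * extend)``.
    """
    _check_pair(a, b, m)
    ai = m.encode(a.residues)
    bi = m.encode(b.residues)
    go, ge = g.open_cost, g.extend_cost
    la, lb = len(ai), len(bi)
    score_rows = m.table[ai][:, bi]  # la x lb substitution scores

    cols = np.arange(lb + 1, dtype=float)
    # row 0: only horizontal gaps possible
    prev_M = np.full(lb + 1, NEG_INF)
    prev_M[0] = 0.0
    prev_Ix = np.full(lb + 1, NEG_INF)
    prev_Iy = np.full(lb + 1, NEG_INF)
    prev_Iy[1:] = -(go + cols[1:] * ge)

    for i in range(1, la + 1):
        curr_M = np.full(lb + 1, NEG_INF)
        curr_M[1:] = score_rows[i - 1] + np.maximum(
            prev_M[:-1], np.maximum(prev_Ix[:-1], prev_Iy[:-1])
        )
        # vertical gap: extend down from row i-1
        curr_Ix = np.maximum(
            np.maximum(prev_M, prev_Iy) - go - ge,
            prev_Ix - ge,
        )
        # horizontal gap via prefix max of u[k] = best2[k] - open + k*extend
        u = np.maximum(curr_M, curr_Ix) - go + cols * ge
        run = np.maximum.accumulate(u[:-1])
        curr_Iy = np.full(lb + 1, NEG_INF)
        curr_Iy[1:] = run - cols[1:] * ge
        prev_M, prev_Ix, prev_Iy = curr_M, curr_Ix, curr_Iy

    return float(max(prev_M[lb], prev_Ix[lb], prev_Iy[lb]))


def _self_score(rec: SequenceRecord, m: SubstitutionMatrix) -> float:
    idx = m.encode(rec.residues)
    return float(m.table[idx, idx].sum())


def max_score(a: SequenceRecord, b: SequenceRecord, m: SubstitutionMatrix) -> float:
    """Maximum attainable score: the smaller of the two ungapped self-scores.

    For unequal lengths a mismatch-free gap-free alignment does not exist;
    taking the minimum of the self-alignment scores keeps P(a, a) = 0 exactly
    and makes P scale-free.
    """
    _check_pair(a, b, m)
    M = min(_self_score(a, m), _self_score(b, m))
    if M <= 0:
        raise ValueError(
            f"maximum score {M} is not positive; P undefined under matrix {m.name}"
        )
    return M


def p_distance(
    a: SequenceRecord,
    b: SequenceRecord,
    m: SubstitutionMatrix,
    g: GapPenalty = GapPenalty(),
) -> float:
    """P = 1 - S/M; zero for identical sequences, may exceed 1 for bad alignments."""
    return 1.0 - nw_score(a, b, m, g) / max_score(a, b, m)


def alignment_score(
    a: SequenceRecord,
    b: SequenceRecord,
    m: SubstitutionMatrix,
    g: GapPenalty = GapPenalty(),
) -> AlignmentScore:
    S = nw_score(a, b, m, g)
    M = max_score(a, b, m)
    return AlignmentScore(S=S, M=M, P=1.0 - S / M)


def organism_pair_distance(
    seqsA: Sequence[SequenceRecord],
    seqsB: Sequence[SequenceRecord],
    m: SubstitutionMatrix,
    g: GapPenalty = GapPenalty(),
) -> float:
    """Best-match averaged P between two organisms' copies of one marker.

    Each sequence of the smaller list (ties resolved in favor of the first
    argument) is paired with its minimum-P partner in the other list
    (many-to-one allowed); the mean of those minima is the distance.  Applying
    the rule from the smaller side regardless of argument order makes the
    result symmetric.
    """
    if not seqsA or not seqsB:
        raise ValueError("organism_pair_distance requires non-empty sequence lists")
    if len(seqsB) < len(seqsA):
        small, large = seqsB, seqsA
    else:
        small, large = seqsA, seqsB
    minima = [min(p_distance(x, y, m, g) for y in large) for x in small]
    return float(np.mean(minima))


def common_markers(orgs: Sequence[str], dataset: Dataset) -> set[str]:
    """EC-style markers present in every organism of the set (RIBO excluded)."""
    if not orgs:
        return set()
    common: set[str] | None = None
    for org in orgs:
        markers = {m for m in dataset.markers_of(org) if m != RIBO_MARKER}
        common = markers if common is None else common & markers
    return common or set()


def _marker_matrix(
    orgs: list[str],
    dataset: Dataset,
    marker: str,
    m: SubstitutionMatrix,
    g: GapPenalty,
) -> np.ndarray:
    n = len(orgs)
    vals = np.zeros((n, n))
    seqs = {org: dataset.get_seqs(org, marker) for org in orgs}
    for org in orgs:
        if not seqs[org]:
            raise ValueError(f"organism {org!r} has no sequence for marker {marker!r}")
    for i in range(n):
        for j in range(i + 1, n):
            d = organism_pair_distance(seqs[orgs[i]], seqs[orgs[j]], m, g)
            vals[i, j] = vals[j, i] = d
    return vals


def distance_matrix_gene(
    orgs: Sequence[str],
    dataset: Dataset,
    method: str,
    m: SubstitutionMatrix | None = None,
    g: GapPenalty = GapPenalty(),
    rng: np.random.Generator | None = None,
) -> DistanceMatrix:
    """Gene-based distance matrix for one organism set.

    ``DRIBO`` aligns the nucleotide RIBO sequences under the NUC scheme (or a
    caller-supplied matrix); ``DENZS`` averages the per-EC matrices uniformly
    over all common EC numbers; ``D1ENZ`` uses a single common EC number drawn
    with the supplied seeded generator.
    """
    orgs = sorted(orgs)
    if len(set(orgs)) != len(orgs):
        raise ValueError("duplicate organism ids")
    if method not in GENE_METHODS:
        raise ValueError(f"unknown gene distance method {method!r}")
    if method == "DRIBO":
        mat = m or load_matrix("NUC")
        vals = _marker_matrix(list(orgs), dataset, RIBO_MARKER, mat, g)
        return DistanceMatrix(labels=list(orgs), values=vals)
    mat = m or load_matrix("BLOSUM62")
    markers = sorted(common_markers(orgs, dataset))
    if not markers:
        raise ValueError(f"no EC number common to all organisms in set {list(orgs)}")
    if method == "D1ENZ":
        if rng is None:
            raise ValueError("D1ENZ requires a seeded random generator")
        markers = [markers[rng.integers(len(markers))]]
    per_marker = [_marker_matrix(list(orgs), dataset, mk, mat, g) for mk in markers]
    vals = np.mean(per_marker, axis=0)
    return DistanceMatrix(labels=list(orgs), values=vals)
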