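"""Affine-gap pairwise alignment and a progressive multiple aligner.

This is the dynamic-programming core behind profile construction and the
search stages: local and global alignment with affine gap costs over an
arbitrary symmetric substitution matrix, and a progressive multiple
alignment (k-mer distance guide tree + UPGMA + profile-profile merges).
Inputs here are desk-scale (curated family members), so the DP is written
for exactness and deterministic traceback rather than speed; the bulk
fragment search uses the vectorized kernels in :mod:`ihat._dp`.

Gap convention: a gap of length ``k`` costs ``gap_open + (k-1)*gap_extend``
(the opening charge covers the first gapped position). Defaults are
BLOSUM62 with gap_open 11, gap_extend 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

__all__ = [
    "PROTEIN_ALPHABET",
    "SubstitutionMatrix",
    "PairwiseAlignment",
    "MultipleAlignment",
    "pairwise_align",
    "progressive_msa",
]

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Robinson & Robinson amino-acid background frequencies (normalized),
#: the standard background for profile pseudocounts and null models.
_ROBINSON = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}

NEG = float("-inf")


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric residue-pair scores (half-bit units) plus a background.

    ``alphabet`` is the ordered residue alphabet, ``scores`` the (k, k)
    symmetric score table and ``background`` a positive frequency vector
    summing to one.
    """

    alphabet: str
    scores: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.alphabet)
        if self.scores.shape != (k, k):
            raise ValueError("score table shape does not match alphabet")
        if not np.allclose(self.scores, self.scores.T):
            raise ValueError("score table must be symmetric")
        if np.any(self.background <= 0) or abs(self.background.sum() - 1) > 1e-9:
            raise ValueError("background must be positive and sum to 1")

    def index(self, seq: str) -> np.ndarray:
        idx = np.array([self.alphabet.find(c) for c in seq], dtype=np.intp)
        if np.any(idx < 0):
            bad = sorted({c for c in seq if c not in self.alphabet})
            raise ValueError(f"residues {bad} outside matrix alphabet")
        return idx

    def score(self, a: str, b: str) -> float:
        return float(self.scores[self.alphabet.index(a), self.alphabet.index(b)])

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        """The default scoring fixture: BLOSUM62 over the 20 amino acids."""
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        k = len(PROTEIN_ALPHABET)
        scores = np.empty((k, k))
        for i, a in enumerate(PROTEIN_ALPHABET):
            for j, b in enumerate(PROTEIN_ALPHABET):
                scores[i, j] = mat[a, b]
        bg = np.array([_ROBINSON[c] for c in PROTEIN_ALPHABET])
        return cls(PROTEIN_ALPHABET, scores, bg / bg.sum())

    @classmethod
    def from_ncbi(cls, path, background=None) -> "SubstitutionMatrix":
        """Load a matrix in NCBI text format, restricted to the 20 residues."""
        from Bio.Align import substitution_matrices

        with open(path) as fh:
            mat = substitution_matrices.read(fh)
        k = len(PROTEIN_ALPHABET)
        scores = np.empty((k, k))
        for i, a in enumerate(PROTEIN_ALPHABET):
            for j, b in enumerate(PROTEIN_ALPHABET):
                scores[i, j] = mat[a, b]
        if background is None:
            bg = np.array([_ROBINSON[c] for c in PROTEIN_ALPHABET])
        else:
            bg = np.asarray(background, dtype=float)
        return cls(PROTEIN_ALPHABET, scores, bg / bg.sum())


@dataclass(frozen=True)
class PairwiseAlignment:
    score: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    aligned_query: str
    aligned_subject: str


@dataclass
class MultipleAlignment:
    """Gapped rows keyed by sequence id, all of equal length."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("MSA rows differ in length")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def ungapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace("-", "")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for seq_id in self.rows:
                fh.write(f">{seq_id}\n{self.rows[seq_id]}\n")


# ---------------------------------------------------------------------------
# generic affine DP over a precomputed cell-score matrix
#
# Three states per cell: M (diagonal), U (gap in subject, consumes query),
# L (gap in query, consumes subject). Traceback prefers M > U > L on ties.

_DIAG, _UP, _LEFT = 0, 1, 2


def _affine_global(S: np.ndarray, go: float, ge: float):
    """Optimal global alignment over cell scores S (m x n). Returns
    (score, moves) where moves is a list of _DIAG/_UP/_LEFT from start."""
    m, n = S.shape
    M = np.full((m + 1, n + 1), NEG)
    U = np.full((m + 1, n + 1), NEG)
    L = np.full((m + 1, n + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        U[i, 0] = -(go + (i - 1) * ge)
    for j in range(1, n + 1):
        L[0, j] = -(go + (j - 1) * ge)
    for i in range(1, m + 1):
        Si = S[i - 1]
        for j in range(1, n + 1):
            M[i, j] = Si[j - 1] + max(M[i - 1, j - 1], U[i - 1, j - 1], L[i - 1, j - 1])
            U[i, j] = max(M[i - 1, j] - go, U[i - 1, j] - ge, L[i - 1, j] - go)
            L[i, j] = max(M[i, j - 1] - go, L[i, j - 1] - ge, U[i, j - 1] - go)
    end_scores = (M[m, n], U[m, n], L[m, n])
    score = max(end_scores)
    state = end_scores.index(score)  # tie order M > U > L

    moves = []
    i, j = m, n
    while i > 0 or j > 0:
        if state == _DIAG:
            moves.append(_DIAG)
            prev = (M[i - 1, j - 1], U[i - 1, j - 1], L[i - 1, j - 1])
            state = prev.index(max(prev))
            i, j = i - 1, j - 1
        elif state == _UP:
            moves.append(_UP)
            cand = (M[i - 1, j] - go, U[i - 1, j] - ge, L[i - 1, j] - go)
            state = cand.index(max(cand))
            i -= 1
        else:
            moves.append(_LEFT)
            # cand order is (M, L, U); map back to state codes
            cand = (M[i, j - 1] - go, L[i, j - 1] - ge, U[i, j - 1] - go)
            state = (_DIAG, _LEFT, _UP)[cand.index(max(cand))]
            j -= 1
    moves.reverse()
    return float(score), moves


def _affine_local(S: np.ndarray, go: float, ge: float):
    """Best local alignment over cell scores S. Local alignments start and
    end on a matched cell (trimming terminal gaps never lowers the score).
    Returns (score, moves, (i0, i1, j0, j1)) with 1-based inclusive spans;
    score 0 means the empty alignment (spans (0, 0))."""
    m, n = S.shape
    M = np.zeros((m + 1, n + 1))
    U = np.full((m + 1, n + 1), NEG)
    L = np.full((m + 1, n + 1), NEG)
    M[0, :] = NEG
    M[:, 0] = NEG
    M[0, 0] = 0.0
    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        Si = S[i - 1]
        for j in range(1, n + 1):
            M[i, j] = Si[j - 1] + max(
                0.0, M[i - 1, j - 1], U[i - 1, j - 1], L[i - 1, j - 1]
            )
            U[i, j] = max(M[i - 1, j] - go, U[i - 1, j] - ge, L[i - 1, j] - go)
            L[i, j] = max(M[i, j - 1] - go, L[i, j - 1] - ge, U[i, j - 1] - go)
            if M[i, j] > best:
                best, bi, bj = M[i, j], i, j
    if best <= 0.0:
        return 0.0, [], (0, 0, 0, 0)

    moves = []
    i, j, state = bi, bj, _DIAG
    while True:
        if state == _DIAG:
            moves.append(_DIAG)
            prev = (M[i - 1, j - 1], U[i - 1, j - 1], L[i - 1, j - 1])
            mx = max(prev)
            i, j = i - 1, j - 1
            if mx <= 0.0:
                break
            state = prev.index(mx)
        elif state == _UP:
            moves.append(_UP)
            cand = (M[i - 1, j] - go, U[i - 1, j] - ge, L[i - 1, j] - go)
            state = cand.index(max(cand))
            i -= 1
        else:
            moves.append(_LEFT)
            cand = (M[i, j - 1] - go, L[i, j - 1] - ge, U[i, j - 1] - go)
            k = cand.index(max(cand))
            state = (_DIAG, _LEFT, _UP)[k]
            j -= 1
    moves.reverse()
    return float(best), moves, (i + 1, bi, j + 1, bj)


def _moves_to_strings(a: str, b: str, moves, i0: int, j0: int):
    qa, qb = [], []
    i, j = i0, j0
    for mv in moves:
        if mv == _DIAG:
            qa.append(a[i]); qb.append(b[j]); i += 1; j += 1
        elif mv == _UP:
            qa.append(a[i]); qb.append("-"); i += 1
        else:
            qa.append("-"); qb.append(b[j]); j += 1
    return "".join(qa), "".join(qb)


def pairwise_align(
    a: str,
    b: str,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    mode: str = "local",
) -> PairwiseAlignment:
    """Optimal affine-gap alignment of two protein sequences.

    ``mode`` is ``"local"`` (Smith-Waterman; the best-scoring non-negative
    segment pair) or ``"global"`` (Needleman-Wunsch). Traceback is
    deterministic with tie order diagonal > up > left. Spans are 1-based
    inclusive; a score-zero local alignment has empty spans ``(0, 0)``.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if not gap_open >= gap_extend >= 0:
        raise ValueError("require gap_open >= gap_extend >= 0")
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    ia, ib = matrix.index(a), matrix.index(b)
    S = matrix.scores[np.ix_(ia, ib)]
    if mode == "global":
        score, moves = _affine_global(S, gap_open, gap_extend)
        qa, qb = _moves_to_strings(a, b, moves, 0, 0)
        return PairwiseAlignment(score, (1, len(a)), (1, len(b)), qa, qb)
    if mode == "local":
        score, moves, (i0, i1, j0, j1) = _affine_local(S, gap_open, gap_extend)
        if not moves:
            return PairwiseAlignment(0.0, (0, 0), (0, 0), "", "")
        qa, qb = _moves_to_strings(a, b, moves, i0 - 1, j0 - 1)
        return PairwiseAlignment(score, (i0, i1), (j0, j1), qa, qb)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# progressive multiple alignment


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _freq_matrix(rows: list[str], matrix: SubstitutionMatrix) -> np.ndarray:
    """Per-column residue+gap frequency matrix (L x k+1), gap index last."""
    k = len(matrix.alphabet)
    L = len(rows[0])
    F = np.zeros((L, k + 1))
    lookup = {c: i for i, c in enumerate(matrix.alphabet)}
    lookup["-"] = k
    for row in rows:
        for j, c in enumerate(row):
            F[j, lookup[c]] += 1.0
    return F / len(rows)


def _merge(groupA, groupB, matrix, gap_open, gap_extend):
    """Profile-profile merge with mean-of-pairs column scores.

    Residue pairs score by the substitution matrix; residue-vs-gap pairs
    score -gap_extend and gap-gap pairs 0 (existing gaps are not re-opened).
    """
    k = len(matrix.alphabet)
    M21 = np.zeros((k + 1, k + 1))
    M21[:k, :k] = matrix.scores
    M21[:k, k] = -gap_extend
    M21[k, :k] = -gap_extend
    rowsA = [groupA[i] for i in sorted(groupA)]
    rowsB = [groupB[i] for i in sorted(groupB)]
    S = _freq_matrix(rowsA, matrix) @ M21 @ _freq_matrix(rowsB, matrix).T
    _, moves = _affine_global(S, gap_open, gap_extend)
    outA: dict[str, list[str]] = {i: [] for i in groupA}
    outB: dict[str, list[str]] = {i: [] for i in groupB}
    ia = ib = 0
    for mv in moves:
        if mv == _DIAG:
            for i in groupA:
                outA[i].append(groupA[i][ia])
            for i in groupB:
                outB[i].append(groupB[i][ib])
            ia += 1
            ib += 1
        elif mv == _UP:
            for i in groupA:
                outA[i].append(groupA[i][ia])
            for i in groupB:
                outB[i].append("-")
            ia += 1
        else:
            for i in groupA:
                outA[i].append("-")
            for i in groupB:
                outB[i].append(groupB[i][ib])
            ib += 1
    merged = {i: "".join(outA[i]) for i in outA}
    merged.update({i: "".join(outB[i]) for i in outB})
    return merged


def progressive_msa(
    seqs,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> MultipleAlignment:
    """Progressive multiple alignment of protein records.

    The guide tree is UPGMA over fractional shared 3-mer distances; groups
    are merged bottom-up with profile-profile global alignment using
    mean-of-pairs column scores. Merge order and all traceback ties are
    deterministic (sequences are processed lexicographically by id).

    ``seqs`` is an iterable of objects with ``.id`` and ``.seq`` (Biopython
    SeqRecords) or (id, sequence) tuples.
    """
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    items = []
    for s in seqs:
        if hasattr(s, "id"):
            items.append((s.id, str(s.seq)))
        else:
            items.append((s[0], str(s[1])))
    if not items:
        raise ValueError("progressive_msa requires at least one sequence")
    if len({i for i, _ in items}) != len(items):
        raise ValueError("duplicate sequence ids")
    items.sort(key=lambda t: t[0])
    if len(items) == 1:
        return MultipleAlignment({items[0][0]: items[0][1]})

    n = len(items)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _kmer_distance(items[i][1], items[j][1])
    Z = average(squareform(D, checks=False))

    clusters: dict[int, dict[str, str]] = {
        i: {items[i][0]: items[i][1]} for i in range(n)
    }
    for step, (ca, cb, _, _) in enumerate(Z):
        a, b = clusters.pop(int(ca)), clusters.pop(int(cb))
        clusters[n + step] = _merge(a, b, matrix, gap_open, gap_extend)
    (merged,) = clusters.values()
    return MultipleAlignment({i: merged[i] for i, _ in items})
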