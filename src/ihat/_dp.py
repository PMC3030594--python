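"""Vectorized affine-gap dynamic programming kernels for profile search.

These kernels score many equal-length sequences against one profile at
once, vectorizing each DP row across the batch with numpy. The horizontal
(insertion) state is resolved with a running-maximum prefix scan: for
gap_open >= gap_extend an insertion never closes and immediately reopens,
so the best insertion ending at column c is

    E[c] = max_{k < c} (H'[k] + k*ge) - go - (c-1)*ge

where H' is the cell score before insertions are considered. This makes
every row a handful of O(n) array operations instead of a scalar loop.

Scores here are profile column scores (bits); gap penalties are in the
same units. All kernels are exact (verified against brute-force
enumeration in the test suite), not heuristic.
"""

from __future__ import annotations

import numpy as np

NEG = -1.0e30


def batch_local(col_scores: np.ndarray, idx: np.ndarray, gap_open: float, gap_extend: float):
    """Best local (Smith-Waterman) score of each batch sequence vs a profile.

    Parameters
    ----------
    col_scores:
        (m, n_symbols) per-column scores for every encoded symbol.
    idx:
        (B, n) integer-encoded sequences (columns of ``col_scores``).
    gap_open, gap_extend:
        Affine penalties; a gap of length k costs open + (k-1)*extend.

    Returns
    -------
    (best, end_i, end_j):
        Best score per sequence (0 when no positive segment exists), the
        1-based profile row and 0-based sequence column of the alignment
        end. Ties resolve to the earliest profile row, then the earliest
        sequence column.
    """
    if not gap_open >= gap_extend >= 0:
        raise ValueError("require gap_open >= gap_extend >= 0")
    idx = np.atleast_2d(idx)
    B, n = idx.shape
    m = col_scores.shape[0]
    go, ge = float(gap_open), float(gap_extend)

    Hprev = np.zeros((B, n + 1))
    Fprev = np.full((B, n + 1), NEG)
    best = np.zeros(B)
    end_i = np.zeros(B, dtype=np.intp)
    end_j = np.zeros(B, dtype=np.intp)
    ramp = np.arange(n) * ge

    for i in range(1, m + 1):
        row_s = col_scores[i - 1][idx]
        D = Hprev[:, :-1] + row_s
        F = np.maximum(Hprev[:, 1:] - go, Fprev[:, 1:] - ge)
        Hp = np.maximum(np.maximum(D, F), 0.0)
        A = np.maximum.accumulate(Hp + ramp, axis=1)
        E = np.empty((B, n))
        E[:, 0] = NEG
        if n > 1:
            E[:, 1:] = A[:, :-1] - go - ramp[1:] + ge
        H = np.maximum(Hp, E)

        row_best = Hp.max(axis=1)
        upd = row_best > best
        if upd.any():
            best = np.where(upd, row_best, best)
            row_arg = np.argmax(Hp, axis=1)
            end_i[upd] = i
            end_j[upd] = row_arg[upd]
        Hprev[:, 1:] = H
        Fprev[:, 1:] = F
    return best, end_i, end_j


def local_span(col_scores: np.ndarray, idx: np.ndarray, gap_open: float, gap_extend: float):
    """Best local score plus 1-based inclusive profile and sequence spans.

    The alignment end comes from a forward pass; the start from rerunning
    the same kernel on the reversed prefix submatrix (the classic
    two-pass trick), which avoids storing traceback matrices.
    """
    idx = np.asarray(idx)
    (score,), (ei,), (ej,) = batch_local(col_scores, idx[None, :], gap_open, gap_extend)
    if score <= 0.0:
        return 0.0, (0, 0), (0, 0)
    rev_cols = col_scores[ei - 1 :: -1]
    rev_idx = idx[ej::-1]
    (rscore,), (ri,), (rj,) = batch_local(rev_cols, rev_idx[None, :], gap_open, gap_extend)
    if not np.isclose(score, rscore):  # pragma: no cover - internal check
        raise AssertionError("forward/reverse local DP scores disagree")
    i0 = ei - ri + 1
    j0 = ej - rj + 1
    return float(score), (int(i0), int(ei)), (int(j0), int(ej + 1))


def glocal_score(col_scores: np.ndarray, idx: np.ndarray, gap_open: float, gap_extend: float) -> float:
    """Score a sequence against the FULL profile with free sequence ends.

    Every profile column must be accounted for (matched or deleted at
    affine cost); the sequence contributes an unpenalized window. Used for
    member verification against a provisional profile.
    """
    if not gap_open >= gap_extend >= 0:
        raise ValueError("require gap_open >= gap_extend >= 0")
    idx = np.asarray(idx)
    n = idx.shape[0]
    m = col_scores.shape[0]
    go, ge = float(gap_open), float(gap_extend)

    Hprev = np.zeros(n + 1)
    Fprev = np.full(n + 1, NEG)
    ramp = np.arange(n) * ge
    for i in range(1, m + 1):
        row_s = col_scores[i - 1][idx]
        D = Hprev[:-1] + row_s
        F = np.maximum(Hprev[1:] - go, Fprev[1:] - ge)
        Hp = np.maximum(D, F)
        A = np.maximum.accumulate(Hp + ramp)
        E = np.empty(n)
        E[0] = NEG
        if n > 1:
            E[1:] = A[:-1] - go - ramp[1:] + ge
        H = np.maximum(Hp, E)
        Hprev[1:] = H
        Hprev[0] = -(go + (i - 1) * ge)  # leading profile columns deleted
        Fprev[1:] = F
        Fprev[0] = NEG
    return float(Hprev.max())
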