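"""Shared fixtures: scoring matrices, compact synthetic worlds, and
brute-force alignment enumerators used as independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from ihat.alignment import SubstitutionMatrix
from ihat.fragment_sim import (
    SimulationSpec,
    fragments_to_records,
    label_truth,
    make_toy_world,
    sample_fragments,
)


@pytest.fixture(scope="session")
def blosum62():
    return SubstitutionMatrix.blosum62()


@pytest.fixture(scope="session")
def small_world():
    """A compact toy world (short spacers) for fast pipeline tests."""
    return make_toy_world(5, spacer_length=600)


@pytest.fixture(scope="session")
def small_world_fragments(small_world):
    frags = sample_fragments(
        small_world.genome, SimulationSpec(fragment_length=350, coverage=20.0, seed=5)
    )
    return label_truth(frags, small_world.loci)


@pytest.fixture(scope="session")
def small_world_records(small_world_fragments):
    return fragments_to_records(small_world_fragments)


# ---------------------------------------------------------------------------
# brute-force oracles: exhaustive enumeration of alignment move sequences,
# independent of any DP recurrence in the package


def brute_global(a: str, b: str, score_fn, go: float, ge: float) -> float:
    """Optimal global alignment score by exhaustive path enumeration.

    A gap of length k costs go + (k-1)*ge; consecutive same-direction gap
    moves extend, anything else opens.
    """
    best = [-np.inf]

    def rec(i, j, prev, acc):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], acc)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "D", acc + score_fn(a[i], b[j]))
        if i < len(a):
            rec(i + 1, j, "U", acc - (ge if prev == "U" else go))
        if j < len(b):
            rec(i, j + 1, "L", acc - (ge if prev == "L" else go))

    rec(0, 0, "", 0.0)
    return best[0]


def brute_local_matrix(S: np.ndarray, go: float, ge: float) -> float:
    """Best local alignment score over a cell-score matrix by enumerating
    every path from every start cell (paths begin with a match; scores at
    every intermediate point are candidates, so trailing gaps never win)."""
    m, n = S.shape
    best = [0.0]

    def rec(i, j, prev, acc):
        best[0] = max(best[0], acc)
        if i < m and j < n:
            rec(i + 1, j + 1, "D", acc + S[i, j])
        if i < m:
            rec(i + 1, j, "U", acc - (ge if prev == "U" else go))
        if j < n:
            rec(i, j + 1, "L", acc - (ge if prev == "L" else go))

    for i0 in range(m):
        for j0 in range(n):
            rec(i0 + 1, j0 + 1, "D", S[i0, j0])
    return best[0]


def brute_local(a: str, b: str, score_fn, go: float, ge: float) -> float:
    S = np.array([[score_fn(x, y) for y in b] for x in a])
    return brute_local_matrix(S, go, ge)


def brute_glocal_matrix(S: np.ndarray, go: float, ge: float) -> float:
    """Best glocal score (all profile rows consumed, free sequence ends)
    by exhaustive enumeration."""
    m, n = S.shape
    best = [-np.inf]

    def rec(i, j, prev, acc):
        if i == m:
            best[0] = max(best[0], acc)
            return
        if j < n:
            rec(i + 1, j + 1, "D", acc + S[i, j])
            rec(i, j + 1, "L", acc - (ge if prev == "L" else go))
        rec(i + 1, j, "U", acc - (ge if prev == "U" else go))

    for j0 in range(n + 1):
        rec(0, j0, "", 0.0)
    return best[0]


@pytest.fixture(scope="session")
def toy_matrix():
    """A small mixed-sign matrix over a 4-letter alphabet for oracle tests."""
    alphabet = "ACDE"
    rng = np.random.default_rng(99)
    half = rng.integers(-4, 6, size=(4, 4))
    scores = ((half + half.T) // 2).astype(float)
    np.fill_diagonal(scores, np.abs(np.diag(scores)) + 2)
    bg = np.full(4, 0.25)
    return SubstitutionMatrix(alphabet, scores, bg)
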