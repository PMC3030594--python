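"""Whole-gene position-specific score models built from curated members.

A gene's model is built from the multiple alignment of its non-fused COG
members: Henikoff position-based sequence weights give effective residue
counts per column, background-blended pseudocounts turn them into
frequencies, and the per-column log-odds (bits) form the PSSM. Columns
with >= 50% gaps are not match columns and are dropped. The consensus —
the per-column argmax of weighted residue frequency — is emitted alongside
and seeds the downstream searches.

Modelling the FULL gene rather than single conserved domains is the point:
a read spanning two domains, or a domain plus variable sequence, scores
against the whole-gene model where a single-domain model would miss or
mis-assign it.

Member curation mirrors the reference-database checks: members whose
glocal score against a provisional profile falls below a fraction of the
median member score are rejected as contaminants, and the profile is
rebuilt once from the survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _dp
from .alignment import (
    PROTEIN_ALPHABET,
    MultipleAlignment,
    SubstitutionMatrix,
    progressive_msa,
)

__all__ = [
    "Profile",
    "MemberFilterResult",
    "ScoredSpan",
    "build_profile",
    "consensus_of",
    "profile_score",
    "filter_members",
    "build_gene_profile",
    "write_checkfile",
    "read_checkfile",
]

#: Sentinel for log-odds of a residue absent from a column at beta = 0
#: (the -infinity case); large and finite so the DP stays well-defined.
ABSENT_SCORE = -1000.0

#: Score for an alignment column crossing a stop codon ('*' in a
#: translated frame), at every profile column.
STOP_SCORE = -4.0

#: Score for the ambiguity residue 'X' at every profile column.
X_SCORE = 0.0

#: Default affine gap penalties for profile-sequence alignment, in bits.
PROFILE_GAP_OPEN = 7.0
PROFILE_GAP_EXTEND = 1.0

_X_INDEX = len(PROTEIN_ALPHABET)
_STOP_INDEX = len(PROTEIN_ALPHABET) + 1


@dataclass
class Profile:
    """Per-column residue bit scores plus the emitted consensus."""

    gene_name: str
    cog_id: str
    columns: np.ndarray  # (n_columns, 20) log2-odds scores
    consensus: str
    beta: float
    background: np.ndarray
    member_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.columns.shape != (len(self.consensus), len(PROTEIN_ALPHABET)):
            raise ValueError("column count does not match consensus length")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    def __len__(self) -> int:
        return self.columns.shape[0]

    def scoring_table(self) -> np.ndarray:
        """Columns extended with the 'X' and '*' symbol scores."""
        m = len(self)
        ext = np.empty((m, len(PROTEIN_ALPHABET) + 2))
        ext[:, : len(PROTEIN_ALPHABET)] = self.columns
        ext[:, _X_INDEX] = X_SCORE
        ext[:, _STOP_INDEX] = STOP_SCORE
        return ext

    @staticmethod
    def encode(seq: str) -> np.ndarray:
        """Encode a peptide for scoring; accepts the 20 residues, X and *."""
        idx = np.empty(len(seq), dtype=np.intp)
        for k, c in enumerate(seq):
            p = PROTEIN_ALPHABET.find(c)
            if p >= 0:
                idx[k] = p
            elif c == "X":
                idx[k] = _X_INDEX
            elif c == "*":
                idx[k] = _STOP_INDEX
            else:
                raise ValueError(f"cannot score residue {c!r}")
        return idx


@dataclass
class MemberFilterResult:
    kept: list[str]
    rejected_fused: list[str]
    rejected_below_threshold: list[str]
    threshold_used: float


@dataclass(frozen=True)
class ScoredSpan:
    score: float
    profile_span: tuple[int, int]
    seq_span: tuple[int, int] | None


def henikoff_weights(rows: dict[str, str]) -> dict[str, float]:
    """Henikoff & Henikoff position-based sequence weights.

    Each column distributes one unit of weight: a sequence showing residue
    ``a`` in a column with ``r`` distinct residues, ``n_a`` of them ``a``,
    receives 1/(r*n_a). Gap positions contribute nothing. Weights are
    normalized to sum to the number of sequences.
    """
    ids = sorted(rows)
    raw = {i: 0.0 for i in ids}
    length = len(rows[ids[0]])
    for j in range(length):
        col = {i: rows[i][j] for i in ids if rows[i][j] != "-"}
        if not col:
            continue
        counts: dict[str, int] = {}
        for c in col.values():
            counts[c] = counts.get(c, 0) + 1
        r = len(counts)
        for i, c in col.items():
            raw[i] += 1.0 / (r * counts[c])
    total = sum(raw.values())
    if total == 0:
        return {i: 1.0 for i in ids}
    scale = len(ids) / total
    return {i: w * scale for i, w in raw.items()}


def build_profile(
    msa: MultipleAlignment,
    background: np.ndarray | None = None,
    beta: float = 10.0,
    gene_name: str = "",
    cog_id: str = "",
    max_gap_fraction: float = 0.5,
) -> Profile:
    """Build a whole-gene PSSM from a multiple alignment.

    Per match column ``j`` (gap fraction < ``max_gap_fraction``): effective
    counts are Henikoff-weighted residue counts ``c_aj``; frequencies are
    ``f_aj = (c_aj + beta*p_a) / (sum_a c_aj + beta)``; scores are
    ``log2(f_aj / p_a)`` bits. With ``beta = 0`` a residue absent from a
    column receives :data:`ABSENT_SCORE`. The consensus is the per-column
    argmax of weighted counts, ties broken alphabetically.
    """
    if background is None:
        background = SubstitutionMatrix.blosum62().background
    p = np.asarray(background, dtype=float)
    if beta < 0:
        raise ValueError("beta must be >= 0")
    rows = msa.rows
    if not rows:
        raise ValueError("empty alignment")
    ids = sorted(rows)
    weights = henikoff_weights(rows)
    n_seq = len(ids)
    k = len(PROTEIN_ALPHABET)
    lookup = {c: i for i, c in enumerate(PROTEIN_ALPHABET)}

    columns = []
    consensus = []
    for j in range(msa.length):
        chars = [rows[i][j] for i in ids]
        gap_fraction = chars.count("-") / n_seq
        if gap_fraction >= max_gap_fraction and n_seq > 1:
            continue
        if chars.count("-") == n_seq:
            continue
        c = np.zeros(k)
        for i, ch in zip(ids, chars):
            if ch == "-":
                continue
            if ch == "X":
                continue  # ambiguity carries no count
            c[lookup[ch]] += weights[i]
        if c.sum() == 0:
            continue
        f = (c + beta * p) / (c.sum() + beta)
        with np.errstate(divide="ignore"):
            s = np.log2(f / p)
        s[np.isneginf(s)] = ABSENT_SCORE
        columns.append(s)
        consensus.append(PROTEIN_ALPHABET[int(np.argmax(c))])

    return Profile(
        gene_name=gene_name,
        cog_id=cog_id,
        columns=np.array(columns).reshape(len(columns), k),
        consensus="".join(consensus),
        beta=float(beta),
        background=p,
        member_ids=list(ids),
    )


def consensus_of(profile: Profile) -> str:
    """The profile's emitted consensus sequence (idempotent accessor)."""
    return profile.consensus


def profile_score(
    profile: Profile,
    seq: str,
    mode: str = "local",
    gap_open: float = PROFILE_GAP_OPEN,
    gap_extend: float = PROFILE_GAP_EXTEND,
) -> ScoredSpan:
    """Score a peptide against the profile.

    ``mode="local"`` finds the best-scoring segment pair (score >= 0,
    1-based inclusive spans; empty spans at score 0). ``mode="glocal"``
    forces the full profile with free sequence ends and reports the score
    only (span over the whole profile).
    """
    if not seq:
        raise ValueError("empty sequence")
    idx = Profile.encode(seq)
    table = profile.scoring_table()
    if mode == "local":
        score, pspan, sspan = _dp.local_span(table, idx, gap_open, gap_extend)
        return ScoredSpan(score, pspan, sspan)
    if mode == "glocal":
        score = _dp.glocal_score(table, idx, gap_open, gap_extend)
        return ScoredSpan(score, (1, len(profile)), None)
    raise ValueError(f"unknown mode {mode!r}")


def filter_members(
    members,
    profile: Profile,
    fraction: float = 0.5,
    gap_open: float = PROFILE_GAP_OPEN,
    gap_extend: float = PROFILE_GAP_EXTEND,
) -> MemberFilterResult:
    """Apply the inclusion-threshold member filter.

    Members are scored glocally against the provisional profile; the
    threshold is ``fraction`` times the median member score (clamped at
    zero), and members scoring below it are rejected.
    """
    if not members:
        raise ValueError("no members to filter")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    scores = {
        m.protein_id: profile_score(
            profile, m.sequence, "glocal", gap_open, gap_extend
        ).score
        for m in members
    }
    threshold = max(0.0, fraction * float(np.median(list(scores.values()))))
    kept = sorted(pid for pid, s in scores.items() if s >= threshold)
    rejected = sorted(pid for pid, s in scores.items() if s < threshold)
    if not kept:
        raise ValueError("all members rejected; profile cannot be built")
    return MemberFilterResult(
        kept=kept,
        rejected_fused=[],
        rejected_below_threshold=rejected,
        threshold_used=threshold,
    )


def build_gene_profile(
    gene_name: str,
    cog_id: str,
    members,
    matrix: SubstitutionMatrix | None = None,
    beta: float = 10.0,
    fraction: float = 0.5,
    rejected_fused: list[str] | None = None,
) -> tuple[Profile, MemberFilterResult]:
    """Full query-information build for one gene.

    Aligns the (already fusion-filtered) members, builds a provisional
    profile, applies the inclusion-threshold filter, then rebuilds the
    alignment and profile from the kept members (a single iteration).
    """
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    members = sorted(members, key=lambda m: m.protein_id)
    msa = progressive_msa([(m.protein_id, m.sequence) for m in members], matrix)
    provisional = build_profile(
        msa, matrix.background, beta, gene_name=gene_name, cog_id=cog_id
    )
    result = filter_members(members, provisional, fraction)
    if rejected_fused:
        result.rejected_fused = sorted(rejected_fused)
    kept = [m for m in members if m.protein_id in set(result.kept)]
    msa2 = progressive_msa([(m.protein_id, m.sequence) for m in kept], matrix)
    final = build_profile(
        msa2, matrix.background, beta, gene_name=gene_name, cog_id=cog_id
    )
    final.member_ids = list(result.kept)
    return final, result


# ---------------------------------------------------------------------------
# checkfile serialization (text, exact round-trip)


def write_checkfile(profile: Profile, path) -> None:
    """Serialize a profile to its text checkfile (exact round-trip)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("# ihat profile checkfile v1\n")
        fh.write(f"# gene: {profile.gene_name}\n")
        fh.write(f"# cog: {profile.cog_id}\n")
        fh.write(f"# beta: {profile.beta!r}\n")
        fh.write(f"# columns: {len(profile)}\n")
        fh.write(f"# alphabet: {PROTEIN_ALPHABET}\n")
        fh.write(
            "# background: " + "\t".join(repr(float(v)) for v in profile.background) + "\n"
        )
        fh.write("# members: " + ",".join(profile.member_ids) + "\n")
        for row in profile.columns:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")
        fh.write(f">consensus\n{profile.consensus}\n")


def read_checkfile(path) -> Profile:
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    consensus = ""
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("# "):
            body = line[2:]
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
        elif line.startswith(">consensus"):
            consensus = lines[i + 1]
            i += 1
        elif line.strip():
            rows.append([float(v) for v in line.split("\t")])
        i += 1
    columns = np.array(rows).reshape(len(rows), len(PROTEIN_ALPHABET))
    background = np.array([float(v) for v in meta["background"].split("\t")])
    members = meta.get("members", "")
    profile = Profile(
        gene_name=meta.get("gene", ""),
        cog_id=meta.get("cog", ""),
        columns=columns,
        consensus=consensus,
        beta=float(meta["beta"]),
        background=background,
        member_ids=members.split(",") if members else [],
    )
    if len(profile) != int(meta["columns"]):
        raise ValueError(f"{path}: column count mismatch")
    return profile
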