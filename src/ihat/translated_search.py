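"""Translated search of nucleotide fragments against a gene profile.

Each fragment is translated in all six reading frames (bacterial code,
table 11, by default) and the best local profile alignment over the frames
is kept — one hit per fragment, so multiple high-scoring segments never
inflate counts. Alignments may cross stop codons ('*' scores -4 bits per
column), reflecting that unassembled reads are searched directly without
ORF calling.

Significance is empirical: because a gapped PSSM has no closed-form
Karlin-Altschul parameters, the score null is calibrated per profile by
scoring random background-composition peptides and fitting a Gumbel by the
method of moments. E-values then use a FIXED effective database length
(1e9 residues by default) regardless of the actual database size, so that
expectations are comparable across databases of different depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from . import _dp
from .profile import PROFILE_GAP_EXTEND, PROFILE_GAP_OPEN, Profile

__all__ = [
    "SearchConfig",
    "NullCalibration",
    "AlignmentHit",
    "FramedPeptide",
    "six_frame_translate",
    "fit_gumbel_moments",
    "calibrate_null",
    "evalue",
    "search_fragments",
]

EULER_GAMMA = 0.57721566490153286

FRAME_ORDER = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the translated search stage.

    ``e_cutoff=None`` disables expect filtering entirely (every fragment
    with a positive-scoring segment is reported); the default of 10
    matches the permissive reporting threshold of standard search tools.
    """

    e_cutoff: float | None = 10.0
    effective_db_length: float = 1.0e9
    genetic_code: int = 11
    frameshift_bridge: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effective_db_length <= 0:
            raise ValueError("effective_db_length must be positive")


@dataclass(frozen=True)
class NullCalibration:
    """Gumbel null for one profile: E(S) = (L_eff/len) * exp(-lambda*(S-mu))."""

    lmbda: float
    mu: float
    n_decoys: int
    seed: int
    decoy_length: int = 300

    def __post_init__(self) -> None:
        if self.lmbda <= 0:
            raise ValueError("lambda must be positive")
        if self.n_decoys < 100:
            raise ValueError("need at least 100 decoys")


@dataclass(frozen=True)
class AlignmentHit:
    fragment_id: str
    frame: int
    bit_score: float
    e_value: float
    profile_span: tuple[int, int]
    fragment_span: tuple[int, int]  # nucleotide coordinates, 1-based inclusive


@dataclass(frozen=True)
class FramedPeptide:
    """One reading frame of a fragment, with its coordinate mapping."""

    frame: int
    peptide: str
    parent_length: int

    def nt_span(self, pep_start: int, pep_end: int) -> tuple[int, int]:
        """Map a 1-based inclusive peptide span to original-strand
        nucleotide coordinates (1-based inclusive)."""
        f = abs(self.frame)
        lo = f + 3 * (pep_start - 1)
        hi = f + 3 * (pep_end - 1) + 2
        if self.frame > 0:
            return lo, hi
        return self.parent_length - hi + 1, self.parent_length - lo + 1


def six_frame_translate(nt: str, genetic_code: int = 11) -> list[FramedPeptide]:
    """Translate a nucleotide sequence in all six frames.

    Frames +1..+3 read the sequence, -1..-3 its reverse complement; stop
    codons appear as '*'. Sequences shorter than one codon yield an empty
    list; frames whose remainder is shorter than a codon yield an empty
    peptide.
    """
    nt = str(nt).upper()
    L = len(nt)
    if L < 3:
        return []
    rc = str(Seq(nt).reverse_complement())
    out = []
    for frame in FRAME_ORDER:
        src = nt if frame > 0 else rc
        off = abs(frame) - 1
        usable = (L - off) // 3 * 3
        pep = str(Seq(src[off : off + usable]).translate(table=genetic_code)) if usable else ""
        out.append(FramedPeptide(frame=frame, peptide=pep, parent_length=L))
    return out


def fit_gumbel_moments(scores: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Gumbel fit: lambda = pi/(sigma*sqrt(6)),
    mu = mean - gamma/lambda."""
    scores = np.asarray(scores, dtype=float)
    sigma = scores.std(ddof=1)
    if sigma == 0:
        raise ValueError("degenerate decoy score distribution (zero variance)")
    lmbda = math.pi / (sigma * math.sqrt(6.0))
    mu = scores.mean() - EULER_GAMMA / lmbda
    return float(lmbda), float(mu)


def calibrate_null(
    profile: Profile,
    config: SearchConfig,
    n_decoys: int = 500,
    decoy_length: int = 300,
    gap_open: float = PROFILE_GAP_OPEN,
    gap_extend: float = PROFILE_GAP_EXTEND,
) -> NullCalibration:
    """Empirically calibrate the profile's score null.

    Scores ``n_decoys`` random peptides drawn from the profile's
    background residue frequencies (seeded by ``config.seed``) with the
    same local profile DP used in the search, and fits a Gumbel to the
    score sample by the method of moments.
    """
    # salted stream: decoy draws must be independent of any other
    # component seeded with the same base seed
    rng = np.random.default_rng([config.seed, 101])
    k = profile.background.shape[0]
    idx = rng.choice(k, size=(n_decoys, decoy_length), p=profile.background)
    scores, _, _ = _dp.batch_local(profile.scoring_table(), idx, gap_open, gap_extend)
    lmbda, mu = fit_gumbel_moments(scores)
    return NullCalibration(
        lmbda=lmbda, mu=mu, n_decoys=n_decoys, seed=config.seed,
        decoy_length=decoy_length,
    )


def evalue(score: float, calib: NullCalibration, config: SearchConfig) -> float:
    """Expected chance hits at or above ``score`` over the effective
    database length."""
    return float(
        (config.effective_db_length / calib.decoy_length)
        * math.exp(-calib.lmbda * (score - calib.mu))
    )


def _frame_spans(profile, framed, gap_open, gap_extend):
    """Per-frame (score, profile_span, nt_span) via span-resolving DP."""
    table = profile.scoring_table()
    out = {}
    for fp in framed:
        if not fp.peptide:
            continue
        idx = Profile.encode(fp.peptide)
        score, pspan, sspan = _dp.local_span(table, idx, gap_open, gap_extend)
        if score <= 0:
            continue
        out[fp.frame] = (score, pspan, fp.nt_span(*sspan))
    return out


def _chain_frameshift(per_frame, bridge_penalty=10.0):
    """Best two-segment same-strand chain with a fixed bridge penalty.

    Segments from two different frames on the same strand are chained when
    both their profile spans and their nucleotide spans are disjoint and
    collinear. Returns (score, frame, profile_span, nt_span) or None.
    """
    best = None
    frames = list(per_frame)
    for fa in frames:
        for fb in frames:
            if fa == fb or (fa > 0) != (fb > 0):
                continue
            sa, pa, na = per_frame[fa]
            sb, pb, nb = per_frame[fb]
            if not (pa[1] < pb[0] and na[1] < nb[0]):
                continue
            score = sa + sb - bridge_penalty
            lead_frame = fa if sa >= sb else fb
            cand = (score, lead_frame, (pa[0], pb[1]), (na[0], nb[1]))
            if best is None or score > best[0]:
                best = cand
    return best


def search_fragments(
    profile: Profile,
    fragments,
    config: SearchConfig,
    calib: NullCalibration,
    gap_open: float = PROFILE_GAP_OPEN,
    gap_extend: float = PROFILE_GAP_EXTEND,
) -> list[AlignmentHit]:
    """Search nucleotide fragments against a profile, one hit per fragment.

    For each fragment the best local profile score over all six frames is
    kept (ties resolve by frame order +1, +2, +3, -1, -2, -3); its E-value
    comes from the profile's Gumbel calibration at the configured
    effective database length. With ``config.frameshift_bridge`` the two
    best same-strand, different-frame segments may be chained with a
    10-bit bridge penalty when their spans are disjoint and collinear.
    Fragments with no positive-scoring segment yield no hit; hits above
    ``config.e_cutoff`` (when set) are dropped. Results are independent
    of fragment processing order.
    """
    fragments = list(fragments)
    table = profile.scoring_table()
    framed_all = [six_frame_translate(str(f.seq), config.genetic_code) for f in fragments]

    # batch equal-length peptides per frame for the vectorized kernel
    best_score = np.zeros(len(fragments))
    best_frame = np.zeros(len(fragments), dtype=int)
    for fi, frame in enumerate(FRAME_ORDER):
        groups: dict[int, list[int]] = {}
        for i, framed in enumerate(framed_all):
            if framed and framed[fi].peptide:
                groups.setdefault(len(framed[fi].peptide), []).append(i)
        for plen, members in sorted(groups.items()):
            idx = np.stack(
                [Profile.encode(framed_all[i][fi].peptide) for i in members]
            )
            scores, _, _ = _dp.batch_local(table, idx, gap_open, gap_extend)
            for i, s in zip(members, scores):
                if s > best_score[i]:  # strict: earlier frames win ties
                    best_score[i] = s
                    best_frame[i] = frame

    hits: list[AlignmentHit] = []
    for i, frag in enumerate(fragments):
        if best_score[i] <= 0:
            continue
        framed = framed_all[i]
        if config.frameshift_bridge:
            per_frame = _frame_spans(profile, framed, gap_open, gap_extend)
            score = best_score[i]
            frame = int(best_frame[i])
            pspan, nspan = per_frame[frame][1], per_frame[frame][2]
            chained = _chain_frameshift(per_frame)
            if chained is not None and chained[0] > score:
                score, frame, pspan, nspan = chained
            e = evalue(float(score), calib, config)
            if config.e_cutoff is not None and e > config.e_cutoff:
                continue
        else:
            score = float(best_score[i])
            e = evalue(score, calib, config)
            if config.e_cutoff is not None and e > config.e_cutoff:
                continue
            frame = int(best_frame[i])
            fp = framed[FRAME_ORDER.index(frame)]
            pidx = Profile.encode(fp.peptide)
            score, pspan, sspan = _dp.local_span(table, pidx, gap_open, gap_extend)
            nspan = fp.nt_span(*sspan)
            e = evalue(float(score), calib, config)
        hits.append(
            AlignmentHit(
                fragment_id=frag.id,
                frame=int(frame),
                bit_score=float(score),
                e_value=e,
                profile_span=pspan,
                fragment_span=nspan,
            )
        )
    return hits
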