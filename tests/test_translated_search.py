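import random

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats as sps

from ihat.alignment import MultipleAlignment
from ihat.fragment_sim import PREFERRED_CODON
from ihat.profile import Profile, build_profile
from ihat.translated_search import (
    FRAME_ORDER,
    NullCalibration,
    SearchConfig,
    calibrate_null,
    evalue,
    fit_gumbel_moments,
    search_fragments,
    six_frame_translate,
)

UNIFORM = np.full(20, 0.05)


def _random_nt(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestSixFrameTranslate:
    def test_bacterial_code_frame_one(self):
        framed = six_frame_translate("ATGGCC", 11)
        assert framed[0].frame == 1 and framed[0].peptide == "MA"

    def test_minus_frames_equal_plus_frames_of_reverse_complement(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            nt = _random_nt(rng, int(rng.integers(3, 60)))
            rc = str(Seq(nt).reverse_complement())
            mine = {f.frame: f.peptide for f in six_frame_translate(nt)}
            flipped = {f.frame: f.peptide for f in six_frame_translate(rc)}
            for k in (1, 2, 3):
                assert mine[-k] == flipped[k]

    def test_total_peptide_length_arithmetic(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            L = int(rng.integers(3, 200))
            nt = _random_nt(rng, L)
            total = sum(len(f.peptide) for f in six_frame_translate(nt))
            assert total == 2 * (L // 3 + (L - 1) // 3 + (L - 2) // 3)

    def test_too_short_input_yields_no_frames(self):
        assert six_frame_translate("AT") == []

    def test_stop_codons_render_as_asterisk(self):
        assert six_frame_translate("ATGTAA")[0].peptide == "M*"

    def test_nt_span_maps_back_to_source_codons(self):
        rng = np.random.default_rng(3)
        nt = _random_nt(rng, 31)
        for fp in six_frame_translate(nt):
            for k in range(1, len(fp.peptide) + 1):
                lo, hi = fp.nt_span(k, k)
                codon = nt[lo - 1 : hi]
                if fp.frame < 0:
                    codon = str(Seq(codon).reverse_complement())
                assert str(Seq(codon).translate(table=11)) == fp.peptide[k - 1]


@pytest.fixture(scope="module")
def profile():
    rng = np.random.default_rng(4)
    rows = {
        f"s{i}": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=40))
        for i in range(4)
    }
    return build_profile(MultipleAlignment(rows), beta=2.0)


@pytest.fixture(scope="module")
def search_setup():
    rng = np.random.default_rng(5)
    core = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
    rows = {}
    for i in range(5):
        s = list(core)
        for pos in rng.choice(80, size=4, replace=False):
            s[pos] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(0, 20)]
        rows[f"s{i}"] = "".join(s)
    from ihat.alignment import progressive_msa

    prof = build_profile(progressive_msa(list(rows.items())), beta=2.0)
    config = SearchConfig(seed=6)
    calib = calibrate_null(prof, config)
    return prof, config, calib


class TestCalibration:
    def test_same_seed_gives_identical_parameters(self, profile):
        config = SearchConfig(seed=9)
        c1 = calibrate_null(profile, config, n_decoys=150)
        c2 = calibrate_null(profile, config, n_decoys=150)
        assert (c1.lmbda, c1.mu) == (c2.lmbda, c2.mu)

    def test_evalue_at_mu_equals_database_scaling(self, profile):
        config = SearchConfig()
        calib = NullCalibration(lmbda=0.5, mu=20.0, n_decoys=500, seed=0)
        assert evalue(20.0, calib, config) == pytest.approx(
            config.effective_db_length / calib.decoy_length
        )

    def test_evalues_strictly_decrease_in_score(self):
        config = SearchConfig()
        calib = NullCalibration(lmbda=0.4, mu=15.0, n_decoys=500, seed=0)
        es = [evalue(s, calib, config) for s in (10, 20, 30, 40)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_gumbel_parameters_recovered_from_synthetic_draws(self):
        rng = np.random.default_rng(23)
        draws = sps.gumbel_r.rvs(loc=20.0, scale=1 / 0.27, size=5000, random_state=rng)
        lmbda, mu = fit_gumbel_moments(draws)
        assert abs(lmbda - 0.27) / 0.27 < 0.10
        assert abs(mu - 20.0) / 20.0 < 0.10

    def test_degenerate_variance_is_an_error(self):
        prof = Profile(
            gene_name="g", cog_id="c", columns=np.full((3, 20), -9.0),
            consensus="AAA", beta=1.0, background=UNIFORM,
        )
        with pytest.raises(ValueError, match="variance"):
            calibrate_null(prof, SearchConfig(seed=1), n_decoys=120)


class TestSearchFragments:
    def _planted(self, profile):
        return "".join(PREFERRED_CODON[c] for c in profile.consensus)

    def test_planted_consensus_fragment_is_best_in_frame_one(self, search_setup):
        profile, config, calib = search_setup
        rng = np.random.default_rng(7)
        planted = SeqRecord(Seq(self._planted(profile)), id="planted")
        noise = [
            SeqRecord(Seq(_random_nt(rng, len(planted.seq))), id=f"n{i}")
            for i in range(10)
        ]
        hits = search_fragments(profile, [planted] + noise, config, calib)
        by_id = {h.fragment_id: h for h in hits}
        assert "planted" in by_id
        assert by_id["planted"].frame == 1
        assert by_id["planted"].e_value == min(h.e_value for h in hits)

    def test_reverse_complement_scores_identically_on_minus_strand(self, search_setup):
        profile, config, calib = search_setup
        fwd = self._planted(profile)
        rev = str(Seq(fwd).reverse_complement())
        hits = search_fragments(
            profile,
            [SeqRecord(Seq(fwd), id="f"), SeqRecord(Seq(rev), id="r")],
            config,
            calib,
        )
        by_id = {h.fragment_id: h for h in hits}
        assert by_id["f"].bit_score == by_id["r"].bit_score
        assert by_id["f"].frame == 1 and by_id["r"].frame < 0
        # the minus-strand hit maps back to the same nucleotide window
        assert by_id["r"].fragment_span == (
            len(rev) - by_id["f"].fragment_span[1] + 1,
            len(rev) - by_id["f"].fragment_span[0] + 1,
        )

    def test_one_hit_per_fragment_and_spans_in_bounds(self, search_setup):
        profile, config, calib = search_setup
        rng = np.random.default_rng(8)
        frags = [
            SeqRecord(Seq(_random_nt(rng, 120)), id=f"x{i}") for i in range(30)
        ]
        hits = search_fragments(profile, frags, SearchConfig(e_cutoff=None, seed=6), calib)
        ids = [h.fragment_id for h in hits]
        assert len(ids) == len(set(ids))
        for h in hits:
            lo, hi = h.fragment_span
            assert 1 <= lo <= hi <= 120
            assert 1 <= h.profile_span[0] <= h.profile_span[1] <= len(profile)
            assert h.frame in FRAME_ORDER

    def test_results_independent_of_fragment_order(self, search_setup):
        profile, config, calib = search_setup
        rng = np.random.default_rng(9)
        frags = [SeqRecord(Seq(_random_nt(rng, 150)), id=f"x{i}") for i in range(20)]
        frags.append(SeqRecord(Seq(self._planted(profile)[:150]), id="p"))
        a = search_fragments(profile, frags, SearchConfig(e_cutoff=None, seed=6), calib)
        shuffled = list(frags)
        random.Random(0).shuffle(shuffled)
        b = search_fragments(profile, shuffled, SearchConfig(e_cutoff=None, seed=6), calib)
        assert sorted(a, key=lambda h: h.fragment_id) == sorted(
            b, key=lambda h: h.fragment_id
        )

    def test_hit_count_monotone_in_cutoff(self, search_setup):
        profile, config, calib = search_setup
        rng = np.random.default_rng(10)
        frags = [SeqRecord(Seq(_random_nt(rng, 200)), id=f"x{i}") for i in range(25)]
        frags.append(SeqRecord(Seq(self._planted(profile)), id="p"))
        counts = []
        for cutoff in (None, 1e3, 10.0, 1e-3, 1e-20):
            cfg = SearchConfig(e_cutoff=cutoff, seed=6)
            counts.append(len(search_fragments(profile, frags, cfg, calib)))
        assert counts == sorted(counts, reverse=True)

    def test_frameshift_bridge_chains_split_segments(self, search_setup):
        """A fragment whose two halves encode the consensus in different
        frames is recovered by two-segment chaining."""
        profile, config, calib = search_setup
        cons = profile.consensus
        half = len(cons) // 2
        # frameshifting linker with stops in every frame, so the two
        # segments stay disjoint and collinear
        linker = "TTAACTAGTTAGCTAA"
        nt = (
            "".join(PREFERRED_CODON[c] for c in cons[:half])
            + linker
            + "".join(PREFERRED_CODON[c] for c in cons[half:])
        )
        frag = SeqRecord(Seq(nt), id="fs")
        plain = search_fragments(profile, [frag], SearchConfig(e_cutoff=None, seed=6), calib)
        bridged = search_fragments(
            profile, [frag],
            SearchConfig(e_cutoff=None, frameshift_bridge=True, seed=6),
            calib,
        )
        assert bridged[0].bit_score > plain[0].bit_score
        lo, hi = bridged[0].profile_span
        assert hi - lo + 1 > half  # the chain covers both halves
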