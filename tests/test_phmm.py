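"""Profile HMM construction and forward/Viterbi scoring."""

import itertools

import numpy as np
import pytest

from citsift import build_phmm, forward_bits, scan_proteome, viterbi_bits
from citsift.errors import ValidationError
from citsift.phmm import ProfileHMM, load_phmm, save_phmm
from citsift.sequences import ALPHABET

from oracles import brute_force_forward_bits, brute_force_sequence_probability


def _background_match_hmm():
    """Hand-built single-match-state model whose match emission equals
    the background and whose transitions are deterministic."""
    bg = np.full(20, 1 / 20)
    zeros = np.zeros(2)
    t = {
        "MM": np.ones(2),  # B->M1, M1->E
        "MI": zeros.copy(),
        "MD": zeros.copy(),
        "IM": np.ones(2),
        "II": zeros.copy(),
        "DM": np.array([0.0, 1.0]),
        "DD": zeros.copy(),
    }
    return ProfileHMM(
        n_match_states=1,
        match_emissions=bg[None, :].copy(),
        insert_emissions=bg.copy(),
        background=bg.copy(),
        transitions=t,
    )


class TestBuild:
    def test_identical_ungapped_sequences(self):
        hmm = build_phmm(["MKVRA"] * 3)
        assert hmm.n_match_states == 5
        # Laplace pseudocount 1: observed residue gets (3+1)/(3+20)
        for col, res in enumerate("MKVRA"):
            assert hmm.match_emissions[col, ALPHABET.index(res)] == pytest.approx(4 / 23)

    def test_gap_majority_column_is_not_match(self):
        msa = ["MA", "M-", "M-", "M-", "MA"]  # 60% gaps in column 2
        assert build_phmm(msa, gap_threshold=0.5).n_match_states == 1

    def test_random_msa_distributions_normalise(self):
        rng = np.random.default_rng(5)
        msa = ["".join(rng.choice(list(ALPHABET + "-"), 10)) for _ in range(4)]
        build_phmm(msa).validate()  # raises on any non-normalised row

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValidationError, match="ragged"):
            build_phmm(["MK", "MKV"])

    def test_all_gap_columns_rejected(self):
        with pytest.raises(ValidationError, match="match"):
            build_phmm(["--", "--", "AA"], gap_threshold=0.5)


class TestForward:
    @pytest.mark.parametrize(
        "msa", [["M", "M", "A"], ["MK", "MK", "MR"], ["MKV-A", "MKVQA", "MRVQA"]]
    )
    @pytest.mark.parametrize("seq", ["M", "MK", "AK", "MKV", "WWWW", "MKVQA"])
    def test_matches_brute_force_path_enumeration(self, msa, seq):
        hmm = build_phmm(msa)
        assert forward_bits(hmm, seq) == pytest.approx(
            brute_force_forward_bits(hmm, seq), abs=1e-4
        )

    def test_background_emission_scores_zero_bits(self):
        hmm = _background_match_hmm()
        for seq in ["A", "W", "M"]:
            assert forward_bits(hmm, seq) == pytest.approx(0.0, abs=1e-6)

    def test_learned_single_state_model_near_zero_for_any_residue(self):
        # With Laplace-smoothed emissions/transitions the log-odds
        # identity only holds up to a few bits of smoothing overhead.
        hmm = build_phmm(["M", "K", "V"])
        bits = [forward_bits(hmm, s) for s in ALPHABET]
        assert all(abs(b) < 3.5 for b in bits)

    def test_forward_at_least_viterbi(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            ncols = int(rng.integers(1, 6))
            msa = ["".join(rng.choice(list("MKVAR-"), ncols)) for _ in range(3)]
            try:
                hmm = build_phmm(msa)
            except ValidationError:
                continue
            seq = "".join(rng.choice(list(ALPHABET), int(rng.integers(1, 8))))
            assert forward_bits(hmm, seq) >= viterbi_bits(hmm, seq) - 1e-6

    def test_empty_sequence_is_error_not_nan(self):
        hmm = build_phmm(["MK", "MK", "MR"])
        with pytest.raises(ValidationError):
            forward_bits(hmm, "")

    def test_unknown_residue_is_error(self):
        hmm = build_phmm(["MK", "MK", "MR"])
        with pytest.raises(ValidationError, match="X"):
            forward_bits(hmm, "MXK")

    @pytest.mark.parametrize("length", [1, 2])
    def test_total_probability_per_length_at_most_one(self, length):
        # Exhaustive over a reduced 3-letter alphabet on a model built
        # from those letters: a partial sum of P(seq, exactly L) <= 1.
        hmm = build_phmm(["AC", "AC", "AD"])
        total = sum(
            brute_force_sequence_probability(hmm, "".join(chars))
            for chars in itertools.product("ACD", repeat=length)
        )
        fast = sum(
            2.0 ** forward_bits(hmm, "".join(chars))
            * np.prod([hmm.background[ALPHABET.index(c)] for c in chars])
            for chars in itertools.product("ACD", repeat=length)
        )
        assert fast == pytest.approx(total, rel=1e-4)
        assert total <= 1.0 + 1e-9


class TestScan:
    def test_seed_consensus_ranks_first(self):
        # Decoys share the seed alignment's residue composition, so the
        # comparison isolates positional signal from composition bias.
        rng = np.random.default_rng(3)
        consensus = "MKVLLADERW" * 3
        msa = [consensus] * 3
        proteome = {"decoy_%d" % i: "".join(rng.choice(list("MKVLADERW"), 30))
                    for i in range(10)}
        proteome["target"] = consensus
        hits = scan_proteome(build_phmm(msa), proteome, top_n=3)
        assert hits[0].protein_id == "target"
        # oracle: explicit rescoring of every protein one by one
        scores = {pid: forward_bits(build_phmm(msa), s) for pid, s in proteome.items()}
        assert max(scores, key=scores.get) == "target"

    def test_truncation(self):
        hmm = build_phmm(["MK", "MK", "MR"])
        hits = scan_proteome(hmm, {"a": "MK", "b": "ML"}, top_n=3)
        assert len(hits) == 2

    def test_identical_sequences_tie_break_by_id(self):
        hmm = build_phmm(["MK", "MK", "MR"])
        hits = scan_proteome(hmm, {"zz": "MK", "aa": "MK"}, top_n=2)
        assert hits[0].protein_id == "aa" and hits[1].protein_id == "zz"
        assert hits[0].score == hits[1].score
        assert [h.rank for h in hits] == [1, 2]

    def test_score_independent_of_input_order(self):
        hmm = build_phmm(["MKVA", "MKVA", "MRVA"])
        p1 = {"a": "MKVA", "b": "WWWW", "c": "MKWA"}
        p2 = dict(reversed(list(p1.items())))
        s1 = {h.protein_id: h.score for h in scan_proteome(hmm, p1, top_n=3)}
        s2 = {h.protein_id: h.score for h in scan_proteome(hmm, p2, top_n=3)}
        assert s1 == s2

    def test_bad_top_n(self):
        hmm = build_phmm(["MK", "MK", "MR"])
        with pytest.raises(ValidationError):
            scan_proteome(hmm, {"a": "MK"}, top_n=0)


class TestSerialisation:
    def test_round_trip_preserves_scores(self, tmp_path):
        hmm = build_phmm(["MKV-A", "MKVQA", "MRVQA"])
        path = tmp_path / "model.phmm"
        save_phmm(hmm, path)
        loaded = load_phmm(path)
        for seq in ["MKVQA", "WWWW", "M"]:
            assert forward_bits(loaded, seq) == pytest.approx(
                forward_bits(hmm, seq), abs=1e-6
            )

    def test_rejects_foreign_file(self, tmp_path):
        path = tmp_path / "x.txt"
        path.write_text("not a model\n")
        with pytest.raises(ValidationError):
            load_phmm(path)
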