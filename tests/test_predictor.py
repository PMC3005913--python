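"""Matching, voting, structure calling, confidence, end-to-end prediction."""

import numpy as np
import pytest

from synpss import (
    LocalAlignment,
    PredictorConfig,
    ProteinChain,
    QueryWordSet,
    VoteProfile,
    WordItem,
    accumulate_votes,
    build_query_word_set,
    call_structure,
    confidence_level,
    exclude_sources,
    match_exact,
    match_inexact,
    predict,
    q3,
    voting_score,
)
from synpss.dictionary import build_dictionary
from synpss.matrices import STANDARD_AA
from synpss.predictor import WildcardIndex

from conftest import random_chain, random_dictionary


def brute_force_hamming1(word, dictionary):
    """Oracle: scan every dictionary word for Hamming distance <= 1."""
    hits = set()
    for w in dictionary.words():
        if sum(1 for a, b in zip(word, w) if a != b) <= 1:
            hits.add(w)
    return hits


class TestQueryWordSet:
    def test_original_words_only(self, rng):
        target = random_chain(rng, 20, "t", with_ss=False)
        ws = build_query_word_set(target, [], 8)
        assert len(ws) <= 13  # 13 windows, fewer if duplicate words
        total_positions = sum(
            len(it.target_positions) for it in ws.items.values()
        )
        assert total_positions == 13
        for it in ws.items.values():
            assert it.sim_t == 8

    def test_synonym_aggregation(self):
        target = ProteinChain("t", "WAKV")
        alns = [
            LocalAlignment("t", f"s{i}", 1, 1, "WAKV", "WGPV", 1e-9)
            for i in range(5)
        ]
        ws = build_query_word_set(target, alns, 4)
        item = ws.items["WGPV"]
        assert item.freq_t == 5
        assert item.sim_t == 2  # W and V interchangeable with themselves
        assert item.target_positions == (1,)

    def test_word_both_original_and_synonym_merges(self):
        target = ProteinChain("t", "WAKV")
        # the target's own word harvested once more from a similar protein
        alns = [LocalAlignment("t", "s", 1, 1, "WAKV", "WAKV", 1e-9)]
        ws = build_query_word_set(target, alns, 4)
        item = ws.items["WAKV"]
        assert item.freq_t == 2
        assert item.sim_t == 4


class TestMatching:
    def test_exact_hits_worked_example(self, wgpv_dictionary):
        recs = match_exact("WGPV", wgpv_dictionary)
        assert {r.source_id for r in recs} == {"A", "B", "C"}

    def test_exact_miss(self, wgpv_dictionary):
        assert match_exact("AAAA", wgpv_dictionary) == []

    def test_exact_respects_exclusion(self, wgpv_dictionary):
        view = exclude_sources(wgpv_dictionary, ["B"])
        assert {r.source_id for r in match_exact("WGPV", view)} == {"A", "C"}

    def test_inexact_one_mismatch(self, wgpv_dictionary):
        # WGAV differs from WGPV at one position
        hits = match_inexact("WGAV", wgpv_dictionary)
        assert {(r.source_id, w) for r, w in hits} == {
            ("A", "WGPV"), ("B", "WGPV"), ("C", "WGPV")
        }

    def test_inexact_two_mismatches_rejected(self, wgpv_dictionary):
        assert match_inexact("WAAV", wgpv_dictionary) == []

    def test_wrong_length_rejected(self, wgpv_dictionary):
        with pytest.raises(ValueError, match="length"):
            match_exact("WGPVA", wgpv_dictionary)

    def test_inexact_superset_of_exact_random(self, rng):
        """One-don't-care matching contains every exact match, over many
        random word/dictionary draws."""
        d = random_dictionary(rng, 300, 5)
        aa = np.array(list(STANDARD_AA))
        dict_words = list(d.words())
        for _ in range(1000):
            if rng.random() < 0.5:
                word = "".join(aa[rng.integers(0, 20, size=5)])
            else:  # bias toward near-dictionary words
                base = dict_words[rng.integers(0, len(dict_words))]
                i = rng.integers(0, 5)
                word = base[:i] + str(aa[rng.integers(0, 20)]) + base[i + 1 :]
            exact = {id(r) for r in match_exact(word, d)}
            inexact = {id(r) for r, _ in match_inexact(word, d)}
            assert exact <= inexact

    def test_index_equivalent_to_brute_force(self, rng):
        """The wildcard-projection index returns exactly the Hamming<=1
        neighbour set on a 10^4-word dictionary."""
        d = random_dictionary(rng, 10_000, 8, max_sources=1)
        index = WildcardIndex(d.words(), 8)
        aa = np.array(list(STANDARD_AA))
        dict_words = list(d.words())
        # vectorized oracle over the full dictionary
        arr = np.frombuffer(
            "".join(dict_words).encode(), dtype=np.uint8
        ).reshape(len(dict_words), 8)
        words_arr = np.array(dict_words)
        for trial in range(200):
            if trial % 2:
                word = "".join(aa[rng.integers(0, 20, size=8)])
            else:
                base = dict_words[rng.integers(0, len(dict_words))]
                i = rng.integers(0, 8)
                word = base[:i] + str(aa[rng.integers(0, 20)]) + base[i + 1 :]
            q = np.frombuffer(word.encode(), dtype=np.uint8)
            oracle = set(words_arr[(arr != q).sum(axis=1) <= 1])
            assert index.neighbors(word) == oracle


class TestVotingScore:
    @pytest.mark.parametrize(
        "freq_t,sim_t,freq_i,sim_i,expected",
        [
            (5, 4, 7, 3, 20),
            (5, 4, 11, 4, 25),
            (5, 4, 3, 2, 9),
            (0, 3, 7, 3, 0),
        ],
    )
    def test_worked_examples(self, freq_t, sim_t, freq_i, sim_i, expected):
        assert voting_score(freq_t, sim_t, freq_i, sim_i) == expected

    def test_monotone_in_every_argument(self, rng):
        for _ in range(200):
            args = rng.integers(0, 12, size=4)
            base = voting_score(*args)
            for k in range(4):
                bumped = args.copy()
                bumped[k] += 1
                assert voting_score(*bumped) >= base

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            voting_score(-1, 2, 3, 4)


def worked_example_profile(wgpv_dictionary, length=14):
    """The canonical voting fixture: WGPV (freq_t=5, Sim_t=4) matched at
    target position 11 against the three-source entry."""
    ws = QueryWordSet("t", 4, {"WGPV": WordItem(5, 4, (11,))})
    return accumulate_votes(ws, wgpv_dictionary, "exact", length=length)


class TestAccumulateVotes:
    def test_worked_example_contributions(self, wgpv_dictionary):
        prof = worked_example_profile(wgpv_dictionary)
        # A adds 20 to H(11..14); B adds 25 to H,H,C,H; C adds 9 to C,H,H,H
        assert list(prof.H[10:14]) == [45, 54, 29, 54]
        assert list(prof.C[10:14]) == [9, 0, 25, 0]
        assert list(prof.E[10:14]) == [0, 0, 0, 0]
        # residues outside the word receive nothing
        assert prof.H[:10].sum() == 0 and prof.norm[:10].sum() == 0

    def test_vote_conservation(self, rng):
        """Total votes at each residue equal an independently accumulated
        sum over covering (word position, record) pairs."""
        d = random_dictionary(rng, 200, 4)
        target = random_chain(rng, 40, "t", with_ss=False)
        ws = build_query_word_set(target, [], 4)
        prof = accumulate_votes(ws, d, "inexact", length=40)
        expected = np.zeros(40)
        for word, item in ws.items.items():
            for rec, _ in match_inexact(word, d):
                s = voting_score(
                    item.freq_t, item.sim_t, rec.frequency, rec.similarity_level
                )
                for start in item.target_positions:
                    expected[start - 1 : start + 3] += s
        assert np.allclose(prof.H + prof.E + prof.C, expected)

    def test_empty_word_set_zero_profile(self, wgpv_dictionary):
        ws = QueryWordSet("t", 4, {})
        prof = accumulate_votes(ws, wgpv_dictionary, "exact", length=6)
        assert prof.H.sum() == prof.E.sum() == prof.C.sum() == 0

    def test_repeated_word_votes_each_position(self, wgpv_dictionary):
        ws = QueryWordSet("t", 4, {"WGPV": WordItem(5, 4, (1, 11))})
        prof = accumulate_votes(ws, wgpv_dictionary, "exact", length=14)
        assert list(prof.H[0:4]) == list(prof.H[10:14])

    def test_length_mismatch_rejected(self, wgpv_dictionary):
        ws = QueryWordSet("t", 5, {})
        with pytest.raises(ValueError, match="length"):
            accumulate_votes(ws, wgpv_dictionary, "exact")


class TestCallStructure:
    def test_worked_example_calls_helix(self, wgpv_dictionary):
        prof = worked_example_profile(wgpv_dictionary)
        assert call_structure(prof)[10:14] == "HHHH"

    @pytest.mark.parametrize(
        "h,e,c,expected",
        [
            (29, 0, 25, "H"),
            (10, 0, 10, "C"),  # C beats H on ties
            (7, 7, 0, "H"),    # H beats E on ties
            (3, 3, 3, "C"),
            (0, 0, 0, "C"),    # no votes defaults to coil
            (0, 5, 0, "E"),
        ],
    )
    def test_tie_priority(self, h, e, c, expected):
        prof = VoteProfile(
            "t", np.array([h], float), np.array([e], float),
            np.array([c], float), np.array([1.0]),
        )
        assert call_structure(prof) == expected


class TestConfidence:
    def test_full_votes_clamped_to_nine(self):
        prof = VoteProfile(
            "t", np.array([54.0]), np.array([0.0]), np.array([0.0]),
            np.array([54.0]),
        )
        assert confidence_level(prof, 0) == 9

    def test_zero_votes_zero_confidence(self):
        prof = VoteProfile.zeros("t", 3)
        assert confidence_level(prof, 1) == 0

    def test_ratio_rounds_down(self):
        prof = VoteProfile(
            "t", np.array([45.0]), np.array([0.0]), np.array([9.0]),
            np.array([54.0]),
        )
        assert confidence_level(prof, 0) == 8  # floor(450/54) = 8

    def test_scale_invariance_in_frequencies(self, rng):
        """Multiplying every frequency by a constant scales votes and
        normalization alike, leaving confidence levels unchanged."""
        from synpss import SynonymDictionary, WordRecord

        d = random_dictionary(rng, 100, 4)
        target = random_chain(rng, 30, "t", with_ss=False)
        ws = build_query_word_set(target, [], 4)
        k = 7
        scaled_entries = {
            w: [
                WordRecord(r.word, r.source_id, r.ss, r.similarity_level,
                           r.frequency * k, r.source_positions)
                for r in d.records(w)
            ]
            for w in d.words()
        }
        d_scaled = SynonymDictionary(4, scaled_entries)
        ws_scaled = QueryWordSet(
            "t", 4,
            {w: WordItem(it.freq_t * k, it.sim_t, it.target_positions)
             for w, it in ws.items.items()},
        )
        p1 = accumulate_votes(ws, d, "inexact", length=30)
        p2 = accumulate_votes(ws_scaled, d_scaled, "inexact", length=30)
        for i in range(30):
            assert confidence_level(p1, i) == confidence_level(p2, i)


class TestPredict:
    def test_self_prediction_is_perfect(self, rng):
        """With a dictionary built from the target alone and nothing
        excluded, the prediction reproduces the stored structure."""
        target = random_chain(rng, 60, "t")
        d = build_dictionary([target], {}, 8)
        bare = ProteinChain("t", target.sequence)
        pred = predict(bare, [], d, PredictorConfig(8, "inexact"))
        assert pred.ss3 == target.ss3
        assert q3(pred.ss3, target.ss3) == 100.0

    def test_all_sources_excluded_falls_back_to_coil(self, rng):
        target = random_chain(rng, 30, "t")
        d = build_dictionary([target], {}, 8)
        view = exclude_sources(d, ["t"])
        pred = predict(
            ProteinChain("t", target.sequence), [], view,
            PredictorConfig(8, "inexact"),
        )
        assert pred.ss3 == "C" * 30
        assert list(pred.confidence) == [0] * 30

    def test_worked_example_micro_fixture(self, wgpv_dictionary):
        """A 14-residue target whose only matched word is WGPV at
        position 11 is called helix at 11-14."""
        target = ProteinChain("t", "A" * 10 + "WGPV")
        alns = [
            LocalAlignment("t", f"s{i}", 11, 1, "WGPV", "WGPV", 1e-9)
            for i in range(4)
        ]  # freq_t = 5 (1 original + 4 copies), Sim_t = 4
        pred = predict(target, alns, wgpv_dictionary, PredictorConfig(4, "exact"))
        assert pred.ss3[10:14] == "HHHH"

    def test_word_length_mismatch_rejected(self, wgpv_dictionary, rng):
        target = random_chain(rng, 20, "t", with_ss=False)
        with pytest.raises(ValueError, match="word length"):
            predict(target, [], wgpv_dictionary, PredictorConfig(8, "exact"))

    def test_deterministic(self, rng):
        target = random_chain(rng, 40, "t")
        d = build_dictionary([target], {}, 8)
        bare = ProteinChain("t", target.sequence)
        p1 = predict(bare, [], d, PredictorConfig(8, "inexact"))
        p2 = predict(bare, [], d, PredictorConfig(8, "inexact"))
        assert p1.ss3 == p2.ss3
        assert list(p1.confidence) == list(p2.confidence)
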