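"""Dictionary-based secondary structure inference by weighted word voting.

The target's word set (its own n-grams plus synonyms harvested from its
similar proteins) is matched against the dictionary, exactly or with one
don't-care position. Each matched per-source record votes its inherited
structure onto the covered target residues with score

    min(freq_t, freq_i) * (1 + min(Sim_t, Sim_i))

where ``freq``/``Sim`` are occurrence frequency and similarity level of the
word on the target side (t) and in the source-i record. Per residue the
state with the highest vote total wins; ties resolve C > H > E. A per-residue
confidence level in 0..9 is the winning vote share of the maximum attainable
score, rounded down.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .dictionary import (
    DictionaryView,
    SynonymDictionary,
    WordRecord,
    extract_words,
    harvest_synonyms,
)
from .types import LocalAlignment, PredictorConfig, ProteinChain


@dataclass(frozen=True)
class WordItem:
    """One word of the target's word set."""

    freq_t: int
    sim_t: int
    target_positions: tuple[int, ...]  # 1-based window starts on the target


@dataclass
class QueryWordSet:
    """The target's words and synonyms, with frequencies and levels."""

    target_id: str
    n: int
    items: dict[str, WordItem] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.items)


@dataclass
class VoteProfile:
    """Per-residue vote totals for H, E, C plus the normalization sums."""

    target_id: str
    H: np.ndarray
    E: np.ndarray
    C: np.ndarray
    norm: np.ndarray

    @classmethod
    def zeros(cls, target_id: str, length: int) -> "VoteProfile":
        return cls(
            target_id,
            np.zeros(length),
            np.zeros(length),
            np.zeros(length),
            np.zeros(length),
        )

    def votes(self, state: str) -> np.ndarray:
        return {"H": self.H, "E": self.E, "C": self.C}[state]

    def __len__(self) -> int:
        return len(self.H)


@dataclass
class Prediction:
    """A called three-state structure with per-residue confidence 0..9."""

    target_id: str
    ss3: str
    confidence: np.ndarray
    per_residue_votes: VoteProfile | None = None

    def __post_init__(self) -> None:
        if len(self.ss3) != len(self.confidence):
            raise ValueError("ss3 and confidence lengths differ")


def build_query_word_set(
    target: ProteinChain,
    alignments: Iterable[LocalAlignment],
    n: int,
) -> QueryWordSet:
    """Compile the target's word set.

    Original target words enter at similarity level ``n``; synonyms from
    gapless alignment windows enter at their level to the target-side word,
    positioned at the target-side window start. Occurrences of the same word
    are clustered: total frequency, maximum level, union of positions.
    """
    # word -> [max level, freq, positions]
    acc: dict[str, list] = {}

    def add(word: str, level: int, pos: int) -> None:
        if word in acc:
            ent = acc[word]
            ent[0] = max(ent[0], level)
            ent[1] += 1
            ent[2].add(pos)
        else:
            acc[word] = [level, 1, {pos}]

    for word, start, _ss in extract_words(target, n):
        add(word, n, start)
    for sword, qstart, _ss, level in harvest_synonyms(
        target, alignments, n, require_ss=False
    ):
        add(sword, level, qstart)

    items = {
        w: WordItem(freq_t=freq, sim_t=lvl, target_positions=tuple(sorted(pos)))
        for w, (lvl, freq, pos) in acc.items()
    }
    return QueryWordSet(target.id, n, items)


def match_exact(word: str, dictionary: SynonymDictionary | DictionaryView
                ) -> list[WordRecord]:
    """Records filed under exactly this word (after source exclusion)."""
    if len(word) != dictionary.n:
        raise ValueError(
            f"word length {len(word)} != dictionary word length {dictionary.n}"
        )
    return list(dictionary.records(word))


class WildcardIndex:
    """One-mismatch lookup via n position-masked projections per word.

    Each dictionary word of length n is indexed n times with one position
    replaced by a wildcard. A query word probes its own n projections; the
    union of hits is exactly the set of dictionary words at Hamming
    distance <= 1 (any index achieving the brute-force result is
    acceptable; this one is O(n) probes per query).
    """

    def __init__(self, words: Iterable[str], n: int) -> None:
        self.n = n
        self._buckets: dict[tuple[int, str], set[str]] = defaultdict(set)
        for w in words:
            for i in range(n):
                self._buckets[(i, w[:i] + w[i + 1 :])].add(w)

    def neighbors(self, word: str) -> set[str]:
        hits: set[str] = set()
        for i in range(self.n):
            hits |= self._buckets.get((i, word[:i] + word[i + 1 :]), set())
        return hits


def match_inexact(
    word: str,
    dictionary: SynonymDictionary | DictionaryView,
    index: WildcardIndex | None = None,
) -> list[tuple[WordRecord, str]]:
    """Records under dictionary words within one don't-care of ``word``.

    Always a superset of the exact matches (the zero-mismatch case). Each
    result carries the dictionary word actually matched. The don't-care is
    a mismatched character, never a gap, and incurs no score penalty: the
    record's frequency and level are used unmodified.
    """
    if len(word) != dictionary.n:
        raise ValueError(
            f"word length {len(word)} != dictionary word length {dictionary.n}"
        )
    if index is None:
        index = WildcardIndex(dictionary.words(), dictionary.n)
    out: list[tuple[WordRecord, str]] = []
    for hit in sorted(index.neighbors(word)):
        for rec in dictionary.records(hit):
            out.append((rec, hit))
    return out


def voting_score(freq_t: int, sim_t: int, freq_i: int, sim_i: int) -> int:
    """min(freq_t, freq_i) * (1 + min(Sim_t, Sim_i)).

    High when the word is conserved on both sides (frequency) and close to
    both source words (similarity level); monotone non-decreasing in every
    argument.
    """
    if min(freq_t, sim_t, freq_i, sim_i) < 0:
        raise ValueError("voting score arguments must be non-negative")
    return min(freq_t, freq_i) * (1 + min(sim_t, sim_i))


def accumulate_votes(
    word_set: QueryWordSet,
    dictionary: SynonymDictionary | DictionaryView,
    matching: str = "inexact",
    length: int | None = None,
) -> VoteProfile:
    """Sum voting scores of all matched records over the target residues.

    For each word item, at each of its target positions, each matched
    record adds its voting score to H/E/C at the n covered residues,
    following the record's structure string. The normalization array
    accumulates, for every covering (item, record) contribution, the
    maximum score that contribution could attain, freq_t * (1 + Sim_t).
    """
    if matching not in ("exact", "inexact"):
        raise ValueError(f"unknown matching mode {matching!r}")
    n = word_set.n
    if n != dictionary.n:
        raise ValueError(
            f"word set length {n} != dictionary word length {dictionary.n}"
        )
    if length is None:
        length = max(
            (p + n - 1 for it in word_set.items.values() for p in it.target_positions),
            default=0,
        )
    profile = VoteProfile.zeros(word_set.target_id, length)
    arrays = {"H": profile.H, "E": profile.E, "C": profile.C}

    index = None
    if matching == "inexact":
        index = WildcardIndex(dictionary.words(), n)

    for word, item in word_set.items.items():
        if matching == "exact":
            matched: list[WordRecord] = match_exact(word, dictionary)
        else:
            matched = [rec for rec, _ in match_inexact(word, dictionary, index)]
        if not matched:
            continue
        cap = item.freq_t * (1 + item.sim_t)
        for rec in matched:
            score = voting_score(
                item.freq_t, item.sim_t, rec.frequency, rec.similarity_level
            )
            for start in item.target_positions:
                i0 = start - 1
                for k, state in enumerate(rec.ss):
                    arrays[state][i0 + k] += score
                profile.norm[i0 : i0 + n] += cap
    return profile


# tie priority: C beats H beats E
_STATE_PRIORITY = ("C", "H", "E")


def call_structure(profile: VoteProfile) -> str:
    """Per-residue argmax of (H, E, C); ties resolve C > H > E.

    Residues with no votes at all default to coil.
    """
    out = []
    for i in range(len(profile)):
        scores = {"H": profile.H[i], "E": profile.E[i], "C": profile.C[i]}
        best = max(scores.values())
        for state in _STATE_PRIORITY:
            if scores[state] == best:
                out.append(state)
                break
    return "".join(out)


def confidence_level(profile: VoteProfile, i: int) -> int:
    """Confidence 0..9 at residue ``i`` (0-based).

    floor(10 * winning-state votes / normalization sum), clamped into
    [0, 9]; a residue with zero normalization (no covering match) gets 0.
    """
    wins = max(profile.H[i], profile.E[i], profile.C[i])
    denom = profile.norm[i]
    if denom <= 0:
        return 0
    return min(9, int(10.0 * wins / denom))


def predict(
    target: ProteinChain,
    alignments: Iterable[LocalAlignment],
    dictionary: SynonymDictionary | DictionaryView,
    config: PredictorConfig | None = None,
) -> Prediction:
    """Predict the target's three-state structure.

    Composes word-set construction, dictionary matching, vote accumulation,
    structure calling and confidence scoring. Deterministic for fixed
    inputs. Residues with no votes (e.g. every source excluded) fall back
    to coil with confidence 0.
    """
    config = config or PredictorConfig()
    n = config.word_length
    if n != dictionary.n:
        raise ValueError(
            f"configured word length {n} != dictionary word length {dictionary.n}"
        )
    word_set = build_query_word_set(target, alignments, n)
    profile = accumulate_votes(
        word_set, dictionary, matching=config.matching, length=len(target)
    )
    ss3 = call_structure(profile)
    conf = np.array([confidence_level(profile, i) for i in range(len(target))],
                    dtype=int)
    return Prediction(target.id, ss3, conf, per_residue_votes=profile)
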