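"""Protein-dependent synonymous-word dictionary.

A *word* is an n-gram of a protein sequence. A *synonymous word* of a word
``w`` in protein ``p`` is the n-gram of a similar protein that is aligned,
gap-free, with ``w`` in a significant local alignment; it inherits the
secondary structure of ``w``. The dictionary maps each word to per-source
records carrying the inherited structure, the similarity level (number of
aligned positions with a positive BLOSUM62 score) and the occurrence
frequency. Because each source harvests synonyms from its own set of similar
proteins, the dictionary is protein-dependent: unrelated proteins rarely
share synonymous words even when they share identical n-grams.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .matrices import blosum62, is_word
from .types import LocalAlignment, ProteinChain


@dataclass(frozen=True)
class WordRecord:
    """One dictionary entry row: a word seen for one protein source.

    ``similarity_level`` counts the positions at which the word and the
    source word it was aligned with are interchangeable (positive BLOSUM62
    score); an original word of the source has level ``n`` by definition.
    ``frequency`` is the number of occurrences clustered into this record.
    ``source_positions`` are 1-based start positions of the corresponding
    word on the source protein.
    """

    word: str
    source_id: str
    ss: str
    similarity_level: int
    frequency: int
    source_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.word) != len(self.ss):
            raise ValueError(
                f"record {self.word!r}/{self.source_id!r}: ss length mismatch"
            )
        if not 0 <= self.similarity_level <= len(self.word):
            raise ValueError("similarity_level outside [0, n]")
        if self.frequency < 1:
            raise ValueError("frequency must be >= 1")
        if "-" in self.word:
            raise ValueError("words may not contain gaps")


class SynonymDictionary:
    """Word -> per-source records, plus build provenance.

    Equality is order-independent in both the word keys and the records
    under each word.
    """

    def __init__(
        self,
        n: int,
        entries: Mapping[str, Sequence[WordRecord]] | None = None,
        provenance: dict | None = None,
    ) -> None:
        self.n = n
        self.entries: dict[str, list[WordRecord]] = {
            w: list(rs) for w, rs in (entries or {}).items()
        }
        self.provenance = dict(provenance or {})
        for w, recs in self.entries.items():
            for r in recs:
                if r.word != w:
                    raise ValueError(f"record word {r.word!r} filed under {w!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def words(self) -> Iterable[str]:
        return self.entries.keys()

    def records(self, word: str) -> list[WordRecord]:
        return self.entries.get(word, [])

    def source_ids(self) -> set[str]:
        return {r.source_id for recs in self.entries.values() for r in recs}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SynonymDictionary):
            return NotImplemented
        if self.n != other.n or set(self.entries) != set(other.entries):
            return False
        for w, recs in self.entries.items():
            if sorted(recs, key=_rec_key) != sorted(other.entries[w], key=_rec_key):
                return False
        return True

    @classmethod
    def merge(cls, dicts: Sequence["SynonymDictionary"]) -> "SynonymDictionary":
        """Merge dictionaries built from disjoint pools.

        Records for the same (word, source, ss) are re-aggregated: maximum
        similarity level, summed frequency, unioned positions — the same rule
        used during building, so merging is associative.
        """
        if not dicts:
            raise ValueError("nothing to merge")
        n = dicts[0].n
        if any(d.n != n for d in dicts):
            raise ValueError("word-length mismatch between dictionaries")
        acc: dict[tuple[str, str, str], list] = {}
        for d in dicts:
            for recs in d.entries.values():
                for r in recs:
                    key = (r.word, r.source_id, r.ss)
                    if key in acc:
                        prev = acc[key]
                        prev[0] = max(prev[0], r.similarity_level)
                        prev[1] += r.frequency
                        prev[2].update(r.source_positions)
                    else:
                        acc[key] = [r.similarity_level, r.frequency,
                                    set(r.source_positions)]
        entries: dict[str, list[WordRecord]] = defaultdict(list)
        for (word, src, ss), (lvl, freq, pos) in acc.items():
            entries[word].append(
                WordRecord(word, src, ss, lvl, freq, tuple(sorted(pos)))
            )
        prov = dict(dicts[0].provenance)
        return cls(n, entries, prov)


def _rec_key(r: WordRecord):
    return (r.source_id, r.ss, r.similarity_level, r.frequency, r.source_positions)


def extract_words(chain: ProteinChain, n: int) -> list[tuple[str, int, str | None]]:
    """Slide a window of size ``n`` over the chain.

    Returns ``(word, start, ss)`` triples with 1-based starts; ``ss`` is the
    structure of the window when the chain carries one. A length-L sequence
    yields max(0, L-n+1) windows. Windows containing non-standard letters
    (X, B, Z, U) are skipped.
    """
    if n < 2:
        raise ValueError("word length must be >= 2")
    seq, ss3 = chain.sequence, chain.ss3
    out = []
    for i in range(len(seq) - n + 1):
        word = seq[i : i + n]
        if not is_word(word):
            continue
        out.append((word, i + 1, ss3[i : i + n] if ss3 is not None else None))
    return out


def similarity_level(w1: str, w2: str) -> int:
    """Number of interchangeable positions between two aligned words.

    Two aligned residues are interchangeable when their BLOSUM62 score is
    strictly positive. The result lies in [0, n]; it is symmetric, and a
    word is always at level n with itself (the BLOSUM62 diagonal is
    positive for all standard residues).
    """
    if len(w1) != len(w2):
        raise ValueError(f"word length mismatch: {w1!r} vs {w2!r}")
    if "-" in w1 or "-" in w2:
        raise ValueError("similarity level is undefined for gapped words")
    return sum(1 for a, b in zip(w1, w2) if blosum62(a, b) > 0)


def harvest_synonyms(
    query: ProteinChain,
    alignments: Iterable[LocalAlignment],
    n: int,
    require_ss: bool = True,
) -> list[tuple[str, int, str | None, int]]:
    """Collect synonymous words of ``query`` from its local alignments.

    For every gapless window of ``n`` alignment columns, the subject-side
    word is a synonym of the query-side word: it inherits the structure of
    the query window and is scored by the similarity level between the two
    words. Windows overlapping a gap column in either row are skipped, as
    are windows containing non-standard letters on either side.

    Returns ``(word, query_window_start_1based, inherited_ss, level)``.
    """
    if require_ss and query.ss3 is None:
        raise ValueError(f"query {query.id!r} has no ss3; structure inheritance "
                         "requires a known-structure query")
    out = []
    for aln in alignments:
        if aln.query_id != query.id:
            continue
        aln.check_against(query)
        qrow, srow = aln.query_aln, aln.subject_aln
        ncols = len(qrow)
        # 0-based query position of each column's residue (gap columns carry
        # the position of the next residue; unused since gapped windows skip)
        qpos = []
        p = aln.query_start - 1
        for c in range(ncols):
            qpos.append(p)
            if qrow[c] != "-":
                p += 1
        # rightmost column index (exclusive) of a run without gaps
        for c in range(ncols - n + 1):
            qword = qrow[c : c + n]
            sword = srow[c : c + n]
            if "-" in qword or "-" in sword:
                continue
            if not (is_word(qword) and is_word(sword)):
                continue
            q0 = qpos[c]
            ss = query.ss3[q0 : q0 + n] if query.ss3 is not None else None
            out.append((sword, q0 + 1, ss, similarity_level(qword, sword)))
    return out


def build_dictionary(
    pool: Sequence[ProteinChain],
    alignments_by_protein: Mapping[str, Sequence[LocalAlignment]] | None,
    n: int,
    pool_name: str = "pool",
    search_params: dict | None = None,
) -> SynonymDictionary:
    """Build the synonymous dictionary from a template pool.

    Every pool protein contributes its own words (similarity level ``n``)
    and the synonyms harvested from its local alignments. Identical
    (word, source, structure) occurrences are clustered; the record stores
    the occurrence count as frequency and the maximum similarity level seen.
    Distinct structure strings for the same (word, source) are kept as
    separate records and vote independently.
    """
    seen_ids = set()
    for chain in pool:
        if chain.id in seen_ids:
            raise ValueError(f"duplicate protein id {chain.id!r} in pool")
        seen_ids.add(chain.id)
        if chain.ss3 is None:
            raise ValueError(f"pool protein {chain.id!r} has no ss3")

    alignments_by_protein = alignments_by_protein or {}
    # (word, source, ss) -> [max level, freq, positions]
    acc: dict[tuple[str, str, str], list] = {}

    def add(word: str, source: str, ss: str, level: int, pos: int) -> None:
        key = (word, source, ss)
        if key in acc:
            ent = acc[key]
            ent[0] = max(ent[0], level)
            ent[1] += 1
            ent[2].add(pos)
        else:
            acc[key] = [level, 1, {pos}]

    for chain in pool:
        for word, start, ss in extract_words(chain, n):
            add(word, chain.id, ss, n, start)
        for sword, qstart, ss, level in harvest_synonyms(
            chain, alignments_by_protein.get(chain.id, ()), n
        ):
            add(sword, chain.id, ss, level, qstart)

    entries: dict[str, list[WordRecord]] = defaultdict(list)
    for (word, src, ss), (lvl, freq, pos) in acc.items():
        entries[word].append(WordRecord(word, src, ss, lvl, freq, tuple(sorted(pos))))
    provenance = {
        "pool": pool_name,
        "n": n,
        "n_sources": len(pool),
        "search_params": search_params or {"j": 3, "b": 500, "e": 1e-3},
    }
    return SynonymDictionary(n, entries, provenance)


class DictionaryView:
    """A read-only view of a dictionary with some sources hidden.

    Used to honour sequence-identity exclusion protocols: when predicting a
    target, all structural information from pool proteins sharing at least
    the threshold identity with the target is discarded. The underlying
    dictionary is not modified.
    """

    def __init__(self, dictionary: SynonymDictionary, excluded: Iterable[str] = ()):
        self.dictionary = dictionary
        self.excluded = frozenset(excluded)
        unknown = self.excluded - dictionary.source_ids()
        if unknown:
            warnings.warn(
                f"excluded ids not present in dictionary: {sorted(unknown)}",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return self.dictionary.n

    def words(self) -> Iterable[str]:
        return self.dictionary.words()

    def records(self, word: str) -> list[WordRecord]:
        return [
            r
            for r in self.dictionary.records(word)
            if r.source_id not in self.excluded
        ]


def exclude_sources(
    dictionary: SynonymDictionary,
    excluded_ids: Iterable[str] | None = None,
    identity_to_target: Mapping[str, float] | None = None,
    threshold: float | None = None,
) -> DictionaryView:
    """Hide sources from matching, by explicit ids or by pairwise identity.

    ``identity_to_target`` maps source id -> sequence identity with the
    prediction target (any consistent unit); sources at or above
    ``threshold`` are hidden (25% is the customary redundancy cut between a
    target and the template pool).
    """
    ids = set(excluded_ids or ())
    if identity_to_target is not None:
        if threshold is None:
            raise ValueError("threshold required with an identity table")
        ids.update(
            src for src, ident in identity_to_target.items() if ident >= threshold
        )
    return DictionaryView(dictionary, ids)
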