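"""Sequence alignment driven by shared synonymous words.

Remote homologs that align poorly at the residue level often share many
synonymous words, because homology is transitive through their common
similar proteins. Counting, for every residue pair (x_i, y_j), the
synonymous words shared by the two proteins that cover the pair yields a
protein-pair-specific substitution surface; a global dynamic-programming
alignment over that surface can recover a structure-informed alignment of
sequences with very low direct identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .predictor import QueryWordSet


@dataclass
class SharedWordMatrix:
    """counts[i, j] = number of shared synonymous words covering (x_i, y_j)."""

    x_id: str
    y_id: str
    counts: np.ndarray  # shape (len(x), len(y)), non-negative ints


@dataclass
class PairAlignment:
    """A global alignment as matched index pairs.

    ``pairs`` lists (i, j) tuples over 0-based residue indices; ``i`` or
    ``j`` is None in gap columns.
    """

    x_id: str
    y_id: str
    pairs: list[tuple[int | None, int | None]]
    score: float

    def matched_pairs(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j in self.pairs if i is not None and j is not None}


def shared_word_counts(
    wordset_x: QueryWordSet,
    wordset_y: QueryWordSet,
    len_x: int | None = None,
    len_y: int | None = None,
) -> SharedWordMatrix:
    """Count shared synonymous words per residue pair.

    For every word present in both word sets, every occurrence pair
    (start i on x, start j on y) marks the n diagonal residue pairs
    (x_i, y_j) ... (x_{i+n-1}, y_{j+n-1}) as sharing that word. Transposing
    the inputs transposes the matrix.
    """
    if wordset_x.n != wordset_y.n:
        raise ValueError("word sets have different word lengths")
    n = wordset_x.n
    if len_x is None:
        len_x = max(
            (p + n - 1 for it in wordset_x.items.values() for p in it.target_positions),
            default=0,
        )
    if len_y is None:
        len_y = max(
            (p + n - 1 for it in wordset_y.items.values() for p in it.target_positions),
            default=0,
        )
    counts = np.zeros((len_x, len_y), dtype=np.int64)
    shared = wordset_x.items.keys() & wordset_y.items.keys()
    for word in shared:
        for i in wordset_x.items[word].target_positions:
            for j in wordset_y.items[word].target_positions:
                for k in range(n):
                    counts[i - 1 + k, j - 1 + k] += 1
    return SharedWordMatrix(wordset_x.target_id, wordset_y.target_id, counts)


def align_by_shared_words(
    matrix: SharedWordMatrix, gap_penalty: float = 0.0
) -> PairAlignment:
    """Global alignment maximizing shared-word counts over matched pairs.

    Needleman-Wunsch with ``matrix.counts`` as the substitution surface and
    a linear gap penalty (default 0: gaps are free, so the path simply
    maximizes collected counts). Deterministic tie-break during traceback:
    match is preferred over a gap in y (consuming x), which is preferred
    over a gap in x.
    """
    counts = matrix.counts
    lx, ly = counts.shape
    score = np.zeros((lx + 1, ly + 1))
    # moves: 0 = diag, 1 = up (consume x / gap in y), 2 = left (gap in x)
    move = np.zeros((lx + 1, ly + 1), dtype=np.int8)
    for i in range(1, lx + 1):
        score[i, 0] = score[i - 1, 0] - gap_penalty
        move[i, 0] = 1
    for j in range(1, ly + 1):
        score[0, j] = score[0, j - 1] - gap_penalty
        move[0, j] = 2
    for i in range(1, lx + 1):
        diag_row = score[i - 1]
        for j in range(1, ly + 1):
            d = diag_row[j - 1] + counts[i - 1, j - 1]
            u = score[i - 1, j] - gap_penalty
            l = score[i, j - 1] - gap_penalty
            # tie-break: match > x-consuming gap > y-consuming gap
            if d >= u and d >= l:
                score[i, j] = d
                move[i, j] = 0
            elif u >= l:
                score[i, j] = u
                move[i, j] = 1
            else:
                score[i, j] = l
                move[i, j] = 2
    pairs: list[tuple[int | None, int | None]] = []
    i, j = lx, ly
    while i > 0 or j > 0:
        m = move[i, j]
        if m == 0 and i > 0 and j > 0:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif m == 1 and i > 0:
            pairs.append((i - 1, None))
            i -= 1
        else:
            pairs.append((None, j - 1))
            j -= 1
    pairs.reverse()
    return PairAlignment(matrix.x_id, matrix.y_id, pairs, float(score[lx, ly]))


def alignment_pair_accuracy(
    test_alignment: PairAlignment | set[tuple[int, int]],
    reference_alignment: PairAlignment | set[tuple[int, int]],
) -> tuple[int, int, float]:
    """How many reference residue pairs the test alignment reproduces.

    Returns (matched, total reference pairs, percent). 76 of 78 reference
    pairs reproduced reports 97.4%.
    """
    test = (
        test_alignment.matched_pairs()
        if isinstance(test_alignment, PairAlignment)
        else set(test_alignment)
    )
    ref = (
        reference_alignment.matched_pairs()
        if isinstance(reference_alignment, PairAlignment)
        else set(reference_alignment)
    )
    total = len(ref)
    matched = len(test & ref)
    percent = 100.0 * matched / total if total else float("nan")
    return matched, total, percent
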