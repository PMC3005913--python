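"""Desk-scale experiments: held-out prediction and the word-length study.

These drive the synthetic generator through the full pipeline. The
word-length study reproduces, qualitatively, the specificity/sensitivity
trade-off of the dictionary word length: short words match promiscuously
across unrelated sources, long words starve the matcher; one don't-care
position (inexact matching) shifts the optimum toward longer words.
"""

from __future__ import annotations

import numpy as np

from .dictionary import build_dictionary, exclude_sources
from .evaluation import q3
from .predictor import predict
from .simulate import FamilyPoolConfig, generate_family_pool
from .types import ProteinChain, PredictorConfig


def word_length_study(
    seed: int,
    word_lengths: tuple[int, ...] = (3, 4, 5, 6, 8, 10),
    n_targets: int = 12,
    config: FamilyPoolConfig | None = None,
) -> dict[tuple[int, str], float]:
    """Mean leave-one-out Q3 per (word length, matching mode).

    Builds one family-structured pool, then for each word length and each
    matching mode predicts ``n_targets`` held-out members (their own
    structural information excluded, relatives retained) and averages the
    per-protein Q3.
    """
    config = config or FamilyPoolConfig(seed=seed)
    chains, alignments = generate_family_pool(config)
    rng = np.random.default_rng(seed + 1)
    idx = rng.choice(len(chains), size=min(n_targets, len(chains)), replace=False)
    targets = [chains[i] for i in idx]
    results: dict[tuple[int, str], float] = {}
    for n in word_lengths:
        dictionary = build_dictionary(chains, alignments, n)
        for mode in ("exact", "inexact"):
            scores = []
            for t in targets:
                view = exclude_sources(dictionary, [t.id])
                bare = ProteinChain(t.id, t.sequence)  # structure withheld
                pred = predict(
                    bare, alignments[t.id], view, PredictorConfig(n, mode)
                )
                scores.append(q3(pred.ss3, t.ss3))
            results[(n, mode)] = float(np.mean(scores))
    return results


def best_word_length(
    results: dict[tuple[int, str], float], mode: str
) -> int:
    """Word length with the highest mean Q3 for a matching mode."""
    subset = {n: v for (n, m), v in results.items() if m == mode}
    return max(subset, key=subset.get)
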