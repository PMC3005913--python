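"""Accuracy measures for three-state secondary structure predictions.

Q3 is the fraction of residues whose predicted state equals the assigned
state. Per-state observed Q3 (Q3Ho, Q3Eo, Q3Co) is the recall over residues
whose *true* state is H, E or C. SOV is the 1999 revision of the segment
overlap measure (Zemla, Venclovas, Fidelis & Rost, Proteins 34:220-223):
segment-based, with an allowance ``delta`` that forgives small boundary
deviations, so it punishes fragmented predictions more and single-residue
slips less than Q3 does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .predictor import Prediction

STATES = "HEC"


@dataclass
class EvalReport:
    q3: float
    q3_obs: dict[str, float]  # state -> recall percent, NaN if state absent
    sov: float
    sov_per_state: dict[str, float]
    n_residues: int


@dataclass
class AccuracyTable:
    """Mean per-residue Q3 at each confidence level 0..9.

    The calibration that lets confidence levels of different predictors be
    compared on a common scale: rows map each level to (mean accuracy
    percent, residue count). Levels never emitted have count 0 and NaN
    accuracy.
    """

    method_id: str
    rows: dict[int, tuple[float, int]]

    def accuracy(self, level: int) -> float:
        if level not in self.rows:
            raise KeyError(f"confidence level {level} missing from table "
                           f"{self.method_id!r}")
        acc, count = self.rows[level]
        if count == 0 or math.isnan(acc):
            raise KeyError(f"confidence level {level} has no calibration data "
                           f"in table {self.method_id!r}")
        return acc

    def total_residues(self) -> int:
        return sum(c for _, c in self.rows.values())


def _check_pair(pred: str, truth: str) -> None:
    if len(pred) != len(truth):
        raise ValueError(
            f"prediction length {len(pred)} != truth length {len(truth)}"
        )


def q3(pred: str, truth: str) -> float:
    """Percent of residues with matching state."""
    _check_pair(pred, truth)
    if not truth:
        raise ValueError("empty structure strings")
    correct = sum(1 for p, t in zip(pred, truth) if p == t)
    return 100.0 * correct / len(truth)


def q3_observed(pred: str, truth: str, state: str) -> float:
    """Recall over residues whose true state is ``state``; NaN if absent."""
    _check_pair(pred, truth)
    idx = [i for i, t in enumerate(truth) if t == state]
    if not idx:
        return float("nan")
    correct = sum(1 for i in idx if pred[i] == state)
    return 100.0 * correct / len(idx)


def segments(ss: str, state: str) -> list[tuple[int, int]]:
    """Maximal runs of ``state`` as 0-based half-open (start, end) pairs."""
    out = []
    start = None
    for i, c in enumerate(ss):
        if c == state and start is None:
            start = i
        elif c != state and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(ss)))
    return out


def _sov_state(pred: str, truth: str, state: str) -> tuple[float, float]:
    """Return (sum of pair terms, normalization N) for one state."""
    t_segs = segments(truth, state)
    p_segs = segments(pred, state)
    total = 0.0
    norm = 0.0
    for ts, te in t_segs:
        overlapping = [
            (ps, pe) for ps, pe in p_segs if max(ts, ps) < min(te, pe)
        ]
        tlen = te - ts
        if not overlapping:
            norm += tlen  # observed segment with no counterpart
            continue
        for ps, pe in overlapping:
            minov = min(te, pe) - max(ts, ps)
            maxov = max(te, pe) - min(ts, ps)
            plen = pe - ps
            delta = min(maxov - minov, minov, tlen // 2, plen // 2)
            total += (minov + delta) / maxov * tlen
            norm += tlen  # each overlapping pair contributes len(s1)
    return total, norm


def sov(pred: str, truth: str) -> tuple[float, dict[str, float]]:
    """SOV'99 of a prediction against the assignment.

    Returns the combined measure over H, E and C and the per-state values
    (NaN for a state absent from the assignment). Identical strings score
    100 for any segmentation.
    """
    _check_pair(pred, truth)
    per_state: dict[str, float] = {}
    grand_total = 0.0
    grand_norm = 0.0
    for state in STATES:
        total, norm = _sov_state(pred, truth, state)
        per_state[state] = 100.0 * total / norm if norm > 0 else float("nan")
        grand_total += total
        grand_norm += norm
    combined = 100.0 * grand_total / grand_norm if grand_norm > 0 else float("nan")
    return combined, per_state


def evaluate(pred: str, truth: str) -> EvalReport:
    """All measures for one prediction/assignment pair."""
    combined, per_state = sov(pred, truth)
    return EvalReport(
        q3=q3(pred, truth),
        q3_obs={s: q3_observed(pred, truth, s) for s in STATES},
        sov=combined,
        sov_per_state=per_state,
        n_residues=len(truth),
    )


def mean_q3(pairs: Sequence[tuple[str, str]], per_protein: bool = True) -> float:
    """Average Q3 over a set, per-protein (default) or pooled per-residue."""
    if not pairs:
        raise ValueError("no prediction/truth pairs")
    if per_protein:
        return float(np.mean([q3(p, t) for p, t in pairs]))
    correct = sum(sum(1 for a, b in zip(p, t) if a == b) for p, t in pairs)
    total = sum(len(t) for _, t in pairs)
    return 100.0 * correct / total


def calibrate_confidence(
    predictions: Sequence[Prediction],
    truths: Mapping[str, str] | Sequence[str],
    method_id: str = "method",
) -> AccuracyTable:
    """Build the confidence -> mean Q3 accuracy table.

    ``truths`` is either a mapping from target id to structure string or a
    sequence parallel to ``predictions``. Every residue is binned by its
    confidence level; each level's row holds the mean per-residue accuracy
    and the residue count.
    """
    if len(predictions) == 0:
        raise ValueError("no predictions to calibrate")
    correct = {lvl: 0 for lvl in range(10)}
    count = {lvl: 0 for lvl in range(10)}
    for i, pred in enumerate(predictions):
        truth = (
            truths[pred.target_id] if isinstance(truths, Mapping) else truths[i]
        )
        _check_pair(pred.ss3, truth)
        for p, t, lvl in zip(pred.ss3, truth, pred.confidence):
            lvl = int(lvl)
            count[lvl] += 1
            if p == t:
                correct[lvl] += 1
    rows = {
        lvl: (
            100.0 * correct[lvl] / count[lvl] if count[lvl] else float("nan"),
            count[lvl],
        )
        for lvl in range(10)
    }
    return AccuracyTable(method_id, rows)
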