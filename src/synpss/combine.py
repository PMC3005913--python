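"""Confidence-calibrated consensus of two per-residue predictors.

Two predictors express confidence on incomparable scales, so their levels
are first transformed into mean Q3 accuracies via per-method accuracy
tables. At each residue the state of the method whose level calibrates to
the higher accuracy is emitted; ties go to method A by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import AccuracyTable
from .predictor import Prediction


@dataclass
class CombinerConfig:
    table_a: AccuracyTable
    table_b: AccuracyTable
    tie_rule: str = "a"  # "a" or "b": winner on equal calibrated accuracy

    def __post_init__(self) -> None:
        if self.tie_rule not in ("a", "b"):
            raise ValueError("tie_rule must be 'a' or 'b'")


def combine(
    pred_a: Prediction, pred_b: Prediction, config: CombinerConfig
) -> Prediction:
    """Per-residue consensus by calibrated confidence.

    Raises ``KeyError`` if a residue's confidence level has no calibration
    row. The output confidence is the winning method's level, so combined
    predictions can themselves be re-calibrated.
    """
    if len(pred_a.ss3) != len(pred_b.ss3):
        raise ValueError("predictions have different lengths")
    out_ss = []
    out_conf = np.empty(len(pred_a.ss3), dtype=int)
    for i, (sa, sb) in enumerate(zip(pred_a.ss3, pred_b.ss3)):
        la, lb = int(pred_a.confidence[i]), int(pred_b.confidence[i])
        if sa == sb:
            out_ss.append(sa)
            out_conf[i] = max(la, lb)
            continue
        acc_a = config.table_a.accuracy(la)
        acc_b = config.table_b.accuracy(lb)
        if acc_a > acc_b or (acc_a == acc_b and config.tie_rule == "a"):
            out_ss.append(sa)
            out_conf[i] = la
        else:
            out_ss.append(sb)
            out_conf[i] = lb
    return Prediction(
        target_id=pred_a.target_id, ss3="".join(out_ss), confidence=out_conf
    )
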