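"""Recovery metrics against planted ground truth.

Used by simulation studies: given the verdict table of one cohort and
the generator's ground truth, score how well each planted class was
recovered.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .synthetic import GroundTruth


@dataclass(frozen=True)
class ClassRecovery:
    true_positives: int
    false_positives: int
    false_negatives: int

    @property
    def sensitivity(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else float("nan")

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else float("nan")


def recovery_metrics(verdicts: pd.DataFrame, truth: GroundTruth) -> dict[str, ClassRecovery]:
    """Sensitivity/precision of the efficacy and (pooled) bias calls.

    Bias is scored as a pooled class: a bias_up call on a planted
    bias-down metabolite still counts the metabolite as found, direction
    errors being essentially impossible at the planted effect sizes.
    """
    called_eff = set(verdicts.index[verdicts["class"] == "efficacy"])
    called_bias = set(verdicts.index[verdicts["class"].isin(["bias_up", "bias_down"])])
    analyzed = set(verdicts.index)
    true_eff = truth.efficacy_ids & analyzed
    true_bias = truth.bias_ids & analyzed
    return {
        "efficacy": ClassRecovery(
            true_positives=len(called_eff & true_eff),
            false_positives=len(called_eff - true_eff),
            false_negatives=len(true_eff - called_eff),
        ),
        "bias": ClassRecovery(
            true_positives=len(called_bias & true_bias),
            false_positives=len(called_bias - true_bias),
            false_negatives=len(true_bias - called_bias),
        ),
    }


def unclassified_fraction(verdicts: pd.DataFrame) -> float:
    return float((verdicts["class"] == "unclassified").mean())
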