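"""Cohort-level evaluation: per-system performance, concordance, accuracy.

Bundles the pipeline the validation study runs on its cohort: score every
case with both systems, evaluate each system against the gold labels
(blastoid HGBL as the positive class), compare the two systems on the
jointly scoreable subset, and measure the accuracy of concordant calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .model import UNKNOWN, Cohort
from .scoring import score_cohort
from .stats import (
    ConcordanceReport,
    PerformanceReport,
    concordance,
    pct,
    performance,
)


def truth_labels(cohort: Cohort) -> dict[str, str]:
    """case_id -> gold label, for cases whose label is known."""
    return {
        c.case_id: c.group_truth for c in cohort if c.group_truth != UNKNOWN
    }


def favored_calls(scores: pd.DataFrame) -> dict[str, str]:
    """case_id -> favored diagnosis, for scoreable cases only."""
    scored = scores[scores["scoreable"].astype(bool)]
    return dict(zip(scored["case_id"], scored["favored"]))


@dataclass
class EvaluationReport:
    six_performance: PerformanceReport
    three_performance: Optional[PerformanceReport]
    concordance: ConcordanceReport
    concordant_correct: int
    concordant_total: int

    @property
    def concordant_accuracy(self) -> Optional[float]:
        if self.concordant_total == 0:
            return None
        return self.concordant_correct / self.concordant_total

    @property
    def concordant_accuracy_pct(self) -> Optional[int]:
        return pct(self.concordant_correct, self.concordant_total)

    def as_dict(self) -> dict:
        return {
            "six_point": self.six_performance.as_dict(),
            "three_point": (
                self.three_performance.as_dict()
                if self.three_performance else None
            ),
            "concordance": {
                "n_compared": self.concordance.n_compared,
                "n_concordant": self.concordance.n_concordant,
                "n_discordant": self.concordance.n_discordant,
                "concordance_rate": self.concordance.concordance_rate,
                "concordance_pct": self.concordance.concordance_pct,
                "n_misleading": self.concordance.n_misleading,
                "misleading_ids": self.concordance.misleading_ids,
            },
            "concordant_subset": {
                "correct": self.concordant_correct,
                "total": self.concordant_total,
                "accuracy": self.concordant_accuracy,
                "accuracy_pct": self.concordant_accuracy_pct,
            },
        }


def evaluate_cohort(cohort: Cohort, positive_label: str = "HGBL") -> EvaluationReport:
    """Run the full two-system evaluation against gold labels."""
    truths = truth_labels(cohort)
    if not truths:
        raise ValueError("evaluate_cohort: no truth labels in cohort")
    six = score_cohort(cohort, "six_point")
    three = score_cohort(cohort, "three_point")

    six_perf = performance(favored_calls(six), truths, positive_label)
    three_calls = favored_calls(three)
    three_perf = performance(three_calls, truths, positive_label) if three_calls else None

    conc = concordance(six, three, truths)

    # accuracy restricted to jointly scoreable cases with concordant calls
    six_calls = favored_calls(six)
    correct = total = 0
    for cid in six_calls.keys() & three_calls.keys():
        if six_calls[cid] == three_calls[cid]:
            total += 1
            if six_calls[cid] == truths[cid]:
                correct += 1
    return EvaluationReport(
        six_performance=six_perf,
        three_performance=three_perf,
        concordance=conc,
        concordant_correct=correct,
        concordant_total=total,
    )


def site_subgroup_performance(cohort: Cohort, site: str,
                              positive_label: str = "HGBL") -> PerformanceReport:
    """Six-point performance with positive-group cases restricted to a site.

    The comparison group (all scoreable cases of the other label) is kept
    whole, mirroring how the validation study evaluates bone-marrow and
    extramedullary subgroups against the full B-ALL comparison set.
    """
    truths = truth_labels(cohort)
    scores = score_cohort(cohort, "six_point")
    calls = favored_calls(scores)
    kept = {}
    for cid, call in calls.items():
        truth = truths.get(cid, UNKNOWN)
        if truth == positive_label and cohort[cid].site != site:
            continue
        kept[cid] = call
    return performance(kept, truths, positive_label)
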