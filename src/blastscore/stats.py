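"""Diagnostic-performance metrics, concordance and 2x2 group comparisons.

Conventions: blastoid HGBL is the "positive" class by default; percents are
rounded to the nearest integer with half-away-from-zero rounding (so 86.96
prints as 87 and 84.6 as 85); undefined ratios (zero denominator) are
reported as ``None``, never as 0; per-feature denominators include only
cases in which the feature was assessed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd
from scipy import stats as sps

from .model import UNKNOWN, CaseRecord, Cohort
from .scoring import BCL2_IHC_CUTOFF, BCL6_IHC_CUTOFF, MYC_IHC_CUTOFF


def round_half_up(x: float) -> int:
    """Round half away from zero (0.5 -> 1), unlike banker's rounding."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def pct(numerator: int, denominator: int) -> Optional[int]:
    """Nearest-integer percent, or None when the denominator is zero."""
    if denominator == 0:
        return None
    return round_half_up(100.0 * numerator / denominator)


@dataclass
class ContingencyTable:
    """2x2 table: a,b = group-1 positive/negative; c,d = group-2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")

    @property
    def degenerate(self) -> bool:
        """An all-zero row or column pair: association is untestable."""
        return (
            self.a + self.b == 0 or self.c + self.d == 0
            or self.a + self.c == 0 or self.b + self.d == 0
        )


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value (point-probability method).

    Sums hypergeometric probabilities of all tables with the observed
    margins whose point probability does not exceed the observed table's.
    Degenerate margins return 1.0 by convention.
    """
    if table.degenerate:
        return 1.0
    _, p = sps.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    return float(min(p, 1.0))


@dataclass
class PerformanceReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: Optional[float]

    @property
    def sensitivity_pct(self) -> Optional[int]:
        return pct(self.tp, self.tp + self.fn)

    @property
    def specificity_pct(self) -> Optional[int]:
        return pct(self.tn, self.tn + self.fp)

    @property
    def ppv_pct(self) -> Optional[int]:
        return pct(self.tp, self.tp + self.fp)

    @property
    def npv_pct(self) -> Optional[int]:
        return pct(self.tn, self.tn + self.fn)

    @property
    def accuracy_pct(self) -> Optional[int]:
        return pct(self.tp + self.tn, self.tp + self.fp + self.tn + self.fn)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "accuracy": self.accuracy,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "ppv_pct": self.ppv_pct, "npv_pct": self.npv_pct,
            "accuracy_pct": self.accuracy_pct,
        }


def performance(predictions: Mapping[str, str], truths: Mapping[str, str],
                positive_label: str = "HGBL") -> PerformanceReport:
    """Confusion-matrix metrics of predicted vs true labels.

    ``predictions`` and ``truths`` map case_id -> label; every predicted
    case must carry a known truth label.
    """
    if not predictions:
        raise ValueError("performance: no predictions supplied")
    tp = fp = tn = fn = 0
    for case_id, pred in predictions.items():
        truth = truths.get(case_id, UNKNOWN)
        if truth in (None, UNKNOWN):
            raise ValueError(f"performance: case {case_id!r} has no truth label")
        pred_pos = pred == positive_label
        true_pos = truth == positive_label
        if pred_pos and true_pos:
            tp += 1
        elif pred_pos:
            fp += 1
        elif true_pos:
            fn += 1
        else:
            tn += 1

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den else None

    return PerformanceReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        accuracy=ratio(tp + tn, tp + fp + tn + fn),
    )


@dataclass
class ConcordanceReport:
    n_compared: int
    n_concordant: int
    n_discordant: int
    concordance_rate: float
    n_misleading: int
    misleading_ids: list[str]

    @property
    def concordance_pct(self) -> Optional[int]:
        return pct(self.n_concordant, self.n_compared)


def concordance(six_results: pd.DataFrame, three_results: pd.DataFrame,
                truths: Mapping[str, str]) -> ConcordanceReport:
    """Compare the two systems' favored calls case by case.

    Only cases scoreable in both systems enter the comparison.  A case is
    concordant when both systems favor the same diagnosis, and misleading
    when either system's favored call contradicts the truth label.
    """
    six = six_results[six_results["scoreable"].astype(bool)].set_index("case_id")
    three = three_results[three_results["scoreable"].astype(bool)].set_index("case_id")
    shared = [cid for cid in six.index if cid in three.index]
    if not shared:
        raise ValueError("concordance: no cases scoreable in both systems")
    n_concordant = 0
    misleading: list[str] = []
    for cid in shared:
        f6 = six.loc[cid, "favored"]
        f3 = three.loc[cid, "favored"]
        if f6 == f3:
            n_concordant += 1
        truth = truths.get(cid, UNKNOWN)
        if truth not in (None, UNKNOWN) and (f6 != truth or f3 != truth):
            misleading.append(cid)
    n = len(shared)
    return ConcordanceReport(
        n_compared=n,
        n_concordant=n_concordant,
        n_discordant=n - n_concordant,
        concordance_rate=n_concordant / n,
        n_misleading=len(misleading),
        misleading_ids=misleading,
    )


# ---------------------------------------------------------------------------
# group comparison (Table-style feature prevalence + Fisher exact)

def _enum_feature(attr_path: str, positive: set[str]):
    def extract(case: CaseRecord) -> Optional[bool]:
        obj = case
        *path, last = attr_path.split(".")
        for part in path:
            obj = getattr(obj, part)
        value = getattr(obj, last)
        if value == UNKNOWN:
            return None
        return value in positive
    return extract


def _pct_feature(attr: str, cutoff: float):
    def extract(case: CaseRecord) -> Optional[bool]:
        value = getattr(case.ihc, attr)
        if value is None:
            return None
        return value >= cutoff
    return extract


def _bool_feature(attr: str):
    def extract(case: CaseRecord) -> Optional[bool]:
        return getattr(case.genetics, attr)
    return extract


def _tdt_combined(case: CaseRecord) -> Optional[bool]:
    tdt = case.consolidated_tdt()
    return None if tdt == UNKNOWN else tdt == "negative"


#: Feature extractors for group comparison, keyed by report row name.
FEATURE_EXTRACTORS = {
    "cd45_gt_granulocytes": _enum_feature("flow.cd45_vs_granulocytes", {"greater"}),
    "cd10_not_bright": _enum_feature("flow.cd10_level", {"not_bright", "negative"}),
    "cd20_ge_mature_b": _enum_feature("flow.cd20_vs_mature_b", {"ge"}),
    "cd38_bright": _enum_feature("flow.cd38_level", {"bright_approx_hematogones"}),
    "cd34": _enum_feature("flow.cd34", {"positive"}),
    "surface_light_chain": _enum_feature("flow.surface_light_chain", {"monotypic"}),
    "myeloid_markers": _enum_feature("flow.myeloid_markers", {"positive"}),
    "tdt_negative": _tdt_combined,
    "myc_ihc": _pct_feature("myc_pct", MYC_IHC_CUTOFF),
    "bcl6_ihc": _pct_feature("bcl6_pct", BCL6_IHC_CUTOFF),
    "bcl2_ihc": _pct_feature("bcl2_pct", BCL2_IHC_CUTOFF),
    "myc_r": _bool_feature("myc_r"),
    "complex_karyotype": _bool_feature("complex_karyotype"),
    "ball_translocation": _bool_feature("ball_translocation"),
    "tp53_mut": _bool_feature("tp53_mut"),
    "kras_mut": _bool_feature("kras_mut"),
    "nras_mut": _bool_feature("nras_mut"),
}


def group_compare(cohort: Cohort, features: Iterable[str] | None = None,
                  group1: str = "HGBL", group2: str = "BALL") -> pd.DataFrame:
    """Per-feature positives/totals per truth group with Fisher p-values.

    Denominators count only cases with the feature assessed, so they vary
    per feature.  Features unknown in every case are flagged not-assessable
    (NA counts and p-value).
    """
    names = list(features) if features is not None else list(FEATURE_EXTRACTORS)
    groups = {case.group_truth for case in cohort}
    if group1 not in groups or group2 not in groups:
        raise ValueError("group_compare: cohort must contain both truth groups")
    rows = []
    for name in names:
        extract = FEATURE_EXTRACTORS[name]
        counts = {group1: [0, 0], group2: [0, 0]}  # [positive, total]
        for case in cohort:
            if case.group_truth not in counts:
                continue
            value = extract(case)
            if value is None:
                continue
            counts[case.group_truth][1] += 1
            counts[case.group_truth][0] += int(value)
        (p1, t1), (p2, t2) = counts[group1], counts[group2]
        if t1 == 0 and t2 == 0:
            rows.append({
                "feature": name, "assessable": False,
                "group1_pos": pd.NA, "group1_total": pd.NA, "group1_pct": pd.NA,
                "group2_pos": pd.NA, "group2_total": pd.NA, "group2_pct": pd.NA,
                "p_value": pd.NA,
            })
            continue
        table = ContingencyTable(p1, t1 - p1, p2, t2 - p2)
        rows.append({
            "feature": name, "assessable": True,
            "group1_pos": p1, "group1_total": t1, "group1_pct": pct(p1, t1),
            "group2_pos": p2, "group2_total": t2, "group2_pct": pct(p2, t2),
            "p_value": fisher_exact(table),
        })
    return pd.DataFrame(rows)


def tdt_modality_concordance(cohort: Cohort) -> tuple[int, int, Optional[float]]:
    """Agreement between flow and IHC TdT among dual-tested cases.

    Returns ``(n_dual, n_concordant, rate)``; rate is None with no
    dual-tested cases.
    """
    n_dual = n_concordant = 0
    for case in cohort:
        if case.flow.tdt_flow != UNKNOWN and case.ihc.tdt_ihc != UNKNOWN:
            n_dual += 1
            if case.flow.tdt_flow == case.ihc.tdt_ihc:
                n_concordant += 1
    rate = n_concordant / n_dual if n_dual else None
    return n_dual, n_concordant, rate
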