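"""The two immunophenotype scoring systems.

Six-point flow-cytometry-focused system, one point per criterion:

======================  ====================================================
criterion               earns a point when
======================  ====================================================
cd45_gt_granulocytes    CD45 intensity greater than granulocytes
cd10_not_bright         CD10 not bright relative to hematogones (or negative)
cd20_ge_mature_b        CD20 intensity at or above mature B cells
cd38_bright             CD38 bright, approximately at hematogone level
tdt_negative            TdT negative (flow call preferred, else IHC)
myc_pos_or_r            MYC IHC >= 40% and/or MYC rearrangement
======================  ====================================================

A total of three or more favors blastoid HGBL; below three favors B-ALL.
Totals of >=4 or <=2 lie in the more definitive band.

Three-point IHC-focused system: one point each for BCL6 IHC >= 30%,
TdT negative, and the same MYC criterion.  A total of two or three favors
blastoid HGBL; zero or one favors B-ALL.  Totals of 3 or 0 are the
definitive band.

All percent cutoffs are inclusive (>=).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .model import (
    UNKNOWN,
    CaseRecord,
    Cohort,
    FlowProfile,
    GeneticProfile,
    IhcProfile,
    validate_for_system,
)

MYC_IHC_CUTOFF = 40.0
BCL6_IHC_CUTOFF = 30.0
BCL2_IHC_CUTOFF = 50.0

SIX_POINT_CRITERIA = (
    "cd45_gt_granulocytes",
    "cd10_not_bright",
    "cd20_ge_mature_b",
    "cd38_bright",
    "tdt_negative",
    "myc_pos_or_r",
)
THREE_POINT_CRITERIA = ("bcl6_pos", "tdt_negative", "myc_pos_or_r")

SIX_POINT_THRESHOLD = 3   # total >= 3 favors HGBL
THREE_POINT_THRESHOLD = 2  # total >= 2 favors HGBL


class IncomputableScoreError(ValueError):
    """A required criterion input is unknown."""


@dataclass
class ScoreResult:
    system: str                      # six_point | three_point
    criterion_points: dict[str, int]
    total: int
    favored: str                     # HGBL | BALL
    definitive_band: bool


def myc_criterion(myc_pct: Optional[float], myc_r: Optional[bool]) -> int:
    """MYC point: IHC >= 40% and/or rearrangement by FISH/karyotype.

    Raises :class:`IncomputableScoreError` when neither modality was
    assessed.  A known sub-cutoff percent with unknown rearrangement status
    scores 0 (the available evidence is negative).
    """
    if myc_pct is None and myc_r is None:
        raise IncomputableScoreError(
            "MYC criterion needs myc_pct or myc_r; both unknown"
        )
    if myc_pct is not None and myc_pct >= MYC_IHC_CUTOFF:
        return 1
    if myc_r is True:
        return 1
    return 0


def _tdt_negative_point(flow: FlowProfile, ihc: IhcProfile) -> int:
    tdt = flow.tdt_flow if flow.tdt_flow != UNKNOWN else ihc.tdt_ihc
    if tdt == UNKNOWN:
        raise IncomputableScoreError(
            "TdT criterion needs a flow or IHC TdT call; both unknown"
        )
    return 1 if tdt == "negative" else 0


def _finish(system: str, points: dict[str, int]) -> ScoreResult:
    total = sum(points.values())
    if system == "six_point":
        favored = "HGBL" if total >= SIX_POINT_THRESHOLD else "BALL"
        definitive = total >= 4 or total <= 2
    else:
        favored = "HGBL" if total >= THREE_POINT_THRESHOLD else "BALL"
        definitive = total in (3, 0)
    return ScoreResult(
        system=system,
        criterion_points=points,
        total=total,
        favored=favored,
        definitive_band=definitive,
    )


def six_point_score(flow: FlowProfile, ihc: IhcProfile,
                    genetics: GeneticProfile) -> ScoreResult:
    """Score the six-point flow-cytometry-focused system."""
    flow_bits = {
        "cd45_gt_granulocytes": ("cd45_vs_granulocytes", {"greater"}),
        # outright CD10 negativity is below hematogone level, so it counts
        "cd10_not_bright": ("cd10_level", {"not_bright", "negative"}),
        "cd20_ge_mature_b": ("cd20_vs_mature_b", {"ge"}),
        "cd38_bright": ("cd38_level", {"bright_approx_hematogones"}),
    }
    points: dict[str, int] = {}
    for criterion in SIX_POINT_CRITERIA[:4]:
        field_name, hit = flow_bits[criterion]
        value = getattr(flow, field_name)
        if value == UNKNOWN:
            raise IncomputableScoreError(
                f"six-point criterion {criterion!r} needs {field_name}"
            )
        points[criterion] = 1 if value in hit else 0
    points["tdt_negative"] = _tdt_negative_point(flow, ihc)
    points["myc_pos_or_r"] = myc_criterion(ihc.myc_pct, genetics.myc_r)
    return _finish("six_point", points)


def three_point_score(ihc: IhcProfile, flow: FlowProfile,
                      genetics: GeneticProfile) -> ScoreResult:
    """Score the three-point IHC-focused system."""
    if ihc.bcl6_pct is None:
        raise IncomputableScoreError(
            "three-point criterion 'bcl6_pos' needs bcl6_pct"
        )
    points = {
        "bcl6_pos": 1 if ihc.bcl6_pct >= BCL6_IHC_CUTOFF else 0,
        "tdt_negative": _tdt_negative_point(flow, ihc),
        "myc_pos_or_r": myc_criterion(ihc.myc_pct, genetics.myc_r),
    }
    return _finish("three_point", points)


def score_case(case: CaseRecord, system: str) -> ScoreResult:
    """Score one case with either system."""
    if system == "six_point":
        return six_point_score(case.flow, case.ihc, case.genetics)
    if system == "three_point":
        return three_point_score(case.ihc, case.flow, case.genetics)
    raise ValueError(f"unknown scoring system {system!r}")


def score_cohort(cohort: Cohort, system: str) -> pd.DataFrame:
    """Score every case; unscoreable cases are reported, never dropped.

    Returns a DataFrame with one row per case: ``case_id``, ``system``, one
    0/1 column per criterion, ``total``, ``favored``, ``definitive_band``,
    ``scoreable`` and ``missing`` (semicolon-joined missing inputs).
    Criterion columns and totals are NA for unscoreable cases.
    """
    criteria = SIX_POINT_CRITERIA if system == "six_point" else THREE_POINT_CRITERIA
    rows = []
    for case in cohort:
        report = validate_for_system(case, system)
        row: dict = {"case_id": case.case_id, "system": system}
        if report.scoreable:
            result = score_case(case, system)
            row.update(result.criterion_points)
            row["total"] = result.total
            row["favored"] = result.favored
            row["definitive_band"] = result.definitive_band
            row["scoreable"] = True
            row["missing"] = ""
        else:
            for criterion in criteria:
                row[criterion] = pd.NA
            row["total"] = pd.NA
            row["favored"] = pd.NA
            row["definitive_band"] = pd.NA
            row["scoreable"] = False
            row["missing"] = ";".join(report.missing)
        rows.append(row)
    columns = (
        ["case_id", "system"]
        + list(criteria)
        + ["total", "favored", "definitive_band", "scoreable", "missing"]
    )
    df = pd.DataFrame(rows, columns=columns)
    return df.astype({"total": "Int64"})
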