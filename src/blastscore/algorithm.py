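"""Combined diagnostic decision procedure for blastoid B-cell neoplasms.

The procedure applies, in order:

1. cyclin D1 positivity or *CCND1* rearrangement excludes the HGBL/B-ALL
   differential (mantle cell lymphoma territory) and stops.
2. CD34 positivity — even in a subset of blasts — is definitive for B-ALL
   and stops; no score can override it.
3. Both scoring systems are computed where their inputs allow.
4. If only one system is scoreable, its call stands when the total lies in
   the more definitive band (six-point >=4 or <=2; three-point 3 or 0).
5. If both are scoreable and favor the same diagnosis, that call stands.
6. Discordant scores mark an extremely challenging case; it is resolved by
   an unweighted tally over ancillary clinical/genetic features — a
   non-Hodgkin-lymphoma history, MYC rearrangement, complex karyotype and
   TP53 mutation each favor HGBL; myeloid-marker expression, KRAS or NRAS
   mutation and a B-ALL-associated translocation each favor B-ALL.  Unknown
   features contribute nothing.  A nonzero balance decides; a tie stays
   indeterminate.
7. With insufficient data for any score the case is indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .model import UNKNOWN, CaseRecord, Cohort, validate_for_system
from .scoring import IncomputableScoreError, ScoreResult, score_case

# ancillary feature name -> (direction, predicate on CaseRecord)
ANCILLARY_FEATURES = {
    "history_nhl": ("favors_HGBL", lambda c: c.history_nhl is True),
    "myc_r": ("favors_HGBL", lambda c: c.genetics.myc_r is True),
    "complex_karyotype": ("favors_HGBL", lambda c: c.genetics.complex_karyotype is True),
    "tp53_mut": ("favors_HGBL", lambda c: c.genetics.tp53_mut is True),
    "myeloid_markers": ("favors_BALL", lambda c: c.flow.myeloid_markers == "positive"),
    "kras_mut": ("favors_BALL", lambda c: c.genetics.kras_mut is True),
    "nras_mut": ("favors_BALL", lambda c: c.genetics.nras_mut is True),
    "ball_translocation": ("favors_BALL", lambda c: c.genetics.ball_translocation is True),
}


@dataclass
class DiagnosticCall:
    case_id: str
    call: str  # BALL | HGBL | MCL_excluded | challenging_indeterminate
    pathway: list[str]
    six_result: Optional[ScoreResult] = None
    three_result: Optional[ScoreResult] = None
    ancillary_evidence: list[tuple[str, str]] = field(default_factory=list)
    evidence_balance: int = 0


def _try_score(case: CaseRecord, system: str) -> Optional[ScoreResult]:
    if not validate_for_system(case, system).scoreable:
        return None
    try:
        return score_case(case, system)
    except IncomputableScoreError:  # pragma: no cover - guarded by validate
        return None


def run_algorithm(case: CaseRecord) -> DiagnosticCall:
    """Classify one case; every input yields a DiagnosticCall."""
    pathway: list[str] = []

    # 1. exclude blastoid MCL up front
    pathway.append("cyclin_d1_check")
    if case.ihc.cyclin_d1 == "positive" or case.genetics.ccnd1_r is True:
        return DiagnosticCall(case.case_id, "MCL_excluded", pathway + ["mcl_excluded"])

    # 2. CD34 positivity is definitive for B-ALL
    pathway.append("cd34_check")
    if case.flow.cd34 == "positive":
        return DiagnosticCall(case.case_id, "BALL", pathway + ["cd34_definitive"])

    # 3. compute available scores
    pathway.append("score_systems")
    six = _try_score(case, "six_point")
    three = _try_score(case, "three_point")

    if six is None and three is None:
        return DiagnosticCall(case.case_id, "challenging_indeterminate",
                              pathway + ["unscoreable"])

    # 4. single scoreable system: call only within the definitive band
    if six is None or three is None:
        only = six if six is not None else three
        if only.definitive_band:
            return DiagnosticCall(
                case.case_id, only.favored,
                pathway + [f"single_system_definitive:{only.system}"],
                six_result=six, three_result=three,
            )
        return DiagnosticCall(
            case.case_id, "challenging_indeterminate",
            pathway + [f"single_system_nondefinitive:{only.system}"],
            six_result=six, three_result=three,
        )

    # 5. concordant scores: firm classification, no ancillary evidence needed
    if six.favored == three.favored:
        return DiagnosticCall(
            case.case_id, six.favored, pathway + ["concordant_scores"],
            six_result=six, three_result=three,
        )

    # 6. discordant scores: unweighted ancillary-evidence tally
    pathway.append("discordant_scores")
    evidence = [
        (name, direction)
        for name, (direction, pred) in ANCILLARY_FEATURES.items()
        if pred(case)
    ]
    balance = sum(1 for _, d in evidence if d == "favors_HGBL") - sum(
        1 for _, d in evidence if d == "favors_BALL"
    )
    if balance > 0:
        call, step = "HGBL", "ancillary_resolved"
    elif balance < 0:
        call, step = "BALL", "ancillary_resolved"
    else:
        call, step = "challenging_indeterminate", "ancillary_tied"
    return DiagnosticCall(
        case.case_id, call, pathway + [step],
        six_result=six, three_result=three,
        ancillary_evidence=evidence, evidence_balance=balance,
    )


def classify_cohort(cohort: Cohort) -> tuple[pd.DataFrame, dict]:
    """Run the algorithm on every case.

    Returns ``(table, summary)``: one row per case (call, pathway, score
    totals, evidence balance, fired ancillary features) and a summary with
    counts per call and per terminal pathway step, plus score-concordance
    counts over cases scoreable in both systems.
    """
    calls = [run_algorithm(case) for case in cohort]
    rows = []
    for dc in calls:
        rows.append({
            "case_id": dc.case_id,
            "call": dc.call,
            "pathway": ";".join(dc.pathway),
            "six_total": dc.six_result.total if dc.six_result else pd.NA,
            "three_total": dc.three_result.total if dc.three_result else pd.NA,
            "evidence_balance": dc.evidence_balance,
            "ancillary_features": ";".join(n for n, _ in dc.ancillary_evidence),
        })
    table = pd.DataFrame(
        rows,
        columns=["case_id", "call", "pathway", "six_total", "three_total",
                 "evidence_balance", "ancillary_features"],
    )
    per_call: dict[str, int] = {}
    per_pathway: dict[str, int] = {}
    n_concordant = n_discordant = 0
    for case, dc in zip(cohort, calls):
        per_call[dc.call] = per_call.get(dc.call, 0) + 1
        terminal = dc.pathway[-1]
        per_pathway[terminal] = per_pathway.get(terminal, 0) + 1
        six = _try_score(case, "six_point")
        three = _try_score(case, "three_point")
        if six is not None and three is not None:
            if six.favored == three.favored:
                n_concordant += 1
            else:
                n_discordant += 1
    summary = {
        "n_cases": len(cohort),
        "calls": per_call,
        "pathways": per_pathway,
        "n_score_concordant": n_concordant,
        "n_score_discordant": n_discordant,
    }
    return table, summary
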