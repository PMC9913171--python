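"""Deterministic fixture cohort reconstructing the validation study's counts.

The fixture emits 121 blastoid-HGBL and 47 B-ALL case records whose
score-level structure matches the published cross-tabulation of the two
scoring systems:

* 92 HGBL cases are six-point-scoreable (33 bone marrow, 59 extramedullary),
  all with total >= 3 (69 at >= 4, 23 at exactly 3); the 46 scoreable B-ALL
  cases split 40 at <= 2 and 6 at exactly 3.
* 64 HGBL and 37 B-ALL cases are scoreable in both systems.  Of the 64 HGBL,
  59 have three-point total >= 2 and 5 have a misleading total of 1.  The 37
  B-ALL partition 5/1/2/29 over (six>=3, three<2) / (six>=3, three>=2) /
  (six<3, three>=2) / (six<3, three<2); the single doubly-misleading case is
  the only CD34-positive one among the six-point false positives.
* The TdT dual-modality subtable holds 23 HGBL (21 concordant, 2 with weak
  IHC positivity but negative flow) and 17 B-ALL, all concordant.

Marker margins the downstream statistics touch are matched exactly:
CD45 > granulocytes 72/96 vs 11/47, myeloid markers 0/30 vs 19/46, CD34
0/96 vs 22/47, CD10 not bright 83/96 vs 27/47, CD38 bright 67/96 vs 18/47,
MYC IHC 78/93 vs 9/37, MYC-R 87/121 vs 0/44, BCL6 positive fraction 77%
vs 6/37, complex karyotype 53/57 vs 19/41, B-ALL translocations 0/57 vs
27/47, TP53 11/25 vs 6/41, KRAS 0/25 vs 7/41, NRAS 0/25 vs 9/41.  Margins
that cannot coexist with the scoreable-subset sizes (combined TdT and BCL6
denominators, CD20) are matched in proportion instead; see docs/methods.md.

Criterion patterns are under-determined by the published totals, so each
block of cases carries a fixed, hand-specified pattern chosen to satisfy
the marginal constraints above; the build involves no randomness and is
byte-identical across runs.
"""

from __future__ import annotations

from .model import CaseRecord, Cohort, FlowProfile, GeneticProfile, IhcProfile

_POS, _NEG = "positive", "negative"


def _flow_from_bits(cd45: int, cd10: int, cd20: int, cd38: int) -> dict:
    return {
        "cd45_vs_granulocytes": "greater" if cd45 else "not_greater",
        "cd10_level": "not_bright" if cd10 else "bright_ge_hematogones",
        "cd20_vs_mature_b": "ge" if cd20 else "lt",
        "cd38_level": "bright_approx_hematogones" if cd38 else "not_bright",
    }


# ---------------------------------------------------------------------------
# HGBL construction
#
# Scoreable blocks (six-point criterion bits: cd45, cd10, cd20, cd38,
# tdt_negative, myc):
#   A  35x (1,1,1,1,1,1) total 6   comparison subset, BCL6 27+/8-
#   B  10x (1,1,1,1,0,1) total 5   comparison subset, BCL6 10+ (TdT+ cases)
#   C  14x (1,1,0,1,1,1) total 5   comparison subset, BCL6 12+/2-
#   E5  5x (0,1,0,1,1,0) total 3   comparison subset, BCL6 - (misleading 3pt)
#   D  10x (1,0,1,0,1,1) total 4   BCL6 not assessed
#   E3  3x (0,1,0,1,1,0) total 3   BCL6 not assessed
#   F   7x (0,1,1,0,1,0) total 3   BCL6 not assessed
#   G   5x (0,1,0,0,1,1) total 3   BCL6 not assessed
#   H   3x (1,1,0,0,0,1) total 3   BCL6 not assessed (TdT+ by IHC)

_HGBL_BLOCKS = [
    # (tag, count, (cd45, cd10, cd20, cd38, tdt_neg, myc))
    ("A", 35, (1, 1, 1, 1, 1, 1)),
    ("B", 10, (1, 1, 1, 1, 0, 1)),
    ("C", 14, (1, 1, 0, 1, 1, 1)),
    ("E5", 5, (0, 1, 0, 1, 1, 0)),
    ("D", 10, (1, 0, 1, 0, 1, 1)),
    ("E3", 3, (0, 1, 0, 1, 1, 0)),
    ("F", 7, (0, 1, 1, 0, 1, 0)),
    ("G", 5, (0, 1, 0, 0, 1, 1)),
    ("H", 3, (1, 1, 0, 0, 0, 1)),
]


def _build_hgbl() -> list[CaseRecord]:
    cases: list[CaseRecord] = []
    idx = 0  # index within the 92 scoreable cases
    for tag, count, bits in _HGBL_BLOCKS:
        cd45, cd10, cd20, cd38, tdt_neg, myc = bits
        for j in range(count):  # j is 0-based position within the block
            idx += 1
            case_id = f"H{idx:03d}"
            in_comparison = tag in ("A", "B", "C", "E5")

            # TdT modality layout: 30 flow-tested (5 positive), 23 dual
            # (A1-16 and B1-5 concordant, A17-18 IHC+/flow-), 7 flow-only
            # (C1-7); all remaining scoreable cases are IHC-only.
            tdt_call = _NEG if tdt_neg else _POS
            if tag == "A" and j < 18:
                tdt_flow = _NEG
                tdt_ihc = _NEG if j < 16 else _POS  # A17, A18 discordant
            elif tag == "B" and j < 5:
                tdt_flow, tdt_ihc = _POS, _POS
            elif tag == "C" and j < 7:
                tdt_flow, tdt_ihc = _NEG, "unknown"
            else:
                tdt_flow, tdt_ihc = "unknown", tdt_call

            flow = FlowProfile(
                **_flow_from_bits(cd45, cd10, cd20, cd38),
                tdt_flow=tdt_flow,
                cd34=_NEG,
                surface_light_chain=(
                    "monotypic" if tag in ("A", "B", "C", "D") else "absent"
                ),
                myeloid_markers=_NEG if (tag == "A" and j < 30) else "unknown",
            )

            # BCL6: assessed only in the 64-case comparison subset among
            # scoreable cases; positives 27 A + 10 B + 12 C = 49.
            if in_comparison:
                if tag == "A":
                    bcl6 = 80.0 if j < 27 else 10.0
                elif tag == "B":
                    bcl6 = 80.0
                elif tag == "C":
                    bcl6 = 80.0 if j < 12 else 10.0
                else:  # E5: misleading three-point score of 1
                    bcl6 = 10.0
            else:
                bcl6 = None

            # BCL2 overexpression: 78/92 among scoreable (A-D always, first
            # 9 of the 23 score-three cases).
            low_block_rank = {"E5": 0, "E3": 5, "F": 8, "G": 15, "H": 20}
            if tag in ("A", "B", "C", "D"):
                bcl2 = 90.0
            else:
                bcl2 = 90.0 if low_block_rank[tag] + j < 9 else 30.0

            ihc = IhcProfile(
                myc_pct=80.0 if myc else 10.0,
                bcl6_pct=bcl6,
                bcl2_pct=bcl2,
                tdt_ihc=tdt_ihc,
                cyclin_d1=_NEG,
                ki67_pct=90.0 if idx % 4 != 0 else 70.0,
            )

            # karyotype/translocation panel: 57 assessed (A1-30, B, C1-12,
            # E5); complex in all but C9-12.
            karyo_known = (
                (tag == "A" and j < 30) or tag == "B"
                or (tag == "C" and j < 12) or tag == "E5"
            )
            complex_k = None
            ball_tr = None
            if karyo_known:
                complex_k = not (tag == "C" and 8 <= j < 12)
                ball_tr = False
            ngs_known = tag == "A" and j < 25
            genetics = GeneticProfile(
                myc_r=bool(myc),
                ccnd1_r=False,
                complex_karyotype=complex_k,
                ball_translocation=ball_tr,
                tp53_mut=(j < 11) if ngs_known else None,
                kras_mut=False if ngs_known else None,
                nras_mut=False if ngs_known else None,
            )
            cases.append(CaseRecord(
                case_id=case_id,
                group_truth="HGBL",
                site="bone_marrow" if idx <= 33 else "extramedullary",
                history_nhl=tag == "A" or tag == "E5",
                flow=flow,
                ihc=ihc,
                genetics=genetics,
            ))

    # 4 flow-tested but not fully scoreable cases (CD20 not assessed
    # pre-treatment), bone marrow; CD10 positive criterion in the first.
    for j in range(4):
        cases.append(CaseRecord(
            case_id=f"H{93 + j:03d}",
            group_truth="HGBL",
            site="bone_marrow",
            history_nhl=False,
            flow=FlowProfile(
                cd45_vs_granulocytes="not_greater",
                cd10_level="not_bright" if j == 0 else "bright_ge_hematogones",
                cd20_vs_mature_b="unknown",
                cd38_level="not_bright",
                cd34=_NEG,
                surface_light_chain="monotypic" if j < 3 else "absent",
            ),
            ihc=IhcProfile(
                bcl6_pct=80.0 if j < 3 else 10.0,
                bcl2_pct=90.0,
                cyclin_d1=_NEG,
                ki67_pct=90.0,
            ),
            genetics=GeneticProfile(myc_r=False, ccnd1_r=False),
        ))

    # 25 extramedullary cases without flow cytometry; BCL6 assessed in all
    # (20 positive), MYC IHC in the first (positive), MYC-R in the first 10.
    for j in range(25):
        cases.append(CaseRecord(
            case_id=f"H{97 + j:03d}",
            group_truth="HGBL",
            site="extramedullary",
            history_nhl=False,
            flow=FlowProfile(),
            ihc=IhcProfile(
                myc_pct=80.0 if j == 0 else None,
                bcl6_pct=80.0 if j < 20 else 10.0,
                bcl2_pct=(90.0 if j < 16 else 30.0) if j < 19 else None,
                cyclin_d1=_NEG,
                ki67_pct=90.0 if j % 4 != 0 else 70.0,
            ),
            genetics=GeneticProfile(myc_r=j < 10, ccnd1_r=False),
        ))
    return cases


# ---------------------------------------------------------------------------
# B-ALL construction
#
# Scoreable blocks:
#   M1-M5   six-point total 3 (misleading), three-point 1; CD34-, myeloid+,
#           TdT negative; M1/M3/M5 carry MLL rearrangements
#   X       six 3 / three 2, the single CD34+ doubly-misleading case
#   D1,D2   six 2 / three 2 (misleading three-point), KRAS-mutated
#   c01-c29 comparison subset, six <= 2 and three <= 1
#   n1-n9   six-point-scoreable only (BCL6 not assessed); n1-n7 BCR::ABL1+
#   P       one case without complete flow (CD20 not assessed)

_BALL_BLOCKS = [
    ("M1", (0, 1, 1, 0, 1, 0)), ("M2", (0, 1, 1, 0, 1, 0)),
    ("M3", (1, 1, 0, 0, 1, 0)), ("M4", (1, 0, 1, 0, 1, 0)),
    ("M5", (0, 1, 0, 1, 1, 0)),
    ("X", (0, 1, 0, 1, 0, 1)),
    ("D1", (0, 1, 0, 0, 0, 1)), ("D2", (0, 0, 0, 1, 0, 1)),
]
_BALL_BLOCKS += [(f"c{j:02d}", (0, 0, 0, 0, 0, 1)) for j in range(1, 7)]
_BALL_BLOCKS += [(f"c{j:02d}", (0, 1, 0, 0, 0, 0)) for j in range(7, 13)]
_BALL_BLOCKS += [(f"c{j:02d}", (0, 1, 0, 1, 0, 0)) for j in range(13, 26)]
_BALL_BLOCKS += [("c26", (0, 1, 1, 0, 0, 0)), ("c27", (0, 0, 1, 0, 0, 0)),
                 ("c28", (0, 0, 0, 1, 0, 0)), ("c29", (0, 0, 0, 1, 0, 0))]
_BALL_BLOCKS += [(f"n{j}", (1, 0, 0, 0, 0, 0)) for j in range(1, 10)]

_BALL_CD34_POS = {"X"} | {f"c{j:02d}" for j in range(1, 13)} | {
    f"n{j}" for j in range(1, 10)
}
_BALL_MYELOID_POS = {"M1", "M2", "M3", "M4", "M5"} | {
    f"c{j:02d}" for j in range(13, 27)
}
_BALL_BCL6_POS = {"X", "D1", "D2", "c07", "c08", "c09"}
_BALL_DUAL_TDT = {"X", "D1", "D2"} | {f"c{j:02d}" for j in range(1, 15)}
_BALL_MLL = {"M1", "M3", "M5"} | {f"c{j:02d}" for j in range(13, 20)}
_BALL_TCF3 = {f"c{j:02d}" for j in range(20, 30)}
_BALL_BCR_ABL = {f"n{j}" for j in range(1, 8)}
_BALL_COMPLEX = {f"c{j:02d}" for j in range(1, 13)} | _BALL_BCR_ABL
_BALL_TP53 = {f"c{j:02d}" for j in range(1, 7)}
_BALL_KRAS = {"D1", "D2"} | {f"c{j:02d}" for j in range(7, 12)}
_BALL_NRAS = {f"c{j:02d}" for j in range(13, 22)}
_BALL_BCL2_KNOWN = {"X", "D1", "D2", "c01", "c02", "c03", "c04"}


def _build_ball() -> list[CaseRecord]:
    cases: list[CaseRecord] = []
    for k, (tag, bits) in enumerate(_BALL_BLOCKS, start=1):
        cd45, cd10, cd20, cd38, tdt_neg, myc = bits
        case_id = f"B{k:03d}"
        in_comparison = not tag.startswith("n")
        tdt_flow = _NEG if tdt_neg else _POS
        tdt_ihc = tdt_flow if tag in _BALL_DUAL_TDT else "unknown"
        flow = FlowProfile(
            **_flow_from_bits(cd45, cd10, cd20, cd38),
            tdt_flow=tdt_flow,
            cd34=_POS if tag in _BALL_CD34_POS else _NEG,
            surface_light_chain="absent" if tag.startswith("M") else "unknown",
            myeloid_markers=_POS if tag in _BALL_MYELOID_POS else _NEG,
        )
        ihc = IhcProfile(
            myc_pct=(60.0 if myc else 10.0) if in_comparison else None,
            bcl6_pct=(
                (60.0 if tag in _BALL_BCL6_POS else 10.0)
                if in_comparison else None
            ),
            bcl2_pct=90.0 if tag in _BALL_BCL2_KNOWN else None,
            tdt_ihc=tdt_ihc,
            cyclin_d1=_NEG if in_comparison else "unknown",
            ki67_pct=85.0 if in_comparison else None,
        )
        panel_known = not tag.startswith("M")
        # MYC-R assessed in 44 cases: unknown in c28/c29 (which carry MYC
        # IHC instead) and the flow-incomplete case, keeping all 46
        # flow-complete cases MYC-evaluable.
        genetics = GeneticProfile(
            myc_r=False if tag not in ("c28", "c29") else None,
            ccnd1_r=False,
            complex_karyotype=(tag in _BALL_COMPLEX) if panel_known else None,
            ball_translocation=tag in (_BALL_MLL | _BALL_TCF3 | _BALL_BCR_ABL),
            tp53_mut=(tag in _BALL_TP53) if panel_known else None,
            kras_mut=(tag in _BALL_KRAS) if panel_known else None,
            nras_mut=(tag in _BALL_NRAS) if panel_known else None,
        )
        cases.append(CaseRecord(
            case_id=case_id,
            group_truth="BALL",
            site="bone_marrow",
            history_nhl=False,
            flow=flow,
            ihc=ihc,
            genetics=genetics,
        ))

    # the single flow-incomplete B-ALL case
    cases.append(CaseRecord(
        case_id="B047",
        group_truth="BALL",
        site="bone_marrow",
        history_nhl=False,
        flow=FlowProfile(
            cd45_vs_granulocytes="not_greater",
            cd10_level="not_bright",
            cd38_level="not_bright",
            cd34=_NEG,
        ),
        ihc=IhcProfile(),
        genetics=GeneticProfile(ccnd1_r=False, ball_translocation=False),
    ))
    return cases


# ---------------------------------------------------------------------------

class FixtureIntegrityError(RuntimeError):
    """The built fixture violates one of its structural invariants."""


def _verify(cohort: Cohort) -> None:
    """Structural self-check on every documented fixture invariant."""
    from .model import validate_for_system
    from .scoring import score_case

    def fail(msg: str) -> None:
        raise FixtureIntegrityError(f"fixture invariant violated: {msg}")

    hgbl = [c for c in cohort if c.group_truth == "HGBL"]
    ball = [c for c in cohort if c.group_truth == "BALL"]
    if (len(hgbl), len(ball)) != (121, 47):
        fail("group sizes != 121 HGBL + 47 B-ALL")

    six_h = [c for c in hgbl if validate_for_system(c, "six_point").scoreable]
    six_b = [c for c in ball if validate_for_system(c, "six_point").scoreable]
    if (len(six_h), len(six_b)) != (92, 46):
        fail("six-point scoreable counts != 92 / 46")
    totals_h = [score_case(c, "six_point").total for c in six_h]
    if not all(t >= 3 for t in totals_h):
        fail("an HGBL scoreable case scored < 3")
    if sum(t >= 4 for t in totals_h) != 69 or sum(t == 3 for t in totals_h) != 23:
        fail("HGBL six-point totals not 69 at >=4 and 23 at 3")
    sites = [c.site for c in six_h]
    if (sites.count("bone_marrow"), sites.count("extramedullary")) != (33, 59):
        fail("HGBL scoreable site split != 33 BM / 59 extramedullary")
    totals_b = [score_case(c, "six_point").total for c in six_b]
    if sum(t == 3 for t in totals_b) != 6 or sum(t <= 2 for t in totals_b) != 40:
        fail("B-ALL six-point totals not 6 at 3 and 40 at <=2")
    if not all(1 <= t <= 3 for t in totals_b):
        fail("a B-ALL six-point total outside 1..3")

    both_h = [c for c in six_h if validate_for_system(c, "three_point").scoreable]
    both_b = [c for c in six_b if validate_for_system(c, "three_point").scoreable]
    if (len(both_h), len(both_b)) != (64, 37):
        fail("jointly scoreable counts != 64 / 37")
    three_h = [score_case(c, "three_point").total for c in both_h]
    if sum(t >= 2 for t in three_h) != 59 or sum(t < 2 for t in three_h) != 5:
        fail("HGBL three-point split != 59 at >=2 and 5 at <2")
    cells = {(True, True): 0, (True, False): 0, (False, True): 0, (False, False): 0}
    cd34_pos_double = 0
    for c in both_b:
        s6 = score_case(c, "six_point").total >= 3
        s3 = score_case(c, "three_point").total >= 2
        cells[(s6, s3)] += 1
        if s6 and s3 and c.flow.cd34 == _POS:
            cd34_pos_double += 1
    if cells != {(True, False): 5, (True, True): 1, (False, True): 2,
                 (False, False): 29}:
        fail(f"B-ALL score cross-tabulation wrong: {cells}")
    if cd34_pos_double != 1:
        fail("the doubly-misleading B-ALL case is not the unique CD34+ one")

    dual_h = [c for c in hgbl if c.flow.tdt_flow != "unknown"
              and c.ihc.tdt_ihc != "unknown"]
    dual_b = [c for c in ball if c.flow.tdt_flow != "unknown"
              and c.ihc.tdt_ihc != "unknown"]
    disc_h = [c for c in dual_h if c.tdt_modality_discordant()]
    if len(dual_h) != 23 or len(disc_h) != 2:
        fail("HGBL TdT dual-modality subtable != 23 cases with 2 discordant")
    if any(c.flow.tdt_flow != _NEG or c.ihc.tdt_ihc != _POS for c in disc_h):
        fail("discordant TdT cases must be IHC-positive / flow-negative")
    if len(dual_b) != 17 or any(c.tdt_modality_discordant() for c in dual_b):
        fail("B-ALL TdT dual-modality subtable != 17 concordant cases")


def build_fixture_cohort(verify: bool = True) -> Cohort:
    """Build the fixture cohort; deterministic and randomness-free.

    With ``verify`` (the default) every structural invariant is re-checked
    after construction and a :class:`FixtureIntegrityError` names the first
    violated one.
    """
    cohort = Cohort(cases=_build_hgbl() + _build_ball(), provenance="fixture")
    if verify:
        _verify(cohort)
    return cohort
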