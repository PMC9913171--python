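"""Combined diagnostic algorithm: step order, short-circuits, tally."""

from hypothesis import given, settings
from hypothesis import strategies as st

from blastscore import (
    CaseRecord,
    Cohort,
    FlowProfile,
    GeneticProfile,
    IhcProfile,
    classify_cohort,
    run_algorithm,
)
from blastscore.model import ENUM_VALUES


def _case(flow=None, ihc=None, genetics=None, **kw):
    return CaseRecord(
        case_id=kw.pop("case_id", "case"),
        flow=flow or FlowProfile(),
        ihc=ihc or IhcProfile(),
        genetics=genetics or GeneticProfile(),
        **kw,
    )


_random_case = st.builds(
    _case,
    flow=st.builds(FlowProfile, **{
        name: st.sampled_from(sorted(ENUM_VALUES[name]) + ["unknown"])
        for name in ("cd45_vs_granulocytes", "cd10_level", "cd20_vs_mature_b",
                     "cd38_level", "tdt_flow", "cd34", "myeloid_markers")
    }),
    ihc=st.builds(
        IhcProfile,
        myc_pct=st.one_of(st.none(), st.floats(0, 100, allow_nan=False)),
        bcl6_pct=st.one_of(st.none(), st.floats(0, 100, allow_nan=False)),
        tdt_ihc=st.sampled_from(["positive", "negative", "unknown"]),
    ),
    genetics=st.builds(GeneticProfile, **{
        name: st.one_of(st.none(), st.booleans())
        for name in ("myc_r", "complex_karyotype", "ball_translocation",
                     "tp53_mut", "kras_mut", "nras_mut")
    }),
    history_nhl=st.one_of(st.none(), st.booleans()),
)


@settings(max_examples=200, deadline=None)
@given(case=_random_case)
def test_cd34_positivity_dominates_all_scores(case):
    """CD34 expression, even partial, is definitive for B-ALL: no
    combination of scores or other markers can override it."""
    case.flow.cd34 = "positive"
    call = run_algorithm(case)
    assert call.call == "BALL"
    assert call.pathway[-1] == "cd34_definitive"


@settings(max_examples=200, deadline=None)
@given(case=_random_case)
def test_determinism_and_total_function(case):
    """Every input yields a call, and identical cases yield identical calls."""
    c1, c2 = run_algorithm(case), run_algorithm(case)
    assert c1 == c2
    assert c1.call in {"BALL", "HGBL", "MCL_excluded", "challenging_indeterminate"}
    assert c1.pathway


def test_cyclin_d1_exclusion_precedes_everything():
    case = _case(
        flow=FlowProfile(cd34="positive"),
        ihc=IhcProfile(cyclin_d1="positive"),
    )
    assert run_algorithm(case).call == "MCL_excluded"
    case2 = _case(genetics=GeneticProfile(ccnd1_r=True))
    assert run_algorithm(case2).call == "MCL_excluded"


def test_cd34_overrides_concordant_hgbl_like_scores():
    """A CD34+ B-ALL whose scores both mimic lymphoma is still B-ALL."""
    case = _case(
        flow=FlowProfile(
            cd45_vs_granulocytes="not_greater", cd10_level="not_bright",
            cd20_vs_mature_b="lt", cd38_level="bright_approx_hematogones",
            tdt_flow="positive", cd34="positive",
        ),
        ihc=IhcProfile(myc_pct=60.0, bcl6_pct=60.0),
        genetics=GeneticProfile(myc_r=False),
    )
    call = run_algorithm(case)
    assert call.call == "BALL"
    assert "cd34_definitive" in call.pathway


def test_concordant_scores_decide_without_ancillary_evidence():
    """Challenging leukemic presentation: six-point 2 and three-point 1
    concordantly favor B-ALL despite negative CD34 and TdT."""
    case = _case(
        flow=FlowProfile(
            cd45_vs_granulocytes="not_greater",
            cd10_level="bright_ge_hematogones",
            cd20_vs_mature_b="lt",
            cd38_level="bright_approx_hematogones",
            tdt_flow="negative", cd34="negative",
            surface_light_chain="absent",
        ),
        ihc=IhcProfile(myc_pct=0.0, bcl6_pct=20.0, tdt_ihc="negative"),
        genetics=GeneticProfile(myc_r=False, tp53_mut=True),
    )
    call = run_algorithm(case)
    assert call.six_result.total == 2
    assert call.three_result.total == 1
    assert call.call == "BALL"
    assert call.pathway[-1] == "concordant_scores"
    assert call.ancillary_evidence == []  # tally never consulted


class TestDiscordantResolution:
    def _discordant_case(self, genetics, **kw):
        # six-point 3 (favors HGBL), three-point 1 (favors B-ALL)
        return _case(
            flow=FlowProfile(
                cd45_vs_granulocytes="greater", cd10_level="not_bright",
                cd20_vs_mature_b="ge", cd38_level="not_bright",
                tdt_flow="positive", cd34="negative",
                myeloid_markers=kw.pop("myeloid", "negative"),
            ),
            ihc=IhcProfile(myc_pct=60.0, bcl6_pct=0.0),
            genetics=genetics,
            **kw,
        )

    def test_ball_side_features_resolve_to_ball(self):
        call = run_algorithm(self._discordant_case(
            GeneticProfile(myc_r=False, kras_mut=True, ball_translocation=True)
        ))
        assert call.call == "BALL"
        assert call.pathway[-1] == "ancillary_resolved"
        assert call.evidence_balance == -2

    def test_hgbl_side_features_resolve_to_hgbl(self):
        call = run_algorithm(self._discordant_case(
            GeneticProfile(myc_r=True, complex_karyotype=True, tp53_mut=True)
        ))
        assert call.call == "HGBL"
        assert call.evidence_balance == 3

    def test_balanced_evidence_stays_indeterminate(self):
        call = run_algorithm(self._discordant_case(
            GeneticProfile(myc_r=True, kras_mut=True)
        ))
        assert call.call == "challenging_indeterminate"
        assert call.evidence_balance == 0

    def test_unknown_features_contribute_nothing(self):
        call = run_algorithm(self._discordant_case(GeneticProfile(myc_r=False)))
        assert call.call == "challenging_indeterminate"
        assert call.ancillary_evidence == []


def test_unscoreable_case_is_indeterminate():
    call = run_algorithm(_case())
    assert call.call == "challenging_indeterminate"
    assert call.pathway[-1] == "unscoreable"


def test_single_system_definitive_band_calls():
    # three-point only, total 3 (definitive) -> HGBL
    case = _case(ihc=IhcProfile(bcl6_pct=80.0, myc_pct=80.0, tdt_ihc="negative"),
                 genetics=GeneticProfile(myc_r=False))
    call = run_algorithm(case)
    assert call.call == "HGBL"
    assert call.pathway[-1] == "single_system_definitive:three_point"
    # three-point only, total 2 (non-definitive) -> indeterminate
    case2 = _case(ihc=IhcProfile(bcl6_pct=80.0, myc_pct=80.0, tdt_ihc="positive"),
                  genetics=GeneticProfile(myc_r=False))
    assert run_algorithm(case2).call == "challenging_indeterminate"


class TestClassifyCohort:
    def test_fixture_comparison_subset_concordance_split(self, fixture_cohort):
        from blastscore import validate_for_system
        ids = [
            c.case_id for c in fixture_cohort
            if validate_for_system(c, "six_point").scoreable
            and validate_for_system(c, "three_point").scoreable
        ]
        sub = fixture_cohort.subset(ids)
        table, summary = classify_cohort(sub)
        assert summary["n_cases"] == 101
        assert summary["n_score_concordant"] == 89
        assert summary["n_score_discordant"] == 12
        # correlated with all available features, every case resolves
        truth = {c.case_id: c.group_truth for c in sub}
        assert all(row.call == truth[row.case_id] for row in table.itertuples())

    def test_counts_conserve_cohort_size(self, fixture_cohort):
        table, summary = classify_cohort(fixture_cohort)
        assert len(table) == len(fixture_cohort)
        assert sum(summary["calls"].values()) == len(fixture_cohort)
        assert sum(summary["pathways"].values()) == len(fixture_cohort)

    def test_single_cyclin_d1_positive_case(self):
        cohort = Cohort(cases=[_case(ihc=IhcProfile(cyclin_d1="positive"))])
        table, summary = classify_cohort(cohort)
        assert summary["calls"] == {"MCL_excluded": 1}

    def test_empty_cohort(self):
        table, summary = classify_cohort(Cohort())
        assert len(table) == 0
        assert summary["n_cases"] == 0
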