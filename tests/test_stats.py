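"""Performance metrics, concordance, Fisher exact test, group comparison."""

import math
from itertools import product

import numpy as np
import pytest

from blastscore import (
    CaseRecord,
    Cohort,
    ContingencyTable,
    concordance,
    fisher_exact,
    group_compare,
    pct,
    performance,
    round_half_up,
    score_cohort,
    tdt_modality_concordance,
)


# ---------------------------------------------------------------------------
# independent oracle: exhaustive hypergeometric enumeration

def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with the same margins.

    Sums hypergeometric point probabilities not exceeding the observed
    table's (with a 1e-7 relative guard against ties lost to rounding).
    """
    r1, c1, n = a + b, a + c, a + b + c + d

    def point(x):
        return (
            math.comb(r1, x) * math.comb(n - r1, c1 - x) / math.comb(n, c1)
        )

    p_obs = point(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(
        point(x) for x in range(lo, hi + 1)
        if point(x) <= p_obs * (1 + 1e-7)
    )


class TestFisherExact:
    @pytest.mark.parametrize("a,b,c,d,expected", [
        (11, 14, 6, 35, 0.018),   # TP53 mutation prevalence contrast
        (0, 25, 7, 34, 0.039),    # KRAS
        (0, 25, 9, 32, 0.011),    # NRAS
    ])
    def test_published_mutation_contrasts(self, a, b, c, d, expected):
        assert fisher_exact(ContingencyTable(a, b, c, d)) == pytest.approx(
            expected, abs=5e-4
        )

    def test_identical_proportions_give_p_one(self):
        assert fisher_exact(ContingencyTable(5, 5, 5, 5)) == 1.0

    def test_degenerate_margins_return_one(self):
        assert fisher_exact(ContingencyTable(0, 0, 3, 4)) == 1.0
        assert fisher_exact(ContingencyTable(0, 3, 0, 4)) == 1.0

    def test_matches_exhaustive_enumeration_small_tables(self):
        """Implementation equals the brute-force oracle for random small
        tables (seeded draw over totals <= 30)."""
        rng = np.random.default_rng(20230848)
        for _ in range(300):
            n = int(rng.integers(1, 31))
            cuts = sorted(rng.integers(0, n + 1, size=3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = n - a - b - c
            table = ContingencyTable(a, b, c, d)
            if table.degenerate:
                continue
            assert fisher_exact(table) == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-9
            )

    def test_symmetry_under_group_and_label_swap(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            if a + b + c + d == 0:
                continue
            p = fisher_exact(ContingencyTable(a, b, c, d))
            assert fisher_exact(ContingencyTable(c, d, a, b)) == pytest.approx(p)
            assert fisher_exact(ContingencyTable(b, a, d, c)) == pytest.approx(p)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestRounding:
    def test_half_away_from_zero(self):
        assert round_half_up(0.5) == 1
        assert round_half_up(1.5) == 2
        assert round_half_up(2.5) == 3  # not banker's rounding
        assert round_half_up(-0.5) == -1

    def test_published_integer_percents(self):
        assert pct(40, 46) == 87   # 86.96
        assert pct(33, 39) == 85   # 84.6
        assert pct(59, 65) == 91   # 90.8
        assert pct(89, 101) == 88  # 88.1

    def test_zero_denominator_is_none(self):
        assert pct(0, 0) is None


class TestPerformance:
    def test_perfect_predictor(self):
        preds = {"a": "HGBL", "b": "BALL"}
        truths = {"a": "HGBL", "b": "BALL"}
        rep = performance(preds, truths)
        assert (rep.sensitivity, rep.specificity, rep.ppv, rep.npv,
                rep.accuracy) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_all_positive_predictor_on_balanced_cohort(self):
        preds = {f"c{i}": "HGBL" for i in range(20)}
        truths = {f"c{i}": "HGBL" if i < 10 else "BALL" for i in range(20)}
        rep = performance(preds, truths)
        assert rep.sensitivity == 1.0
        assert rep.specificity == 0.0
        assert rep.accuracy == 0.5
        assert rep.npv is None  # no negative calls: undefined, not zero

    def test_metric_identities(self):
        rng = np.random.default_rng(11)
        labels = ["HGBL", "BALL"]
        preds = {f"c{i}": labels[rng.integers(2)] for i in range(60)}
        truths = {f"c{i}": labels[rng.integers(2)] for i in range(60)}
        rep = performance(preds, truths)
        fnr = rep.fn / (rep.tp + rep.fn)
        assert rep.sensitivity + fnr == pytest.approx(1.0)
        # accuracy is the prevalence-weighted mean of sensitivity/specificity
        n_pos, n_neg = rep.tp + rep.fn, rep.tn + rep.fp
        weighted = (
            rep.sensitivity * n_pos + rep.specificity * n_neg
        ) / (n_pos + n_neg)
        assert rep.accuracy == pytest.approx(weighted)

    def test_missing_truth_label_rejected(self):
        with pytest.raises(ValueError, match="truth"):
            performance({"a": "HGBL"}, {})

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            performance({}, {})


class TestConcordance:
    @staticmethod
    def _results(rows, system):
        import pandas as pd
        return pd.DataFrame([
            {"case_id": cid, "favored": fav, "scoreable": True}
            for cid, fav in rows
        ])

    def test_identical_results_fully_concordant(self):
        rows = [("a", "HGBL"), ("b", "BALL")]
        rep = concordance(self._results(rows, "six"), self._results(rows, "three"),
                          {"a": "HGBL", "b": "BALL"})
        assert rep.concordance_rate == 1.0
        assert rep.n_misleading == 0

    def test_one_disagreement_in_four(self):
        six = [("a", "HGBL"), ("b", "BALL"), ("c", "HGBL"), ("d", "HGBL")]
        three = [("a", "HGBL"), ("b", "BALL"), ("c", "HGBL"), ("d", "BALL")]
        truths = dict(six)
        rep = concordance(self._results(six, "six"), self._results(three, "three"),
                          truths)
        assert rep.n_compared == 4
        assert rep.n_discordant == 1
        assert rep.concordance_rate == 0.75
        assert rep.misleading_ids == ["d"]

    def test_no_jointly_scoreable_cases_rejected(self):
        import pandas as pd
        empty = pd.DataFrame(columns=["case_id", "favored", "scoreable"])
        with pytest.raises(ValueError):
            concordance(empty, empty, {})


class TestGroupCompare:
    def test_fixture_cd45_row(self, fixture_cohort):
        row = group_compare(fixture_cohort, ["cd45_gt_granulocytes"]).iloc[0]
        assert (row.group1_pos, row.group1_total, row.group1_pct) == (72, 96, 75)
        assert (row.group2_pos, row.group2_total, row.group2_pct) == (11, 47, 23)
        assert row.p_value < 0.0001

    def test_fixture_myeloid_row(self, fixture_cohort):
        row = group_compare(fixture_cohort, ["myeloid_markers"]).iloc[0]
        assert (row.group1_pos, row.group1_total, row.group1_pct) == (0, 30, 0)
        assert (row.group2_pos, row.group2_total, row.group2_pct) == (19, 46, 41)

    def test_all_unknown_feature_not_assessable(self):
        cases = [
            CaseRecord(case_id="a", group_truth="HGBL"),
            CaseRecord(case_id="b", group_truth="BALL"),
        ]
        row = group_compare(Cohort(cases=cases), ["tp53_mut"]).iloc[0]
        assert not row.assessable

    def test_single_group_cohort_rejected(self):
        cohort = Cohort(cases=[CaseRecord(case_id="a", group_truth="HGBL")])
        with pytest.raises(ValueError):
            group_compare(cohort, ["cd34"])


class TestTdtModalityConcordance:
    def test_fixture_subtable(self, fixture_cohort):
        n_dual, n_conc, rate = tdt_modality_concordance(fixture_cohort)
        assert (n_dual, n_conc) == (40, 38)
        assert rate == pytest.approx(0.95)

    def test_no_dual_tested_cases(self):
        cohort = Cohort(cases=[CaseRecord(case_id="a")])
        assert tdt_modality_concordance(cohort) == (0, 0, None)

    def test_single_concordant_case(self):
        from blastscore import FlowProfile, IhcProfile
        case = CaseRecord(case_id="a", flow=FlowProfile(tdt_flow="negative"),
                          ihc=IhcProfile(tdt_ihc="negative"))
        assert tdt_modality_concordance(Cohort(cases=[case])) == (1, 1, 1.0)
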