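"""Agreement coefficients: hand-computed oracles, cross-checks, invariances."""

import numpy as np
import pytest
from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss_kappa

from crowdval import (
    Assignment,
    Label,
    RaterSource,
    VoteSet,
    agreement_report,
    build_ratings_table,
    fleiss_kappa,
    krippendorff_alpha_nominal,
    qualitative_label,
)
from crowdval.agreement import RatingsTable, qualitative_label_hedged
from crowdval.errors import UndefinedAgreementError, ValidationError


class TestFleissKappa:
    def test_perfect_agreement_two_categories(self):
        table = RatingsTable(np.array([[3, 0], [0, 3], [3, 0]]), categories=("T", "F"))
        assert fleiss_kappa(table) == pytest.approx(1.0)

    def test_hand_computed_micro_example(self):
        # N=2 items, n=2 raters, rows (2,0) and (1,1): kappa = -1/3 by the
        # P_i / p_j formulas evaluated by hand
        table = RatingsTable(np.array([[2, 0], [1, 1]]), categories=("T", "F"))
        assert fleiss_kappa(table) == pytest.approx(-1 / 3)

    def test_single_category_undefined(self):
        table = RatingsTable(np.array([[3, 0], [3, 0]]), categories=("T", "F"))
        with pytest.raises(UndefinedAgreementError):
            fleiss_kappa(table)

    def test_ragged_design_rejected(self):
        table = RatingsTable(np.array([[2, 1], [1, 1]]), categories=("T", "F"))
        with pytest.raises(ValidationError, match="unequal rater counts"):
            fleiss_kappa(table)

    def test_matches_statsmodels_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            counts = rng.multinomial(7, [0.5, 0.3, 0.2], size=30)
            ours = fleiss_kappa(RatingsTable(counts))
            theirs = sm_fleiss_kappa(counts, method="fleiss")
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        counts = rng.multinomial(5, [0.4, 0.4, 0.2], size=20)
        base = fleiss_kappa(RatingsTable(counts))
        assert fleiss_kappa(RatingsTable(counts[::-1])) == pytest.approx(base)
        assert fleiss_kappa(RatingsTable(counts[:, [2, 0, 1]])) == pytest.approx(base)


class TestKrippendorffAlpha:
    def test_perfect_agreement(self):
        assert krippendorff_alpha_nominal([["a", "a"], ["b", "b"]]) == pytest.approx(1.0)

    def test_hand_computed_coincidence_example(self):
        # units {a,a} and {a,b}: o_aa=2, o_ab=o_ba=1, D_o = 0.5, D_e = 0.5 -> 0
        assert krippendorff_alpha_nominal([["a", "a"], ["a", "b"]]) == pytest.approx(0.0)

    def test_single_rating_units_ignored(self):
        with_singleton = [["a", "a"], ["a", "b"], ["b"]]
        without = [["a", "a"], ["a", "b"]]
        assert krippendorff_alpha_nominal(with_singleton) == pytest.approx(
            krippendorff_alpha_nominal(without)
        )

    def test_no_pairable_values_undefined(self):
        with pytest.raises(UndefinedAgreementError):
            krippendorff_alpha_nominal([["a"], ["b"]])

    def test_single_category_undefined(self):
        with pytest.raises(UndefinedAgreementError):
            krippendorff_alpha_nominal([["a", "a"], ["a", "a"]])

    def test_permutation_invariance(self):
        units = [["a", "b", "a"], ["c", "c", "c"], ["a", "c", "b"], ["b", "b", "a"]]
        base = krippendorff_alpha_nominal(units)
        assert krippendorff_alpha_nominal(units[::-1]) == pytest.approx(base)
        renamed = [[{"a": "z", "b": "y", "c": "x"}[v] for v in u] for u in units]
        assert krippendorff_alpha_nominal(renamed) == pytest.approx(base)

    def test_alpha_close_to_kappa_on_complete_designs(self):
        # alpha's finite-sample correction vanishes as N grows; at N=1000 the
        # two chance-corrected coefficients agree to 0.01 on a complete design
        rng = np.random.default_rng(3)
        counts = rng.multinomial(7, [0.6, 0.25, 0.15], size=1000)
        table = RatingsTable(counts)
        assert abs(fleiss_kappa(table) - krippendorff_alpha_nominal(table)) <= 0.01


class TestQualitativeScale:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.6549, "substantial"),
            (0.2050, "fair"),
            (-0.5, "poor"),
            (0.0, "slight"),
            (0.20, "slight"),
            (0.40, "fair"),
            (0.601, "substantial"),
            (0.81, "almost perfect"),
            (1.0, "almost perfect"),
        ],
    )
    def test_landis_koch_bands(self, value, band):
        assert qualitative_label(value) == band

    def test_hedged_near_boundary(self):
        assert qualitative_label_hedged(0.2028) == "slight to fair"
        assert qualitative_label_hedged(0.2050) == "slight to fair"
        assert qualitative_label_hedged(0.30) == "fair"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            qualitative_label(1.5)


def _campaign_votes(n_items=3, crowd=7):
    """crowd unanimous-ish votes plus one extra rater and one expert per item."""
    votes = VoteSet()
    for i in range(n_items):
        rel = f"rel{i}"
        for w in range(crowd):
            votes.add(rel, Assignment(f"h{i}", f"W{w}", Label.TRUE))
        votes.add(
            rel,
            Assignment(f"h{i}", "extra", Label.TRUE if i else Label.FALSE,
                       rater_source=RaterSource.EXTRA_RATER),
        )
        votes.add(
            rel, Assignment(f"h{i}", "expert", Label.TRUE, rater_source=RaterSource.EXPERT)
        )
    return votes


class TestRatingsTableAndReport:
    def test_group_row_sums(self):
        votes = _campaign_votes()
        assert set(build_ratings_table(votes, sources=(RaterSource.CROWD,)).row_sums) == {7}
        both = build_ratings_table(
            votes, sources=(RaterSource.CROWD, RaterSource.EXTRA_RATER)
        )
        assert set(both.row_sums) == {8}
        pair = build_ratings_table(
            votes, sources=(RaterSource.EXTRA_RATER, RaterSource.EXPERT)
        )
        assert set(pair.row_sums) == {2}

    def test_report_perfect_agreement_deviation_zero(self):
        votes = VoteSet()
        for i in range(4):
            lab = Label.TRUE if i % 2 else Label.FALSE
            for w in range(3):
                votes.add(f"rel{i}", Assignment(f"h{i}", f"W{w}", lab))
        (report,) = agreement_report(votes, {"workers": (RaterSource.CROWD,)})
        assert report.fleiss_kappa == pytest.approx(1.0)
        assert report.krippendorff_alpha == pytest.approx(1.0)
        assert report.deviation == pytest.approx(0.0)
        assert report.qualitative == "almost perfect"

    def test_report_two_rater_group(self):
        votes = _campaign_votes()
        (report,) = agreement_report(
            votes, {"extra+expert": (RaterSource.EXTRA_RATER, RaterSource.EXPERT)}
        )
        assert report.n_items == 3
        assert report.n_distinct_raters == 2
        assert report.fleiss_kappa is not None
        assert report.deviation == pytest.approx(
            abs(report.fleiss_kappa - report.krippendorff_alpha)
        )
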