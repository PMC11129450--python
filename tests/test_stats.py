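"""Wald odds ratios, IRLS logistic regression, Mann–Whitney, power."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxtraj.stats import (
    ContingencyTable,
    PowerInput,
    SeparationError,
    ZeroCellError,
    cohens_h,
    expand_2x2,
    logistic_fit,
    mann_whitney_u,
    odds_ratio_wald,
    power_two_proportions,
)


def _table(a, b, c, d, group="IM/PM", ref="NM"):
    counts = pd.DataFrame(
        {"maintained": {ref: d, group: b}, "event": {ref: c, group: a}}
    )
    return ContingencyTable(counts, reference_group=ref,
                            reference_outcome="maintained")


class TestOddsRatioWald:
    def test_worked_example_discontinued(self):
        # NM 352 maintained / 88 discontinued; IM/PM 60 / 22
        est = odds_ratio_wald(_table(22, 60, 88, 352), "IM/PM", "event")
        assert round(est.odds_ratio, 2) == 1.47
        assert round(est.ci_low, 2) == 0.85
        assert round(est.ci_high, 2) == 2.52

    def test_worked_example_ultrarapid(self):
        est = odds_ratio_wald(_table(4, 13, 24, 120), "IM/PM", "event")
        assert round(est.odds_ratio, 2) == 1.54

    def test_equal_proportions_give_unit_or(self):
        est = odds_ratio_wald(_table(30, 60, 10, 20), "IM/PM", "event")
        assert est.odds_ratio == pytest.approx(1.0)
        assert est.ci_low < 1.0 < est.ci_high

    def test_zero_cell_raises_without_haldane(self):
        with pytest.raises(ZeroCellError):
            odds_ratio_wald(_table(0, 13, 24, 120), "IM/PM", "event")

    def test_haldane_correction_on_request(self):
        est = odds_ratio_wald(_table(0, 13, 24, 120), "IM/PM", "event",
                              haldane=True)
        expected = (0.5 * 120.5) / (13.5 * 24.5)
        assert est.odds_ratio == pytest.approx(expected)

    def test_interval_brackets_estimate(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 200, 4)
            est = odds_ratio_wald(_table(a, b, c, d), "IM/PM", "event")
            assert est.ci_low <= est.odds_ratio <= est.ci_high

    def test_from_labels_crosstab(self):
        groups = ["NM"] * 10 + ["IM/PM"] * 8
        outcomes = ["maintained"] * 6 + ["event"] * 4 + ["maintained"] * 3 + \
            ["event"] * 5
        table = ContingencyTable.from_labels(groups, outcomes,
                                             reference_group="NM",
                                             reference_outcome="maintained")
        est = odds_ratio_wald(table, "IM/PM", "event")
        assert est.odds_ratio == pytest.approx((5 * 6) / (3 * 4))


class TestLogisticFit:
    def test_reproduces_switched_odds_ratio(self):
        # NM 352 maintained / 223 switched; IM/PM 60 / 51
        y, x = expand_2x2(51, 60, 223, 352)
        res = logistic_fit(y, x, names=["group"])
        assert round(float(np.exp(res.params[1])), 2) == 1.34

    @given(st.tuples(*(st.integers(1, 200),) * 4))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_closed_form_on_any_2x2(self, cells):
        a, b, c, d = cells
        y, x = expand_2x2(a, b, c, d)
        res = logistic_fit(y, x)
        assert float(np.exp(res.params[1])) == pytest.approx(
            (a * d) / (b * c), abs=1e-9, rel=1e-9
        )
        # Wald SE of the log OR equals the reciprocal-cell formula
        assert float(res.bse[1]) == pytest.approx(
            math.sqrt(1 / a + 1 / b + 1 / c + 1 / d), rel=1e-9
        )

    def test_agrees_with_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        y, x = expand_2x2(22, 60, 88, 352)
        ours = logistic_fit(y, x)
        theirs = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose(ours.params, theirs.params, atol=1e-6)
        np.testing.assert_allclose(ours.bse, theirs.bse, atol=1e-6)

    def test_degenerate_outcome_errors(self):
        with pytest.raises(SeparationError):
            logistic_fit(np.zeros(10), np.arange(10))

    def test_perfect_separation_detected(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        x = np.array([0, 1, 2, 3, 10, 11, 12, 13], dtype=float)
        with pytest.raises(SeparationError):
            logistic_fit(y, x)

    def test_rank_deficient_design_rejected(self):
        y = np.array([0, 1, 0, 1], dtype=float)
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValueError, match="rank"):
            logistic_fit(y, X, add_intercept=False)


class TestMannWhitney:
    def test_identical_samples_are_null(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney_u(x, list(x))
        assert res.u == len(x) ** 2 / 2
        assert res.z == 0.0
        assert res.p_value == 1.0

    def test_exact_enumeration_small_case(self):
        res = mann_whitney_u([1, 2], [3, 4], method="exact")
        assert res.u == 0
        assert res.p_value == pytest.approx(2 / 6)

    def test_all_tied_reports_p_one(self):
        res = mann_whitney_u([5, 5, 5], [5, 5])
        assert res.p_value == 1.0 and res.z == 0.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=8), rng.normal(size=6)
        base = mann_whitney_u(x, y)
        trans = mann_whitney_u(np.exp(x), np.exp(y))
        assert trans.u == base.u
        assert trans.z == pytest.approx(base.z)

    def test_matches_scipy_asymptotic(self):
        from scipy.stats import mannwhitneyu as scipy_mwu

        rng = np.random.default_rng(8)
        for _ in range(25):
            x = rng.integers(0, 5, rng.integers(3, 12)).astype(float)
            y = rng.integers(0, 5, rng.integers(3, 12)).astype(float)
            ours = mann_whitney_u(x, y)
            ref = scipy_mwu(x, y, use_continuity=False, method="asymptotic")
            assert ours.u == pytest.approx(ref.statistic)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        from scipy.stats import mannwhitneyu as scipy_mwu

        rng = np.random.default_rng(9)
        for _ in range(10):
            x = rng.permutation(100)[:5].astype(float)
            y = rng.permutation(50)[:6].astype(float) + 0.5
            ours = mann_whitney_u(x, y, method="exact")
            ref = scipy_mwu(x, y, method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_continuity_corrected_approximation_accuracy(self):
        """The continuity-corrected normal approximation stays within 0.05
        of exact enumeration, exhaustively over all achievable
        configurations with min(n1, n2) >= 3 and n1 + n2 <= 12."""
        worst = 0.0
        for n1 in range(3, 10):
            for n2 in range(n1, 13 - n1):
                pooled = list(range(1, n1 + n2 + 1))
                seen: set[float] = set()
                for idx in itertools.combinations(range(n1 + n2), n1):
                    # with distinct pooled values both p-values depend on the
                    # configuration only through U, so test one sample per U
                    u = sum(idx) + n1 - n1 * (n1 + 1) / 2
                    if u in seen:
                        continue
                    seen.add(u)
                    x = [pooled[i] for i in idx]
                    y = [pooled[i] for i in range(n1 + n2) if i not in idx]
                    exact = mann_whitney_u(x, y, method="exact").p_value
                    approx = mann_whitney_u(x, y, continuity=True).p_value
                    worst = max(worst, abs(exact - approx))
        assert worst <= 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_mode_size_limit(self):
        with pytest.raises(ValueError, match="n1\\+n2"):
            mann_whitney_u(list(range(7)), list(range(7)), method="exact")


class TestPower:
    def test_worked_example(self):
        # switched vs maintained: 223/575 NM vs 51/111 IM/PM
        power = power_two_proportions(
            PowerInput(p1=223 / 575, p2=51 / 111, n1=575, n2=111)
        )
        assert round(power, 2) == 0.29

    def test_null_effect_power_equals_alpha(self):
        power = power_two_proportions(
            PowerInput(p1=0.3, p2=0.3, n1=100, n2=100, alpha=0.05)
        )
        assert power == pytest.approx(0.05)

    def test_monotone_in_sample_size_and_effect(self):
        base = PowerInput(p1=0.3, p2=0.4, n1=100, n2=100)
        p0 = power_two_proportions(base)
        assert power_two_proportions(
            PowerInput(0.3, 0.4, 200, 200)
        ) > p0
        assert power_two_proportions(PowerInput(0.3, 0.5, 100, 100)) > p0
        assert power_two_proportions(
            PowerInput(0.3, 0.4, 100, 100, alpha=0.10)
        ) > p0
        # grid: doubling both n never decreases power
        for p2 in (0.32, 0.35, 0.45, 0.6):
            for n in (20, 50, 200):
                small = power_two_proportions(PowerInput(0.3, p2, n, n))
                large = power_two_proportions(PowerInput(0.3, p2, 2 * n, 2 * n))
                assert large >= small

    def test_cohens_h_is_antisymmetric(self):
        assert cohens_h(0.2, 0.5) == pytest.approx(-cohens_h(0.5, 0.2))

    def test_degenerate_proportions_rejected(self):
        with pytest.raises(ValueError):
            PowerInput(p1=0.0, p2=0.5, n1=10, n2=10)
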