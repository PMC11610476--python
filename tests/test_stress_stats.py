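import itertools

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from oracles import pearson_r
from zfx import synthetic
from zfx.stress_stats import (
    CorrelationResult,
    benjamini_hochberg,
    correlate_expression,
    percent_change,
    significance_letters,
    summarize_panel,
)


def panel_from(values: dict[str, list[float]], analyte: str = "SOD") -> pd.DataFrame:
    rows = [
        {"treatment": t, "replicate": i + 1, "analyte": analyte, "value": v}
        for t, reps in values.items()
        for i, v in enumerate(reps)
    ]
    return pd.DataFrame(rows)


class TestSummarizePanel:
    def test_mean_and_sample_sd(self):
        out = summarize_panel(panel_from({"CK": [1.0, 2.0, 3.0]}))
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(1.0)

    def test_constant_replicates_sd_zero(self):
        out = summarize_panel(panel_from({"CK": [5.0, 5.0, 5.0]}))
        assert out.iloc[0]["sd"] == 0.0

    def test_single_replicate_flagged(self):
        with pytest.warns(UserWarning, match="single replicate"):
            out = summarize_panel(panel_from({"CK": [5.0]}))
        assert np.isnan(out.iloc[0]["sd"])

    def test_estimates_near_truth_at_n3(self):
        mean, sd = 630.85, 19.01
        panel = synthetic.make_enzyme_panel(
            {"SOD": {"CK": (mean, sd)}}, n_replicates=3, seed=42
        )
        out = summarize_panel(panel)
        assert abs(out.iloc[0]["mean"] - mean) < 3 * sd


class TestPercentChange:
    @pytest.mark.parametrize("treated,control,expected", [
        (71.87, 59.94, 19.90),
        (70.05, 59.94, 16.87),
        (68.91, 59.94, 14.96),
        (0.045, 0.175, -74.29),
        (0.035, 0.175, -80.00),
        (0.044, 0.175, -74.86),
    ])
    def test_reference_panel_values(self, treated, control, expected):
        assert percent_change(treated, control) == expected

    def test_no_change_is_zero(self):
        assert percent_change(3.7, 3.7) == 0.0

    def test_zero_control_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_change(1.0, 0.0)


class TestSignificanceLetters:
    def test_identical_treatments_share_a(self):
        reps = [10.0, 11.0, 12.0]
        panel = panel_from({t: reps for t in ("CK", "LS", "MS", "SS")})
        assert set(significance_letters(panel, "SOD").values()) == {"a"}

    def test_huge_separation_distinct_letters(self):
        panel = panel_from({"CK": [10.0, 10.1, 9.9], "SS": [1000.0, 1000.1, 999.9]})
        letters = significance_letters(panel, "SOD")
        assert set(letters["CK"]) & set(letters["SS"]) == set()
        assert letters["SS"] == "a"  # highest mean lettered first

    def test_shared_letter_means_not_significant(self):
        rng = np.random.default_rng(0)
        panel = panel_from({
            "CK": list(rng.normal(100, 5, 3)),
            "LS": list(rng.normal(104, 5, 3)),
            "MS": list(rng.normal(108, 5, 3)),
            "SS": list(rng.normal(160, 5, 3)),
        })
        letters = significance_letters(panel, "SOD")
        from scipy import stats as ss
        groups = {t: panel[panel["treatment"] == t]["value"].to_numpy()
                  for t in letters}
        order = sorted(letters, key=lambda t: -groups[t].mean())
        tukey = ss.tukey_hsd(*[groups[t] for t in order])
        for i, j in itertools.combinations(range(len(order)), 2):
            a, b = order[i], order[j]
            if set(letters[a]) & set(letters[b]):
                assert tukey.pvalue[i, j] >= 0.05

    def test_zero_variance_everywhere_letters_by_means(self):
        panel = panel_from({"CK": [5.0, 5.0], "LS": [7.0, 7.0], "MS": [7.0, 7.0]})
        with pytest.warns(UserWarning, match="zero within-group variance"):
            letters = significance_letters(panel, "SOD")
        assert letters == {"LS": "a", "MS": "a", "CK": "b"}


class TestCorrelateExpression:
    def make_frames(self, x, y):
        cols = [f"s{i}" for i in range(len(x))]
        expr = pd.DataFrame([x], index=["gene1"], columns=cols)
        physio = pd.DataFrame([y], index=["SOD"], columns=cols)
        return expr, physio

    def test_perfect_positive(self):
        x = [1.0, 2.0, 3.0, 4.0]
        expr, physio = self.make_frames(x, [2 * v for v in x])
        (res,) = correlate_expression(expr, physio)
        assert res.r == pytest.approx(1.0)
        assert res.significant

    def test_perfect_negative(self):
        x = [1.0, 2.0, 3.0, 4.0]
        expr, physio = self.make_frames(x, [-v for v in x])
        (res,) = correlate_expression(expr, physio)
        assert res.r == pytest.approx(-1.0)

    def test_matches_hand_rolled_pearson(self):
        rng = np.random.default_rng(11)
        x = list(rng.normal(size=12))
        y = list(rng.normal(size=12))
        expr, physio = self.make_frames(x, y)
        (res,) = correlate_expression(expr, physio)
        assert res.r == pytest.approx(pearson_r(x, y))

    def test_affine_rescaling_invariant(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        expr, physio = self.make_frames(list(x), list(y))
        (base,) = correlate_expression(expr, physio)
        expr2, physio2 = self.make_frames(list(3.0 * x + 7.0), list(y))
        (scaled,) = correlate_expression(expr2, physio2)
        assert scaled.r == pytest.approx(base.r)

    def test_analyte_analyte_pairs_included(self):
        cols = ["a", "b", "c", "d"]
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 4)),
                            index=["g1", "g2"], columns=cols)
        physio = pd.DataFrame(np.random.default_rng(1).normal(size=(3, 4)),
                              index=["SOD", "POD", "CAT"], columns=cols)
        results = correlate_expression(expr, physio)
        assert len(results) == 2 * 3 + 3  # gene x analyte + analyte pairs

    def test_low_n_emits_without_p(self):
        expr, physio = self.make_frames([1.0, 2.0], [3.0, 4.0])
        with pytest.warns(UserWarning, match="n=2"):
            (res,) = correlate_expression(expr, physio)
        assert res.p is None and not res.significant

    def test_r_bounds_validated(self):
        with pytest.raises(ValueError):
            CorrelationResult("a", "b", 1.5, 0.1, 4, False)


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self):
        rng = np.random.default_rng(1)
        p = list(rng.uniform(size=40))
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(benjamini_hochberg(p), expected)
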