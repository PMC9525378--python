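"""Randomized-complete-block statistics: ANOVA, binomial proportions, letters."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import scipy.stats as st

from penergetics.rcbd import (
    DesignError,
    classify_significance,
    fit_binomial_proportions,
    fit_rcbd,
    letter_grouping,
)


def _design(values):
    """values[block][treatment] -> long table, one pen per cell."""
    rows = []
    for b, per_trt in values.items():
        for t, v in per_trt.items():
            rows.append({"block": b, "treatment": t, "value": v})
    return pd.DataFrame(rows)


class TestClassifySignificance:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.04, "significant"), (0.05, "significant"), (0.08, "tendency"),
         (0.10, "tendency"), (0.29, "ns")],
    )
    def test_thresholds(self, p, expected):
        assert classify_significance(p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_significance(1.5)


class TestFitRcbd:
    def test_textbook_two_by_two(self):
        """Hand-worked two-way ANOVA: SS_trt=16, SS_block=9, SS_err=1,
        F(1,1)=16, p = 1 - (2/pi) atan(4) = 0.15596."""
        df = _design({1: {"T1": 10, "T2": 13}, 2: {"T1": 12, "T2": 17}})
        res = fit_rcbd(df)
        assert res.ls_means == pytest.approx({"T1": 11.0, "T2": 15.0})
        assert res.sem == pytest.approx(np.sqrt(1 / 2), rel=1e-9)
        assert res.p_value == pytest.approx(1 - (2 / np.pi) * np.arctan(4.0), abs=1e-6)

    def test_zero_noise_zero_effect_convention(self):
        df = _design({b: {"T1": 5.0, "T2": 5.0} for b in range(4)})
        res = fit_rcbd(df)
        assert res.p_value == 1.0
        assert res.classification == "ns"

    def test_balanced_ls_means_equal_raw_means(self):
        rng = np.random.default_rng(42)
        df = _design(
            {b: {t: rng.normal() for t in "ABC"} for b in range(6)}
        )
        res = fit_rcbd(df)
        raw = df.groupby("treatment")["value"].mean()
        for t in "ABC":
            assert res.ls_means[t] == pytest.approx(raw[t], rel=1e-9)

    def test_shift_invariance(self):
        rng = np.random.default_rng(7)
        df = _design({b: {t: rng.normal() for t in "AB"} for b in range(5)})
        base = fit_rcbd(df)
        shifted = df.assign(value=df["value"] + 100.0)
        res = fit_rcbd(shifted)
        assert res.p_value == pytest.approx(base.p_value, rel=1e-9)
        assert res.sem == pytest.approx(base.sem, rel=1e-9)
        for t in "AB":
            assert res.ls_means[t] == pytest.approx(base.ls_means[t] + 100.0)

    def test_fixed_and_random_block_agree_when_balanced(self):
        rng = np.random.default_rng(5)
        rows = []
        for b in range(10):
            eff = rng.normal(0, 1.0)
            for t in "ABC":
                rows.append({"block": b, "treatment": t,
                             "value": {"A": 0, "B": 0.1, "C": 0.2}[t] + eff
                             + rng.normal(0, 0.3)})
        df = pd.DataFrame(rows)
        fixed = fit_rcbd(df, block_effect="fixed")
        random = fit_rcbd(df, block_effect="random")
        assert random.p_value == pytest.approx(fixed.p_value, rel=1e-3)

    def test_missing_pen_tolerated(self):
        rng = np.random.default_rng(3)
        df = _design({b: {t: rng.normal() for t in "ABC"} for b in range(5)})
        res = fit_rcbd(df.iloc[1:])  # drop one pen
        assert 0 <= res.p_value <= 1

    def test_single_treatment_rejected(self):
        df = _design({1: {"T1": 1.0}, 2: {"T1": 2.0}})
        with pytest.raises(DesignError):
            fit_rcbd(df)

    def test_type_i_error_calibration(self):
        """Under the null, the treatment F-test at alpha=0.05 rejects at the
        nominal rate (2,000 simulated RCBDs, three-sigma binomial envelope)."""
        rng = np.random.default_rng(20200127)
        n_reps, rejections = 2000, 0
        for _ in range(n_reps):
            blocks = rng.normal(0, 1.0, 10)
            df = pd.DataFrame(
                [
                    {"block": b, "treatment": t,
                     "value": blocks[b] + rng.normal(0, 0.5)}
                    for b in range(10)
                    for t in "ABC"
                ]
            )
            if fit_rcbd(df).p_value <= 0.05:
                rejections += 1
        rate = rejections / n_reps
        tol = 3 * np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate - 0.05) <= tol


class TestBinomialProportions:
    def _counts(self, cells):
        rows = []
        for (b, t), (s, n) in cells.items():
            rows.append({"block": b, "treatment": t, "successes": s, "trials": n})
        return pd.DataFrame(rows)

    def test_equal_counts_equal_proportions(self):
        counts = self._counts(
            {(b, t): (3, 8) for b in range(3) for t in ("A", "B")}
        )
        res = fit_binomial_proportions(counts)
        assert res.ls_means["A"] == pytest.approx(res.ls_means["B"], rel=1e-9)
        assert res.ls_means["A"] == pytest.approx(100 * 3 / 8, rel=1e-6)

    def test_likelihood_ratio_matches_direct_optimization(self):
        """Independent oracle: maximize the binomial log-likelihood of the
        logit model directly with scipy and compare deviances."""
        counts = self._counts(
            {(0, "A"): (2, 8), (1, "A"): (3, 8), (0, "B"): (5, 8), (1, "B"): (6, 8)}
        )
        res = fit_binomial_proportions(counts)

        def nll(params, with_treatment):
            mu, blk, trt = params[0], params[1], (params[2] if with_treatment else 0.0)
            ll = 0.0
            for row in counts.itertuples():
                eta = mu + (blk if row.block == 1 else 0.0) + (
                    trt if row.treatment == "B" else 0.0
                )
                p = 1 / (1 + np.exp(-eta))
                ll += st.binom.logpmf(row.successes, row.trials, p)
            return -ll

        full = scipy.optimize.minimize(nll, [0, 0, 0], args=(True,), method="Nelder-Mead",
                                       options={"xatol": 1e-10, "fatol": 1e-12})
        red = scipy.optimize.minimize(nll, [0, 0], args=(False,), method="Nelder-Mead",
                                      options={"xatol": 1e-10, "fatol": 1e-12})
        lr = 2 * (red.fun - full.fun)
        expected_p = st.chi2.sf(lr, 1)
        assert res.p_value == pytest.approx(expected_p, abs=1e-4)

    def test_all_zero_category_degenerates_with_flag(self):
        counts = self._counts(
            {(b, t): (0, 8) for b in range(3) for t in ("A", "B")}
        )
        res = fit_binomial_proportions(counts)
        assert res.separation
        assert res.p_value == 1.0
        assert res.ls_means["A"] == 0.0

    def test_zero_trials_rejected(self):
        counts = self._counts({(0, "A"): (0, 0), (0, "B"): (1, 8),
                               (1, "A"): (1, 8), (1, "B"): (1, 8)})
        with pytest.raises(DesignError):
            fit_binomial_proportions(counts)


class TestLetterGrouping:
    def test_no_differences_share_one_letter(self):
        labels = letter_grouping(
            {"A": 1.0, "B": 1.1, "C": 0.9},
            {("A", "B"): 0.5, ("A", "C"): 0.6, ("B", "C"): 0.4},
        )
        assert set(labels.values()) == {"a"}

    def test_reported_yield_grade_pattern(self):
        """High vs low differ, middle shares with both: a / ab / b."""
        labels = letter_grouping(
            {"CON": 2.78, "CBCDS": 2.66, "WCGF": 2.61},
            {("CBCDS", "CON"): 0.14, ("CBCDS", "WCGF"): 0.52, ("CON", "WCGF"): 0.04},
            alpha=0.10,
        )
        assert labels["CON"] == "a"
        assert labels["WCGF"] == "b"
        assert labels["CBCDS"] == "ab"

    def test_all_different(self):
        labels = letter_grouping(
            {"A": 3.0, "B": 2.0, "C": 1.0},
            {("A", "B"): 0.01, ("A", "C"): 0.001, ("B", "C"): 0.02},
            alpha=0.05,
        )
        assert len({labels["A"], labels["B"], labels["C"]}) == 3
        assert labels["A"] == "a"  # highest mean gets the first letter

    def test_symmetric_inputs_symmetric_labels(self):
        labels = letter_grouping(
            {"A": 1.0, "B": 1.0}, {("A", "B"): 1.0}
        )
        assert labels["A"] == labels["B"]
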