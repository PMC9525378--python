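"""Pen performance assembly: shrink, carcass adjustment, intake accounting."""

import numpy as np
import pandas as pd
import pytest

from penergetics.performance import (
    SchemaError,
    build_pen_performance,
    carcass_adjusted_final_bw,
    cumulative_adg,
    exclude_deads_removals,
    pen_dmi,
    shrink_bw,
    steer_summary,
)


class TestShrink:
    @pytest.mark.parametrize(
        "bw, frac, expected",
        [(401, 0.04, 384.96), (100, 0.0, 100.0), (500, 0.04, 480.0)],
    )
    def test_values(self, bw, frac, expected):
        assert shrink_bw(bw, frac) == pytest.approx(expected, abs=1e-9)

    def test_negative_bw_rejected(self):
        with pytest.raises(ValueError):
            shrink_bw(-1.0, 0.04)


class TestCarcassAdjustment:
    @pytest.mark.parametrize(
        "hcw, y, expected",
        [(411, 0.6433, 638.9), (0.6433, 0.6433, 1.0), (410, 0.6433, 637.3)],
    )
    def test_values(self, hcw, y, expected):
        assert carcass_adjusted_final_bw(hcw, y) == pytest.approx(expected, abs=0.05)

    def test_round_trip(self):
        assert carcass_adjusted_final_bw(411, 0.6433) * 0.6433 == pytest.approx(
            411, rel=1e-12
        )

    def test_zero_yield_rejected(self):
        with pytest.raises(ValueError):
            carcass_adjusted_final_bw(411, 0.0)


class TestCumulativeAdg:
    @pytest.mark.parametrize(
        "init, final, days, expected",
        [(386, 640, 145.5, 1.746), (386, 386, 100, 0.0), (385, 637, 145.5, 1.732)],
    )
    def test_values(self, init, final, days, expected):
        assert cumulative_adg(init, final, days) == pytest.approx(expected, abs=5e-4)


def _feed(rows):
    return pd.DataFrame(
        rows, columns=["pen_id", "day", "as_fed_kg", "dm_fraction", "destination", "steer_id"]
    )


class TestPenDmi:
    def test_single_steer_home_feed(self):
        feed = _feed([("P1", d, 10.0, 0.80, "home", None) for d in range(1, 11)])
        assert pen_dmi(feed, head_days=10) == pytest.approx(8.0)

    def test_split_delivery_invariance(self):
        one = _feed([("P1", 1, 10.0, 0.8, "home", None)])
        two = _feed(
            [("P1", 1, 4.0, 0.8, "home", None), ("P1", 1, 6.0, 0.8, "home", None)]
        )
        assert pen_dmi(one, 5) == pytest.approx(pen_dmi(two, 5), rel=1e-12)

    def test_hospital_feed_excluded_when_steer_never_returns(self):
        # steer leaves the home pen on day 6 and never returns: home feed runs
        # days 1-5, hospital feed days 6-10 is debited, head-days stop at day 6
        rows = [("P1", d, 10.0, 0.8, "home", None) for d in range(1, 6)]
        rows += [("P1", d, 6.25, 0.8, "hospital", "S1") for d in range(6, 11)]
        feed = _feed(rows)
        dmi = pen_dmi(feed, head_days=6, returned={"S1": False})
        assert dmi == pytest.approx(5 * 8.0 / 6)

    def test_hospital_feed_credited_when_steer_returns(self):
        rows = [("P1", 1, 10.0, 0.8, "home", None), ("P1", 2, 10.0, 0.8, "hospital", "S1")]
        dmi = pen_dmi(_feed(rows), head_days=2, returned={"S1": True})
        assert dmi == pytest.approx(8.0)

    def test_unknown_hospital_steer_rejected(self):
        feed = _feed([("P1", 1, 10.0, 0.8, "hospital", "ghost")])
        with pytest.raises(SchemaError):
            pen_dmi(feed, 1, returned={})

    def test_bad_dm_fraction_rejected(self):
        with pytest.raises(ValueError):
            pen_dmi(_feed([("P1", 1, 10.0, 1.5, "home", None)]), 1)


class TestExcludeDeadsRemovals:
    def test_counts(self):
        df = pd.DataFrame(
            {
                "steer_id": range(80),
                "disposition": ["finished"] * 78 + ["died", "removed"],
            }
        )
        assert len(exclude_deads_removals(df)) == 78

    def test_empty(self):
        df = pd.DataFrame({"steer_id": [], "disposition": []})
        assert exclude_deads_removals(df).empty


def _tiny_study():
    """Two pens x two steers, hand-computable end to end."""
    steers = []
    for pen, block, trt, bws in [
        ("P1", 1, "CON", [(400, 600), (420, 640)]),
        ("P2", 1, "TEST", [(390, 610), (410, 630)]),
    ]:
        for i, (b0, b1) in enumerate(bws):
            sid = f"{pen}_S{i}"
            steers += [
                dict(steer_id=sid, pen_id=pen, block=block, treatment=trt,
                     day=0, bw_kg=b0, disposition="finished", disposition_day=None),
                dict(steer_id=sid, pen_id=pen, block=block, treatment=trt,
                     day=100, bw_kg=b1, disposition="finished", disposition_day=None),
            ]
    steers = pd.DataFrame(steers)
    feed = _feed(
        [(p, d, 25.0, 0.8, "home", None) for p in ("P1", "P2") for d in range(1, 101)]
    )
    carcass = pd.DataFrame(
        {
            "steer_id": ["P1_S0", "P1_S1", "P2_S0", "P2_S1"],
            "hcw_kg": [0.64 * 600 * 0.96, 0.64 * 640 * 0.96,
                       0.64 * 610 * 0.96, 0.64 * 630 * 0.96],
        }
    )
    return steers, feed, carcass


class TestBuildPenPerformance:
    def test_hand_computed_pipeline(self):
        steers, feed, carcass = _tiny_study()
        pens = build_pen_performance(steers, feed, carcass).set_index("pen_id")
        # every steer dresses at exactly 0.64 of shrunk final BW
        assert pens["common_dressed_yield"].iloc[0] == pytest.approx(0.64)
        # carcass-adjusted final = shrunk final live BW
        assert pens.loc["P1", "carcass_adjusted_final_bw_kg"] == pytest.approx(
            0.96 * 620
        )
        assert pens.loc["P1", "initial_shrunk_bw_kg"] == pytest.approx(0.96 * 410)
        assert pens.loc["P1", "adg_kg_d"] == pytest.approx(0.96 * 210 / 100)
        # 25 kg as-fed at 0.8 DM over 2 head = 10 kg DM/steer/day
        assert pens.loc["P1", "dmi_kg_d"] == pytest.approx(10.0)

    def test_gf_identity(self):
        steers, feed, carcass = _tiny_study()
        pens = build_pen_performance(steers, feed, carcass)
        assert np.allclose(
            pens["gf"], pens["adg_kg_d"] / pens["dmi_kg_d"], rtol=1e-12
        )

    def test_fixed_dressed_yield_option(self):
        steers, feed, carcass = _tiny_study()
        pens = build_pen_performance(
            steers, feed, carcass, dressed_yield=0.6433
        ).set_index("pen_id")
        assert pens.loc["P1", "carcass_adjusted_final_bw_kg"] == pytest.approx(
            carcass["hcw_kg"][:2].mean() / 0.6433
        )

    def test_missing_column_raises_schema_error(self):
        steers, feed, carcass = _tiny_study()
        with pytest.raises(SchemaError):
            build_pen_performance(steers.drop(columns=["block"]), feed, carcass)

    def test_excluding_zero_steers_leaves_aggregates_unchanged(self):
        steers, feed, carcass = _tiny_study()
        filtered = exclude_deads_removals(steers)
        a = build_pen_performance(steers, feed, carcass)
        b = build_pen_performance(filtered, feed, carcass)
        pd.testing.assert_frame_equal(a, b)


class TestSyntheticStudyAggregates:
    def test_finisher_counts_and_dmi_match_configuration(self, zero_noise_tables):
        pens = build_pen_performance(**zero_noise_tables)
        assert (pens["n_head_final"] == 8).all()
        by_trt = pens.groupby("treatment")["dmi_kg_d"].mean()
        assert by_trt["CON"] == pytest.approx(10.69, rel=1e-9)
        assert by_trt["CBCDS"] == pytest.approx(10.76, rel=1e-9)
        assert by_trt["WCGF"] == pytest.approx(10.67, rel=1e-9)

    def test_default_noise_dmi_near_configured(self, default_tables):
        pens = build_pen_performance(**default_tables)
        assert pens["dmi_kg_d"].mean() == pytest.approx(10.71, abs=0.3)

    def test_steer_summary_days_on_feed_groups(self, default_tables):
        summary = steer_summary(default_tables["steers"])
        fin = summary[summary["disposition"] == "finished"]
        days = fin.groupby(fin["pen_id"])["final_day"].max()
        assert set(days.unique()) == {145, 146}
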