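"""Carcass-trait derivations: dressing %, calculated yield grade, retail
yield, empty-body fat, adjusted final BW, and USDA grade distributions.

The yield-grade, retail-yield, and empty-body-fat regressions are linear
equations on carcass traits taken from the standard grading literature; the
constant sets are pinned here as named frozen structures so an alternate set
can be swapped via configuration.  Inputs are metric (cm, cm², kg, %); the
classic equations are defined on imperial units, so the exact conversion
constants live next to them.

Quality-grade coding for the empty-body-fat equation (a numeric code per
marbling band) is likewise a configuration table: the source trial reports
no coding, so the default (Select=4 … Prime=8) is a documented choice, not a
measured fact.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType

import numpy as np
import pandas as pd

__all__ = [
    "CM_PER_IN",
    "CM2_PER_IN2",
    "LB_PER_KG",
    "YieldGradeCoefficients",
    "RetailYieldCoefficients",
    "EmptyBodyFatCoefficients",
    "USDA_YIELD_GRADE",
    "RETAIL_YIELD_FOUR_TERM",
    "EBF_CARCASS_REGRESSION",
    "QUALITY_GRADE_BANDS",
    "QUALITY_GRADE_CODES",
    "dressing_percentage",
    "usda_calculated_yield_grade",
    "retail_yield",
    "quality_grade_from_marbling",
    "empty_body_fat",
    "adjusted_final_bw",
    "grade_distribution",
]

CM_PER_IN = 2.54
CM2_PER_IN2 = 6.4516
LB_PER_KG = 2.20462


@dataclass(frozen=True)
class YieldGradeCoefficients:
    """USDA cutability regression on imperial units."""

    intercept: float = 2.50
    per_in_rib_fat: float = 2.5
    per_pct_kph: float = 0.2
    per_lb_hcw: float = 0.0038
    per_in2_rea: float = -0.32


@dataclass(frozen=True)
class RetailYieldCoefficients:
    """Percent closely trimmed boneless retail cuts (round, loin, rib,
    chuck), imperial units."""

    intercept: float = 51.34
    per_in_rib_fat: float = -5.784
    per_pct_kph: float = -0.462
    per_in2_rea: float = 0.740
    per_lb_hcw: float = -0.0093


@dataclass(frozen=True)
class EmptyBodyFatCoefficients:
    """Empty-body fat % from carcass traits, metric units, with a numeric
    quality-grade code; includes the kg-per-EBF-point slope used to adjust
    final BW to the 28% EBF endpoint."""

    intercept: float = 17.76207
    per_cm_rib_fat: float = 4.68142
    per_kg_hcw: float = 0.01945
    per_grade_code: float = 0.81855
    per_cm2_rea: float = -0.06754
    target_ebf_pct: float = 28.0
    kg_per_ebf_point: float = 14.26


USDA_YIELD_GRADE = YieldGradeCoefficients()
RETAIL_YIELD_FOUR_TERM = RetailYieldCoefficients()
EBF_CARCASS_REGRESSION = EmptyBodyFatCoefficients()

# Marbling bands (400 = Small00 = USDA Low Choice threshold, 100-point bands).
QUALITY_GRADE_BANDS = (
    ("Select", 0, 400),
    ("LowChoice", 400, 500),
    ("AvgChoice", 500, 600),
    ("HighChoice", 600, 700),
    ("Prime", 700, float("inf")),
)

# Numeric quality-grade codes for the EBF regression; a config table because
# the coding is not uniquely determined by the trial report.
QUALITY_GRADE_CODES = MappingProxyType(
    {"Select": 4, "LowChoice": 5, "AvgChoice": 6, "HighChoice": 7, "Prime": 8}
)

QUALITY_CLASSES = tuple(name for name, *_ in QUALITY_GRADE_BANDS)
YIELD_CLASSES = (1, 2, 3, 4, 5)


def _positive(**values: object) -> None:
    for name, value in values.items():
        if np.any(np.asarray(value) <= 0):
            raise ValueError(f"{name} must be strictly positive")


def dressing_percentage(hcw_kg, final_bw_kg, shrink_fraction: float = 0.04):
    """Dressed yield, % = 100 * HCW / (final live BW * (1 - shrink)).

    The final live BW is pencil-shrunk by the same fraction as the initial
    BW, so the one formula covers both statements of the calculation.
    """
    _positive(hcw_kg=hcw_kg, final_bw_kg=final_bw_kg)
    if not 0 <= shrink_fraction < 1:
        raise ValueError("shrink_fraction must be in [0, 1)")
    return 100.0 * np.asarray(hcw_kg) / (
        np.asarray(final_bw_kg) * (1.0 - shrink_fraction)
    )


def usda_calculated_yield_grade(
    rf_cm,
    kph_pct,
    hcw_kg,
    rea_cm2,
    coefficients: YieldGradeCoefficients = USDA_YIELD_GRADE,
):
    """USDA calculated yield grade from metric traits.

    Converts rib fat to inches, HCW to pounds, and ribeye area to square
    inches, then evaluates the linear cutability regression.  Lower is
    leaner; zero traits return the intercept.
    """
    c = coefficients
    return (
        c.intercept
        + c.per_in_rib_fat * np.asarray(rf_cm) / CM_PER_IN
        + c.per_pct_kph * np.asarray(kph_pct)
        + c.per_lb_hcw * np.asarray(hcw_kg) * LB_PER_KG
        + c.per_in2_rea * np.asarray(rea_cm2) / CM2_PER_IN2
    )


def retail_yield(
    rf_cm,
    kph_pct,
    hcw_kg,
    rea_cm2,
    coefficients: RetailYieldCoefficients = RETAIL_YIELD_FOUR_TERM,
):
    """Estimated % closely trimmed boneless retail cuts (round, loin, rib,
    chuck) from metric traits via the four-term linear regression."""
    c = coefficients
    return (
        c.intercept
        + c.per_in_rib_fat * np.asarray(rf_cm) / CM_PER_IN
        + c.per_pct_kph * np.asarray(kph_pct)
        + c.per_in2_rea * np.asarray(rea_cm2) / CM2_PER_IN2
        + c.per_lb_hcw * np.asarray(hcw_kg) * LB_PER_KG
    )


def quality_grade_from_marbling(marbling):
    """Map marbling score(s) to USDA quality classes (Select < 400 ≤ Low
    Choice < 500 ≤ Average Choice < 600 ≤ High Choice < 700 ≤ Prime)."""
    m = np.asarray(marbling)
    if np.any(m < 0):
        raise ValueError("marbling must be non-negative")
    out = np.empty(m.shape, dtype=object)
    for name, lo, hi in QUALITY_GRADE_BANDS:
        out[(m >= lo) & (m < hi)] = name
    return out[()] if out.ndim == 0 else out


def empty_body_fat(
    rf_cm,
    hcw_kg,
    rea_cm2,
    quality_grade_code,
    coefficients: EmptyBodyFatCoefficients = EBF_CARCASS_REGRESSION,
):
    """Estimated empty-body fat % from carcass traits and the numeric
    quality-grade code."""
    _positive(rf_cm=rf_cm, hcw_kg=hcw_kg, rea_cm2=rea_cm2)
    c = coefficients
    return (
        c.intercept
        + c.per_cm_rib_fat * np.asarray(rf_cm)
        + c.per_kg_hcw * np.asarray(hcw_kg)
        + c.per_grade_code * np.asarray(quality_grade_code)
        + c.per_cm2_rea * np.asarray(rea_cm2)
    )


def adjusted_final_bw(
    ebf_pct,
    final_shrunk_bw_kg,
    coefficients: EmptyBodyFatCoefficients = EBF_CARCASS_REGRESSION,
):
    """Final BW adjusted to the common empty-body-fat endpoint (28% EBF).

    AFBW = final shrunk BW - kg_per_ebf_point * (EBF - 28); a carcass at
    exactly 28% EBF keeps its shrunk final BW.
    """
    c = coefficients
    return np.asarray(final_shrunk_bw_kg) - c.kg_per_ebf_point * (
        np.asarray(ebf_pct) - c.target_ebf_pct
    )


def yield_grade_class(calc_yield_grade):
    """Whole yield-grade class: floor of the calculated YG, bounded 1–5."""
    return np.clip(np.floor(np.asarray(calc_yield_grade)), 1, 5).astype(int)


def grade_distribution(records: pd.DataFrame) -> pd.DataFrame:
    """Per-pen proportions in each USDA quality and yield-grade class.

    ``records`` needs pen_id, marbling, and calc_yield_grade columns.
    Returns one row per pen with ``quality_<class>`` and ``yield_<k>``
    proportion columns plus n_head; each family sums to 1 per pen.
    """
    for col in ("pen_id", "marbling", "calc_yield_grade"):
        if col not in records.columns:
            raise ValueError(f"records table is missing column {col!r}")
    df = records.copy()
    df["quality"] = quality_grade_from_marbling(df["marbling"].to_numpy())
    df["yg_class"] = yield_grade_class(df["calc_yield_grade"].to_numpy())

    out = pd.DataFrame(index=sorted(df["pen_id"].unique()))
    out.index.name = "pen_id"
    n = df.groupby("pen_id").size()
    out["n_head"] = n
    for name in QUALITY_CLASSES:
        out[f"quality_{name}"] = (
            df[df["quality"] == name].groupby("pen_id").size().reindex(out.index, fill_value=0)
            / n
        )
    for k in YIELD_CLASSES:
        out[f"yield_{k}"] = (
            df[df["yg_class"] == k].groupby("pen_id").size().reindex(out.index, fill_value=0)
            / n
        )
    return out.reset_index()


def derive_carcass_traits(
    carcass: pd.DataFrame,
    final_live_bw_kg: pd.Series | None = None,
    *,
    shrink: float = 0.04,
    final_shrunk_bw_kg: pd.Series | None = None,
    grade_codes=QUALITY_GRADE_CODES,
) -> pd.DataFrame:
    """Per-steer derived carcass metrics.

    ``carcass`` needs steer_id, hcw_kg, rea_cm2, rf_cm, kph_pct, marbling.
    ``final_live_bw_kg`` (indexed like ``carcass``) enables dressing %;
    ``final_shrunk_bw_kg`` (the carcass-adjusted final BW) enables AFBW.
    """
    out = carcass.copy()
    out["calc_yield_grade"] = usda_calculated_yield_grade(
        out["rf_cm"], out["kph_pct"], out["hcw_kg"], out["rea_cm2"]
    )
    out["retail_yield_pct"] = retail_yield(
        out["rf_cm"], out["kph_pct"], out["hcw_kg"], out["rea_cm2"]
    )
    quality = quality_grade_from_marbling(out["marbling"].to_numpy())
    out["usda_quality_grade"] = quality
    codes = pd.Series(quality).map(dict(grade_codes)).to_numpy(dtype=float)
    out["ebf_pct"] = empty_body_fat(
        out["rf_cm"], out["hcw_kg"], out["rea_cm2"], codes
    )
    out["usda_yield_grade_class"] = yield_grade_class(
        out["calc_yield_grade"].to_numpy()
    )
    if final_live_bw_kg is not None:
        out["dressing_pct"] = dressing_percentage(
            out["hcw_kg"].to_numpy(), np.asarray(final_live_bw_kg), shrink
        )
    if final_shrunk_bw_kg is not None:
        out["afbw_kg"] = adjusted_final_bw(
            out["ebf_pct"].to_numpy(), np.asarray(final_shrunk_bw_kg)
        )
    return out
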