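"""Pen-level growth-performance assembly from steer and feed-delivery records.

Turns per-steer weigh-day records, per-pen feed deliveries (with batch DM
assays), and per-steer hot carcass weights into cumulative pen performance on
a deads- and removals-excluded basis: shrunk initial BW, carcass-adjusted
final BW, ADG, DMI and G:F, the inputs the energetics stage consumes.

Conventions
-----------
* Initial BW carries a fixed pencil shrink (default 4%) for gut fill.
* Final BW for carcass-adjusted performance is HCW divided by a common
  dressed yield (either supplied or the study-wide mean of per-steer
  HCW / shrunk final live BW over all finishers) — no additional shrink.
* A steer that died or was removed contributes no gain; its head-days run
  through its disposition day, and hospital-pen feed is credited back to the
  home pen only if the steer returned (finished), otherwise excluded
  retroactively to the hospitalization date.

Input tables (all plain CSV-able DataFrames):

``steers``  one row per weigh event: steer_id, pen_id, block, treatment,
            day, bw_kg, disposition, disposition_day (NaN for finishers).
``feed``    one row per delivery: pen_id, day, as_fed_kg, dm_fraction,
            destination ('home'|'hospital'), steer_id (hospital rows only).
``carcass`` one row per finished steer: steer_id, hcw_kg, ... (only hcw_kg
            is used here).
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "shrink_bw",
    "carcass_adjusted_final_bw",
    "cumulative_adg",
    "pen_dmi",
    "exclude_deads_removals",
    "steer_summary",
    "common_dressed_yield",
    "pen_head_days",
    "pen_intake",
    "build_pen_performance",
]

STEER_COLUMNS = [
    "steer_id",
    "pen_id",
    "block",
    "treatment",
    "day",
    "bw_kg",
    "disposition",
    "disposition_day",
]
FEED_COLUMNS = [
    "pen_id",
    "day",
    "as_fed_kg",
    "dm_fraction",
    "destination",
    "steer_id",
]


class SchemaError(ValueError):
    """An input table is missing required columns."""


def require_columns(df: pd.DataFrame, columns, name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing columns {missing}")


def shrink_bw(bw_kg, shrink_fraction: float):
    """Apply a pencil shrink: BW * (1 - shrink_fraction)."""
    if np.any(np.asarray(bw_kg) < 0):
        raise ValueError("bw_kg must be non-negative")
    if not 0 <= shrink_fraction < 1:
        raise ValueError("shrink_fraction must be in [0, 1)")
    return np.asarray(bw_kg) * (1.0 - shrink_fraction) if np.ndim(bw_kg) else bw_kg * (
        1.0 - shrink_fraction
    )


def carcass_adjusted_final_bw(hcw_kg, common_dressed_yield: float):
    """Carcass-adjusted final BW = HCW / common dressed yield."""
    if np.any(np.asarray(hcw_kg) <= 0):
        raise ValueError("hcw_kg must be strictly positive")
    if not 0 < common_dressed_yield < 1:
        raise ValueError("common_dressed_yield must be in (0, 1)")
    return np.asarray(hcw_kg) / common_dressed_yield if np.ndim(hcw_kg) else (
        hcw_kg / common_dressed_yield
    )


def cumulative_adg(initial_shrunk_bw, final_bw, days):
    """Cumulative ADG = (final - initial) / days on feed, kg/d."""
    if np.any(np.asarray(days) <= 0):
        raise ValueError("days must be strictly positive")
    return (np.asarray(final_bw) - initial_shrunk_bw) / days if np.ndim(
        final_bw
    ) else (final_bw - initial_shrunk_bw) / days


def exclude_deads_removals(steers: pd.DataFrame) -> pd.DataFrame:
    """Keep only weigh rows of steers that finished the study."""
    require_columns(steers, ["disposition"], "steers")
    return steers[steers["disposition"] == "finished"].copy()


def pen_dmi(
    deliveries: pd.DataFrame,
    head_days: float,
    returned: Mapping[object, bool] | None = None,
) -> float:
    """Dry-matter intake for one pen, kg DM per steer per day.

    Sums as-fed mass times batch DM fraction over the pen's deliveries.
    Hospital deliveries are credited to the home pen when the hospitalized
    steer returned (``returned[steer_id]`` true) and excluded otherwise —
    the retroactive debit back to the hospitalization date.  The total is
    divided by the pen's head-days.
    """
    require_columns(deliveries, ["as_fed_kg", "dm_fraction", "destination"], "feed")
    if not head_days > 0:
        raise ValueError("head_days must be strictly positive")
    if np.any(deliveries["as_fed_kg"].to_numpy() < 0):
        raise ValueError("as_fed_kg must be non-negative")
    dm_frac = deliveries["dm_fraction"].to_numpy(dtype=float)
    if np.any((dm_frac <= 0) | (dm_frac > 1)):
        raise ValueError("dm_fraction must be in (0, 1]")

    dm = deliveries["as_fed_kg"].to_numpy(dtype=float) * dm_frac
    is_hospital = (deliveries["destination"] == "hospital").to_numpy()
    keep = ~is_hospital
    if is_hospital.any():
        returned = returned or {}
        hospital_ids = deliveries.loc[is_hospital, "steer_id"]
        unknown = set(hospital_ids.dropna()) - set(returned)
        if unknown:
            raise SchemaError(
                f"hospital deliveries reference unknown steers: {sorted(unknown)!r}"
            )
        credited = np.zeros_like(keep)
        credited[is_hospital] = hospital_ids.map(
            lambda s: bool(returned.get(s, False))
        ).to_numpy()
        keep = keep | credited
    return float(dm[keep].sum()) / float(head_days)


def steer_summary(steers: pd.DataFrame, shrink: float = 0.04) -> pd.DataFrame:
    """Collapse weigh events to one row per steer.

    Returns steer_id, pen_id, block, treatment, disposition, disposition_day,
    initial_bw_kg (first weigh), initial_shrunk_bw_kg, final_live_bw_kg (last
    weigh), final_day.
    """
    require_columns(steers, STEER_COLUMNS, "steers")
    if (steers["bw_kg"] <= 0).any():
        raise ValueError("bw_kg must be strictly positive")
    s = steers.sort_values(["steer_id", "day"])
    grouped = s.groupby("steer_id", sort=True)
    out = grouped.agg(
        pen_id=("pen_id", "first"),
        block=("block", "first"),
        treatment=("treatment", "first"),
        disposition=("disposition", "first"),
        disposition_day=("disposition_day", "first"),
        initial_bw_kg=("bw_kg", "first"),
        final_live_bw_kg=("bw_kg", "last"),
        final_day=("day", "last"),
    ).reset_index()
    out["initial_shrunk_bw_kg"] = shrink_bw(
        out["initial_bw_kg"].to_numpy(), shrink
    )
    return out


def common_dressed_yield(
    summary: pd.DataFrame, carcass: pd.DataFrame, shrink: float = 0.04
) -> float:
    """Study-wide mean of per-steer HCW / shrunk final live BW (finishers)."""
    require_columns(carcass, ["steer_id", "hcw_kg"], "carcass")
    fin = summary[summary["disposition"] == "finished"]
    merged = fin.merge(carcass[["steer_id", "hcw_kg"]], on="steer_id", how="inner")
    if merged.empty:
        raise SchemaError("no finished steers with carcass records")
    yields = merged["hcw_kg"] / shrink_bw(
        merged["final_live_bw_kg"].to_numpy(), shrink
    )
    return float(yields.mean())


def pen_head_days(summary: pd.DataFrame) -> pd.Series:
    """Head-days per pen: finishers through the pen's final weigh day,
    non-finishers through their disposition day."""
    days_on_feed = (
        summary[summary["disposition"] == "finished"]
        .groupby("pen_id")["final_day"]
        .max()
    )
    contrib = np.where(
        summary["disposition"] == "finished",
        pd.to_numeric(summary["pen_id"].map(days_on_feed)),
        pd.to_numeric(summary["disposition_day"]),
    ).astype(float)
    return pd.Series(contrib, index=summary["pen_id"]).groupby(level=0).sum()


def pen_intake(feed: pd.DataFrame, summary: pd.DataFrame) -> pd.Series:
    """Total DM intake (kg) per pen under the hospital crediting rule."""
    require_columns(feed, FEED_COLUMNS, "feed")
    known = set(summary["steer_id"])
    hospital_ids = feed.loc[feed["destination"] == "hospital", "steer_id"].dropna()
    unknown = set(hospital_ids) - known
    if unknown:
        raise SchemaError(
            f"hospital deliveries reference unknown steers: {sorted(unknown)!r}"
        )
    returned = dict(
        zip(summary["steer_id"], summary["disposition"] == "finished")
    )
    dm = feed["as_fed_kg"] * feed["dm_fraction"]
    credited = (feed["destination"] != "hospital") | feed["steer_id"].map(
        lambda s: bool(returned.get(s, False))
    )
    return dm[credited].groupby(feed.loc[credited, "pen_id"]).sum()


def build_pen_performance(
    steers: pd.DataFrame,
    feed: pd.DataFrame,
    carcass: pd.DataFrame,
    *,
    shrink: float = 0.04,
    dressed_yield: float | str = "study_mean",
) -> pd.DataFrame:
    """Assemble the cumulative, carcass-adjusted pen performance table.

    Parameters
    ----------
    dressed_yield : float or "study_mean"
        The common dressed yield used to convert HCW to carcass-adjusted
        final BW.  ``"study_mean"`` computes the simple mean of per-steer
        HCW / shrunk final live BW across all finishers.

    Returns one row per pen with columns pen_id, block, treatment,
    n_head_final, days_on_feed, initial_shrunk_bw_kg, final_live_bw_kg,
    carcass_adjusted_final_bw_kg, adg_kg_d, dmi_kg_d, gf, plus the
    common_dressed_yield used.  Means are over finishers only; intake
    follows the hospital crediting rule.
    """
    summary = steer_summary(steers, shrink=shrink)
    if dressed_yield == "study_mean":
        cdy = common_dressed_yield(summary, carcass, shrink=shrink)
    else:
        cdy = float(dressed_yield)
        if not 0 < cdy < 1:
            raise ValueError("dressed_yield must be in (0, 1)")

    head_days = pen_head_days(summary)
    intake = pen_intake(feed, summary)

    fin = summary[summary["disposition"] == "finished"].merge(
        carcass[["steer_id", "hcw_kg"]], on="steer_id", how="left"
    )
    if fin["hcw_kg"].isna().any():
        missing = fin.loc[fin["hcw_kg"].isna(), "steer_id"].tolist()
        raise SchemaError(f"finished steers missing carcass records: {missing!r}")
    fin["carcass_adjusted_final_bw_kg"] = carcass_adjusted_final_bw(
        fin["hcw_kg"].to_numpy(), cdy
    )

    pens = fin.groupby("pen_id").agg(
        block=("block", "first"),
        treatment=("treatment", "first"),
        n_head_final=("steer_id", "size"),
        days_on_feed=("final_day", "max"),
        initial_shrunk_bw_kg=("initial_shrunk_bw_kg", "mean"),
        final_live_bw_kg=("final_live_bw_kg", "mean"),
        carcass_adjusted_final_bw_kg=("carcass_adjusted_final_bw_kg", "mean"),
    )
    pens["adg_kg_d"] = cumulative_adg(
        pens["initial_shrunk_bw_kg"].to_numpy(),
        pens["carcass_adjusted_final_bw_kg"].to_numpy(),
        pens["days_on_feed"].to_numpy(dtype=float),
    )
    pens["dmi_kg_d"] = intake.reindex(pens.index) / head_days.reindex(pens.index)
    pens["gf"] = pens["adg_kg_d"] / pens["dmi_kg_d"]
    pens["common_dressed_yield"] = cdy
    return pens.reset_index()
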