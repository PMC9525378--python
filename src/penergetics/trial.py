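"""The ``FeedlotTrial`` model: one object for the whole analysis.

Built from the three raw tables (steer weigh records, feed deliveries,
carcass traits) plus analysis options, ``fit()`` runs the full pipeline —
pen performance assembly, dietary-NE back-calculation, carcass-trait
derivation, grade tallies, and the randomized-complete-block treatment
comparison — and returns a :class:`FeedlotTrialResults` carrying the
pen-level tables, per-response RCBD fits, replacement-technique ingredient
NE values, and a ``summary()`` rendered in the familiar trial-report layout
(treatment columns, SEM, P-value, superscript letters).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import carcass as carcass_mod
from . import performance as perf_mod
from .energetics import EnergeticsInput, ReplacementNEInput, pen_energetics, replacement_ne
from .rcbd import RCBDResult, fit_binomial_proportions, fit_rcbd
from .reporting import render_table

__all__ = ["TrialConfig", "FeedlotTrial", "FeedlotTrialResults"]

PERFORMANCE_RESPONSES = [
    "initial_shrunk_bw_kg",
    "carcass_adjusted_final_bw_kg",
    "adg_kg_d",
    "dmi_kg_d",
    "gf",
]
ENERGETICS_RESPONSES = ["nem_mcal_kg", "neg_mcal_kg", "obs_exp_nem", "obs_exp_neg"]
CARCASS_RESPONSES = [
    "dressing_pct",
    "hcw_kg",
    "rea_cm2",
    "rf_cm",
    "marbling",
    "kph_pct",
    "calc_yield_grade",
    "retail_yield_pct",
    "ebf_pct",
    "afbw_kg",
]


class TrialConfig(BaseModel):
    """Analysis options for a trial.

    ``tabular_ne`` maps treatment → (NE_m, NE_g) book diet values for the
    observed:expected ratios; ``inclusion`` maps each test ingredient
    (= its treatment name) to the realized fraction of diet DM it replaced;
    ``displaced_corn_ne`` is the weighted NE of the corn it displaced.
    ``printed_precision`` applies 2-dp rounding to the treatment-mean diet
    NE values before the replacement calculation, matching hand
    calculations done from a printed table.
    """

    shrink: float = Field(default=0.04, ge=0, lt=1)
    dressed_yield: float | str = "study_mean"
    control: str = "CON"
    tabular_ne: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "CON": (2.09, 1.40),
            "CBCDS": (2.09, 1.40),
            "WCGF": (2.08, 1.40),
        }
    )
    displaced_corn_ne: dict[str, float] = Field(
        default_factory=lambda: {"nem": 2.24, "neg": 1.52}
    )
    inclusion: dict[str, float] = Field(
        default_factory=lambda: {"CBCDS": 0.2037, "WCGF": 0.2025}
    )
    block_effect: str = "fixed"
    alpha_letters: float = 0.10
    printed_precision: bool = True


@dataclass
class FeedlotTrialResults:
    """Fitted results for a trial; see :class:`FeedlotTrial`."""

    config: TrialConfig
    pen_performance: pd.DataFrame
    pen_energetics: pd.DataFrame
    carcass_derived: pd.DataFrame
    grade_distribution: pd.DataFrame
    performance_tests: dict[str, RCBDResult]
    carcass_tests: dict[str, RCBDResult]
    grade_tests: dict[str, RCBDResult]
    replacement_ne: dict[str, dict[str, float]]
    common_dressed_yield: float
    treatments: list[str] = dc_field(default_factory=list)

    def treatment_means(self, table: str = "performance") -> pd.DataFrame:
        """LS means by treatment for the requested response family."""
        tests = {
            "performance": self.performance_tests,
            "carcass": self.carcass_tests,
            "grades": self.grade_tests,
        }[table]
        rows = [r.as_row() for r in tests.values()]
        return pd.DataFrame(rows).set_index("response")

    def summary(self) -> str:
        """Render the trial-report tables as text."""
        parts = [
            "Growth performance and dietary NE",
            render_table(
                list(self.performance_tests.values()), "performance", self.treatments
            ),
            "",
            "Estimated replacement NE of test ingredients, Mcal/kg",
        ]
        for ingredient, vals in self.replacement_ne.items():
            parts.append(
                f"  {ingredient}: NE_m {vals['nem']:.2f}  NE_g {vals['neg']:.2f}"
            )
        parts += [
            "",
            "Carcass traits",
            render_table(
                list(self.carcass_tests.values()), "carcass", self.treatments
            ),
            "",
            "USDA grade distribution, %",
            render_table(list(self.grade_tests.values()), "grades", self.treatments),
        ]
        return "\n".join(parts)

    def plot_treatment_means(self, response: str = "nem_mcal_kg", ax=None):
        """Bar plot of per-pen values and treatment means for one response."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        df = self.pen_energetics if response in self.pen_energetics else (
            self.pen_performance
            if response in self.pen_performance
            else self.carcass_derived
        )
        for i, trt in enumerate(self.treatments):
            vals = df.loc[df["treatment"] == trt, response]
            ax.scatter(np.full(len(vals), i), vals, alpha=0.6, s=12)
            ax.hlines(vals.mean(), i - 0.25, i + 0.25, color="k")
        ax.set_xticks(range(len(self.treatments)), self.treatments)
        ax.set_ylabel(response)
        return ax


class FeedlotTrial:
    """Feedlot RCBD trial model over raw steer/feed/carcass tables.

    Parameters
    ----------
    steers, feed, carcass : DataFrames in the schemas documented in
        :mod:`penergetics.performance` and :mod:`penergetics.carcass`.
    config : TrialConfig, optional
    """

    def __init__(
        self,
        steers: pd.DataFrame,
        feed: pd.DataFrame,
        carcass: pd.DataFrame,
        config: TrialConfig | None = None,
    ) -> None:
        self.steers = steers
        self.feed = feed
        self.carcass = carcass
        self.config = config or TrialConfig()
        perf_mod.require_columns(steers, perf_mod.STEER_COLUMNS, "steers")
        perf_mod.require_columns(feed, perf_mod.FEED_COLUMNS, "feed")
        perf_mod.require_columns(
            carcass,
            ["steer_id", "hcw_kg", "rea_cm2", "rf_cm", "kph_pct", "marbling"],
            "carcass",
        )

    @classmethod
    def from_directory(
        cls, directory: str | Path, config: TrialConfig | None = None
    ) -> "FeedlotTrial":
        """Build from ``steers.csv``, ``feed.csv``, ``carcass.csv``."""
        directory = Path(directory)
        return cls(
            pd.read_csv(directory / "steers.csv"),
            pd.read_csv(directory / "feed.csv"),
            pd.read_csv(directory / "carcass.csv"),
            config,
        )

    def fit(self) -> FeedlotTrialResults:
        cfg = self.config
        pens = perf_mod.build_pen_performance(
            self.steers,
            self.feed,
            self.carcass,
            shrink=cfg.shrink,
            dressed_yield=cfg.dressed_yield,
        )
        cdy = float(pens["common_dressed_yield"].iloc[0])
        treatments = [t for t in cfg.tabular_ne if t in set(pens["treatment"])]
        if not treatments:
            treatments = sorted(pens["treatment"].unique())

        # --- pen energetics --------------------------------------------
        energy_rows = []
        for _, pen in pens.iterrows():
            tab = cfg.tabular_ne.get(pen["treatment"], (np.nan, np.nan))
            try:
                res = pen_energetics(
                    EnergeticsInput(
                        initial_shrunk_bw_kg=pen["initial_shrunk_bw_kg"],
                        carcass_adjusted_final_bw_kg=pen[
                            "carcass_adjusted_final_bw_kg"
                        ],
                        adg_kg_d=pen["adg_kg_d"],
                        dmi_kg_d=pen["dmi_kg_d"],
                    ),
                    *tab,
                )
            except ValueError as err:
                raise type(err)(f"pen {pen['pen_id']}: {err}") from err
            energy_rows.append(
                {
                    "pen_id": pen["pen_id"],
                    "block": pen["block"],
                    "treatment": pen["treatment"],
                    "median_w_kg": res.median_w_kg,
                    "em_mcal_d": res.em_mcal_d,
                    "eg_mcal_d": res.eg_mcal_d,
                    "nem_mcal_kg": res.nem_mcal_kg,
                    "neg_mcal_kg": res.neg_mcal_kg,
                    "obs_exp_nem": res.obs_exp_nem,
                    "obs_exp_neg": res.obs_exp_neg,
                }
            )
        energy = pd.DataFrame(energy_rows)

        # --- carcass derivations ---------------------------------------
        summary = perf_mod.steer_summary(self.steers, shrink=cfg.shrink)
        fin = summary[summary["disposition"] == "finished"]
        cc = self.carcass.merge(
            fin[["steer_id", "pen_id", "block", "treatment", "final_live_bw_kg"]],
            on="steer_id",
            how="inner",
            suffixes=("", "_steer"),
        )
        for col in ("pen_id", "block", "treatment"):
            dup = f"{col}_steer"
            if dup in cc.columns:
                cc[col] = cc[col].where(cc[col].notna(), cc[dup])
                cc = cc.drop(columns=dup)
        derived = carcass_mod.derive_carcass_traits(
            cc,
            final_live_bw_kg=cc["final_live_bw_kg"],
            shrink=cfg.shrink,
            final_shrunk_bw_kg=cc["hcw_kg"] / cdy,
        )
        grades = carcass_mod.grade_distribution(derived)
        design = (
            derived.groupby("pen_id")
            .agg(block=("block", "first"), treatment=("treatment", "first"))
            .reset_index()
        )
        grades = grades.merge(design, on="pen_id")

        # --- RCBD tests ------------------------------------------------
        perf_tests: dict[str, RCBDResult] = {}
        pen_table = pens.merge(
            energy[["pen_id"] + ENERGETICS_RESPONSES], on="pen_id"
        )
        for resp in PERFORMANCE_RESPONSES + ENERGETICS_RESPONSES:
            perf_tests[resp] = fit_rcbd(
                pen_table,
                resp,
                block_effect=cfg.block_effect,
                alpha_letters=cfg.alpha_letters,
            )

        carcass_pen = derived.groupby("pen_id").agg(
            block=("block", "first"),
            treatment=("treatment", "first"),
            **{c: (c, "mean") for c in CARCASS_RESPONSES if c in derived},
        ).reset_index()
        carcass_tests = {
            resp: fit_rcbd(
                carcass_pen,
                resp,
                block_effect=cfg.block_effect,
                alpha_letters=cfg.alpha_letters,
            )
            for resp in CARCASS_RESPONSES
            if resp in carcass_pen
        }

        grade_tests: dict[str, RCBDResult] = {}
        for col in grades.columns:
            if not (col.startswith("quality_") or col.startswith("yield_")):
                continue
            counts = grades[["treatment", "block"]].copy()
            counts["trials"] = grades["n_head"]
            counts["successes"] = (grades[col] * grades["n_head"]).round().astype(int)
            grade_tests[col] = fit_binomial_proportions(
                counts, col, alpha_letters=cfg.alpha_letters
            )

        # --- replacement-technique ingredient NE -----------------------
        obs_nem = energy.groupby("treatment")["nem_mcal_kg"].mean()
        obs_neg = energy.groupby("treatment")["neg_mcal_kg"].mean()
        if cfg.printed_precision:
            obs_nem = obs_nem.round(2)
            obs_neg = obs_neg.round(2)
        repl: dict[str, dict[str, float]] = {}
        for ingredient, incl in cfg.inclusion.items():
            if ingredient not in obs_nem.index or cfg.control not in obs_nem.index:
                continue
            repl[ingredient] = {
                "nem": replacement_ne(
                    ReplacementNEInput(
                        float(obs_nem[ingredient]),
                        float(obs_nem[cfg.control]),
                        incl,
                        cfg.displaced_corn_ne["nem"],
                    )
                ),
                "neg": replacement_ne(
                    ReplacementNEInput(
                        float(obs_neg[ingredient]),
                        float(obs_neg[cfg.control]),
                        incl,
                        cfg.displaced_corn_ne["neg"],
                    )
                ),
            }

        return FeedlotTrialResults(
            config=cfg,
            pen_performance=pens,
            pen_energetics=energy,
            carcass_derived=derived,
            grade_distribution=grades,
            performance_tests=perf_tests,
            carcass_tests=carcass_tests,
            grade_tests=grade_tests,
            replacement_ne=repl,
            common_dressed_yield=cdy,
            treatments=treatments,
        )
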