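"""Published summary data of the reference feedlot trial.

This package reimplements the analysis pipeline of a 3-treatment × 10-block
randomized-complete-block finishing trial (240 British × Continental steers,
8 per pen, 145.5 d on feed on average) in which dietary corn was replaced at
20% of diet DM by either corn bran plus condensed distillers solubles
(CBCDS) or wet corn gluten feed (WCGF).  The per-animal records are not
public; what the report prints are treatment-level means, the actual diet
formulations by period, and the ingredient assays.  Those printed values are
*inputs* to the worked examples and to the synthetic-study generator, and
are collected here.

Entries marked "calibrated" are not printed anywhere: they are the unique
values consistent with printed diet-level quantities (see docs/methods.md)
and are provided so the diet-level tabular NE reproduces the reported
numbers.
"""

from __future__ import annotations

from .diet import DietFormulation, IngredientAssay

TREATMENTS = ("CON", "CBCDS", "WCGF")
CONTROL = "CON"

N_BLOCKS = 10
STEERS_PER_PEN = 8
# Half the pen replicates started a day after the other half and were fed a
# day less, so days on feed average 145.5.
DAYS_ON_FEED_BY_GROUP = (146, 145)
INITIAL_BW_MEAN = 401.0
INITIAL_BW_SD = 43.2
COMMON_DRESSED_YIELD = 0.6433
SHRINK = 0.04

# Treatment-mean carcass-adjusted growth performance.
PERFORMANCE_MEANS = {
    "initial_shrunk_bw_kg": {"CON": 386.0, "CBCDS": 385.0, "WCGF": 385.0},
    "carcass_adjusted_final_bw_kg": {"CON": 640.0, "CBCDS": 637.0, "WCGF": 634.0},
    "adg_kg_d": {"CON": 1.74, "CBCDS": 1.73, "WCGF": 1.70},
    "dmi_kg_d": {"CON": 10.69, "CBCDS": 10.76, "WCGF": 10.67},
    "gf": {"CON": 0.163, "CBCDS": 0.161, "WCGF": 0.160},
}
OBSERVED_NE_MEANS = {
    "nem_mcal_kg": {"CON": 2.11, "CBCDS": 2.09, "WCGF": 2.08},
    "neg_mcal_kg": {"CON": 1.44, "CBCDS": 1.42, "WCGF": 1.41},
}
FINISHERS = {"CON": 78, "CBCDS": 80, "WCGF": 78}

# Treatment-mean carcass traits.
CARCASS_MEANS = {
    "dressing_pct": {"CON": 64.14, "CBCDS": 64.71, "WCGF": 64.13},
    "hcw_kg": {"CON": 411.0, "CBCDS": 410.0, "WCGF": 408.0},
    "rea_cm2": {"CON": 97.29, "CBCDS": 98.13, "WCGF": 97.00},
    "rf_cm": {"CON": 1.32, "CBCDS": 1.24, "WCGF": 1.22},
    "marbling": {"CON": 487.0, "CBCDS": 479.0, "WCGF": 473.0},
    "kph_pct": {"CON": 1.82, "CBCDS": 1.80, "WCGF": 1.78},
    "calc_yield_grade": {"CON": 2.78, "CBCDS": 2.66, "WCGF": 2.61},
    "retail_yield_pct": {"CON": 50.97, "CBCDS": 51.24, "WCGF": 51.35},
    "ebf_pct": {"CON": 30.16, "CBCDS": 29.71, "WCGF": 29.46},
    "afbw_kg": {"CON": 609.0, "CBCDS": 614.0, "WCGF": 615.0},
}

# Reported USDA grade distributions, percent of carcasses per treatment.
QUALITY_GRADE_PCT = {
    "Select": {"CON": 15.00, "CBCDS": 16.25, "WCGF": 18.75},
    "LowChoice": {"CON": 47.38, "CBCDS": 46.25, "WCGF": 48.33},
    "AvgChoice": {"CON": 25.54, "CBCDS": 31.25, "WCGF": 26.25},
    "HighChoice": {"CON": 12.08, "CBCDS": 5.00, "WCGF": 6.67},
    "Prime": {"CON": 0.00, "CBCDS": 1.25, "WCGF": 0.00},
}

# Diet-level tabular (expected) NE, Mcal/kg DM, for the obs:exp ratios.
TABULAR_DIET_NE = {
    "CON": (2.09, 1.40),
    "CBCDS": (2.09, 1.40),
    "WCGF": (2.08, 1.40),
}

# Replacement-technique constants: weighted NE of the displaced DRC:HMC corn
# blend, and the realized test-ingredient inclusion of diet DM.
DISPLACED_CORN_NE = {"nem": 2.24, "neg": 1.52}
TEST_INGREDIENT_INCLUSION = {"CBCDS": 0.2037, "WCGF": 0.2025}

# Test-ingredient nutrient assays (DM basis except DM), trial means.
INGREDIENT_ASSAYS = {
    "CBCDS": IngredientAssay(
        "CBCDS", dm_pct=47.84, cp_pct=27.69, ndf_pct=37.07,
        adf_pct=12.06, ee_pct=6.01, ash_pct=7.82,
    ),
    "WCGF": IngredientAssay(
        "WCGF", dm_pct=43.67, cp_pct=20.48, ndf_pct=43.20,
        adf_pct=12.34, ee_pct=3.42, ash_pct=4.82,
    ),
}

# Default nutrient profiles for the remaining ingredients.  Corn NDF/ADF are
# the trial's stated estimates (9% and 3%); the supplements and hay are
# assembled from the reported supplement recipes with standard book values —
# defaults for reconstruction, not assayed facts.
DEFAULT_INGREDIENT_NUTRIENTS = {
    "DRC": {"dm_pct": 87.0, "cp_pct": 8.0, "ndf_pct": 9.0, "adf_pct": 3.0,
            "ee_pct": 3.9, "ash_pct": 1.5},
    "HMC": {"dm_pct": 73.0, "cp_pct": 8.0, "ndf_pct": 9.0, "adf_pct": 3.0,
            "ee_pct": 4.0, "ash_pct": 1.5},
    "CBCDS": INGREDIENT_ASSAYS["CBCDS"].as_dict(),
    "WCGF": INGREDIENT_ASSAYS["WCGF"].as_dict(),
    "meal_supplement_CON": {"dm_pct": 89.0, "cp_pct": 46.0, "ndf_pct": 10.0,
                            "adf_pct": 6.0, "ee_pct": 1.5, "ash_pct": 9.0},
    "meal_supplement_CBCDS": {"dm_pct": 89.0, "cp_pct": 9.0, "ndf_pct": 33.0,
                              "adf_pct": 21.0, "ee_pct": 2.0, "ash_pct": 11.0},
    "meal_supplement_WCGF": {"dm_pct": 89.0, "cp_pct": 31.0, "ndf_pct": 9.0,
                             "adf_pct": 5.0, "ee_pct": 1.5, "ash_pct": 14.0},
    "grass_hay": {"dm_pct": 88.0, "cp_pct": 10.0, "ndf_pct": 65.0,
                  "adf_pct": 40.0, "ee_pct": 2.0, "ash_pct": 8.0},
    "liquid_supplement": {"dm_pct": 65.0, "cp_pct": 44.18, "ndf_pct": 0.0,
                          "adf_pct": 0.0, "ee_pct": 0.80, "ash_pct": 50.77},
}

# Tabular ingredient NE, Mcal/kg DM, (NE_m, NE_g).  DRC and the coproducts
# are the reported book values; the liquid supplement NE is as labeled.  HMC
# is calibrated to the stated displaced-corn blend NE (2.24/1.52) given the
# cumulative DRC:HMC split; the meal supplements and grass hay are calibrated
# so each cumulative diet reproduces the reported diet-level tabular NE.
INGREDIENT_TABULAR_NE = {
    "DRC": (2.20, 1.50),
    "HMC": (2.3155, 1.5577),            # calibrated
    "CBCDS": (2.20, 1.50),
    "WCGF": (2.20, 1.50),
    "meal_supplement_CON": (1.932, 1.243),    # calibrated
    "meal_supplement_CBCDS": (2.032, 1.287),  # calibrated
    "meal_supplement_WCGF": (1.893, 1.292),   # calibrated
    "grass_hay": (1.17, 0.58),                # calibrated
    "liquid_supplement": (1.06, 0.73),
}

# Actual DM formulation by period (fractions of diet DM).  HMC inventory ran
# out on day 101, after which DRC replaced it.
PERIOD_DAYS = {"d1_101": 101.0, "d101_end": 44.5}

DIET_FORMULATIONS = {
    "CON": [
        DietFormulation("CON", "d1_101", {
            "DRC": 0.4079, "HMC": 0.4068, "meal_supplement_CON": 0.0700,
            "grass_hay": 0.0652, "liquid_supplement": 0.0501,
        }, days=101.0),
        DietFormulation("CON", "d101_end", {
            "DRC": 0.8169, "meal_supplement_CON": 0.0686,
            "grass_hay": 0.0656, "liquid_supplement": 0.0489,
        }, days=44.5),
    ],
    "CBCDS": [
        DietFormulation("CBCDS", "d1_101", {
            "DRC": 0.3052, "HMC": 0.3059, "CBCDS": 0.2049,
            "meal_supplement_CBCDS": 0.0702, "grass_hay": 0.0641,
            "liquid_supplement": 0.0497,
        }, days=101.0),
        DietFormulation("CBCDS", "d101_end", {
            "DRC": 0.6155, "CBCDS": 0.2011, "meal_supplement_CBCDS": 0.0692,
            "grass_hay": 0.0654, "liquid_supplement": 0.0488,
        }, days=44.5),
    ],
    "WCGF": [
        DietFormulation("WCGF", "d1_101", {
            "DRC": 0.3070, "HMC": 0.3076, "WCGF": 0.2005,
            "meal_supplement_WCGF": 0.0699, "grass_hay": 0.0650,
            "liquid_supplement": 0.0500,
        }, days=101.0),
        DietFormulation("WCGF", "d101_end", {
            "DRC": 0.6115, "WCGF": 0.2069, "meal_supplement_WCGF": 0.0683,
            "grass_hay": 0.0649, "liquid_supplement": 0.0484,
        }, days=44.5),
    ],
}

# Reported actual diet nutrient composition (DM basis), period 1, for
# reconstruction cross-checks.
DIET_COMPOSITION_D1_101 = {
    "CON": {"dm_pct": 78.83, "cp_pct": 12.31, "ndf_pct": 12.84,
            "adf_pct": 5.73, "ee_pct": 3.76, "ash_pct": 4.82},
    "CBCDS": {"dm_pct": 69.66, "cp_pct": 13.36, "ndf_pct": 20.14,
              "adf_pct": 8.66, "ee_pct": 4.22, "ash_pct": 6.31},
    "WCGF": {"dm_pct": 68.10, "cp_pct": 13.44, "ndf_pct": 19.59,
             "adf_pct": 7.47, "ee_pct": 3.75, "ash_pct": 5.88},
}

REPLACEMENT_NE_REPORTED = {
    "CBCDS": {"nem": 2.14, "neg": 1.42},
    "WCGF": {"nem": 2.09, "neg": 1.37},
}
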