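"""Performance-based dietary net-energy estimation for finishing cattle.

Growth performance over a feeding period encodes the net-energy (NE) content
of the diet that produced it.  Daily retained energy and maintenance energy
are computed from average daily gain (ADG) and the median feeding shrunk body
weight W; together with observed dry-matter intake (DMI) they determine the
dietary NE for maintenance (``NE_m``, Mcal/kg DM) through the intake identity

    DMI = EM / NE_m + EG / NE_g,        NE_g = 0.877 NE_m - 0.41,

which rearranges to a quadratic in ``NE_m``.  The module solves that quadratic
(the classic performance-based NE back-calculation for feedlot cattle), maps
``NE_m`` to ``NE_g`` through the fixed linear relation, forms observed-to-
expected (tabular) NE ratios, and values a test ingredient by the replacement
technique: the whole diet-level NE difference from the control diet is
attributed to the substituted ingredient, scaled by its inclusion, plus the NE
of the corn it displaced.

All energies are Mcal, all masses kg, all intakes kg DM; no unit conversion
happens in this module.  Functions accept scalars or numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EnergeticsInput",
    "EnergeticsResult",
    "ReplacementNEInput",
    "InfeasiblePerformanceError",
    "retained_energy",
    "maintenance_energy",
    "solve_dietary_nem",
    "neg_from_nem",
    "pen_energetics",
    "replacement_ne",
    "predict_adg",
    "NEM_FLOOR",
]

# NE_g = NEG_SLOPE * NE_m - NEG_INTERCEPT (Mcal/kg); below NEM_FLOOR a diet
# supplies no energy for gain and the back-calculation is undefined.
NEG_SLOPE = 0.877
NEG_INTERCEPT = 0.41
NEM_FLOOR = NEG_INTERCEPT / NEG_SLOPE

# Retained energy EG = EG_COEF * ADG**EG_EXP * W**0.75 (Mcal/d) for a
# medium-frame steer; maintenance EM = EM_COEF * W**0.75 (Mcal/d).
EG_COEF = 0.0493
EG_EXP = 1.097
EM_COEF = 0.077
METABOLIC_EXP = 0.75


class InfeasiblePerformanceError(ValueError):
    """Observed performance is inconsistent with any positive dietary NE."""


@dataclass(frozen=True)
class EnergeticsInput:
    """Pen-level performance inputs for the NE back-calculation.

    ``initial_shrunk_bw_kg`` and ``carcass_adjusted_final_bw_kg`` bracket the
    feeding period; their mean is the median feeding shrunk BW (W).
    """

    initial_shrunk_bw_kg: float
    carcass_adjusted_final_bw_kg: float
    adg_kg_d: float
    dmi_kg_d: float

    def __post_init__(self) -> None:
        for name in (
            "initial_shrunk_bw_kg",
            "carcass_adjusted_final_bw_kg",
            "adg_kg_d",
            "dmi_kg_d",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.adg_kg_d < self.dmi_kg_d:
            raise ValueError("adg_kg_d must be less than dmi_kg_d")


@dataclass(frozen=True)
class EnergeticsResult:
    """Back-calculated dietary NE and observed:expected ratios for one pen."""

    median_w_kg: float
    em_mcal_d: float
    eg_mcal_d: float
    nem_mcal_kg: float
    neg_mcal_kg: float
    obs_exp_nem: float
    obs_exp_neg: float


@dataclass(frozen=True)
class ReplacementNEInput:
    """Inputs to the replacement-technique ingredient NE valuation."""

    test_diet_ne: float
    control_diet_ne: float
    inclusion_fraction: float
    displaced_corn_ne: float

    def __post_init__(self) -> None:
        if not 0 < self.inclusion_fraction <= 1:
            raise ValueError("inclusion_fraction must be in (0, 1]")


def _check_positive(**values: object) -> None:
    for name, value in values.items():
        if np.any(np.asarray(value) <= 0):
            raise ValueError(f"{name} must be strictly positive")


def retained_energy(adg, median_w):
    """Daily retained (gain) energy EG, Mcal/d.

    EG = ADG**1.097 * 0.0493 * W**0.75 with ADG in kg/d and W the median
    feeding shrunk BW in kg.
    """
    _check_positive(adg=adg, median_w=median_w)
    return EG_COEF * np.power(adg, EG_EXP) * np.power(median_w, METABOLIC_EXP)


def maintenance_energy(median_w):
    """Daily maintenance energy EM = 0.077 * W**0.75, Mcal/d."""
    _check_positive(median_w=median_w)
    return EM_COEF * np.power(median_w, METABOLIC_EXP)


def solve_dietary_nem(dmi, em, eg):
    """Back-solve dietary NE_m (Mcal/kg DM) from intake and energy flows.

    Solves DMI = EM/NE_m + EG/(0.877 NE_m - 0.41) via the quadratic with
    coefficients a = -0.41*EM, b = 0.877*EM + 0.41*DMI + EG, c = -0.877*DMI,
    taking the root x = (-b - sqrt(b^2 - 4ac)) / (2c): the larger positive
    root, the only one on the physical branch NE_g > 0.

    Raises
    ------
    InfeasiblePerformanceError
        If the discriminant is negative or the root does not exceed
        0.41/0.877 (the NE_m at which NE_g vanishes).
    """
    _check_positive(dmi=dmi, em=em)
    if np.any(np.asarray(eg) < 0):
        raise ValueError("eg must be non-negative")
    dmi = np.asarray(dmi, dtype=float)
    a = -NEG_INTERCEPT * np.asarray(em, dtype=float)
    b = NEG_SLOPE * np.asarray(em, dtype=float) + NEG_INTERCEPT * dmi + eg
    c = -NEG_SLOPE * dmi
    disc = b * b - 4.0 * a * c
    if np.any(disc < 0):
        raise InfeasiblePerformanceError(
            "negative discriminant: observed intake cannot supply the "
            "implied maintenance plus gain energy at any dietary NE_m"
        )
    nem = (-b - np.sqrt(disc)) / (2.0 * c)
    # the root collapses onto the NE_g = 0 floor (up to rounding) exactly
    # when intake cannot cover maintenance at any NE_m on the physical branch
    if np.any(nem <= NEM_FLOOR + 1e-9):
        raise InfeasiblePerformanceError(
            f"solved NE_m does not exceed {NEM_FLOOR:.4f} Mcal/kg; "
            "performance implies a diet with no energy for gain"
        )
    return nem[()] if np.ndim(nem) == 0 else nem


def neg_from_nem(nem):
    """Dietary NE_g from NE_m via the linear relation 0.877*NE_m - 0.41."""
    if np.any(np.asarray(nem) <= NEM_FLOOR):
        raise ValueError(f"nem must exceed {NEM_FLOOR:.4f} Mcal/kg")
    return NEG_SLOPE * np.asarray(nem) - NEG_INTERCEPT


def pen_energetics(
    inp: EnergeticsInput, tabular_nem: float, tabular_neg: float
) -> EnergeticsResult:
    """Full NE back-calculation for one pen (or one treatment mean).

    W is the mean of initial shrunk BW and carcass-adjusted final BW; EM and
    EG follow from W and ADG; the quadratic solve yields NE_m, the linear
    relation NE_g; observed:expected ratios divide by the tabular diet values.
    """
    w = 0.5 * (inp.initial_shrunk_bw_kg + inp.carcass_adjusted_final_bw_kg)
    em = maintenance_energy(w)
    eg = retained_energy(inp.adg_kg_d, w)
    nem = solve_dietary_nem(inp.dmi_kg_d, em, eg)
    neg = neg_from_nem(nem)
    _check_positive(tabular_nem=tabular_nem, tabular_neg=tabular_neg)
    return EnergeticsResult(
        median_w_kg=w,
        em_mcal_d=em,
        eg_mcal_d=eg,
        nem_mcal_kg=nem,
        neg_mcal_kg=neg,
        obs_exp_nem=nem / tabular_nem,
        obs_exp_neg=neg / tabular_neg,
    )


def replacement_ne(r: ReplacementNEInput) -> float:
    """Replacement-technique NE of a test ingredient, Mcal/kg DM.

    (test diet NE - control diet NE) / inclusion + NE of the displaced corn.
    Applies identically to NE_m and NE_g with the matching displaced-corn
    value.
    """
    return (
        r.test_diet_ne - r.control_diet_ne
    ) / r.inclusion_fraction + r.displaced_corn_ne


def predict_adg(nem, dmi, median_w):
    """ADG implied by a diet NE_m at a given DMI and median shrunk BW.

    Exact algebraic inverse of the back-calculation: intake above maintenance
    (DMI - EM/NE_m) retains energy at density NE_g, and the retained-energy
    equation is inverted for ADG.  Used by the synthetic-study generator so
    that simulated growth is exactly consistent with the energy system.

    Raises
    ------
    InfeasiblePerformanceError
        If intake does not exceed maintenance (DMI <= EM/NE_m).
    """
    _check_positive(nem=nem, dmi=dmi, median_w=median_w)
    if np.any(np.asarray(nem) <= NEM_FLOOR):
        raise ValueError(f"nem must exceed {NEM_FLOOR:.4f} Mcal/kg")
    em = maintenance_energy(median_w)
    surplus = np.asarray(dmi, dtype=float) - em / np.asarray(nem, dtype=float)
    if np.any(surplus < 0):
        raise InfeasiblePerformanceError(
            "intake below maintenance: no gain is feasible at this NE_m"
        )
    eg = surplus * neg_from_nem(nem)
    adg = np.power(
        eg / (EG_COEF * np.power(median_w, METABOLIC_EXP)), 1.0 / EG_EXP
    )
    return adg[()] if np.ndim(adg) == 0 else adg
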