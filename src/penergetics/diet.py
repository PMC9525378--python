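"""Diet composition accounting on a dry-matter basis.

Reconstructs actual diet composition from ingredient inclusion fractions and
ingredient nutrient assays, combines multi-period formulations into a
cumulative diet (weighted by delivered feed DM, or by days as a sensitivity
option), and carries tabular (book) net-energy values of the ingredients up
to the diet level for the observed:expected comparison in the energetics
stage.

All operators are linear in the inclusion vector, permutation-invariant, and
respect the simplex constraint (inclusions sum to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np

__all__ = [
    "IngredientAssay",
    "DietFormulation",
    "weighted_composition",
    "period_weighted_diet",
    "diet_tabular_ne",
]

SIMPLEX_TOL = 1e-6


@dataclass(frozen=True)
class IngredientAssay:
    """One ingredient's nutrient assay, percent of DM except DM itself."""

    ingredient: str
    dm_pct: float
    cp_pct: float
    ndf_pct: float
    adf_pct: float
    ee_pct: float
    ash_pct: float
    week: int | None = None

    @property
    def om_pct(self) -> float:
        return 100.0 - self.ash_pct

    def __post_init__(self) -> None:
        for name in ("dm_pct", "cp_pct", "ndf_pct", "adf_pct", "ee_pct", "ash_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")

    def as_dict(self) -> dict[str, float]:
        return {
            "dm_pct": self.dm_pct,
            "cp_pct": self.cp_pct,
            "ndf_pct": self.ndf_pct,
            "adf_pct": self.adf_pct,
            "ee_pct": self.ee_pct,
            "ash_pct": self.ash_pct,
            "om_pct": self.om_pct,
        }


@dataclass
class DietFormulation:
    """Per-period diet: ingredient → DM inclusion fraction, with optional
    weighting metadata (days fed, total feed DM) and derived values."""

    treatment: str
    period: str
    inclusions: Mapping[str, float]
    days: float | None = None
    feed_dm_kg: float | None = None
    nutrient_composition: dict[str, float] = field(default_factory=dict)
    tabular_nem: float | None = None
    tabular_neg: float | None = None

    def __post_init__(self) -> None:
        _check_simplex(self.inclusions)


def _check_simplex(inclusions: Mapping[str, float]) -> None:
    total = float(sum(inclusions.values()))
    if any(v < 0 for v in inclusions.values()):
        raise ValueError("inclusion fractions must be non-negative")
    if abs(total - 1.0) > SIMPLEX_TOL:
        raise ValueError(
            f"inclusion fractions must sum to 1 ± {SIMPLEX_TOL}, got {total:.8f}"
        )


def weighted_composition(
    inclusions: Mapping[str, float],
    assays: Mapping[str, IngredientAssay | Mapping[str, float]],
) -> dict[str, float]:
    """Diet nutrient composition as the inclusion-weighted assay mean.

    Every nutrient is Σ inclusion_i × nutrient_i on a DM basis; OM + ash =
    100 is preserved because the weighting is linear.
    """
    _check_simplex(inclusions)
    missing = [i for i in inclusions if i not in assays]
    if missing:
        raise KeyError(f"no assay for ingredients {missing}")
    nutrients: dict[str, float] = {}
    for ingredient, frac in inclusions.items():
        assay = assays[ingredient]
        values = assay.as_dict() if isinstance(assay, IngredientAssay) else assay
        for nutrient, value in values.items():
            nutrients[nutrient] = nutrients.get(nutrient, 0.0) + frac * float(value)
    return nutrients


def period_weighted_diet(
    formulations: Sequence[DietFormulation],
    *,
    by: str = "feed_dm",
) -> DietFormulation:
    """Cumulative diet as the convex combination of period formulations.

    Weighted by delivered feed DM per period (``by="feed_dm"``, the default,
    because net-energy exposure is intake-weighted) or by days on feed
    (``by="days"``).  Zero-weight periods are ignored.
    """
    if not formulations:
        raise ValueError("at least one period formulation is required")
    if by not in ("feed_dm", "days"):
        raise ValueError("by must be 'feed_dm' or 'days'")
    attr = "feed_dm_kg" if by == "feed_dm" else "days"
    weights = []
    for f in formulations:
        w = getattr(f, attr)
        if w is None:
            raise ValueError(f"formulation {f.period!r} has no {attr}")
        if w < 0:
            raise ValueError(f"{attr} must be non-negative")
        weights.append(float(w))
    total = sum(weights)
    if total <= 0:
        raise ValueError("total period weight must be positive")

    ingredients: dict[str, float] = {}
    for f, w in zip(formulations, weights):
        for ingredient, frac in f.inclusions.items():
            ingredients[ingredient] = (
                ingredients.get(ingredient, 0.0) + (w / total) * frac
            )
    # renormalize away float dust so the simplex invariant holds exactly
    s = sum(ingredients.values())
    inclusions = {k: v / s for k, v in ingredients.items()}
    return DietFormulation(
        treatment=formulations[0].treatment,
        period="cumulative",
        inclusions=inclusions,
        days=sum(f.days for f in formulations if f.days is not None) or None,
        feed_dm_kg=(
            sum(f.feed_dm_kg for f in formulations if f.feed_dm_kg is not None)
            or None
        ),
    )


def diet_tabular_ne(
    inclusions: Mapping[str, float],
    ingredient_ne: Mapping[str, tuple[float, float]],
) -> tuple[float, float]:
    """Inclusion-weighted tabular (NE_m, NE_g) of a diet, Mcal/kg DM.

    ``ingredient_ne`` maps ingredient → (NE_m, NE_g).  Every included
    ingredient must have an entry.
    """
    _check_simplex(inclusions)
    missing = [i for i in inclusions if i not in ingredient_ne]
    if missing:
        raise KeyError(f"no tabular NE for ingredients {missing}")
    nem = float(
        np.sum([frac * ingredient_ne[i][0] for i, frac in inclusions.items()])
    )
    neg = float(
        np.sum([frac * ingredient_ne[i][1] for i, frac in inclusions.items()])
    )
    return nem, neg
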