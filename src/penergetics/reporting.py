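"""Publication-style rendering of treatment-comparison tables.

Fixed column order (treatments, then SEM, then P-value), printed rounding
matching trial-report conventions (BW integer; ADG/NE two decimals; G:F
three decimals; percentages two decimals), and superscript letters appended
when the treatment P-value reaches the tendency threshold.  Display
rounding is round-half-even at the stated precision (IEEE/decimal banker's
rounding); full precision is always retained in the CSV outputs, so every
printed value equals the stored value rounded once under this single
policy.
"""

from __future__ import annotations

from collections.abc import Sequence
from decimal import ROUND_HALF_EVEN, Decimal

from .rcbd import RCBDResult

__all__ = ["round_half_even", "format_value", "render_table", "LAYOUT_PRECISION"]

# response → decimal places for each table layout
LAYOUT_PRECISION = {
    "performance": {
        "initial_shrunk_bw_kg": 0,
        "carcass_adjusted_final_bw_kg": 0,
        "final_live_bw_kg": 0,
        "adg_kg_d": 2,
        "dmi_kg_d": 2,
        "gf": 3,
        "nem_mcal_kg": 2,
        "neg_mcal_kg": 2,
        "obs_exp_nem": 2,
        "obs_exp_neg": 2,
    },
    "energetics": {
        "nem_mcal_kg": 2,
        "neg_mcal_kg": 2,
        "obs_exp_nem": 2,
        "obs_exp_neg": 2,
    },
    "carcass": {
        "dressing_pct": 2,
        "hcw_kg": 0,
        "rea_cm2": 2,
        "rf_cm": 2,
        "marbling": 0,
        "kph_pct": 2,
        "calc_yield_grade": 2,
        "retail_yield_pct": 2,
        "ebf_pct": 2,
        "afbw_kg": 0,
    },
    "grades": {},  # all percentages, 2 dp
}
DEFAULT_PRECISION = 2
SEM_PRECISION = 3
P_PRECISION = 2


def round_half_even(value: float, ndigits: int) -> float:
    """Round a float at its shortest decimal representation, half to even.

    ``Decimal(repr(value))`` deliberately rounds the value a human would
    read (1.435 -> 1.44), not the underlying binary expansion.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_EVEN))


def format_value(value: float, ndigits: int) -> str:
    if value != value:  # NaN
        return "-"
    return f"{round_half_even(value, ndigits):.{ndigits}f}"


def render_table(
    results: Sequence[RCBDResult],
    layout: str,
    treatments: Sequence[str] | None = None,
) -> str:
    """Render RCBD results as a fixed-width text table.

    One row per response, columns in order: response label, one column per
    treatment, SEM, P-value.  Superscript letters (``^a``, ``^ab`` …) are
    appended to means when the result carries letter groups.
    """
    if layout not in LAYOUT_PRECISION:
        raise ValueError(f"unknown layout {layout!r}")
    precision = LAYOUT_PRECISION[layout]
    if not results:
        header_trts = list(treatments or [])
        return "  ".join(["Item"] + header_trts + ["SEM", "P-value"])
    if treatments is None:
        treatments = list(results[0].ls_means)

    header = ["Item"] + list(treatments) + ["SEM", "P-value"]
    rows = [header]
    for res in results:
        ndigits = precision.get(res.response, DEFAULT_PRECISION)
        cells = [res.response]
        for trt in treatments:
            if trt not in res.ls_means:
                cells.append("-")
                continue
            text = format_value(res.ls_means[trt], ndigits)
            letters = res.letter_groups.get(trt, "")
            if letters:
                text += "^" + letters
            cells.append(text)
        cells.append(format_value(res.sem, SEM_PRECISION))
        cells.append(format_value(res.p_value, P_PRECISION))
        rows.append(cells)

    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    lines = []
    for r in rows:
        lines.append(
            "  ".join(
                cell.ljust(widths[i]) if i == 0 else cell.rjust(widths[i])
                for i, cell in enumerate(r)
            )
        )
    return "\n".join(lines)
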