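"""Reference-intake exceedance and availability statistics.

The UK adult daily reference intakes are 2000 kcal energy, 70 g total fat,
20 g saturated fat, 260 g carbohydrate, 90 g total sugars and 6 g salt.
The per-meal recommendation for energy is 600 kcal for a main meal; for the
other nutrients the per-meal threshold is set at 30% of the daily reference
intake (proportional to the energy recommendation, with which it coincides
at the defaults: 600 = 0.30 x 2000).

A menu item *exceeds* a threshold when its value is strictly greater than
it — the recommendations are phrased "no more than"/"less than", so equality
does not exceed.  Items missing a nutrient are excluded from that
nutrient's denominator.  Pooled summaries count each wave-item record once
per wave it appears in, so pooled denominators are sums over the per-wave
counts.  Protein and fiber carry no reference values and therefore get
availability statistics only.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, fields as dc_fields
from typing import Mapping

import pandas as pd

from .standardize import NUTRIENT_COLUMNS

#: Nutrients with reference values and therefore exceedance thresholds.
THRESHOLDED_NUTRIENTS = ("energy", "fat", "saturated_fat", "carbohydrate", "sugar", "salt")
#: Nutrients reported in item-level availability (Table-style summary).
AVAILABILITY_NUTRIENTS = ("fat", "saturated_fat", "carbohydrate", "sugar", "protein", "salt", "fiber")

MEAL_FRACTION_OF_DAILY = 0.30


class ThresholdConfigurationError(KeyError):
    """Unknown nutrient requested from the reference-intake configuration."""


@dataclass(frozen=True)
class ReferenceIntakes:
    """UK adult daily reference intakes (configurable)."""

    energy: float = 2000.0  # kcal
    fat: float = 70.0  # g
    saturated_fat: float = 20.0  # g
    carbohydrate: float = 260.0  # g
    sugar: float = 90.0  # g
    salt: float = 6.0  # g

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"reference intake {f.name} must be positive")

    def daily(self, nutrient: str) -> float:
        try:
            return getattr(self, nutrient)
        except AttributeError:
            raise ThresholdConfigurationError(nutrient) from None


@dataclass(frozen=True)
class MealThresholds:
    """Per-meal thresholds: 600 kcal for energy, 30% of daily for nutrients."""

    energy: float = 600.0
    fat: float = MEAL_FRACTION_OF_DAILY * 70.0
    saturated_fat: float = MEAL_FRACTION_OF_DAILY * 20.0
    carbohydrate: float = MEAL_FRACTION_OF_DAILY * 260.0
    sugar: float = MEAL_FRACTION_OF_DAILY * 90.0
    salt: float = MEAL_FRACTION_OF_DAILY * 6.0

    @classmethod
    def from_intakes(
        cls, intakes: ReferenceIntakes, energy_meal_kcal: float = 600.0
    ) -> "MealThresholds":
        # The energy threshold is the configured per-meal recommendation,
        # not 30% of daily energy (the two coincide at the defaults).
        return cls(
            energy=energy_meal_kcal,
            **{
                n: MEAL_FRACTION_OF_DAILY * intakes.daily(n)
                for n in THRESHOLDED_NUTRIENTS
                if n != "energy"
            },
        )

    def meal(self, nutrient: str) -> float:
        try:
            return getattr(self, nutrient)
        except AttributeError:
            raise ThresholdConfigurationError(nutrient) from None


def per_meal_threshold(
    nutrient: str, intakes: ReferenceIntakes, energy_meal_kcal: float = 600.0
) -> float:
    """Per-meal threshold for one nutrient (600 kcal or 30% of daily)."""
    if nutrient == "energy":
        return energy_meal_kcal
    return MEAL_FRACTION_OF_DAILY * intakes.daily(nutrient)


def format_percent(numerator: int, denominator: int) -> float | None:
    """``100 * n/d`` rounded half-away-from-zero to one decimal.

    Returns ``None`` (not assessable) for a zero denominator.
    """
    if denominator == 0:
        return None
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    quotient = decimal.Decimal(100 * numerator) / decimal.Decimal(denominator)
    return float(quotient.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))


def flag_items(
    master: pd.DataFrame,
    intakes: ReferenceIntakes | None = None,
    thresholds: MealThresholds | None = None,
) -> pd.DataFrame:
    """Attach per-nutrient assessability and exceedance flags to a master.

    For each thresholded nutrient three boolean columns are added:
    ``assessable_<n>`` (value non-missing), ``exceeds_meal_<n>`` and
    ``exceeds_daily_<n>`` (strict comparisons; missing values assert
    neither).  Daily exceedance implies meal exceedance since every daily
    intake is above its meal threshold.
    """
    intakes = intakes or ReferenceIntakes()
    thresholds = thresholds or MealThresholds.from_intakes(intakes)
    out = master.copy()
    for nutrient in THRESHOLDED_NUTRIENTS:
        values = out[NUTRIENT_COLUMNS[nutrient]]
        assessable = values.notna()
        out[f"assessable_{nutrient}"] = assessable
        out[f"exceeds_meal_{nutrient}"] = assessable & (values > thresholds.meal(nutrient))
        out[f"exceeds_daily_{nutrient}"] = assessable & (values > intakes.daily(nutrient))
    return out


def summarize_exceedance(flagged: pd.DataFrame, stratum: str) -> pd.DataFrame:
    """Per-nutrient exceedance counts and formatted percentages.

    ``stratum`` labels the summary (a wave label, or a pooled label for the
    concatenation of all wave masters, in which case each wave-item record
    counts once per wave).  Zero denominators yield null percentages rather
    than a division error.
    """
    rows = []
    for nutrient in THRESHOLDED_NUTRIENTS:
        denominator = int(flagged[f"assessable_{nutrient}"].sum())
        n_meal = int(flagged[f"exceeds_meal_{nutrient}"].sum())
        n_daily = int(flagged[f"exceeds_daily_{nutrient}"].sum())
        rows.append(
            {
                "stratum": stratum,
                "nutrient": nutrient,
                "denominator": denominator,
                "n_exceed_meal": n_meal,
                "pct_meal": format_percent(n_meal, denominator) if denominator else None,
                "n_exceed_daily": n_daily,
                "pct_daily": format_percent(n_daily, denominator) if denominator else None,
            }
        )
    return pd.DataFrame(rows)


def availability_summary(masters: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Item-level availability per wave.

    For each wave: number of chains, of menu items and of items providing
    energy; then, per nutrient and for serving weight, the count and the
    percentage among energy-reporting items.  Serving-weight counts include
    weights derived from nutrient density (stated or derived provenance).
    """
    rows = []
    for wave, master in masters.items():
        with_energy = master[master["energy_kcal"].notna()]
        n_energy = len(with_energy)
        row = {
            "wave": wave,
            "n_chains": int(master["chain"].nunique()),
            "n_menu_items": len(master),
            "n_energy": n_energy,
        }
        for nutrient in AVAILABILITY_NUTRIENTS:
            n = int(with_energy[NUTRIENT_COLUMNS[nutrient]].notna().sum())
            row[f"n_{nutrient}"] = n
            row[f"pct_{nutrient}"] = format_percent(n, n_energy) if n_energy else None
        n_weight = int(with_energy["serving_weight_g"].notna().sum())
        row["n_serving_weight"] = n_weight
        row["pct_serving_weight"] = format_percent(n_weight, n_energy) if n_energy else None
        rows.append(row)
    return pd.DataFrame(rows)


def plot_exceedance(summary: pd.DataFrame, path: str) -> None:
    """Bar chart of per-meal and daily exceedance proportions per nutrient."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    x = range(len(summary))
    ax.bar([i - 0.2 for i in x], summary["pct_meal"], width=0.4, label="> per-meal recommendation")
    ax.bar([i + 0.2 for i in x], summary["pct_daily"], width=0.4, label="> daily reference intake")
    ax.set_xticks(list(x))
    ax.set_xticklabels(summary["nutrient"].str.replace("_", " "), rotation=20)
    ax.set_ylabel("% of menu items")
    ax.set_title(f"Menu items exceeding intake recommendations ({summary['stratum'].iloc[0]})")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
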