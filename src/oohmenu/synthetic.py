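"""Synthetic multi-chain, multi-wave menu nutrition data with ground truth.

Online menu nutrition tables are heterogeneous: every chain publishes in
its own "dialect" — synonym headers, per-serving and/or per-100g panels,
kcal or kJ energy, operator-laden trace values ("<0.05"), dash-or-blank
missing markers, and pizza items published per slice in several sizes.
This module emulates that heterogeneity with a generator whose ground truth
is known exactly, so that every downstream stage (standardization,
inclusion filtering, exceedance analysis) can be tested end to end without
any scraped data.

Design notes
------------
* Nutrient values are lognormal.  For each nutrient carrying reference
  values both distribution parameters are solved so that the probability of
  exceeding the per-meal threshold and the daily reference intake equal the
  configured targets — a closed form, since both conditions are quantile
  constraints on the same lognormal.
* Ground-truth values are the values a menu would print: grams rounded to
  one decimal, energy to whole kcal.  Values falling inside a small guard
  band around a threshold are nudged to the boundary of the band (on their
  original side, so target probabilities are preserved exactly); the band
  exceeds the worst-case harmonization rounding error, which makes
  pipeline exceedance flags provably equal to ground-truth flags.
* Pizza ground truth is defined as ``3 x the printed per-slice value``
  (or the printed whole-pizza value for individual sizes), so portion
  normalization is exact by construction.
* Each chain keeps one dialect across all waves, mirroring the observation
  that a chain publishes in a single format.
* Item identifiers embed chain, wave and index, so ground truth joins to
  pipeline output without any record-linkage machinery.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from statistics import NormalDist
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .analysis import MealThresholds, ReferenceIntakes, THRESHOLDED_NUTRIENTS
from .filters import BusinessMeta
from .standardize import NUTRIENT_KEYS, RawMenuRecord

KCAL_PER_KJ = 4.184

#: Decimal places of emitted raw strings (the generator's declared rounding).
ROUNDING = {
    "energy": 0,  # kcal and kJ printed as integers
    "grams": 1,
    "per100_energy": 1,
    "per100_grams": 2,
    "weight": 1,
}

#: Declared recovery tolerances implied by the rounding rules: harmonized
#: values agree with ground truth within these bounds on every emission path.
TOLERANCES = {
    "energy": 2.0,  # kcal
    "grams": 0.3,  # g
    "weight_stated": 0.5,  # g
    "weight_derived_rel": 0.06,  # relative, when derived from nutrient density
}

# Guard band around each exceedance threshold: ground-truth values are kept
# at least (band + tick) away from every threshold so that recovery error
# (< band on all paths) can never flip an exceedance flag.
_GUARD_BAND = {"energy": 2.0, "grams": 0.3}
_GUARD_TICK = {"energy": 1.0, "grams": 0.1}

_GRAM_NUTRIENTS = tuple(n for n in NUTRIENT_KEYS if n != "energy")

_CITIES = [
    "Manchester",
    "Birmingham",
    "Leeds",
    "Glasgow",
    "Bristol",
    "Liverpool",
    "Sheffield",
    "Cardiff",
    "Newcastle",
]
_LONDON = ["London Soho", "London Bank", "London Camden"]
_SECTIONS = ["Mains", "Burgers", "Sides", "Desserts", "Drinks", "Salads", "Breakfast"]
_SIC_CODES = ["56.10", "56.21", "56.30", "47.11", "55.10", "91.03"]


class GenerationError(RuntimeError):
    """An item cannot be emitted under the requested dialect."""


# --------------------------------------------------------------------------
# Dialects
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Dialect:
    """One source publication format.

    ``headers`` maps canonical per-serving fields (and metadata fields) to
    the header text this dialect prints; every canonical field maps to at
    most one header.  ``basis`` is the value panel emitted: per-serving
    only, per-100g only, or both.
    """

    name: str
    basis: str  # "serving" | "per100" | "both"
    energy_unit: str  # "kcal" | "kj" | "both"
    missing_marker: str
    headers: Mapping[str, str]
    per100_headers: Mapping[str, str] | None = None
    weight_header: str | None = None
    thousands: bool = False

    def __post_init__(self) -> None:
        if self.basis not in ("serving", "per100", "both"):
            raise ValueError(f"unknown dialect basis {self.basis!r}")
        if self.basis in ("per100", "both") and not self.per100_headers:
            raise ValueError("per-100g basis requires per100_headers")
        if self.basis == "per100" and self.weight_header is None:
            raise ValueError("per-100g-only dialect must state a serving weight")


_CLASSIC_META = {"item_id": "Item ID", "item_name": "Item Name", "menu_section": "Menu Section"}
_CLASSIC_HEADERS = {
    **_CLASSIC_META,
    "energy_kcal": "Energy (kcal)",
    "energy_kj": "Energy (kJ)",
    "fat": "Fat (g)",
    "saturated_fat": "Saturated Fat (g)",
    "carbohydrate": "Carbohydrates (g)",
    "sugar": "Sugars (g)",
    "protein": "Protein (g)",
    "salt": "Salt (g)",
    "fiber": "Fibre (g)",
}
_PER100_HEADERS = {
    "energy_kcal": "Energy (kcal) per 100g",
    "fat": "Fat per 100g",
    "saturated_fat": "Saturated Fat per 100g",
    "carbohydrate": "Carbohydrates per 100g",
    "sugar": "Sugars per 100g",
    "protein": "Protein per 100g",
    "salt": "Salt per 100g",
    "fiber": "Fibre per 100g",
}

DIALECTS: dict[str, Dialect] = {
    "classic": Dialect(
        name="classic",
        basis="serving",
        energy_unit="kcal",
        missing_marker="-",
        headers=_CLASSIC_HEADERS,
        weight_header="Serving Weight (g)",
        thousands=True,
    ),
    "terse": Dialect(
        name="terse",
        basis="serving",
        energy_unit="kcal",
        missing_marker="",
        headers={
            "item_id": "item id",
            "item_name": "item",
            "menu_section": "section",
            "energy_kcal": "kcal",
            "energy_kj": "kJ",
            "fat": "fat",
            "saturated_fat": "sat fat",
            "carbohydrate": "carbs",
            "sugar": "sugar content",
            "protein": "protein",
            "salt": "salt",
            "fiber": "fiber",
        },
        weight_header="weight",
    ),
    "dual": Dialect(
        name="dual",
        basis="both",
        energy_unit="both",
        missing_marker="-",
        headers=_CLASSIC_HEADERS,
        per100_headers=_PER100_HEADERS,
        weight_header="Serving Weight (g)",
    ),
    "density": Dialect(
        name="density",
        basis="per100",
        energy_unit="kcal",
        missing_marker="",
        headers=dict(_CLASSIC_META),
        per100_headers=_PER100_HEADERS,
        weight_header="Serving Size (g)",
    ),
}


def kj_variant(dialect: Dialect) -> Dialect:
    """The same dialect reporting energy in kJ only."""
    return replace(dialect, name=dialect.name + "_kj", energy_unit="kj")


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

_DEFAULT_WAVES = ["2021-03-01", "2021-06-01", "2021-09-01", "2021-12-01"]


class GeneratorConfig(BaseModel):
    """Study conditions for the synthetic dataset.

    Defaults emulate one year of quarterly collection from the large UK
    out-of-home chains that publish nutrition information online: 85 chains
    with data across four 2021 waves, drawn from a frame of 1043 large
    businesses of which 256 publish online (196 of those as franchisees,
    3 retained because their franchisor is uncaptured) plus 3 chains added
    from the top-100 sales frame.  Per-meal / daily exceedance targets and
    field missingness rates default to the proportions observed in that
    population.
    """

    n_chains: int = Field(default=85, gt=0)
    waves: list[str] = Field(default_factory=lambda: list(_DEFAULT_WAVES))
    items_per_chain: tuple[int, int] = (150, 300)
    dialect_mix: dict[str, float] = Field(
        default_factory=lambda: {"classic": 0.45, "terse": 0.35, "dual": 0.12, "density": 0.08}
    )
    target_exceedance: dict[str, float] = Field(
        default_factory=lambda: {
            "energy": 0.247,
            "fat": 0.347,
            "saturated_fat": 0.464,
            "carbohydrate": 0.176,
            "sugar": 0.178,
            "salt": 0.352,
        }
    )
    target_daily_exceedance: dict[str, float] = Field(
        default_factory=lambda: {
            "energy": 0.007,
            "fat": 0.036,
            "saturated_fat": 0.071,
            "carbohydrate": 0.001,
            "sugar": 0.004,
            "salt": 0.042,
        }
    )
    missingness: dict[str, float] = Field(
        default_factory=lambda: {
            "energy": 0.13,
            "fat": 0.04,
            "saturated_fat": 0.04,
            "carbohydrate": 0.035,
            "sugar": 0.035,
            "protein": 0.045,
            "salt": 0.035,
            "fiber": 0.49,
            "serving_weight": 0.75,
        }
    )
    operator_rate: float = Field(default=0.02, ge=0.0, le=1.0)
    pizza_chain_fraction: float = Field(default=0.04, ge=0.0, le=1.0)
    kj_only_rate: float = Field(default=0.10, ge=0.0, le=1.0)
    stale_chain_count: int = Field(default=1, ge=0)
    n_businesses: int = Field(default=1043, gt=0)
    n_online: int = Field(default=256, gt=0)
    n_franchisee_online: int = Field(default=196, ge=0)
    n_franchise_included: int = Field(default=3, ge=0)
    n_supplementary: int = Field(default=3, ge=0)
    seed: int = 0

    @field_validator("items_per_chain")
    @classmethod
    def _check_range(cls, v: tuple[int, int]) -> tuple[int, int]:
        lo, hi = v
        if lo <= 0 or hi < lo:
            raise ValueError("items_per_chain must be a positive (low, high) range")
        return v

    @field_validator("dialect_mix")
    @classmethod
    def _check_mix(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = sorted(set(v) - set(DIALECTS))
        if unknown:
            raise ValueError(f"dialect_mix names unknown dialects: {unknown}")
        if any(not 0.0 <= p <= 1.0 for p in v.values()):
            raise ValueError("dialect_mix proportions must lie in [0, 1]")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("dialect_mix proportions must sum to 1")
        return v

    @field_validator("target_exceedance", "target_daily_exceedance", "missingness")
    @classmethod
    def _check_probs(cls, v: dict[str, float]) -> dict[str, float]:
        if any(not 0.0 <= p <= 1.0 for p in v.values()):
            raise ValueError("probabilities must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _check_structure(self) -> "GeneratorConfig":
        missing = sorted(set(THRESHOLDED_NUTRIENTS) - set(self.target_exceedance))
        if missing:
            raise ValueError(f"target_exceedance lacks nutrients: {missing}")
        for n, p_meal in self.target_exceedance.items():
            p_daily = self.target_daily_exceedance.get(n, 0.0)
            if 0.0 < p_meal < 1.0 and p_daily >= p_meal:
                raise ValueError(
                    f"target_daily_exceedance[{n}] must be below target_exceedance[{n}]"
                )
        if self.n_online > self.n_businesses:
            raise ValueError("n_online cannot exceed n_businesses")
        if self.n_franchisee_online >= self.n_online:
            raise ValueError("n_franchisee_online must leave at least one direct business")
        if self.n_franchise_included > self.n_franchisee_online:
            raise ValueError("n_franchise_included cannot exceed n_franchisee_online")
        n_main = self.n_chains - self.n_supplementary - self.n_franchise_included
        n_direct = self.n_online - self.n_franchisee_online - self.stale_chain_count
        if n_direct < 1:
            raise ValueError("n_online must leave at least one directly-reporting business")
        if n_main < n_direct:
            raise ValueError(
                "n_chains too small: every directly-reporting business carries at least one chain"
            )
        return self

    @classmethod
    def small(cls, n_chains: int = 8, **overrides) -> "GeneratorConfig":
        """A structurally consistent scaled-down configuration for tests."""
        n_fr_inc = 1 if n_chains >= 4 else 0
        n_supp = 1 if n_chains >= 4 else 0
        n_main = n_chains - n_fr_inc - n_supp
        n_direct = max(1, n_main // 2)
        n_franchisee = n_fr_inc + 2
        n_online = n_direct + n_franchisee
        defaults = dict(
            n_chains=n_chains,
            items_per_chain=(40, 80),
            waves=["2021-03-01", "2021-06-01"],
            n_businesses=n_online + 6,
            n_online=n_online,
            n_franchisee_online=n_franchisee,
            n_franchise_included=n_fr_inc,
            n_supplementary=n_supp,
            stale_chain_count=0,
        )
        defaults.update(overrides)
        return cls(**defaults)


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------


@dataclass
class ItemTruth:
    """Ground truth for one emitted record (values per reporting portion)."""

    item_id: str
    chain: str
    wave: str
    name: str
    section: str
    values: dict[str, float]  # truth per portion; energy in kcal
    reported: dict[str, bool]
    weight: float
    weight_stated: bool
    weight_reported: bool  # stated, or derivable from the emitted panels
    flags: dict[str, tuple[bool, bool]]  # nutrient -> (exceeds_meal, exceeds_daily)
    pizza_size: str = ""
    emit_values: dict[str, float] = field(default_factory=dict)  # as printed (per slice etc.)
    emit_weight: float = 0.0


def lognormal_params(
    t_meal: float, t_daily: float, p_meal: float, p_daily: float, fallback_sigma: float = 0.8
) -> tuple[float, float, str | None]:
    """Lognormal (mu, sigma) hitting both exceedance targets.

    ``P(X > t_meal) = p_meal`` and ``P(X > t_daily) = p_daily`` are quantile
    constraints with the closed-form solution
    ``sigma = (ln t_daily - ln t_meal) / (z_daily - z_meal)``,
    ``mu = ln t_meal - sigma * z_meal`` where ``z = Phi^-1(1 - p)``.
    Degenerate targets (0 or 1) fall back to a fixed spread plus clipping,
    signalled by the third return element.
    """
    if p_meal <= 0.0:
        return math.log(t_meal) - 5 * fallback_sigma, fallback_sigma, "clip_below"
    if p_meal >= 1.0:
        return math.log(t_meal) + 5 * fallback_sigma, fallback_sigma, "clip_above"
    z_meal = NormalDist().inv_cdf(1.0 - p_meal)
    if 0.0 < p_daily < p_meal:
        z_daily = NormalDist().inv_cdf(1.0 - p_daily)
        sigma = (math.log(t_daily) - math.log(t_meal)) / (z_daily - z_meal)
    else:
        sigma = fallback_sigma
    return math.log(t_meal) - sigma * z_meal, sigma, None


def _round(value: float, decimals: int) -> float:
    return float(round(value, decimals)) if decimals else float(round(value))


def _nudge(rounded: float, raw: float, threshold: float, band: float, tick: float, decimals: int) -> float:
    """Push a printed value out of the threshold guard band, keeping the side
    of the threshold that the unrounded value was on."""
    if abs(rounded - threshold) <= band:
        target = threshold + band + tick if raw > threshold else threshold - band - tick
        return _round(target, decimals)
    return rounded


def _truth_value(
    raw: float, nutrient: str, clip: str | None, thresholds: MealThresholds, intakes: ReferenceIntakes
) -> float:
    decimals = ROUNDING["energy"] if nutrient == "energy" else ROUNDING["grams"]
    kind = "energy" if nutrient == "energy" else "grams"
    band, tick = _GUARD_BAND[kind], _GUARD_TICK[kind]
    t_meal, t_daily = thresholds.meal(nutrient), intakes.daily(nutrient)
    if clip == "clip_below":
        raw = min(raw, t_meal - band - tick)
    elif clip == "clip_above":
        raw = max(raw, t_meal + band + tick)
    value = _round(raw, decimals)
    value = _nudge(value, raw, t_meal, band, tick, decimals)
    value = _nudge(value, raw, t_daily, band, tick, decimals)
    return value


# --------------------------------------------------------------------------
# Emission
# --------------------------------------------------------------------------


def _fmt(value: float, decimals: int, thousands: bool = False) -> str:
    if thousands:
        return f"{value:,.{decimals}f}"
    return f"{value:.{decimals}f}"


def _per100(value: float, weight: float, nutrient: str) -> float:
    decimals = ROUNDING["per100_energy"] if nutrient == "energy" else ROUNDING["per100_grams"]
    return _round(100.0 * value / weight, decimals)


def apply_dialect(
    truth: ItemTruth,
    dialect: Dialect,
    operator_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> RawMenuRecord:
    """Emit one raw record for an item under a dialect.

    Per-100g values equal ``100 x per-serving value / true serving weight``
    before rounding; kJ values equal ``kcal x 4.184`` before rounding.
    Missing fields and operator-wrapped trace values follow the dialect's
    conventions.  A per-100g-only dialect requires a stated serving weight.
    """
    if dialect.basis == "per100" and not truth.weight_stated:
        raise GenerationError(
            f"item {truth.item_id}: dialect {dialect.name!r} requires a stated serving weight"
        )
    rng = rng or np.random.default_rng(0)
    marker = dialect.missing_marker
    emit = truth.emit_values or truth.values
    fields: dict[str, str] = {
        dialect.headers["item_id"]: truth.item_id,
        dialect.headers["item_name"]: truth.name,
        dialect.headers["menu_section"]: truth.section,
    }

    if dialect.basis in ("serving", "both"):
        energy = emit["energy"]
        if dialect.energy_unit in ("kcal", "both"):
            fields[dialect.headers["energy_kcal"]] = (
                _fmt(energy, ROUNDING["energy"], dialect.thousands)
                if truth.reported["energy"]
                else marker
            )
        if dialect.energy_unit in ("kj", "both"):
            kj = round(energy * KCAL_PER_KJ)
            fields[dialect.headers["energy_kj"]] = (
                _fmt(kj, ROUNDING["energy"], dialect.thousands)
                if truth.reported["energy"]
                else marker
            )
        for nutrient in _GRAM_NUTRIENTS:
            header = dialect.headers[nutrient]
            if not truth.reported[nutrient]:
                fields[header] = marker
                continue
            text = _fmt(emit[nutrient], ROUNDING["grams"])
            if emit[nutrient] <= 1.0 and rng.random() < operator_rate:
                text = "<" + text
            fields[header] = text

    if dialect.weight_header is not None:
        fields[dialect.weight_header] = (
            _fmt(truth.emit_weight or truth.weight, ROUNDING["weight"])
            if truth.weight_stated
            else marker
        )

    if dialect.basis in ("per100", "both"):
        # Density panel always refers to the item as served (portion values
        # over the true portion weight), never to the per-slice emission.
        for nutrient in NUTRIENT_KEYS:
            header = (
                dialect.per100_headers["energy_kcal"]
                if nutrient == "energy"
                else dialect.per100_headers[nutrient]
            )
            if not truth.reported[nutrient]:
                fields[header] = marker
            else:
                fields[header] = _fmt(
                    _per100(truth.values[nutrient], truth.weight, nutrient),
                    ROUNDING["per100_energy"] if nutrient == "energy" else ROUNDING["per100_grams"],
                )

    return RawMenuRecord(chain=truth.chain, wave=truth.wave, fields=fields, dialect=dialect.name)


def _derivable_weight(truth: ItemTruth) -> bool:
    # Mirrors the serving-weight derivation contract: a usable candidate
    # needs a reported nutrient with per-serving value >= 2 and a positive
    # printed density value.
    for nutrient in NUTRIENT_KEYS:
        if not truth.reported[nutrient]:
            continue
        value = truth.values[nutrient]
        if value >= 2.0 and _per100(value, truth.weight, nutrient) > 0:
            return True
    return False


# --------------------------------------------------------------------------
# Chains and businesses
# --------------------------------------------------------------------------


@dataclass
class ChainMeta:
    name: str
    business: str
    dialect: str
    is_pizza: bool
    locations: list[str]
    menus: list[tuple[str, str]]
    last_updated: str | None


def _chain_extras(rng: np.random.Generator, wave0: str) -> tuple[list[str], list[tuple[str, str]], str | None]:
    n_loc = int(rng.integers(1, 4))
    locations = [str(c) for c in rng.choice(_CITIES, size=n_loc, replace=False)]
    if rng.random() < 0.6:
        locations.insert(int(rng.integers(0, len(locations) + 1)), str(rng.choice(_LONDON)))
    menus: list[tuple[str, str]] = [("Core Menu", "main")]
    if rng.random() < 0.4:
        menus.append(("Kids Menu", "children"))
    if rng.random() < 0.3:
        menus.append(("Seasonal Specials", "promotional"))
    if rng.random() < 0.3:
        menus.append(("Delivery Menu", "delivery"))
    if rng.random() < 0.2:
        last_updated = None
    else:
        # Updated some time in the two years before the first wave.
        updated = date.fromisoformat(wave0) - timedelta(days=int(rng.integers(1, 731)))
        last_updated = updated.isoformat()
    return locations, menus, last_updated


def _build_frame(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[list[BusinessMeta], list[ChainMeta]]:
    """Businesses (included and excluded) and the chains that carry data."""
    wave0 = config.waves[0]
    n_main = config.n_chains - config.n_supplementary - config.n_franchise_included
    # Stale chains are extra online businesses on top of n_chains: they are
    # dropped at the document-validity stage, so the analyzed chain count
    # still equals n_chains.
    n_direct = config.n_online - config.n_franchisee_online - config.stale_chain_count

    main_chain_names = [f"Chain {i:03d}" for i in range(1, n_main + 1)]
    # Distribute main chains over directly-reporting businesses, round robin
    # so some businesses own several brands.
    per_business: list[list[str]] = [[] for _ in range(n_direct)]
    for i, chain in enumerate(main_chain_names):
        per_business[i % n_direct].append(chain)

    businesses: list[BusinessMeta] = []
    chains: list[ChainMeta] = []

    def employees() -> int:
        return 250 + int(rng.lognormal(math.log(400.0), 1.2))

    for j, owned in enumerate(per_business):
        name = f"Business {j + 1:04d}"
        online = {c: True for c in owned}
        if j == 0 and len(owned) > 1:
            # One brand of the first multi-chain business never published
            # nutrition information online.
            online[owned[0] + " Cafe"] = False
            owned = owned + [owned[0] + " Cafe"]
        businesses.append(
            BusinessMeta(
                name=name,
                employee_count=employees(),
                sic_code=str(rng.choice(_SIC_CODES)),
                chains=list(owned),
                provides_nutrition_online=online,
            )
        )

    # Franchise operators with online information: a few franchise chains
    # whose franchisor is not otherwise captured are retained.
    for j in range(config.n_franchisee_online):
        included = j < config.n_franchise_included
        chain = f"Chain F{j + 1:02d}"
        franchisor = f"Uncaptured Franchisor {j + 1}" if included else str(rng.choice(main_chain_names))
        businesses.append(
            BusinessMeta(
                name=f"Franchise Business {j + 1:03d}",
                employee_count=employees(),
                sic_code=str(rng.choice(_SIC_CODES)),
                chains=[chain],
                provides_nutrition_online={chain: True},
                franchisee_of=franchisor,
            )
        )

    # The remainder of the >=250-employee frame never published online.
    n_offline = config.n_businesses - config.n_online
    for j in range(n_offline):
        name = f"Offline Business {j + 1:04d}"
        businesses.append(
            BusinessMeta(
                name=name,
                employee_count=employees(),
                sic_code=str(rng.choice(_SIC_CODES)),
                chains=[name],
                provides_nutrition_online={name: False},
            )
        )

    # Supplementary top-100 sales frame (below the employee threshold).
    ranks = sorted(rng.choice(np.arange(1, 101), size=config.n_supplementary, replace=False))
    for j in range(config.n_supplementary):
        chain = f"Chain S{j + 1:02d}"
        businesses.append(
            BusinessMeta(
                name=f"Supplementary Business {j + 1:02d}",
                employee_count=int(rng.integers(20, 250)),
                sic_code=str(rng.choice(_SIC_CODES)),
                chains=[chain],
                provides_nutrition_online={chain: True},
                sales_rank=int(ranks[j]),
            )
        )

    # Chains with a stale nutrition document (dropped at the document stage).
    stale_chain_names = [f"Chain Z{j + 1:02d}" for j in range(config.stale_chain_count)]
    for j, chain in enumerate(stale_chain_names):
        businesses.append(
            BusinessMeta(
                name=f"Stale Business {j + 1:02d}",
                employee_count=employees(),
                sic_code=str(rng.choice(_SIC_CODES)),
                chains=[chain],
                provides_nutrition_online={chain: True},
            )
        )

    data_chain_names = (
        main_chain_names
        + [f"Chain F{j + 1:02d}" for j in range(config.n_franchise_included)]
        + [f"Chain S{j + 1:02d}" for j in range(config.n_supplementary)]
        + stale_chain_names
    )
    business_of = {c: b.name for b in businesses for c in b.chains}

    mix_names = sorted(config.dialect_mix)
    mix_probs = np.array([config.dialect_mix[k] for k in mix_names])
    n_pizza = int(round(config.pizza_chain_fraction * config.n_chains))
    pizza_set = set(
        str(c) for c in rng.choice(main_chain_names, size=min(n_pizza, n_main), replace=False)
    )

    for chain in data_chain_names:
        locations, menus, last_updated = _chain_extras(rng, wave0)
        if chain in pizza_set:
            # Pizza chains publish per-slice kcal tables (one fixed format).
            dialect = "classic"
        else:
            dialect = str(rng.choice(mix_names, p=mix_probs))
            if dialect in ("classic", "terse") and rng.random() < config.kj_only_rate:
                dialect += "_kj"
        if chain in stale_chain_names:
            year0 = int(wave0[:4])
            last_updated = f"{year0 - 4}-06-15"
        chains.append(
            ChainMeta(
                name=chain,
                business=business_of[chain],
                dialect=dialect,
                is_pizza=chain in pizza_set,
                locations=locations,
                menus=menus,
                last_updated=last_updated,
            )
        )
    return businesses, chains


def resolve_dialect(name: str) -> Dialect:
    if name.endswith("_kj"):
        return kj_variant(DIALECTS[name[: -len("_kj")]])
    return DIALECTS[name]


# --------------------------------------------------------------------------
# Item generation
# --------------------------------------------------------------------------

_PROTEIN_PARAMS = (math.log(18.0), 0.7)
_FIBER_PARAMS = (math.log(3.0), 0.9)
_WEIGHT_PARAMS = (math.log(300.0), 0.45)
_WEIGHT_CLIP = (80.0, 1000.0)
_PIZZA_ITEM_FRACTION = 0.6
_PIZZA_SIZES = ("Individual", "Medium", "Large")


def _nutrient_params(config: GeneratorConfig, thresholds: MealThresholds, intakes: ReferenceIntakes):
    params = {}
    for nutrient in THRESHOLDED_NUTRIENTS:
        params[nutrient] = lognormal_params(
            thresholds.meal(nutrient),
            intakes.daily(nutrient),
            config.target_exceedance[nutrient],
            config.target_daily_exceedance.get(nutrient, 0.0),
        )
    return params


def _flags(values: dict[str, float], thresholds: MealThresholds, intakes: ReferenceIntakes):
    return {
        n: (values[n] > thresholds.meal(n), values[n] > intakes.daily(n))
        for n in THRESHOLDED_NUTRIENTS
    }


def _chain_wave_items(
    chain: ChainMeta,
    wave: str,
    rng: np.random.Generator,
    config: GeneratorConfig,
    params,
    thresholds: MealThresholds,
    intakes: ReferenceIntakes,
) -> list[ItemTruth]:
    lo, hi = config.items_per_chain
    n = int(rng.integers(lo, hi + 1))
    dialect = resolve_dialect(chain.dialect)
    slug = chain.name.replace(" ", "-").lower()
    miss = config.missingness

    n_flavors = int(round(_PIZZA_ITEM_FRACTION * n / len(_PIZZA_SIZES))) if chain.is_pizza else 0
    n_plain = n - n_flavors * len(_PIZZA_SIZES)

    items: list[ItemTruth] = []

    def reported_flags() -> dict[str, bool]:
        # An item that gives no calorie information gives nothing else
        # either, so nutrient missingness is conditional on energy being
        # reported (availability shares are quoted on the energy base).
        flags = {k: bool(rng.random() >= miss.get(k, 0.0)) for k in NUTRIENT_KEYS}
        if not flags["energy"]:
            flags = {k: False for k in NUTRIENT_KEYS}
        return flags

    def draw_values() -> dict[str, float]:
        raw = {}
        for nutrient in THRESHOLDED_NUTRIENTS:
            mu, sigma, _clip = params[nutrient]
            raw[nutrient] = float(rng.lognormal(mu, sigma))
        raw["protein"] = float(rng.lognormal(*_PROTEIN_PARAMS))
        raw["fiber"] = float(rng.lognormal(*_FIBER_PARAMS))
        return raw

    index = 0
    for _ in range(n_plain):
        index += 1
        raw = draw_values()
        values = {
            n_: _truth_value(raw[n_], n_, params[n_][2], thresholds, intakes)
            for n_ in THRESHOLDED_NUTRIENTS
        }
        values["protein"] = _round(raw["protein"], ROUNDING["grams"])
        values["fiber"] = _round(raw["fiber"], ROUNDING["grams"])
        weight = _round(
            float(np.clip(rng.lognormal(*_WEIGHT_PARAMS), *_WEIGHT_CLIP)), ROUNDING["weight"]
        )
        reported = reported_flags()
        weight_stated = dialect.basis == "per100" or bool(
            rng.random() >= miss.get("serving_weight", 0.0)
        )
        truth = ItemTruth(
            item_id=f"{slug}|{wave}|{index:05d}",
            chain=chain.name,
            wave=wave,
            name=f"Item {index:04d}",
            section=str(rng.choice(_SECTIONS)),
            values=values,
            reported=reported,
            weight=weight,
            weight_stated=weight_stated,
            weight_reported=False,
            flags=_flags(values, thresholds, intakes),
        )
        truth.weight_reported = truth.weight_stated or (
            dialect.basis == "both" and _derivable_weight(truth)
        )
        items.append(truth)

    for flavor in range(n_flavors):
        for size in _PIZZA_SIZES:
            index += 1
            raw = draw_values()
            emit_values: dict[str, float] = {}
            values: dict[str, float] = {}
            if size in ("Medium", "Large"):
                # Published per slice; truth is the 3-slice portion, exactly
                # 3 x the printed slice value.
                for n_ in THRESHOLDED_NUTRIENTS:
                    mu_clip = params[n_][2]
                    raw_v = raw[n_]
                    if mu_clip == "clip_below":
                        raw_v = min(raw_v, thresholds.meal(n_) - 2 * _GUARD_BAND["grams" if n_ != "energy" else "energy"])
                    decimals = ROUNDING["energy"] if n_ == "energy" else ROUNDING["grams"]
                    slice_v = _round(raw_v / 3.0, decimals)
                    emit_values[n_] = slice_v
                    values[n_] = slice_v * 3.0
                for n_ in ("protein", "fiber"):
                    slice_v = _round(raw[n_] / 3.0, ROUNDING["grams"])
                    emit_values[n_] = slice_v
                    values[n_] = slice_v * 3.0
                whole = _round(
                    float(np.clip(rng.lognormal(math.log(600.0), 0.3), 240.0, 2000.0)) / 3.0,
                    ROUNDING["weight"],
                )
                emit_weight, weight = whole, whole * 3.0
            else:
                for n_ in NUTRIENT_KEYS:
                    decimals = ROUNDING["energy"] if n_ == "energy" else ROUNDING["grams"]
                    v = _round(raw[n_], decimals)
                    if n_ in THRESHOLDED_NUTRIENTS and params[n_][2] == "clip_below":
                        kind = "energy" if n_ == "energy" else "grams"
                        v = min(v, _round(thresholds.meal(n_) - _GUARD_BAND[kind] - _GUARD_TICK[kind], decimals))
                    emit_values[n_] = v
                    values[n_] = v
                weight = _round(
                    float(np.clip(rng.lognormal(math.log(450.0), 0.3), 160.0, 1000.0)),
                    ROUNDING["weight"],
                )
                emit_weight = weight
            reported = reported_flags()
            weight_stated = bool(rng.random() >= miss.get("serving_weight", 0.0))
            truth = ItemTruth(
                item_id=f"{slug}|{wave}|{index:05d}",
                chain=chain.name,
                wave=wave,
                name=f"Pizza {flavor + 1:02d} ({size})",
                section="Pizzas",
                values=values,
                reported=reported,
                weight=weight,
                weight_stated=weight_stated,
                weight_reported=weight_stated,
                flags=_flags(values, thresholds, intakes),
                pizza_size=size.lower(),
                emit_values=emit_values,
                emit_weight=emit_weight,
            )
            items.append(truth)
    return items


# --------------------------------------------------------------------------
# Dataset assembly and persistence
# --------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    records: dict[tuple[str, str], list[RawMenuRecord]]  # (chain, wave) -> records
    truth: pd.DataFrame
    businesses: list[BusinessMeta]
    chains: list[ChainMeta]
    config: GeneratorConfig
    seed: int


def _truth_frame(items: list[ItemTruth]) -> pd.DataFrame:
    rows = []
    for it in items:
        row = {
            "item_id": it.item_id,
            "chain": it.chain,
            "wave": it.wave,
            "pizza_size": it.pizza_size,
            "serving_weight_g": it.weight,
            "weight_reported": it.weight_reported,
        }
        for nutrient in NUTRIENT_KEYS:
            row[f"{nutrient}_value"] = it.values[nutrient]
            row[f"{nutrient}_reported"] = it.reported[nutrient]
        for nutrient in THRESHOLDED_NUTRIENTS:
            meal, daily = it.flags[nutrient]
            row[f"{nutrient}_exceeds_meal"] = meal
            row[f"{nutrient}_exceeds_daily"] = daily
        rows.append(row)
    return pd.DataFrame(rows)


def generate_dataset(
    config: GeneratorConfig,
    seed: int | None = None,
    intakes: ReferenceIntakes | None = None,
    energy_meal_kcal: float = 600.0,
) -> SyntheticDataset:
    """Generate the full synthetic dataset for the configured conditions.

    Identical ``(config, seed)`` pairs reproduce identical datasets; the
    seed defaults to ``config.seed``.
    """
    seed = config.seed if seed is None else int(seed)
    intakes = intakes or ReferenceIntakes()
    thresholds = MealThresholds.from_intakes(intakes, energy_meal_kcal)
    params = _nutrient_params(config, thresholds, intakes)

    frame_rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    businesses, chains = _build_frame(config, frame_rng)

    records: dict[tuple[str, str], list[RawMenuRecord]] = {}
    all_items: list[ItemTruth] = []
    for ci, chain in enumerate(chains):
        dialect = resolve_dialect(chain.dialect)
        for wi, wave in enumerate(config.waves):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 1, ci, wi]))
            items = _chain_wave_items(chain, wave, rng, config, params, thresholds, intakes)
            records[(chain.name, wave)] = [
                apply_dialect(it, dialect, config.operator_rate, rng) for it in items
            ]
            all_items.extend(items)

    return SyntheticDataset(
        records=records,
        truth=_truth_frame(all_items),
        businesses=businesses,
        chains=chains,
        config=config,
        seed=seed,
    )


def _chain_slug(chain: str) -> str:
    return chain.replace(" ", "-").lower()


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write the dataset as delimited text plus manifest; returns the manifest path.

    Layout: one UTF-8 CSV per chain per wave under ``raw/``, the ground
    truth as CSV, chain/business metadata as YAML, and a JSON manifest
    listing every file with its wave label.
    """
    out = Path(out_dir)
    (out / "raw").mkdir(parents=True, exist_ok=True)

    files = []
    for (chain, wave), recs in dataset.records.items():
        path = out / "raw" / f"{_chain_slug(chain)}__{wave}.csv"
        fieldnames = list(recs[0].fields) if recs else []
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fieldnames)
            writer.writeheader()
            for rec in recs:
                writer.writerow(rec.fields)
        files.append(
            {
                "chain": chain,
                "wave": wave,
                "dialect": recs[0].dialect if recs else "",
                "path": str(path.relative_to(out)),
                "n_records": len(recs),
            }
        )

    dataset.truth.to_csv(out / "truth.csv", index=False)

    chain_info = {c.name: c for c in dataset.chains}
    biz_payload = []
    for b in dataset.businesses:
        chains_payload = {}
        for chain in b.chains:
            entry: dict = {"online": bool(b.provides_nutrition_online.get(chain, False))}
            meta = chain_info.get(chain)
            if meta is not None:
                entry.update(
                    dialect=meta.dialect,
                    is_pizza=meta.is_pizza,
                    locations=list(meta.locations),
                    menus=[list(m) for m in meta.menus],
                    last_updated=meta.last_updated,
                )
            chains_payload[chain] = entry
        biz_payload.append(
            {
                "name": b.name,
                "employee_count": b.employee_count,
                "sic_code": b.sic_code,
                "sales_rank": b.sales_rank,
                "franchisee_of": b.franchisee_of,
                "chains": chains_payload,
            }
        )
    with open(out / "businesses.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(biz_payload, fh, sort_keys=False, allow_unicode=True)

    manifest = {
        "format": "oohmenu-synthetic/1",
        "seed": dataset.seed,
        "waves": list(dataset.config.waves),
        "rounding": ROUNDING,
        "tolerances": TOLERANCES,
        "config": json.loads(dataset.config.model_dump_json()),
        "businesses_file": "businesses.yaml",
        "truth_file": "truth.csv",
        "files": files,
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=False)
        fh.write("\n")
    return manifest_path


def load_manifest(dataset_dir: str | Path) -> dict:
    with open(Path(dataset_dir) / "manifest.json", "r", encoding="utf-8") as fh:
        return json.load(fh)


def load_businesses(dataset_dir: str | Path, manifest: dict | None = None):
    """Read business metadata back as (BusinessMeta list, chain-info dict)."""
    manifest = manifest or load_manifest(dataset_dir)
    path = Path(dataset_dir) / manifest["businesses_file"]
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    businesses = []
    chain_info: dict[str, dict] = {}
    for raw in payload:
        chains = list(raw["chains"])
        businesses.append(
            BusinessMeta(
                name=raw["name"],
                employee_count=int(raw["employee_count"]),
                sic_code=raw.get("sic_code", ""),
                chains=chains,
                provides_nutrition_online={
                    c: bool(info.get("online", False)) for c, info in raw["chains"].items()
                },
                franchisee_of=raw.get("franchisee_of"),
                sales_rank=raw.get("sales_rank"),
            )
        )
        for c, info in raw["chains"].items():
            chain_info[c] = info
    return businesses, chain_info
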