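"""Harmonization of raw per-chain menu records into a canonical master table.

The standardization stage takes verbatim per-chain records (one CSV per
chain per collection wave, in whatever header/value dialect the chain
publishes) and produces one canonical row per menu item:

* headers are mapped through the synonym map (:mod:`oohmenu.fields`);
* cell text is parsed with operator/missing handling (:mod:`oohmenu.values`);
* energy is resolved to kcal, converting from kJ at 4.184 kJ/kcal when a
  chain reports kJ only, with a unit-inconsistency warning when both units
  are present but disagree by more than 2 kcal;
* serving weight is taken as stated, or derived from paired per-serving and
  per-100g values (100 x per-serving / per-100g, median across nutrients);
* pizza items are portion-normalized to 3 slices or the whole pizza
  according to their size keyword, with the original values preserved;
* all chains' items for a wave are compiled into one master table with a
  fixed column order.

Verbatim source text is preserved for every nutrient so the master table
remains auditable back to the published cells.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .fields import FieldSynonymMap, META_FIELDS, standardize_field_name
from .values import MISSING, NutrientParseError, ValueParse, parse_nutrient_value

KCAL_PER_KJ = 4.184
#: kcal/kJ disagreement beyond this is flagged as a unit inconsistency.
ENERGY_TOLERANCE_KCAL = 2.0
#: Relative spread gate for serving-weight candidates (max/min - 1).
WEIGHT_SPREAD_GATE = 0.15
#: Per-serving values below this (g or kcal) are too coarse, relative to the
#: one-decimal print precision of menus, to give a usable weight candidate.
WEIGHT_MIN_PER_SERVING = 2.0

#: Canonical nutrient keys of the per-serving panel (energy carried in kcal).
NUTRIENT_KEYS = (
    "energy",
    "fat",
    "saturated_fat",
    "carbohydrate",
    "sugar",
    "protein",
    "salt",
    "fiber",
)

#: Master-table column per nutrient key.
NUTRIENT_COLUMNS = {
    "energy": "energy_kcal",
    "fat": "fat_g",
    "saturated_fat": "saturated_fat_g",
    "carbohydrate": "carbohydrate_g",
    "sugar": "sugars_g",
    "protein": "protein_g",
    "salt": "salt_g",
    "fiber": "fiber_g",
}

MASTER_COLUMNS = [
    "wave",
    "chain",
    "item_id",
    "item_name",
    "menu_section",
    "serving_weight_g",
    "serving_weight_source",
    *NUTRIENT_COLUMNS.values(),
    "portion_normalized",
    *[f"verbatim_{key}" for key in NUTRIENT_KEYS],
]


class StandardizationError(ValueError):
    """Base class for harmonization failures."""


class CompilationError(StandardizationError):
    """Duplicate or inconsistent records while compiling a wave master."""


class PizzaNormalizationError(StandardizationError):
    """Pizza item whose portion basis or size keyword cannot be resolved."""


@dataclass
class RawMenuRecord:
    """One menu item exactly as published: verbatim header -> cell text."""

    chain: str
    wave: str
    fields: dict[str, str]
    dialect: str = ""
    portion_normalized: bool = False  # set when re-ingesting a master table

    def __post_init__(self) -> None:
        if not self.chain or not self.wave:
            raise ValueError("chain and wave must be non-empty")


@dataclass
class StandardizedItem:
    """Canonical numeric view of one menu item with preserved verbatim text."""

    chain: str
    wave: str
    item_id: str
    item_name: str
    menu_section: str
    nutrients: dict[str, ValueParse]
    per_100g: dict[str, ValueParse] = field(default_factory=dict)
    serving_weight_g: float | None = None
    serving_weight_source: str = "missing"  # stated | derived | missing
    energy_source: str = "missing"  # kcal | kj | per_100g | missing
    item_description: str = ""
    portion_normalized: bool = False
    pre_normalization: dict[str, ValueParse] | None = None
    pre_normalization_weight: float | None = None
    unmapped: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def resolve_energy(
    kcal: ValueParse | None, kj: ValueParse | None
) -> tuple[ValueParse, str, str | None]:
    """Resolve per-item energy to kcal.

    kcal is preferred when present; otherwise kJ is converted at 4.184.
    Returns ``(value, source, warning)`` where source records the conversion
    provenance and warning is set when both units are present but disagree
    by more than 2 kcal.
    """
    kcal = kcal if kcal is not None else MISSING
    kj = kj if kj is not None else MISSING
    warning = None
    if not kcal.missing:
        if not kj.missing and abs(kcal.value - kj.value / KCAL_PER_KJ) > ENERGY_TOLERANCE_KCAL:
            warning = (
                f"energy unit inconsistency: {kcal.value} kcal vs {kj.value} kJ "
                f"({kj.value / KCAL_PER_KJ:.1f} kcal)"
            )
        return kcal, "kcal", warning
    if not kj.missing:
        return ValueParse(kj.value / KCAL_PER_KJ, kj.operator, kj.verbatim), "kj", None
    return MISSING, "missing", None


def derive_serving_weight(
    per_serving: Mapping[str, ValueParse], per_100g: Mapping[str, ValueParse]
) -> tuple[float | None, str | None]:
    """Derive serving weight (g) from paired per-serving and per-100g values.

    Every nutrient (energy included) with both values present, a positive
    per-100g value and a per-serving value of at least 2 (g or kcal)
    contributes the candidate ``100 x per_serving / per_100g``.  The median
    candidate is returned when the relative spread (max/min - 1) is at most
    0.15; otherwise the panel is inconsistent and the weight stays missing.
    """
    candidates = []
    for key, ps in per_serving.items():
        density = per_100g.get(key)
        if density is None or density.missing or ps.missing:
            continue
        if density.value <= 0 or ps.value < WEIGHT_MIN_PER_SERVING:
            continue
        candidates.append(100.0 * ps.value / density.value)
    if not candidates:
        return None, None
    spread = max(candidates) / min(candidates) - 1.0
    if spread > WEIGHT_SPREAD_GATE:
        return None, f"inconsistent weight candidates (spread {spread:.2f})"
    candidates.sort()
    mid = len(candidates) // 2
    if len(candidates) % 2:
        return candidates[mid], None
    return (candidates[mid - 1] + candidates[mid]) / 2.0, None


def standardize_record(rec: RawMenuRecord, synonyms: FieldSynonymMap) -> StandardizedItem:
    """Standardize one raw record into canonical per-serving values."""
    per_serving_raw: dict[str, ValueParse] = {}
    per100_raw: dict[str, ValueParse] = {}
    meta: dict[str, str] = {}
    unmapped: dict[str, str] = {}
    weight_vp = MISSING
    warnings: list[str] = []

    for header, cell in rec.fields.items():
        canonical = standardize_field_name(header, synonyms)
        if canonical is None:
            unmapped[header] = cell
            continue
        if canonical in META_FIELDS:
            meta[canonical] = (cell or "").strip()
            continue
        record_id = f"{rec.chain}:{rec.wave}:{header}"
        vp = parse_nutrient_value(cell, record_id=record_id)
        if canonical.endswith("_per_100g"):
            per100_raw[canonical[: -len("_per_100g")]] = vp
        elif canonical == "serving_weight":
            weight_vp = vp
        else:
            per_serving_raw[canonical] = vp

    item_name = meta.get("item_name", "")
    if not item_name:
        raise StandardizationError(f"record in {rec.chain}/{rec.wave} lacks an item name")

    energy, energy_source, warn = resolve_energy(
        per_serving_raw.get("energy_kcal"), per_serving_raw.get("energy_kj")
    )
    if warn:
        warnings.append(warn)
    energy100, _, warn100 = resolve_energy(
        per100_raw.get("energy_kcal"), per100_raw.get("energy_kj")
    )
    if warn100:
        warnings.append(warn100)

    nutrients = {key: per_serving_raw.get(key, MISSING) for key in NUTRIENT_KEYS}
    nutrients["energy"] = energy
    per_100g = {key: per100_raw.get(key, MISSING) for key in NUTRIENT_KEYS}
    per_100g["energy"] = energy100
    per_100g = {k: v for k, v in per_100g.items() if not v.missing}

    if not weight_vp.missing:
        weight, weight_source = weight_vp.value, "stated"
    else:
        weight, note = derive_serving_weight(nutrients, per_100g)
        weight_source = "derived" if weight is not None else "missing"
        if note:
            warnings.append(note)

    # A chain publishing only the per-100g panel alongside a stated serving
    # weight still yields per-serving values: value = per-100g x weight/100.
    # Only a stated weight is used here, to avoid compounding a derived one.
    if weight_source == "stated":
        for key, density in per_100g.items():
            if nutrients[key].missing:
                scaled = density.value * weight / 100.0
                nutrients[key] = ValueParse(scaled, density.operator, density.verbatim)
                if key == "energy":
                    energy_source = "per_100g"

    return StandardizedItem(
        chain=rec.chain,
        wave=rec.wave,
        item_id=meta.get("item_id", ""),
        item_name=item_name,
        menu_section=meta.get("menu_section", ""),
        nutrients=nutrients,
        per_100g=per_100g,
        serving_weight_g=weight,
        serving_weight_source=weight_source,
        energy_source=energy_source if not nutrients["energy"].missing else "missing",
        item_description=meta.get("item_description", ""),
        portion_normalized=rec.portion_normalized,
        unmapped=unmapped,
        warnings=warnings,
    )


# --------------------------------------------------------------------------
# Pizza portion normalization
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PizzaConfig:
    """Size-keyword rules for pizza portion normalization."""

    sizes: Mapping[str, Mapping[str, str]]  # keyword -> {basis, portion}
    slices_per_pizza: int = 8
    sections: tuple[str, ...] = ("pizzas",)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PizzaConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            sizes=raw["sizes"],
            slices_per_pizza=int(raw.get("slices_per_pizza", 8)),
            sections=tuple(raw.get("sections", ["pizzas"])),
        )

    @classmethod
    def default(cls) -> "PizzaConfig":
        ref = resources.files("oohmenu.data").joinpath("pizza.yaml")
        raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
        return cls(
            sizes=raw["sizes"],
            slices_per_pizza=int(raw.get("slices_per_pizza", 8)),
            sections=tuple(raw.get("sections", ["pizzas"])),
        )


def find_size_keyword(item_name: str, config: PizzaConfig) -> str | None:
    """Longest size keyword occurring in the item name (case-insensitive)."""
    name = item_name.casefold()
    best = None
    for keyword in config.sizes:
        if keyword.casefold() in name and (best is None or len(keyword) > len(best)):
            best = keyword
    return best


def _portion_factor(basis: str, portion: str, slices_per_pizza: int) -> float:
    if portion == "three_slices":
        if basis == "slice":
            return 3.0
        if basis == "whole":
            return 3.0 / slices_per_pizza
    elif portion == "whole":
        if basis == "whole":
            return 1.0
        if basis == "slice":
            return float(slices_per_pizza)
    raise PizzaNormalizationError(f"unknown pizza basis/portion: {basis}/{portion}")


def normalize_pizza_portion(item: StandardizedItem, config: PizzaConfig) -> StandardizedItem:
    """Normalize a pizza item to its reporting portion (3 slices or whole).

    The caller decides which items are pizzas (chain and menu-section
    based); already-normalized items pass through unchanged, as do items
    handed in that are not flagged for normalization.  Original values and
    weight are preserved on the returned item.
    """
    if item.portion_normalized:
        return item
    keyword = find_size_keyword(item.item_name, config)
    if keyword is None:
        raise PizzaNormalizationError(
            f"pizza item {item.item_id or item.item_name!r} has no recognized size keyword"
        )
    rule = config.sizes[keyword]
    factor = _portion_factor(rule["basis"], rule["portion"], config.slices_per_pizza)

    scaled = {
        key: vp if vp.missing else ValueParse(vp.value * factor, vp.operator, vp.verbatim)
        for key, vp in item.nutrients.items()
    }
    weight = None if item.serving_weight_g is None else item.serving_weight_g * factor
    return replace(
        item,
        nutrients=scaled,
        serving_weight_g=weight,
        portion_normalized=True,
        pre_normalization=dict(item.nutrients),
        pre_normalization_weight=item.serving_weight_g,
    )


def is_pizza_item(item: StandardizedItem, config: PizzaConfig, pizza_chains: Iterable[str]) -> bool:
    return item.chain in set(pizza_chains) and item.menu_section.casefold() in config.sections


def standardize_records(
    records: Iterable[RawMenuRecord],
    synonyms: FieldSynonymMap | None = None,
    pizza_config: PizzaConfig | None = None,
    pizza_chains: Iterable[str] = (),
) -> list[StandardizedItem]:
    """Standardize a batch of raw records, applying pizza normalization."""
    synonyms = synonyms or FieldSynonymMap.default()
    pizza_config = pizza_config or PizzaConfig.default()
    pizza_chains = set(pizza_chains)
    items = []
    for rec in records:
        item = standardize_record(rec, synonyms)
        if is_pizza_item(item, pizza_config, pizza_chains):
            item = normalize_pizza_portion(item, pizza_config)
        items.append(item)
    return items


# --------------------------------------------------------------------------
# Wave master compilation and round-tripping
# --------------------------------------------------------------------------


def _verbatim(item: StandardizedItem, key: str) -> str:
    source = item.pre_normalization if item.pre_normalization is not None else item.nutrients
    return source[key].verbatim


def compile_wave(items: Sequence[StandardizedItem], wave: str) -> pd.DataFrame:
    """Compile all chains' standardized items for one wave into one master.

    One row per item record, fixed column order, row count preserved.
    Duplicate (chain, item name) keys within the wave are rejected: menu
    items of different sizes or customizations must already carry distinct
    descriptors in their names.
    """
    off_wave = [it.item_id or it.item_name for it in items if it.wave != wave]
    if off_wave:
        raise CompilationError(f"records not in wave {wave!r}: {off_wave[:5]}")
    seen: dict[tuple[str, str], int] = {}
    duplicates = []
    for it in items:
        key = (it.chain, it.item_name)
        seen[key] = seen.get(key, 0) + 1
        if seen[key] == 2:
            duplicates.append(key)
    if duplicates:
        raise CompilationError(f"duplicate (chain, item) keys in wave {wave!r}: {duplicates[:10]}")

    rows = []
    for it in items:
        row = {
            "wave": it.wave,
            "chain": it.chain,
            "item_id": it.item_id,
            "item_name": it.item_name,
            "menu_section": it.menu_section,
            "serving_weight_g": it.serving_weight_g,
            "serving_weight_source": it.serving_weight_source,
            "portion_normalized": it.portion_normalized,
        }
        for key, column in NUTRIENT_COLUMNS.items():
            row[column] = it.nutrients[key].value
            row[f"verbatim_{key}"] = _verbatim(it, key)
        rows.append(row)
    return pd.DataFrame(rows, columns=MASTER_COLUMNS)


def write_master(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, na_rep="")


def read_master(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={c: str for c in ("wave", "chain", "item_id")}, keep_default_na=False, na_values=[""])
    for col in ("item_name", "menu_section", "serving_weight_source"):
        df[col] = df[col].fillna("").astype(str)
    if df["portion_normalized"].dtype == object:
        df["portion_normalized"] = df["portion_normalized"].astype(str).str.strip().eq("True")
    return df


def master_to_records(df: pd.DataFrame) -> list[RawMenuRecord]:
    """Re-express a master table as raw records (canonical headers).

    Used to show that harmonization is idempotent: feeding a master table
    back through standardization reproduces the same values.
    """
    records = []
    value_columns = ["item_id", "item_name", "menu_section", "serving_weight_g"] + list(
        NUTRIENT_COLUMNS.values()
    )
    for _, row in df.iterrows():
        fields = {}
        for col in value_columns:
            val = row[col]
            fields[col] = "" if pd.isna(val) else str(val)
        records.append(
            RawMenuRecord(
                chain=row["chain"],
                wave=row["wave"],
                fields=fields,
                portion_normalized=bool(row["portion_normalized"]),
            )
        )
    return records


def read_raw_file(path: str | Path, chain: str, wave: str, dialect: str = "") -> list[RawMenuRecord]:
    """Read one chain/wave delimited text file into raw records."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        return [
            RawMenuRecord(chain=chain, wave=wave, fields=dict(row), dialect=dialect)
            for row in reader
        ]
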