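"""Standardization: energy resolution, serving weight, pizza portions, compilation."""

import pandas as pd
import pytest

from oohmenu.fields import FieldSynonymMap
from oohmenu.standardize import (
    CompilationError,
    PizzaConfig,
    PizzaNormalizationError,
    RawMenuRecord,
    StandardizedItem,
    compile_wave,
    derive_serving_weight,
    master_to_records,
    normalize_pizza_portion,
    read_master,
    resolve_energy,
    standardize_record,
    standardize_records,
    write_master,
)
from oohmenu.values import MISSING, ValueParse, parse_nutrient_value


@pytest.fixture(scope="module")
def synonyms():
    return FieldSynonymMap.default()


def vp(value, operator=""):
    return ValueParse(value, operator, str(value))


# -------------------------------------------------------------- energy


class TestResolveEnergy:
    def test_kcal_preferred(self):
        value, source, warning = resolve_energy(vp(600.0), None)
        assert (value.value, source, warning) == (600.0, "kcal", None)

    def test_kj_converted(self):
        value, source, warning = resolve_energy(None, vp(2092.0))
        assert value.value == pytest.approx(500.0)
        assert (source, warning) == ("kj", None)

    def test_consistent_pair_has_no_warning(self):
        # |600 - 2510/4.184| = 0.04 kcal, well inside the 2 kcal tolerance
        value, source, warning = resolve_energy(vp(600.0), vp(2510.0))
        assert value.value == 600.0
        assert warning is None

    def test_inconsistent_pair_warns(self):
        _, _, warning = resolve_energy(vp(600.0), vp(2600.0))
        assert warning is not None and "inconsistency" in warning

    def test_both_missing(self):
        value, source, _ = resolve_energy(None, None)
        assert value.missing and source == "missing"


# ------------------------------------------------------- serving weight


class TestDeriveServingWeight:
    def test_single_nutrient(self):
        weight, note = derive_serving_weight({"fat": vp(10.0)}, {"fat": vp(5.0)})
        assert weight == pytest.approx(200.0)
        assert note is None

    def test_no_density_panel(self):
        weight, _ = derive_serving_weight({"fat": vp(10.0)}, {})
        assert weight is None

    def test_median_of_candidates(self):
        per_serving = {"fat": vp(10.0), "carbohydrate": vp(40.2), "protein": vp(19.9)}
        per_100g = {"fat": vp(5.0), "carbohydrate": vp(20.0), "protein": vp(10.0)}
        # candidates 200, 201, 199; spread 201/199 - 1 ~ 0.01 <= 0.15
        weight, note = derive_serving_weight(per_serving, per_100g)
        assert weight == pytest.approx(200.0)
        assert note is None

    def test_inconsistent_candidates_rejected(self):
        per_serving = {"fat": vp(10.0), "protein": vp(30.0)}
        per_100g = {"fat": vp(5.0), "protein": vp(10.0)}  # candidates 200 vs 300
        weight, note = derive_serving_weight(per_serving, per_100g)
        assert weight is None
        assert "inconsistent" in note

    def test_trace_values_do_not_contribute(self):
        # 0.1 g printed at one decimal is too coarse to date a weight from
        weight, _ = derive_serving_weight({"salt": vp(0.1)}, {"salt": vp(0.03)})
        assert weight is None


# ------------------------------------------------------------ records


def _record(fields, chain="Chain A", wave="2021-03-01"):
    return RawMenuRecord(chain=chain, wave=wave, fields=fields)


class TestStandardizeRecord:
    def test_basic_record(self, synonyms):
        rec = _record(
            {
                "Item ID": "a|1",
                "Item Name": "Burger",
                "Menu Section": "Mains",
                "Energy (kcal)": "650",
                "Fat (g)": "33.1",
                "Sugars (g)": "<0.5",
                "Salt (g)": "-",
                "Serving Weight (g)": "320.0",
            }
        )
        item = standardize_record(rec, synonyms)
        assert item.item_name == "Burger"
        assert item.nutrients["energy"].value == 650.0
        assert item.energy_source == "kcal"
        assert item.nutrients["fat"].value == 33.1
        assert item.nutrients["sugar"].operator == "<"
        assert item.nutrients["salt"].missing
        assert item.serving_weight_g == 320.0
        assert item.serving_weight_source == "stated"

    def test_kj_only_chain(self, synonyms):
        rec = _record({"item": "Latte", "kJ": "1,046"})
        item = standardize_record(rec, synonyms)
        assert item.nutrients["energy"].value == pytest.approx(250.0, abs=0.01)
        assert item.energy_source == "kj"

    def test_density_panel_with_stated_weight(self, synonyms):
        rec = _record(
            {
                "Item Name": "Soup",
                "Serving Size (g)": "300.0",
                "Energy (kcal) per 100g": "50.0",
                "Fat per 100g": "2.50",
            }
        )
        item = standardize_record(rec, synonyms)
        assert item.nutrients["energy"].value == pytest.approx(150.0)
        assert item.energy_source == "per_100g"
        assert item.nutrients["fat"].value == pytest.approx(7.5)
        assert item.serving_weight_source == "stated"

    def test_derived_weight_from_dual_panels(self, synonyms):
        rec = _record(
            {
                "Item Name": "Wrap",
                "Energy (kcal)": "400",
                "Fat (g)": "10.0",
                "Energy (kcal) per 100g": "200.0",
                "Fat per 100g": "5.00",
            }
        )
        item = standardize_record(rec, synonyms)
        assert item.serving_weight_source == "derived"
        assert item.serving_weight_g == pytest.approx(200.0)

    def test_unmapped_headers_reported(self, synonyms):
        rec = _record({"Item Name": "Cake", "Allergens": "nuts", "Energy (kcal)": "410"})
        item = standardize_record(rec, synonyms)
        assert item.unmapped == {"Allergens": "nuts"}

    def test_verbatim_preserved(self, synonyms):
        rec = _record({"Item Name": "Tea", "Sugars (g)": "<0.5"})
        item = standardize_record(rec, synonyms)
        assert item.nutrients["sugar"].verbatim == "<0.5"


# -------------------------------------------------------------- pizza


@pytest.fixture(scope="module")
def pizza_cfg():
    return PizzaConfig.default()


def _pizza_item(name, energy, weight=None):
    nutrients = {k: MISSING for k in ("energy", "fat", "saturated_fat", "carbohydrate", "sugar", "protein", "salt", "fiber")}
    nutrients["energy"] = vp(energy)
    return StandardizedItem(
        chain="PizzaCo",
        wave="2021-03-01",
        item_id="p|1",
        item_name=name,
        menu_section="Pizzas",
        nutrients=nutrients,
        serving_weight_g=weight,
        serving_weight_source="stated" if weight else "missing",
    )


class TestPizzaNormalization:
    def test_large_per_slice_times_three(self, pizza_cfg):
        item = normalize_pizza_portion(_pizza_item("Margherita (Large)", 250.0), pizza_cfg)
        assert item.nutrients["energy"].value == 750.0
        assert item.portion_normalized
        assert item.pre_normalization["energy"].value == 250.0  # original preserved

    def test_individual_whole_pizza_unchanged_except_flag(self, pizza_cfg):
        item = normalize_pizza_portion(_pizza_item("Veggie (Individual)", 900.0), pizza_cfg)
        assert item.nutrients["energy"].value == 900.0
        assert item.portion_normalized

    def test_medium_whole_basis_uses_slice_count(self):
        config = PizzaConfig(
            sizes={"medium": {"basis": "whole", "portion": "three_slices"}},
            slices_per_pizza=8,
        )
        item = normalize_pizza_portion(_pizza_item("Hot One (Medium)", 1600.0), config)
        assert item.nutrients["energy"].value == pytest.approx(600.0)  # 1600/8*3

    def test_unknown_size_keyword_is_an_error(self, pizza_cfg):
        with pytest.raises(PizzaNormalizationError):
            normalize_pizza_portion(_pizza_item("Calzone", 800.0), pizza_cfg)

    def test_weight_scaled_with_values(self, pizza_cfg):
        item = normalize_pizza_portion(_pizza_item("Meaty (Family)", 300.0, weight=120.0), pizza_cfg)
        assert item.serving_weight_g == pytest.approx(360.0)
        assert item.pre_normalization_weight == 120.0

    def test_already_normalized_passes_through(self, pizza_cfg):
        item = _pizza_item("Margherita (Large)", 750.0)
        item.portion_normalized = True
        assert normalize_pizza_portion(item, pizza_cfg) is item

    def test_non_pizza_items_untouched_by_batch(self, synonyms, pizza_cfg):
        rec = _record({"Item Name": "Garlic Bread", "Energy (kcal)": "300"}, chain="PizzaCo")
        [item] = standardize_records([rec], synonyms, pizza_cfg, pizza_chains={"PizzaCo"})
        assert not item.portion_normalized  # no pizza menu section


# --------------------------------------------------------- compilation


def _items(n, chain="Chain A", wave="2021-03-01"):
    out = []
    for i in range(n):
        nutrients = {k: MISSING for k in ("energy", "fat", "saturated_fat", "carbohydrate", "sugar", "protein", "salt", "fiber")}
        nutrients["energy"] = vp(100.0 + i)
        out.append(
            StandardizedItem(
                chain=chain,
                wave=wave,
                item_id=f"{chain}|{i}",
                item_name=f"Item {i}",
                menu_section="Mains",
                nutrients=nutrients,
            )
        )
    return out


class TestCompileWave:
    def test_count_conservation(self):
        items = _items(10, "A") + _items(10, "B") + _items(10, "C")
        master = compile_wave(items, "2021-03-01")
        assert len(master) == 30
        assert list(master.columns)[:5] == ["wave", "chain", "item_id", "item_name", "menu_section"]

    def test_empty_input_gives_header_only(self):
        master = compile_wave([], "2021-03-01")
        assert len(master) == 0 and len(master.columns) > 0

    def test_duplicate_keys_rejected(self):
        items = _items(3) + _items(1)
        with pytest.raises(CompilationError):
            compile_wave(items, "2021-03-01")

    def test_wrong_wave_rejected(self):
        with pytest.raises(CompilationError):
            compile_wave(_items(2, wave="2021-06-01"), "2021-03-01")


def test_standardization_is_idempotent(mixed_run, synonyms, tmp_path):
    """Re-standardizing a compiled master reproduces its values unchanged."""
    wave, master = next(iter(mixed_run.result.masters.items()))
    path = tmp_path / "master.csv"
    write_master(master, path)
    again = compile_wave(
        standardize_records(master_to_records(read_master(path)), synonyms),
        wave,
    )
    value_cols = [
        "wave", "chain", "item_id", "item_name", "menu_section", "serving_weight_g",
        "energy_kcal", "fat_g", "saturated_fat_g", "carbohydrate_g", "sugars_g",
        "protein_g", "salt_g", "fiber_g", "portion_normalized",
    ]
    pd.testing.assert_frame_equal(
        master[value_cols].reset_index(drop=True),
        again[value_cols].reset_index(drop=True),
        check_dtype=False,
    )
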