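"""Synthetic generator: determinism, dialect emission, target calibration."""

import math
from statistics import NormalDist

import numpy as np
import pydantic
import pytest

from oohmenu.analysis import MealThresholds, ReferenceIntakes, THRESHOLDED_NUTRIENTS
from oohmenu.standardize import NUTRIENT_KEYS
from oohmenu.synthetic import (
    DIALECTS,
    Dialect,
    GenerationError,
    GeneratorConfig,
    ItemTruth,
    apply_dialect,
    generate_dataset,
    kj_variant,
    lognormal_params,
    write_dataset,
)


def _all(p):
    return {n: p for n in THRESHOLDED_NUTRIENTS}


class TestConfigValidation:
    def test_dialect_mix_must_sum_to_one(self):
        with pytest.raises(pydantic.ValidationError, match="dialect_mix"):
            GeneratorConfig.small(dialect_mix={"classic": 0.5, "terse": 0.4})

    def test_unknown_dialect_rejected(self):
        with pytest.raises(pydantic.ValidationError, match="unknown dialects"):
            GeneratorConfig.small(dialect_mix={"pdf_ocr": 1.0})

    def test_probabilities_bounded(self):
        with pytest.raises(pydantic.ValidationError, match="operator_rate"):
            GeneratorConfig.small(operator_rate=1.5)

    def test_items_range_ordered(self):
        with pytest.raises(pydantic.ValidationError, match="items_per_chain"):
            GeneratorConfig.small(items_per_chain=(80, 40))

    def test_daily_target_below_meal_target(self):
        with pytest.raises(pydantic.ValidationError, match="target_daily_exceedance"):
            GeneratorConfig.small(
                target_exceedance=_all(0.2), target_daily_exceedance=_all(0.3)
            )

    def test_default_config_is_valid(self):
        config = GeneratorConfig()
        assert config.n_chains == 85
        assert len(config.waves) == 4


class TestLognormalCalibration:
    def test_both_quantile_constraints_hold(self):
        mu, sigma, clip = lognormal_params(600.0, 2000.0, 0.247, 0.007)
        assert clip is None
        z = NormalDist()
        assert 1 - z.cdf((math.log(600) - mu) / sigma) == pytest.approx(0.247, abs=1e-12)
        assert 1 - z.cdf((math.log(2000) - mu) / sigma) == pytest.approx(0.007, abs=1e-12)

    def test_degenerate_targets_clip(self):
        _, _, clip0 = lognormal_params(600.0, 2000.0, 0.0, 0.0)
        _, _, clip1 = lognormal_params(600.0, 2000.0, 1.0, 0.0)
        assert (clip0, clip1) == ("clip_below", "clip_above")


class TestDeterminism:
    def test_identical_seed_identical_files(self, tmp_path):
        config = GeneratorConfig.small(n_chains=5, items_per_chain=(20, 30))
        for sub in ("a", "b"):
            write_dataset(generate_dataset(config, seed=42), tmp_path / sub)
        a_files = sorted(p for p in (tmp_path / "a").rglob("*") if p.is_file())
        b_files = sorted(p for p in (tmp_path / "b").rglob("*") if p.is_file())
        assert [p.name for p in a_files] == [p.name for p in b_files]
        for pa, pb in zip(a_files, b_files):
            assert pa.read_bytes() == pb.read_bytes(), pa.name

    def test_different_seeds_differ(self):
        config = GeneratorConfig.small(n_chains=5, items_per_chain=(20, 30))
        a = generate_dataset(config, seed=1)
        b = generate_dataset(config, seed=2)
        assert not a.truth.equals(b.truth)

    def test_each_record_has_one_truth_entry(self, mixed_run):
        emitted_ids = []
        synonyms_header = None
        for (chain, wave), records in mixed_run.dataset.records.items():
            for rec in records:
                for header, value in rec.fields.items():
                    if header.casefold().replace(" ", "").replace("_", "") == "itemid":
                        emitted_ids.append(value)
        truth_ids = mixed_run.truth["item_id"]
        assert sorted(emitted_ids) == sorted(truth_ids)
        assert truth_ids.is_unique


def _truth_item(values, weight=250.0, reported=None, weight_stated=True):
    full = {n: 1.0 for n in NUTRIENT_KEYS}
    full.update(values)
    return ItemTruth(
        item_id="c|w|1",
        chain="Chain A",
        wave="2021-03-01",
        name="Item 1",
        section="Mains",
        values=full,
        reported=reported or {n: True for n in NUTRIENT_KEYS},
        weight=weight,
        weight_stated=weight_stated,
        weight_reported=weight_stated,
        flags={n: (False, False) for n in THRESHOLDED_NUTRIENTS},
    )


class TestApplyDialect:
    def test_per_100g_emission(self):
        # fat 10 g per serving over 200 g -> 5 g per 100 g
        truth = _truth_item({"fat": 10.0}, weight=200.0)
        rec = apply_dialect(truth, DIALECTS["density"])
        assert rec.fields["Fat per 100g"] == "5.00"

    def test_kj_emission_is_kcal_times_4184(self):
        truth = _truth_item({"energy": 600.0})
        rec = apply_dialect(truth, kj_variant(DIALECTS["terse"]))
        assert rec.fields["kJ"] == "2510"  # round(600 x 4.184)
        assert "kcal" not in rec.fields

    def test_missing_marker_convention(self):
        reported = {n: True for n in NUTRIENT_KEYS}
        reported["fiber"] = False
        truth = _truth_item({}, reported=reported)
        dash = apply_dialect(truth, DIALECTS["classic"])
        blank = apply_dialect(truth, DIALECTS["terse"])
        assert dash.fields["Fibre (g)"] == "-"
        assert blank.fields["fiber"] == ""

    def test_density_dialect_requires_stated_weight(self):
        truth = _truth_item({}, weight_stated=False)
        with pytest.raises(GenerationError):
            apply_dialect(truth, DIALECTS["density"])

    def test_operator_emission_keeps_value(self):
        truth = _truth_item({"salt": 0.4})
        rng = np.random.default_rng(0)
        rec = apply_dialect(truth, DIALECTS["classic"], operator_rate=1.0, rng=rng)
        assert rec.fields["Salt (g)"] == "<0.4"

    def test_thousands_separator_in_classic_energy(self):
        truth = _truth_item({"energy": 1204.0})
        rec = apply_dialect(truth, DIALECTS["classic"])
        assert rec.fields["Energy (kcal)"] == "1,204"

    def test_dialect_header_uniqueness(self):
        for dialect in DIALECTS.values():
            headers = list(dialect.headers.values())
            if dialect.per100_headers:
                headers += list(dialect.per100_headers.values())
            if dialect.weight_header:
                headers.append(dialect.weight_header)
            assert len(headers) == len(set(headers)), dialect.name

    def test_per100_only_dialect_must_state_weight(self):
        with pytest.raises(ValueError):
            Dialect(
                name="bad",
                basis="per100",
                energy_unit="kcal",
                missing_marker="",
                headers={},
                per100_headers={"fat": "Fat per 100g"},
            )


class TestTargetCalibration:
    def test_zero_target_yields_zero_exceedance(self):
        config = GeneratorConfig.small(
            n_chains=5,
            items_per_chain=(200, 200),
            waves=["2021-03-01"],
            target_exceedance=_all(0.0),
            target_daily_exceedance=_all(0.0),
        )
        truth = generate_dataset(config, seed=3).truth
        assert len(truth) >= 1000
        assert truth["energy_value"].le(600.0).all()
        for nutrient in THRESHOLDED_NUTRIENTS:
            assert not truth[f"{nutrient}_exceeds_meal"].any()

    def test_empirical_fraction_tracks_target(self, recovery_run):
        """Observed ground-truth exceedance stays in the 99% binomial band."""
        from scipy.stats import binom

        truth = recovery_run.truth
        n = len(truth)
        lo, hi = binom.ppf([0.005, 0.995], n, 0.25)
        for nutrient in THRESHOLDED_NUTRIENTS:
            count = int(truth[f"{nutrient}_exceeds_meal"].sum())
            assert lo <= count <= hi, nutrient

    def test_flags_consistent_with_values(self, mixed_run):
        truth = mixed_run.truth
        intakes = ReferenceIntakes()
        thresholds = MealThresholds.from_intakes(intakes)
        for nutrient in THRESHOLDED_NUTRIENTS:
            values = truth[f"{nutrient}_value"]
            assert truth[f"{nutrient}_exceeds_meal"].equals(values > thresholds.meal(nutrient))
            assert truth[f"{nutrient}_exceeds_daily"].equals(values > intakes.daily(nutrient))
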