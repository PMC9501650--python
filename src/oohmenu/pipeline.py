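"""Orchestration: inclusion filtering -> harmonization -> analysis.

Runs the whole workflow over an on-disk dataset (as written by
:func:`oohmenu.synthetic.write_dataset`): decide which businesses and
chains enter, check document validity per wave, read and standardize every
included chain's raw file, compile one master table per wave, and compute
availability and exceedance summaries.  Every stage keeps counts that are
conserved (records in = records out + exclusions) and every dropped entity
carries one machine-readable reason code in the audit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .analysis import (
    MealThresholds,
    ReferenceIntakes,
    availability_summary,
    flag_items,
    summarize_exceedance,
)
from .fields import FieldSynonymMap
from .filters import (
    AuditEntry,
    BusinessMeta,
    MenuDoc,
    audit_frame,
    document_valid,
    include_business,
    include_chain,
    select_menus,
)
from .standardize import PizzaConfig, compile_wave, read_raw_file, standardize_records, write_master
from .synthetic import load_businesses, load_manifest

logger = logging.getLogger("oohmenu")


@dataclass
class StageCounts:
    n_in: int = 0
    n_out: int = 0
    exclusions: dict[str, int] = field(default_factory=dict)

    def exclude(self, reason: str) -> None:
        self.exclusions[reason] = self.exclusions.get(reason, 0) + 1

    def conserved(self) -> bool:
        return self.n_in == self.n_out + sum(self.exclusions.values())

    def as_dict(self) -> dict:
        return {"in": self.n_in, "out": self.n_out, "exclusions": dict(self.exclusions)}


@dataclass
class InclusionResult:
    included_chains: list[str]
    audit: list[AuditEntry]
    business_counts: StageCounts
    chain_counts: StageCounts


def apply_inclusion(businesses: list[BusinessMeta]) -> InclusionResult:
    """Business- and chain-level inclusion with a full audit trail.

    Directly-owned chains are processed before franchise operations so that
    the franchisee rule sees the complete set of captured chains.
    """
    audit: list[AuditEntry] = []
    business_counts = StageCounts(n_in=len(businesses))
    chain_counts = StageCounts()
    included_businesses = []
    for meta in businesses:
        decision = include_business(meta)
        audit.append(AuditEntry(meta.name, "business", "business_frame", decision.include, decision.reason))
        if decision:
            business_counts.n_out += 1
            included_businesses.append(meta)
        else:
            business_counts.exclude(decision.reason)
            logger.info("excluded business %s: %s", meta.name, decision.reason)

    captured: set[str] = set()
    included_chains: list[str] = []

    def review(meta: BusinessMeta) -> None:
        for chain in meta.chains:
            chain_counts.n_in += 1
            decision = include_chain(chain, meta, captured)
            audit.append(AuditEntry(chain, "chain", "chain_review", decision.include, decision.reason))
            if decision:
                chain_counts.n_out += 1
                captured.add(chain)
                included_chains.append(chain)
            else:
                chain_counts.exclude(decision.reason)
                logger.info("excluded chain %s: %s", chain, decision.reason)

    for meta in included_businesses:
        if meta.franchisee_of is None:
            review(meta)
    for meta in included_businesses:
        if meta.franchisee_of is not None:
            review(meta)

    return InclusionResult(included_chains, audit, business_counts, chain_counts)


@dataclass
class RunResult:
    masters: dict[str, pd.DataFrame]
    availability: pd.DataFrame
    exceedance: pd.DataFrame
    audit: pd.DataFrame
    manifest: dict
    included_chains: list[str]
    analyzed_chains: dict[str, list[str]]  # wave -> chains contributing records


def _pooled_label(waves: list[str]) -> str:
    years = {w[:4] for w in waves}
    return f"pooled-{years.pop()}" if len(years) == 1 else "pooled"


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_all(
    dataset_dir: str | Path,
    out_dir: str | Path,
    seed: int = 0,
    synonyms: FieldSynonymMap | None = None,
    pizza_config: PizzaConfig | None = None,
    intakes: ReferenceIntakes | None = None,
    energy_meal_kcal: float = 600.0,
    write: bool = True,
) -> RunResult:
    """Run filter -> harmonize -> analyze over a dataset directory.

    Writes one master CSV per wave, availability and exceedance reports,
    the exclusion audit, and a run manifest with conserved per-stage
    counts.  With ``write=False`` nothing is written and the results are
    only returned (used by tests).
    """
    started = datetime.now(timezone.utc).isoformat()
    dataset_dir = Path(dataset_dir)
    out = Path(out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    synonyms = synonyms or FieldSynonymMap.default()
    pizza_config = pizza_config or PizzaConfig.default()
    intakes = intakes or ReferenceIntakes()
    thresholds = MealThresholds.from_intakes(intakes, energy_meal_kcal)

    manifest_in = load_manifest(dataset_dir)
    businesses, chain_info = load_businesses(dataset_dir, manifest_in)
    waves: list[str] = list(manifest_in["waves"])

    inclusion = apply_inclusion(businesses)
    audit = list(inclusion.audit)

    files: dict[tuple[str, str], dict] = {
        (f["chain"], f["wave"]): f for f in manifest_in["files"]
    }
    pizza_chains = {c for c, info in chain_info.items() if info.get("is_pizza")}

    # Menu and location selection is held fixed per chain across waves.
    selections: dict[str, dict] = {}
    for chain in inclusion.included_chains:
        info = chain_info.get(chain, {})
        menus = [tuple(m) for m in info.get("menus", [])]
        if menus:
            chosen, location = select_menus(menus, info.get("locations", []), chain, seed)
            selections[chain] = {"menus": [m[0] for m in chosen], "location": location}

    document_counts = StageCounts()
    record_counts: dict[str, StageCounts] = {w: StageCounts() for w in waves}
    masters: dict[str, pd.DataFrame] = {}
    analyzed_chains: dict[str, list[str]] = {}

    for wave in waves:
        wave_date = date.fromisoformat(wave)
        wave_items = []
        contributing = []
        for chain in inclusion.included_chains:
            entry = files.get((chain, wave))
            if entry is None or entry["n_records"] == 0:
                audit.append(AuditEntry(f"{chain}@{wave}", "chain", "data_files", False, "no_data_collected"))
                logger.info("chain %s skipped in wave %s: no data collected", chain, wave)
                continue
            info = chain_info.get(chain, {})
            last_updated = info.get("last_updated")
            doc = MenuDoc(
                chain=chain,
                menu_name=selections.get(chain, {}).get("menus", ["Core Menu"])[0],
                menu_type="main",
                wave_date=wave_date,
                last_updated=date.fromisoformat(last_updated) if last_updated else None,
            )
            document_counts.n_in += 1
            if not document_valid(doc):
                document_counts.exclude("stale_document")
                audit.append(AuditEntry(f"{chain}@{wave}", "document", "document_validity", False, "stale_document"))
                logger.info("chain %s dropped in wave %s: nutrition document stale", chain, wave)
                continue
            document_counts.n_out += 1
            records = read_raw_file(
                dataset_dir / entry["path"], chain, wave, dialect=entry.get("dialect", "")
            )
            record_counts[wave].n_in += len(records)
            wave_items.extend(
                standardize_records(records, synonyms, pizza_config, pizza_chains)
            )
            contributing.append(chain)
        master = compile_wave(wave_items, wave)
        record_counts[wave].n_out = len(master)
        masters[wave] = master
        analyzed_chains[wave] = contributing
        if write:
            write_master(master, out / f"master_{wave}.csv")

    availability = availability_summary(masters)
    per_wave = [
        summarize_exceedance(flag_items(master, intakes, thresholds), wave)
        for wave, master in masters.items()
    ]
    pooled = summarize_exceedance(
        flag_items(pd.concat(masters.values(), ignore_index=True), intakes, thresholds),
        _pooled_label(waves),
    )
    exceedance = pd.concat([pooled, *per_wave], ignore_index=True)
    audit_df = audit_frame(audit)

    stages = {
        "businesses": inclusion.business_counts.as_dict(),
        "chains": inclusion.chain_counts.as_dict(),
        "documents": document_counts.as_dict(),
        "records": {w: c.as_dict() for w, c in record_counts.items()},
    }
    conserved = (
        inclusion.business_counts.conserved()
        and inclusion.chain_counts.conserved()
        and document_counts.conserved()
        and all(c.conserved() for c in record_counts.values())
    )
    run_manifest = {
        "tool_version": __version__,
        "config_hash": _config_hash(
            {
                "seed": seed,
                "waves": waves,
                "energy_meal_kcal": energy_meal_kcal,
                "intakes": {n: intakes.daily(n) for n in ("energy", "fat", "saturated_fat", "carbohydrate", "sugar", "salt")},
                "dataset_manifest": manifest_in.get("config", {}),
            }
        ),
        "seed": seed,
        "stages": stages,
        "counts_conserved": conserved,
        "chain_selections": selections,
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
    }

    if write:
        availability.to_csv(out / "availability.csv", index=False)
        exceedance.to_csv(out / "exceedance.csv", index=False)
        audit_df.to_csv(out / "exclusion_audit.csv", index=False)
        with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
            json.dump(run_manifest, fh, indent=1)
            fh.write("\n")

    return RunResult(
        masters=masters,
        availability=availability,
        exceedance=exceedance,
        audit=audit_df,
        manifest=run_manifest,
        included_chains=inclusion.included_chains,
        analyzed_chains=analyzed_chains,
    )
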