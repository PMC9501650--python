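"""Inclusion criteria for businesses, chains, menus and documents.

Two sampling frames define the survey population: all businesses with 250
or more employees (the population covered by the UK calorie-labelling
policy), supplemented by the top-100 restaurants by sales volume.  Within
an included business, each chain (brand) is included if it publishes
nutrition information online; franchise operators are excluded unless the
franchisor's chain has not been captured, since franchisees typically serve
the franchisor's menu.  For each chain the main menu (plus children's and
promotional menus) at a fixed location is used, and a nutrition document is
considered stale once it is more than 3 calendar years older than the wave.

Every decision carries exactly one machine-readable reason code so that an
exclusion audit can be reconstructed from the run outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from dateutil.relativedelta import relativedelta

#: Years after which an undated refresh makes a nutrition document invalid.
STALENESS_YEARS = 3
EMPLOYEE_THRESHOLD = 250


class MenuSelectionError(ValueError):
    """No main menu could be identified for a chain."""


@dataclass(frozen=True)
class Decision:
    include: bool
    reason: str

    def __bool__(self) -> bool:
        return self.include


@dataclass
class BusinessMeta:
    """Business attributes driving frame-level inclusion."""

    name: str
    employee_count: int
    sic_code: str = ""
    chains: list[str] = field(default_factory=list)
    provides_nutrition_online: dict[str, bool] = field(default_factory=dict)
    franchisee_of: str | None = None
    sales_rank: int | None = None  # top-100 sales frame, 1..100

    def __post_init__(self) -> None:
        if self.employee_count < 0:
            raise ValueError("employee_count must be non-negative")
        if self.sales_rank is not None and not 1 <= self.sales_rank <= 100:
            raise ValueError("sales_rank must lie in [1, 100]")


@dataclass(frozen=True)
class MenuDoc:
    """One menu/nutrition document observed at a collection wave."""

    chain: str
    menu_name: str
    menu_type: str  # main | children | promotional | delivery | other
    wave_date: date
    location: str = ""
    last_updated: date | None = None

    def __post_init__(self) -> None:
        if self.last_updated is not None and self.wave_date < self.last_updated:
            raise ValueError("wave_date precedes document last_updated")


def include_business(meta: BusinessMeta) -> Decision:
    """Frame-level inclusion: >=250 employees, or present in the top-100 frame."""
    if meta.employee_count >= EMPLOYEE_THRESHOLD:
        return Decision(True, "employees_ge_250")
    if meta.sales_rank is not None:
        return Decision(True, "top100_sales_rank")
    return Decision(False, "below_employee_threshold")


def include_chain(chain: str, meta: BusinessMeta, captured: Iterable[str]) -> Decision:
    """Chain-level inclusion within an included business.

    A chain is excluded when it does not publish nutrition information
    online, or when it is a franchise operation of a chain that is already
    captured; a franchisee of an uncaptured chain is retained so the brand
    is represented at all.
    """
    if not meta.provides_nutrition_online.get(chain, False):
        return Decision(False, "no_online_nutrition")
    if meta.franchisee_of is not None:
        if meta.franchisee_of in set(captured):
            return Decision(False, "franchisee_of_captured_chain")
        return Decision(True, "franchisee_of_uncaptured_chain")
    return Decision(True, "online_nutrition")


def document_valid(doc: MenuDoc) -> bool:
    """A document is invalid only when last updated more than 3 years before
    the wave (calendar comparison, day precision; exactly 3 years is valid).
    Documents without a timestamp are retained."""
    if doc.last_updated is None:
        return True
    cutoff = doc.wave_date - relativedelta(years=STALENESS_YEARS)
    return doc.last_updated >= cutoff


def _chain_rng(chain: str, seed: int) -> np.random.Generator:
    # Stable per-chain stream: the same (chain, seed) pair selects the same
    # location in every wave.
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(chain.encode("utf-8"))])
    )


def select_menus(
    menus: Sequence[tuple[str, str]],
    locations: Sequence[str],
    chain: str,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], str]:
    """Select the menus and the location representing a chain.

    ``menus`` is a sequence of ``(menu_name, menu_type)`` pairs.  The main
    menu is required; children's and promotional menus are added when
    present.  The location is the first listed London location, or a
    seeded-random one for chains with no London presence; it is stable
    across waves for a given seed.
    """
    if not menus:
        raise MenuSelectionError(f"no menus available for chain {chain!r}")
    main = [m for m in menus if m[1] == "main"]
    if not main:
        raise MenuSelectionError(f"no main menu identifiable for chain {chain!r}")
    selected = main[:1] + [m for m in menus if m[1] in ("children", "promotional")]

    location = ""
    if locations:
        london = [loc for loc in locations if "london" in loc.casefold()]
        if london:
            location = london[0]
        else:
            location = locations[int(_chain_rng(chain, seed).integers(len(locations)))]
    return selected, location


@dataclass(frozen=True)
class AuditEntry:
    entity: str
    entity_type: str  # business | chain | document
    stage: str
    included: bool
    reason: str


def audit_frame(entries: Iterable[AuditEntry]) -> pd.DataFrame:
    """Exclusion audit as a delimited-text-ready table."""
    return pd.DataFrame(
        [
            {
                "entity": e.entity,
                "entity_type": e.entity_type,
                "stage": e.stage,
                "included": e.included,
                "reason": e.reason,
            }
            for e in entries
        ],
        columns=["entity", "entity_type", "stage", "included", "reason"],
    )
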