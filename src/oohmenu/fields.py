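"""Field-name standardization.

Each chain publishes its nutrition table with its own headers ("sugar",
"sugars", "sugar content", "Energy (kJ)", "Fat per 100g", ...).  Headers
are normalized (case-fold, trim, collapse internal whitespace, underscores
to spaces) and looked up in a many-to-one synonym map onto a fixed canonical
field set.  Two refinements:

* a per-100g marker ("per 100g", "/100g") is detected and stripped first and
  re-attached to the canonical name as a ``_per_100g`` suffix, so the same
  synonyms serve both the per-serving and the nutrient-density panel;
* a trailing unit parenthetical is only stripped as a fallback, so that
  "Energy (kJ)" can route to the kJ canonical field while "Fat (g)" falls
  back to "fat".

Unmapped headers are returned as ``None`` and must be reported by callers,
never silently dropped.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

#: Canonical per-serving nutrient fields (energy is carried in kcal).
NUTRIENT_FIELDS = (
    "energy_kcal",
    "energy_kj",
    "fat",
    "saturated_fat",
    "carbohydrate",
    "sugar",
    "protein",
    "salt",
    "fiber",
)

META_FIELDS = ("item_id", "item_name", "menu_section", "item_description")

CANONICAL_FIELDS = frozenset(NUTRIENT_FIELDS + META_FIELDS + ("serving_weight",))

_PER100_RE = re.compile(r"\s*(?:\(?\s*per\s*100\s*g\s*\)?|/\s*100\s*g)\s*$")
_PAREN_RE = re.compile(r"\s*\([^)]*\)\s*$")
_WS_RE = re.compile(r"\s+")


def normalize_header(header: str) -> tuple[str, bool]:
    """Return ``(normalized_text, per_100g)`` for a raw header.

    Normalization: case-fold, underscores to spaces, collapse whitespace,
    trim; a trailing per-100g marker is stripped and reported via the flag.
    """
    text = _WS_RE.sub(" ", header.casefold().replace("_", " ")).strip()
    stripped = _PER100_RE.sub("", text)
    per100 = stripped != text
    return stripped.strip(), per100


class FieldSynonymMap:
    """Many-to-one map from normalized header text to canonical field names."""

    def __init__(self, mapping: Mapping[str, str]):
        bad = sorted(set(mapping.values()) - CANONICAL_FIELDS)
        if bad:
            raise ValueError(f"synonym map targets unknown canonical fields: {bad}")
        self._mapping = dict(mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FieldSynonymMap":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "FieldSynonymMap":
        """The synonym map shipped with the package."""
        ref = resources.files("oohmenu.data").joinpath("synonyms.yaml")
        return cls(yaml.safe_load(ref.read_text(encoding="utf-8")))

    def headers(self) -> Iterable[str]:
        return self._mapping.keys()

    def lookup(self, normalized: str) -> str | None:
        return self._mapping.get(normalized)


def standardize_field_name(header: str, synonyms: FieldSynonymMap) -> str | None:
    """Map a raw header to its canonical field name, or ``None`` if unmapped.

    Per-100g headers map to ``<canonical>_per_100g``.  Deterministic; the
    unit parenthetical is stripped only when the full normalized header has
    no entry, so unit-bearing synonyms ("energy (kj)") take precedence.
    """
    if not header or not header.strip():
        raise ValueError("header must be non-empty")
    normalized, per100 = normalize_header(header)
    canonical = synonyms.lookup(normalized)
    if canonical is None:
        bare = _PAREN_RE.sub("", normalized).strip()
        if bare and bare != normalized:
            canonical = synonyms.lookup(bare)
    if canonical is None:
        return None
    if per100:
        return canonical + "_per_100g"
    return canonical
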