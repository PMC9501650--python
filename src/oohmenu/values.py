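"""Parsing of verbatim nutrition cell text into numeric values.

Menu nutrition tables published online carry three kinds of cells: plain
numerals (possibly with thousands separators or a trailing unit token),
operator-prefixed values such as ``"<0.05"`` used by chains to declare trace
amounts, and missing-value markers (a dash or an empty cell).  Parsing keeps
the verbatim text alongside the numeric interpretation so that every
downstream value remains auditable back to its source cell.

Operator handling is conservative: ``"<0.05"`` is read as 0.05 with a
less-than flag, i.e. the bound itself is used as the value.  ``">"`` is
handled symmetrically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

#: Cell contents that denote a missing value (after stripping whitespace).
MISSING_MARKERS = frozenset({"", "-", "–", "—"})

_VALUE_RE = re.compile(
    r"""^\s*
        (?P<op>[<>]?)\s*
        (?P<num>(?:\d{1,3}(?:,\d{3})+|\d+)(?:\.\d+)?|\.\d+)\s*
        (?P<unit>g|mg|kcal|kj)?\s*$""",
    re.IGNORECASE | re.VERBOSE,
)


class NutrientParseError(ValueError):
    """Raised for non-missing cell text that cannot be read as a number."""

    def __init__(self, verbatim: str, record_id: str | None = None):
        self.verbatim = verbatim
        self.record_id = record_id
        where = f" in record {record_id!r}" if record_id else ""
        super().__init__(f"unparseable nutrition value {verbatim!r}{where}")


@dataclass(frozen=True)
class ValueParse:
    """A parsed nutrition cell: numeric value, operator flag, verbatim text.

    ``value is None`` means the cell was missing; an operator flag is only
    ever set when a numeric value is present.
    """

    value: float | None
    operator: str  # "", "<" or ">"
    verbatim: str

    @property
    def missing(self) -> bool:
        return self.value is None

    def __post_init__(self) -> None:
        if self.value is None and self.operator:
            raise ValueError("operator flag requires a numeric value")


#: Reusable singleton for an absent cell with no verbatim source.
MISSING = ValueParse(None, "", "")


def parse_nutrient_value(raw: str | None, record_id: str | None = None) -> ValueParse:
    """Parse one verbatim cell into a :class:`ValueParse`.

    Rules: ``"<x"`` yields x with a less-than flag (``">"`` symmetric);
    a dash or blank cell is missing; plain numerals may carry thousands
    separators and a trailing unit token (``g``, ``kcal``, ``kJ``).
    Anything else raises :class:`NutrientParseError` carrying the verbatim
    text and the record identifier.
    """
    if raw is None:
        return ValueParse(None, "", "")
    text = raw.strip()
    if text in MISSING_MARKERS:
        return ValueParse(None, "", raw)
    m = _VALUE_RE.match(text)
    if not m:
        raise NutrientParseError(raw, record_id)
    number = float(m.group("num").replace(",", ""))
    return ValueParse(number, m.group("op"), raw)
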