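"""Chemical-formula arithmetic for dose normalization.

Supplement doses are normalized by elemental content (carbon for C-source
screens, nitrogen for N-source screens), so the only chemistry needed here
is counting atoms in Hill-style condensed formulas such as ``C8H14ClN5``
(atrazine). Parentheses, hydrates and charges are not part of the grammar:
the formulas in metabolite tables are plain element/count runs.
"""

from __future__ import annotations

import re

__all__ = ["FormulaError", "parse_formula", "element_count"]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when a formula string does not match the element/count grammar."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a condensed formula into an element -> count map.

    An empty string means unknown composition and parses to ``{}``.
    Counts default to 1 (``Cl`` -> ``{"Cl": 1}``); repeated element
    symbols accumulate. A malformed token raises :class:`FormulaError`
    naming the offending position.
    """
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        m = _TOKEN.match(formula, pos)
        if m is None:
            raise FormulaError(
                f"malformed formula {formula!r}: unexpected character "
                f"{formula[pos]!r} at position {pos}"
            )
        element, digits = m.groups()
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(
                f"malformed formula {formula!r}: zero count for {element} "
                f"at position {pos}"
            )
        counts[element] = counts.get(element, 0) + n
        pos = m.end()
    return counts


def element_count(formula: str, element: str) -> int:
    """Number of atoms of ``element`` in ``formula`` (0 if absent)."""
    return parse_formula(formula).get(element, 0)
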