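"""Elemental-composition parsing and Hill-notation formatting.

A composition is a plain ``dict`` mapping element symbol to a positive
integer count.  The default element alphabet covers common metabolite
space; symbols outside the configured alphabet raise rather than being
dropped silently.
"""

from __future__ import annotations

import re

DEFAULT_ALPHABET: tuple[str, ...] = ("C", "H", "N", "O", "P", "S", "F", "Cl", "Br", "I")

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when a molecular-formula string cannot be interpreted."""


def parse_formula(s: str, alphabet: tuple[str, ...] = DEFAULT_ALPHABET) -> dict[str, int]:
    """Parse a molecular formula like ``C6H12O6`` into ``{'C': 6, 'H': 12, 'O': 6}``.

    Repeated element tokens accumulate.  Raises :class:`FormulaError` on
    malformed input or on elements outside *alphabet*.
    """
    s = s.strip()
    if not s:
        raise FormulaError("empty formula string")
    pos = 0
    counts: dict[str, int] = {}
    for m in _TOKEN.finditer(s):
        if m.start() != pos:
            raise FormulaError(f"unparsable formula {s!r} at position {pos}")
        sym, digits = m.group(1), m.group(2)
        if sym not in alphabet:
            raise FormulaError(f"element {sym!r} in {s!r} outside alphabet {alphabet}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"non-positive count for {sym!r} in {s!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    if pos != len(s):
        raise FormulaError(f"unparsable formula {s!r} at position {pos}")
    if not counts:
        raise FormulaError(f"no elements found in {s!r}")
    return counts


def format_formula(counts: dict[str, int]) -> str:
    """Format a composition in Hill notation.

    Carbon first, hydrogen second, the rest alphabetically; when no carbon
    is present all elements (including H) are alphabetical.  Unit counts
    are written without a digit.
    """
    if not counts or all(v == 0 for v in counts.values()):
        raise FormulaError("empty composition")
    items = {k: v for k, v in counts.items() if v > 0}
    if any(v < 0 for v in counts.values()):
        raise FormulaError("negative element count")
    if "C" in items:
        order = ["C"] + (["H"] if "H" in items else []) + sorted(
            k for k in items if k not in ("C", "H")
        )
    else:
        order = sorted(items)
    return "".join(f"{k}{items[k]}" if items[k] > 1 else k for k in order)


def canonical_formula(f: str | dict[str, int],
                      alphabet: tuple[str, ...] = DEFAULT_ALPHABET) -> str:
    """Canonical Hill-notation string for a formula string or composition dict."""
    if isinstance(f, str):
        f = parse_formula(f, alphabet)
    return format_formula(f)
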