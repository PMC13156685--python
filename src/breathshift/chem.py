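"""Elemental masses, formula handling, and heuristic formula filtering.

Monoisotopic atomic masses follow the IUPAC/CODATA values for the most
abundant isotope of each element.  Masses are in daltons (Da).
"""

from __future__ import annotations

import re

# Monoisotopic masses of the most abundant isotopes (Da).
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "F": 18.99840322,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "I": 126.904473,
}

#: Mass of a proton (Da); added/removed on (de)protonation.
PROTON_MASS = 1.00727646677
#: Mass difference between 13C and 12C (Da); one 13C substitution.
C13_DELTA = 1.0033548378

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a plain molecular formula like ``C6H14N4O2`` into counts."""
    pos = 0
    counts: dict[str, int] = {}
    for m in _TOKEN_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        if not m.group(1):
            break
        element, n = m.group(1), m.group(2)
        if element not in ATOMIC_MASSES:
            raise ValueError(f"unknown element {element!r} in {formula!r}")
        counts[element] = counts.get(element, 0) + (int(n) if n else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def formula_to_string(counts: dict[str, int]) -> str:
    order = ["C", "H"] + sorted(e for e in counts if e not in ("C", "H"))
    return "".join(
        f"{e}{counts[e] if counts[e] != 1 else ''}" for e in order if counts.get(e, 0) > 0
    )


def monoisotopic_mass(formula: dict[str, int] | str) -> float:
    """Monoisotopic (exact) mass of a neutral formula, in Da."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    try:
        return sum(ATOMIC_MASSES[e] * n for e, n in counts.items())
    except KeyError as exc:  # pragma: no cover - guarded by parse_formula
        raise ValueError(f"unknown element {exc.args[0]!r}") from exc


def rdbe(counts: dict[str, int]) -> float:
    """Ring-and-double-bond equivalents for a CHNOPS(+halogen) formula."""
    halogens = sum(counts.get(x, 0) for x in ("F", "Cl", "Br", "I"))
    return (
        counts.get("C", 0)
        - (counts.get("H", 0) + halogens) / 2.0
        + counts.get("N", 0) / 2.0
        + 1.0
    )


# Element-count caps for small molecules (< ~500 Da range), per the heuristic
# filtering rules commonly applied to formulas from accurate-mass data.
_ELEMENT_CAPS = {"C": 39, "H": 72, "N": 20, "O": 20, "P": 9, "S": 10,
                 "F": 16, "Cl": 10, "Br": 4, "I": 6}


def golden_rules_filter(formula: dict[str, int] | str) -> tuple[bool, list[str]]:
    """Heuristic plausibility filter for molecular formulas.

    Applies the formula-only subset of the "seven golden rules" used to
    screen candidate formulas from accurate-mass measurements: element-count
    ranges, ring-and-double-bond (valence) plausibility, H/C and
    heteroatom/C ratio windows, and a joint multi-heteroatom check.
    Isotope-pattern rules are not applicable to single centroid features and
    are deliberately out of scope.

    Returns ``(passed, failed_rules)`` where ``failed_rules`` names each
    violated rule.
    """
    counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    for element in counts:
        if element not in ATOMIC_MASSES:
            raise ValueError(f"unknown element {element!r}")
    failed: list[str] = []

    c = counts.get("C", 0)
    h = counts.get("H", 0)
    n = counts.get("N", 0)
    o = counts.get("O", 0)
    p = counts.get("P", 0)
    s = counts.get("S", 0)

    for element, cap in _ELEMENT_CAPS.items():
        if counts.get(element, 0) > cap:
            failed.append(f"element_count:{element}")
    if c == 0:
        failed.append("element_count:C")

    r = rdbe(counts)
    if r < 0:
        failed.append("rdbe_negative")
    # RDBE of a neutral even-electron molecule is integer or half-integer;
    # reject only clearly inconsistent (non multiple-of-0.5) values.
    if abs(r * 2 - round(r * 2)) > 1e-9:
        failed.append("rdbe_noninteger")

    if c > 0:
        if not (0.2 <= h / c <= 3.1):
            failed.append("h_c_ratio")
        if n / c > 1.3:
            failed.append("n_c_ratio")
        if o / c > 1.2:
            failed.append("o_c_ratio")
        if p / c > 0.3:
            failed.append("p_c_ratio")
        if s / c > 0.8:
            failed.append("s_c_ratio")

    # Joint heteroatom heuristic: when several heteroatoms co-occur in
    # quantity, their counts are individually restricted.
    if n > 1 and o > 1 and p > 1 and s > 1:
        if n >= 10 or o >= 20 or p >= 4 or s >= 3:
            failed.append("nops_all")
    if n > 3 and o > 3 and p > 3 and not (n < 11 and o < 22 and p < 6):
        failed.append("nop_joint")
    if o > 1 and p > 1 and s > 1 and not (o < 14 and p < 3 and s < 3):
        failed.append("ops_joint")
    if p > 1 and s > 1 and n > 1 and not (p < 3 and s < 3 and n < 4):
        failed.append("psn_joint")
    if n > 6 and o > 6 and s > 6 and not (n < 19 and o < 14 and s < 8):
        failed.append("nos_joint")

    return (len(failed) == 0, failed)
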