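"""Isotope constants, fragment specifications and the fragment registry.

Natural-abundance correction of GC/MS mass-isotopomer data needs, for every
measured fragment, (i) the elemental formula of the derivatized ion actually
scanned and (ii) the natural isotope abundances of each element in it.
TBDMS (MTBSTFA) derivatization adds C, H and Si to the analyte, so silicon
isotopes contribute mass shifts well beyond the number of tracer carbons.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "IsotopeTable",
    "FragmentSpec",
    "DEFAULT_ISOTOPES",
    "load_fragment_registry",
    "default_fragment_registry",
]

_ATOL = 1e-9

# IUPAC 2021 representative natural abundances, indexed by integer mass
# shift above the monoisotopic species.
_NATURAL_ABUNDANCES: dict[str, tuple[tuple[int, float], ...]] = {
    "C": ((0, 0.9893), (1, 0.0107)),
    "H": ((0, 0.999885), (1, 0.000115)),
    "N": ((0, 0.99636), (1, 0.00364)),
    "O": ((0, 0.99757), (1, 0.00038), (2, 0.00205)),
    "Si": ((0, 0.92223), (1, 0.04685), (2, 0.03092)),
    "S": ((0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001)),
}


@dataclass(frozen=True)
class IsotopeTable:
    """Per-element isotope mass-shift distributions plus tracer properties.

    Parameters
    ----------
    abundances
        element symbol -> tuple of ``(mass_shift, fraction)`` pairs.  Each
        element's fractions must sum to 1.
    tracer_element
        Element carrying the label (carbon for U-13C tracers).
    tracer_purity
        Isotopic purity of the tracer, i.e. the probability that a
        nominally labelled position actually carries the heavy isotope.
    """

    abundances: Mapping[str, tuple[tuple[int, float], ...]]
    tracer_element: str = "C"
    tracer_purity: float = 0.99

    def __post_init__(self) -> None:
        for el, pairs in self.abundances.items():
            total = sum(p for _, p in pairs)
            if abs(total - 1.0) > _ATOL:
                raise ValueError(
                    f"abundances for element {el!r} sum to {total!r}, not 1"
                )
            for shift, frac in pairs:
                if shift < 0 or int(shift) != shift:
                    raise ValueError(
                        f"element {el!r}: mass shift {shift!r} must be a "
                        "non-negative integer"
                    )
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(f"element {el!r}: abundance {frac!r} not in [0,1]")
        if not 0.0 < self.tracer_purity <= 1.0:
            raise ValueError(f"tracer purity {self.tracer_purity!r} not in (0, 1]")
        if self.tracer_element not in self.abundances:
            raise ValueError(f"tracer element {self.tracer_element!r} has no abundances")

    def shifts_and_fractions(self, element: str) -> tuple[tuple[int, float], ...]:
        try:
            return tuple(self.abundances[element])
        except KeyError:
            raise KeyError(
                f"element {element!r} missing from isotope table"
            ) from None


DEFAULT_ISOTOPES = IsotopeTable(abundances=_NATURAL_ABUNDANCES)

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse ``'C19H42NO4Si3'`` into ``{'C': 19, 'H': 42, ...}``."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        if not m.group(0):
            break
        el = m.group(1)
        counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
        pos = m.end()
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


@dataclass(frozen=True)
class FragmentSpec:
    """A derivatized GC/MS fragment of one metabolite.

    ``n_tracer_carbons`` counts only carbons originating from the metabolite
    backbone; derivatization carbons (TBDMS, methoxyamine) can carry natural
    13C but never tracer label.
    """

    metabolite: str
    formula: Mapping[str, int]
    n_tracer_carbons: int
    note: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.formula, str):  # convenience: accept Hill strings
            object.__setattr__(self, "formula", parse_formula(self.formula))
        for el, n in self.formula.items():
            if n < 0:
                raise ValueError(f"{self.metabolite}: negative count for {el}")
        if self.n_tracer_carbons < 1:
            raise ValueError(
                f"{self.metabolite}: n_tracer_carbons must be >= 1 "
                f"(got {self.n_tracer_carbons})"
            )
        if self.n_tracer_carbons > self.formula.get("C", 0):
            raise ValueError(
                f"{self.metabolite}: n_tracer_carbons "
                f"({self.n_tracer_carbons}) exceeds carbon count "
                f"({self.formula.get('C', 0)})"
            )

    @property
    def total_atoms(self) -> int:
        return sum(self.formula.values())


def load_fragment_registry(path) -> dict[str, FragmentSpec]:
    """Load a YAML fragment registry: metabolite -> {formula, n_tracer_carbons, note}."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    registry: dict[str, FragmentSpec] = {}
    for name, entry in raw.items():
        registry[name] = FragmentSpec(
            metabolite=name,
            formula=parse_formula(entry["formula"]),
            n_tracer_carbons=int(entry["n_tracer_carbons"]),
            note=entry.get("note", ""),
        )
    return registry


def default_fragment_registry() -> dict[str, FragmentSpec]:
    """Registry of typical TBDMS (M-57) fragments for the assayed metabolites."""
    ref = resources.files("oncoflux") / "data" / "fragments.yaml"
    with resources.as_file(ref) as path:
        return load_fragment_registry(path)
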