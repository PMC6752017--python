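"""Elemental formulas, degree-of-reduction electron accounting, and unit conversions.

The degree of reduction of a compound is the number of electrons released per
carbon atom on complete oxidation to CO2, H2O and NH3.  With those reference
states the element weights are +4 per C, +1 per H, -2 per O and -3 per N
(+6 per S when present; P is redox-inert here and weighted 0).  Fermentation
balances in anoxic gut-content microcosms use this bookkeeping to check that
the electrons in the products account for the electrons in the consumed
substrate: e.g. glutamate (C5H9NO4) carries (4*5 + 9 - 2*4 - 3)/5 = 3.6
electrons per carbon.

Amounts throughout the package are expressed per gram fresh weight (FW) of
gut content; :func:`convert_amount` moves between that unit, millimolar in
the slurry aqueous phase, and per gram dry weight (DW).
"""

from __future__ import annotations

import math
import re
import tomllib
import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Mapping

__all__ = [
    "FormulaError",
    "ElementalFormula",
    "Compound",
    "AmountUnit",
    "SlurryParams",
    "parse_formula",
    "degree_of_reduction_per_carbon",
    "electrons_per_molecule",
    "convert_amount",
    "cytoplasm_concentration",
    "load_registry",
    "default_registry",
]

#: Elements accepted in formulas, in canonical rendering order.
_ELEMENTS = ("C", "H", "N", "O", "S", "P")

#: Degree-of-reduction weights (references CO2, H2O, NH3; S as sulfate).
_DOR_WEIGHTS = {"C": 4.0, "H": 1.0, "N": -3.0, "O": -2.0, "S": 6.0, "P": 0.0}


class FormulaError(ValueError):
    """Raised for malformed or chemically unsupported formulas."""


@dataclass
class ElementalFormula:
    """Element -> count mapping for a molecular formula over C, H, N, O, S, P."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        counts = {e: int(n) for e, n in dict(self.counts).items() if n}
        for element, n in counts.items():
            if element not in _ELEMENTS:
                raise FormulaError(f"unknown element {element!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {element!r}")
        if not counts:
            raise FormulaError("formula must contain at least one atom")
        self.counts = counts

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    @property
    def carbons(self) -> int:
        return self["C"]

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for element, n in other.counts.items():
            merged[element] = merged.get(element, 0) + n
        return ElementalFormula(merged)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ElementalFormula) and self.counts == other.counts

    def __str__(self) -> str:
        parts = []
        for element in _ELEMENTS:
            n = self[element]
            if n == 1:
                parts.append(element)
            elif n > 1:
                parts.append(f"{element}{n}")
        return "".join(parts)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string such as ``"C5H9NO4"``.

    Implicit counts default to 1 (``"CH2O2"`` is formate).  Malformed input
    or an element outside C/H/N/O/S/P raises :class:`FormulaError` naming the
    failing position.
    """
    if not isinstance(text, str) or not text:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        element, digits = m.group(1), m.group(2)
        if element not in _ELEMENTS:
            raise FormulaError(
                f"unknown element {element!r} in {text!r} at position {pos}"
            )
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementalFormula(counts)


def degree_of_reduction_per_carbon(f: ElementalFormula) -> float:
    """Electrons available per carbon atom on full oxidation to CO2/H2O/NH3.

    ``(4*C + 1*H - 2*O - 3*N + 6*S) / C``; undefined for carbon-free species
    (use :func:`electrons_per_molecule` for H2).
    """
    if f.carbons < 1:
        raise FormulaError(
            "degree of reduction per carbon is undefined for a carbon-free "
            "formula; use electrons_per_molecule instead"
        )
    if f["P"]:
        warnings.warn(
            "phosphorus is weighted 0 in the degree-of-reduction convention",
            stacklevel=2,
        )
    total = sum(_DOR_WEIGHTS[e] * n for e, n in f.counts.items())
    return total / f.carbons


@dataclass
class Compound:
    """A substrate or product with its electron bookkeeping.

    Either ``formula`` or an explicit ``carbons`` count must be given.  For
    defined molecules the electrons per carbon follow from the formula; for
    mixtures (Casamino Acids, an acid casein hydrolysate) ``mixture=True``
    allows an explicit ``electrons_per_carbon`` override (the study value is
    4.2 e-/C) together with a nominal carbons-per-"molecule" basis.
    """

    name: str
    formula: ElementalFormula | None = None
    carbons: float | None = None
    electrons_per_carbon: float | None = None
    molar_mass: float | None = None
    mixture: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.formula, str):
            self.formula = parse_formula(self.formula)
        if self.formula is None and self.carbons is None:
            raise ValueError(f"{self.name}: need a formula or an explicit carbon count")
        if self.carbons is None:
            self.carbons = float(self.formula.carbons)
        if self.carbons < 0:
            raise ValueError(f"{self.name}: carbons must be >= 0")
        if self.electrons_per_carbon is not None and self.electrons_per_carbon < 0:
            raise ValueError(f"{self.name}: electrons per carbon must be >= 0")
        if (
            self.formula is not None
            and self.electrons_per_carbon is not None
            and not self.mixture
            and self.formula.carbons >= 1
        ):
            computed = degree_of_reduction_per_carbon(self.formula)
            if not math.isclose(self.electrons_per_carbon, computed, abs_tol=1e-9):
                raise ValueError(
                    f"{self.name}: electrons-per-carbon override "
                    f"{self.electrons_per_carbon} contradicts the value "
                    f"{computed} computed from {self.formula}; flag the "
                    "compound as a mixture to override"
                )

    @property
    def epc(self) -> float:
        """Electrons per carbon (override if set, else from the formula)."""
        if self.electrons_per_carbon is not None:
            return self.electrons_per_carbon
        if self.formula is not None and self.formula.carbons >= 1:
            return degree_of_reduction_per_carbon(self.formula)
        return 0.0

    @property
    def electrons(self) -> float:
        return electrons_per_molecule(self)


def electrons_per_molecule(c: Compound | ElementalFormula) -> float:
    """Total electrons released per molecule on full oxidation.

    For carbon compounds this is electrons-per-carbon times the carbon count;
    carbon-free species use the same element weights directly (H2 -> 2.0).
    """
    if isinstance(c, ElementalFormula):
        return sum(_DOR_WEIGHTS[e] * n for e, n in c.counts.items())
    if c.electrons_per_carbon is not None:
        return c.electrons_per_carbon * c.carbons
    if c.formula is not None:
        return electrons_per_molecule(c.formula)
    return 0.0


class AmountUnit(str, Enum):
    UMOL_PER_GFW = "umol_per_gFW"
    UMOL_PER_GDW = "umol_per_gDW"
    MM = "mM"


@dataclass(frozen=True)
class SlurryParams:
    """Microcosm slurry composition: 1 g fresh gut content in 10 ml, 45% dry matter."""

    g_fresh_weight: float = 1.0
    volume_ml: float = 10.0
    dry_fraction: float = 0.45

    def __post_init__(self) -> None:
        if min(self.g_fresh_weight, self.volume_ml, self.dry_fraction) <= 0:
            raise ValueError("slurry parameters must be positive")


def convert_amount(
    value: float,
    from_unit: AmountUnit | str,
    to_unit: AmountUnit | str,
    slurry: SlurryParams = SlurryParams(),
) -> float:
    """Convert an amount between umol/gFW, umol/gDW and slurry mM.

    With the default slurry (1 g FW per 10 ml, dry fraction 0.45),
    100 umol/gFW is 10 mM and 222 umol/gDW.
    """
    from_unit = AmountUnit(from_unit)
    to_unit = AmountUnit(to_unit)
    # canonical intermediate: umol per g fresh weight
    if from_unit is AmountUnit.UMOL_PER_GFW:
        per_gfw = value
    elif from_unit is AmountUnit.UMOL_PER_GDW:
        per_gfw = value * slurry.dry_fraction
    else:  # mM == umol per ml slurry
        per_gfw = value * slurry.volume_ml / slurry.g_fresh_weight
    if to_unit is AmountUnit.UMOL_PER_GFW:
        return per_gfw
    if to_unit is AmountUnit.UMOL_PER_GDW:
        return per_gfw / slurry.dry_fraction
    return per_gfw * slurry.g_fresh_weight / slurry.volume_ml


def cytoplasm_concentration(
    dry_fraction: float,
    polymer_fraction_of_dry: float,
    monomer_mw: float,
    monomer_fraction_of_polymer: float = 1.0,
) -> float:
    """Monomer concentration (mol/L) of a polymer pool in microbial cytoplasm.

    Treats cytoplasm as density 1 g/ml, so 1 L holds 1000 g of which
    ``dry_fraction`` is dry matter, ``polymer_fraction_of_dry`` of that is the
    polymer, and ``monomer_fraction_of_polymer`` of the polymer mass is the
    monomer of interest.  With 20% dry matter, 50% protein and a 100 g/mol
    mean residue this reproduces the ~1 M polymeric amino acid estimate for
    a lysed cell's cytoplasm (and ~0.1 M polymeric ribose via 20% RNA of
    which 40% is ribose, MW 150.13).
    """
    for label, frac in (
        ("dry_fraction", dry_fraction),
        ("polymer_fraction_of_dry", polymer_fraction_of_dry),
        ("monomer_fraction_of_polymer", monomer_fraction_of_polymer),
    ):
        if not 0 < frac <= 1:
            raise ValueError(f"{label} must be in (0, 1], got {frac}")
    if monomer_mw <= 0:
        raise ValueError("monomer molecular weight must be positive")
    grams_per_l = 1000.0 * dry_fraction * polymer_fraction_of_dry
    return grams_per_l * monomer_fraction_of_polymer / monomer_mw


# ---------------------------------------------------------------------------
# Compound registry


def _compound_from_spec(name: str, spec: Mapping) -> Compound:
    return Compound(
        name=name,
        formula=spec.get("formula"),
        carbons=spec.get("carbons"),
        electrons_per_carbon=spec.get("electrons_per_carbon"),
        molar_mass=spec.get("molar_mass"),
        mixture=bool(spec.get("mixture", False)),
    )


def load_registry(path) -> dict[str, Compound]:
    """Load a compound registry from a TOML file (one table per compound)."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return {name.lower(): _compound_from_spec(name, spec) for name, spec in raw.items()}


def default_registry() -> dict[str, Compound]:
    """Registry prefilled with every substrate and product of the balance tables."""
    ref = resources.files("fermstoich").joinpath("data/compounds.toml")
    with ref.open("rb") as fh:
        raw = tomllib.load(fh)
    return {name.lower(): _compound_from_spec(name, spec) for name, spec in raw.items()}
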