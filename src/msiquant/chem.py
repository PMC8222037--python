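"""Molecular-formula arithmetic for derivatization-based MSI targets.

Corticosteroids such as budesonide ionize poorly under MALDI.  On-tissue
chemical derivatization with Girard's reagent P (GirP) condenses the C3
ketone with the reagent's hydrazide, losing one water and leaving a
pre-charged pyridinium hydrazone cation that is detected directly.  This
module computes the exact m/z of such derivative cations and of the other
ions used as extraction targets (internal standard, tissue and spot
markers, lock mass) from elemental compositions.

All masses are monoisotopic (most abundant isotope per element, IUPAC
values via :mod:`pyteomics`), and every ion m/z is electron-mass
corrected, as appropriate for Orbitrap-accuracy arithmetic.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Dict, Mapping

from pyteomics.mass import nist_mass

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "MolecularFormula",
    "IonType",
    "IonSpec",
    "GirardReagent",
    "DerivativeSpec",
    "parse_formula",
    "monoisotopic_mass",
    "derivative_mz",
    "ion_mz",
    "girard_mass_shift",
    "builtin_targets",
    "load_target_table",
]

#: CODATA electron mass in Da.
ELECTRON_MASS = 0.000548579909
#: CODATA proton mass in Da (mass of H minus one electron).
PROTON_MASS = 1.007276466

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically unknown formula strings."""


@dataclass(frozen=True)
class MolecularFormula:
    """An elemental composition, e.g. ``C25H34O6`` for budesonide.

    Element counts are non-negative integers; zero-count entries are
    dropped on construction so equal compositions compare equal.
    """

    elements: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: Dict[str, int] = {}
        for el, n in self.elements.items():
            if el not in nist_mass:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"count for {el} must be a non-negative integer, got {n!r}")
            if n > 0:
                clean[el] = n
        object.__setattr__(self, "elements", clean)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.elements)
        for el, n in other.elements.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.elements)
        for el, n in other.elements.items():
            left = merged.get(el, 0) - n
            if left < 0:
                raise FormulaError(f"subtraction would leave negative count for {el}")
            merged[el] = left
        return MolecularFormula(merged)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def hill(self) -> str:
        """Canonical Hill-notation string (C, H, then alphabetical)."""
        els = self.elements
        order = []
        if "C" in els:
            order.append("C")
            if "H" in els:
                order.append("H")
            order.extend(sorted(e for e in els if e not in ("C", "H")))
        else:
            order.extend(sorted(els))
        return "".join(f"{e}{els[e] if els[e] != 1 else ''}" for e in order)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string such as ``"C24H31FO6"``.

    Raises :class:`FormulaError` naming the offending token for unknown
    element symbols or malformed input.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    pos = 0
    counts: Dict[str, int] = {}
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token {text[pos:m.start()]!r}"
            )
        el, digits = m.group(1), m.group(2)
        if not el:
            continue
        if el not in nist_mass:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r}: trailing {text[pos:]!r}")
    if not counts:
        raise FormulaError(f"malformed formula {text!r}: no elements found")
    return MolecularFormula(counts)


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Monoisotopic mass in Da: sum of count x most-abundant-isotope mass."""
    return sum(nist_mass[el][0][0] * n for el, n in f.elements.items())


class IonType(str, enum.Enum):
    """How a neutral composition acquires its charge."""

    PRECHARGED = "pre-charged-cation"  # intact cation, remove z electrons
    PROTONATED = "protonated"          # add z protons
    RADICAL = "radical-cation"         # remove z electrons from the neutral


@dataclass(frozen=True)
class IonSpec:
    """A detectable ion: composition, charge and charging mechanism.

    For pre-charged species (quaternary ammonium cations like tiotropium
    or Girard hydrazones) the formula is the cation's own composition and
    only the electron deficit is corrected.  Instrument software and the
    source study label such ions "[M + H]+" by convention; the arithmetic
    here makes the distinction explicit.
    """

    formula: MolecularFormula
    charge: int = 1
    ion_type: IonType = IonType.PROTONATED

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")


def ion_mz(ion: IonSpec) -> float:
    """m/z of an ion, electron-mass corrected.

    protonated      (M + z*proton)/z
    radical-cation  (M - z*e)/z
    pre-charged     (M - z*e)/z with M the cation composition
    """
    m = monoisotopic_mass(ion.formula)
    z = ion.charge
    if ion.ion_type is IonType.PROTONATED:
        return (m + z * PROTON_MASS) / z
    # both radical and pre-charged: the composition is the charged species
    # minus its missing electrons
    return (m - z * ELECTRON_MASS) / z


class GirardReagent(str, enum.Enum):
    """Girard hydrazide reagents; the value is the cation composition."""

    GirP = "C7H10N3O"  # 1-(2-hydrazinyl-2-oxoethyl)pyridinium
    GirT = "C5H14N3O"  # (2-hydrazinyl-2-oxoethyl)trimethylammonium

    @property
    def cation(self) -> MolecularFormula:
        return parse_formula(self.value)


WATER = MolecularFormula({"H": 2, "O": 1})


@dataclass(frozen=True)
class DerivativeSpec:
    """A steroid-Girard hydrazone derivative (single condensation).

    The hydrazide condenses with one ketone, losing one water; the product
    keeps the reagent's quaternary-nitrogen charge, so the derivative is a
    singly charged, pre-formed cation.
    """

    steroid: MolecularFormula
    reagent: GirardReagent = GirardReagent.GirP
    n_condensations: int = 1

    def __post_init__(self) -> None:
        if self.steroid.elements.get("O", 0) < 1:
            raise FormulaError("steroid formula must contain at least one oxygen (carbonyl)")


def girard_mass_shift(reagent: GirardReagent = GirardReagent.GirP) -> float:
    """Constant m/z shift from neutral steroid to hydrazone cation.

    Equals mass(reagent cation) - mass(H2O) - electron mass; identical for
    every steroid, which is a useful cross-check when assigning peaks.
    """
    return monoisotopic_mass(reagent.cation) - monoisotopic_mass(WATER) - ELECTRON_MASS


def derivative_mz(d: DerivativeSpec) -> float:
    """m/z of the singly charged Girard hydrazone cation.

    Only single condensation of a singly charged product is supported;
    anything else raises ``NotImplementedError``.
    """
    if d.n_condensations != 1:
        raise NotImplementedError(
            f"only n_condensations=1 supported, got {d.n_condensations}"
        )
    return monoisotopic_mass(d.steroid) + girard_mass_shift(d.reagent)


# ---------------------------------------------------------------------------
# Target tables

#: Roles a target can play downstream.
TARGET_ROLES = ("analyte", "internal_standard", "spot_marker", "tissue_marker", "lock_mass")


@dataclass(frozen=True)
class Target:
    name: str
    mz: float
    role: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.role not in TARGET_ROLES:
            raise ValueError(f"unknown target role {self.role!r}")


def builtin_targets() -> Dict[str, Target]:
    """The study's five extraction targets, m/z computed, not hard-coded.

    budesonide-GirP and triamcinolone-acetonide-GirP hydrazone cations,
    the tiotropium spot marker, the heme B tissue marker (modeled as a
    radical cation M+.; reported elsewhere under the conventional [M+H]+
    label) and the protonated ferulic-acid lock mass.
    """
    bud = parse_formula("C25H34O6")
    ta = parse_formula("C24H31FO6")
    return {
        "BUD-GirP": Target(
            "BUD-GirP", derivative_mz(DerivativeSpec(bud)), "analyte",
            "budesonide Girard-P hydrazone cation"),
        "TA-GirP": Target(
            "TA-GirP", derivative_mz(DerivativeSpec(ta)), "internal_standard",
            "triamcinolone acetonide Girard-P hydrazone cation"),
        "tiotropium": Target(
            "tiotropium",
            ion_mz(IonSpec(parse_formula("C19H22NO4S2"), 1, IonType.PRECHARGED)),
            "spot_marker", "tiotropium quaternary ammonium cation"),
        "hemeB": Target(
            "hemeB",
            ion_mz(IonSpec(parse_formula("C34H32FeN4O4"), 1, IonType.RADICAL)),
            "tissue_marker", "heme B radical cation"),
        "FA": Target(
            "FA",
            ion_mz(IonSpec(parse_formula("C10H10O4"), 1, IonType.PROTONATED)),
            "lock_mass", "protonated ferulic acid (matrix)"),
    }


def load_target_table(rows) -> Dict[str, Target]:
    """Build a target dict from table rows.

    Each row is a mapping with keys ``name``, ``formula_or_mz``,
    ``ion_type`` (ignored when a fixed m/z is given) and ``role``.  A
    ``formula_or_mz`` that parses as a float is used verbatim; otherwise
    it is treated as a Hill formula charged per ``ion_type``.
    """
    out: Dict[str, Target] = {}
    for row in rows:
        name = str(row["name"])
        raw = str(row["formula_or_mz"])
        try:
            mz = float(raw)
        except ValueError:
            ion_type = IonType(row.get("ion_type", IonType.PROTONATED))
            mz = ion_mz(IonSpec(parse_formula(raw), 1, ion_type))
        out[name] = Target(name, mz, str(row["role"]), str(row.get("description", "")))
    return out
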