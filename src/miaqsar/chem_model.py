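"""Congeneric-series chemistry: elements, compounds, 2D assembly, unit conversion.

The modeled series shares a phenyltriazolinone scaffold with four variable
positions: two ring atoms of a fused five-membered heteroaryl (``X`` at ring
position 1 and ``Y`` at ring position 5) and two substituent slots (``R1`` at
the phenyl para position, ``R2`` at heteroaryl positions 3 and/or 5).
Compounds are assembled in 2D from a versioned template library so that every
scaffold atom keeps identical coordinates across the whole series — the
alignment guarantee the pixel descriptors rely on.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

__all__ = [
    "ElementProps",
    "CompoundSpec",
    "Molecule2D",
    "ActivityRecord",
    "TemplateLibrary",
    "element_property",
    "assemble_molecule",
    "molecular_weight",
    "molecular_weight_from_formula",
    "parse_formula",
    "ic50_to_pic50",
    "load_template_library",
    "SULFENTRAZONE_FORMULA",
    "SULFENTRAZONE_IC50_MG_PER_L",
]


@dataclass(frozen=True)
class ElementProps:
    """Per-element constants used for property coding and molar mass."""

    symbol: str
    electronegativity: float  # Pauling scale, dimensionless
    vdw_radius: float  # angstrom
    atomic_mass: float  # g/mol

    def __post_init__(self) -> None:
        if not (0.7 <= self.electronegativity <= 4.0):
            raise ValueError(f"electronegativity out of range for {self.symbol}")
        if self.vdw_radius <= 0 or self.atomic_mass <= 0:
            raise ValueError(f"non-positive constant for {self.symbol}")


# Pauling electronegativities; Bondi van der Waals radii (angstrom);
# IUPAC 2021 standard atomic weights (abridged).  Exactly the elements
# occurring in the series.
ELEMENTS: dict[str, ElementProps] = {
    "H": ElementProps("H", 2.20, 1.20, 1.008),
    "C": ElementProps("C", 2.55, 1.70, 12.011),
    "N": ElementProps("N", 3.04, 1.55, 14.007),
    "O": ElementProps("O", 3.44, 1.52, 15.999),
    "F": ElementProps("F", 3.98, 1.47, 18.998),
    "S": ElementProps("S", 2.58, 1.80, 32.06),
    "Cl": ElementProps("Cl", 3.16, 1.75, 35.45),
    "Br": ElementProps("Br", 2.96, 1.85, 79.904),
}

PROPERTY_KINDS = ("electronegativity", "vdw_radius", "mass")

#: Sulfentrazone, the commercial reference herbicide of the study.
SULFENTRAZONE_FORMULA = "C11H10Cl2F2N4O3S"
SULFENTRAZONE_IC50_MG_PER_L = 0.078

X_CODES = ("S", "O", "CH", "C")
Y_CODES = ("CH", "S", "C")
R1_CODES = ("H", "Cl", "CH3", "CF3", "Br", "F")
R2_CODES = ("H", "3-CH3", "3-Br", "5-CH3", "3,5-CH3")

# R2 table code -> (position-3 substituent, position-5 substituent)
_R2_SPLIT = {
    "H": ("H", "H"),
    "3-CH3": ("CH3", "H"),
    "3-Br": ("Br", "H"),
    "5-CH3": ("H", "CH3"),
    "3,5-CH3": ("CH3", "CH3"),
}


def element_property(symbol: str, kind: str) -> float:
    """Look up a tabulated element constant.

    ``kind`` is one of ``electronegativity`` (Pauling), ``vdw_radius``
    (Bondi, angstrom) or ``mass`` (g/mol).
    """
    try:
        props = ELEMENTS[symbol]
    except KeyError:
        raise KeyError(
            f"unsupported element symbol {symbol!r}; supported: "
            f"{sorted(ELEMENTS)}"
        ) from None
    if kind == "electronegativity":
        return props.electronegativity
    if kind == "vdw_radius":
        return props.vdw_radius
    if kind == "mass":
        return props.atomic_mass
    raise ValueError(f"unknown property kind {kind!r}; expected one of {PROPERTY_KINDS}")


@dataclass(frozen=True)
class CompoundSpec:
    """A series member as substituent choices on the shared scaffold.

    ``X``/``Y`` are the two variable heteroaryl ring atoms, ``R1`` the para
    substituent of the phenyl ring, ``R2`` the heteroaryl 3-/5-substituent
    code as printed in the activity table.  Activities are optional: measured
    compounds carry IC50 (mg/L) and/or pIC50 (-log10 mol/L).
    """

    id: str
    X: str
    Y: str
    R1: str
    R2: str
    ic50_mg_per_L: float | None = None
    pic50: float | None = None

    def __post_init__(self) -> None:
        for value, codes, name in (
            (self.X, X_CODES, "X"),
            (self.Y, Y_CODES, "Y"),
            (self.R1, R1_CODES, "R1"),
            (self.R2, R2_CODES, "R2"),
        ):
            if value not in codes:
                raise ValueError(
                    f"compound {self.id}: {name}={value!r} not in {codes}"
                )
        if self.Y == "S" and _R2_SPLIT[self.R2][1] != "H":
            raise ValueError(
                f"compound {self.id}: R2={self.R2!r} places a substituent at "
                "ring position 5, which is occupied by sulfur (Y=S)"
            )
        if self.ic50_mg_per_L is not None and self.ic50_mg_per_L <= 0:
            raise ValueError(f"compound {self.id}: IC50 must be positive")


@dataclass(frozen=True)
class ActivityRecord:
    """One modeled response value: compound id and pIC50 (-log10 mol/L)."""

    compound_id: str
    y: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.y):
            raise ValueError(f"non-finite activity for {self.compound_id}")


@dataclass(frozen=True)
class Molecule2D:
    """Explicit-hydrogen 2D depiction: atoms, bonds and a scaffold mask.

    ``scaffold_mask[i]`` is True for atoms shared (with identical
    coordinates) by every compound built from the same template library.
    """

    atoms: tuple[tuple[str, float, float], ...]
    bonds: tuple[tuple[int, int, int], ...]
    scaffold_mask: tuple[bool, ...]

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if len(self.scaffold_mask) != n:
            raise ValueError("scaffold_mask length mismatch")
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references missing atom")

    def formula(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for el, _, _ in self.atoms:
            counts[el] = counts.get(el, 0) + 1
        return counts


class TemplateLibrary:
    """Scaffold geometry plus slot attachment rules loaded from JSON."""

    def __init__(self, data: dict):
        self.version = data["version"]
        self.scaffold_atoms = [tuple(a) for a in data["scaffold"]["atoms"]]
        self.scaffold_bonds = [tuple(b) for b in data["scaffold"]["bonds"]]
        self.slots = data["slots"]
        self.substituents = data["substituents"]

    def substituent_codes(self, slot: str) -> list[str]:
        return list(self.slots[slot]["allowed"])


def load_template_library(path: str | None = None) -> TemplateLibrary:
    """Load a template library; default is the packaged phenyltriazolinone set."""
    if path is None:
        text = (
            resources.files("miaqsar.data")
            .joinpath("template_library.json")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    return TemplateLibrary(json.loads(text))


def _rotate(direction: Sequence[float], point: Sequence[float]) -> tuple[float, float]:
    # rotate `point` from the local frame whose +x axis is `direction`
    dx, dy = direction
    norm = math.hypot(dx, dy)
    c, s = dx / norm, dy / norm
    x, y = point
    return (c * x - s * y, s * x + c * y)


def _place_substituent(
    code: str,
    attach_xy: tuple[float, float],
    direction: Sequence[float],
    lib: TemplateLibrary,
    attach_index: int,
    next_index: int,
) -> tuple[list[tuple[str, float, float]], list[tuple[int, int, int]]]:
    tmpl = lib.substituents[code]
    atoms = []
    for el, x, y in tmpl["atoms"]:
        rx, ry = _rotate(direction, (x, y))
        atoms.append((el, round(attach_xy[0] + rx, 4), round(attach_xy[1] + ry, 4)))
    bonds = []
    for i, j, order in tmpl["bonds"]:
        a = attach_index if i == -1 else next_index + i
        b = attach_index if j == -1 else next_index + j
        bonds.append((a, b, order))
    return atoms, bonds


def assemble_molecule(spec: CompoundSpec, templates: TemplateLibrary) -> Molecule2D:
    """Build the 2D molecule for ``spec`` from the template library.

    Scaffold atoms come first, with template coordinates unchanged; slot
    atoms (X, Y, R1, R2) follow in a fixed order so the atom indexing is
    reproducible.  Ring position 5 receives an implicit hydrogen only when it
    is a carbon not carrying an R2 methyl (the table's ``Y=C`` rows are
    exactly the 5-substituted ones).
    """
    atoms: list[tuple[str, float, float]] = [
        (el, x, y) for el, x, y in templates.scaffold_atoms
    ]
    bonds: list[tuple[int, int, int]] = [tuple(b) for b in templates.scaffold_bonds]
    n_scaffold = len(atoms)

    r2_3, r2_5 = _R2_SPLIT[spec.R2]

    # --- ring slot atoms X (position 1) and Y (position 5)
    slot_index: dict[str, int] = {}
    for name, code in (("X", spec.X), ("Y", spec.Y)):
        slot = templates.slots[name]
        if code not in slot["allowed"]:
            raise ValueError(
                f"slot {name}: code {code!r} not in {slot['allowed']}"
            )
        element = "C" if code in ("CH", "C") else code
        px, py = slot["position"]
        slot_index[name] = len(atoms)
        atoms.append((element, px, py))
    for name in ("X", "Y"):
        slot = templates.slots[name]
        for idx in slot["bond_scaffold"]:
            bonds.append((idx, slot_index[name], 1))
        for other in slot["bond_slots"]:
            bonds.append((slot_index[name], slot_index[other], 1))

    # hydrogens on ring slot carbons (position 5 only if unsubstituted)
    for name, code in (("X", spec.X), ("Y", spec.Y)):
        is_carbon = code in ("CH", "C")
        if not is_carbon:
            continue
        if name == "Y" and r2_5 != "H":
            continue  # the 5-substituent replaces this hydrogen
        slot = templates.slots[name]
        hx, hy = slot["h_direction"]
        px, py = slot["position"]
        h_idx = len(atoms)
        atoms.append(("H", round(px + 1.09 * hx, 4), round(py + 1.09 * hy, 4)))
        bonds.append((slot_index[name], h_idx, 1))

    # --- substituent slots
    def place(slot_name: str, code: str) -> None:
        slot = templates.slots[slot_name]
        if code not in slot["allowed"]:
            raise ValueError(
                f"slot {slot_name}: code {code!r} not in {slot['allowed']}"
            )
        if "attach_scaffold" in slot:
            attach_idx = slot["attach_scaffold"]
            ax, ay = templates.scaffold_atoms[attach_idx][1:3]
        else:
            attach_idx = slot_index[slot["attach_slot"]]
            ax, ay = atoms[attach_idx][1], atoms[attach_idx][2]
        new_atoms, new_bonds = _place_substituent(
            code, (ax, ay), slot["direction"], templates, attach_idx, len(atoms)
        )
        atoms.extend(new_atoms)
        bonds.extend(new_bonds)

    place("R1", spec.R1)
    place("R2_3", r2_3)
    if spec.Y != "S" and r2_5 != "H":
        place("R2_5", r2_5)
    # (an unsubstituted carbon position 5 already received its hydrogen above;
    #  Y=S takes no position-5 substituent at all)

    mask = [True] * n_scaffold + [False] * (len(atoms) - n_scaffold)
    return Molecule2D(tuple(atoms), tuple(bonds), tuple(mask))


def molecular_weight(mol: Molecule2D) -> float:
    """Molar mass (g/mol) as the sum of atomic masses."""
    return sum(element_property(el, "mass") for el, _, _ in mol.atoms)


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula such as ``C11H10Cl2F2N4O3S``."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {pos}")
        pos = match.end()
        el, num = match.group(1), match.group(2)
        if el not in ELEMENTS:
            raise KeyError(f"unsupported element {el!r} in formula {formula!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def molecular_weight_from_formula(formula: str) -> float:
    """Molar mass (g/mol) of a molecular formula string."""
    return sum(
        n * element_property(el, "mass") for el, n in parse_formula(formula).items()
    )


def ic50_to_pic50(ic50_mg_per_L: float, mw_g_per_mol: float) -> float:
    """Convert an IC50 in mg/L to pIC50 = -log10 of the molar concentration."""
    if ic50_mg_per_L <= 0:
        raise ValueError("IC50 must be positive")
    if mw_g_per_mol <= 0:
        raise ValueError("molar mass must be positive")
    return -math.log10(ic50_mg_per_L / (1000.0 * mw_g_per_mol))


def check_activity_consistency(
    specs: Iterable[CompoundSpec],
    templates: TemplateLibrary,
    tol: float = 0.01,
) -> dict[str, float]:
    """Verify IC50/pIC50 column agreement for every spec carrying both.

    Returns the per-compound absolute log-unit discrepancy; raises if any
    exceeds ``tol`` (the table's printed precision).
    """
    deviations: dict[str, float] = {}
    for spec in specs:
        if spec.ic50_mg_per_L is None or spec.pic50 is None:
            continue
        mw = molecular_weight(assemble_molecule(spec, templates))
        dev = abs(ic50_to_pic50(spec.ic50_mg_per_L, mw) - spec.pic50)
        deviations[spec.id] = dev
        if dev > tol:
            raise ValueError(
                f"compound {spec.id}: IC50/pIC50 disagree by {dev:.4f} log "
                f"units (> {tol}) at molar mass {mw:.2f}"
            )
    return deviations
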