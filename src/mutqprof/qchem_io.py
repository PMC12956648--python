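"""Q-Chem input-deck generation and output parsing.

Three single-point job flavours are supported, all sharing the same
B3LYP/6-31G* settings and differing in exactly one keyword:

* ESP — CHELPG charges fitted to the molecular electrostatic potential,
* NPA — natural population analysis via the NBO module,
* HOMO_LUMO — frontier orbital energies printed for the gap descriptor.

The parsers accept a documented minimal dialect of the engine's text output
(a ChElPG net-atomic-charges table, an NPA summary table and an
``Orbital Energies (a.u.)`` section with Occupied/Virtual sub-blocks); the
fixtures module emits exactly this dialect, and real engine outputs that
contain the same blocks parse identically. Energies are kept in hartree
internally; eV is a presentation-layer conversion.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import (
    ConsistencyError,
    EmissionError,
    MissingBlockError,
    SpectrumError,
)
from .structure_model import QMFragment

__all__ = [
    "JobFlavour",
    "QChemJobSpec",
    "ChargeSet",
    "OrbitalSpectrum",
    "write_qchem_input",
    "deck_from_xyz",
    "parse_chelpg",
    "parse_npa",
    "parse_orbitals",
    "HARTREE_TO_EV",
    "SHARED_REM",
]

HARTREE_TO_EV = 27.2114

#: Atomic numbers for the elements that occur in capped peptide fragments.
_ATOMIC_NUMBER = {
    "H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "SE": 34,
}


class JobFlavour(str, Enum):
    ESP = "esp"
    NPA = "npa"
    HOMO_LUMO = "homo_lumo"


#: Shared $rem settings, in deck emission order.
SHARED_REM: tuple[tuple[str, str], ...] = (
    ("JOBTYPE", "SP"),
    ("METHOD", "B3LYP"),
    ("BASIS", "6-31G*"),
    ("SCF_CONVERGENCE", "7"),
    ("MAX_SCF_CYCLES", "200"),
    ("SCF_ALGORITHM", "DIIS_GDM"),
    ("SYM_IGNORE", "1"),
    ("NO_REORIENT", "1"),
)

_FLAVOUR_KEYWORD: dict[JobFlavour, tuple[str, str]] = {
    JobFlavour.ESP: ("CHELPG", "TRUE"),
    JobFlavour.NPA: ("NBO", "1"),
    JobFlavour.HOMO_LUMO: ("PRINT_ORBITALS", "TRUE"),
}


@dataclass(frozen=True)
class QChemJobSpec:
    """Parameter set for one single-point job flavour.

    The shared settings are fixed; exactly one flavour-specific keyword is
    active per flavour.
    """

    flavour: JobFlavour
    rem: tuple[tuple[str, str], ...] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "rem", SHARED_REM + (_FLAVOUR_KEYWORD[self.flavour],)
        )

    @property
    def flavour_keyword(self) -> tuple[str, str]:
        return _FLAVOUR_KEYWORD[self.flavour]


def _electron_count(elements: tuple[str, ...], net_charge: int) -> int | None:
    total = 0
    for el in elements:
        z = _ATOMIC_NUMBER.get(el.upper())
        if z is None:
            return None
        total += z
    return total - net_charge


def write_qchem_input(fragment: QMFragment, spec: QChemJobSpec) -> str:
    """Emit the input deck for one fragment and one job flavour.

    The $molecule block starts with ``net_charge multiplicity`` and lists one
    ``Element x y z`` line per atom (6-decimal Å); the $rem block contains the
    shared keywords in fixed order with the flavour keyword last, uppercase
    and single-space separated. Byte-identical across runs for equal inputs.
    """
    if fragment.n_atoms == 0:
        raise EmissionError("cannot emit a deck for an empty fragment")
    n_elec = _electron_count(fragment.elements, fragment.net_charge)
    if n_elec is not None and n_elec % 2 == 1 and fragment.multiplicity == 1:
        warnings.warn(
            f"fragment has an odd electron count ({n_elec}) but multiplicity 1; "
            "check capping and charge assignment",
            stacklevel=2,
        )
    lines = ["$molecule", f"{fragment.net_charge} {fragment.multiplicity}"]
    for atom in fragment.atoms:
        x, y, z = atom.xyz
        lines.append(f"{atom.element:<2s} {x:12.6f} {y:12.6f} {z:12.6f}")
    lines.append("$end")
    lines.append("")
    lines.append("$rem")
    for key, value in spec.rem:
        lines.append(f"{key} {value}")
    lines.append("$end")
    return "\n".join(lines) + "\n"


def deck_from_xyz(
    elements: tuple[str, ...],
    coords,
    net_charge: int,
    flavour: JobFlavour,
    multiplicity: int = 1,
) -> str:
    """Build a deck directly from element symbols and coordinates."""
    from .structure_model import AtomRecord

    atoms = tuple(
        AtomRecord(i + 1, el, el, "UNK", 1, "A",
                   (float(x), float(y), float(z)), 0.0)
        for i, (el, (x, y, z)) in enumerate(zip(elements, np.asarray(coords)))
    )
    frag = QMFragment(atoms=atoms, center=1, window=(1, 1),
                      net_charge=net_charge, multiplicity=multiplicity)
    return write_qchem_input(frag, QChemJobSpec(flavour))


@dataclass(frozen=True)
class ChargeSet:
    """Per-atom partial charges from one population method, in deck atom order."""

    method: str  # "NPA" or "CHELPG"
    charges: tuple[float, ...]
    elements: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.elements and len(self.elements) != len(self.charges):
            raise ConsistencyError("elements/charges length mismatch")
        if any(abs(q) >= 5.0 for q in self.charges):
            raise ConsistencyError("per-atom charge outside the sane |q| < 5 bound")

    @property
    def n_atoms(self) -> int:
        return len(self.charges)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.charges, dtype=float)


@dataclass(frozen=True)
class OrbitalSpectrum:
    """Occupied/virtual orbital energies in hartree, ascending."""

    occupied: tuple[float, ...]
    virtual: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.occupied:
            raise SpectrumError("no occupied orbitals: HOMO undefined")
        if not self.virtual:
            raise SpectrumError("no virtual orbitals: LUMO undefined")
        object.__setattr__(self, "occupied", tuple(sorted(self.occupied)))
        object.__setattr__(self, "virtual", tuple(sorted(self.virtual)))

    @property
    def e_homo(self) -> float:
        return self.occupied[-1]

    @property
    def e_lumo(self) -> float:
        return self.virtual[0]

    @property
    def gap(self) -> float:
        return self.e_lumo - self.e_homo

    @property
    def gap_ev(self) -> float:
        return self.gap * HARTREE_TO_EV


_RULE_RE = re.compile(r"^\s*-{5,}\s*$")
_CHELPG_ROW = re.compile(r"^\s*(\d+)\s+([A-Za-z]{1,2})\s+(-?\d+\.\d+)\s*$")
_NPA_ROW = re.compile(r"^\s*([A-Za-z]{1,2})\s+(\d+)\s+(-?\d+\.\d+)")


def parse_chelpg(text: str) -> ChargeSet:
    """Extract the ChElPG net-atomic-charges table from engine output."""
    lines = text.splitlines()
    start = next(
        (i for i, ln in enumerate(lines)
         if "Ground-State ChElPG Net Atomic Charges" in ln),
        None,
    )
    if start is None:
        raise MissingBlockError("no ChElPG net-atomic-charges block found")
    idx = start + 1
    # skip the ruled header (rule, column titles, rule)
    while idx < len(lines) and not _CHELPG_ROW.match(lines[idx]):
        if idx - start > 6:
            raise MissingBlockError("ChElPG block header malformed or truncated")
        idx += 1
    charges: list[float] = []
    elements: list[str] = []
    closed = False
    for ln in lines[idx:]:
        m = _CHELPG_ROW.match(ln)
        if m:
            index, element, q = m.groups()
            if int(index) != len(charges) + 1:
                raise ConsistencyError(
                    f"non-consecutive atom index {index} in ChElPG table"
                )
            elements.append(element)
            charges.append(float(q))
            continue
        if _RULE_RE.match(ln):
            closed = True
            break
        raise MissingBlockError(f"unexpected line inside ChElPG table: {ln!r}")
    if not closed or not charges:
        raise MissingBlockError("ChElPG table truncated before its closing rule")
    return ChargeSet("CHELPG", tuple(charges), tuple(elements))


def parse_npa(text: str) -> ChargeSet:
    """Extract per-atom natural charges from the NPA summary table."""
    lines = text.splitlines()
    start = next(
        (i for i, ln in enumerate(lines)
         if "Summary of Natural Population Analysis" in ln),
        None,
    )
    if start is None:
        raise MissingBlockError("no Natural Population Analysis summary found")
    idx = start + 1
    while idx < len(lines) and not _NPA_ROW.match(lines[idx]):
        if idx - start > 6:
            raise MissingBlockError("NPA block header malformed or truncated")
        idx += 1
    charges: list[float] = []
    elements: list[str] = []
    closed = False
    for ln in lines[idx:]:
        m = _NPA_ROW.match(ln)
        if m:
            element, index, q = m.groups()
            if int(index) != len(charges) + 1:
                raise ConsistencyError(
                    f"non-consecutive atom index {index} in NPA table"
                )
            elements.append(element)
            charges.append(float(q))
            continue
        if _RULE_RE.match(ln) or ln.strip().startswith("="):
            closed = True
            break
        raise MissingBlockError(f"unexpected line inside NPA table: {ln!r}")
    if not closed or not charges:
        raise MissingBlockError("NPA table truncated before its closing rule")
    return ChargeSet("NPA", tuple(charges), tuple(elements))


def parse_orbitals(text: str) -> OrbitalSpectrum:
    """Extract occupied/virtual orbital energies; HOMO/LUMO/gap derive from them."""
    lines = text.splitlines()
    start = next(
        (i for i, ln in enumerate(lines) if "Orbital Energies (a.u.)" in ln),
        None,
    )
    if start is None:
        raise MissingBlockError("no orbital-energies section found")
    section = None
    occupied: list[float] = []
    virtual: list[float] = []
    for ln in lines[start + 1 :]:
        stripped = ln.strip()
        if stripped.startswith("-- Occupied --"):
            section = occupied
            continue
        if stripped.startswith("-- Virtual --"):
            section = virtual
            continue
        if not stripped or _RULE_RE.match(ln):
            if section is virtual and virtual:
                break
            continue
        if section is None:
            continue
        for token in stripped.split():
            try:
                section.append(float(token))
            except ValueError:
                raise MissingBlockError(
                    f"non-numeric orbital energy {token!r}"
                ) from None
    if not occupied:
        raise SpectrumError("orbital section lists no occupied energies")
    if not virtual:
        raise SpectrumError("orbital section lists no virtual energies")
    return OrbitalSpectrum(tuple(occupied), tuple(virtual))
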