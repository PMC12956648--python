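"""Predicted-structure handling and QM fragment extraction.

Reads fixed-column PDB text (the B-factor column carrying per-residue pLDDT
for predicted models), exposes per-residue confidence, superposes structures
with the Kabsch algorithm, and cuts mutation-centred ±w-residue fragments
whose severed peptide bonds are capped with hydrogens and whose net charge is
assigned from pH-7 side-chain formal charges.

Fragment philosophy: a quantum-chemistry calculation on a whole predicted
protein is both intractable and dominated by low-confidence regions, so the
electronic analysis is restricted to a small window around the mutated
residue. The window keeps all atoms of every residue it contains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    CappingError,
    ChargeAssignmentError,
    DegeneracyError,
    FragmentError,
    ManifestError,
    PairingError,
    PDBParseError,
)

__all__ = [
    "AtomRecord",
    "StructureModel",
    "ConfidenceProfile",
    "QMFragment",
    "ReplicateManifest",
    "read_pdb",
    "confidence_profile",
    "kabsch_rmsd",
    "extract_fragment",
    "cap_fragment",
    "fragment_net_charge",
    "fragment_to_xyz",
    "fragment_to_pdb",
    "build_replicate_manifest",
    "mean_plddt",
    "SIDE_CHAIN_CHARGE",
    "CAP_BOND_LENGTH",
    "DEFAULT_PLDDT_THRESHOLD",
]

#: Formal side-chain charge at pH 7 per 3-letter residue name. Histidine is
#: treated as neutral (pKa ~6); free termini are assumed capped and contribute 0.
SIDE_CHAIN_CHARGE: dict[str, int] = {
    "ALA": 0, "ARG": +1, "ASN": 0, "ASP": -1, "CYS": 0,
    "GLN": 0, "GLU": -1, "GLY": 0, "HIS": 0, "ILE": 0,
    "LEU": 0, "LYS": +1, "MET": 0, "PHE": 0, "PRO": 0,
    "SER": 0, "THR": 0, "TRP": 0, "TYR": 0, "VAL": 0,
}

#: X-H bond length used for link-atom capping, in Å.
CAP_BOND_LENGTH = 1.09

#: pLDDT below this value marks a residue as low-confidence (strict <).
DEFAULT_PLDDT_THRESHOLD = 70.0


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM record: identity, position and confidence."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    xyz: tuple[float, float, float]
    bfactor: float

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)


@dataclass
class StructureModel:
    """An ordered atom list with a residue index (single chain, single model)."""

    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._residue_index: dict[int, list[int]] = {}
        for i, atom in enumerate(self.atoms):
            self._residue_index.setdefault(atom.res_seq, []).append(i)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residue_ids(self) -> list[int]:
        return list(self._residue_index)

    def residue_atoms(self, res_seq: int) -> list[AtomRecord]:
        try:
            idx = self._residue_index[res_seq]
        except KeyError:
            raise FragmentError(f"residue {res_seq} not in structure") from None
        return [self.atoms[i] for i in idx]

    def residue_name(self, res_seq: int) -> str:
        return self.residue_atoms(res_seq)[0].res_name

    def backbone_atom(self, res_seq: int, name: str) -> AtomRecord | None:
        for atom in self.residue_atoms(res_seq):
            if atom.name == name:
                return atom
        return None

    def coords(self, atom_names: set[str] | None = None) -> np.ndarray:
        atoms = self.atoms
        if atom_names is not None:
            atoms = [a for a in atoms if a.name in atom_names]
        return np.array([a.xyz for a in atoms], dtype=float).reshape(-1, 3)


_ELEMENTS_TWO = {"FE", "ZN", "MG", "MN", "SE", "NA", "CL", "CA", "CU", "BR"}


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise PDBParseError(f"cannot infer element from atom name {name!r}")
    two = stripped[:2].upper()
    if two in _ELEMENTS_TWO:
        return two.capitalize()
    return stripped[0].upper()


def read_pdb(text: str, chain: str | None = None) -> StructureModel:
    """Parse fixed-column PDB text into a :class:`StructureModel`.

    Only ATOM records of the first model are read; HETATM records (waters,
    ligands) are skipped. If ``chain`` is None the first chain encountered is
    kept. Malformed fixed-width fields raise :class:`PDBParseError` with the
    offending line number.
    """
    atoms: list[AtomRecord] = []
    wanted_chain = chain
    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip()
        if record == "ENDMDL":
            break
        if record != "ATOM":
            continue
        if len(line) < 54:
            raise PDBParseError("ATOM line shorter than coordinate block", lineno)
        altloc = line[16].strip() if len(line) > 16 else ""
        if altloc not in ("", "A"):
            continue
        this_chain = line[21].strip() if len(line) > 21 else ""
        if wanted_chain is None:
            wanted_chain = this_chain
        if this_chain != wanted_chain:
            continue
        try:
            serial = int(line[6:11])
            res_seq = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(f"bad numeric field ({exc})", lineno) from None
        bfield = line[60:66].strip()
        try:
            bfactor = float(bfield) if bfield else 0.0
        except ValueError:
            raise PDBParseError(f"bad B-factor field {bfield!r}", lineno) from None
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        elem_field = line[76:78].strip() if len(line) > 76 else ""
        element = elem_field.capitalize() if elem_field else _element_from_name(name)
        if not all(map(math.isfinite, (x, y, z))):
            raise PDBParseError("non-finite coordinate", lineno)
        atoms.append(
            AtomRecord(serial, name, element, res_name, res_seq, this_chain,
                       (x, y, z), bfactor)
        )
    return StructureModel(atoms)


@dataclass(frozen=True)
class ConfidenceProfile:
    """Per-residue predicted confidence (pLDDT, 0-100) and the flagged set."""

    per_residue_plddt: Mapping[int, float]
    low_confidence: frozenset[int]
    threshold: float


def confidence_profile(
    model: StructureModel, threshold: float = DEFAULT_PLDDT_THRESHOLD
) -> ConfidenceProfile:
    """Mean B-factor per residue; residues strictly below threshold are flagged."""
    per_res = {
        r: float(np.mean([a.bfactor for a in model.residue_atoms(r)]))
        for r in model.residue_ids
    }
    low = frozenset(r for r, v in per_res.items() if v < threshold)
    return ConfidenceProfile(per_res, low, threshold)


def mean_plddt(model: StructureModel) -> float:
    """Structure-level confidence: mean of the per-residue pLDDT values."""
    profile = confidence_profile(model)
    return float(np.mean(list(profile.per_residue_plddt.values())))


def _selection_coords(
    model: StructureModel | np.ndarray,
    atom_selection: set[str] | Callable[[AtomRecord], bool] | None,
) -> np.ndarray:
    if isinstance(model, np.ndarray):
        return np.asarray(model, dtype=float).reshape(-1, 3)
    if atom_selection is None:
        atoms = model.atoms
    elif callable(atom_selection):
        atoms = [a for a in model.atoms if atom_selection(a)]
    else:
        atoms = [a for a in model.atoms if a.name in atom_selection]
    return np.array([a.xyz for a in atoms], dtype=float).reshape(-1, 3)


def kabsch_rmsd(
    a: StructureModel | np.ndarray,
    b: StructureModel | np.ndarray,
    atom_selection: set[str] | Callable[[AtomRecord], bool] | None = None,
) -> float:
    """RMSD between paired atom sets after optimal rigid superposition.

    Centroids are removed, the optimal proper rotation is found from the SVD
    of the cross-covariance matrix (with the determinant sign correction that
    excludes reflections), and the residual root-mean-square deviation is
    returned in Å.
    """
    P = _selection_coords(a, atom_selection)
    Q = _selection_coords(b, atom_selection)
    if P.shape[0] != Q.shape[0]:
        raise PairingError(
            f"selections have {P.shape[0]} vs {Q.shape[0]} atoms; "
            "superposition needs an ordered one-to-one pairing"
        )
    n = P.shape[0]
    if n < 3:
        raise DegeneracyError(f"need >= 3 paired atoms, got {n}")
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = (R @ P.T).T - Q
    return float(np.sqrt((diff**2).sum() / n))


@dataclass(frozen=True)
class QMFragment:
    """A capped, charge-assigned atom set around a mutation site.

    ``window`` is the inclusive residue range actually kept after clipping at
    the chain termini. Cut-site anchor coordinates (positions of the removed
    neighbouring backbone atoms) are carried until :func:`cap_fragment`
    consumes them.
    """

    atoms: tuple[AtomRecord, ...]
    center: int
    window: tuple[int, int]
    net_charge: int = 0
    multiplicity: int = 1
    n_caps: int = 0
    n_side_anchor: tuple[float, float, float] | None = None
    c_side_anchor: tuple[float, float, float] | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residue_ids(self) -> tuple[int, ...]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.res_seq, None)
        return tuple(seen)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a.element for a in self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)


def extract_fragment(
    model: StructureModel,
    center: int,
    half_width: int = 1,
    *,
    cap: bool = True,
) -> QMFragment:
    """Cut the ±``half_width``-residue window around ``center``.

    The window is clipped at chain termini, all atoms of every window residue
    are kept, and (by default) the severed peptide bonds are hydrogen-capped
    and the formal net charge assigned. Pass ``cap=False`` for the raw
    fragment with its cut-site anchors still attached.
    """
    residues = model.residue_ids
    if center not in model._residue_index:
        raise FragmentError(f"center residue {center} not in structure")
    lo = max(min(residues), center - half_width)
    hi = min(max(residues), center + half_width)
    window_res = [r for r in residues if lo <= r <= hi]
    atoms: list[AtomRecord] = []
    for r in window_res:
        atoms.extend(model.residue_atoms(r))

    n_anchor = c_anchor = None
    prev_res = lo - 1
    if prev_res in model._residue_index:
        prev_c = model.backbone_atom(prev_res, "C")
        if prev_c is not None:
            n_anchor = prev_c.xyz
    next_res = hi + 1
    if next_res in model._residue_index:
        next_n = model.backbone_atom(next_res, "N")
        if next_n is not None:
            c_anchor = next_n.xyz

    fragment = QMFragment(
        atoms=tuple(atoms),
        center=center,
        window=(lo, hi),
        n_side_anchor=n_anchor,
        c_side_anchor=c_anchor,
    )
    if cap:
        fragment = cap_fragment(fragment)
        fragment = replace(fragment, net_charge=fragment_net_charge(fragment))
    return fragment


def _cap_hydrogen(heavy: AtomRecord, anchor: tuple[float, float, float],
                  serial: int) -> AtomRecord:
    direction = np.asarray(anchor, float) - heavy.coords
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        raise CappingError(
            f"cap anchor coincides with backbone atom of residue {heavy.res_seq}"
        )
    pos = heavy.coords + CAP_BOND_LENGTH * direction / norm
    return AtomRecord(
        serial=serial, name="HCP", element="H", res_name=heavy.res_name,
        res_seq=heavy.res_seq, chain=heavy.chain,
        xyz=(float(pos[0]), float(pos[1]), float(pos[2])), bfactor=0.0,
    )


def cap_fragment(fragment: QMFragment) -> QMFragment:
    """Place one link hydrogen along each severed peptide-bond direction.

    The N-side cap sits on the window's first backbone N, the C-side cap on
    its last backbone C, each at 1.09 Å toward the removed neighbour. Existing
    atom coordinates are never modified; only hydrogens are appended.
    """
    by_res: dict[int, list[AtomRecord]] = {}
    for a in fragment.atoms:
        by_res.setdefault(a.res_seq, []).append(a)
    first_res, last_res = fragment.window
    new_atoms = list(fragment.atoms)
    next_serial = max((a.serial for a in fragment.atoms), default=0) + 1
    n_caps = 0

    if fragment.n_side_anchor is not None:
        heavy = next((a for a in by_res.get(first_res, []) if a.name == "N"), None)
        if heavy is None:
            raise CappingError(f"residue {first_res} lacks a backbone N to cap")
        new_atoms.append(_cap_hydrogen(heavy, fragment.n_side_anchor, next_serial))
        next_serial += 1
        n_caps += 1
    if fragment.c_side_anchor is not None:
        heavy = next((a for a in by_res.get(last_res, []) if a.name == "C"), None)
        if heavy is None:
            raise CappingError(f"residue {last_res} lacks a backbone C to cap")
        new_atoms.append(_cap_hydrogen(heavy, fragment.c_side_anchor, next_serial))
        n_caps += 1

    return replace(
        fragment,
        atoms=tuple(new_atoms),
        n_caps=fragment.n_caps + n_caps,
        n_side_anchor=None,
        c_side_anchor=None,
    )


def fragment_net_charge(fragment: QMFragment) -> int:
    """Sum of pH-7 formal side-chain charges over the window residues."""
    seen: dict[int, str] = {}
    for a in fragment.atoms:
        seen.setdefault(a.res_seq, a.res_name)
    total = 0
    for res_seq, res_name in seen.items():
        try:
            total += SIDE_CHAIN_CHARGE[res_name.upper()]
        except KeyError:
            raise ChargeAssignmentError(
                f"no formal-charge entry for residue {res_name} {res_seq}"
            ) from None
    return total


def fragment_to_xyz(fragment: QMFragment, comment: str = "") -> str:
    """Serialise a fragment to XYZ text (element, x, y, z in Å)."""
    lines = [str(fragment.n_atoms), comment]
    for a in fragment.atoms:
        lines.append(f"{a.element:<2s} {a.xyz[0]:12.6f} {a.xyz[1]:12.6f} {a.xyz[2]:12.6f}")
    return "\n".join(lines) + "\n"


def fragment_to_pdb(fragment: QMFragment) -> str:
    """Serialise a fragment back to fixed-column PDB ATOM records."""
    lines = []
    for i, a in enumerate(fragment.atoms, start=1):
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {i:5d} {name:<4s} {a.res_name:<3s} {a.chain or 'A'}"
            f"{a.res_seq:4d}    {a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
            f"{1.00:6.2f}{a.bfactor:6.2f}          {a.element.upper():>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ReplicateManifest:
    """Replicate structure bookkeeping for a mutant cohort.

    Structure predictors are stochastic, so each mutant gets a fixed number
    of replicate predictions (five by default); one representative per mutant
    is chosen as the replicate with the highest mean pLDDT, ties broken by
    file order.
    """

    replicates: Mapping[str, tuple[str, ...]]
    representative: Mapping[str, str]
    n_slots: int = 5

    def __post_init__(self) -> None:
        for mutant, paths in self.replicates.items():
            if self.representative[mutant] not in paths:
                raise ManifestError(
                    f"representative for {mutant} not among its replicates"
                )


def build_replicate_manifest(
    replicates: Mapping[str, Sequence[str | Path]],
    *,
    n_slots: int = 5,
    loader: Callable[[str], StructureModel] | None = None,
) -> ReplicateManifest:
    """Choose one representative per mutant from its replicate predictions.

    ``loader`` maps a path to a :class:`StructureModel`; the default reads
    the file from disk. Each mutant must fill exactly ``n_slots`` replicate
    slots (pass ``n_slots=None`` to disable the check).
    """
    if loader is None:
        loader = lambda p: read_pdb(Path(p).read_text())  # noqa: E731
    reps: dict[str, tuple[str, ...]] = {}
    chosen: dict[str, str] = {}
    for mutant, paths in replicates.items():
        paths = tuple(str(p) for p in paths)
        if n_slots is not None and len(paths) != n_slots:
            raise ManifestError(
                f"mutant {mutant} has {len(paths)} replicates, expected {n_slots}"
            )
        if not paths:
            raise ManifestError(f"mutant {mutant} has no replicates")
        scores = [mean_plddt(loader(p)) for p in paths]
        best = int(np.argmax(scores))  # argmax keeps the first of tied maxima
        reps[mutant] = paths
        chosen[mutant] = paths[best]
    return ReplicateManifest(reps, chosen, n_slots=n_slots if n_slots else 5)
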