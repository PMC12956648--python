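"""Synthetic inputs for the whole pipeline.

Everything the other modules consume can be generated here, offline and
seed-deterministically: mutation cohorts with a configurable missense /
nonsense spectrum, toy extended-chain polypeptide PDBs with controlled
per-residue pLDDT, mock engine outputs with known ground-truth charges and
orbital energies, and a classical point-charge ESP oracle that validates the
charge-from-potential fitting concept without any quantum-chemistry engine.

The bundled reference protein is a synthetic 393-residue sequence carrying
the p53 domain map (TAD1 1-40, TAD2 41-61, PRR 62-93, DBD 94-292, OD
323-356); it stands in for the real sequence so that no download is ever
needed, and any FASTA can be substituted via
:func:`mutqprof.variant_profile.load_reference_fasta`.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

from .errors import ConditioningError, GridError, SpecError
from .qchem_io import JobFlavour
from .variant_profile import (
    STANDARD_AA,
    STOP,
    MutationKind,
    MutationRecord,
    ONE_TO_THREE,
    ReferenceProtein,
    TP53_DOMAINS,
)

__all__ = [
    "SyntheticCohortSpec",
    "ToyStructureSpec",
    "MockQCOutputSpec",
    "synthetic_reference",
    "make_cohort",
    "make_toy_pdb",
    "mock_qchem_output",
    "make_demo_cohort_outputs",
    "point_charge_esp_oracle",
    "fibonacci_shell",
    "DEMO_COHORT_SIZE",
]

#: Size of the end-to-end demo cohort (mutant fragments analysed together).
DEMO_COHORT_SIZE = 28

_REFERENCE_LENGTH = 393
_REFERENCE_SEED = 1993  # fixed: the bundled reference must never change


@functools.cache
def synthetic_reference() -> ReferenceProtein:
    """The bundled synthetic 393-residue reference protein (p53 domain map)."""
    rng = np.random.default_rng(_REFERENCE_SEED)
    body = rng.choice(list(STANDARD_AA), size=_REFERENCE_LENGTH - 1)
    return ReferenceProtein(
        "SYNREF_P53LIKE", "M" + "".join(body), TP53_DOMAINS
    )


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic mutation cohort.

    ``missense_weight`` and ``nonsense_weight`` must sum to 1. Optional
    ``hotspots`` maps residue positions to relative sampling multipliers
    (a weight of 50 makes that position 50× likelier than background),
    emulating recurrent cancer hotspots. ``resample_rate`` is the chance a
    record re-uses an earlier sample id, so unique_samples < total_records
    as in real cohorts.
    """

    n_records: int = 100
    missense_weight: float = 0.8
    nonsense_weight: float = 0.2
    hotspots: tuple[tuple[int, float], ...] = ()
    resample_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise SpecError("n_records must be non-negative")
        if min(self.missense_weight, self.nonsense_weight) < 0:
            raise SpecError("kind weights must be non-negative")
        if abs(self.missense_weight + self.nonsense_weight - 1.0) > 1e-9:
            raise SpecError("missense_weight + nonsense_weight must equal 1")
        for pos, w in self.hotspots:
            if pos < 1 or w <= 0:
                raise SpecError(f"invalid hotspot ({pos}, {w})")


def make_cohort(
    spec: SyntheticCohortSpec, reference: ReferenceProtein | None = None
) -> tuple[str, list[MutationRecord]]:
    """Generate a cohort CSV (sample_id, hgvsp) plus its ground-truth records.

    Pure function of the spec: repeated calls return byte-identical CSV text.
    Every record is consistent with the reference sequence, so downstream
    application never hits a reference mismatch.
    """
    if reference is None:
        reference = synthetic_reference()
    rng = np.random.default_rng(spec.seed)
    length = reference.canonical_length
    weights = np.ones(length)
    for pos, w in spec.hotspots:
        if pos <= length:
            weights[pos - 1] = w
    weights /= weights.sum()

    records: list[MutationRecord] = []
    sample_ids: list[str] = []
    lines = [f"# seed={spec.seed}", "sample_id,hgvsp"]
    for i in range(spec.n_records):
        if sample_ids and rng.random() < spec.resample_rate:
            sid = sample_ids[int(rng.integers(len(sample_ids)))]
        else:
            sid = f"S{i:04d}"
        sample_ids.append(sid)
        position = int(rng.choice(length, p=weights)) + 1
        ref_aa = reference.residue(position)
        if rng.random() < spec.missense_weight:
            choices = [aa for aa in STANDARD_AA if aa != ref_aa]
            alt = choices[int(rng.integers(len(choices)))]
            kind = MutationKind.MISSENSE
        else:
            alt = STOP
            kind = MutationKind.NONSENSE
        alt_token = "Ter" if alt == STOP else ONE_TO_THREE[alt]
        raw = f"p.{ONE_TO_THREE[ref_aa]}{position}{alt_token}"
        records.append(MutationRecord(sid, raw, ref_aa, position, alt, kind))
        lines.append(f"{sid},{raw}")
    return "\n".join(lines) + "\n", records


# Ideal backbone bond lengths (Å) for the extended toy chain.
_BOND_N_CA = 1.46
_BOND_CA_C = 1.52
_BOND_C_N = 1.33
_BOND_C_O = 1.23
_ZIGZAG_ANGLE = np.deg2rad(30.0)


@dataclass(frozen=True)
class ToyStructureSpec:
    """A toy extended-chain polypeptide: sequence plus per-residue pLDDT.

    Backbone-only (N, CA, C, O per residue) with ideal bond lengths; the
    B-factor column of every atom carries the residue's pLDDT.
    """

    sequence: str
    plddt: tuple[float, ...] = ()
    chain: str = "A"
    first_res_seq: int = 1
    jitter: float = 0.0  # Gaussian coordinate noise, Å (0 keeps ideal geometry)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter < 0:
            raise SpecError("jitter must be non-negative")
        bad = set(self.sequence) - set(STANDARD_AA)
        if bad:
            raise SpecError(f"nonstandard residues {sorted(bad)} in toy sequence")
        if self.plddt and len(self.plddt) != len(self.sequence):
            raise SpecError("plddt list must match sequence length")
        if any(not 0 <= v <= 100 for v in self.plddt):
            raise SpecError("pLDDT values must lie in [0, 100]")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def residue_plddt(self, i: int) -> float:
        return self.plddt[i] if self.plddt else 90.0


def _pdb_line(serial: int, name: str, res_name: str, chain: str, res_seq: int,
              xyz: np.ndarray, bfactor: float, element: str) -> str:
    padded = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {padded:<4s} {res_name:<3s} {chain}{res_seq:4d}"
        f"    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{bfactor:6.2f}"
        f"          {element.upper():>2s}"
    )


def make_toy_pdb(spec: ToyStructureSpec) -> str:
    """Emit fixed-column PDB text for an ideal extended chain.

    The backbone zig-zags in the xy-plane with exact N-Cα (1.46 Å), Cα-C
    (1.52 Å) and peptide C-N (1.33 Å) bond lengths; carbonyl oxygens sit
    1.23 Å above their carbons.
    """
    up = np.array([np.cos(_ZIGZAG_ANGLE), np.sin(_ZIGZAG_ANGLE), 0.0])
    down = np.array([np.cos(_ZIGZAG_ANGLE), -np.sin(_ZIGZAG_ANGLE), 0.0])
    rng = np.random.default_rng(spec.seed)
    lines = []
    serial = 1
    pos = np.zeros(3)
    sign_up = True
    for i, aa in enumerate(spec.sequence):
        res_name = ONE_TO_THREE[aa].upper()
        res_seq = spec.first_res_seq + i
        b = spec.residue_plddt(i)
        n_pos = pos
        ca_pos = n_pos + _BOND_N_CA * (up if sign_up else down)
        c_pos = ca_pos + _BOND_CA_C * (down if sign_up else up)
        o_pos = c_pos + np.array([0.0, 0.0, _BOND_C_O])
        for name, p, elem in (
            ("N", n_pos, "N"), ("CA", ca_pos, "C"),
            ("C", c_pos, "C"), ("O", o_pos, "O"),
        ):
            if spec.jitter > 0:
                p = p + rng.normal(0.0, spec.jitter, size=3)
            lines.append(_pdb_line(serial, name, res_name, spec.chain,
                                   res_seq, p, b, elem))
            serial += 1
        pos = c_pos + _BOND_C_N * (up if sign_up else down)
        # keep the zig-zag alternating per bond triplet
        sign_up = not sign_up
    lines.append("END")
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class MockQCOutputSpec:
    """Ground truth for one mock engine output.

    For charge flavours, ``charges`` must sum to ``net_charge`` within 1e-6
    (partial charges always sum to the total molecular charge). For the
    orbital flavour, occupied and virtual energy lists are required.
    """

    flavour: JobFlavour
    charges: tuple[float, ...] = ()
    elements: tuple[str, ...] = ()
    occupied: tuple[float, ...] = ()
    virtual: tuple[float, ...] = ()
    net_charge: float = 0.0

    def __post_init__(self) -> None:
        if self.flavour in (JobFlavour.ESP, JobFlavour.NPA):
            if not self.charges:
                raise SpecError(f"{self.flavour.value} mock requires charges")
            if abs(sum(self.charges) - self.net_charge) > 1e-6:
                raise SpecError(
                    "charges must sum to net_charge within 1e-6 "
                    f"(got {sum(self.charges):.8f} vs {self.net_charge:.8f})"
                )
            if self.elements and len(self.elements) != len(self.charges):
                raise SpecError("elements/charges length mismatch")
        else:
            if not self.occupied or not self.virtual:
                raise SpecError("orbital mock requires occupied and virtual lists")


def _mock_elements(spec: MockQCOutputSpec) -> tuple[str, ...]:
    if spec.elements:
        return spec.elements
    cycle = ("C", "N", "O", "H")
    return tuple(cycle[i % 4] for i in range(len(spec.charges)))


def mock_qchem_output(spec: MockQCOutputSpec) -> str:
    """Render a mock engine output in the dialect the parsers accept."""
    rule = "     " + "-" * 40
    if spec.flavour is JobFlavour.ESP:
        lines = [
            "     Ground-State ChElPG Net Atomic Charges",
            rule,
            "     Atom                 Charge (a.u.)",
            rule,
        ]
        for i, (el, q) in enumerate(zip(_mock_elements(spec), spec.charges), 1):
            lines.append(f"     {i:4d} {el:<2s}            {q:12.6f}")
        lines.append(rule)
        lines.append(f"     Sum of atomic charges = {spec.net_charge:12.6f}")
        return "\n".join(lines) + "\n"
    if spec.flavour is JobFlavour.NPA:
        lines = [
            " Summary of Natural Population Analysis:",
            rule,
            "     Atom No    Charge        Core      Valence    Rydberg      Total",
            rule,
        ]
        for i, (el, q) in enumerate(zip(_mock_elements(spec), spec.charges), 1):
            lines.append(f"      {el:<2s} {i:3d} {q:11.6f}")
        lines.append(" " + "=" * 44)
        lines.append(f" * Total * {spec.net_charge:10.5f}")
        return "\n".join(lines) + "\n"
    lines = [" Orbital Energies (a.u.)", "", " -- Occupied --"]
    occ = sorted(spec.occupied)
    for i in range(0, len(occ), 6):
        lines.append(" " + "  ".join(f"{e:9.5f}" for e in occ[i : i + 6]))
    lines.append(" -- Virtual --")
    vir = sorted(spec.virtual)
    for i in range(0, len(vir), 6):
        lines.append(" " + "  ".join(f"{e:9.5f}" for e in vir[i : i + 6]))
    lines.append("")
    return "\n".join(lines) + "\n"


def _charges_with_sum(rng: np.random.Generator, n: int, total: float,
                      spread: float = 0.3) -> tuple[float, ...]:
    q = rng.normal(0.0, spread, size=n)
    q += (total - q.sum()) / n
    q = np.round(q, 6)
    q[-1] += round(total - q.sum(), 6)  # absorb rounding so Σq == total exactly
    return tuple(float(v) for v in np.round(q, 6))


def make_demo_cohort_outputs(
    n_mutants: int = DEMO_COHORT_SIZE,
    n_atoms: int = 30,
    seed: int = 0,
) -> dict[str, dict[str, MockQCOutputSpec]]:
    """Ground-truth mock outputs for a mutant cohort plus wild type.

    Emulates the descriptor-level statistics of a small missense cohort: NPA
    summed fragment charges concentrated between 0.4 and 0.5 with occasional
    stronger polarisation toward 0.7; occupied orbital stacks whose deepest
    levels lie below −1.5 hartree; mutant HOMO–LUMO gaps spread around a
    slightly smaller wild-type gap. Keys are mutant ids ('WT' plus 'MUT01'…);
    each value maps flavour name → :class:`MockQCOutputSpec`.
    """
    rng = np.random.default_rng(seed)
    cohort: dict[str, dict[str, MockQCOutputSpec]] = {}
    ids = ["WT"] + [f"MUT{i + 1:02d}" for i in range(n_mutants)]
    for mutant in ids:
        is_wt = mutant == "WT"
        n = n_atoms if is_wt else int(n_atoms + rng.integers(-3, 4))
        if is_wt:
            npa_total = 0.45
        elif rng.random() < 0.15:
            npa_total = float(rng.uniform(0.55, 0.7))
        else:
            npa_total = float(rng.uniform(0.4, 0.5))
        npa_total = round(npa_total, 6)
        esp_total = round(float(rng.uniform(-0.6, -0.1)), 6)
        homo = float(rng.uniform(-0.30, -0.22))
        gap = float(rng.uniform(0.18, 0.30)) if not is_wt else 0.20
        deep = tuple(round(float(e), 5) for e in np.sort(rng.uniform(-2.4, -1.6, size=4)))
        mid = tuple(round(float(e), 5) for e in np.sort(rng.uniform(-1.2, -0.4, size=6)))
        occupied = deep + mid + (round(homo, 5),)
        virtual = tuple(
            round(homo + gap + i * 0.08, 5) for i in range(4)
        )
        cohort[mutant] = {
            "esp": MockQCOutputSpec(
                JobFlavour.ESP,
                charges=_charges_with_sum(rng, n, esp_total),
                net_charge=esp_total,
            ),
            "npa": MockQCOutputSpec(
                JobFlavour.NPA,
                charges=_charges_with_sum(rng, n, npa_total),
                net_charge=npa_total,
            ),
            "orbitals": MockQCOutputSpec(
                JobFlavour.HOMO_LUMO, occupied=occupied, virtual=virtual
            ),
        }
    return cohort


def fibonacci_shell(center: np.ndarray, radius: float, n_points: int) -> np.ndarray:
    """Near-uniform points on a sphere (golden-spiral construction)."""
    i = np.arange(n_points)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(1.0 - z**2)
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return np.asarray(center, float) + radius * pts


def point_charge_esp_oracle(
    charges,
    positions,
    grid_points,
    *,
    min_distance: float = 3.0,
) -> np.ndarray:
    """Classical ESP round trip: evaluate Σ qᵢ/rᵢ on a grid, then re-fit.

    Validates the charges-from-potential concept with pure linear algebra:
    the potential of known point charges is evaluated on an external grid
    (every point at least ``min_distance`` Å from every nucleus, echoing the
    unreliability of ESP fits close to nuclei), and the charges are recovered
    by least squares. For a well-conditioned grid the fit reproduces the
    input charges to machine precision.
    """
    q = np.asarray(charges, dtype=float).ravel()
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    grid = np.asarray(grid_points, dtype=float).reshape(-1, 3)
    if pos.shape[0] != q.size:
        raise SpecError("one position required per charge")
    if grid.shape[0] < q.size:
        raise ConditioningError(
            f"need at least {q.size} grid points, got {grid.shape[0]}"
        )
    dists = np.linalg.norm(grid[:, None, :] - pos[None, :, :], axis=2)
    if dists.min(initial=np.inf) < min_distance:
        raise GridError(
            f"grid point within {min_distance} Å of a nucleus; "
            "ESP fits are unreliable close to nuclei"
        )
    site_sep = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    np.fill_diagonal(site_sep, np.inf)
    if pos.shape[0] > 1 and site_sep.min() < 1e-6:
        raise ConditioningError("coincident charge sites make the fit singular")
    design = 1.0 / dists
    rank = np.linalg.matrix_rank(design)
    if rank < q.size:
        raise ConditioningError(
            f"design matrix rank {rank} < {q.size} unknown charges"
        )
    potential = design @ q
    fitted, *_ = np.linalg.lstsq(design, potential, rcond=None)
    return fitted
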