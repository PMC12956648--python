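"""PDB reading, confidence profiles, superposition and fragment extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mutqprof import fixtures as fx
from mutqprof import structure_model as sm
from mutqprof.errors import (
    CappingError,
    ChargeAssignmentError,
    DegeneracyError,
    FragmentError,
    ManifestError,
    PairingError,
    PDBParseError,
)


def test_read_pdb_round_trip(toy_model, toy_spec):
    assert len(toy_model.residue_ids) == toy_spec.n_residues
    assert toy_model.n_atoms == 4 * toy_spec.n_residues  # N, CA, C, O each
    assert toy_model.residue_name(1) == "GLY"
    assert toy_model.residue_name(5) == "LYS"


def test_read_pdb_empty_and_hetatm():
    assert sm.read_pdb("").n_atoms == 0
    text = (
        "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
        "END\n"
    )
    assert sm.read_pdb(text).n_atoms == 0


def test_read_pdb_malformed_line_reports_line_number():
    good = fx.make_toy_pdb(fx.ToyStructureSpec("GA"))
    lines = good.splitlines()
    lines[2] = lines[2][:30] + "  badnum" + lines[2][38:]
    with pytest.raises(PDBParseError) as err:
        sm.read_pdb("\n".join(lines))
    assert err.value.line_number == 3


def test_read_pdb_first_chain_only():
    a = fx.make_toy_pdb(fx.ToyStructureSpec("GAV", chain="A"))
    b = fx.make_toy_pdb(fx.ToyStructureSpec("KDE", chain="B"))
    both = a.replace("END\n", "") + b
    model = sm.read_pdb(both)
    assert {at.chain for at in model.atoms} == {"A"}
    model_b = sm.read_pdb(both, chain="B")
    assert {at.chain for at in model_b.atoms} == {"B"}


def test_confidence_profile_flags_exactly_low_residues(toy_model):
    prof = sm.confidence_profile(toy_model, threshold=70.0)
    assert prof.low_confidence == frozenset({7, 8, 9})
    assert prof.per_residue_plddt[1] == pytest.approx(90.0)


def test_confidence_boundary_is_strict():
    """A residue whose mean pLDDT equals the threshold is not flagged."""
    spec = fx.ToyStructureSpec("GAV", plddt=(70.0, 69.5, 90.0))
    prof = sm.confidence_profile(sm.read_pdb(fx.make_toy_pdb(spec)), 70.0)
    assert prof.low_confidence == frozenset({2})


class TestKabschRMSD:
    def test_identity(self, toy_model):
        assert sm.kabsch_rmsd(toy_model, toy_model) == pytest.approx(0.0, abs=1e-12)

    def test_translation_invariance(self, toy_model):
        P = toy_model.coords()
        assert sm.kabsch_rmsd(P, P + np.array([5.0, 5.0, 5.0])) == pytest.approx(
            0.0, abs=1e-8
        )

    @given(st.integers(0, 2**31 - 1))
    def test_rigid_motion_invariance(self, seed):
        """RMSD is zero under any proper rotation + translation of one copy."""
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(10, 3))
        A = rng.normal(size=(3, 3))
        Q_, _ = np.linalg.qr(A)
        if np.linalg.det(Q_) < 0:
            Q_[:, 0] *= -1
        moved = P @ Q_.T + rng.normal(size=3)
        assert sm.kabsch_rmsd(P, moved) == pytest.approx(0.0, abs=1e-8)

    def test_single_displaced_atom_matches_numerical_minimum(self):
        """SVD solution equals brute-force minimisation over rotations."""
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(42)
        P = rng.normal(size=(10, 3))
        Q = P.copy()
        Q[3] += np.array([1.0, 0.0, 0.0])

        Pc = P - P.mean(0)
        Qc = Q - Q.mean(0)

        def objective(rotvec):
            R = Rotation.from_rotvec(rotvec).as_matrix()
            return np.sqrt((((Pc @ R.T) - Qc) ** 2).sum() / len(Pc))

        best = min(
            minimize(objective, x0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12}).fun
            for x0 in rng.normal(size=(8, 3))
        )
        assert sm.kabsch_rmsd(P, Q) == pytest.approx(best, abs=1e-6)

    def test_selection_and_errors(self, toy_model):
        ca_only = sm.kabsch_rmsd(toy_model, toy_model, atom_selection={"CA"})
        assert ca_only == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(PairingError):
            sm.kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(DegeneracyError):
            sm.kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestFragmentExtraction:
    def test_interior_window(self, toy_model):
        frag = sm.extract_fragment(toy_model, 5, 1)
        assert frag.window == (4, 6)
        assert set(frag.residue_ids) == {4, 5, 6}
        assert frag.n_caps == 2

    def test_terminal_clip(self, toy_model):
        frag = sm.extract_fragment(toy_model, 1, 1)
        assert frag.window == (1, 2)
        assert frag.n_caps == 1
        frag_c = sm.extract_fragment(toy_model, 9, 1)
        assert frag_c.window == (8, 9)
        assert frag_c.n_caps == 1

    def test_zero_half_width(self, toy_model):
        frag = sm.extract_fragment(toy_model, 5, 0)
        assert frag.window == (5, 5)
        assert set(frag.residue_ids) == {5}

    def test_whole_chain_has_no_caps(self, toy_model):
        frag = sm.extract_fragment(toy_model, 5, 10)
        assert frag.window == (1, 9)
        assert frag.n_caps == 0

    def test_missing_center(self, toy_model):
        with pytest.raises(FragmentError):
            sm.extract_fragment(toy_model, 42)

    @given(center=st.integers(1, 9), w=st.integers(0, 12))
    def test_window_law(self, center, w):
        """window == [max(1, c-w), min(L, c+w)] and ≤ 2w+1 residues kept."""
        model = sm.read_pdb(fx.make_toy_pdb(fx.ToyStructureSpec("GAVLKDEFG")))
        frag = sm.extract_fragment(model, center, w, cap=False)
        assert frag.window == (max(1, center - w), min(9, center + w))
        assert len(frag.residue_ids) <= 2 * w + 1

    def test_cap_geometry_and_immutability(self, toy_model):
        raw = sm.extract_fragment(toy_model, 5, 1, cap=False)
        capped = sm.cap_fragment(raw)
        # existing atoms untouched, only hydrogens appended
        assert capped.atoms[: raw.n_atoms] == raw.atoms
        added = capped.atoms[raw.n_atoms:]
        assert all(a.element == "H" for a in added)
        # each cap H sits 1.09 Å from its heavy atom
        first_n = next(a for a in raw.atoms if a.res_seq == 4 and a.name == "N")
        last_c = next(a for a in raw.atoms if a.res_seq == 6 and a.name == "C")
        d_n = np.linalg.norm(added[0].coords - first_n.coords)
        d_c = np.linalg.norm(added[1].coords - last_c.coords)
        assert d_n == pytest.approx(sm.CAP_BOND_LENGTH, abs=1e-3)
        assert d_c == pytest.approx(sm.CAP_BOND_LENGTH, abs=1e-3)

    def test_capping_error_when_backbone_missing(self, toy_model):
        raw = sm.extract_fragment(toy_model, 5, 1, cap=False)
        no_n = sm.QMFragment(
            atoms=tuple(a for a in raw.atoms if not (a.res_seq == 4 and a.name == "N")),
            center=5, window=raw.window,
            n_side_anchor=raw.n_side_anchor, c_side_anchor=raw.c_side_anchor,
        )
        with pytest.raises(CappingError, match="4"):
            sm.cap_fragment(no_n)


@pytest.mark.parametrize(
    "sequence, expected",
    [("GGG", 0), ("GDG", -1), ("KGE", 0), ("KRK", 3), ("DED", -3), ("GHG", 0)],
)
def test_fragment_net_charge(sequence, expected):
    model = sm.read_pdb(fx.make_toy_pdb(fx.ToyStructureSpec(sequence)))
    frag = sm.extract_fragment(model, 2, 1, cap=False)
    assert sm.fragment_net_charge(frag) == expected


def test_fragment_net_charge_rejects_nonstandard(toy_model):
    frag = sm.extract_fragment(toy_model, 5, 1, cap=False)
    weird = sm.QMFragment(
        atoms=tuple(
            sm.AtomRecord(a.serial, a.name, a.element, "UNK", a.res_seq,
                          a.chain, a.xyz, a.bfactor)
            for a in frag.atoms
        ),
        center=5, window=frag.window,
    )
    with pytest.raises(ChargeAssignmentError):
        sm.fragment_net_charge(weird)


def test_fragment_writers_round_trip(toy_model):
    frag = sm.extract_fragment(toy_model, 5, 1)
    xyz = sm.fragment_to_xyz(frag)
    lines = xyz.splitlines()
    assert int(lines[0]) == frag.n_atoms
    assert len(lines) == frag.n_atoms + 2
    reparsed = sm.read_pdb(sm.fragment_to_pdb(frag))
    assert reparsed.n_atoms == frag.n_atoms
    np.testing.assert_allclose(reparsed.coords(), frag.coords(), atol=1e-3)


class TestReplicateManifest:
    @staticmethod
    def _replicates(tmp_path, scores_by_mutant):
        mapping = {}
        for mutant, scores in scores_by_mutant.items():
            paths = []
            for i, score in enumerate(scores):
                spec = fx.ToyStructureSpec("GAV", plddt=(score,) * 3)
                p = tmp_path / f"{mutant}_rep{i}.pdb"
                p.write_text(fx.make_toy_pdb(spec))
                paths.append(p)
            mapping[mutant] = paths
        return mapping

    def test_representative_is_highest_mean_plddt(self, tmp_path):
        mapping = self._replicates(
            tmp_path, {"M1": [60, 90, 70, 80, 50], "M2": [88, 88, 70, 60, 50]}
        )
        manifest = sm.build_replicate_manifest(mapping)
        assert manifest.n_slots == 5
        assert manifest.representative["M1"].endswith("M1_rep1.pdb")
        # tie between rep0 and rep1 -> file order wins
        assert manifest.representative["M2"].endswith("M2_rep0.pdb")
        for mutant, paths in manifest.replicates.items():
            assert manifest.representative[mutant] in paths

    def test_slot_count_enforced(self, tmp_path):
        mapping = self._replicates(tmp_path, {"M1": [90, 80]})
        with pytest.raises(ManifestError):
            sm.build_replicate_manifest(mapping)
        manifest = sm.build_replicate_manifest(mapping, n_slots=2)
        assert len(manifest.replicates["M1"]) == 2
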