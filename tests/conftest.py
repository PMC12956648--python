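import pytest
from hypothesis import settings

from mutqprof import fixtures as fx
from mutqprof import structure_model as sm
from mutqprof import variant_profile as vp

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference() -> vp.ReferenceProtein:
    return fx.synthetic_reference()


@pytest.fixture(scope="session")
def blosum() -> vp.SubstitutionMatrix:
    return vp.blosum62()


@pytest.fixture(scope="session")
def toy_spec() -> fx.ToyStructureSpec:
    """9-residue extended chain: residues 7-9 at pLDDT 50, the rest at 90."""
    return fx.ToyStructureSpec("GAVLKDEFG", plddt=(90.0,) * 6 + (50.0,) * 3)


@pytest.fixture(scope="session")
def toy_model(toy_spec) -> sm.StructureModel:
    return sm.read_pdb(fx.make_toy_pdb(toy_spec))
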