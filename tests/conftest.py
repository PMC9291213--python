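import logging

import pytest

from dynhb.core_chem import assign_atom_types
from dynhb.electrostatics import surrogate_ep
from dynhb.synthetic_data import gen_fixture_molecules

logging.getLogger("dynhb").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def fixture_set():
    """Template molecules + hand-authored charges (deterministic embedding)."""
    mols, charge_sets = gen_fixture_molecules(seed=7)
    return {m.name: m for m in mols}, charge_sets


@pytest.fixture(scope="session")
def typed_fixtures(fixture_set):
    """Atom-type assignments for every fixture molecule."""
    byname, _ = fixture_set
    return {name: assign_atom_types(mol) for name, mol in byname.items()}


@pytest.fixture(scope="session")
def fixture_eps(fixture_set):
    """Surrogate electrostatic potentials for every fixture molecule."""
    byname, charge_sets = fixture_set
    return {name: surrogate_ep(mol, charge_sets[name])
            for name, mol in byname.items()}
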