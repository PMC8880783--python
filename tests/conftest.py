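import numpy as np
import pytest

import cofnet as cn

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def label_map():
    return cn.hydabcsl_label_map()


@pytest.fixture(scope="session")
def apo_structure():
    return cn.make_hydabcsl_fixture("apo", seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def br_structure():
    return cn.make_hydabcsl_fixture("BR", seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def pb_structure():
    return cn.make_hydabcsl_fixture("PB", seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def apo_cofactors(apo_structure, label_map):
    return cn.detect_cofactors(apo_structure, label_map=label_map)


@pytest.fixture(scope="session")
def br_cofactors(br_structure, label_map):
    return cn.detect_cofactors(br_structure, label_map=label_map)


@pytest.fixture(scope="session")
def pb_cofactors(pb_structure, label_map):
    return cn.detect_cofactors(pb_structure, label_map=label_map)


def point_cofactor(label: str, xyz, chain: str = "Z", resnum: int = 1) -> cn.Cofactor:
    """A single-atom stand-in cofactor for pure graph/distance tests."""
    atom = cn.Atom(element="FE", atom_name="FE1", residue_name="SF4",
                   residue_number=resnum, chain_id=chain,
                   position=np.asarray(xyz, float), is_hetero=True)
    return cn.Cofactor(label=label, type=cn.FES4, chain_id=chain,
                       residue_numbers=(resnum,), atoms=[atom], metal_atoms=[atom])


def two_domain_structure(seed: int = 0, n_per_domain: int = 200) -> cn.Structure:
    """A pseudo-protein with a 'core' (chain E) and a mobile 'domain'
    (chain D), each a cloud of CA atoms — the test surface for rigid-body
    rotation recovery at protein-domain size."""
    rng = np.random.default_rng(seed)
    atoms = []
    for chain, offset in (("E", np.zeros(3)), ("D", np.array([25.0, 0.0, 0.0]))):
        for i in range(n_per_domain):
            atoms.append(cn.Atom(element="C", atom_name="CA", residue_name="ALA",
                                 residue_number=i + 1, chain_id=chain,
                                 position=offset + rng.normal(scale=6.0, size=3)))
    return cn.Structure(atoms=atoms)


def random_cluster_cofactor(label: str, rng, n_atoms: int = 10,
                            spread: float = 2.0) -> cn.Cofactor:
    """A random multi-atom cofactor around a random center."""
    center = rng.uniform(-30, 30, size=3)
    atoms = [cn.Atom(element="FE", atom_name=f"FE{i+1}", residue_name="SF4",
                     residue_number=1, chain_id="Z",
                     position=center + rng.normal(scale=spread, size=3),
                     is_hetero=True)
             for i in range(n_atoms)]
    return cn.Cofactor(label=label, type=cn.FES4, chain_id="Z",
                       residue_numbers=(1,), atoms=atoms, metal_atoms=atoms)
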