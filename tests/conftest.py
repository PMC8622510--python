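import numpy as np
import pytest

from gridqsar.params import element_params
from gridqsar.synthdata import SynthSpec, synthetic_dataset
from gridqsar.types import MoleculeRecord


def make_molecule(
    elements,
    coords,
    charges=None,
    mol_id="mol",
    donor=None,
    acceptor=None,
    core=None,
):
    """Build a MoleculeRecord with element-table parameters."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(elements)
    if charges is None:
        charges = np.zeros(n)
    params = [element_params(sym) for sym in elements]
    return MoleculeRecord(
        id=mol_id,
        elements=list(elements),
        coords=coords,
        charges=np.asarray(charges, dtype=float),
        vdw_radius=np.array([p.vdw_radius for p in params]),
        lj_epsilon=np.array([p.lj_epsilon for p in params]),
        hydrophobic_weight=np.array([p.hydrophobic_weight for p in params]),
        donor_flag=np.zeros(n, dtype=bool) if donor is None else np.asarray(donor, dtype=bool),
        acceptor_flag=np.zeros(n, dtype=bool) if acceptor is None else np.asarray(acceptor, dtype=bool),
        core_atom_indices=core or [],
    )


@pytest.fixture
def molecule_factory():
    return make_molecule


@pytest.fixture(scope="session")
def planted_dataset():
    """A full synthetic congeneric series with planted linear activity
    (n = 40, noise 0.2 log units, span 3), shared across tests."""
    spec = SynthSpec(seed=11)
    molecules, grid, block, activity, truth = synthetic_dataset(spec)
    return {
        "spec": spec,
        "molecules": molecules,
        "grid": grid,
        "block": block,
        "activity": activity,
        "truth": truth,
    }
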