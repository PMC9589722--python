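import numpy as np
import pytest

from cgbind.energy_model import ForceField, ModelParameters
from cgbind.model_builder import (build_native_contacts, build_nonnative_pairs)
from cgbind.synthetic_data import (attach_ligand, make_toy_ligand,
                                   make_two_state_protein)


@pytest.fixture(scope="session")
def toy_pair():
    """Deterministic closed/open reference pair of the 60-bead clamshell."""
    return make_two_state_protein(60, hinge_angle=40.0, seed=1)


@pytest.fixture(scope="session")
def holo_system(toy_pair):
    """Closed complex with the 5-bead ligand, contacts and force field."""
    closed, open_ = toy_pair
    pose = make_toy_ligand(closed)
    holo = attach_ligand(closed, [pose])
    params = ModelParameters(coupling_delta=(0.3, 0.3, 0.3))
    contacts = build_nonnative_pairs(
        build_native_contacts(holo, params.contact_threshold), holo)
    ff = ForceField.from_structures(holo, open_, params,
                                    contacts_closed=contacts)
    return {
        "closed": closed, "open": open_, "pose": pose, "holo": holo,
        "contacts": contacts, "params": params, "ff": ff,
        "ligand": holo.ligands[0],
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
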