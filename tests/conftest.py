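"""Shared fixtures: forward model, default network, one simulated subject."""

import numpy as np
import pytest

from bsnet import headmodel as hm
from bsnet import phases, synth


@pytest.fixture(scope="session")
def model():
    return hm.build_sphere_model()


@pytest.fixture(scope="session")
def montage19():
    return hm.standard_montage_1020(19)


@pytest.fixture(scope="session")
def grid(model):
    return hm.build_source_grid(model)


@pytest.fixture(scope="session")
def leadfield(model, montage19, grid):
    return hm.compute_leadfield(model, montage19, grid)


@pytest.fixture(scope="session")
def network():
    return synth.default_network()


@pytest.fixture(scope="session")
def subject0(network):
    """One default simulated subject (recording + ground truth), seed 0."""
    return synth.assemble_burst_suppression(network, seed=0)


@pytest.fixture(scope="session")
def segments0(subject0):
    """Relabeled 60 s burst and suppression segments of subject 0."""
    rec, _ = subject0
    ann = phases.label_phases_by_amplitude(rec)
    return {ph: phases.concatenate_phase_segments(rec, ann, ph, 60.0)
            for ph in ("burst", "suppression")}


def node_positions(network):
    return {n.name: np.asarray(n.location) for n in network.nodes}


def nearest_role(loc, network, max_dist):
    """Ground-truth role of the node nearest to ``loc`` (None if too far)."""
    best, bd = None, np.inf
    for n in network.nodes:
        d = float(np.linalg.norm(np.asarray(n.location) - np.asarray(loc)))
        if d < bd:
            best, bd = n.name, d
    return synth._role(best) if bd <= max_dist else None
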