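import numpy as np
import pytest

from pdnet import fixtures as fx
from pdnet.structure_io import AtomRecord, ResidueRecord


@pytest.fixture(scope="session")
def helix12():
    return fx.make_ideal_helix(12)


@pytest.fixture(scope="session")
def sheet_pair():
    return fx.make_ideal_sheet(8)


@pytest.fixture(scope="session")
def small_dataset():
    """200-cluster separable dataset shared across model/metric tests."""
    return fx.learnable_dataset(n_clusters=200, n_neighbors=5, seed=7)


@pytest.fixture(scope="session")
def trained_small(small_dataset):
    from pdnet.model import TrainConfig, train

    params, trace = train(small_dataset,
                          TrainConfig(batch_size=64, epochs=40, seed=0),
                          val_fold=5)
    return params, trace


def rigid_copy(residues, rotation, translation):
    """Apply a rigid motion to a residue list (helper shared by tests)."""
    return [
        ResidueRecord(
            r.chain_id, r.seq_index, r.insertion_code, r.aa_type,
            [AtomRecord(a.name, a.element, rotation @ a.coord + translation,
                        a.occupancy, a.altloc) for a in r.atoms],
            r.is_standard)
        for r in residues
    ]


def monte_carlo_sasa(coords, radii, probe=1.4, n_points=20000, seed=0):
    """Independent Monte-Carlo surface-sampling SASA oracle.

    For each atom, sample uniform points on its probe-expanded sphere and
    count the fraction not buried inside any other expanded sphere.
    """
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, dtype=float)
    expanded = np.asarray(radii, dtype=float) + probe
    out = np.zeros(len(coords))
    for i in range(len(coords)):
        v = rng.normal(size=(n_points, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = coords[i] + expanded[i] * v
        free = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            free &= np.linalg.norm(pts - coords[j], axis=1) >= expanded[j]
        out[i] = free.mean() * 4.0 * np.pi * expanded[i] ** 2
    return out
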