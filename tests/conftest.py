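import numpy as np
import pytest

from hbstrength.fixtures import FixtureConfig, make_toy_molecules


@pytest.fixture(scope="session")
def toy_molecules():
    """A deterministic pool of 160 small molecules spanning all families."""
    return make_toy_molecules(FixtureConfig(n_molecules=160, seed=7))


@pytest.fixture(scope="session")
def charged_graphs():
    """Random connected graphs with charges and 3D coordinates, as plain
    MoleculeRecord carbon skeletons (chemistry-agnostic descriptor inputs)."""
    from hbstrength.molio import MoleculeRecord

    rng = np.random.default_rng(42)
    graphs = []
    for _ in range(50):
        n = int(rng.integers(4, 12))
        # random spanning tree keeps the graph connected
        bonds = [((int(rng.integers(0, i)), i), 1) for i in range(1, n)]
        rec = MoleculeRecord(
            atoms=[("C", 0, 0)] * n,
            bonds=bonds,
            coords3d=[tuple(map(float, rng.normal(0, 2, 3))) for _ in range(n)],
            atom_charges=[float(q) for q in rng.normal(0, 0.3, n)],
        )
        graphs.append(rec)
    return graphs


def permute_record(record, perm):
    """Relabel a MoleculeRecord's atoms by permutation old->new index."""
    from hbstrength.molio import MoleculeRecord

    perm = [int(p) for p in perm]
    inv = sorted(range(len(perm)), key=lambda i: perm[i])
    return MoleculeRecord(
        atoms=[record.atoms[i] for i in inv],
        bonds=[((perm[i], perm[j]), o) for (i, j), o in record.bonds],
        coords3d=[record.coords3d[i] for i in inv] if record.coords3d else None,
        atom_charges=[record.atom_charges[i] for i in inv]
        if record.atom_charges
        else None,
        props=dict(record.props),
        name=record.name,
    )
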