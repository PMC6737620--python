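"""Radial atomic reactivity descriptors for a designated donor/acceptor atom.

Six families, each a fixed-length block centred on the site atom:

* ``CS`` — charge shell: mean partial charge per topological shell;
* ``sorted_shell`` — per-shell individual charges ordered by substituent
  priority (descending atomic number, mass, recursively compared neighbour
  environments; ties by descending charge then input index), padded/truncated
  to a fixed width per shell;
* ``MS`` — mass shell: summed standard atomic weights per shell;
* ``GACF`` — topological charge autocorrelation: sum over shell k of
  q_center * q_j;
* ``CRDF`` — spatial charge radial distribution function on a distance grid:
  g(r) = sum_j q_j * exp(-beta * (r - d_cj)^2);
* ``CACF`` — spatial charge autocorrelation, the same smoothing applied to
  the products q_center * q_j, split into positive-product and
  negative-product blocks.

All atoms including hydrogens enter the shells.  The charge shell families
are undefined when a requested shell is empty (mean of nothing); strict mode
raises :class:`DescriptorInapplicableError`, mirroring the data loss such
sites incur, while ``zero_fill`` fills 0.0 instead.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from rdkit import Chem

from .molio import MoleculeRecord

FAMILIES = ("sorted_shell", "CS", "CRDF", "CACF", "MS", "GACF")

_PT = Chem.GetPeriodicTable()

#: Pauling electronegativities for the organic subset, used by the empirical
#: charge fallback and the fixture generator.
PAULING_EN = {
    "H": 2.20, "C": 2.55, "N": 3.04, "O": 3.44, "F": 3.98,
    "Cl": 3.16, "S": 2.58, "Br": 2.96, "I": 2.66, "P": 2.19,
}


class DescriptorInapplicableError(ValueError):
    """A shell-averaged descriptor was requested for an empty shell."""


@dataclass(frozen=True)
class DescriptorSpec:
    """Parameters of one descriptor block.

    ``n_shells`` (K) and ``shell_width`` (W) drive the topological families;
    ``r_min``/``r_max``/``r_step`` (Angstrom) and ``beta`` (1/Angstrom^2)
    drive the spatial ones.  Defaults span the 4-shell fragment radius.
    """

    family: str
    n_shells: int = 4
    shell_width: int = 4
    r_min: float = 1.0
    r_max: float = 8.0
    r_step: float = 0.5
    beta: float = 4.0
    zero_fill: bool = False
    charge_source: str = "ATOM_CHARGES"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown descriptor family {self.family!r}")
        if self.n_shells < 1 or self.shell_width < 1:
            raise ValueError("n_shells and shell_width must be >= 1")
        if not (self.r_min < self.r_max and self.r_step > 0 and self.beta > 0):
            raise ValueError("require r_min < r_max, r_step > 0, beta > 0")

    def grid(self) -> np.ndarray:
        m = math.ceil((self.r_max - self.r_min) / self.r_step - 1e-9)
        return self.r_min + self.r_step * np.arange(m + 1)

    def block_length(self) -> int:
        if self.family == "sorted_shell":
            return self.n_shells * self.shell_width
        if self.family in ("CS", "MS", "GACF"):
            return self.n_shells
        glen = len(self.grid())
        return 2 * glen if self.family == "CACF" else glen


@dataclass
class DescriptorVector:
    """Concatenated descriptor blocks with their layout and a spec digest."""

    values: np.ndarray
    block_layout: list[tuple[str, int, int]]
    spec_hash: str

    def block(self, index: int) -> np.ndarray:
        _, offset, length = self.block_layout[index]
        return self.values[offset:offset + length]


# -- shared primitives ---------------------------------------------------


def topological_shells(
    mol: MoleculeRecord, center: int, K: int
) -> list[list[int]]:
    """Shell k (1..K) = atoms at graph distance exactly k from the center,
    hydrogens included; trailing shells may be empty."""
    from .fragmenter import graph_distances

    dist = graph_distances(mol, center)
    shells: list[list[int]] = [[] for _ in range(K)]
    for idx, d in enumerate(dist):
        if 1 <= d <= K:
            shells[d - 1].append(idx)
    return shells


def get_charges(mol: MoleculeRecord, spec: DescriptorSpec) -> np.ndarray:
    """Per-atom charges: record field, then the named property tag, then an
    electronegativity-based empirical fallback (with a warning)."""
    if mol.atom_charges is not None:
        return np.asarray(mol.atom_charges, dtype=float)
    raw = mol.props.get(spec.charge_source)
    if raw is not None:
        charges = np.array([float(v) for v in raw.split()])
        if len(charges) != mol.num_atoms():
            raise ValueError("charge tag length does not match atom count")
        return charges
    warnings.warn(
        "no partial charges on record; falling back to electronegativity-"
        "equalization pseudo-charges",
        stacklevel=2,
    )
    return empirical_charges(mol)


def empirical_charges(mol: MoleculeRecord, kappa: float = 0.1) -> np.ndarray:
    """Topology-derived pseudo-charges: q_i = kappa * sum_bonds (chi_j - chi_i).

    Antisymmetric per bond, so charges sum to zero per molecule.  A crude
    stand-in for QC-derived partial charges, adequate for exercising every
    charge-consuming code path.
    """
    q = np.zeros(mol.num_atoms())
    chi = [PAULING_EN[sym] for sym, _, _ in mol.atoms]
    for (i, j), _ in mol.bonds:
        delta = kappa * (chi[j] - chi[i])
        q[i] += delta
        q[j] -= delta
    return q


def _coords(mol: MoleculeRecord) -> np.ndarray:
    if mol.coords3d is None:
        raise ValueError("spatial descriptor requires 3D coordinates")
    return np.asarray(mol.coords3d, dtype=float)


# -- substituent priority (sorted shell) --------------------------------


def _priority_key(mol: MoleculeRecord, adj, idx: int, depth: int):
    sym = mol.atoms[idx][0]
    z, mass = _PT.GetAtomicNumber(sym), _PT.GetAtomicWeight(sym)
    if depth == 0:
        return (z, mass, ())
    children = sorted(
        (_priority_key(mol, adj, nbr, depth - 1) for nbr in adj[idx]),
        reverse=True,
    )
    return (z, mass, tuple(children))


def _adjacency(mol: MoleculeRecord) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in mol.atoms]
    for (i, j), _ in mol.bonds:
        adj[i].append(j)
        adj[j].append(i)
    return adj


# -- descriptor families -------------------------------------------------


def charge_shell(mol: MoleculeRecord, center: int, spec: DescriptorSpec) -> np.ndarray:
    """CS: mean charge per shell; empty shell is an error unless zero_fill."""
    q = get_charges(mol, spec)
    out = np.zeros(spec.n_shells)
    for k, shell in enumerate(topological_shells(mol, center, spec.n_shells)):
        if shell:
            out[k] = q[shell].mean()
        elif not spec.zero_fill:
            raise DescriptorInapplicableError(
                f"charge shell {k + 1} around atom {center} is empty"
            )
    return out


def sorted_shell(mol: MoleculeRecord, center: int, spec: DescriptorSpec) -> np.ndarray:
    """Per-shell charges in descending substituent priority, W slots/shell."""
    q = get_charges(mol, spec)
    adj = _adjacency(mol)
    blocks = []
    for shell in topological_shells(mol, center, spec.n_shells):
        ranked = sorted(
            shell,
            key=lambda a: (_priority_key(mol, adj, a, depth=3), q[a], -a),
            reverse=True,
        )
        vals = [q[a] for a in ranked[: spec.shell_width]]
        vals += [0.0] * (spec.shell_width - len(vals))
        blocks.append(vals)
    return np.concatenate(blocks) if blocks else np.zeros(0)


def mass_shell(mol: MoleculeRecord, center: int, spec: DescriptorSpec) -> np.ndarray:
    """MS: summed standard atomic weights per shell; empty shell -> 0."""
    out = np.zeros(spec.n_shells)
    for k, shell in enumerate(topological_shells(mol, center, spec.n_shells)):
        out[k] = sum(_PT.GetAtomicWeight(mol.atoms[a][0]) for a in shell)
    return out


def topo_cacf(mol: MoleculeRecord, center: int, spec: DescriptorSpec) -> np.ndarray:
    """GACF: sum over shell k of q_center * q_j; empty shell -> 0."""
    q = get_charges(mol, spec)
    out = np.zeros(spec.n_shells)
    for k, shell in enumerate(topological_shells(mol, center, spec.n_shells)):
        out[k] = q[center] * q[shell].sum()
    return out


def spatial_rdf(mol: MoleculeRecord, center: int, spec: DescriptorSpec) -> np.ndarray:
    """CRDF: charge-weighted Gaussian-smoothed radial distribution."""
    q = get_charges(mol, spec)
    xyz = _coords(mol)
    d = np.linalg.norm(xyz - xyz[center], axis=1)
    mask = np.arange(mol.num_atoms()) != center
    grid = spec.grid()
    return np.array([
        float(np.sum(q[mask] * np.exp(-spec.beta * (r - d[mask]) ** 2)))
        for r in grid
    ])


def spatial_cacf(mol: MoleculeRecord, center: int, spec: DescriptorSpec) -> np.ndarray:
    """CACF: smoothed center-anchored charge products, [positive | negative]."""
    q = get_charges(mol, spec)
    xyz = _coords(mol)
    d = np.linalg.norm(xyz - xyz[center], axis=1)
    products = q[center] * q
    grid = spec.grid()
    others = np.arange(mol.num_atoms()) != center
    pos = others & (products > 0)
    neg = others & (products < 0)
    blocks = []
    for mask in (pos, neg):
        blocks.append(np.array([
            float(np.sum(products[mask] * np.exp(-spec.beta * (r - d[mask]) ** 2)))
            for r in grid
        ]))
    return np.concatenate(blocks)


_DISPATCH = {
    "CS": charge_shell,
    "sorted_shell": sorted_shell,
    "MS": mass_shell,
    "GACF": topo_cacf,
    "CRDF": spatial_rdf,
    "CACF": spatial_cacf,
}


def compute_block(mol: MoleculeRecord, center: int, spec: DescriptorSpec) -> np.ndarray:
    """Evaluate one descriptor family for the given site atom."""
    return _DISPATCH[spec.family](mol, center, spec)


def spec_digest(specs: list[DescriptorSpec]) -> str:
    payload = json.dumps([asdict(s) for s in specs], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def combine_blocks(
    mol: MoleculeRecord, center: int, specs: list[DescriptorSpec]
) -> DescriptorVector:
    """Concatenate descriptor blocks in spec order into one site vector.

    Any strict-mode failure (empty averaged shell) propagates, marking the
    whole site descriptor-inapplicable.
    """
    if not specs:
        raise ValueError("empty descriptor spec list")
    blocks, layout, offset = [], [], 0
    for spec in specs:
        block = compute_block(mol, center, spec)
        layout.append((spec.family, offset, len(block)))
        offset += len(block)
        blocks.append(block)
    return DescriptorVector(
        values=np.concatenate(blocks), block_layout=layout, spec_hash=spec_digest(specs)
    )


def descriptor_matrix(
    items: list[tuple[MoleculeRecord, int]],
    specs: list[DescriptorSpec],
    strict: bool = True,
):
    """Stack site vectors into a pandas DataFrame with block-labelled columns.

    In non-strict mode descriptor-inapplicable sites are dropped (their row
    indices are returned separately) rather than aborting the matrix.
    """
    import pandas as pd

    rows, kept, dropped = [], [], []
    columns: list[str] | None = None
    for row_idx, (mol, center) in enumerate(items):
        try:
            vec = combine_blocks(mol, center, specs)
        except DescriptorInapplicableError:
            if strict:
                raise
            dropped.append(row_idx)
            continue
        if columns is None:
            columns = [
                f"{family}_{i}"
                for family, offset, length in vec.block_layout
                for i in range(length)
            ]
        rows.append(vec.values)
        kept.append(row_idx)
    frame = pd.DataFrame(np.array(rows) if rows else np.zeros((0, 0)), columns=columns)
    frame.index = kept
    return frame, dropped


def specs_from_json(path) -> list[DescriptorSpec]:
    """Load an ordered DescriptorSpec list from a JSON config file."""
    raw = json.loads(open(path).read())
    return [DescriptorSpec(**entry) for entry in raw]
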