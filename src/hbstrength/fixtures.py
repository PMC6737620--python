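"""Synthetic molecules, charges, geometries and targets for desk-scale runs.

The generator enumerates small organic molecules from a scaffold-by-
substituent template grammar spanning every donor/acceptor site kind
(alcohols, amines, ethers, carbonyls, N-heterocycles, thiols, alkynes),
assigns electronegativity-equalization pseudo-charges (charge-conserving by
construction) and embeds deterministic 3D coordinates by distance geometry
with a fixed seed.

``make_synthetic_strength_data`` emulates the statistical structure of the
calibration problem: a latent quantum-chemical free energy drawn uniformly
from [-60, 10] kJ/mol, an "experimental" target that is an affine map of it
plus Gaussian noise (default slope 0.56, intercept -20.12 kJ/mol, residual
sd 2.6 kJ/mol), energy-component triples that compose exactly to the latent
value, and a hydrogen-bond distance correlated with the target at a
configurable Pearson rho (default 0.5).  None of this is physically
realistic; it exists so every downstream stage is testable without any
quantum-chemistry output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import RDLogger
from rdkit.Chem import AllChem

from .descriptors import DescriptorSpec, descriptor_matrix, empirical_charges
from .molio import MoleculeRecord, StrengthEntry
from .sites import find_sites

logger = logging.getLogger(__name__)

ALL_FAMILIES = (
    "alcohols", "amines", "ethers", "carbonyls", "n_heterocycles", "thiols", "alkynes"
)

# scaffold grammar: each family is a list of SMILES templates with one {R}
# slot; substituents keep everything small and organic
_TEMPLATES = {
    "alcohols": ["{R}CO", "{R}C(C)O", "{R}CCO", "OC1CC{R}C1"],
    "amines": ["{R}CN", "{R}CNC", "{R}CCN", "CN(C){R}"],
    "ethers": ["{R}COC", "{R}CCOC", "C1CCOC1{R}", "{R}COCC"],
    "carbonyls": ["{R}C(C)=O", "{R}CC(C)=O", "{R}C(=O)OC", "{R}CC=O"],
    "n_heterocycles": [
        "c1ccncc1{R}", "c1cc[nH]c1{R}", "c1ncc[nH]1{R}", "c1ccnc(c1){R}"
    ],
    "thiols": ["{R}CS", "{R}CCS", "{R}C(C)S", "SC1CC{R}C1"],
    "alkynes": ["{R}CC#C", "{R}C#C", "{R}CCC#C", "CC({R})C#C"],
}

# prefix-safe substituents: valid as the leading atoms of "{R}..." templates;
# carbon/halogen only, so each family contributes exactly its own site kinds
_SUBSTITUENTS = ["C", "CC", "CCC", "CC(C)", "FC", "ClC", "C=CC", "CCCC", "CC(C)C"]


@dataclass
class FixtureConfig:
    n_molecules: int = 200
    seed: int = 0
    # (true slope, true intercept kJ/mol, residual noise sd kJ/mol)
    target_model: tuple[float, float, float] = (0.56, -20.12, 2.6)
    families: tuple[str, ...] = ALL_FAMILIES
    distance_rho: float = 0.5  # Pearson corr of X-H distance with the target

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.target_model[2] < 0:
            raise ValueError("noise sd must be non-negative")
        unknown = set(self.families) - set(ALL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")


def make_toy_molecules(cfg: FixtureConfig) -> list[MoleculeRecord]:
    """Deterministic small molecules with pseudo-charges and 3D coordinates."""
    rng = np.random.default_rng(cfg.seed)
    records: list[MoleculeRecord] = []
    families = list(cfg.families)
    count = 0
    RDLogger.DisableLog("rdApp.error")  # invalid grammar products are expected
    try:
        while len(records) < cfg.n_molecules:
            family = families[count % len(families)]
            template = _TEMPLATES[family][count // len(families) % len(_TEMPLATES[family])]
            sub = _SUBSTITUENTS[int(rng.integers(len(_SUBSTITUENTS)))]
            count += 1
            smiles = template.format(R=sub)
            try:
                record = MoleculeRecord.from_smiles(
                    smiles, name=f"mol{len(records):04d}_{family}"
                )
            except ValueError:
                continue  # a rare template x substituent clash; grammar moves on
            record.atom_charges = [float(q) for q in empirical_charges(record)]
            record.coords3d = _embed_coords(record, seed=cfg.seed + count)
            records.append(record)
    finally:
        RDLogger.EnableLog("rdApp.error")
    return records


def _embed_coords(
    record: MoleculeRecord, seed: int
) -> list[tuple[float, float, float]]:
    """Distance-geometry 3D coordinates; deterministic chain layout fallback."""
    mol = record.to_rdkit(with_coords=False)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed % (2**31 - 1)
    if AllChem.EmbedMolecule(mol, params) == 0:
        conf = mol.GetConformer()
        return [
            (round(p.x, 4), round(p.y, 4), round(p.z, 4))
            for p in (conf.GetAtomPosition(i) for i in range(mol.GetNumAtoms()))
        ]
    # stretched zig-zag keeps interatomic distances distinct and reproducible
    return [(1.3 * i, 0.4 * (i % 2), 0.0) for i in range(record.num_atoms())]


@dataclass
class SyntheticStrengthData:
    """Aligned outputs of the synthetic strength-data generator."""

    X: "object"  # pandas DataFrame of site descriptors
    y: np.ndarray  # synthetic experimental dG, kJ/mol
    entries: list[StrengthEntry] = field(default_factory=list)
    dg_qc: np.ndarray = field(default_factory=lambda: np.zeros(0))


def make_synthetic_strength_data(
    mols: list[MoleculeRecord],
    specs: list[DescriptorSpec],
    cfg: FixtureConfig,
    role: str = "HBA",
) -> SyntheticStrengthData:
    """Latent-linear synthetic targets with exact energy breakdowns.

    For every perceived site: dG_QC ~ U(-60, 10); the target is
    y = slope * dG_QC + intercept + N(0, sd); the emitted component triples
    compose exactly to dG_QC; the X-H distance is built as
    mu + sigma * (rho * z_y + sqrt(1 - rho^2) * eps) with z_y the target
    standardized by its *theoretical* moments, which makes the population
    Pearson correlation with y exactly rho.  Sites whose descriptors are
    inapplicable (empty averaged shell) are skipped with a log entry.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    slope, intercept, noise_sd = cfg.target_model
    sites = [
        (mol_idx, mol, site)
        for mol_idx, mol in enumerate(mols)
        for site in find_sites(mol, role)
    ]
    if not sites:
        raise ValueError("no sites perceived in the input molecules")

    items = [(mol, site.atom_index) for _, mol, site in sites]
    X, dropped = descriptor_matrix(items, specs, strict=False)
    if dropped:
        logger.info("%d descriptor-inapplicable sites skipped", len(dropped))
    kept = [i for i in range(len(sites)) if i not in set(dropped)]

    # theoretical moments of y for exact-population correlation construction
    y_mean_th = slope * (-25.0) + intercept
    y_sd_th = float(np.sqrt(slope**2 * 70.0**2 / 12.0 + noise_sd**2))

    entries: list[StrengthEntry] = []
    dg_qc_all = np.empty(len(kept))
    y_all = np.empty(len(kept))
    for row, site_i in enumerate(kept):
        mol_idx, mol, site = sites[site_i]
        dg_qc = float(rng.uniform(-60.0, 10.0))
        y = slope * dg_qc + intercept + float(rng.normal(0.0, noise_sd))
        z_y = (y - y_mean_th) / y_sd_th
        eps = float(rng.standard_normal())
        xh = 2.0 + 0.15 * (cfg.distance_rho * z_y
                           + np.sqrt(1 - cfg.distance_rho**2) * eps)
        triples = _exact_breakdown(rng, dg_qc)
        entries.append(
            StrengthEntry(
                fragment=mol,
                site_atom=site.atom_index,
                role=role,
                e_highdft=triples[0],
                g_rrho=triples[1],
                dg_solv=triples[2],
                dg_qc=dg_qc,
                dg_calibrated=y,
                xh_distance=float(xh),
                lowest_freq=float(rng.uniform(-45.0, 0.0)),
                converged=True,
                functional_class=site.site_kind,
                record_ordinal=mol_idx,
                donated_h_index=site.donated_h_index,
            )
        )
        dg_qc_all[row] = dg_qc
        y_all[row] = y
    return SyntheticStrengthData(X=X, y=y_all, entries=entries, dg_qc=dg_qc_all)


def _exact_breakdown(
    rng: np.random.Generator, dg_qc: float
) -> list[tuple[float, float, float]]:
    """Three (complex, molecule, reference) triples whose deltas sum to dg_qc."""
    de, dgr = rng.normal(dg_qc - 30.0, 5.0), rng.normal(35.0, 5.0)
    dsolv = dg_qc - de - dgr
    triples = []
    for delta in (de, dgr, dsolv):
        molecule = float(rng.normal(-1000.0, 50.0))
        reference = float(rng.normal(-500.0, 20.0))
        triples.append((float(delta) + molecule + reference, molecule, reference))
    return triples


def default_descriptor_specs(include_spatial: bool = True) -> list[DescriptorSpec]:
    """A modest combinatorial descriptor: CS + sorted_shell (+ CACF), K=W=2.

    Two shells keep the charge-averaged families applicable to the smallest
    fixture molecules while still exercising multi-shell logic.
    """
    specs = [
        DescriptorSpec(family="CS", n_shells=2),
        DescriptorSpec(family="sorted_shell", n_shells=2, shell_width=2),
    ]
    if include_spatial:
        specs.append(DescriptorSpec(family="CACF", r_min=1.0, r_max=4.0, r_step=0.5))
    return specs
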