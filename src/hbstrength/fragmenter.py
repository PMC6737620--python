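"""Shell-based extraction of hydrogen-bonding fragments.

Around each donor/acceptor site the substructure up to the 4th topological
shell is cut out, with three cases decided in priority order:

* ``ring`` — the site atom itself is in a ring: its whole fused ring system
  plus side chains up to the 4th shell are taken;
* ``ring_sidechain`` — a ring atom lies within the 3rd shell: that complete
  ring system is taken in addition to everything within 4 bonds;
* ``chain`` — no ring atom within 3 bonds: atoms within 4 bonds are taken,
  and 4th-shell atoms that sit in a ring are substituted by sp3 carbon caps
  so that shell occupancy is preserved without importing ring context.

Open valences are capped with hydrogens.  Fragments are identified by the
canonical SMILES of the kekulized graph, deduplicated with incidence
counting, filtered (organic elements, ring count, molecular weight, site
count, neutrality), grouped into element-by-topology classes, and
diversity-selected by Tanimoto clustering on MACCS structural keys with a
maximum-dissimilarity seeding strategy.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys
from rdkit.DataStructs import TanimotoSimilarity

from .molio import MoleculeRecord, canonical_smiles
from .sites import SiteAnnotation, find_sites

logger = logging.getLogger(__name__)

TOPO_CASES = ("chain", "ring_sidechain", "ring")


@dataclass
class FragmentRecord:
    """A capped HB fragment with provenance back to its parent molecules."""

    mol: MoleculeRecord
    site: SiteAnnotation
    topo_case: str
    canonical_key: str
    parent_ids: list[str] = field(default_factory=list)
    incidence: int = 1
    class_label: str | None = None


@dataclass
class FragmentFilterConfig:
    """Thresholds of the fragment selection step (all inclusive unless noted)."""

    allowed_elements: frozenset[str] = frozenset("H C N O F Cl S Br I".split())
    max_rings: int = 3
    max_mw: float = 300.0  # strict upper bound (kept iff MW < max_mw)
    max_sites: int = 4
    mw_correction: str = "none"  # none | halogen_corrected

    def __post_init__(self) -> None:
        if self.max_rings <= 0 or self.max_mw <= 0 or self.max_sites <= 0:
            raise ValueError("all thresholds must be positive")
        if self.mw_correction not in ("none", "halogen_corrected"):
            raise ValueError(f"unknown mw_correction {self.mw_correction!r}")


# -- graph helpers -------------------------------------------------------


def graph_distances(mol: MoleculeRecord, center: int) -> list[int]:
    """BFS graph distance from center to every atom (-1 if disconnected)."""
    adj: list[list[int]] = [[] for _ in mol.atoms]
    for (i, j), _ in mol.bonds:
        adj[i].append(j)
        adj[j].append(i)
    dist = [-1] * len(mol.atoms)
    dist[center] = 0
    queue = deque([center])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if dist[v] < 0:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def ring_systems(mol: MoleculeRecord) -> list[set[int]]:
    """Fused ring systems: rings merged when they share a bond."""
    rd = mol.to_rdkit(with_coords=False)
    rings = [set(r) for r in rd.GetRingInfo().AtomRings()]
    ring_bonds = [
        {frozenset(b) for b in zip(list(r), list(r)[1:] + [list(r)[0]])}
        for r in rd.GetRingInfo().AtomRings()
    ]
    systems: list[tuple[set[int], set[frozenset[int]]]] = []
    for atoms, bonds in zip(rings, ring_bonds):
        merged_atoms, merged_bonds = set(atoms), set(bonds)
        rest = []
        for satoms, sbonds in systems:
            if merged_bonds & sbonds:
                merged_atoms |= satoms
                merged_bonds |= sbonds
            else:
                rest.append((satoms, sbonds))
        systems = rest + [(merged_atoms, merged_bonds)]
    return [atoms for atoms, _ in systems]


# -- extraction ----------------------------------------------------------


def _determine_case(dist: list[int], in_ring: set[int], site: int) -> str:
    if site in in_ring:
        return "ring"
    if any(0 < dist[a] <= 3 for a in in_ring):
        return "ring_sidechain"
    return "chain"


def extract_fragment(mol: MoleculeRecord, site: SiteAnnotation) -> FragmentRecord:
    """Cut the 4-shell fragment around one site; cap valences with hydrogens.

    Ring systems containing an atom within 3 bonds of the site are included
    whole; ring atoms at exactly 4 bonds whose system is not included are
    substituted by sp3 carbon caps.
    """
    n = mol.num_atoms()
    if not (0 <= site.atom_index < n):
        raise ValueError(f"site atom {site.atom_index} out of range")
    dist = graph_distances(mol, site.atom_index)
    if dist[site.atom_index] != 0:
        raise ValueError("site atom disconnected")
    systems = ring_systems(mol)
    in_ring: set[int] = set().union(*systems) if systems else set()
    topo_case = _determine_case(dist, in_ring, site.atom_index)

    selected = {i for i in range(n) if 0 <= dist[i] <= 4}
    if topo_case in ("ring", "ring_sidechain"):
        for system in systems:
            if any(0 <= dist[a] <= 3 for a in system):
                selected |= system
    substituted = {
        i for i in selected if dist[i] == 4 and i in in_ring
        and not any(i in system and system <= selected for system in systems)
    }

    bond_order = {frozenset(pair): o for pair, o in mol.bonds}
    sel = sorted(selected)
    remap = {old: new for new, old in enumerate(sel)}

    rw = Chem.RWMol()
    for old in sel:
        sym, charge, hcount = mol.atoms[old]
        if old in substituted:
            sym, charge, hcount = "C", 0, 0
        atom = Chem.Atom(sym)
        atom.SetFormalCharge(charge)
        atom.SetNumExplicitHs(hcount)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for (i, j), o in mol.bonds:
        if i in selected and j in selected:
            if i in substituted or j in substituted:
                o = 1
            rw.AddBond(remap[i], remap[j], {1: Chem.BondType.SINGLE,
                                            2: Chem.BondType.DOUBLE,
                                            3: Chem.BondType.TRIPLE}[o])
    # cap severed valences
    for old in sel:
        atom = rw.GetAtomWithIdx(remap[old])
        if old in substituted:
            kept = sum(1 for (i, j), _ in mol.bonds
                       if frozenset((i, j)) <= selected and old in (i, j))
            atom.SetNumExplicitHs(max(0, 4 - kept))
            continue
        severed = sum(
            bond_order[frozenset((old, nbr))]
            for (i, j), _ in mol.bonds
            for nbr in ((j,) if i == old else (i,) if j == old else ())
            if nbr not in selected
        )
        if severed:
            atom.SetNumExplicitHs(atom.GetNumExplicitHs() + severed)
    frag = rw.GetMol()
    Chem.SanitizeMol(frag)

    frag_record = MoleculeRecord.from_rdkit(frag, name=f"{mol.name}|site{site.atom_index}")
    if mol.atom_charges is not None:
        # substituted caps and added hydrogens have no parent charge; keep the
        # parent charge for carried-over atoms, 0 for caps
        frag_record.atom_charges = [
            0.0 if old in substituted else mol.atom_charges[old] for old in sel
        ]
    donated = site.donated_h_index
    new_site = SiteAnnotation(
        atom_index=remap[site.atom_index],
        role=site.role,
        site_kind=site.site_kind,
        donated_h_index=remap[donated] if donated is not None else None,
    )
    return FragmentRecord(
        mol=frag_record,
        site=new_site,
        topo_case=topo_case,
        canonical_key=canonical_smiles(frag),
        parent_ids=[mol.name] if mol.name else [],
        incidence=1,
    )


def extract_all_fragments(
    mols: list[MoleculeRecord], role: str
) -> list[FragmentRecord]:
    """Extract one fragment per (molecule, site) for the requested role."""
    frags = []
    for idx, mol in enumerate(mols):
        for site in find_sites(mol, role):
            frag = extract_fragment(mol, site)
            if not frag.parent_ids:
                frag.parent_ids = [f"record{idx}"]
            frags.append(frag)
    return frags


# -- filtering / dedup / classes ----------------------------------------

_HALOGEN_MASSES = {"Br": 79.904, "I": 126.904}
_CL_MASS = 35.45


def _corrected_mw(mol: Chem.Mol, mode: str) -> float:
    mw = Descriptors.MolWt(mol)
    if mode == "halogen_corrected":
        for atom in mol.GetAtoms():
            sym = atom.GetSymbol()
            if sym in _HALOGEN_MASSES:
                mw -= _HALOGEN_MASSES[sym] - _CL_MASS
    return mw


def filter_fragments(
    frags: list[FragmentRecord],
    cfg: FragmentFilterConfig | None = None,
    role: str = "HBA",
) -> tuple[list[FragmentRecord], list[tuple[FragmentRecord, str]]]:
    """Keep organic, small, neutral fragments; report first failing rule.

    Rules in order: allowed elements; ring count <= max_rings; (corrected)
    MW < max_mw; site count for ``role`` <= max_sites; net formal charge 0.
    """
    cfg = cfg or FragmentFilterConfig()
    kept, rejected = [], []
    for frag in frags:
        rd = frag.mol.to_rdkit(with_coords=False)
        reason = None
        elements = {sym for sym, _, _ in frag.mol.atoms}
        if not elements <= cfg.allowed_elements:
            reason = "element"
        elif rd.GetRingInfo().NumRings() > cfg.max_rings:
            reason = "rings"
        elif not _corrected_mw(rd, cfg.mw_correction) < cfg.max_mw:
            reason = "mw"
        elif len(find_sites(frag.mol, role)) > cfg.max_sites:
            reason = "sites"
        elif sum(charge for _, charge, _ in frag.mol.atoms) != 0:
            reason = "charge"
        if reason is None:
            kept.append(frag)
        else:
            rejected.append((frag, reason))
    return kept, rejected


def dedup_fragments(frags: list[FragmentRecord]) -> list[FragmentRecord]:
    """Merge fragments with identical canonical SMILES keys.

    Incidences are summed, parent ids concatenated; output is sorted by
    descending incidence then key.  Idempotent.
    """
    by_key: dict[str, FragmentRecord] = {}
    for frag in frags:
        kept = by_key.get(frag.canonical_key)
        if kept is None:
            by_key[frag.canonical_key] = FragmentRecord(
                mol=frag.mol,
                site=frag.site,
                topo_case=frag.topo_case,
                canonical_key=frag.canonical_key,
                parent_ids=list(frag.parent_ids),
                incidence=frag.incidence,
                class_label=frag.class_label,
            )
        else:
            kept.incidence += frag.incidence
            kept.parent_ids.extend(frag.parent_ids)
    return sorted(by_key.values(), key=lambda f: (-f.incidence, f.canonical_key))


def assign_class(frag: FragmentRecord) -> str:
    """Element-by-topology class label, e.g. ``O-chain`` or ``N-ring``.

    Donor elements are O, N, S and sp-carbon (terminal alkynes, labelled
    ``Csp``); acceptor elements are O and N.
    """
    element = frag.mol.atoms[frag.site.atom_index][0]
    if frag.site.role == "HBD" and frag.site.site_kind == "alkyne_CH_donor":
        element = "Csp"
    allowed = ("O", "N") if frag.site.role == "HBA" else ("O", "N", "S", "Csp")
    if element not in allowed:
        raise ValueError(f"unexpected site element {element!r} for {frag.site.role}")
    frag.class_label = f"{element}-{frag.topo_case}"
    return frag.class_label


# -- diversity selection -------------------------------------------------


def _tanimoto_distance_matrix(frags: list[FragmentRecord]) -> list[list[float]]:
    fps = [MACCSkeys.GenMACCSKeys(f.mol.to_rdkit(with_coords=False)) for f in frags]
    n = len(fps)
    dmat = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - TanimotoSimilarity(fps[i], fps[j])
            dmat[i][j] = dmat[j][i] = d
    return dmat


def _cluster_max_dissimilarity(dmat: list[list[float]], k: int) -> list[list[int]]:
    """Deterministic max-dissimilarity seeding + nearest-seed assignment +
    medoid refinement."""
    n = len(dmat)
    k = min(k, n)
    totals = [sum(row) for row in dmat]
    seeds = [max(range(n), key=lambda i: (totals[i], -i))]
    while len(seeds) < k:
        seeds.append(
            max(range(n), key=lambda i: (min(dmat[i][s] for s in seeds), -i))
        )
    medoids = list(seeds)
    for _ in range(20):
        clusters: list[list[int]] = [[] for _ in medoids]
        for i in range(n):
            best = min(range(len(medoids)), key=lambda c: (dmat[i][medoids[c]], c))
            clusters[best].append(i)
        new_medoids = [
            min(members, key=lambda i: (sum(dmat[i][j] for j in members), i))
            if members else medoids[c]
            for c, members in enumerate(clusters)
        ]
        if new_medoids == medoids:
            break
        medoids = new_medoids
    return [members for members in clusters if members]


def select_diverse(
    frags: list[FragmentRecord],
    per_class: bool = True,
    k_divisor: int = 25,
    keep_central: int = 3,
    cluster_cap: int = 30,
    seed: int = 0,
) -> list[FragmentRecord]:
    """Diversity selection: per class, cluster on MACCS/Tanimoto and keep the
    most central members of each cluster.

    Cluster count is ``max(1, floor(N / k_divisor))`` per class; from each
    cluster the ``keep_central`` members with minimum summed intra-cluster
    distance are kept, never more than ``cluster_cap``.  Fully deterministic
    for a given input order; ``seed`` is accepted for interface stability.
    """
    del seed  # the procedure is deterministic; no randomness is consumed
    groups: dict[str, list[FragmentRecord]] = {}
    if per_class:
        for frag in frags:
            label = frag.class_label or assign_class(frag)
            groups.setdefault(label, []).append(frag)
    else:
        groups["all"] = list(frags)

    selected: list[FragmentRecord] = []
    for label in sorted(groups):
        members = groups[label]
        if not members:
            logger.info("class %s is empty; skipped", label)
            continue
        dmat = _tanimoto_distance_matrix(members)
        k = max(1, len(members) // k_divisor)
        clusters = _cluster_max_dissimilarity(dmat, k)
        for cluster in clusters:
            ranked = sorted(
                cluster, key=lambda i: (sum(dmat[i][j] for j in cluster), i)
            )
            keep = min(keep_central, cluster_cap, len(ranked))
            selected.extend(members[i] for i in ranked[:keep])
    return selected


def n_clusters_for(n_fragments: int, k_divisor: int = 25) -> int:
    """Cluster count rule: 1/k_divisor of the class size, at least one."""
    return max(1, n_fragments // k_divisor)
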