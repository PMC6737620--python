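"""Perception of hydrogen-bond acceptor and donor sites.

Acceptors: every oxygen, and every nitrogen except those covalently bound to
an oxygen (any bond order) — this excludes nitro, N-oxide and nitroso
nitrogens while keeping both nitro oxygens as acceptors.  Donors: O-H
(alcohols, carboxylic acids), N-H (primary/secondary amines, amides,
pyrrole-like ring N-H), S-H (thiols) and terminal alkyne C-H.  The patterns
are R-substituted, so bare water/ammonia/H2S are not sites: the heavy atom
must have at least one heavy-atom neighbour.

Donor perception needs the donated hydrogen as a graph atom, so records
should carry explicit hydrogens (``MoleculeRecord.from_smiles`` adds them by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

from .molio import MoleculeRecord

ACCEPTOR_KINDS = ("O_acceptor", "N_acceptor")
DONOR_KINDS = ("OH_donor", "NH2_donor", "NH_donor", "SH_donor", "alkyne_CH_donor")


@dataclass(frozen=True)
class SiteAnnotation:
    """A donor or acceptor heavy atom on a molecule (0-based indices)."""

    atom_index: int
    role: str  # HBA | HBD
    site_kind: str
    donated_h_index: int | None = None

    def __post_init__(self) -> None:
        if self.role == "HBA" and self.site_kind not in ACCEPTOR_KINDS:
            raise ValueError(f"bad acceptor kind {self.site_kind!r}")
        if self.role == "HBD":
            if self.site_kind not in DONOR_KINDS:
                raise ValueError(f"bad donor kind {self.site_kind!r}")
            if self.donated_h_index is None:
                raise ValueError("donor site requires donated_h_index")


def _neighbors(mol: MoleculeRecord) -> list[list[tuple[int, int]]]:
    """Adjacency list of (neighbor index, bond order)."""
    adj: list[list[tuple[int, int]]] = [[] for _ in mol.atoms]
    for (i, j), order in mol.bonds:
        adj[i].append((j, order))
        adj[j].append((i, order))
    return adj


def _symbol(mol: MoleculeRecord, idx: int) -> str:
    return mol.atoms[idx][0]


def _hydrogen_neighbors(mol: MoleculeRecord, adj, idx: int) -> list[int]:
    return sorted(j for j, _ in adj[idx] if _symbol(mol, j) == "H")


def _heavy_neighbors(mol: MoleculeRecord, adj, idx: int) -> list[int]:
    return [j for j, _ in adj[idx] if _symbol(mol, j) != "H"]


def _total_h(mol: MoleculeRecord, adj, idx: int) -> int:
    # graph hydrogens plus the record's implicit-H count for that atom
    return len(_hydrogen_neighbors(mol, adj, idx)) + mol.atoms[idx][2]


def find_acceptor_sites(mol: MoleculeRecord) -> list[SiteAnnotation]:
    """All acceptor sites, ordered by atom index."""
    adj = _neighbors(mol)
    sites = []
    for idx, (sym, _charge, _h) in enumerate(mol.atoms):
        if sym == "O":
            if _heavy_neighbors(mol, adj, idx):
                sites.append(SiteAnnotation(idx, "HBA", "O_acceptor"))
        elif sym == "N":
            bound_to_oxygen = any(_symbol(mol, j) == "O" for j, _ in adj[idx])
            if not bound_to_oxygen and _heavy_neighbors(mol, adj, idx):
                sites.append(SiteAnnotation(idx, "HBA", "N_acceptor"))
    return sites


def find_donor_sites(mol: MoleculeRecord) -> list[SiteAnnotation]:
    """All donor sites, one per heavy atom, ordered by atom index.

    A heavy atom with several hydrogens (e.g. an NH2) yields a single site
    whose donated hydrogen is the lowest-index attached hydrogen.
    """
    adj = _neighbors(mol)
    sites = []
    for idx, (sym, _charge, implicit_h) in enumerate(mol.atoms):
        if sym == "H":
            continue
        hs = _hydrogen_neighbors(mol, adj, idx)
        if implicit_h and sym in ("O", "N", "S"):
            raise ValueError(
                f"atom {idx} ({sym}) carries implicit hydrogens; donor perception "
                "requires explicit hydrogen atoms"
            )
        if not hs:
            continue
        heavy = _heavy_neighbors(mol, adj, idx)
        if not heavy:
            continue  # water / ammonia / H2S: no R group
        kind = None
        if sym == "O":
            kind = "OH_donor"
        elif sym == "N":
            kind = "NH2_donor" if len(hs) >= 2 else "NH_donor"
        elif sym == "S":
            kind = "SH_donor"
        elif sym == "C":
            # terminal alkyne: sp carbon in a triple bond bearing an H
            if any(order == 3 and _symbol(mol, j) == "C" for j, order in adj[idx]):
                kind = "alkyne_CH_donor"
        if kind is not None:
            sites.append(SiteAnnotation(idx, "HBD", kind, donated_h_index=hs[0]))
    return sites


def find_sites(mol: MoleculeRecord, role: str = "both") -> list[SiteAnnotation]:
    """Acceptors, donors, or both (acceptors first)."""
    if role == "HBA":
        return find_acceptor_sites(mol)
    if role == "HBD":
        return find_donor_sites(mol)
    if role == "both":
        return find_acceptor_sites(mol) + find_donor_sites(mol)
    raise ValueError(f"role must be HBA, HBD or both, got {role!r}")
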