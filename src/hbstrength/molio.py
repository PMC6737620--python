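"""Molecule and strength-database I/O in the SDF/SMILES property-tag dialect.

Molecules are held as :class:`MoleculeRecord`, a kekulized graph (integer bond
orders only, no aromatic bond type) with optional 3D coordinates, per-atom
partial charges and a free-form property map.  Hydrogen-bond strength
databases are SDF files whose property tags carry per-site free energies,
energy-component triples and complex geometry metadata; the tag names are
resolved through a JSON-overridable tag dictionary so that dialect drift in
external databases fails loudly instead of silently.

Energies are stored internally in kJ/mol; Hartree and kcal/mol inputs are
converted on read via an explicit unit flag.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

HARTREE_TO_KJ = 2625.4996
KCAL_TO_KJ = 4.184

_BOND_ORDER_TO_TYPE = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}

#: Default property-tag dictionary for strength databases.  Override any
#: entry with a JSON file via ``load_tag_dict``.
DEFAULT_TAG_DICT = {
    "role": "ROLE",
    "site_indices": "SITE_IDX",
    "dg_calibrated": "DG_KJMOL",
    "dg_qc": "DG_SOL_QC_KJMOL",
    "e_highdft": "E_HIGHDFT_KJMOL",
    "g_rrho": "G_RRHO_KJMOL",
    "dg_solv": "DG_SOLV_KJMOL",
    "xh_distance": "XH_DISTANCE_ANG",
    "lowest_freq": "LOWEST_FREQ_CM",
    "converged": "CONVERGED",
    "functional_class": "FUNCTIONAL_CLASS",
    "atom_charges": "ATOM_CHARGES",
    "donated_h_indices": "DONATED_H_IDX",
    "acceptor_indices": "ACCEPTOR_IDX",
}


class MolfileParseError(ValueError):
    """A molblock could not be parsed or kekulized; names the record ordinal."""


def convert_energy(value: float, unit: str = "kj") -> float:
    """Convert an energy to kJ/mol from ``kj``, ``kcal`` or ``hartree``."""
    factors = {"kj": 1.0, "kcal": KCAL_TO_KJ, "hartree": HARTREE_TO_KJ}
    try:
        return value * factors[unit]
    except KeyError:
        raise ValueError(f"unknown energy unit {unit!r}") from None


@dataclass
class MoleculeRecord:
    """Kekulized molecular graph with optional coordinates/charges/props.

    ``atoms`` holds ``(element symbol, formal charge, hydrogen count)``
    triples where the hydrogen count covers hydrogens *not* present as graph
    atoms; ``bonds`` holds ``((i, j), order)`` with integer orders 1-3.
    Atom indexing is 0-based internally (SDF serialization is 1-based).
    """

    atoms: list[tuple[str, int, int]]
    bonds: list[tuple[tuple[int, int], int]]
    coords3d: list[tuple[float, float, float]] | None = None
    atom_charges: list[float] | None = None
    props: dict[str, str] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for (i, j), order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references atom out of range (n={n})")
            if order not in (1, 2, 3):
                raise ValueError(f"bond order {order!r} is not an integer in 1..3")
        if self.coords3d is not None and len(self.coords3d) != n:
            raise ValueError("coords3d length does not match atom count")
        if self.atom_charges is not None and len(self.atom_charges) != n:
            raise ValueError("atom_charges length does not match atom count")

    # -- conversions ----------------------------------------------------

    def to_rdkit(self, with_coords: bool = True) -> Chem.Mol:
        """Build a sanitized RDKit molecule (kekulized bond orders)."""
        rw = Chem.RWMol()
        for sym, charge, hcount in self.atoms:
            atom = Chem.Atom(sym)
            atom.SetFormalCharge(charge)
            atom.SetNumExplicitHs(hcount)
            atom.SetNoImplicit(True)
            rw.AddAtom(atom)
        for (i, j), order in self.bonds:
            rw.AddBond(i, j, _BOND_ORDER_TO_TYPE[order])
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        if with_coords and self.coords3d is not None:
            conf = Chem.Conformer(mol.GetNumAtoms())
            for idx, (x, y, z) in enumerate(self.coords3d):
                conf.SetAtomPosition(idx, Point3D(x, y, z))
            mol.AddConformer(conf, assignId=True)
        if self.name:
            mol.SetProp("_Name", self.name)
        return mol

    @classmethod
    def from_rdkit(
        cls,
        mol: Chem.Mol,
        props: dict[str, str] | None = None,
        atom_charges: Sequence[float] | None = None,
        name: str | None = None,
    ) -> "MoleculeRecord":
        """Extract a kekulized record; raises on non-integer bond orders."""
        mol = Chem.Mol(mol)
        Chem.Kekulize(mol, clearAromaticFlags=True)
        atoms = [
            (a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs(False))
            for a in mol.GetAtoms()
        ]
        bonds = []
        for b in mol.GetBonds():
            order = b.GetBondTypeAsDouble()
            if order != int(order):
                raise ValueError("non-integer bond order after kekulization")
            bonds.append(((b.GetBeginAtomIdx(), b.GetEndAtomIdx()), int(order)))
        coords = None
        if mol.GetNumConformers():
            conf = mol.GetConformer()
            coords = [
                (p.x, p.y, p.z)
                for p in (conf.GetAtomPosition(i) for i in range(mol.GetNumAtoms()))
            ]
        if name is None:
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        return cls(
            atoms=atoms,
            bonds=bonds,
            coords3d=coords,
            atom_charges=list(atom_charges) if atom_charges is not None else None,
            props=dict(props or {}),
            name=name,
        )

    @classmethod
    def from_smiles(
        cls, smiles: str, name: str = "", add_hs: bool = True
    ) -> "MoleculeRecord":
        """Parse SMILES into a kekulized record, adding explicit hydrogens."""
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparsable SMILES: {smiles!r}")
        if add_hs:
            mol = Chem.AddHs(mol)
        return cls.from_rdkit(mol, name=name)

    def to_smiles(self) -> str:
        """Canonical SMILES of the kekulized graph (hydrogens collapsed)."""
        return canonical_smiles(self.to_rdkit(with_coords=False))

    def num_atoms(self) -> int:
        return len(self.atoms)

    def heavy_atom_indices(self) -> list[int]:
        return [i for i, (sym, _, _) in enumerate(self.atoms) if sym != "H"]

    def with_props(self, **props: str) -> "MoleculeRecord":
        merged = dict(self.props)
        merged.update(props)
        return replace(self, props=merged)


def canonical_smiles(mol: Chem.Mol) -> str:
    """Canonical kekulized SMILES used as fragment identity key."""
    mol = Chem.RemoveHs(Chem.Mol(mol))
    Chem.Kekulize(mol, clearAromaticFlags=True)
    return Chem.MolToSmiles(mol, kekuleSmiles=True)


@dataclass
class StrengthEntry:
    """One HBA/HBD site of a database record with its energy breakdown.

    Energy triples are ``(complex, molecule, reference)`` in kJ/mol.  Optional
    fields absent from the source file stay ``None`` (never zero-filled).
    """

    fragment: MoleculeRecord
    site_atom: int
    role: str
    e_highdft: tuple[float, float, float] | None = None
    g_rrho: tuple[float, float, float] | None = None
    dg_solv: tuple[float, float, float] | None = None
    dg_qc: float | None = None
    dg_calibrated: float | None = None
    xh_distance: float | None = None
    lowest_freq: float | None = None
    converged: bool | None = None
    functional_class: str | None = None
    record_ordinal: int = -1
    donated_h_index: int | None = None
    acceptor_index: int | None = None

    def __post_init__(self) -> None:
        if self.role not in ("HBA", "HBD"):
            raise ValueError(f"role must be HBA or HBD, got {self.role!r}")
        if self.xh_distance is not None and not self.xh_distance > 0:
            raise ValueError("xh_distance must be positive when present")
        if (
            self.dg_qc is not None
            and self.e_highdft is not None
            and self.g_rrho is not None
            and self.dg_solv is not None
        ):
            composed = sum(
                t[0] - t[1] - t[2]
                for t in (self.e_highdft, self.g_rrho, self.dg_solv)
            )
            if not math.isclose(self.dg_qc, composed, abs_tol=1e-6):
                raise ValueError(
                    f"dg_qc={self.dg_qc} does not match composed value {composed}"
                )

    def site_element(self) -> str:
        return self.fragment.atoms[self.site_atom][0]


def load_tag_dict(path: str | Path | None) -> dict[str, str]:
    """Merge a user tag-dictionary JSON over the defaults; unknown keys fail."""
    tags = dict(DEFAULT_TAG_DICT)
    if path is not None:
        user = json.loads(Path(path).read_text())
        unknown = sorted(set(user) - set(tags))
        if unknown:
            raise ValueError(f"unknown tag-dictionary keys: {unknown}")
        tags.update(user)
    return tags


# -- SDF reading/writing ------------------------------------------------


def _record_from_supplier_item(
    mol: Chem.Mol, ordinal: int, require_kekulized: bool
) -> MoleculeRecord:
    if mol is None:
        raise MolfileParseError(f"record {ordinal}: malformed molblock")
    try:
        Chem.SanitizeMol(mol)
        record = MoleculeRecord.from_rdkit(mol, props=_string_props(mol))
    except Exception as exc:  # rdkit raises several exception types here
        if require_kekulized:
            raise MolfileParseError(f"record {ordinal}: {exc}") from exc
        raise
    charges_tag = DEFAULT_TAG_DICT["atom_charges"]
    if charges_tag in record.props:
        charges = [float(v) for v in record.props[charges_tag].split()]
        if len(charges) != record.num_atoms():
            raise MolfileParseError(
                f"record {ordinal}: {charges_tag} has {len(charges)} values "
                f"for {record.num_atoms()} atoms"
            )
        record.atom_charges = charges
    return record


def _string_props(mol: Chem.Mol) -> dict[str, str]:
    return {
        key: mol.GetProp(key)
        for key in mol.GetPropNames()
        if not key.startswith("_")
    }


def read_sdf(
    path: str | Path,
    require_kekulized: bool = True,
    rejects_path: str | Path | None = None,
) -> list[MoleculeRecord]:
    """Read a V2000 SDF into kekulized records, in file order.

    Records that fail parsing or kekulization raise
    :class:`MolfileParseError` naming the record ordinal, unless
    ``rejects_path`` is given, in which case they are quarantined there with
    the failure reason and reading continues.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    records: list[MoleculeRecord] = []
    rejects: list[str] = []
    for ordinal, mol in enumerate(supplier):
        try:
            records.append(_record_from_supplier_item(mol, ordinal, require_kekulized))
        except MolfileParseError as exc:
            if rejects_path is None:
                raise
            rejects.append(f"# record {ordinal}: {exc}\n")
    if rejects_path is not None:
        Path(rejects_path).write_text("".join(rejects))
    return records


def write_sdf(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write records as kekulized V2000 SDF; charges go to an ATOM_CHARGES tag."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    try:
        for record in records:
            mol = record.to_rdkit()
            if record.coords3d is None:
                AllChem.Compute2DCoords(mol)
            for key, value in record.props.items():
                mol.SetProp(key, str(value))
            if record.atom_charges is not None:
                mol.SetProp(
                    DEFAULT_TAG_DICT["atom_charges"],
                    " ".join(f"{q:.6f}" for q in record.atom_charges),
                )
            writer.write(mol)
    finally:
        writer.close()


# -- strength-database dialect ------------------------------------------


def _parse_triple(chunk: str, unit: str) -> tuple[float, float, float]:
    values = [convert_energy(float(v), unit) for v in chunk.split()]
    if len(values) != 3:
        raise ValueError(f"expected 3 energy values, got {len(values)}")
    return (values[0], values[1], values[2])


def _per_site(
    record: MoleculeRecord, tag: str, n_sites: int, ordinal: int, triple: bool = False
) -> list[str] | None:
    """Split a per-site tag value; triple-valued tags separate sites by ';'."""
    raw = record.props.get(tag)
    if raw is None:
        return None
    chunks = [c.strip() for c in raw.split(";")] if triple else raw.split()
    if len(chunks) != n_sites:
        raise MolfileParseError(
            f"record {ordinal}: tag {tag} has {len(chunks)} values for {n_sites} sites"
        )
    return chunks


def read_strength_entries(
    path: str | Path,
    role: str,
    tag_dict: dict[str, str] | None = None,
    energy_unit: str = "kj",
) -> list[StrengthEntry]:
    """Read a strength database SDF into one entry per annotated site.

    Per-site tags hold one value per site index (semicolon-separated for
    triple-valued tags, whitespace otherwise), aligned with the 1-based
    ``SITE_IDX`` tag.  Missing optional tags leave fields ``None``.
    """
    if role not in ("HBA", "HBD"):
        raise ValueError(f"role must be HBA or HBD, got {role!r}")
    tags = dict(DEFAULT_TAG_DICT, **(tag_dict or {}))
    entries: list[StrengthEntry] = []
    for ordinal, record in enumerate(read_sdf(path)):
        file_role = record.props.get(tags["role"])
        if file_role is not None and file_role != role:
            raise ValueError(
                f"record {ordinal}: role tag {file_role!r} does not match requested {role!r}"
            )
        site_raw = record.props.get(tags["site_indices"])
        if site_raw is None:
            raise MolfileParseError(f"record {ordinal}: missing {tags['site_indices']} tag")
        sites = [int(v) - 1 for v in site_raw.split()]
        n = len(sites)

        def col(key: str, triple: bool = False, n=n, record=record, ordinal=ordinal):
            return _per_site(record, tags[key], n, ordinal, triple=triple)

        try:
            dg_cal = col("dg_calibrated")
            dg_qc = col("dg_qc")
            e_hi = col("e_highdft", triple=True)
            g_rrho = col("g_rrho", triple=True)
            dg_solv = col("dg_solv", triple=True)
            xh = col("xh_distance")
            freq = col("lowest_freq")
            conv = col("converged")
            fclass = col("functional_class")
            h_idx = col("donated_h_indices")
            acc_idx = col("acceptor_indices")
            for k, site in enumerate(sites):
                entries.append(
                    StrengthEntry(
                        fragment=record,
                        site_atom=site,
                        role=role,
                        e_highdft=_parse_triple(e_hi[k], energy_unit) if e_hi else None,
                        g_rrho=_parse_triple(g_rrho[k], energy_unit) if g_rrho else None,
                        dg_solv=_parse_triple(dg_solv[k], energy_unit) if dg_solv else None,
                        dg_qc=convert_energy(float(dg_qc[k]), energy_unit) if dg_qc else None,
                        dg_calibrated=(
                            convert_energy(float(dg_cal[k]), energy_unit) if dg_cal else None
                        ),
                        xh_distance=float(xh[k]) if xh else None,
                        lowest_freq=float(freq[k]) if freq else None,
                        converged=conv[k].lower() in ("1", "true", "yes") if conv else None,
                        functional_class=fclass[k] if fclass else None,
                        record_ordinal=ordinal,
                        donated_h_index=int(h_idx[k]) - 1 if h_idx else None,
                        acceptor_index=int(acc_idx[k]) - 1 if acc_idx else None,
                    )
                )
        except MolfileParseError:
            raise
        except ValueError as exc:
            raise MolfileParseError(f"record {ordinal}: {exc}") from exc
    return entries


def write_strength_entries(
    entries: Sequence[StrengthEntry], path: str | Path, tag_dict: dict[str, str] | None = None
) -> None:
    """Serialize entries grouped by parent record, inverse of the reader."""
    tags = dict(DEFAULT_TAG_DICT, **(tag_dict or {}))
    grouped: dict[int, list[StrengthEntry]] = {}
    for e in entries:
        grouped.setdefault(e.record_ordinal, []).append(e)

    def fmt_triple(t: tuple[float, float, float]) -> str:
        return " ".join(f"{v:.10f}" for v in t)

    records = []
    for ordinal in sorted(grouped):
        group = grouped[ordinal]
        rec = group[0].fragment
        props = dict(rec.props)
        props[tags["role"]] = group[0].role
        props[tags["site_indices"]] = " ".join(str(e.site_atom + 1) for e in group)

        def put(key: str, values: list[str | None], sep: str = " ") -> None:
            if all(v is not None for v in values):
                props[tags[key]] = sep.join(values)  # type: ignore[arg-type]

        put("dg_calibrated", [None if e.dg_calibrated is None else f"{e.dg_calibrated:.10f}" for e in group])
        put("dg_qc", [None if e.dg_qc is None else f"{e.dg_qc:.10f}" for e in group])
        put("e_highdft", [None if e.e_highdft is None else fmt_triple(e.e_highdft) for e in group], ";")
        put("g_rrho", [None if e.g_rrho is None else fmt_triple(e.g_rrho) for e in group], ";")
        put("dg_solv", [None if e.dg_solv is None else fmt_triple(e.dg_solv) for e in group], ";")
        put("xh_distance", [None if e.xh_distance is None else f"{e.xh_distance:.4f}" for e in group])
        put("lowest_freq", [None if e.lowest_freq is None else f"{e.lowest_freq:.2f}" for e in group])
        put("converged", [None if e.converged is None else str(int(e.converged)) for e in group])
        put("functional_class", [e.functional_class for e in group])
        put("donated_h_indices", [None if e.donated_h_index is None else str(e.donated_h_index + 1) for e in group])
        put("acceptor_indices", [None if e.acceptor_index is None else str(e.acceptor_index + 1) for e in group])
        records.append(replace(rec, props=props))
    write_sdf(records, path)


def read_smiles_file(path: str | Path, add_hs: bool = True) -> list[MoleculeRecord]:
    """Read one SMILES per line with an optional whitespace-separated name."""
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        name = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
        records.append(MoleculeRecord.from_smiles(smiles, name=name, add_hs=add_hs))
    return records
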