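"""Molecular model, structure I/O and GRID-style hydrogen-bond atom typing.

Atoms of a 3D molecule are classified into hydrogen-bond atom-type codes
(``N:=`` aromatic nitrogen, ``OH`` phenolic hydroxyl, ...) by substructure
patterns evaluated in a fixed precedence order. The pattern table lives in
``data/atom_type_patterns.csv`` and is deliberately editable: the codes
describe chemistry (hybridization, hydrogen count, neighbours), and the
patterns are the package's transcription of those textual descriptions.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import FormatError, GeometryError, InputError, StateError

logger = logging.getLogger(__name__)

#: Codes an atom may be assigned. ``C_generic``/``H_polar``/``other`` carry no
#: hydrogen-bond role and exist so every atom has a classification.
HB_CODES = (
    "N:", "N1:", "N2:", "ON", "N:=", "N::", "N:#",
    "O1", "OC1", "OC2", "OC=", "OES", "OFU", "OH", "O=S", "OS", "O=", "O",
)
NON_HB_CODES = ("C_generic", "H_polar", "other")

ACCEPTOR = "acceptor"
DONOR = "donor"

_SMILES_EMBED_SEED = 20210819  # fixed: single deterministic conformer


@dataclass(frozen=True)
class Atom:
    element: str
    formal_charge: int
    aromatic: bool
    coords: tuple[float, float, float]
    n_h: int  # explicit hydrogens bonded to this atom


@dataclass
class Molecule:
    """A 3D small molecule with explicit hydrogens.

    Thin immutable view over an RDKit molecule; the RDKit object is kept for
    perception tasks (SMARTS matching, ring info) so it is never re-derived.
    """

    name: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    provenance: str = ""
    rdmol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise InputError(f"bond ({i},{j}) outside atom range of {self.name}")
        if not np.isfinite(self.coords_array()).all():
            raise InputError(f"non-finite coordinates in {self.name}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @classmethod
    def from_rdkit(cls, rdmol: Chem.Mol, name: str = "", provenance: str = "") -> "Molecule":
        if rdmol.GetNumConformers() == 0:
            raise StateError(f"molecule {name!r} has no 3D conformer")
        conf = rdmol.GetConformer()
        atoms = []
        for a in rdmol.GetAtoms():
            p = conf.GetAtomPosition(a.GetIdx())
            atoms.append(Atom(
                element=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                aromatic=a.GetIsAromatic(),
                coords=(p.x, p.y, p.z),
                n_h=sum(1 for nb in a.GetNeighbors() if nb.GetAtomicNum() == 1),
            ))
        bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
                 for b in rdmol.GetBonds()]
        return cls(name=name or (rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""),
                   atoms=atoms, bonds=bonds, provenance=provenance, rdmol=rdmol)


@dataclass(frozen=True)
class AtomTypeAssignment:
    atom_index: int
    at_code: str
    roles: frozenset[str]


def mol_from_smiles(smiles: str, name: str = "", seed: int = _SMILES_EMBED_SEED) -> Molecule:
    """Parse SMILES, add explicit hydrogens and embed a single 3D conformer.

    The embedding (ETKDGv3, fixed seed) is a stand-in for a proper
    semi-empirical geometry optimisation; typing and topological fingerprints
    do not depend on the geometry, only the interaction fields do.
    """
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise FormatError(f"unparseable SMILES: {smiles!r}")
    rdmol = Chem.AddHs(rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(rdmol, params) != 0:
        raise GeometryError(f"3D embedding failed for {smiles!r}")
    return Molecule.from_rdkit(rdmol, name=name or smiles, provenance=f"smiles:{smiles}")


def read_structures(path: str | Path, fmt: str | None = None) -> list[Molecule]:
    """Read molecules from an SDF (V2000, 3D) or a SMILES file.

    Unparseable records are skipped with a logged warning carrying their
    record index. Raises ``InputError`` if the file is missing or yields no
    parseable molecule at all.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() in (".sdf", ".mol", ".sd") else "smiles"
    mols: list[Molecule] = []
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for idx, rdmol in enumerate(supplier):
            if rdmol is None:
                logger.warning("skipping unparseable SDF record %d in %s", idx, path)
                continue
            name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else f"{path.stem}_{idx}"
            try:
                mols.append(Molecule.from_rdkit(rdmol, name=name, provenance=f"{path}:{idx}"))
            except StateError:
                logger.warning("skipping SDF record %d in %s: no 3D coordinates", idx, path)
    elif fmt == "smiles":
        with open(path) as fh:
            for idx, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                smiles, name = parts[0], (parts[1] if len(parts) > 1 else f"{path.stem}_{idx}")
                try:
                    m = mol_from_smiles(smiles, name=name)
                except Exception:
                    logger.warning("skipping unparseable SMILES record %d in %s", idx, path)
                    continue
                m.provenance = f"{path}:{idx}"
                mols.append(m)
    else:
        raise InputError(f"unknown format {fmt!r}")
    if not mols:
        raise InputError(f"no parseable records in {path}")
    return mols


def _load_pattern_table() -> list[tuple[int, str, frozenset[str], Chem.Mol]]:
    rows = []
    with resources.files("dynhb.data").joinpath("atom_type_patterns.csv").open() as fh:
        for row in csv.DictReader(fh):
            roles = frozenset(
                {"A": ACCEPTOR, "D": DONOR}[r] for r in row["roles"].split("|") if r
            )
            patt = Chem.MolFromSmarts(row["smarts"])
            if patt is None:  # pragma: no cover - packaged table is validated by tests
                raise FormatError(f"bad SMARTS for {row['at_code']}: {row['smarts']}")
            rows.append((int(row["priority"]), row["at_code"], roles, patt))
    rows.sort(key=lambda r: r[0])
    return rows


_PATTERNS: list[tuple[int, str, frozenset[str], Chem.Mol]] | None = None


def _patterns():
    global _PATTERNS
    if _PATTERNS is None:
        _PATTERNS = _load_pattern_table()
    return _PATTERNS


def assign_atom_types(mol: Molecule) -> list[AtomTypeAssignment]:
    """Classify every atom with a hydrogen-bond atom-type code.

    Patterns are evaluated most-specific-first (the ``priority`` column of the
    packaged table); the first pattern whose first query atom matches wins.
    Atoms matching nothing are assigned ``other`` with no role.
    """
    if mol.rdmol is None:
        raise StateError("molecule lacks a perceived chemical graph")
    code = {i: "other" for i in range(mol.n_atoms)}
    roles: dict[int, frozenset[str]] = {i: frozenset() for i in range(mol.n_atoms)}
    for _prio, at_code, at_roles, patt in _patterns():
        for match in mol.rdmol.GetSubstructMatches(patt, maxMatches=10000):
            root = match[0]
            if code[root] == "other":
                code[root] = at_code
                roles[root] = at_roles
    return [AtomTypeAssignment(i, code[i], roles[i]) for i in range(mol.n_atoms)]


def write_annotations(path: str | Path,
                      items: Iterable[tuple[str, Molecule, Sequence[AtomTypeAssignment]]]) -> None:
    """Write per-atom annotations (molecule id, atom index, element, code, roles)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["molecule_id", "atom_index", "element", "at_code", "roles"])
        for mol_id, mol, assignments in items:
            for a in assignments:
                w.writerow([mol_id, a.atom_index, mol.atoms[a.atom_index].element,
                            a.at_code, "|".join(sorted(a.roles))])


def read_annotations(path: str | Path) -> dict[str, list[AtomTypeAssignment]]:
    """Inverse of :func:`write_annotations` (element column is ignored)."""
    out: dict[str, list[AtomTypeAssignment]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh)
        required = {"molecule_id", "atom_index", "at_code", "roles"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(f"annotation CSV missing columns {required}")
        for row in reader:
            roles = frozenset(r for r in row["roles"].split("|") if r)
            out.setdefault(row["molecule_id"], []).append(
                AtomTypeAssignment(int(row["atom_index"]), row["at_code"], roles))
    return out
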