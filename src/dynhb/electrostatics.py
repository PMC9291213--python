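"""Per-atom electrostatic potentials (EP) at nuclear positions.

The EP of a molecule at a point is the interaction energy of a unit positive
test charge with the molecular charge distribution. The package consumes EP
values per atom (evaluated at each nucleus) in atomic units, from either of
two sources:

* an external table of QM-computed values (``load_ep_table``), or
* a point-charge surrogate (``surrogate_ep``): the discrete analogue of the
  continuous charge-distribution integral, ``ep(a) = sum_{b != a} q_b / r_ab``
  with distances in bohr and charges in elementary charge units. The
  contribution of the atom's own site is excluded to avoid the singularity.

Downstream code is agnostic to the source, so real QM tables drop in.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core_chem import Molecule
from .errors import ConfigError, FormatError, GeometryError

#: 1 Å in bohr (CODATA)
ANG_TO_BOHR = 1.0 / 0.52917721092
#: 1 hartree per elementary charge, in kcal/mol per e
HARTREE_TO_KCAL = 627.509


@dataclass(frozen=True)
class EPRecord:
    molecule_id: str
    atom_index: int
    ep: float  # atomic units (hartree / e)
    source: str  # "external" | "surrogate"


@dataclass(frozen=True)
class ChargeSet:
    molecule_id: str
    charges: tuple[float, ...]  # elementary charge units, one per atom
    scheme: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.charges).all():
            raise FormatError(f"non-finite charge in {self.molecule_id}")


def load_ep_table(path: str | Path) -> list[EPRecord]:
    """Read an EP CSV with header ``molecule_id, atom_index, ep_au``.

    Rows with non-numeric fields raise ``FormatError`` naming the row;
    duplicate (molecule, atom) keys are rejected.
    """
    path = Path(path)
    records: list[EPRecord] = []
    seen: set[tuple[str, int]] = set()
    with open(path) as fh:
        reader = csv.DictReader(fh)
        required = {"molecule_id", "atom_index", "ep_au"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(f"{path}: missing required columns {sorted(required)}")
        for rownum, row in enumerate(reader, start=2):
            try:
                idx = int(row["atom_index"])
                ep = float(row["ep_au"])
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}: malformed row {rownum}: {row}") from exc
            if not np.isfinite(ep):
                raise FormatError(f"{path}: non-finite ep at row {rownum}")
            key = (row["molecule_id"], idx)
            if key in seen:
                raise FormatError(f"{path}: duplicate record for {key} at row {rownum}")
            seen.add(key)
            records.append(EPRecord(row["molecule_id"], idx, ep, "external"))
    return records


def surrogate_ep(mol: Molecule, charges: ChargeSet) -> list[EPRecord]:
    """Point-charge EP at every nucleus, self term excluded, in atomic units."""
    if len(charges.charges) != mol.n_atoms:
        raise FormatError(
            f"charge set for {charges.molecule_id} has {len(charges.charges)} entries, "
            f"molecule has {mol.n_atoms} atoms")
    coords = mol.coords_array() * ANG_TO_BOHR
    q = np.asarray(charges.charges, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    off_diag = ~np.eye(mol.n_atoms, dtype=bool)
    if np.any(dist[off_diag] < 1e-6):
        raise GeometryError(f"coincident atom positions in {charges.molecule_id}")
    with np.errstate(divide="ignore"):
        inv = np.where(off_diag, 1.0 / np.where(dist == 0, np.inf, dist), 0.0)
    ep = inv @ q
    return [EPRecord(charges.molecule_id, i, float(ep[i]), "surrogate")
            for i in range(mol.n_atoms)]


def assign_partial_charges(mol: Molecule, scheme: str = "gasteiger") -> ChargeSet:
    """Deterministic per-atom partial charges.

    ``scheme="gasteiger"`` delegates to RDKit's Gasteiger-Marsili iterative
    partial-equalisation model; ``scheme="file:<path>"`` reads a charges CSV
    (``molecule_id, atom_index, q_e``) and selects this molecule's rows.
    """
    if scheme == "gasteiger":
        from rdkit.Chem import rdPartialCharges
        if mol.rdmol is None:
            raise ConfigError("gasteiger charges need the perceived molecule")
        rdPartialCharges.ComputeGasteigerCharges(mol.rdmol)
        q = tuple(a.GetDoubleProp("_GasteigerCharge") for a in mol.rdmol.GetAtoms())
        return ChargeSet(mol.name, q, "gasteiger")
    if scheme.startswith("file:"):
        path = Path(scheme[5:])
        per_atom: dict[int, float] = {}
        with open(path) as fh:
            reader = csv.DictReader(fh)
            required = {"molecule_id", "atom_index", "q_e"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise FormatError(f"{path}: missing required columns {sorted(required)}")
            for row in reader:
                if row["molecule_id"] == mol.name:
                    per_atom[int(row["atom_index"])] = float(row["q_e"])
        if sorted(per_atom) != list(range(mol.n_atoms)):
            raise FormatError(f"{path}: incomplete charges for {mol.name}")
        return ChargeSet(mol.name, tuple(per_atom[i] for i in range(mol.n_atoms)),
                         scheme)
    raise ConfigError(f"unknown charge scheme {scheme!r}")


def write_charges_csv(path: str | Path, charge_sets: list[ChargeSet]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["molecule_id", "atom_index", "q_e"])
        for cs in charge_sets:
            for i, q in enumerate(cs.charges):
                w.writerow([cs.molecule_id, i, repr(q)])


def write_ep_csv(path: str | Path, records: list[EPRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["molecule_id", "atom_index", "ep_au", "source"])
        for r in records:
            w.writerow([r.molecule_id, r.atom_index, repr(r.ep), r.source])
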