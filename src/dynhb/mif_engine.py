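"""Molecular interaction fields on a 3D grid.

A probe (an idealised chemical group: amide NH donor, carbonyl O acceptor,
methyl) is moved over a lattice covering the target molecule and the
interaction energy at each point is the sum of a Lennard-Jones, an
electrostatic and a hydrogen-bond term (an entropic term exists in the full
force-field description but is not parametrized here and is fixed to zero):

    E = sum E_LJ + sum E_EL + sum E_HB,        E_HB = Er * Et * Ep

Er is the radial hydrogen-bond factor, parametrized by the well depth Emin
(static per atom type, or the dynamic per-atom dEmin) and the optimum
distance Rmin. The 6-4 form is used:

    Er(r) = Emin * [3 (Rmin/r)^4 - 2 (Rmin/r)^6]

which has its minimum exactly at (Rmin, Emin), decays to zero at long range
and turns repulsive at short range (capped at +5 kcal/mol, as is the
Lennard-Jones clash term). Et and Ep are the dimensionless angular factors at
target and probe: the probe is taken at its optimal orientation (Ep = 1) and
Et = max(0, cos t)^2 with t the angle between the target's ideal
hydrogen-bond direction and the target→probe vector.

Approximate pieces that the underlying physics does not pin down here are all
in editable packaged tables: per-element 12-6 Lennard-Jones parameters, probe
definitions, and the distance-dependent dielectric eps(r) = 4r of the Coulomb
term.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .calibration import MapStore, apply_linear_map
from .core_chem import ACCEPTOR, DONOR, AtomTypeAssignment, Molecule
from .electrostatics import ANG_TO_BOHR, EPRecord
from .errors import InputError, ParameterError
from .registry import static_emin, static_rmin

logger = logging.getLogger(__name__)

ENERGY_CAP = 5.0            # kcal/mol; repulsive clash cap
COULOMB_KCAL = 332.0636     # kcal·Å/(mol·e²)
_ELEMENT_NUMBERS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16,
    "Cl": 17, "Br": 35, "I": 53,
}


@dataclass(frozen=True)
class ProbeDefinition:
    name: str
    hb_role: str            # "donor" | "acceptor" | "none"
    charge: float           # e
    lj_epsilon: float       # kcal/mol
    lj_sigma: float         # Å
    rmin_contrib: float     # Å, probe half of the H-bond optimum distance


def load_probes() -> dict[str, ProbeDefinition]:
    probes = {}
    with resources.files("dynhb.data").joinpath("probes.csv").open() as fh:
        for row in csv.DictReader(fh):
            probes[row["name"]] = ProbeDefinition(
                row["name"], row["hb_role"], float(row["charge_e"]),
                float(row["lj_epsilon_kcal"]), float(row["lj_sigma_ang"]),
                float(row["rmin_contrib_ang"]))
    return probes


def _lj_table() -> dict[str, tuple[float, float]]:
    table = {}
    with resources.files("dynhb.data").joinpath("lj_params.csv").open() as fh:
        for row in csv.DictReader(fh):
            table[row["element"]] = (float(row["epsilon_kcal"]), float(row["sigma_ang"]))
    return table


@dataclass(frozen=True)
class GridSpec:
    origin: tuple[float, float, float]  # Å
    spacing: float                       # Å
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise InputError("grid spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise InputError("grid dims must all be >= 1")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All lattice points, x-major then y then z (shape n_points × 3)."""
        nx, ny, nz = self.dims
        ax = self.origin[0] + self.spacing * np.arange(nx)
        ay = self.origin[1] + self.spacing * np.arange(ny)
        az = self.origin[2] + self.spacing * np.arange(nz)
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


@dataclass
class MIFGrid:
    spec: GridSpec
    total: np.ndarray        # kcal/mol, flat (n_points,)
    components: dict[str, np.ndarray] = field(default_factory=dict)

    def reshape(self, arr: np.ndarray | None = None) -> np.ndarray:
        return (self.total if arr is None else arr).reshape(self.spec.dims)


def build_grid(mol: Molecule, spacing: float = 0.5, padding: float = 4.0) -> GridSpec:
    """Axis-aligned box: molecular bounding box plus padding on every side."""
    if mol.n_atoms == 0:
        raise InputError("empty molecule")
    coords = mol.coords_array()
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    dims = tuple(int(np.ceil((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
    return GridSpec(tuple(float(v) for v in lo), spacing, dims)


def hb_radial(r, emin: float, rmin: float):
    """6-4 radial hydrogen-bond energy, capped at +5 kcal/mol."""
    if emin >= 0:
        raise ParameterError("emin must be negative")
    if rmin <= 0:
        raise ParameterError("rmin must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ParameterError("r must be positive")
    x = rmin / r
    er = emin * (3.0 * x ** 4 - 2.0 * x ** 6)
    out = np.minimum(er, ENERGY_CAP)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class HBGeometry:
    r: float       # Å, target heavy atom ↔ probe
    t: float       # degrees, angle at the target
    p: float = 0.0  # degrees, angle at the probe (kept at the optimum)


def hb_angular(geom: HBGeometry, exponent: int = 2) -> float:
    """Product Et·Ep in [0, 1]; Ep = 1 (probe at its optimal orientation)."""
    if not 0.0 <= geom.t <= 180.0:
        raise ParameterError("target angle must be within [0, 180] degrees")
    et = max(0.0, float(np.cos(np.radians(geom.t)))) ** exponent
    return et * 1.0


def _ideal_hb_directions(mol: Molecule, atom_index: int, role: str) -> np.ndarray:
    """Unit vector(s) of the ideal hydrogen-bond direction at a target atom.

    Donors: one direction per bound hydrogen, along the heavy-atom→H axis.
    Acceptors: the lone-pair proxy — negated, normalised sum of the covalent
    bond vectors. Returns an (k, 3) array; empty if no direction is defined.
    """
    coords = mol.coords_array()
    centre = coords[atom_index]
    neighbours = [j if i == atom_index else i
                  for i, j, _ in mol.bonds if atom_index in (i, j)]
    if role == DONOR:
        dirs = []
        for j in neighbours:
            if mol.atoms[j].element == "H":
                v = coords[j] - centre
                n = np.linalg.norm(v)
                if n > 0:
                    dirs.append(v / n)
        return np.array(dirs) if dirs else np.empty((0, 3))
    bond_sum = np.zeros(3)
    for j in neighbours:
        v = coords[j] - centre
        n = np.linalg.norm(v)
        if n > 0:
            bond_sum += v / n
    norm = np.linalg.norm(bond_sum)
    if norm == 0:
        return np.empty((0, 3))
    return (-bond_sum / norm)[None, :]


def resolve_demin(typing: list[AtomTypeAssignment], target_role: str,
                  demin_source, mol: Molecule | None = None) -> dict[int, float]:
    """Per-atom dEmin for every target atom carrying ``target_role``.

    ``demin_source`` may be the string ``"static"`` (registry values per
    code), an explicit {atom_index: dEmin} dict, or a (MapStore, EPRecord
    list) pair for the dynamic path. Atoms whose dynamic value cannot be
    resolved fall back to the static value with a logged warning.
    """
    out: dict[int, float] = {}
    ep_by_index: dict[int, float] = {}
    maps: MapStore | None = None
    explicit: dict[int, float] | None = None
    if isinstance(demin_source, dict):
        explicit = demin_source
    elif isinstance(demin_source, tuple):
        maps, ep_records = demin_source
        ep_by_index = {r.atom_index: r.ep for r in ep_records}
    elif demin_source != "static":
        raise InputError(f"unrecognised demin source {demin_source!r}")
    for a in typing:
        if target_role not in a.roles:
            continue
        if explicit is not None:
            if a.atom_index in explicit:
                out[a.atom_index] = explicit[a.atom_index]
                continue
            logger.warning("no dEmin for atom %d; using static Emin", a.atom_index)
        elif maps is not None:
            lmap = maps.get(a.at_code, target_role)
            if lmap is not None and a.atom_index in ep_by_index:
                out[a.atom_index] = apply_linear_map(lmap, ep_by_index[a.atom_index])
                continue
            logger.warning("unresolvable dEmin for atom %d (%s); using static Emin",
                           a.atom_index, a.at_code)
        out[a.atom_index] = static_emin(a.at_code)
    return out


def compute_mif(mol: Molecule, typing: list[AtomTypeAssignment], demin_source,
                probe: ProbeDefinition, spec: GridSpec | None = None,
                charges=None, et_exponent: int = 2) -> MIFGrid:
    """Probe–target interaction field over the grid.

    Hydrogen bonds form only between the probe and target atoms of the
    complementary role (donor probe ↔ acceptor atoms and vice versa); the
    optimum distance is the sum of the target and probe Rmin contributions.
    ``charges`` (a ChargeSet or per-atom array) enables the electrostatic
    term; without it E_EL is zero.
    """
    spec = spec or build_grid(mol)
    pts = spec.points()
    coords = mol.coords_array()
    diff = pts[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    # grid points may fall on nuclei; a 0.05 Å floor keeps all terms finite
    # while leaving every physically meaningful distance untouched
    np.maximum(dist, 0.05, out=dist)

    lj_table = _lj_table()
    clash_ceiling = 1e6  # internal bound so the +5 cap below stays exact
    e_lj = np.zeros(spec.n_points)
    for i, atom in enumerate(mol.atoms):
        eps_a, sig_a = lj_table.get(atom.element, lj_table["X"])
        eps = np.sqrt(eps_a * probe.lj_epsilon)
        sig = 0.5 * (sig_a + probe.lj_sigma)
        x6 = (sig / dist[:, i]) ** 6
        e_lj += np.minimum(4.0 * eps * (x6 ** 2 - x6), clash_ceiling)

    e_el = np.zeros(spec.n_points)
    if charges is not None and probe.charge != 0.0:
        q = np.asarray(getattr(charges, "charges", charges), dtype=float)
        if q.shape[0] != mol.n_atoms:
            raise InputError("charge vector length does not match atom count")
        # distance-dependent dielectric eps(r) = 4r  →  E = k q Q / (4 r^2)
        e_el = (COULOMB_KCAL * probe.charge / 4.0) * (q / dist ** 2).sum(axis=1)

    e_hb = np.zeros(spec.n_points)
    if probe.hb_role in (DONOR, ACCEPTOR):
        target_role = ACCEPTOR if probe.hb_role == DONOR else DONOR
        demin = resolve_demin(typing, target_role, demin_source, mol)
        code_of = {a.atom_index: a.at_code for a in typing}
        for idx, emin in demin.items():
            rmin = static_rmin(code_of[idx]) + probe.rmin_contrib
            dirs = _ideal_hb_directions(mol, idx, target_role)
            if dirs.size == 0:
                logger.warning("atom %d has no ideal H-bond direction; skipped", idx)
                continue
            er = hb_radial(dist[:, idx], emin, rmin)
            to_probe = diff[:, idx, :] / dist[:, idx, None]
            cos_t = np.max(to_probe @ dirs.T, axis=1)  # best direction per point
            et = np.maximum(cos_t, 0.0) ** et_exponent
            e_hb += er * et
    # clash cap: steric overlap saturates at +5 kcal/mol; the excess is
    # absorbed into the LJ component so total == E_LJ + E_EL + E_HB exactly
    excess = np.maximum(e_lj + e_el + e_hb - ENERGY_CAP, 0.0)
    e_lj -= excess
    total = e_lj + e_el + e_hb
    return MIFGrid(spec, total, {"E_LJ": e_lj, "E_EL": e_el, "E_HB": e_hb})


def isovolume(grid: MIFGrid, threshold: float,
              component: str | None = None) -> tuple[int, float]:
    """Points at or below the threshold and the volume they occupy (Å³)."""
    values = grid.total if component is None else grid.components[component]
    count = int((values <= threshold).sum())
    return count, count * grid.spec.spacing ** 3


def export_cube(grid: MIFGrid, mol: Molecule, path: str | Path,
                comment: str = "dynhb molecular interaction field") -> None:
    """Write the total field as a Gaussian cube file (lengths in bohr)."""
    spec = grid.spec
    nx, ny, nz = spec.dims
    lines = [comment, "energies in kcal/mol"]
    ox, oy, oz = (v * ANG_TO_BOHR for v in spec.origin)
    step = spec.spacing * ANG_TO_BOHR
    lines.append(f"{mol.n_atoms:5d}{ox:12.6f}{oy:12.6f}{oz:12.6f}")
    lines.append(f"{nx:5d}{step:12.6f}{0.0:12.6f}{0.0:12.6f}")
    lines.append(f"{ny:5d}{0.0:12.6f}{step:12.6f}{0.0:12.6f}")
    lines.append(f"{nz:5d}{0.0:12.6f}{0.0:12.6f}{step:12.6f}")
    for atom in mol.atoms:
        z = _ELEMENT_NUMBERS.get(atom.element, 0)
        x, y, zc = (v * ANG_TO_BOHR for v in atom.coords)
        lines.append(f"{z:5d}{float(z):12.6f}{x:12.6f}{y:12.6f}{zc:12.6f}")
    vals = grid.reshape()
    for ix in range(nx):
        for iy in range(ny):
            row = vals[ix, iy, :]
            for start in range(0, nz, 6):
                chunk = row[start:start + 6]
                lines.append("".join(f"{v:13.5E}" for v in chunk))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    """Parse a cube file back into (GridSpec, values); inverse of export."""
    lines = Path(path).read_text().splitlines()
    natoms = int(lines[2].split()[0])
    origin = tuple(float(v) / ANG_TO_BOHR for v in lines[2].split()[1:4])
    dims = []
    spacing = None
    for k in range(3):
        parts = lines[3 + k].split()
        dims.append(int(parts[0]))
        axis_step = float(parts[1 + k]) / ANG_TO_BOHR
        spacing = axis_step if spacing is None else spacing
    values = np.array(
        [float(v) for line in lines[6 + natoms:] for v in line.split()])
    spec = GridSpec(origin, float(spacing), tuple(dims))
    return spec, values.reshape(spec.dims).ravel()
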