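"""Deterministic synthetic fixtures for the whole pipeline.

Three generators:

* ``gen_fixture_molecules`` — a small set of template molecules (pyridine and
  its nitro/amino para-substituted relatives, phenol, furan, benzene, a
  two-ring electron-rich/electron-poor biaryl, an amide) with hand-authored
  partial charges. The charges are not from any charge model: they are fixed
  per heavy atom (in SMILES atom order, hydrogens balancing the total to the
  formal charge) and constructed so the qualitative electrostatic orderings
  the package documents hold by construction — the pyridine-nitrogen EP is
  least negative for the nitro derivative and most negative for the amino
  one, and the biaryl's phenyl ring is electron-rich relative to its pyridine
  ring.

* ``gen_synthetic_training`` — (X, y) pairs with known linear structure:
  sparse non-negative counts shaped like tree-fingerprint statistics and
  y = X·w + Normal(0, σ).

* ``gen_scale_benchmark`` — paired (predicted dEmin, experimental-scale)
  tables with a controlled population correlation, emulating a single-site
  hydrogen-bond basicity benchmark.

All generators are pure functions of their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .core_chem import Molecule, mol_from_smiles
from .electrostatics import ChargeSet, write_charges_csv
from .errors import InputError
from .fingerprints import FingerprintSchema

# name → (SMILES, heavy-atom charges in SMILES order,
#          per-heavy-atom charge of each attached hydrogen)
_FIXTURES: dict[str, tuple[str, dict[int, float], dict[int, float]]] = {
    "pyridine": ("c1ccncc1",
                 {0: -0.046, 1: -0.046, 2: -0.046, 3: -0.02, 4: -0.046, 5: -0.046},
                 {0: 0.05, 1: 0.05, 2: 0.05, 4: 0.05, 5: 0.05}),
    "nitropyridine": ("O=[N+]([O-])c1ccncc1",
                      {0: -0.40, 1: 0.55, 2: -0.40, 3: 0.04, 4: 0.02,
                       5: 0.04, 6: -0.02, 7: 0.04, 8: 0.02},
                      {4: 0.028, 5: 0.028, 7: 0.028, 8: 0.028}),
    "aminopyridine": ("Nc1ccncc1",
                      {0: -0.518, 1: 0.03, 2: -0.10, 3: -0.02, 4: -0.02,
                       5: -0.02, 6: -0.10},
                      {0: 0.32, 2: 0.028, 3: 0.028, 5: 0.028, 6: 0.028}),
    "phenol": ("Oc1ccccc1",
               {0: -0.48, 1: 0.10, 2: 0.01, 3: 0.01, 4: 0.01, 5: 0.01, 6: 0.01},
               {0: 0.28, 2: 0.01, 3: 0.01, 4: 0.01, 5: 0.01, 6: 0.01}),
    "furan": ("c1ccoc1",
              {0: 0.00, 1: 0.00, 2: 0.06, 3: -0.24, 4: 0.06},
              {0: 0.03, 1: 0.03, 2: 0.03, 4: 0.03}),
    "benzene": ("c1ccccc1",
                {i: -0.01 for i in range(6)},
                {i: 0.01 for i in range(6)}),
    "phenylpyridine": ("c1ccc(cc1)-c2ccncc2",
                       {0: -0.04, 1: -0.04, 2: -0.04, 3: -0.04, 4: -0.04,
                        5: -0.04, 6: 0.02, 7: 0.00, 8: 0.02, 9: -0.02,
                        10: 0.02, 11: 0.00},
                       {0: 0.022, 1: 0.022, 2: 0.022, 4: 0.022, 5: 0.022,
                        7: 0.028, 8: 0.028, 10: 0.028, 11: 0.028}),
    "methylacetamide": ("CNC(C)=O",
                        {0: -0.18, 1: -0.42, 2: 0.42, 3: -0.21, 4: -0.40},
                        {0: 0.09, 1: 0.25, 3: 0.09}),
}


def gen_fixture_molecules(seed: int = 7) -> tuple[list[Molecule], dict[str, ChargeSet]]:
    """Template molecules with hand-authored charges; pure function of seed.

    The seed controls only the 3D embedding; topology and charges are fixed.
    Heavy-atom and hydrogen charges are authored together; any rounding
    residual against the molecule's formal charge is spread equally over all
    atoms so charge conservation is exact.
    """
    mols: list[Molecule] = []
    charge_sets: dict[str, ChargeSet] = {}
    for name, (smiles, heavy_q, h_q) in _FIXTURES.items():
        mol = mol_from_smiles(smiles, name=name, seed=seed)
        assert mol.rdmol is not None
        q = np.zeros(mol.n_atoms)
        for i, atom in enumerate(mol.atoms):
            if atom.element != "H":
                q[i] = heavy_q[i]
        for i, rdatom in enumerate(mol.rdmol.GetAtoms()):
            if rdatom.GetAtomicNum() == 1:
                parent = rdatom.GetNeighbors()[0].GetIdx()
                q[i] = h_q[parent]
        net = float(sum(a.formal_charge for a in mol.atoms))
        q += (net - q.sum()) / mol.n_atoms
        mols.append(mol)
        charge_sets[name] = ChargeSet(name, tuple(float(v) for v in q), "fixture")
    return mols, charge_sets


def write_fixture_files(dirpath: str | Path, seed: int = 7) -> tuple[Path, Path]:
    """Write the fixtures as an SDF plus a charges CSV; returns the two paths."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    mols, charge_sets = gen_fixture_molecules(seed)
    sdf_path = dirpath / "fixtures.sdf"
    writer = Chem.SDWriter(str(sdf_path))
    for mol in mols:
        rdmol = Chem.Mol(mol.rdmol)
        rdmol.SetProp("_Name", mol.name)
        writer.write(rdmol)
    writer.close()
    csv_path = dirpath / "fixture_charges.csv"
    write_charges_csv(csv_path, [charge_sets[m.name] for m in mols])
    return sdf_path, csv_path


@dataclass(frozen=True)
class SyntheticSpec:
    n: int
    weights: tuple[float, ...]        # true coefficient per fingerprint feature
    sigma: float                      # kcal/mol residual noise
    seed: int
    schema: FingerprintSchema = field(default_factory=FingerprintSchema)

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InputError("sigma must be >= 0")
        if len(self.weights) != self.schema.n_features:
            raise InputError(
                f"{len(self.weights)} weights for {self.schema.n_features} features")
        if not np.isfinite(self.weights).all():
            raise InputError("weights must be finite")


def default_weights(schema: FingerprintSchema | None = None,
                    n_informative: int = 12, seed: int = 20210819
                    ) -> tuple[float, ...]:
    """A fixed sparse weight vector: a handful of informative shell/category
    slots with decaying magnitude and alternating sign."""
    schema = schema or FingerprintSchema()
    rng = np.random.default_rng(seed)
    w = np.zeros(schema.n_features)
    idx = rng.choice(schema.n_features, size=n_informative, replace=False)
    for rank, i in enumerate(sorted(idx)):
        w[i] = ((-1) ** rank) * 0.8 * 0.85 ** rank
    return tuple(float(v) for v in w)


def gen_synthetic_training(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Counts X with decaying per-shell intensity and y = X·w + N(0, σ)."""
    rng = np.random.default_rng(spec.seed)
    schema = spec.schema
    v = len(schema.vocabulary)
    # shell-major Poisson rates: near shells dense, distant ones sparse;
    # common organic categories more abundant than exotic ones
    common = {"C_aliph", "C_arom", "H"}
    base = np.array([1.8 if c in common else 0.25 for c in schema.vocabulary])
    lam = np.concatenate([base * 0.75 ** (k - 1) for k in range(1, schema.depth + 1)])
    X = rng.poisson(lam, size=(spec.n, schema.n_features)).astype(float)
    w = np.asarray(spec.weights)
    y = X @ w + rng.normal(0.0, spec.sigma, size=spec.n)
    return X, y


def noise_for_target_r(target_r: float, slope: float, signal_sd: float) -> float:
    """Noise SD giving a population Pearson correlation of ``target_r``.

    For exp = slope·x + ε the population correlation satisfies
    r² = 1 / (1 + σ²/(slope²·var(x))), so σ = |slope|·sd(x)·sqrt(1/r² − 1).
    """
    if not 0 < abs(target_r) <= 1:
        raise InputError("target correlation must be in (0, 1]")
    return abs(slope) * signal_sd * np.sqrt(1.0 / target_r ** 2 - 1.0)


def gen_scale_benchmark(n: int, slope: float = -1.0, noise: float | None = None,
                        seed: int = 0, target_r: float = -0.85
                        ) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Synthetic single-site benchmark: one hydrogen-bond site per molecule.

    Predicted dEmin values are drawn uniformly over the force-field band
    [−8.25, −2.75] kcal/mol; the experimental value is slope·dEmin plus
    Gaussian noise. With ``noise=None`` the noise SD is set analytically so
    the population correlation equals ``target_r`` (the sign of the
    correlation comes from ``slope``).
    """
    if n < 10:
        raise InputError("benchmark needs n >= 10")
    rng = np.random.default_rng(seed)
    lo, hi = -8.25, -2.75
    demin = rng.uniform(lo, hi, size=n)
    if noise is None:
        signal_sd = (hi - lo) / np.sqrt(12.0)  # SD of the uniform draw
        noise = noise_for_target_r(target_r, slope, signal_sd)
    exp = slope * demin + rng.normal(0.0, noise, size=n)
    sites = [f"site{i:04d}" for i in range(n)]
    predictions = list(zip(sites, (float(v) for v in demin)))
    experimental = list(zip(sites, (float(v) for v in exp)))
    return predictions, experimental
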