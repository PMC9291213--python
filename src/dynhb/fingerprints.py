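"""Tree-structured atom-environment count fingerprints.

Each atom's chemical environment is summarised by counting, for every
topological distance k = 1..depth (bond counts on the molecular graph, default
depth 10), how many neighbours of each atom category sit at exactly distance
k from the root. Categories pool element, aromaticity and formal-charge sign;
the root atom itself is excluded (its identity is fixed by the per-atom-type
model it feeds). Counts — not bits — are kept, so the regression sees
magnitude information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .core_chem import Molecule
from .errors import ConsistencyError, InputError, StateError

DEFAULT_VOCABULARY = (
    "C_aliph", "C_arom", "N_aliph", "N_arom", "O_aliph", "O_arom",
    "S", "P", "halogen", "H", "pos_charged", "neg_charged", "other",
)

_HALOGENS = {"F", "Cl", "Br", "I"}


@dataclass(frozen=True)
class FingerprintSchema:
    depth: int = 10
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY
    version: str = "1"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise InputError("fingerprint depth must be >= 1")
        if not self.vocabulary:
            raise InputError("empty category vocabulary")

    @property
    def n_features(self) -> int:
        return self.depth * len(self.vocabulary)

    def feature_labels(self) -> list[str]:
        return [f"d{k}:{c}" for k in range(1, self.depth + 1) for c in self.vocabulary]

    def categorize(self, atom: "AtomView") -> str:
        """Category of one atom; falls through to the overflow bucket."""
        if atom.formal_charge > 0:
            return "pos_charged" if "pos_charged" in self.vocabulary else "other"
        if atom.formal_charge < 0:
            return "neg_charged" if "neg_charged" in self.vocabulary else "other"
        el = atom.element
        if el in ("C", "N", "O"):
            cat = f"{el}_{'arom' if atom.aromatic else 'aliph'}"
        elif el in _HALOGENS:
            cat = "halogen"
        else:
            cat = el if el in self.vocabulary else "other"
        return cat if cat in self.vocabulary else "other"


@dataclass(frozen=True)
class AtomView:
    element: str
    aromatic: bool
    formal_charge: int


@dataclass(frozen=True)
class TreeFingerprint:
    molecule_id: str
    root_index: int
    vector: tuple[int, ...]  # shell-major: [(d1,cat1..catV), (d2,...), ...]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vector, dtype=float)


def compute_tree_fingerprint(mol: Molecule, atom_index: int,
                             schema: FingerprintSchema | None = None) -> TreeFingerprint:
    """Count atoms of each category at every topological distance from the root."""
    schema = schema or FingerprintSchema()
    if not (0 <= atom_index < mol.n_atoms):
        raise IndexError(f"root index {atom_index} outside molecule {mol.name}")
    if mol.rdmol is None:
        raise StateError("fingerprints require the perceived molecular graph")
    dists = Chem.GetDistanceMatrix(mol.rdmol)[atom_index]
    vec = np.zeros((schema.depth, len(schema.vocabulary)), dtype=int)
    cat_index = {c: i for i, c in enumerate(schema.vocabulary)}
    for j, a in enumerate(mol.atoms):
        if j == atom_index:
            continue
        k = dists[j]
        if not np.isfinite(k) or k > schema.depth:
            continue  # disconnected fragment or beyond horizon
        cat = schema.categorize(AtomView(a.element, a.aromatic, a.formal_charge))
        vec[int(k) - 1, cat_index[cat]] += 1
    return TreeFingerprint(mol.name, atom_index, tuple(int(v) for v in vec.ravel()))


def build_design_matrix(fps: list[TreeFingerprint],
                        schema: FingerprintSchema | None = None) -> pd.DataFrame:
    """Stack fingerprints into a labelled matrix.

    Rows are sorted by (molecule id, atom index) so the matrix is independent
    of input order; the row index is ``molecule_id:atom_index``.
    """
    schema = schema or FingerprintSchema()
    labels = schema.feature_labels()
    if not fps:
        return pd.DataFrame(columns=labels, dtype=float)
    for fp in fps:
        if len(fp.vector) != schema.n_features:
            raise ConsistencyError(
                f"fingerprint for {fp.molecule_id}:{fp.root_index} has "
                f"{len(fp.vector)} features, schema expects {schema.n_features}")
    ordered = sorted(fps, key=lambda f: (f.molecule_id, f.root_index))
    data = np.vstack([f.as_array() for f in ordered])
    index = [f"{f.molecule_id}:{f.root_index}" for f in ordered]
    return pd.DataFrame(data, index=index, columns=labels)
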