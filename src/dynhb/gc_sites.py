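"""GRID charges (GC): the EP-derived descriptor extended to non-HB atoms,
and ranking of aromatic carbon sites for electrophilic reactions.

Hydrogen-bonding atoms keep their dEmin as the descriptor (single source of
truth with the calibration module); every other heavy atom receives the same
affine EP transform through a generic map calibrated with the same
window-to-band rule under a generic atom-type code. Because all values live
on one kcal/mol-derived scale, carbons can be compared across a molecule:
the most electron-rich aromatic CH carbon (most negative GC) is the prime
candidate for electrophilic halogenation, and per-ring mean GC separates
electron-rich from electron-poor rings for radical-addition chemistry.

Steric control (e.g. Ir-catalysed borylation) is deliberately out of scope:
the descriptor is electronic only.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calibration import (CalibrationConfig, LinearMap, MapStore,
                          apply_linear_map, fit_linear_map)
from .core_chem import ACCEPTOR, DONOR, AtomTypeAssignment, Molecule
from .electrostatics import EPRecord, surrogate_ep
from .errors import InputError, StateError
from .registry import static_emin

logger = logging.getLogger(__name__)

GENERIC_CODE = "GENERIC"


@dataclass(frozen=True)
class GCValue:
    atom_index: int
    gc: float      # kcal/mol-derived common scale
    source: str    # "surrogate EP" | "external EP" | "model prediction"


@dataclass(frozen=True)
class SiteRanking:
    sites: tuple[tuple[int, float], ...]   # (atom_index, gc), ascending gc
    eligible: tuple[int, ...]              # aromatic CH carbons considered
    ring_means: tuple[tuple[int, float], ...]  # (ring id, mean GC over ring)


def fit_generic_map(ep_values, cfg: CalibrationConfig | None = None) -> LinearMap:
    """Calibrate the generic (non-HB) EP → GC map with the standard rule.

    The generic code behaves like an acceptor-type map (more negative EP →
    more negative GC) anchored on the packaged generic static value.
    """
    return fit_linear_map(ep_values, GENERIC_CODE, ACCEPTOR,
                          static_emin(GENERIC_CODE), cfg)


def compute_gc(mol: Molecule, typing: list[AtomTypeAssignment],
               ep_records: list[EPRecord], maps: MapStore,
               charges=None) -> list[GCValue]:
    """GC for every heavy atom.

    HB atoms get their dEmin through their own (atom type, role) map
    (acceptor map preferred when an atom holds both roles); other heavy atoms
    go through the generic map, which is fitted on this molecule's heavy-atom
    EP distribution if the store does not already hold one. Missing EP
    records fall back to the point-charge surrogate when charges are given.
    """
    ep_by_index = {r.atom_index: (r.ep, r.source) for r in ep_records}
    missing = [i for i, a in enumerate(mol.atoms)
               if a.element != "H" and i not in ep_by_index]
    if missing:
        if charges is None:
            raise InputError(f"no EP for atoms {missing} and no charges for surrogate")
        logger.info("EP missing for %d atoms of %s; using point-charge surrogate",
                    len(missing), mol.name)
        for r in surrogate_ep(mol, charges):
            ep_by_index.setdefault(r.atom_index, (r.ep, r.source))

    generic = maps.get(GENERIC_CODE, ACCEPTOR)
    if generic is None:
        heavy_eps = [ep_by_index[i][0] for i, a in enumerate(mol.atoms)
                     if a.element != "H"]
        generic = fit_generic_map(heavy_eps)
        maps.add(generic)

    out: list[GCValue] = []
    source_label = {"external": "external EP", "surrogate": "surrogate EP"}
    for a in typing:
        atom = mol.atoms[a.atom_index]
        if atom.element == "H":
            continue
        ep, src = ep_by_index[a.atom_index]
        lmap = None
        for role in (ACCEPTOR, DONOR):
            if role in a.roles:
                lmap = maps.get(a.at_code, role)
                if lmap is not None:
                    break
        if lmap is None:
            lmap = generic
        out.append(GCValue(a.atom_index, float(apply_linear_map(lmap, ep)),
                           source_label.get(src, src)))
    return out


def rank_electrophilic_sites(mol: Molecule, gc_values: list[GCValue]) -> SiteRanking:
    """Order aromatic CH carbons by ascending GC (most electron-rich first).

    Ties break toward the lower atom index. Ring aggregates (mean GC per
    aromatic ring, over the ring's carbon atoms) support the electron-rich
    versus electron-poor ring call for radical additions.
    """
    if mol.rdmol is None:
        raise StateError("ranking needs the perceived molecular graph")
    gc_by_index = {g.atom_index: g.gc for g in gc_values}
    eligible = [i for i, a in enumerate(mol.atoms)
                if a.element == "C" and a.aromatic and a.n_h >= 1
                and i in gc_by_index]
    if not eligible:
        logger.warning("no aromatic CH carbon in %s; empty ranking", mol.name)
        return SiteRanking((), (), ())
    ordered = sorted(eligible, key=lambda i: (gc_by_index[i], i))
    ring_means = []
    for ring_id, ring in enumerate(mol.rdmol.GetRingInfo().AtomRings()):
        members = [i for i in ring
                   if mol.atoms[i].aromatic and mol.atoms[i].element == "C"
                   and i in gc_by_index]
        if members:
            ring_means.append((ring_id, float(np.mean([gc_by_index[i] for i in members]))))
    return SiteRanking(tuple((i, gc_by_index[i]) for i in ordered),
                       tuple(eligible), tuple(ring_means))


def write_site_report(path: str | Path, mol: Molecule, ranking: SiteRanking) -> None:
    """Site report CSV: molecule id, rank, atom index, element, ring id, gc."""
    ring_of: dict[int, int] = {}
    if mol.rdmol is not None:
        for ring_id, ring in enumerate(mol.rdmol.GetRingInfo().AtomRings()):
            for i in ring:
                ring_of.setdefault(i, ring_id)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["molecule_id", "rank", "atom_index", "element", "ring_id", "gc"])
        for rank, (idx, gc) in enumerate(ranking.sites, start=1):
            w.writerow([mol.name, rank, idx, mol.atoms[idx].element,
                        ring_of.get(idx, -1), f"{gc:.4f}"])
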