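"""Packaged reference tables: published model statistics and static parameters.

The package ships a transcription of the published per-atom-type model
statistics (22 slots: atom type, role, training-set size, latent variables,
R², Q², SDEC, SDEP) plus the static force-field parameters (Emin, Rmin) per
hydrogen-bond atom type. Only two static Emin values are public (−5.5
kcal/mol for the aromatic nitrogen ``N:=`` and −4.0 for the secondary amine
``N1:``); the rest are clearly labelled placeholders in an override-able CSV.
Rmin values are package defaults (1.6 Å for nitrogen codes, 1.5 Å for
oxygen), not published numbers.

Registry content is immutable at runtime: overrides go through a user file in
the same dialect, never through mutation of the packaged data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import DynHBError, InputError, InsufficientDataError


@dataclass(frozen=True)
class ModelSlot:
    at_code: str
    role: str  # "A" or "D"
    n_atoms: int
    n_lv: int
    r2: float
    q2: float
    sdec: float
    sdep: float
    description: str


@dataclass(frozen=True)
class StaticParams:
    at_code: str
    emin: float   # kcal/mol, < 0
    rmin: float   # Å, > 0
    provenance: str  # "published" | "placeholder"


@dataclass(frozen=True)
class AggregateStats:
    count: int
    mean_r2: float
    mean_q2: float
    mean_sdec: float
    sdep_min: float
    sdep_max: float
    lv_min: int
    lv_max: int


def load_reference_table() -> list[ModelSlot]:
    """The packaged 22-slot transcription, in stable (file) order."""
    slots = []
    with resources.files("dynhb.data").joinpath("reference_models.csv").open() as fh:
        for row in csv.DictReader(fh):
            slots.append(ModelSlot(
                at_code=row["at_code"], role=row["role"],
                n_atoms=int(row["n_atoms"]), n_lv=int(row["n_lv"]),
                r2=float(row["r2"]), q2=float(row["q2"]),
                sdec=float(row["sdec"]), sdep=float(row["sdep"]),
                description=row["description"]))
    return slots


def aggregate_stats(slots: list[ModelSlot]) -> AggregateStats:
    """Arithmetic means (2-decimal rounded) and exact extrema over slots."""
    if not slots:
        raise InputError("empty slot list")
    return AggregateStats(
        count=len(slots),
        mean_r2=round(float(np.mean([s.r2 for s in slots])), 2),
        mean_q2=round(float(np.mean([s.q2 for s in slots])), 2),
        mean_sdec=round(float(np.mean([s.sdec for s in slots])), 2),
        sdep_min=min(s.sdep for s in slots),
        sdep_max=max(s.sdep for s in slots),
        lv_min=min(s.n_lv for s in slots),
        lv_max=max(s.n_lv for s in slots),
    )


def _load_static_table(override_path: str | Path | None = None) -> dict[str, StaticParams]:
    table: dict[str, StaticParams] = {}
    with resources.files("dynhb.data").joinpath("static_params.csv").open() as fh:
        for row in csv.DictReader(fh):
            table[row["at_code"]] = StaticParams(
                row["at_code"], float(row["emin_kcal"]), float(row["rmin_ang"]),
                row["provenance"])
    if override_path is not None:
        with open(override_path) as fh:
            for row in csv.DictReader(fh):
                table[row["at_code"]] = StaticParams(
                    row["at_code"], float(row["emin_kcal"]), float(row["rmin_ang"]),
                    row.get("provenance", "override"))
    return table


def static_emin(at_code: str, override_path: str | Path | None = None) -> float:
    """Static hydrogen-bond well depth (kcal/mol) for an atom-type code."""
    table = _load_static_table(override_path)
    if at_code not in table:
        raise DynHBError(f"no static parameters for atom type {at_code!r}")
    return table[at_code].emin


def static_rmin(at_code: str, override_path: str | Path | None = None) -> float:
    """Target-side Rmin contribution (Å) for an atom-type code."""
    table = _load_static_table(override_path)
    if at_code not in table:
        raise DynHBError(f"no static parameters for atom type {at_code!r}")
    return table[at_code].rmin


def correlate_with_scale(predictions: list[tuple[str, float]],
                         experimental: list[tuple[str, float]]) -> tuple[float, int]:
    """Pearson r between predicted dEmin and an experimental HB scale.

    Both lists carry (site id, value) pairs; pairs are joined on site id and
    the standard Pearson correlation is computed on the matches. Sites are
    expected to be unique per molecule (molecules with several hydrogen-bond
    sites are excluded upstream, so one site measures one interaction).
    Returns (r, number of matched pairs).
    """
    pred = dict(predictions)
    exp = dict(experimental)
    common = sorted(set(pred) & set(exp))
    if len(common) < 3:
        raise InsufficientDataError(
            f"only {len(common)} matched sites; need at least 3")
    x = np.array([pred[s] for s in common])
    y = np.array([exp[s] for s in common])
    r, _ = stats.pearsonr(x, y)
    return float(r), len(common)
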