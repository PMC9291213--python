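"""Linear EP → dEmin calibration per (atom type, role).

The hydrogen-bond well depth of an atom type has a fixed, "static" force-field
value Emin. The dynamic parametrization replaces it with an affine function of
the atom's electrostatic potential at the nucleus:

    acceptors:  dEmin =  m · EP + q          (m > 0)
    donors:     dEmin = −m · EP − q          (m > 0)

so for acceptors a more negative EP (more electron-rich site) deepens the
well, while for donors a more positive EP does. The slope and intercept for
each atom type are fitted so the training EP window (clamped to configurable
percentiles) maps onto a symmetric energy band around the static value,
``[Emin·(1+δ), Emin·(1−δ)]`` — every emitted dEmin stays in a range the
force field accepts, and the window midpoint maps exactly to the static Emin.
EP values outside the fitted window are clamped to its edges before
evaluation, never extrapolated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_chem import ACCEPTOR, DONOR
from .errors import CalibrationError, ConfigError


@dataclass(frozen=True)
class CalibrationConfig:
    delta: float = 0.5          # half-width of the energy band, fraction of |Emin|
    clamp_lo: float = 1.0       # lower EP percentile of the fitting window
    clamp_hi: float = 99.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta < 1.0:
            raise ConfigError("delta must be in [0, 1)")
        if not 0.0 <= self.clamp_lo < self.clamp_hi <= 100.0:
            raise ConfigError("percentile clamp must satisfy 0 <= lo < hi <= 100")


@dataclass(frozen=True)
class LinearMap:
    """Affine EP → dEmin map for one (atom type, role).

    ``slope``/``intercept`` are the raw coefficients of dEmin = slope·EP +
    intercept. The conventional parameters (``m``, ``q``), positive by
    construction, are exposed as properties: for acceptors m = slope,
    q-as-written = intercept; for donors the map is written −m·EP − q.
    """

    at_code: str
    role: str
    slope: float       # kcal/mol per a.u.
    intercept: float   # kcal/mol
    ep_window: tuple[float, float]
    delta: float = 0.5

    def __post_init__(self) -> None:
        if self.role not in (ACCEPTOR, DONOR):
            raise ConfigError(f"unknown role {self.role!r}")

    @property
    def m(self) -> float:
        return self.slope if self.role == ACCEPTOR else -self.slope

    @property
    def q(self) -> float:
        return self.intercept if self.role == ACCEPTOR else -self.intercept


def fit_linear_map(ep_values, at_code: str, role: str, static_emin: float,
                   cfg: CalibrationConfig | None = None) -> LinearMap:
    """Fit the affine map from the training EP distribution of one atom type.

    The EP window is the [clamp_lo, clamp_hi] percentile interval of
    ``ep_values``; it is mapped onto [Emin·(1+δ), Emin·(1−δ)] with the
    orientation dictated by the role (acceptor: low-EP edge → deep end;
    donor: high-EP edge → deep end). With δ = 0 the map degenerates to the
    static force field (constant Emin).
    """
    cfg = cfg or CalibrationConfig()
    if static_emin >= 0:
        raise CalibrationError("static Emin must be negative (an attractive well)")
    ep = np.asarray(list(ep_values), dtype=float)
    if ep.size < 2 or not np.isfinite(ep).all():
        raise CalibrationError(f"{at_code}/{role}: need >= 2 finite EP values")
    lo, hi = np.percentile(ep, [cfg.clamp_lo, cfg.clamp_hi])
    if hi - lo <= 0:
        raise CalibrationError(f"{at_code}/{role}: degenerate EP window ({lo}, {hi})")
    deep = static_emin * (1.0 + cfg.delta)   # most negative admissible dEmin
    shallow = static_emin * (1.0 - cfg.delta)
    if role == ACCEPTOR:
        y_lo, y_hi = deep, shallow           # EP=lo → deepest well
    elif role == DONOR:
        y_lo, y_hi = shallow, deep           # EP=hi → deepest well
    else:
        raise ConfigError(f"unknown role {role!r}")
    slope = (y_hi - y_lo) / (hi - lo)
    intercept = y_lo - slope * lo
    return LinearMap(at_code, role, float(slope), float(intercept),
                     (float(lo), float(hi)), cfg.delta)


def apply_linear_map(lmap: LinearMap, ep: float | np.ndarray) -> float | np.ndarray:
    """Evaluate dEmin (kcal/mol); EP is clamped to the fitted window first."""
    lo, hi = lmap.ep_window
    clamped = np.clip(ep, lo, hi)
    out = lmap.slope * clamped + lmap.intercept
    return float(out) if np.isscalar(ep) else out


# ---------------------------------------------------------------------------
# map store serialization

def save_maps(path: str | Path, maps: list[LinearMap]) -> None:
    payload = [
        {"at_code": m.at_code, "role": m.role, "slope": m.slope,
         "intercept": m.intercept, "ep_window": list(m.ep_window), "delta": m.delta}
        for m in maps
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_maps(path: str | Path) -> list[LinearMap]:
    payload = json.loads(Path(path).read_text())
    return [LinearMap(d["at_code"], d["role"], d["slope"], d["intercept"],
                      tuple(d["ep_window"]), d["delta"]) for d in payload]


class MapStore:
    """Keyed lookup of fitted linear maps by (atom type, role)."""

    def __init__(self, maps: list[LinearMap] | None = None):
        self._maps: dict[tuple[str, str], LinearMap] = {}
        for m in maps or []:
            self.add(m)

    def add(self, m: LinearMap) -> None:
        self._maps[(m.at_code, m.role)] = m

    def get(self, at_code: str, role: str) -> LinearMap | None:
        return self._maps.get((at_code, role))

    def __iter__(self):
        return iter(self._maps.values())

    def __len__(self) -> int:
        return len(self._maps)
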