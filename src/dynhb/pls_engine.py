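"""Partial least squares regression from fingerprint space to dEmin.

The regression core is a native NIPALS implementation wrapped in a
scikit-learn-style estimator (:class:`TreePLSRegressor`): ``fit``/``predict``,
``get_params``/``set_params``, fitted attributes with trailing underscores, so
it composes with sklearn model selection. X and y are mean-centred before
decomposition; unit-variance scaling is off by default because count
fingerprints share a natural scale (a flag turns it on).

Model quality is summarised the chemometrics way:

* R²   — coefficient of determination on the training fit,
* Q²   — cross-validated R², here from random-groups cross-validation
         (default five groups, twenty independent partitionings, PRESS pooled
         over all folds of all partitionings),
* SDEC — root-mean-square error of calculation (training residuals, kcal/mol),
* SDEP — root-mean-square error of external prediction (kcal/mol).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .calibration import MapStore, apply_linear_map
from .errors import ConfigError, ConsistencyError, DegenerateTargetError, InputError
from .fingerprints import FingerprintSchema

logger = logging.getLogger(__name__)

_TOL = 1e-12


@dataclass(frozen=True)
class CVConfig:
    """Random-groups cross-validation settings (defaults match the protocol
    of five groups and twenty partitionings)."""
    n_groups: int = 5
    n_partitionings: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ConfigError("n_groups must be >= 2")
        if self.n_partitionings < 1:
            raise ConfigError("n_partitionings must be >= 1")


@dataclass(frozen=True)
class FitMetrics:
    at_code: str
    role: str
    n_atoms: int
    n_lv: int
    r2: float
    q2: float
    sdec: float
    sdep: float


class TreePLSRegressor(BaseEstimator, RegressorMixin):
    """NIPALS partial least squares for a single response.

    Parameters
    ----------
    n_components : int
        Latent variables to extract. Extraction stops early (with a logged
        note) if the residual X carries no covariance with y, so the
        effective count is ``n_components_``.
    scale : bool
        Autoscale X columns to unit variance (constant columns untouched).

    Attributes (after ``fit``)
    --------------------------
    x_mean_, y_mean_, x_std_ : centring/scaling vectors.
    x_weights_, x_loadings_, y_loadings_ : (p, k) and (k,) NIPALS arrays.
    coef_, intercept_ : the equivalent affine predictor
        ``y = X @ coef_ + intercept_``.
    """

    def __init__(self, n_components: int = 2, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y) -> "TreePLSRegressor":
        X, y = check_X_y(X, y, dtype=float, y_numeric=True)
        n, p = X.shape
        if self.n_components < 1:
            raise ConfigError("n_components must be >= 1")
        if n < 2:
            raise InputError("need at least two training rows")
        if np.ptp(y) == 0:
            raise DegenerateTargetError("y is constant; nothing to regress")
        k_max = min(self.n_components, n - 1, p)

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        self.x_std_ = X.std(axis=0, ddof=1) if self.scale else np.ones(p)
        self.x_std_ = np.where(self.x_std_ > 0, self.x_std_, 1.0)
        Xc = (X - self.x_mean_) / self.x_std_
        yc = y - self.y_mean_

        W = np.zeros((p, k_max))
        P = np.zeros((p, k_max))
        c = np.zeros(k_max)
        k_eff = 0
        for k in range(k_max):
            w = Xc.T @ yc
            wn = np.linalg.norm(w)
            if wn < _TOL:
                logger.debug("stopping at %d latent variables: no residual covariance", k)
                break
            w /= wn
            t = Xc @ w
            tt = float(t @ t)
            if tt < _TOL:
                break
            pk = Xc.T @ t / tt
            ck = float(yc @ t / tt)
            Xc = Xc - np.outer(t, pk)
            yc = yc - ck * t
            W[:, k], P[:, k], c[k] = w, pk, ck
            k_eff += 1
        if k_eff == 0:
            raise DegenerateTargetError("X carries no covariance with y")
        self.n_components_ = k_eff
        self.x_weights_ = W[:, :k_eff]
        self.x_loadings_ = P[:, :k_eff]
        self.y_loadings_ = c[:k_eff]
        # B = W (P'W)^-1 c  on the centred/scaled problem
        R = self.x_weights_ @ np.linalg.solve(
            self.x_loadings_.T @ self.x_weights_, np.eye(k_eff))
        beta = R @ self.y_loadings_
        self.coef_ = beta / self.x_std_
        self.intercept_ = self.y_mean_ - float(self.x_mean_ @ self.coef_)
        self.n_features_in_ = p
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ConsistencyError(
                f"X has {X.shape[1]} features, model was trained with "
                f"{self.n_features_in_}")
        return X @ self.coef_ + self.intercept_


def fit_pls(X, y, n_lv: int, scale: bool = False) -> TreePLSRegressor:
    """Functional wrapper over :class:`TreePLSRegressor`."""
    return TreePLSRegressor(n_components=n_lv, scale=scale).fit(X, y)


def _partition(n: int, n_groups: int, rng: np.random.Generator) -> np.ndarray:
    """Random assignment of n rows to n_groups groups of near-equal size."""
    labels = np.arange(n) % n_groups
    rng.shuffle(labels)
    return labels


def cross_validate(X, y, n_lv: int, cfg: CVConfig | None = None,
                   scale: bool = False) -> float:
    """Q² by random-groups cross-validation.

    For each partitioning every group is predicted by a model trained on the
    remaining groups; PRESS is pooled over all folds of all partitionings and
    Q² = 1 − PRESS / (n_partitionings · TSS) with TSS about the full-data
    mean. Deterministic given ``cfg.seed``.
    """
    cfg = cfg or CVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < cfg.n_groups:
        raise InputError(f"{n} rows cannot form {cfg.n_groups} groups")
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise DegenerateTargetError("y is constant; Q2 undefined")
    rng = np.random.default_rng(cfg.seed)
    press = 0.0
    for _ in range(cfg.n_partitionings):
        labels = _partition(n, cfg.n_groups, rng)
        for g in range(cfg.n_groups):
            test = labels == g
            model = TreePLSRegressor(n_components=n_lv, scale=scale)
            model.fit(X[~test], y[~test])
            resid = y[test] - model.predict(X[test])
            press += float(resid @ resid)
    return 1.0 - press / (cfg.n_partitionings * tss)


def select_lv(X, y, cfg: CVConfig | None = None, max_lv: int = 15,
              scale: bool = False) -> int:
    """Latent-variable count in [1, max_lv] maximising Q²; ties favour fewer."""
    if max_lv < 1:
        raise ConfigError("max_lv must be >= 1")
    X = np.asarray(X, dtype=float)
    hard_cap = min(max_lv, len(y) - 1, X.shape[1])
    best_lv, best_q2 = 1, -np.inf
    for lv in range(1, hard_cap + 1):
        q2 = cross_validate(X, y, lv, cfg, scale=scale)
        if q2 > best_q2 + 1e-12:
            best_lv, best_q2 = lv, q2
    return best_lv


def compute_metrics(y, y_fit, y_ext=None, y_ext_pred=None, q2: float = float("nan"),
                    at_code: str = "", role: str = "", n_lv: int = 0) -> FitMetrics:
    """R²/SDEC on the training pairs, SDEP on the external pairs."""
    y = np.asarray(y, dtype=float)
    y_fit = np.asarray(y_fit, dtype=float)
    if y.shape != y_fit.shape:
        raise ConsistencyError("y and y_fit lengths differ")
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise DegenerateTargetError("y has zero variance")
    rss = float(((y - y_fit) ** 2).sum())
    r2 = 1.0 - rss / tss
    sdec = float(np.sqrt(rss / len(y)))
    if y_ext is not None and y_ext_pred is not None and len(np.atleast_1d(y_ext)):
        y_ext = np.asarray(y_ext, dtype=float)
        y_ext_pred = np.asarray(y_ext_pred, dtype=float)
        if y_ext.shape != y_ext_pred.shape:
            raise ConsistencyError("external y and prediction lengths differ")
        sdep = float(np.sqrt(((y_ext - y_ext_pred) ** 2).mean()))
    else:
        sdep = float("nan")
    return FitMetrics(at_code, role, len(y), n_lv, r2, float(q2), sdec, sdep)


# ---------------------------------------------------------------------------
# end-to-end training over (atom type, role) groups


def train_at_models(groups: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]],
                    cfg: CVConfig | None = None, max_lv: int = 15,
                    min_atoms: int = 50, scale: bool = False
                    ) -> tuple[dict[tuple[str, str], TreePLSRegressor], pd.DataFrame]:
    """Train one PLS model per (atom type, role) group.

    ``groups`` maps (at_code, role) to its (design matrix, dEmin vector).
    Groups below ``min_atoms`` rows are skipped with a logged note. Returns
    the model store and a metrics table with one row per trained model
    (columns: at_code, role, n_atoms, n_lv, r2, q2, sdec, sdep).
    """
    cfg = cfg or CVConfig()
    store: dict[tuple[str, str], TreePLSRegressor] = {}
    rows = []
    for (at_code, role), (X, y) in sorted(groups.items()):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(y) < min_atoms:
            logger.info("skipping %s/%s: %d atoms < threshold %d",
                        at_code, role, len(y), min_atoms)
            continue
        n_lv = select_lv(X, y, cfg, max_lv=max_lv, scale=scale)
        model = TreePLSRegressor(n_components=n_lv, scale=scale).fit(X, y)
        q2 = cross_validate(X, y, n_lv, cfg, scale=scale)
        m = compute_metrics(y, model.predict(X), q2=q2,
                            at_code=at_code, role=role, n_lv=model.n_components_)
        store[(at_code, role)] = model
        rows.append(m)
    table = pd.DataFrame(
        [{"at_code": m.at_code, "role": m.role, "n_atoms": m.n_atoms,
          "n_lv": m.n_lv, "r2": m.r2, "q2": m.q2, "sdec": m.sdec, "sdep": m.sdep}
         for m in rows],
        columns=["at_code", "role", "n_atoms", "n_lv", "r2", "q2", "sdec", "sdep"])
    return store, table


def make_demin_groups(dataset, maps: MapStore, schema: FingerprintSchema | None = None
                      ) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
    """Assemble per-(atom type, role) training groups from a typed dataset.

    ``dataset`` is an iterable of (at_code, role, fingerprint vector, ep)
    records; the fitted linear maps turn EP into the dEmin regression target.
    Records whose (at_code, role) has no fitted map are skipped.
    """
    schema = schema or FingerprintSchema()
    buckets: dict[tuple[str, str], tuple[list, list]] = {}
    for at_code, role, fp_vec, ep in dataset:
        lmap = maps.get(at_code, role)
        if lmap is None:
            continue
        xs, ys = buckets.setdefault((at_code, role), ([], []))
        xs.append(np.asarray(fp_vec, dtype=float))
        ys.append(apply_linear_map(lmap, float(ep)))
    return {key: (np.vstack(xs), np.asarray(ys)) for key, (xs, ys) in buckets.items()}


# ---------------------------------------------------------------------------
# model store serialization (JSON metadata + CSV arrays, no binary files)


def save_model_store(dirpath: str | Path,
                     store: dict[tuple[str, str], TreePLSRegressor],
                     table: pd.DataFrame) -> None:
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    meta = []
    for (at_code, role), model in sorted(store.items()):
        stem = f"{at_code.replace(':', '_').replace('=', 'eq').replace('#', 'h')}_{role}"
        arr = pd.DataFrame({"coef": model.coef_})
        arr.to_csv(dirpath / f"{stem}_coef.csv", index=False)
        meta.append({"at_code": at_code, "role": role, "stem": stem,
                     "intercept": model.intercept_,
                     "n_components": int(model.n_components_),
                     "n_features": int(model.n_features_in_)})
    (dirpath / "models.json").write_text(json.dumps(meta, indent=1))
    table.to_csv(dirpath / "metrics.csv", index=False)


def load_model_store(dirpath: str | Path) -> dict[tuple[str, str], TreePLSRegressor]:
    """Rehydrate saved models as affine predictors (coef/intercept only)."""
    dirpath = Path(dirpath)
    meta = json.loads((dirpath / "models.json").read_text())
    store: dict[tuple[str, str], TreePLSRegressor] = {}
    for d in meta:
        model = TreePLSRegressor(n_components=d["n_components"])
        model.coef_ = pd.read_csv(dirpath / f"{d['stem']}_coef.csv")["coef"].to_numpy()
        model.intercept_ = float(d["intercept"])
        model.n_features_in_ = int(d["n_features"])
        model.n_components_ = int(d["n_components"])
        store[(d["at_code"], d["role"])] = model
    return store
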