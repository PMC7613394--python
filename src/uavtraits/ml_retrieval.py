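"""Machine-learning retrieval: hybrid (RTM-trained) and in-situ regression.

Two distinct uses of regression live here:

* the *hybrid* strategy trains regressors (random forest, Gaussian
  process regression, canonical correlation forest) on subsets of the
  simulated look-up table and validates against the field measurements,
  selecting the best (method, training-set size) per trait;
* the *in-situ* strategy trains a random forest directly on the field
  plots under leave-one-date-out cross-validation, optionally with the
  camera exposure time as an extra predictor so the model can compensate
  for date-level illumination differences (``RFexp``).

RF and GPR are delegated to scikit-learn.  The canonical correlation
forest (CCF) -- an ensemble of oblique trees whose node splits act on a
canonical-correlation projection of a random feature subset -- has no
established Python implementation and is provided here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .evaluation import metrics

__all__ = [
    "RegressorSpec",
    "HybridConfig",
    "HybridSelection",
    "CanonicalCorrelationForest",
    "train_regressor",
    "hybrid_select",
    "insitu_rf_lodo",
    "DEFAULT_SUBSET_SIZES",
]

TRAITS = ("lai", "fcover", "ccc")

#: Training-subset sizes spanning the 100-5000 range.
DEFAULT_SUBSET_SIZES = (100, 250, 500, 750, 1000, 1500, 2000, 3000, 4000, 5000)


@dataclass
class RegressorSpec:
    """Choice of regression method and its hyperparameters."""

    method: str = "rf"             # rf | gpr | ccf
    n_trees: int = 500             # rf/ccf ensembles
    max_depth: int | None = None
    gpr_restarts: int = 3          # marginal-likelihood optimiser restarts
    seed: int | None = None

    def __post_init__(self):
        if self.method not in ("rf", "gpr", "ccf"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


# ---------------------------------------------------------------------------
# Canonical correlation forest
# ---------------------------------------------------------------------------

class _CCNode:
    __slots__ = ("w", "threshold", "features", "left", "right", "value")

    def __init__(self):
        self.value = None


def _cca_direction(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Feature projection maximising correlation with a scalar target.

    For a univariate response the first canonical direction solves the
    ridge-regularised normal equations (Sxx + eps I) w = Sxy.
    """
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = Xc.T @ Xc / len(y)
    sxy = Xc.T @ yc / len(y)
    eps = 1e-8 * max(np.trace(sxx) / max(X.shape[1], 1), 1e-12)
    w = np.linalg.solve(sxx + eps * np.eye(X.shape[1]), sxy)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def _variance_min_split(proj: np.ndarray, y: np.ndarray):
    """Best threshold on a projection by weighted child-variance minimisation."""
    order = np.argsort(proj, kind="stable")
    p, t = proj[order], y[order]
    n = len(t)
    csum = np.cumsum(t)
    csq = np.cumsum(t ** 2)
    best, best_i = np.inf, None
    for i in range(1, n):
        if p[i] == p[i - 1]:
            continue
        sl, ql = csum[i - 1], csq[i - 1]
        sr, qr = csum[-1] - sl, csq[-1] - ql
        cost = (ql - sl ** 2 / i) + (qr - sr ** 2 / (n - i))
        if cost < best:
            best, best_i = cost, i
    if best_i is None:
        return None
    return 0.5 * (p[best_i] + p[best_i - 1])


class _CCTree:
    def __init__(self, max_depth, min_samples_leaf, rng):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.rng = rng
        self.root = None

    def fit(self, X, y):
        self.root = self._grow(X, y, depth=0)
        return self

    def _grow(self, X, y, depth):
        node = _CCNode()
        if (
            len(y) < 2 * self.min_samples_leaf
            or (self.max_depth is not None and depth >= self.max_depth)
            or np.ptp(y) == 0
        ):
            node.value = float(y.mean())
            return node
        p = X.shape[1]
        k = max(1, int(np.ceil(np.sqrt(p))))
        feats = np.sort(self.rng.choice(p, size=k, replace=False))
        Xs = X[:, feats]
        w = _cca_direction(Xs, y)
        proj = Xs @ w
        thr = _variance_min_split(proj, y)
        if thr is None:
            node.value = float(y.mean())
            return node
        mask = proj <= thr
        if mask.sum() < self.min_samples_leaf or (~mask).sum() < self.min_samples_leaf:
            node.value = float(y.mean())
            return node
        node.features, node.w, node.threshold = feats, w, thr
        node.left = self._grow(X[mask], y[mask], depth + 1)
        node.right = self._grow(X[~mask], y[~mask], depth + 1)
        return node

    def predict(self, X):
        out = np.empty(len(X))
        for i, x in enumerate(X):
            node = self.root
            while node.value is None:
                if x[node.features] @ node.w <= node.threshold:
                    node = node.left
                else:
                    node = node.right
            out[i] = node.value
        return out


class CanonicalCorrelationForest:
    """Bootstrap ensemble of oblique regression trees.

    Each node projects a random feature subset onto its first canonical
    coordinate against the target and splits at the variance-minimising
    threshold; tree predictions are averaged.
    """

    def __init__(self, n_trees: int = 100, max_depth: int | None = None,
                 min_samples_leaf: int = 3, seed: int | None = None):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.seed = seed
        self.trees_: list = []

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.seed)
        self.trees_ = []
        for _ in range(self.n_trees):
            idx = rng.integers(0, len(y), size=len(y))
            tree = _CCTree(self.max_depth, self.min_samples_leaf, rng)
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return np.mean([t.predict(X) for t in self.trees_], axis=0)


# ---------------------------------------------------------------------------
# Unified training front end
# ---------------------------------------------------------------------------

class _GPRWrapper:
    """Predict in original units around the training mean, expose sd."""

    def __init__(self, gpr, y_mean):
        self._gpr = gpr
        self._y_mean = y_mean

    def predict(self, X, return_std: bool = False):
        if return_std:
            mu, sd = self._gpr.predict(X, return_std=True)
            return mu + self._y_mean, sd
        return self._gpr.predict(X) + self._y_mean


def train_regressor(X, y, spec: RegressorSpec):
    """Fit one regressor on (spectra, trait) pairs.

    Returns a fitted model exposing ``predict(X)``; the GPR model also
    supports ``predict(X, return_std=True)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per y value")
    if len(y) < 10:
        raise ValueError("need at least 10 training rows")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in training data")
    p = X.shape[1]
    if spec.method == "rf":
        model = RandomForestRegressor(
            n_estimators=spec.n_trees,
            max_depth=spec.max_depth,
            max_features=max(1, int(np.ceil(p / 3))),
            random_state=spec.seed,
            n_jobs=1,
        )
        return model.fit(X, y)
    if spec.method == "ccf":
        return CanonicalCorrelationForest(
            n_trees=spec.n_trees, max_depth=spec.max_depth, seed=spec.seed
        ).fit(X, y)
    # GPR: anisotropic squared-exponential + additive noise, hyperparameters
    # by marginal-likelihood maximisation
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
        length_scale=np.full(p, 1.0), length_scale_bounds=(1e-3, 1e4)
    ) + WhiteKernel(noise_level=1e-4, noise_level_bounds=(1e-10, 1e1))
    gpr = GaussianProcessRegressor(
        kernel=kernel,
        n_restarts_optimizer=spec.gpr_restarts,
        random_state=spec.seed,
        normalize_y=False,
        alpha=1e-10,
    )
    y_mean = y.mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gpr.fit(X, y - y_mean)
    return _GPRWrapper(gpr, y_mean)


# ---------------------------------------------------------------------------
# Hybrid selection over LUT subsets
# ---------------------------------------------------------------------------

@dataclass
class HybridConfig:
    """Training-subset sizes and repetitions of the hybrid experiment."""

    subset_sizes: tuple = DEFAULT_SUBSET_SIZES
    repeats: int = 10
    folds: int = 10          # internal CV granularity (diagnostics only)
    targets: tuple = TRAITS

    def __post_init__(self):
        if any(not 100 <= s <= 5000 for s in self.subset_sizes):
            raise ValueError("subset sizes must lie in [100, 5000]")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class HybridSelection:
    """Ground-validation scores per method x size x trait, plus the winners."""

    results: pd.DataFrame    # method, size, variable, r2, nrmse_pct
    chosen: dict             # variable -> {"method", "size", "nrmse_pct", "r2"}


def hybrid_select(
    lut,
    config: HybridConfig,
    validation: pd.DataFrame,
    specs: dict | None = None,
    rng: np.random.Generator | int | None = None,
) -> HybridSelection:
    """Rank regression methods and training sizes by ground validation.

    For each subset size, ``repeats`` random subsets of the LUT are drawn;
    each method is fitted per repeat per target trait and scored against
    the independent field validation set (measured traits).  Scores are
    averaged over repeats; the winner per trait minimises NRMSE, ties
    resolved toward the smaller training size.

    ``validation`` needs spectral columns matching the LUT band count plus
    one column per target trait.
    """
    if len(validation) == 0:
        raise ValueError("validation set is empty")
    if max(config.subset_sizes) > len(lut):
        raise ValueError("LUT smaller than the largest subset size")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if specs is None:
        specs = {
            "rf": RegressorSpec("rf"),
            "gpr": RegressorSpec("gpr"),
            "ccf": RegressorSpec("ccf", n_trees=100),
        }
    band_cols = [c for c in validation.columns if c.startswith("b")]
    if len(band_cols) != lut.n_bands:
        raise ValueError("validation spectra do not match LUT band count")
    Xval = validation[band_cols].to_numpy(dtype=float)

    rows = []
    for size in config.subset_sizes:
        for rep in range(config.repeats):
            idx = gen.choice(len(lut), size=size, replace=False)
            Xtr = lut.spectra[idx]
            for name, rspec in specs.items():
                for trait in config.targets:
                    ytr = lut.traits[trait].to_numpy()[idx]
                    try:
                        model = train_regressor(Xtr, ytr, rspec)
                        pred = model.predict(Xval)
                        sc = metrics(validation[trait].to_numpy(), pred)
                    except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                        warnings.warn(
                            f"{name} fit failed at size {size} rep {rep}: {exc}",
                            stacklevel=2,
                        )
                        continue
                    rows.append({
                        "method": name, "size": size, "repeat": rep,
                        "variable": trait, "r2": sc.r2,
                        "nrmse_pct": sc.nrmse_pct,
                    })
    raw = pd.DataFrame(rows)
    results = (
        raw.groupby(["method", "size", "variable"], as_index=False)
        [["r2", "nrmse_pct"]].mean()
    )
    chosen = {}
    for trait in config.targets:
        sub = results[results["variable"] == trait]
        if sub.empty:
            continue
        sub = sub.sort_values(["nrmse_pct", "size"], kind="stable")
        best = sub.iloc[0]
        chosen[trait] = {
            "method": best["method"], "size": int(best["size"]),
            "nrmse_pct": float(best["nrmse_pct"]), "r2": float(best["r2"]),
        }
    return HybridSelection(results=results, chosen=chosen)


# ---------------------------------------------------------------------------
# In-situ random forest with leave-one-date-out validation
# ---------------------------------------------------------------------------

def insitu_rf_lodo(
    plots: pd.DataFrame,
    use_exposure: bool = False,
    spec: RegressorSpec | None = None,
    targets: tuple = TRAITS,
) -> pd.DataFrame:
    """Leave-one-date-out predictions from in-situ training data.

    For every observation date, a model is trained on all other dates'
    plots and predicts the held-out date, so each plot is predicted
    exactly once from data it never trained on.  Features are the band
    reflectances; with ``use_exposure`` the per-date VIS exposure time
    joins the feature set (``RFexp``), letting the model absorb date-level
    illumination/gain differences.

    ``plots`` needs columns ``plot_id``, ``date``, spectral columns
    ``b*``, the measured targets, and ``exposure_vis`` when used.
    """
    spec = spec or RegressorSpec("rf")
    dates = plots["date"].unique()
    if len(dates) < 2:
        raise ValueError("need at least 2 distinct dates")
    band_cols = [c for c in plots.columns if c.startswith("b")]
    feat_cols = band_cols + (["exposure_vis"] if use_exposure else [])
    out = []
    for date in dates:
        test = plots[plots["date"] == date]
        train = plots[plots["date"] != date]
        if len(test) == 0:
            warnings.warn(f"date {date} has no plots; skipped", stacklevel=2)
            continue
        rec = test[["plot_id", "date"]].copy()
        rec["n_train"] = len(train)
        for trait in targets:
            model = train_regressor(
                train[feat_cols].to_numpy(dtype=float),
                train[trait].to_numpy(dtype=float),
                spec,
            )
            rec[trait] = model.predict(test[feat_cols].to_numpy(dtype=float))
        out.append(rec)
    preds = pd.concat(out, ignore_index=True)
    preds.insert(0, "method", "rfexp" if use_exposure else "rf")
    return preds
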