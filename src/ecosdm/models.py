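"""The four-family SDM engine: GLM, GAM, RF and a MaxEnt-style model.

Each species is fit over repeated stratified train/test splits ("replicates")
in up to three variable arms (climate-only, soil-only, climate + soil).  The
families:

* **GLM** — weighted logistic regression with linear + quadratic terms per
  variable (standardized predictors).
* **GAM** — weighted additive logistic model with shrinkage-penalized cubic
  splines (basis dimension 4).
* **RF** — 500-tree classification forest with balanced class weights,
  mtry = ceil(sqrt(p)); the suitability score is the class-1 vote fraction.
* **MAXENT** — the penalized-logistic equivalent of maximum entropy on an
  expanded feature basis (linear + quadratic + hinge features at 10 knots),
  with heavy background case weights approximating the infinitely-weighted
  presence-background scheme.

Every model predicts a suitability in [0, 1]; ensembles combine family x
replicate members by an unweighted cellwise mean (default) or a TSS-weighted
mean with an optional inclusion cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .covsel import DesignMatrix
from .landscape import Landscape

FAMILIES = ("GLM", "GAM", "RF", "MAXENT")
N_REPLICATES_DEFAULT = 10
TEST_FRACTION_DEFAULT = 0.2


# ---------------------------------------------------------------------------
# Replicate splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplicateSplit:
    replicate_id: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int


def split_replicates(design: DesignMatrix, n_replicates: int = N_REPLICATES_DEFAULT,
                     test_fraction: float = TEST_FRACTION_DEFAULT,
                     seed: int = 0) -> list[ReplicateSplit]:
    """Repeated stratified random splits: presences and backgrounds are split
    separately so both classes appear in every train and test part."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    pres = np.flatnonzero(design.y == 1)
    back = np.flatnonzero(design.y == 0)
    n_tp = int(round(test_fraction * pres.size))
    n_tb = int(round(test_fraction * back.size))
    if min(n_tp, n_tb) == 0 or n_tp == pres.size or n_tb == back.size:
        raise ValueError("test_fraction leaves an empty class in train or test")
    rng = np.random.default_rng(seed)
    splits = []
    for rep in range(1, n_replicates + 1):
        rep_seed = int(rng.integers(2**31))
        r = np.random.default_rng(rep_seed)
        tp = r.choice(pres, size=n_tp, replace=False)
        tb = r.choice(back, size=n_tb, replace=False)
        test = np.sort(np.concatenate([tp, tb]))
        train = np.setdiff1d(np.arange(design.y.size), test)
        splits.append(ReplicateSplit(rep, train, test, rep_seed))
    return splits


# ---------------------------------------------------------------------------
# Feature transforms + fitted-model wrappers
# ---------------------------------------------------------------------------

class _Standardizer:
    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def _weighted_logistic_deviance(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """McFadden explained deviance of a weighted logistic fit (with intercept)."""
    clf = LogisticRegression(C=1e4, max_iter=1000)
    clf.fit(_Standardizer(X)(X), y, sample_weight=w)
    p = np.clip(clf.predict_proba(_Standardizer(X)(X))[:, 1], 1e-12, 1 - 1e-12)
    ll = np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p)))
    p0 = np.clip(np.average(y, weights=w), 1e-12, 1 - 1e-12)
    ll0 = np.sum(w * (y * np.log(p0) + (1 - y) * np.log(1 - p0)))
    return float(1.0 - ll / ll0) if ll0 != 0 else 0.0


@dataclass
class FittedModel:
    """A fitted member: family tag, the variables it consumes and a predictor
    closure mapping a variable matrix to suitabilities in [0, 1]."""

    family: str
    variables: list[str]
    _predict: callable
    diagnostics: dict = field(default_factory=dict)

    def predict_matrix(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [v for v in self.variables if v not in X.columns]
            if missing:
                raise KeyError(f"prediction input lacks variables: {missing}")
            X = X[self.variables].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        return np.clip(self._predict(X), 0.0, 1.0)

    def predict_landscape(self, landscape: Landscape) -> np.ndarray:
        """Cellwise suitability map; nodata in -> NaN out."""
        missing = [v for v in self.variables if v not in landscape.layers]
        if missing:
            raise KeyError(f"landscape lacks variables: {missing}")
        stack = np.stack([landscape.layers[v] for v in self.variables], axis=-1)
        flat = stack.reshape(-1, len(self.variables))
        ok = ~landscape.nodata_mask.ravel()
        out = np.full(flat.shape[0], np.nan)
        out[ok] = self.predict_matrix(flat[ok])
        return out.reshape(landscape.shape)


def _fit_glm(X, y, w, seed, hp):
    std = _Standardizer(X)

    def expand(A):
        Z = std(A)
        return np.hstack([Z, Z ** 2])

    clf = LogisticRegression(C=hp.get("glm_C", 1e4), max_iter=2000)
    clf.fit(expand(X), y, sample_weight=w)
    return lambda A: clf.predict_proba(expand(A))[:, 1]


def _fit_gam(X, y, w, seed, hp):
    from .covsel import ShrinkageGAM

    gam = ShrinkageGAM(X, y, w, df=hp.get("gam_df", 4),
                       alpha=hp.get("gam_alpha", 1.0))
    return gam.predict


def _fit_rf(X, y, w, seed, hp):
    p = X.shape[1]
    clf = RandomForestClassifier(
        n_estimators=hp.get("rf_trees", 500),
        max_features=min(p, int(np.ceil(np.sqrt(p)))),
        class_weight="balanced", random_state=seed, n_jobs=1,
        min_samples_leaf=hp.get("rf_min_leaf", 1))
    clf.fit(X, y, sample_weight=w)
    one = int(np.flatnonzero(clf.classes_ == 1)[0])
    return lambda A: clf.predict_proba(A)[:, one]


def _hinge_knots(X: np.ndarray, n_knots: int) -> np.ndarray:
    qs = np.linspace(0, 1, n_knots + 2)[1:-1]
    return np.quantile(X, qs, axis=0)  # (n_knots, p)


def _fit_maxent(X, y, w, seed, hp):
    """Penalized logistic on linear + quadratic + hinge features with heavy
    background weights, the standard GLM realization of maximum entropy."""
    n_knots = hp.get("maxent_knots", 10)
    std = _Standardizer(X)
    knots = _hinge_knots(std(X), n_knots)

    def expand(A):
        Z = std(A)
        feats = [Z, Z ** 2]
        for k in range(knots.shape[0]):
            feats.append(np.maximum(Z - knots[k], 0.0))   # forward hinge
            feats.append(np.maximum(knots[k] - Z, 0.0))   # reverse hinge
        return np.hstack(feats)

    # presences weight 1, background weight 100 x the prevalence-balanced
    # weights: approximates the infinitely-weighted background scheme
    w_me = np.where(y == 1, 1.0, 100.0 * w / np.where(w > 0, w, 1.0).mean())
    clf = LogisticRegression(penalty="l1", solver="liblinear",
                             C=hp.get("maxent_C", 1.0), max_iter=2000,
                             random_state=seed)
    clf.fit(expand(X), y, sample_weight=w_me)
    return lambda A: clf.predict_proba(expand(A))[:, 1]


_FITTERS = {"GLM": _fit_glm, "GAM": _fit_gam, "RF": _fit_rf, "MAXENT": _fit_maxent}


def fit_model(design_train: DesignMatrix, family: str,
              hyperparams: dict | None = None, seed: int = 0) -> FittedModel:
    """Fit one family on a training design; deterministic for a fixed seed."""
    if family not in _FITTERS:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    hp = hyperparams or {}
    X = design_train.X.to_numpy(dtype=float)
    nvar = X.shape[1]
    if family in ("GLM", "GAM") and X.shape[0] < 5 * nvar:
        warnings.warn(f"{family}: only {X.shape[0]} training rows for {nvar} variables")
    predict = _FITTERS[family](X, design_train.y, design_train.weights, seed, hp)
    return FittedModel(family, list(design_train.X.columns), predict)


def predict_model(model: FittedModel, data: pd.DataFrame | Landscape) -> np.ndarray:
    """Suitability scores for a variable matrix, or a map for a landscape."""
    if isinstance(data, Landscape):
        return model.predict_landscape(data)
    return model.predict_matrix(data)


# ---------------------------------------------------------------------------
# Bundles and ensembles
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """All fitted (family, replicate) members for one species and arm."""

    species_id: str
    arm: str
    variables: list[str]
    members: dict[tuple[str, int], FittedModel | None]  # None = failed fit
    splits: list[ReplicateSplit]

    def live_members(self) -> dict[tuple[str, int], FittedModel]:
        return {k: m for k, m in self.members.items() if m is not None}


def fit_bundle(design: DesignMatrix, splits: list[ReplicateSplit],
               families: tuple[str, ...] = FAMILIES, arm: str = "climate_soil",
               hyperparams: dict | None = None, seed: int = 0) -> ModelBundle:
    """Fit every family on every replicate's training rows.  A member whose
    fit raises is flagged failed and skipped downstream."""
    members: dict[tuple[str, int], FittedModel | None] = {}
    rng = np.random.default_rng(seed)
    for split in splits:
        sub = DesignMatrix(design.species_id,
                           design.X.iloc[split.train_idx].reset_index(drop=True),
                           design.y[split.train_idx], design.weights[split.train_idx],
                           design.categories)
        for family in families:
            fit_seed = int(rng.integers(2**31))
            try:
                members[(family, split.replicate_id)] = fit_model(
                    sub, family, hyperparams, seed=fit_seed)
            except Exception as exc:  # noqa: BLE001 - per-member resilience
                warnings.warn(f"{design.species_id}/{arm}: {family} replicate "
                              f"{split.replicate_id} failed ({exc})")
                members[(family, split.replicate_id)] = None
    return ModelBundle(design.species_id, arm, list(design.X.columns), members, splits)


def ensemble_predict(bundle: ModelBundle, data: pd.DataFrame | Landscape,
                     rule: str = "mean", member_tss: dict[tuple[str, int], float] | None = None,
                     inclusion_cutoff: float | None = None) -> np.ndarray:
    """Committee prediction: cellwise mean (default) or TSS-weighted mean of
    member predictions, optionally excluding members below a TSS cutoff.

    The ensemble is always bracketed cellwise by the member min and max.
    """
    live = bundle.live_members()
    if rule == "tss_weighted" and member_tss is None:
        raise ValueError("tss_weighted rule requires member_tss")
    keys = list(live)
    if inclusion_cutoff is not None:
        if member_tss is None:
            raise ValueError("inclusion_cutoff requires member_tss")
        keys = [k for k in keys if member_tss.get(k, -np.inf) >= inclusion_cutoff]
        if not keys:
            raise ValueError(f"all members below TSS cutoff {inclusion_cutoff}; "
                             f"member TSS: {member_tss}")
    if not keys:
        raise ValueError("no live members to ensemble")
    preds = np.stack([predict_model(live[k], data) for k in keys])
    if rule == "mean":
        return np.mean(preds, axis=0)
    if rule == "tss_weighted":
        wts = np.array([max(member_tss[k], 0.0) for k in keys])
        if wts.sum() == 0:
            return np.mean(preds, axis=0)
        return np.tensordot(wts / wts.sum(), preds, axes=(0, 0))
    raise ValueError(f"unknown ensemble rule {rule!r}")
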