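"""Embedded covariate selection: from 17 candidates to 5 climate + 5 soil.

Dimensionality of the predictor set is reduced per species in two passes:

1. ``vif_prescreen`` — iterative variance-inflation-factor screening of the
   raw candidate pool (VIF_j = 1 / (1 - R²_j) from regressing variable j on
   the remaining candidates; the worst offender is dropped until all VIF fall
   below the threshold).
2. ``covsel_embed`` — a collinearity filter (among any pair with |Pearson r|
   above ``r_cut``, the member with lower univariate explained deviance is
   removed, processing pairs in decreasing |r|) followed by three embedded
   regularization rankings: a logistic elastic net (ranked by order of entry
   along the penalty path), a shrinkage-penalized additive logistic model
   (ranked by each smooth's explained-deviance share), and a guided
   regularized random forest (second-forest importance scaled by penalties
   derived from a preliminary forest).  Per-method ranks are averaged and the
   top-k variables are chosen within each category (climate, soil).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .landscape import Landscape

R_CUT_DEFAULT = 0.7
VIF_THRESHOLD_DEFAULT = 10.0
EMBED_METHODS = ("glm_elasticnet", "gam_shrinkage", "guided_rrf")


@dataclass
class DesignMatrix:
    """Presence/background rows for one species: predictors, 1/0 response and
    case weights (weights equalize total presence and background mass so the
    effective prevalence is 0.5)."""

    species_id: str
    X: pd.DataFrame
    y: np.ndarray
    weights: np.ndarray
    categories: dict[str, str]  # variable -> climate | soil

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("design matrix contains missing values")
        if not (self.y == 1).any() or not (self.y == 0).any():
            raise ValueError("design matrix needs at least one presence and one background row")

    @property
    def n_presence(self) -> int:
        return int((self.y == 1).sum())

    @property
    def n_background(self) -> int:
        return int((self.y == 0).sum())

    def variables(self, category: str | None = None) -> list[str]:
        return [v for v in self.X.columns
                if category is None or self.categories[v] == category]

    def subset(self, variables: list[str]) -> "DesignMatrix":
        return DesignMatrix(self.species_id, self.X[variables].copy(), self.y,
                            self.weights, {v: self.categories[v] for v in variables})


def build_design(presences: pd.DataFrame, background: pd.DataFrame,
                 landscape: Landscape, variables: list[str] | None = None,
                 species_id: str | None = None) -> DesignMatrix:
    """Assemble the presence + background design matrix from landscape values.

    Rows whose coordinates fall on masked cells are silently excluded.
    """
    variables = variables or landscape.variable_names()
    species_id = species_id or str(presences["species"].iloc[0])

    def extract(df: pd.DataFrame) -> pd.DataFrame:
        vals = landscape.values_at(df["x"].to_numpy(), df["y"].to_numpy(), variables)
        out = pd.DataFrame(vals, columns=variables)
        return out.dropna()

    Xp, Xb = extract(presences), extract(background)
    if Xp.empty or Xb.empty:
        raise ValueError(f"species {species_id!r}: no usable presence or background rows")
    X = pd.concat([Xp, Xb], ignore_index=True)
    y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xb))])
    w = np.concatenate([np.ones(len(Xp)), np.full(len(Xb), len(Xp) / len(Xb))])
    cats = {v: landscape.category_of(v) for v in variables}
    return DesignMatrix(species_id, X, y, w, cats)


# ---------------------------------------------------------------------------
# VIF pre-screening
# ---------------------------------------------------------------------------

def vif_scores(X: pd.DataFrame) -> pd.Series:
    """VIF_j = 1/(1 - R²_j) from regressing column j on the others (with
    intercept).  Perfect collinearity yields inf."""
    Z = X.to_numpy(dtype=float)
    Z = (Z - Z.mean(axis=0)) / np.where(Z.std(axis=0) > 0, Z.std(axis=0), 1.0)
    out = {}
    for j, name in enumerate(X.columns):
        others = np.delete(Z, j, axis=1)
        target = Z[:, j]
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        tss = (target ** 2).sum()
        r2 = 1.0 - (resid ** 2).sum() / tss if tss > 0 else 0.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_prescreen(X: pd.DataFrame, threshold: float = VIF_THRESHOLD_DEFAULT) -> list[str]:
    """Iteratively drop the highest-VIF variable until all VIF < threshold.

    Survivors are returned in input order.  Among equal offenders (e.g. a
    perfectly duplicated pair) the later column is dropped.
    """
    if X.shape[1] < 2:
        return list(X.columns)
    if X.shape[0] < X.shape[1] + 1:
        raise ValueError("need more rows than variables for VIF screening")
    cols = list(X.columns)
    while len(cols) > 1:
        vif = vif_scores(X[cols])
        worst = vif.max()
        if worst < threshold:
            break
        # last position among the maxima -> deterministic tie-break
        offenders = [c for c in cols if vif[c] == worst]
        cols.remove(offenders[-1])
    return cols


# ---------------------------------------------------------------------------
# Collinearity filter
# ---------------------------------------------------------------------------

def _univariate_deviance(design: DesignMatrix) -> pd.Series:
    """Explained deviance (McFadden) of each variable fit alone against the
    response by weighted logistic regression."""
    from .models import _weighted_logistic_deviance
    out = {}
    for var in design.X.columns:
        out[var] = _weighted_logistic_deviance(
            design.X[[var]].to_numpy(), design.y, design.weights)
    return pd.Series(out)


def collinearity_filter(design: DesignMatrix, r_cut: float = R_CUT_DEFAULT
                        ) -> tuple[list[str], pd.Series]:
    """Greedy removal of collinear pairs, keeping the stronger univariate driver.

    Pairs are processed in decreasing |Pearson r|; whenever both members of a
    pair with |r| > r_cut are still present, the one with the lower univariate
    explained deviance is removed.  Returns (survivors in input order,
    univariate deviance of every candidate).
    """
    cols = list(design.X.columns)
    if len(cols) < 2:
        return cols, _univariate_deviance(design)
    dev = _univariate_deviance(design)
    corr = design.X.corr().abs()
    pairs = [(corr.iloc[i, j], cols[i], cols[j])
             for i in range(len(cols)) for j in range(i + 1, len(cols))
             if corr.iloc[i, j] > r_cut]
    alive = set(cols)
    for _, a, b in sorted(pairs, reverse=True):
        if a in alive and b in alive:
            alive.discard(a if dev[a] < dev[b] else b)
    return [c for c in cols if c in alive], dev


# ---------------------------------------------------------------------------
# Embedded rankings
# ---------------------------------------------------------------------------

def _standardize(X: pd.DataFrame) -> np.ndarray:
    Z = X.to_numpy(dtype=float)
    sd = Z.std(axis=0)
    return (Z - Z.mean(axis=0)) / np.where(sd > 0, sd, 1.0)


def _rank_elasticnet(design: DesignMatrix, seed: int, l1_ratio: float = 0.5,
                     n_lambdas: int = 30) -> pd.Series:
    """Rank variables by order of entry along the elastic-net penalty path
    (standardized predictors; earlier entry = more important)."""
    Z = _standardize(design.X)
    y, w = design.y, design.weights
    n = len(y)
    # lambda_max: smallest penalty zeroing every coefficient (KKT at beta=0)
    p0 = np.average(y, weights=w)
    grad = np.abs(Z.T @ (w * (y - p0))) / w.sum()
    lam_max = grad.max() / max(l1_ratio, 1e-3)
    lams = lam_max * np.geomspace(1.0, 1e-3, n_lambdas)
    entry = np.full(Z.shape[1], np.inf)
    clf = LogisticRegression(penalty="elasticnet", solver="saga", l1_ratio=l1_ratio,
                             max_iter=2000, tol=1e-4, warm_start=True,
                             random_state=seed)
    last_coef = np.zeros(Z.shape[1])
    from sklearn.exceptions import ConvergenceWarning
    for k, lam in enumerate(lams):
        clf.C = 1.0 / (n * lam)
        with warnings.catch_warnings():
            # the path is used only for entry order; early-stopped saga
            # iterations at small penalties are acceptable
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(Z, y, sample_weight=w)
        coef = clf.coef_.ravel()
        newly = (np.abs(coef) > 1e-8) & ~np.isfinite(entry)
        entry[newly] = k + np.argsort(np.argsort(-np.abs(coef[newly]))) / (Z.shape[1] + 1.0)
        last_coef = coef
    # never-entered variables rank last, ordered by final |coef|
    never = ~np.isfinite(entry)
    entry[never] = n_lambdas + np.argsort(np.argsort(-np.abs(last_coef[never])))
    order = np.argsort(entry)
    ranks = np.empty(Z.shape[1])
    ranks[order] = np.arange(1, Z.shape[1] + 1)
    return pd.Series(ranks, index=design.X.columns)


class ShrinkageGAM:
    """Weighted additive logistic model with shrinkage-penalized cubic splines.

    Each variable gets a B-spline smooth (basis dimension ``df``), centered so
    the intercept is identifiable; the penalty is alpha * (curvature + ridge)
    per smooth, where the ridge term shrinks the penalty null space so a
    smooth can be removed entirely — the behaviour of selection-capable
    shrinkage smoothers.  Fit by penalized IRLS; fully deterministic.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, w: np.ndarray,
                 df: int = 4, alpha: float = 1.0, ridge: float = 0.1,
                 max_iter: int = 50, tol: float = 1e-8):
        from statsmodels.gam.api import BSplines

        X = np.asarray(X, dtype=float)
        self.lo, self.hi = X.min(axis=0), X.max(axis=0)
        self.nvar = X.shape[1]
        self.bs = BSplines(X, df=[df] * self.nvar, degree=[3] * self.nvar)
        basis = self.bs.basis
        self.col_means = np.average(basis, axis=0, weights=w)
        B = np.hstack([np.ones((X.shape[0], 1)), basis - self.col_means])

        P = np.zeros((B.shape[1], B.shape[1]))
        for j in range(self.nvar):
            idx = np.flatnonzero(self.bs.mask[j]) + 1
            k = idx.size
            D2 = np.diff(np.eye(k), n=2, axis=0) if k > 2 else np.zeros((1, k))
            P[np.ix_(idx, idx)] = alpha * (D2.T @ D2 + ridge * np.eye(k))

        beta = np.zeros(B.shape[1])
        for _ in range(max_iter):
            eta = B @ beta
            mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
            wt = w * np.clip(mu * (1 - mu), 1e-6, None)
            z = eta + (y - mu) / np.clip(mu * (1 - mu), 1e-6, None)
            new = np.linalg.solve(B.T @ (wt[:, None] * B) + P, B.T @ (wt * z))
            if np.max(np.abs(new - beta)) < tol:
                beta = new
                break
            beta = new
        self.beta = beta
        self.weights = w

    def component(self, j: int) -> np.ndarray:
        """Fitted (centered) contribution of smooth j on the training rows."""
        idx = np.flatnonzero(self.bs.mask[j])
        return (self.bs.basis[:, idx] - self.col_means[idx]) @ self.beta[idx + 1]

    def predict(self, A: np.ndarray) -> np.ndarray:
        # B-spline bases do not extrapolate: clip to the training range
        A = np.clip(np.asarray(A, dtype=float), self.lo, self.hi)
        basis = self.bs.transform(A)
        if basis.ndim == 1:
            basis = basis[None, :]
        eta = self.beta[0] + (basis - self.col_means) @ self.beta[1:]
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))


def _rank_gam(design: DesignMatrix, seed: int, df_spline: int = 4,
              alpha: float = 1.0) -> pd.Series:
    """Rank variables by explained-deviance share of shrinkage-penalized
    cubic-spline smooths in an additive logistic model; smooths shrunk to
    (near) zero rank last."""
    gam = ShrinkageGAM(design.X.to_numpy(dtype=float), design.y, design.weights,
                       df=df_spline, alpha=alpha)
    shares = np.array([np.average(gam.component(j) ** 2, weights=design.weights)
                       for j in range(gam.nvar)])
    order = np.argsort(-shares)
    ranks = np.empty(gam.nvar)
    ranks[order] = np.arange(1, gam.nvar + 1)
    return pd.Series(ranks, index=design.X.columns)


def _rank_guided_rrf(design: DesignMatrix, seed: int, gamma: float = 0.5,
                     n_trees: int = 500) -> pd.Series:
    """Guided-regularized-forest ranking: a preliminary forest's importances
    set per-variable penalty factors lambda_j = (1 - gamma) + gamma *
    imp_j / max(imp); the regularized ranking is the second forest's
    importance scaled by lambda_j."""
    rng = np.random.default_rng(seed)
    common = dict(n_estimators=n_trees, class_weight="balanced", n_jobs=1)
    f0 = RandomForestClassifier(random_state=int(rng.integers(2**31)), **common)
    f0.fit(design.X, design.y, sample_weight=design.weights)
    imp0 = f0.feature_importances_
    lam = (1.0 - gamma) + gamma * imp0 / max(imp0.max(), 1e-12)
    f1 = RandomForestClassifier(random_state=int(rng.integers(2**31)), **common)
    f1.fit(design.X, design.y, sample_weight=design.weights)
    score = f1.feature_importances_ * lam
    order = np.argsort(-score)
    ranks = np.empty(len(score))
    ranks[order] = np.arange(1, len(score) + 1)
    return pd.Series(ranks, index=design.X.columns)


def embedded_rank(design: DesignMatrix, method: str, seed: int = 0, **kw) -> pd.Series:
    """Strict 1-based ranking of the design's variables (1 = most important)
    by one embedded method: ``glm_elasticnet``, ``gam_shrinkage`` or
    ``guided_rrf``.  Deterministic for a fixed seed."""
    if design.X.shape[1] < 2:
        raise ValueError("embedded ranking needs at least 2 variables")
    dispatch = {"glm_elasticnet": _rank_elasticnet,
                "gam_shrinkage": _rank_gam,
                "guided_rrf": _rank_guided_rrf}
    if method not in dispatch:
        raise ValueError(f"unknown method {method!r}; expected one of {EMBED_METHODS}")
    return dispatch[method](design, seed, **kw)


@dataclass
class SelectedCovariates:
    """Outcome of the embedded selection: the full rank table and the chosen
    top-k_climate + top-k_soil set."""

    species_id: str
    table: pd.DataFrame  # variable, category, per-method ranks, aggregate, chosen
    chosen: list[str] = field(default_factory=list)

    def chosen_by_category(self, category: str) -> list[str]:
        sub = self.table[(self.table["chosen"]) & (self.table["category"] == category)]
        return sub["variable"].tolist()


def covsel_embed(design: DesignMatrix, k_climate: int = 5, k_soil: int = 5,
                 r_cut: float = R_CUT_DEFAULT, seed: int = 0,
                 rrf_trees: int = 500) -> SelectedCovariates:
    """Collinearity filter, three embedded rankings, mean-rank aggregation and
    top-k choice within each category.

    Ties in the aggregate rank break toward the higher univariate explained
    deviance.  A method that fails to converge is dropped from the average
    with a warning.  If a category holds fewer than k survivors, all of them
    are chosen (with a warning).
    """
    survivors, dev = collinearity_filter(design, r_cut=r_cut)
    sub = design.subset(survivors)
    ranks: dict[str, pd.Series] = {}
    for method in EMBED_METHODS:
        try:
            kw = {"n_trees": rrf_trees} if method == "guided_rrf" else {}
            ranks[method] = embedded_rank(sub, method, seed=seed, **kw)
        except Exception as exc:  # noqa: BLE001 - convergence failures tolerated
            warnings.warn(f"{method} ranking failed ({exc}); aggregating remaining methods")
    if not ranks:
        raise RuntimeError("every embedded ranking method failed")

    agg = pd.concat(ranks, axis=1).mean(axis=1)
    table = pd.DataFrame({
        "variable": survivors,
        "category": [design.categories[v] for v in survivors],
        "aggregate_rank": agg[survivors].to_numpy(),
        "univariate_deviance": dev[survivors].to_numpy(),
    })
    for method in EMBED_METHODS:
        table[f"rank_{method}"] = (ranks[method][survivors].to_numpy()
                                   if method in ranks else np.nan)
    table = table.sort_values(["aggregate_rank", "univariate_deviance"],
                              ascending=[True, False], kind="mergesort")

    chosen: list[str] = []
    for category, k in (("climate", k_climate), ("soil", k_soil)):
        cands = table[table["category"] == category]["variable"].tolist()
        if len(cands) < k:
            warnings.warn(f"species {design.species_id!r}: only {len(cands)} "
                          f"{category} candidates survive the collinearity filter "
                          f"(requested {k}); choosing all")
        chosen += cands[:k]
    table["chosen"] = table["variable"].isin(chosen)
    table = table.reset_index(drop=True)
    return SelectedCovariates(design.species_id, table, chosen)
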