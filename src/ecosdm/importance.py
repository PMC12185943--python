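"""Permutation variable importance and relative-contribution tables.

Importance of a variable to a fitted model is measured by prediction
disruption under permutation: shuffle that column only, re-predict, and take
1 minus the Pearson correlation between reference and permuted predictions
(clipped to [0, 1]), averaged over a small number of random permutations
(default 5).  Constant prediction vectors score 0.

Per species, importances are averaged over all families and replicates and
normalized to percentages summing to 100 ("relative contributions"); per
ecoregion, contribution vectors are averaged unweighted across the species
assigned to it at a given threshold, yielding the variables x ecoregion
contribution table with per-category (climate/soil) mean rows.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .covsel import DesignMatrix
from .models import FittedModel, ModelBundle

N_PERMUTATIONS_DEFAULT = 5


def permutation_importance(model: FittedModel, X: pd.DataFrame, variable: str,
                           n_perm: int = N_PERMUTATIONS_DEFAULT, seed: int = 0,
                           method: str = "pearson") -> float:
    """Mean over permutations of clip(1 - r(reference, permuted), 0, 1).

    ``method`` selects Pearson (default) or Spearman correlation between the
    reference and permuted prediction vectors.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if variable not in X.columns:
        raise KeyError(f"variable {variable!r} not in prediction matrix")
    rng = np.random.default_rng(seed)
    ref = model.predict_matrix(X)
    vals = []
    Xp = X.copy()
    for _ in range(n_perm):
        Xp[variable] = rng.permutation(X[variable].to_numpy())
        perm = model.predict_matrix(Xp)
        if np.std(ref) == 0 or np.std(perm) == 0:
            vals.append(0.0)  # constant predictions carry no signal
            continue
        if method == "spearman":
            from scipy.stats import spearmanr
            r = spearmanr(ref, perm).statistic
        else:
            r = np.corrcoef(ref, perm)[0, 1]
        vals.append(float(np.clip(1.0 - r, 0.0, 1.0)))
    return float(np.mean(vals))


def bundle_importance(bundle: ModelBundle, design: DesignMatrix,
                      n_perm: int = N_PERMUTATIONS_DEFAULT, seed: int = 0,
                      keys: dict | None = None) -> pd.DataFrame:
    """Permutation importance of every variable for every live member, on the
    full presence + background matrix."""
    keys = keys or {}
    rng = np.random.default_rng(seed)
    rows = []
    for (family, rep), model in sorted(bundle.live_members().items()):
        for var in bundle.variables:
            imp = permutation_importance(model, design.X, var, n_perm=n_perm,
                                         seed=int(rng.integers(2**31)))
            rows.append({**keys, "species": bundle.species_id, "arm": bundle.arm,
                         "family": family, "replicate": rep, "variable": var,
                         "importance": imp, "n_permutations": n_perm})
    return pd.DataFrame(rows)


def relative_contributions(records: pd.DataFrame) -> pd.DataFrame:
    """Per-variable mean importance across families x replicates, normalized
    to percentages summing to 100 for the species.

    An all-zero importance vector stays zero and is flagged.
    """
    if records.empty:
        raise ValueError("no importance records")
    mean_imp = records.groupby("variable", sort=False)["importance"].mean()
    total = mean_imp.sum()
    flagged = total == 0
    pct = mean_imp * 0.0 if flagged else 100.0 * mean_imp / total
    out = pct.reset_index().rename(columns={"importance": "contribution_pct"})
    out["species"] = records["species"].iloc[0]
    out["all_zero"] = flagged
    return out


def aggregate_contributions(per_species: pd.DataFrame, assignments: pd.DataFrame,
                            tau: float, categories: dict[str, str]) -> pd.DataFrame:
    """Ecoregion-mean contribution table at assignment threshold tau.

    Rows are variables (climate block first, then soil, each followed by a
    category "Mean" row); columns are the ecoregions with at least one species
    assigned at tau; cells are unweighted means over those species'
    contribution percentages.
    """
    col = f"assigned_{tau}"
    if col not in assignments.columns:
        raise KeyError(f"assignments lack column {col!r}")
    merged = per_species.merge(assignments[["species", col]], on="species", how="left")
    merged = merged.rename(columns={col: "ecoregion"})
    regions = [r for r in merged["ecoregion"].dropna().unique()]
    if not regions:
        warnings.warn(f"no species assigned at threshold {tau}; empty table")
        return pd.DataFrame()
    wide = (merged.dropna(subset=["ecoregion"])
            .pivot_table(index="variable", columns="ecoregion",
                         values="contribution_pct", aggfunc="mean"))
    missing = [r for r in regions if r not in wide.columns]
    if missing:
        warnings.warn(f"ecoregions without assigned species omitted: {missing}")

    blocks = []
    for category in ("climate", "soil"):
        vars_cat = [v for v in wide.index if categories.get(v) == category]
        if not vars_cat:
            continue
        block = wide.loc[vars_cat].copy()
        block.insert(0, "category", category)
        mean_row = block.drop(columns="category").mean().to_frame().T
        mean_row.index = [f"Mean ({category})"]
        mean_row.insert(0, "category", category)
        blocks.append(pd.concat([block, mean_row]))
    table = pd.concat(blocks)
    table.index.name = "variable"
    return table.reset_index()
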