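"""Ecoregion-level analyses: raster value extraction at occurrences,
per-ecoregion response densities, and the threshold x ecoregion sensitivity
analysis (two-way ANOVA with interaction, type II sums of squares, followed
by Tukey HSD on each factor's marginal means).

Significance bands follow the usual convention: ns (p >= 0.05), * (< 0.05),
** (< 0.01), *** (< 0.001), **** (< 0.0001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import gaussian_kde
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .landscape import EcoregionMap, Landscape

SIGNIFICANCE_BANDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_band(p: float) -> str:
    for cut, band in SIGNIFICANCE_BANDS:
        if p < cut:
            return band
    return "ns"


def extract_values(occ: pd.DataFrame, landscape: Landscape,
                   ecoregions: EcoregionMap | None = None,
                   variables: list[str] | None = None) -> pd.DataFrame:
    """Layer values at the containing cell of each occurrence (cell-center
    semantics, no interpolation).  Off-grid or masked points are flagged
    ``nodata`` rather than dropped; ecoregion labels are attached when a map
    is supplied."""
    variables = variables or landscape.variable_names()
    vals = landscape.values_at(occ["x"].to_numpy(), occ["y"].to_numpy(), variables)
    out = occ[["species", "x", "y"]].reset_index(drop=True)
    for j, var in enumerate(variables):
        out[var] = vals[:, j]
    out["nodata"] = ~np.isfinite(vals).all(axis=1)
    if ecoregions is not None:
        codes = ecoregions.region_at(landscape, occ["x"].to_numpy(), occ["y"].to_numpy())
        out["ecoregion"] = [ecoregions.labels.get(c, pd.NA) if c >= 0 else pd.NA
                            for c in codes]
    return out


def response_density(values: pd.DataFrame, variable: str, group_col: str = "ecoregion",
                     n_grid: int = 128, min_group: int = 5,
                     species_col: str | None = "species") -> pd.DataFrame:
    """Gaussian kernel density of a variable per group on a shared grid.

    When a species column is present, densities are computed per species and
    averaged within each group (the group curve is the mean of its species'
    curves).  Groups with fewer than ``min_group`` finite values are omitted
    with a warning.  Long-format output: (variable, group, grid_x, density).
    """
    ok = ~values["nodata"] if "nodata" in values.columns else np.ones(len(values), bool)
    cols = [c for c in {variable, group_col, species_col} if c in values.columns]
    sub = values.loc[ok, cols].dropna()
    finite = np.isfinite(sub[variable].to_numpy(dtype=float))
    sub = sub[finite]
    if sub.empty:
        raise ValueError(f"no finite values of {variable!r}")
    lo, hi = sub[variable].min(), sub[variable].max()
    pad = 0.1 * (hi - lo) if hi > lo else 1.0
    grid = np.linspace(lo - pad, hi + pad, n_grid)

    def kde_curve(v: np.ndarray) -> np.ndarray | None:
        if np.unique(v).size < 2:
            return None
        return gaussian_kde(v)(grid)

    rows = []
    for group, gdf in sub.groupby(group_col, sort=True):
        if len(gdf) < min_group:
            warnings.warn(f"group {group!r} has {len(gdf)} < {min_group} values; omitted")
            continue
        if species_col in gdf.columns and gdf[species_col].nunique() > 1:
            curves = [kde_curve(s[variable].to_numpy(dtype=float))
                      for _, s in gdf.groupby(species_col) if len(s) >= min_group]
            curves = [c for c in curves if c is not None]
            if not curves:
                continue
            dens = np.mean(curves, axis=0)
        else:
            dens = kde_curve(gdf[variable].to_numpy(dtype=float))
            if dens is None:
                warnings.warn(f"group {group!r} is degenerate; omitted")
                continue
        rows.append(pd.DataFrame({"variable": variable, group_col: group,
                                  "grid_x": grid, "density": dens}))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["variable", group_col, "grid_x", "density"])


@dataclass
class SensitivityResult:
    """Two-way ANOVA table plus all pairwise Tukey comparisons per factor."""

    anova: pd.DataFrame
    tukey: pd.DataFrame  # factor, group1, group2, meandiff, p_adj, band

    def pairs_for(self, factor: str) -> pd.DataFrame:
        return self.tukey[self.tukey["factor"] == factor].reset_index(drop=True)


def sensitivity_anova(table: pd.DataFrame, response: str,
                      factors: tuple[str, str] = ("ecoregion", "threshold"),
                      tukey: bool = True) -> SensitivityResult:
    """Two-way ANOVA with interaction (type II SS) and Tukey HSD per factor.

    ``tukey=False`` skips the post hoc comparisons (the studentized-range
    quantile is expensive), returning an empty comparison table; useful in
    permutation loops that only consume the ANOVA p-values.

    If any factor-combination cell has fewer than 2 observations (or is
    empty) the interaction is dropped with a warning and main effects are
    reported from the additive model.
    """
    fa, fb = factors
    df = table[[response, fa, fb]].dropna().copy()
    df.columns = ["y", "A", "B"]
    for col in ("A", "B"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col} needs >= 2 levels")
    cells = df.groupby(["A", "B"]).size()
    full_grid = df["A"].nunique() * df["B"].nunique()
    with_interaction = (len(cells) == full_grid) and (cells.min() >= 2)
    formula = "y ~ C(A) * C(B)" if with_interaction else "y ~ C(A) + C(B)"
    if not with_interaction:
        warnings.warn("sparse or empty factor cells: interaction dropped, "
                      "main effects reported from the additive model")
    fit = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    anova = anova.rename(index={"C(A)": fa, "C(B)": fb, "C(A):C(B)": f"{fa}:{fb}"})

    tukey_rows = []
    for name, col in ((fa, "A"), (fb, "B")) if tukey else ():
        res = pairwise_tukeyhsd(df["y"].to_numpy(), df[col].astype(str).to_numpy())
        i1, i2 = res._multicomp.pairindices
        groups = res.groupsunique
        for a, b, md, p in zip(i1, i2, res.meandiffs, res.pvalues):
            p = float(p)
            tukey_rows.append({"factor": name, "group1": str(groups[a]),
                               "group2": str(groups[b]), "meandiff": float(md),
                               "p_adj": p, "band": significance_band(p)})
    return SensitivityResult(anova=anova, tukey=pd.DataFrame(tukey_rows))


def sensitivity_export(results: dict[str, SensitivityResult],
                       categories: dict[str, str] | None = None) -> pd.DataFrame:
    """Dot-plot export: one row per (variable, factor, comparison, band),
    covering all pairwise ecoregion and threshold contrasts."""
    rows = []
    for variable, res in results.items():
        for _, r in res.tukey.iterrows():
            rows.append({"variable": variable,
                         "category": (categories or {}).get(variable, pd.NA),
                         "factor": r["factor"],
                         "comparison": f"{r['group1']} vs {r['group2']}",
                         "meandiff": r["meandiff"], "p_adj": r["p_adj"],
                         "band": r["band"]})
    return pd.DataFrame(rows)
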