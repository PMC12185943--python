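"""Occurrence pre-processing: cleaning, thinning, ecoregion assignment and
density-weighted background allocation.

The stages mirror standard presence-only SDM hygiene: coordinate validity and
extent checks, geographic thinning to one record per grid cell, assignment of
each species to the ecoregion holding at least a threshold fraction tau of its
records (tau in {0.6, 0.7, 0.8, 0.9, 1.0}; high tau selects ecoregion
specialists), environmental filtering on a binned multidimensional grid, and
background-point allocation weighted by a 2-D kernel density of the presences
so pseudo-absences inherit the occurrence data's spatial sampling bias.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .landscape import EcoregionMap, Landscape

DEFAULT_THRESHOLDS = (0.6, 0.7, 0.8, 0.9, 1.0)
#: Minimum records for a species to enter modeling.  The continental study
#: gates at >100 records; the synthetic default is 50 to keep fixtures small.
MIN_RECORDS_DEFAULT = 50


def clean_coordinates(occ: pd.DataFrame, landscape: Landscape) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop invalid records, labelling each drop with a reason code.

    Reasons: ``incomplete`` (missing/non-finite coordinate), ``off_extent``
    (outside the landscape), ``off_mask`` (on a nodata cell), ``duplicate``
    (exact repeat of an earlier record of the same species).

    Returns (kept, dropped-with-reason); an empty input yields two empty frames.
    """
    occ = occ.reset_index(drop=True)
    reason = pd.Series(pd.NA, index=occ.index, dtype="object")

    x = pd.to_numeric(occ.get("x"), errors="coerce")
    y = pd.to_numeric(occ.get("y"), errors="coerce")
    finite = np.isfinite(x.to_numpy(dtype=float, na_value=np.nan)) & \
        np.isfinite(y.to_numpy(dtype=float, na_value=np.nan))
    reason[~finite] = "incomplete"

    cand = finite.copy()
    if cand.any():
        inext = landscape.in_extent(x[cand].to_numpy(), y[cand].to_numpy())
        off = np.flatnonzero(cand)[~inext]
        reason.iloc[off] = "off_extent"
        cand[off] = False
    if cand.any():
        row, col = landscape.xy_to_rowcol(x[cand].to_numpy(), y[cand].to_numpy())
        masked = landscape.nodata_mask[row, col]
        off = np.flatnonzero(cand)[masked]
        reason.iloc[off] = "off_mask"
        cand[off] = False

    valid = occ[cand].assign(_x=x[cand], _y=y[cand])
    dup = valid.duplicated(subset=["species", "_x", "_y"], keep="first")
    reason[dup[dup].index] = "duplicate"

    kept = occ[reason.isna()].copy()
    dropped = occ[reason.notna()].copy()
    dropped["drop_reason"] = reason[reason.notna()]
    return kept.reset_index(drop=True), dropped.reset_index(drop=True)


def geographic_filter(occ: pd.DataFrame, landscape: Landscape) -> pd.DataFrame:
    """Keep no more than one presence point per grid cell (first by input order).

    Idempotent, and commutes with :func:`clean_coordinates`.
    """
    if occ.empty:
        return occ.copy()
    row, col = landscape.xy_to_rowcol(occ["x"].to_numpy(), occ["y"].to_numpy())
    cell = row.astype(np.int64) * landscape.n_cols + col
    keep = ~pd.DataFrame({"species": occ["species"].to_numpy(), "cell": cell}).duplicated()
    return occ[keep.to_numpy()].reset_index(drop=True)


def min_records_gate(occ: pd.DataFrame, min_records: int = MIN_RECORDS_DEFAULT) -> pd.DataFrame:
    """Retain only species with more than ``min_records`` presence points."""
    counts = occ.groupby("species")["x"].size()
    ok = counts[counts > min_records].index
    return occ[occ["species"].isin(ok)].reset_index(drop=True)


def assign_to_ecoregions(occ: pd.DataFrame, landscape: Landscape, ecoregions: EcoregionMap,
                         thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Assign each species to the ecoregion holding >= tau of its records.

    Frequencies are computed over on-map records only.  A species is assigned
    at threshold tau iff its maximum per-ecoregion frequency is >= tau (the
    inclusive comparator keeps the 100% class non-empty); assignment at tau
    implies assignment at every lower tau.

    Returns one row per species: per-ecoregion frequency columns
    ``freq_<label>`` and per-threshold assignment columns ``assigned_<tau>``
    (ecoregion label, or NA when unassigned).
    """
    rows = []
    labels = ecoregions.labels
    for sp, grp in occ.groupby("species", sort=True):
        codes = ecoregions.region_at(landscape, grp["x"].to_numpy(), grp["y"].to_numpy())
        on_map = codes >= 0
        rec = {"species": sp, "n_records": int(on_map.sum())}
        if not on_map.any():
            warnings.warn(f"species {sp!r} has no on-map records; unassigned at every threshold")
            freqs = {code: 0.0 for code in labels}
        else:
            counts = pd.Series(codes[on_map]).value_counts()
            freqs = {code: counts.get(code, 0) / on_map.sum() for code in labels}
        for code, label in labels.items():
            rec[f"freq_{label}"] = freqs[code]
        best_code = max(freqs, key=lambda c: freqs[c])
        for tau in thresholds:
            rec[f"assigned_{tau}"] = labels[best_code] if freqs[best_code] >= tau else pd.NA
        rows.append(rec)
    return pd.DataFrame(rows)


def richness_table(assignments: pd.DataFrame, ecoregions: EcoregionMap,
                   thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Species counts per (threshold, ecoregion): the richness-by-threshold
    summary.  Counts are non-increasing in tau within each ecoregion."""
    out = []
    for tau in thresholds:
        col = assignments[f"assigned_{tau}"]
        rec = {"threshold": tau}
        for label in ecoregions.labels.values():
            rec[label] = int((col == label).sum())
        out.append(rec)
    return pd.DataFrame(out)


def environmental_filter(occ: pd.DataFrame, landscape: Landscape,
                         variables: list[str] | None = None,
                         n_bins: int = 8, seed: int = 0) -> pd.DataFrame:
    """Thin records on a binned multidimensional environmental grid.

    Each variable's observed range (per species) is split into ``n_bins``
    equal-width intervals and exactly one record is retained uniformly at
    random per occupied bin combination.  A constant variable collapses to a
    single bin.  Deterministic for a fixed seed.
    """
    if occ.empty:
        return occ.copy()
    variables = variables or landscape.variable_names()
    rng = np.random.default_rng(seed)
    kept_idx: list[int] = []
    for _, grp in occ.groupby("species", sort=True):
        env = landscape.values_at(grp["x"].to_numpy(), grp["y"].to_numpy(), variables)
        bins = np.zeros(env.shape, dtype=int)
        for j in range(env.shape[1]):
            vals = env[:, j]
            lo, hi = np.nanmin(vals), np.nanmax(vals)
            if not np.isfinite(lo) or hi == lo or n_bins <= 1:
                continue  # constant variable: single bin
            edges = np.linspace(lo, hi, n_bins + 1)
            bins[:, j] = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, n_bins - 1)
        combo = pd.DataFrame(bins, index=grp.index)
        for _, cell in combo.groupby(list(combo.columns), sort=True):
            kept_idx.append(int(rng.choice(cell.index.to_numpy())))
    return occ.loc[sorted(kept_idx)].reset_index(drop=True)


def _nrd_bandwidth(vals: np.ndarray) -> float:
    """Normal-reference bandwidth (kernel sd): 1.06 min(sd, IQR/1.34) n^(-1/5)."""
    n = vals.size
    sd = vals.std(ddof=1)
    q75, q25 = np.percentile(vals, [75, 25])
    spread = min(sd, (q75 - q25) / 1.34) if (q75 - q25) > 0 else sd
    return 1.06 * spread * n ** (-0.2)


def kde_density(occ: pd.DataFrame, landscape: Landscape,
                bandwidth: tuple[float, float] | None = None,
                bandwidth_scale: float = 1.0) -> pd.DataFrame:
    """Bivariate Gaussian KDE of presence coordinates at every unmasked cell.

    Product kernel with per-axis normal-reference bandwidth unless supplied.
    Returns one row per unmasked cell center: (x, y, density).
    """
    if len(occ) < 3:
        raise ValueError("kde density requires at least 3 presence records")
    px = occ["x"].to_numpy(dtype=float)
    py = occ["y"].to_numpy(dtype=float)
    if bandwidth is None:
        hx, hy = _nrd_bandwidth(px), _nrd_bandwidth(py)
        if hx <= 0 or hy <= 0:
            raise ValueError("degenerate presence spread; supply an explicit bandwidth")
        hx *= bandwidth_scale
        hy *= bandwidth_scale
    else:
        hx, hy = bandwidth
        if hx <= 0 or hy <= 0:
            raise ValueError("bandwidth components must be positive")
    cx, cy = landscape.cell_centers()
    unmasked = ~landscape.nodata_mask.ravel()
    cx, cy = cx[unmasked], cy[unmasked]
    # product Gaussian kernel, cell x presence; O(cells * presences)
    dx = (cx[:, None] - px[None, :]) / hx
    dy = (cy[:, None] - py[None, :]) / hy
    density = np.exp(-0.5 * (dx ** 2 + dy ** 2)).sum(axis=1) / (2 * np.pi * hx * hy * len(px))
    return pd.DataFrame({"x": cx, "y": cy, "density": density})


def kde_background(occ: pd.DataFrame, landscape: Landscape, n_points: int = 10_000,
                   bandwidth: tuple[float, float] | None = None,
                   bandwidth_scale: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Allocate background points from a kernel-density surface of presences.

    Cells are sampled without replacement with probability proportional to
    the :func:`kde_density` surface, so background effort mirrors the
    presences' spatial sampling bias.  At most one point per cell, at cell
    center; the draw is capped at the number of unmasked cells holding
    positive density (a warning reports the cap).

    Returns a frame (species, x, y, density).
    """
    dens = kde_density(occ, landscape, bandwidth, bandwidth_scale)
    density = dens["density"].to_numpy()
    positive = np.flatnonzero(density > 0)
    n_draw = min(n_points, positive.size)
    if n_draw < n_points:
        warnings.warn(f"requested {n_points} background points but only "
                      f"{positive.size} cells carry positive density; "
                      f"capped at {positive.size}")
    rng = np.random.default_rng(seed)
    p = density[positive] / density[positive].sum()
    chosen = positive[rng.choice(positive.size, size=n_draw, replace=False, p=p)]
    sp = occ["species"].iloc[0] if "species" in occ else "background"
    return pd.DataFrame({"species": sp, "x": dens["x"].to_numpy()[chosen],
                         "y": dens["y"].to_numpy()[chosen],
                         "density": density[chosen]})
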