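"""Synthetic landscapes and virtual species.

Every downstream stage of the pipeline — occurrence filtering, covariate
selection, model fitting, evaluation, importance, sensitivity analysis —
is exercised offline on landscapes generated here.  The generator emulates
the statistical structure the analysis assumes in real data:

* spatially autocorrelated, cross-correlated "climate" and "soil" layers
  (Gaussian random fields smoothed by convolution, then mixed through a
  Cholesky factor of the target cross-correlation matrix);
* a contiguous ecoregion mosaic with controllable area fractions, grown
  competitively from spread seed cells with noise-perturbed frontiers;
* virtual species with product-Gaussian niche responses, whose known
  suitability surface makes parameter recovery checkable;
* presence sampling that can be spatially biased, mimicking the uneven
  collection effort that background weighting is meant to correct.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .landscape import (CLIMATE, CLIMATE_NAMES, SOIL, SOIL_NAMES, EcoregionMap,
                        Landscape, VariableInfo)

DEFAULT_ECOREGION_LABELS = {0: "Desert", 1: "Mediterranean", 2: "Temperate", 3: "Tropical"}
#: Share of the study area held by each of the four focal ecoregions
#: (desert/mediterranean/temperate/tropical), mirroring the continental map.
DEFAULT_AREA_FRACTIONS = (0.49, 0.11, 0.12, 0.28)


@dataclass
class VirtualSpecies:
    """A species with a known Gaussian niche over a subset of variables.

    ``response_params`` maps a variable name to (optimum, breadth sigma);
    narrow breadths make a specialist, wide ones a generalist.
    """

    species_id: str
    response_params: dict[str, tuple[float, float]]
    niche_class: str = "generalist"  # "specialist" | "generalist"
    prevalence_target: float = 0.1
    active_variables: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.active_variables:
            self.active_variables = list(self.response_params)
        for var in self.active_variables:
            _, sigma = self.response_params[var]
            if sigma <= 0:
                raise ValueError(f"breadth for {var!r} must be positive, got {sigma}")


def _variable_names(n_climate: int, n_soil: int) -> list[VariableInfo]:
    def pick(n: int, pool: tuple[str, ...], category: str, prefix: str) -> list[VariableInfo]:
        names = list(pool[:n]) + [f"{prefix}{i}" for i in range(len(pool), n)]
        return [VariableInfo(nm, category) for nm in names]

    return pick(n_climate, CLIMATE_NAMES, CLIMATE, "clim") + pick(n_soil, SOIL_NAMES, SOIL, "soil")


def _smooth_standard_field(rng: np.random.Generator, shape: tuple[int, int],
                           autocorr_range: float) -> np.ndarray:
    """White noise smoothed to the requested range, restandardized to N(0,1)."""
    z = rng.standard_normal(shape)
    if autocorr_range > 0:
        z = ndimage.gaussian_filter(z, sigma=autocorr_range, mode="reflect")
    z = z - z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def generate_env_layers(n_climate: int = 9, n_soil: int = 8,
                        grid_spec: tuple[int, int] = (64, 64),
                        autocorr_range: float = 4.0,
                        cross_corr: np.ndarray | None = None,
                        nodata_fraction: float = 0.0,
                        seed: int = 0,
                        cell_size: float = 1.0) -> Landscape:
    """Generate cross-correlated Gaussian-random-field environmental layers.

    Each layer is white noise convolved with a Gaussian kernel of scale
    ``autocorr_range`` (in cells); the stack is then mixed through the
    Cholesky factor of ``cross_corr`` so empirical cross-correlations
    approach the target as the grid grows.  Deterministic for a fixed seed.
    """
    n_vars = n_climate + n_soil
    if cross_corr is None:
        cross_corr = np.eye(n_vars)
    cross_corr = np.asarray(cross_corr, dtype=float)
    if cross_corr.shape != (n_vars, n_vars):
        raise ValueError(f"cross_corr must be {n_vars}x{n_vars}, got {cross_corr.shape}")
    if not np.allclose(cross_corr, cross_corr.T):
        raise ValueError("cross_corr must be symmetric")
    eigvals = np.linalg.eigvalsh(cross_corr)
    if eigvals[0] < -1e-10:
        raise ValueError(
            f"cross_corr is not positive semi-definite: smallest eigenvalue {eigvals[0]:.3g}")

    rng = np.random.default_rng(seed)
    fields = np.stack([_smooth_standard_field(rng, grid_spec, autocorr_range)
                       for _ in range(n_vars)])
    # Cholesky with a tiny jitter so exactly-singular targets still factor.
    chol = np.linalg.cholesky(cross_corr + 1e-10 * np.eye(n_vars))
    mixed = np.tensordot(chol, fields, axes=(1, 0))

    mask = np.zeros(grid_spec, dtype=bool)
    if nodata_fraction > 0:
        n_cells = grid_spec[0] * grid_spec[1]
        n_mask = int(round(nodata_fraction * n_cells))
        flat = rng.choice(n_cells, size=n_mask, replace=False)
        mask.ravel()[flat] = True

    catalog = _variable_names(n_climate, n_soil)
    layers = {info.name: mixed[i] for i, info in enumerate(catalog)}
    return Landscape(layers=layers, nodata_mask=mask, catalog=catalog, cell_size=cell_size)


def generate_ecoregions(landscape: Landscape, n_regions: int = 4,
                        smoothing: float = 12.0,
                        area_fractions: tuple[float, ...] | None = None,
                        labels: dict[int, str] | None = None,
                        seed: int = 0) -> EcoregionMap:
    """Partition the landscape into contiguous ecoregions with target areas.

    Regions are grown competitively from well-separated seed cells (chosen by
    farthest-point sampling).  Each region repeatedly claims the unassigned
    frontier cell with the lowest priority — distance from its seed plus a
    smoothed latent noise field that makes boundaries organic — and a region
    stops growing once it reaches its area quota.  Growth from a single seed
    guarantees every region is one connected blob, and the quotas make the
    realized area fractions match ``area_fractions`` to within a few cells.
    """
    import heapq

    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    unmasked = ~landscape.nodata_mask
    n_cells = int(unmasked.sum())
    if n_regions > n_cells:
        raise ValueError(f"n_regions={n_regions} exceeds {n_cells} unmasked cells")
    if area_fractions is None:
        area_fractions = (DEFAULT_AREA_FRACTIONS if n_regions == 4
                          else tuple([1.0 / n_regions] * n_regions))
    if len(area_fractions) != n_regions:
        raise ValueError("area_fractions length must equal n_regions")
    fr = np.asarray(area_fractions, dtype=float)
    fr = fr / fr.sum()

    rng = np.random.default_rng(seed)
    noise = _smooth_standard_field(rng, landscape.shape, max(smoothing / 4.0, 1.0))
    rows, cols = np.nonzero(unmasked)
    cells = np.stack([rows, cols], axis=1)

    # farthest-point seeds, first one random
    seeds = [cells[rng.integers(len(cells))]]
    for _ in range(1, n_regions):
        d = np.min([np.hypot(cells[:, 0] - s[0], cells[:, 1] - s[1]) for s in seeds],
                   axis=0)
        seeds.append(cells[int(np.argmax(d))])

    quota = np.maximum(1, np.round(fr * n_cells).astype(int))
    while quota.sum() > n_cells:  # rounding overshoot
        quota[int(np.argmax(quota))] -= 1
    codes = np.full(landscape.shape, -1, dtype=int)
    heaps: list[list] = [[] for _ in range(n_regions)]
    counter = 0  # heap tie-break

    def priority(k: int, r: int, c: int) -> float:
        return float(np.hypot(r - seeds[k][0], c - seeds[k][1])
                     + 3.0 * noise[r, c])

    for k, (r, c) in enumerate(seeds):
        heapq.heappush(heaps[k], (priority(k, r, c), k, int(r), int(c)))
    grown = np.zeros(n_regions, dtype=int)
    n_assigned = 0
    while n_assigned < n_cells:
        # the region furthest below its quota grows next; regions at quota
        # only absorb leftovers once every under-quota frontier is blocked
        live = [k for k in range(n_regions) if heaps[k] and grown[k] < quota[k]]
        if not live:
            live = [k for k in range(n_regions) if heaps[k]]
        if not live:
            break  # unreachable cells (disconnected mask): handled below
        k = min(live, key=lambda j: grown[j] / quota[j])
        cell = None
        while heaps[k]:
            _, _, r, c = heapq.heappop(heaps[k])
            if codes[r, c] == -1:
                cell = (r, c)
                break
        if cell is None:
            continue
        r, c = cell
        codes[r, c] = k
        grown[k] += 1
        n_assigned += 1
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if (0 <= rr < codes.shape[0] and 0 <= cc < codes.shape[1]
                    and unmasked[rr, cc] and codes[rr, cc] == -1):
                heapq.heappush(heaps[k], (priority(k, rr, cc), counter, rr, cc))
                counter += 1
    if n_assigned < n_cells:  # mask islands: nearest seed wins
        for r, c in cells[codes[cells[:, 0], cells[:, 1]] == -1]:
            codes[r, c] = int(np.argmin([np.hypot(r - s[0], c - s[1]) for s in seeds]))
    if labels is None:
        labels = ({k: DEFAULT_ECOREGION_LABELS[k] for k in range(n_regions)}
                  if n_regions <= 4 else {k: f"region_{k}" for k in range(n_regions)})
    return EcoregionMap(codes=codes, labels=labels, nodata_mask=landscape.nodata_mask)


def imprint_ecoregions(landscape: Landscape, ecoregions: EcoregionMap,
                       variables: tuple[str, ...], strength: float = 1.5) -> Landscape:
    """Shift the named layers by distinct per-region offsets (in place).

    Real ecoregions are defined by distinct environmental conditions; this
    couples the otherwise independent random fields to the region mosaic so
    that a narrow niche centered on one region's mean environment confines a
    species to that region.  Offsets are an evenly spaced pattern of width
    ``strength`` (in layer SD units), rotated across variables so every
    region gets a distinct environmental combination.
    """
    codes = ecoregions.codes
    n_regions = len(ecoregions.labels)
    if n_regions < 2:
        return landscape
    # Regions sit at the corners of a +-1 hypercube over the driver variables
    # (bit j of the region code signs variable j), giving uniform pairwise
    # separation of the region mean environments.
    n_bits = max(1, int(np.ceil(np.log2(n_regions))))
    for j, var in enumerate(variables):
        grid = landscape.layers[var]
        for k in range(n_regions):
            sign = 1.0 if (k >> (j % n_bits)) & 1 else -1.0
            grid[codes == k] += strength * sign
    return landscape


def suitability_surface(species: VirtualSpecies, landscape: Landscape) -> np.ndarray:
    """Product-Gaussian suitability in [0, 1], rescaled to a grid maximum of 1.

    suitability(cell) ∝ ∏_v exp(−(x_v − optimum_v)² / (2 σ_v²)) over the
    species' active variables.  Masked cells carry NaN.  The rescaling is by
    the realized grid maximum, so every landscape contains at least one
    perfectly suitable cell (this couples suitability to the realization).
    """
    if not species.active_variables:
        raise ValueError(f"species {species.species_id!r} has no active variables: no niche defined")
    missing = [v for v in species.active_variables if v not in landscape.layers]
    if missing:
        raise KeyError(f"active variables absent from landscape: {missing}")
    log_suit = np.zeros(landscape.shape)
    for var in species.active_variables:
        opt, sigma = species.response_params[var]
        log_suit -= (landscape.layers[var] - opt) ** 2 / (2.0 * sigma ** 2)
    suit = np.exp(log_suit)
    suit[landscape.nodata_mask] = np.nan
    peak = np.nanmax(suit)
    if peak > 0:
        suit = suit / peak
    return suit


def sample_occurrences(suitability: np.ndarray, landscape: Landscape,
                       n_points: int, species_id: str = "sp",
                       bias_surface: np.ndarray | None = None,
                       seed: int = 0) -> pd.DataFrame:
    """Draw presence cells without replacement, probability ∝ suitability × bias.

    Points are placed at cell centers; the returned occurrence table has one
    row per distinct cell with columns (species, x, y).
    """
    weights = np.where(landscape.nodata_mask | ~np.isfinite(suitability), 0.0, suitability)
    if bias_surface is not None:
        if bias_surface.shape != suitability.shape:
            raise ValueError("bias_surface shape mismatch")
        weights = weights * np.clip(bias_surface, 0.0, None)
    flat = weights.ravel()
    positive = np.flatnonzero(flat > 0)
    if positive.size == 0:
        raise ValueError("all selection weights are zero: nothing to sample")
    if n_points > positive.size:
        raise ValueError(f"n_points={n_points} exceeds {positive.size} cells with positive weight")
    rng = np.random.default_rng(seed)
    p = flat[positive] / flat[positive].sum()
    chosen = rng.choice(positive, size=n_points, replace=False, p=p)
    row, col = np.unravel_index(chosen, suitability.shape)
    x, y = landscape.rowcol_to_xy(row, col)
    return pd.DataFrame({"species": species_id, "x": x, "y": y})


def corner_bias_surface(shape: tuple[int, int], corner: str = "sw",
                        strength: float = 8.0) -> np.ndarray:
    """Exponential sampling-effort gradient toward one corner of the grid.

    ``strength`` is the log-ratio of effort between the favored corner and
    the opposite one; the default concentrates most sampling in one quadrant.
    """
    rows, cols = np.indices(shape)
    r = rows / max(shape[0] - 1, 1)
    c = cols / max(shape[1] - 1, 1)
    toward = {"sw": (r + (1 - c)), "nw": ((1 - r) + (1 - c)),
              "se": (r + c), "ne": ((1 - r) + c)}[corner]
    return np.exp(strength * (toward / 2.0))


def make_virtual_flora(landscape: Landscape, ecoregions: EcoregionMap,
                       n_specialists: int = 2, n_generalists: int = 2,
                       driver_variables: tuple[str, ...] = ("bio1", "bio12"),
                       specialist_breadth: float = 0.4,
                       generalist_breadth: float = 1.2,
                       region_offset: int = 0,
                       seed: int = 0) -> list[VirtualSpecies]:
    """A small flora of specialists and generalists driven by the same
    variables.  Every species' niche is centered on the mean environment of a
    home ecoregion (rotating over regions); specialists get narrow breadths
    that confine them to that region, generalists broad breadths that let
    their records spill across region boundaries."""
    rng = np.random.default_rng(seed)
    flora: list[VirtualSpecies] = []
    region_codes = sorted(ecoregions.labels)

    def region_niche(code: int, breadth: float) -> dict[str, tuple[float, float]]:
        in_region = (ecoregions.codes == code) & ~landscape.nodata_mask
        return {var: (float(landscape.layers[var][in_region].mean()) + rng.normal(0.0, 0.1),
                      breadth)
                for var in driver_variables}

    for i in range(n_specialists):
        code = region_codes[(i + region_offset) % len(region_codes)]
        flora.append(VirtualSpecies(f"specialist_{ecoregions.labels[code]}_{i}",
                                    region_niche(code, specialist_breadth),
                                    niche_class="specialist"))
    for i in range(n_generalists):
        code = region_codes[(i + 1 + region_offset) % len(region_codes)]
        flora.append(VirtualSpecies(f"generalist_{ecoregions.labels[code]}_{i}",
                                    region_niche(code, generalist_breadth),
                                    niche_class="generalist"))
    return flora
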