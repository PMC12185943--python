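"""Shared fixtures: small synthetic landscapes and planted-signal designs.

Everything is generated at test time; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ecosdm import covsel, synthetic
from ecosdm.landscape import Landscape, VariableInfo
from ecosdm.pipeline import _block_cross_corr

VARIABLE_NAMES = ["bio1", "bio2", "bio4", "bio5", "bio6", "bio12", "bio13",
                  "bio14", "bio15", "BDW", "CEC", "CLY", "DES", "NTO", "PTO",
                  "TWI", "SOC"]
CATEGORIES = {v: ("climate" if v.startswith("bio") else "soil")
              for v in VARIABLE_NAMES}


@pytest.fixture(scope="session")
def landscape32() -> Landscape:
    """32x32 landscape with the full 9 climate + 8 soil catalog."""
    return synthetic.generate_env_layers(
        9, 8, (32, 32), autocorr_range=3.0,
        cross_corr=_block_cross_corr(9, 8, 0.3), seed=42)


@pytest.fixture(scope="session")
def ecoregions32(landscape32):
    return synthetic.generate_ecoregions(landscape32, 4, smoothing=8.0, seed=42)


@pytest.fixture()
def masked_landscape() -> Landscape:
    """8x8 two-variable landscape whose top-left 2x2 corner is nodata."""
    rng = np.random.default_rng(5)
    mask = np.zeros((8, 8), dtype=bool)
    mask[:2, :2] = True
    layers = {"bio1": rng.normal(size=(8, 8)), "SOC": rng.normal(size=(8, 8))}
    catalog = [VariableInfo("bio1", "climate"), VariableInfo("SOC", "soil")]
    return Landscape(layers=layers, nodata_mask=mask, catalog=catalog)


def make_design(n: int = 500, seed: int = 0, effect: float = 2.0,
                signal_vars: tuple[int, ...] = (0, 16), rho: float = 0.3,
                n_vars: int = 17) -> covsel.DesignMatrix:
    """Planted logistic signal on ``signal_vars`` among correlated decoys."""
    rng = np.random.default_rng(seed)
    names = VARIABLE_NAMES[:n_vars]
    signal_vars = tuple(i for i in signal_vars if i < n_vars)
    if n_vars == 17:
        C = _block_cross_corr(9, 8, rho)
        chol = np.linalg.cholesky(C + 1e-10 * np.eye(n_vars))
        X = rng.standard_normal((n, n_vars)) @ chol.T
    else:
        X = rng.standard_normal((n, n_vars))
    logit = np.zeros(n) + sum(effect * (1 if i % 2 == 0 else -1) * X[:, i]
                              for i in signal_vars)
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-logit))).astype(float)
    return covsel.DesignMatrix(
        "virtual", pd.DataFrame(X, columns=names), y, np.ones(n),
        {v: CATEGORIES[v] for v in names})


@pytest.fixture()
def planted_design() -> covsel.DesignMatrix:
    return make_design(seed=7)
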