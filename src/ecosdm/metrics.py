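"""Discrimination metrics: AUC and the true skill statistic (TSS).

AUC is computed in its rank-statistic form — the probability that a randomly
chosen presence outranks a randomly chosen background point, ties counted
half.  TSS is max over thresholds of sensitivity + specificity - 1, with the
candidate thresholds being the distinct observed scores plus the endpoints 0
and 1 (exact and scale-free); classification uses score >= threshold =>
predicted presence, and threshold ties break toward the smaller threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .covsel import DesignMatrix
from .models import ModelBundle, ReplicateSplit


def _check_two_class(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    if not pos.any() or pos.all():
        raise ValueError("both classes must be present")
    return pos, ~pos


def auc(labels, scores) -> float:
    """Rank-statistic AUC with midranks for ties (Mann-Whitney form)."""
    pos, neg = _check_two_class(labels)
    scores = np.asarray(scores, dtype=float)
    ranks = rankdata(scores)
    n1, n0 = pos.sum(), neg.sum()
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def tss(labels, scores, threshold_grid=None) -> tuple[float, float]:
    """Maximum of sensitivity + specificity - 1 over candidate thresholds.

    Returns (tss, best_threshold) with the smallest threshold achieving the
    maximum.  Candidates default to the distinct scores plus 0 and 1.
    """
    pos, neg = _check_two_class(labels)
    scores = np.asarray(scores, dtype=float)
    if threshold_grid is None:
        threshold_grid = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    else:
        threshold_grid = np.unique(np.asarray(threshold_grid, dtype=float))
    # score >= t => predicted presence
    sens = (scores[pos][:, None] >= threshold_grid[None, :]).mean(axis=0)
    spec = (scores[neg][:, None] < threshold_grid[None, :]).mean(axis=0)
    vals = sens + spec - 1.0
    best = int(np.flatnonzero(vals == vals.max())[0])
    return float(vals[best]), float(threshold_grid[best])


def evaluate_bundle(bundle: ModelBundle, splits: list[ReplicateSplit] | None,
                    design: DesignMatrix,
                    keys: dict | None = None) -> pd.DataFrame:
    """Held-out AUC/TSS per (family, replicate), plus an ensemble row per
    replicate (mean of the replicate's live family predictions).

    ``keys`` (species, ecoregion, threshold, arm, ...) are carried through
    onto every row for downstream aggregation.  Failed members contribute no
    rows; an empty bundle yields an empty table.
    """
    splits = splits if splits is not None else bundle.splits
    keys = keys or {}
    rows = []
    for split in splits:
        test_X = design.X.iloc[split.test_idx]
        test_y = design.y[split.test_idx]
        rep_preds = []
        for family in sorted({f for f, _ in bundle.members}):
            model = bundle.members.get((family, split.replicate_id))
            if model is None:
                continue
            scores = model.predict_matrix(test_X)
            rep_preds.append(scores)
            a = auc(test_y, scores)
            t, thr = tss(test_y, scores)
            rows.append({**keys, "species": bundle.species_id, "arm": bundle.arm,
                         "family": family, "replicate": split.replicate_id,
                         "auc": a, "tss": t, "tss_threshold": thr,
                         "n_test_presence": int((test_y == 1).sum()),
                         "n_test_background": int((test_y == 0).sum())})
        if rep_preds:
            scores = np.mean(rep_preds, axis=0)
            a = auc(test_y, scores)
            t, thr = tss(test_y, scores)
            rows.append({**keys, "species": bundle.species_id, "arm": bundle.arm,
                         "family": "ENSEMBLE", "replicate": split.replicate_id,
                         "auc": a, "tss": t, "tss_threshold": thr,
                         "n_test_presence": int((test_y == 1).sum()),
                         "n_test_background": int((test_y == 0).sum())})
    return pd.DataFrame(rows)


def summarize_metrics(metrics: pd.DataFrame,
                      by: tuple[str, ...] = ("species", "arm", "family")) -> pd.DataFrame:
    """Replicate-averaged AUC/TSS (the per-model performance summary)."""
    if metrics.empty:
        return pd.DataFrame(columns=[*by, "auc", "tss"])
    return (metrics.groupby(list(by), dropna=False)[["auc", "tss"]]
            .mean().reset_index())
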