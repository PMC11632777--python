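"""Accumulated-relevance feature pruning and the MAE-versus-dimensionality scan.

Features are ranked by their gradient-boosting relevance fractions; pruning
keeps the smallest top-ranked prefix whose cumulative relevance reaches a
threshold. The scan retrains a model (GP or MLP) at each threshold of a
descending grid, always including the full-dimensional baseline, and tabulates
MAE and r^2 against the retained dimensionality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ModelReport, RelevanceTable, SplitPlan, train_gp, train_mlp

__all__ = ["PruneResult", "default_threshold_grid", "prune_by_accumulated_relevance", "scan"]


@dataclass(frozen=True)
class PruneResult:
    """Outcome of one pruning: the kept labels (smallest rank prefix whose
    relevance sum reaches the threshold), the relevance actually accumulated,
    and the resulting dimension."""

    kept: tuple[str, ...]
    accumulated_relevance: float
    dimension: int


def prune_by_accumulated_relevance(rel: RelevanceTable, threshold: float) -> PruneResult:
    """Keep the top-ranked features whose cumulative relevance first reaches
    ``threshold`` (0 < threshold <= 1); relevance ties keep original column
    order. Monotone: a larger threshold keeps a superset."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    order = rel.rank
    cum = np.cumsum(rel.relevance[order])
    if threshold >= 1.0:  # keep everything, including zero-relevance features
        n_keep = len(order)
    else:
        # first index where the cumulative relevance reaches the threshold
        n_keep = int(np.searchsorted(cum, threshold - 1e-12)) + 1
        n_keep = min(n_keep, len(order))
    kept = tuple(rel.labels[i] for i in order[:n_keep])
    return PruneResult(kept, float(cum[n_keep - 1]), n_keep)


def default_threshold_grid(start: float = 1.0, stop: float = 0.10, step: float = 0.02) -> list[float]:
    """Descending threshold grid, default 100%..10% in 2% steps."""
    grid = np.arange(start, stop - 1e-9, -step)
    return [round(float(t), 10) for t in grid]


def scan(
    X: pd.DataFrame,
    y: np.ndarray,
    rel: RelevanceTable,
    thresholds: list[float],
    model: str,
    plan: SplitPlan,
    **model_kwargs,
) -> pd.DataFrame:
    """MAE-versus-dimensionality scan.

    ``thresholds`` must be sorted descending; a full-dimensional baseline row
    (threshold 1.0) is always included. Pruning is computed once from ``rel``
    (not re-estimated per threshold). Returns a table with one row per
    threshold: threshold, dimension, accumulated relevance, mae_mean, mae_sd,
    r2_mean, r2_sd.
    """
    if model not in {"gp", "mlp"}:
        raise ValueError(f"scan model must be 'gp' or 'mlp', got {model!r}")
    if list(thresholds) != sorted(thresholds, reverse=True):
        raise ValueError("thresholds must be sorted descending")
    if list(X.columns) != list(rel.labels):
        raise ValueError("feature matrix columns and relevance labels disagree")
    trainer = train_gp if model == "gp" else train_mlp

    rows = []
    todo = list(thresholds)
    if not todo or todo[0] != 1.0:
        todo = [1.0] + todo
    seen_dims: dict[int, dict] = {}
    for t in todo:
        pruned = prune_by_accumulated_relevance(rel, t)
        if pruned.dimension in seen_dims:  # same column set -> same model
            rows.append({**seen_dims[pruned.dimension], "threshold": t})
            continue
        report: ModelReport = trainer(X[list(pruned.kept)], y, plan, **model_kwargs)
        row = {
            "threshold": t,
            "dimension": pruned.dimension,
            "accumulated_relevance": pruned.accumulated_relevance,
            **report.to_dict(),
        }
        rows.append(row)
        seen_dims[pruned.dimension] = row
    return pd.DataFrame(rows)
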