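"""Panel detection by the all-markers-positive rule, multi-assignment
resolution by specificity, and between-group proportion comparison.

A cell is *panel-positive* when every high-direction gene of the panel has
expression above ``positive_min`` (raw counts by default, so "positive"
means detected transcript).  A panel is *detected* in a subset when its
positive-cell proportion strictly exceeds ``positivity_threshold``.

The threshold default (0.10) is a deliberately conservative round value: the
source procedure acknowledges a threshold exists but does not publish it, and
warns that lowering it reduces specificity.  Treat it as a config knob, not
an established constant.
"""

from __future__ import annotations

import itertools
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from anndata import AnnData

from .matrix import COUNTS_LAYER, SAMPLE_KEY, SUBSET_KEY, counts_matrix
from .panels import GenePanel, PanelRegistry

__all__ = [
    "count_positive_cells",
    "detect_panels",
    "resolve_multi_assignment",
    "compare_groups",
    "exact_ranksum_pvalue",
]


def _panel_gene_index(adata: AnnData, panel: GenePanel) -> np.ndarray:
    high = panel.high_genes
    if not high:
        raise ValueError(f"panel {panel.name!r} has no high-direction genes")
    var_index = pd.Index(adata.var_names)
    idx = var_index.get_indexer(list(high))
    if (idx < 0).any():
        missing = [g for g, i in zip(high, idx) if i < 0]
        raise ValueError(
            f"panel {panel.name!r} has genes absent from the matrix: {missing}; "
            "run restrict_to_matrix first"
        )
    return idx


def _expression(adata: AnnData, layer: str | None):
    if layer is None or layer == COUNTS_LAYER:
        return counts_matrix(adata)
    if layer == "X":
        return adata.X
    return adata.layers[layer]


def count_positive_cells(
    adata: AnnData,
    panel: GenePanel,
    positive_min: float = 0.0,
    *,
    layer: str | None = None,
) -> pd.Series:
    """Per-subset count of cells positive for *all* high-direction panel genes."""
    idx = _panel_gene_index(adata, panel)
    X = _expression(adata, layer)[:, idx]
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    positive = (X > positive_min).all(axis=1)
    labels = adata.obs[SUBSET_KEY].astype(str)
    counts = pd.Series(positive, index=labels.values).groupby(level=0).sum()
    return counts.reindex(sorted(labels.unique()), fill_value=0).astype(int)


def detect_panels(
    adata: AnnData,
    registry: PanelRegistry,
    positivity_threshold: float = 0.10,
    positive_min: float = 0.0,
    *,
    layer: str | None = None,
) -> pd.DataFrame:
    """Audit table over every (panel, subset) pair.

    ``detected`` is True where the positive-cell proportion strictly exceeds
    the threshold; ``panel_detected`` marks panels detected in >= 1 subset.
    """
    labels = adata.obs[SUBSET_KEY].astype(str)
    sizes = labels.value_counts().sort_index()
    rows = []
    for panel in registry:
        counts = count_positive_cells(adata, panel, positive_min, layer=layer)
        for subset, n_pos in counts.items():
            size = int(sizes[subset])
            frac = n_pos / size
            rows.append(
                {
                    "panel": panel.name,
                    "subset": subset,
                    "positive_cells": int(n_pos),
                    "subset_size": size,
                    "positivity": frac,
                    "detected": frac > positivity_threshold,
                }
            )
    out = pd.DataFrame(rows, columns=["panel", "subset", "positive_cells", "subset_size", "positivity", "detected"])
    detected_any = out.groupby("panel")["detected"].transform("any")
    out["panel_detected"] = detected_any
    return out


def resolve_multi_assignment(
    detections: pd.DataFrame,
    profiles: Mapping[str, "OERProfile"],  # noqa: F821 - see panelscope.oer
) -> dict[str, str]:
    """Exclusive subset -> panel map: the most specific candidate wins.

    Among panels detected on a subset, the winner has the smallest
    n_>30, ties broken by smaller n_>60, then lexicographic panel name.
    Deterministic and invariant to the input row order.
    """
    assignment: dict[str, str] = {}
    hits = detections[detections["detected"]]
    for subset, group in hits.groupby("subset"):
        candidates = sorted(group["panel"].unique())
        for name in candidates:
            if name not in profiles:
                raise KeyError(f"panel {name!r} has no OER profile; compute OER before resolving")
        best = min(candidates, key=lambda n: (profiles[n].n_gt30, profiles[n].n_gt60, n))
        assignment[str(subset)] = best
    return assignment


def exact_ranksum_pvalue(x, y) -> float:
    """Two-sided exact permutation rank-sum p-value (tie-aware).

    Enumerates every assignment of pooled mid-ranks to the two groups and
    counts assignments whose rank-sum deviates from its mean by at least the
    observed deviation.  Identical samples give p = 1.0 exactly.  Intended
    for total n <= 10 (C(10,5) = 252 assignments).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    nx, n = len(x), len(pooled)
    mu = nx * (n + 1) / 2.0
    obs_dev = abs(ranks[:nx].sum() - mu)
    hits = total = 0
    for combo in itertools.combinations(range(n), nx):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= obs_dev - 1e-9:
            hits += 1
    return hits / total


def compare_groups(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    *,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-panel two-sided rank-sum comparison of proportions between groups.

    ``table`` needs columns (sample, group, panel, proportion).  Exact
    permutation p-values for total n <= 10 samples, normal approximation with
    tie correction otherwise.  No multiplicity correction by default;
    ``bh_correct=True`` adds a Benjamini-Hochberg column.
    """
    for col in ("sample", "group", "panel", "proportion"):
        if col not in table.columns:
            raise ValueError(f"proportion table is missing column {col!r}")
    rows = []
    for panel, sub in table.groupby("panel", sort=True):
        a = sub.loc[sub["group"] == group_a].set_index("sample")["proportion"]
        b = sub.loc[sub["group"] == group_b].set_index("sample")["proportion"]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                f"panel {panel!r}: each group needs >=2 samples "
                f"({group_a}: {len(a)}, {group_b}: {len(b)})"
            )
        if len(a) + len(b) <= 10:
            p = exact_ranksum_pvalue(a.to_numpy(), b.to_numpy())
        else:
            p = float(
                scipy.stats.mannwhitneyu(
                    a.to_numpy(), b.to_numpy(), alternative="two-sided", method="asymptotic"
                ).pvalue
            )
        effect = float(np.median(b) - np.median(a))
        rows.append(
            {
                "panel": panel,
                "p_value": p,
                "effect": effect,
                "direction": "up" if effect > 0 else ("down" if effect < 0 else "none"),
                "n_a": len(a),
                "n_b": len(b),
            }
        )
    out = pd.DataFrame(rows)
    if bh_correct and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
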