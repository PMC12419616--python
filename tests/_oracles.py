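"""Independent oracles used by unit and acceptance tests.

These deliberately use brute force (explicit loops, exhaustive subset
enumeration) and never share code with the implementation paths they check.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd


def brute_force_window_mean(days, values, t, window_days, align="centered"):
    """Moving-average estimate at day ``t`` by explicit window membership."""
    if align == "centered":
        half = window_days // 2
        lo, hi = t - half, t + half
    else:  # trailing: only information >= t days before death
        lo, hi = t, t + window_days - 1
    members = [v for d, v in zip(days, values) if lo <= d <= hi]
    return float(np.mean(members)) if members else np.nan


def _tree_value(tree: dict, x: np.ndarray, in_coalition: set) -> float:
    """Path-dependent conditional expectation of one tree.

    Splits on coalition features follow ``x``; splits on other features
    weight both children by their training cover, the game definition
    underlying tree-path-dependent Shapley values.
    """

    def descend(node) -> float:
        if "leaf_value" in node:
            return node["leaf_value"]
        j = node["split_feature"]
        thr = node["threshold"]
        left, right = node["left_child"], node["right_child"]
        if j in in_coalition:
            goes_left = x[j] <= thr if node["decision_type"] == "<=" \
                else x[j] < thr
            return descend(left if goes_left else right)
        cl = _cover(left)
        cr = _cover(right)
        return (cl * descend(left) + cr * descend(right)) / (cl + cr)

    def _cover(node) -> float:
        return node.get("internal_count", node.get("leaf_count", 1))

    return descend(tree)


def brute_force_tree_shap(booster, x: np.ndarray) -> np.ndarray:
    """Exhaustive Shapley values over all feature coalitions of a booster.

    Returns per-feature attributions plus the base value as the last entry,
    matching the layout of LightGBM's ``pred_contrib`` output.
    """
    dump = booster.dump_model()
    trees = [t["tree_structure"] for t in dump["tree_info"]]
    p = dump["max_feature_idx"] + 1

    def value(coalition: set) -> float:
        return sum(_tree_value(t, x, coalition) for t in trees)

    phi = np.zeros(p + 1)
    features = list(range(p))
    for j in features:
        others = [f for f in features if f != j]
        for size in range(len(others) + 1):
            weight = (factorial(size) * factorial(p - size - 1)
                      / factorial(p))
            for subset in combinations(others, size):
                s = set(subset)
                phi[j] += weight * (value(s | {j}) - value(s))
    phi[p] = value(set())
    return phi


def exhaustive_auc(pos_scores, neg_scores) -> float:
    """AUROC by counting all positive/negative score pairs."""
    wins = 0.0
    for sp in pos_scores:
        for sn in neg_scores:
            wins += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return wins / (len(pos_scores) * len(neg_scores))
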