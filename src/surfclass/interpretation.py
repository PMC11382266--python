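"""Decision-path contribution decomposition and class-boundary thresholds.

Every forest prediction is decomposed as

    P(cytosol | x) = bias + sum_f contribution_f(x)

by walking each sample root-to-leaf in every tree and crediting the change
in the node's cytosol-class probability at each split to the feature the
split tests, then averaging over trees (the bias is the mean root
probability, i.e. the class prior at the forest roots). Positive
contributions therefore push toward the cytosol class; plotted against the
feature's value they show where the forest flips sides, and the boundary
is extracted as the sign-separating one-dimensional stump with the best
separation score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "ContributionProfile",
    "ThresholdEntry",
    "decompose",
    "contribution_matrix",
    "extract_threshold",
    "threshold_report",
    "NoBoundaryWarning",
]

CYTOSOL = "cytosol"


class NoBoundaryWarning(UserWarning):
    """All contributions share one sign: the feature draws no boundary."""


@dataclass
class ContributionProfile:
    """Per-sample (feature value, signed contribution toward cytosol) pairs
    for one feature, plus the shared forest bias."""

    feature: str
    values: np.ndarray
    contributions: np.ndarray
    bias: float


@dataclass
class ThresholdEntry:
    """One feature's class boundary.

    secreted_side is '<' or '>': the side of the boundary on which the
    forest votes secreted. separation is the fraction of (nonzero-
    contribution) samples whose contribution sign matches their side."""

    feature: str
    boundary: float | None
    secreted_side: str | None
    separation: float | None


def _positive_class_index(forest, class_label: str | None) -> int:
    classes = list(forest.classes_)
    if class_label is None:
        class_label = CYTOSOL if CYTOSOL in classes else classes[0]
    if class_label not in classes:
        raise ValueError(f"class {class_label!r} not in forest classes {classes}")
    return classes.index(class_label)


def contribution_matrix(
    forest, X: pd.DataFrame, class_label: str | None = None
) -> tuple[float, np.ndarray, np.ndarray]:
    """(bias, contributions[n_samples, n_features], predicted probability).

    ``bias + contributions.sum(axis=1)`` equals the forest's predicted
    probability of the target class for every sample (conservation holds
    to float round-off).
    """
    trained = list(getattr(forest, "feature_names_in_", X.columns))
    if set(X.columns) != set(trained):
        raise ValueError(
            f"sample features {sorted(X.columns)} != training features {sorted(trained)}"
        )
    X = X[trained]
    ci = _positive_class_index(forest, class_label)
    n, p = X.shape
    Xv = X.to_numpy()

    total = np.zeros((n, p))
    bias = 0.0
    estimators = getattr(forest, "estimators_", [forest])
    for est in estimators:
        tree = est.tree_
        value = tree.value[:, 0, :]
        prob = value / value.sum(axis=1, keepdims=True)  # robust to count/fraction storage
        left, right = tree.children_left, tree.children_right
        feat = tree.feature
        parent = np.full(tree.node_count, -1)
        for node in range(tree.node_count):
            if left[node] != -1:
                parent[left[node]] = node
                parent[right[node]] = node
        # credit each non-root node's probability change to its parent's feature
        rows, cols, deltas = [], [], []
        for node in range(tree.node_count):
            par = parent[node]
            if par == -1:
                continue
            rows.append(node)
            cols.append(feat[par])
            deltas.append(prob[node, ci] - prob[par, ci])
        D = sparse.csr_matrix(
            (deltas, (rows, cols)), shape=(tree.node_count, p)
        )
        path = est.decision_path(Xv)  # (n_samples, n_nodes) indicator
        total += (path @ D).toarray()
        bias += prob[0, ci]

    k = len(estimators)
    return bias / k, total / k, np.asarray(bias / k + (total / k).sum(axis=1))


def decompose(
    forest, samples: pd.DataFrame, class_label: str | None = None
) -> dict[str, ContributionProfile]:
    """Per-feature :class:`ContributionProfile` for every sample."""
    trained = list(getattr(forest, "feature_names_in_", samples.columns))
    bias, contrib, _ = contribution_matrix(forest, samples, class_label)
    Xo = samples[trained]
    return {
        name: ContributionProfile(
            feature=name,
            values=Xo[name].to_numpy(dtype=float),
            contributions=contrib[:, j],
            bias=bias,
        )
        for j, name in enumerate(trained)
    }


def extract_threshold(
    profile: ContributionProfile,
    min_samples: int = 10,
    zero_tol: float = 1e-12,
) -> ThresholdEntry:
    """Boundary value where the contribution sign flips.

    Fits a one-dimensional stump on the sign of the contribution: the
    boundary maximizing the fraction of samples whose sign matches their
    side, reported as the midpoint between the straddling sample values,
    rounded to 1 decimal. Contributions are toward cytosol, so the secreted
    side is the side with negative mean contribution.
    """
    keep = np.abs(profile.contributions) > zero_tol
    v = profile.values[keep]
    c = profile.contributions[keep]
    if len(v) < min_samples:
        warnings.warn(
            f"{profile.feature}: only {len(v)} samples with nonzero contributions",
            NoBoundaryWarning,
        )
        return ThresholdEntry(profile.feature, None, None, None)
    signs = np.sign(c)
    if np.all(signs > 0) or np.all(signs < 0):
        warnings.warn(
            f"{profile.feature}: contributions all one sign, no boundary",
            NoBoundaryWarning,
        )
        return ThresholdEntry(profile.feature, None, None, None)

    order = np.argsort(v, kind="stable")
    v_s, s_s = v[order], signs[order]
    n = len(v_s)
    pos_prefix = np.cumsum(s_s > 0)            # positives among first k samples
    total_pos = pos_prefix[-1]
    best_score, best_boundary, best_side = -1.0, None, None
    for k in range(1, n):                       # split after sample k-1
        if v_s[k] == v_s[k - 1]:
            continue
        left_pos = pos_prefix[k - 1]
        left_neg = k - left_pos
        right_pos = total_pos - left_pos
        right_neg = (n - k) - right_pos
        # orientation A: cytosol(+) on the left; B: cytosol(+) on the right
        score_a = (left_pos + right_neg) / n
        score_b = (left_neg + right_pos) / n
        score, side = max((score_a, ">"), (score_b, "<"))
        # side is where secreted (negative contribution) lives
        if score > best_score:
            best_score = score
            best_boundary = round(0.5 * (v_s[k - 1] + v_s[k]), 1)
            best_side = side
    if best_boundary is None:  # all values identical
        warnings.warn(
            f"{profile.feature}: constant feature values, no boundary",
            NoBoundaryWarning,
        )
        return ThresholdEntry(profile.feature, None, None, None)
    return ThresholdEntry(profile.feature, float(best_boundary), best_side,
                          float(best_score))


def threshold_report(
    result,
    table: pd.DataFrame,
    top_n: int = 3,
    label_col: str = "class",
    min_samples: int = 10,
) -> pd.DataFrame:
    """Boundary table for the top-n features by averaged Gini importance.

    ``result`` is a :class:`~surfclass.rf_protocol.ProtocolResult`; its best
    forest is decomposed over every row of ``table``, and each top feature's
    contribution-vs-value profile is reduced to a boundary, the secreted
    side and a separation score (the Table-2-style report).
    """
    forest = result.best.forest
    X = table.drop(columns=[label_col]) if label_col in table.columns else table
    profiles = decompose(forest, X)
    top = list(result.mean_importances.sort_values(ascending=False).index[:top_n])
    rows = []
    for feature in top:
        entry = extract_threshold(profiles[feature], min_samples=min_samples)
        rows.append(
            {
                "feature": feature,
                "mean_importance": float(result.mean_importances[feature]),
                "boundary_pct": entry.boundary,
                "secreted_side": entry.secreted_side,
                "separation": entry.separation,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
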