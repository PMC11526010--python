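"""Exact interventional Tree SHAP for random-forest meta-models.

Attributions use the interventional (background-marginal) value function:
for a coalition S, the payoff is the model output with features in S taken
from the explained gene and the rest from a background gene, averaged over
a background set.  For a single background sample z and a decision tree,
the payoff restricted to one leaf is a conjunction of literals — the leaf
is reached iff every path feature on which x and z diverge lies on the
required side — and the Shapley value of a conjunction has a closed form:

    leaf reached iff  S ⊇ X  and  S ∩ Z = ∅,  |X| = a, |Z| = b
    φ_i = +v·(a-1)!·b!/(a+b)!   for i ∈ X
    φ_i = -v·a!·(b-1)!/(a+b)!   for i ∈ Z

Summing over leaves, averaging over background samples and trees gives the
exact interventional Tree SHAP values; additivity
(Σ_i φ_i + E_z f(z) = f(x)) holds to float precision.  The per-pair tree
walk is JIT-compiled with numba.
"""

from __future__ import annotations

import logging
from math import factorial

import numpy as np
import pandas as pd
from numba import njit

from ._util import spawn_rng
from .errors import SchemaError

logger = logging.getLogger(__name__)

__all__ = ["compute_shap", "summarize_shap", "aggregate_feature_ranks"]

_MAX_PATH = 128
_FACT = np.array([float(factorial(k)) for k in range(_MAX_PATH)])


@njit(cache=True)
def _shap_pair_tree(children_left, children_right, feature, threshold, value,
                    x, z, phi, fact):  # pragma: no cover - compiled
    """Add one tree's baseline-Shapley contributions for foreground x vs background z."""
    n_features = x.shape[0]
    state = np.zeros(n_features, dtype=np.int8)  # 0 free, 1 x-side, 2 z-side
    path_f = np.empty(_MAX_PATH, dtype=np.int64)
    path_side = np.empty(_MAX_PATH, dtype=np.int8)
    depth = 0
    a = 0
    b = 0

    # frame actions: 0 visit node, 1 setup (push x-side), 2 transition to
    # z-side, 3 cleanup (pop)
    stack_node = np.empty(4096, dtype=np.int64)
    stack_act = np.empty(4096, dtype=np.int8)
    stack_feat = np.empty(4096, dtype=np.int64)
    top = 0
    stack_node[top], stack_act[top], stack_feat[top] = 0, 0, -1
    top += 1
    while top > 0:
        top -= 1
        node = stack_node[top]
        act = stack_act[top]
        f = stack_feat[top]
        if act == 1:
            state[f] = 1
            path_f[depth] = f
            path_side[depth] = 1
            depth += 1
            a += 1
            continue
        if act == 2:
            state[f] = 2
            path_side[depth - 1] = 2
            a -= 1
            b += 1
            continue
        if act == 3:
            state[f] = 0
            depth -= 1
            b -= 1
            continue
        left = children_left[node]
        if left < 0:  # leaf
            if a + b > 0:
                v = value[node]
                if a > 0:
                    w_x = fact[a - 1] * fact[b] / fact[a + b]
                else:
                    w_x = 0.0
                if b > 0:
                    w_z = fact[a] * fact[b - 1] / fact[a + b]
                else:
                    w_z = 0.0
                for d in range(depth):
                    if path_side[d] == 1:
                        phi[path_f[d]] += w_x * v
                    else:
                        phi[path_f[d]] -= w_z * v
            continue
        right = children_right[node]
        nf = feature[node]
        thr = threshold[node]
        x_child = left if x[nf] <= thr else right
        z_child = left if z[nf] <= thr else right
        if x_child == z_child:
            stack_node[top], stack_act[top], stack_feat[top] = x_child, 0, -1
            top += 1
        elif state[nf] == 1:
            stack_node[top], stack_act[top], stack_feat[top] = x_child, 0, -1
            top += 1
        elif state[nf] == 2:
            stack_node[top], stack_act[top], stack_feat[top] = z_child, 0, -1
            top += 1
        else:
            # LIFO: cleanup, z-subtree, transition, x-subtree, setup
            stack_node[top], stack_act[top], stack_feat[top] = node, 3, nf
            top += 1
            stack_node[top], stack_act[top], stack_feat[top] = z_child, 0, -1
            top += 1
            stack_node[top], stack_act[top], stack_feat[top] = node, 2, nf
            top += 1
            stack_node[top], stack_act[top], stack_feat[top] = x_child, 0, -1
            top += 1
            stack_node[top], stack_act[top], stack_feat[top] = node, 1, nf
            top += 1


@njit(cache=True)
def _shap_all(trees_cl, trees_cr, trees_feat, trees_thr, trees_val, tree_offsets,
              X, Z, fact):  # pragma: no cover - compiled
    n_fg = X.shape[0]
    n_bg = Z.shape[0]
    n_features = X.shape[1]
    n_trees = tree_offsets.shape[0] - 1
    phi = np.zeros((n_fg, n_features))
    scale = 1.0 / (n_bg * n_trees)
    for t in range(n_trees):
        s, e = tree_offsets[t], tree_offsets[t + 1]
        cl = trees_cl[s:e]
        cr = trees_cr[s:e]
        ft = trees_feat[s:e]
        th = trees_thr[s:e]
        vl = trees_val[s:e]
        for i in range(n_fg):
            row = np.zeros(n_features)
            for j in range(n_bg):
                _shap_pair_tree(cl, cr, ft, th, vl, X[i], Z[j], row, fact)
            for k in range(n_features):
                phi[i, k] += row[k] * scale
    return phi


def _pack_forest(estimator):
    """Flatten a fitted sklearn forest (or single tree) into contiguous arrays."""
    trees = getattr(estimator, "estimators_", [estimator])
    cls_, crs, fts, ths, vls, offsets = [], [], [], [], [], [0]
    for est in trees:
        t = est.tree_
        cls_.append(t.children_left.astype(np.int64))
        crs.append(t.children_right.astype(np.int64))
        fts.append(t.feature.astype(np.int64))
        ths.append(t.threshold.astype(np.float64))
        vls.append(t.value.reshape(-1).astype(np.float64))
        offsets.append(offsets[-1] + t.node_count)
    return (
        np.concatenate(cls_), np.concatenate(crs), np.concatenate(fts),
        np.concatenate(ths), np.concatenate(vls),
        np.asarray(offsets, dtype=np.int64),
    )


def _forest_predict_mean(estimator, background: pd.DataFrame) -> float:
    if getattr(estimator, "feature_names_in_", None) is None:
        return float(np.mean(estimator.predict(background.to_numpy(np.float64))))
    return float(np.mean(estimator.predict(background)))


def compute_shap(
    estimator,
    features: pd.DataFrame,
    background: pd.DataFrame | None = None,
    max_background: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Interventional Tree SHAP attributions for every row of ``features``.

    Parameters
    ----------
    estimator
        A fitted ``RandomForestRegressor`` (or single ``DecisionTreeRegressor``)
        trained on the same feature columns.
    background
        Reference table for the interventional value function; defaults to
        ``features`` itself, subsampled to ``max_background`` rows (seeded)
        when larger.

    Returns a gene × feature frame of attributions; the expected model
    output over the background is stored in ``result.attrs["base_value"]``
    so that ``row.sum() + base_value`` equals the model prediction.
    """
    n_model_features = getattr(estimator, "n_features_in_", features.shape[1])
    if features.shape[1] != n_model_features:
        raise SchemaError(
            f"model expects {n_model_features} features, table has {features.shape[1]}"
        )
    if features.shape[1] >= _MAX_PATH:
        raise SchemaError(f"at most {_MAX_PATH - 1} features supported")
    if background is None:
        background = features
    if list(background.columns) != list(features.columns):
        raise SchemaError("background columns must match the feature table")
    if len(background) > max_background:
        rng = spawn_rng(seed, 42)
        idx = rng.choice(len(background), size=max_background, replace=False)
        background = background.iloc[np.sort(idx)]
    X = np.ascontiguousarray(features.to_numpy(np.float64))
    Z = np.ascontiguousarray(background.to_numpy(np.float64))
    packed = _pack_forest(estimator)
    phi = _shap_all(*packed, X, Z, _FACT)
    out = pd.DataFrame(phi, index=features.index, columns=features.columns)
    out.attrs["base_value"] = _forest_predict_mean(estimator, background)
    return out


def summarize_shap(attributions: pd.DataFrame, feature_values: pd.DataFrame,
                   vep_name: str = "VEP") -> pd.DataFrame:
    """Per-feature summary of one model's attributions.

    ``mean_abs_shap`` measures importance; ``rank`` orders features by it
    (1 = most important); ``direction`` is the sign of the correlation
    between feature value and signed attribution — positive means higher
    feature values push the predicted AUROC up.
    """
    mean_abs = attributions.abs().mean(axis=0)
    mean_signed = attributions.mean(axis=0)
    direction = {}
    for col in attributions.columns:
        v = feature_values[col].to_numpy(float)
        a = attributions[col].to_numpy(float)
        if np.std(v) == 0 or np.std(a) == 0:
            direction[col] = 0.0
        else:
            direction[col] = float(np.sign(np.corrcoef(v, a)[0, 1]))
    out = pd.DataFrame(
        {
            "vep": vep_name,
            "mean_abs_shap": mean_abs,
            "mean_signed_shap": mean_signed,
            "direction": pd.Series(direction),
        }
    )
    out["rank"] = out["mean_abs_shap"].rank(ascending=False, method="first").astype(int)
    out.index.name = "feature"
    return out


def aggregate_feature_ranks(summaries: list[pd.DataFrame]) -> pd.DataFrame:
    """Cross-VEP synthesis: average importance rank and direction consensus.

    Features are aligned on the intersection when the per-VEP summaries
    disagree (with a warning); output is sorted by average rank (best
    first).  ``direction_consensus`` is the sign of the mean per-VEP
    direction.
    """
    if not summaries:
        raise SchemaError("no summaries supplied")
    common = set(summaries[0].index)
    for s in summaries[1:]:
        common &= set(s.index)
    if any(len(common) != len(s.index) for s in summaries):
        logger.warning("aggregate_feature_ranks: aligning on %d common features", len(common))
    common = sorted(common)
    ranks = pd.DataFrame({s["vep"].iloc[0]: s.loc[common, "rank"] for s in summaries})
    dirs = pd.DataFrame({s["vep"].iloc[0]: s.loc[common, "direction"] for s in summaries})
    out = pd.DataFrame(
        {
            "average_rank": ranks.mean(axis=1),
            "direction_consensus": np.sign(dirs.mean(axis=1)),
            "n_veps": ranks.shape[1],
        }
    )
    out.index.name = "feature"
    return out.sort_values("average_rank")
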