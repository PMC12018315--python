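"""Exact Shapley attributions for scikit-learn tree ensembles.

Implements the polynomial-time path-dependent tree-Shapley algorithm: for
a decision tree, the value of a feature coalition S is the expectation of
the tree output where splits on features outside S are averaged over both
children weighted by training cover, and splits on features in S follow
the sample.  The algorithm tracks, along each root-to-leaf path, the
proportion of all feature subsets of each size that flow to the leaf,
maintained in an incrementally extended/unwound path representation, and
yields the exact Shapley values of that coalition game in
O(leaves * depth^2) per sample per tree.

Attributions satisfy local accuracy by construction: for every sample,
``phi.sum() + expected_value == model.predict(x)`` (up to float error).

The per-sample kernel is compiled with numba; the public entry point
:func:`shap_values` accepts a fitted ``RandomForestRegressor``,
``DecisionTreeRegressor`` or any ensemble exposing ``estimators_`` whose
members carry a ``tree_``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _extend(fi, zf, of, w, unique_depth, pz, po, pi):
    fi[unique_depth] = pi
    zf[unique_depth] = pz
    of[unique_depth] = po
    w[unique_depth] = 1.0 if unique_depth == 0 else 0.0
    for i in range(unique_depth - 1, -1, -1):
        w[i + 1] += po * w[i] * (i + 1.0) / (unique_depth + 1.0)
        w[i] = pz * w[i] * (unique_depth - i) / (unique_depth + 1.0)


@njit(cache=True)
def _unwind(fi, zf, of, w, unique_depth, path_index):
    po = of[path_index]
    pz = zf[path_index]
    next_one = w[unique_depth]
    for i in range(unique_depth - 1, -1, -1):
        if po != 0.0:
            tmp = w[i]
            w[i] = next_one * (unique_depth + 1.0) / ((i + 1.0) * po)
            next_one = tmp - w[i] * pz * (unique_depth - i) / (unique_depth + 1.0)
        else:
            w[i] = w[i] * (unique_depth + 1.0) / (pz * (unique_depth - i))
    for i in range(path_index, unique_depth):
        fi[i] = fi[i + 1]
        zf[i] = zf[i + 1]
        of[i] = of[i + 1]


@njit(cache=True)
def _unwound_sum(zf, of, w, unique_depth, path_index):
    po = of[path_index]
    pz = zf[path_index]
    next_one = w[unique_depth]
    total = 0.0
    for i in range(unique_depth - 1, -1, -1):
        if po != 0.0:
            tmp = next_one * (unique_depth + 1.0) / ((i + 1.0) * po)
            total += tmp
            next_one = w[i] - tmp * pz * (unique_depth - i) / (unique_depth + 1.0)
        else:
            total += w[i] / pz * (unique_depth + 1.0) / (unique_depth - i)
    return total


@njit(cache=True)
def _tree_shap_sample(left, right, feature, threshold, value, cover, x, phi, max_depth):
    """Accumulate one tree's Shapley values for one sample into phi."""
    maxlen = max_depth + 2
    # per-level path buffers; a frame at tree depth L owns row L
    fi = np.empty((maxlen, maxlen), dtype=np.int64)
    zf = np.empty((maxlen, maxlen), dtype=np.float64)
    of = np.empty((maxlen, maxlen), dtype=np.float64)
    w = np.empty((maxlen, maxlen), dtype=np.float64)

    # explicit DFS stack: node, parent level, unique_depth arg, pz, po, pi
    cap = 4 * maxlen + 4
    st_node = np.empty(cap, dtype=np.int64)
    st_plev = np.empty(cap, dtype=np.int64)
    st_ud = np.empty(cap, dtype=np.int64)
    st_pz = np.empty(cap, dtype=np.float64)
    st_po = np.empty(cap, dtype=np.float64)
    st_pi = np.empty(cap, dtype=np.int64)

    top = 0
    st_node[top] = 0
    st_plev[top] = -1
    st_ud[top] = 0
    st_pz[top] = 1.0
    st_po[top] = 1.0
    st_pi[top] = -1
    top += 1

    while top > 0:
        top -= 1
        node = st_node[top]
        plev = st_plev[top]
        ud = st_ud[top]
        pz = st_pz[top]
        po = st_po[top]
        pi = st_pi[top]
        lev = plev + 1

        if plev >= 0:
            for i in range(ud):
                fi[lev, i] = fi[plev, i]
                zf[lev, i] = zf[plev, i]
                of[lev, i] = of[plev, i]
                w[lev, i] = w[plev, i]
        _extend(fi[lev], zf[lev], of[lev], w[lev], ud, pz, po, pi)

        if right[node] < 0:  # leaf
            for i in range(1, ud + 1):
                s = _unwound_sum(zf[lev], of[lev], w[lev], ud, i)
                phi[fi[lev, i]] += s * (of[lev, i] - zf[lev, i]) * value[node]
        else:
            split = feature[node]
            if x[split] <= threshold[node]:
                hot = left[node]
                cold = right[node]
            else:
                hot = right[node]
                cold = left[node]
            hot_zf = cover[hot] / cover[node]
            cold_zf = cover[cold] / cover[node]
            iz = 1.0
            io = 1.0
            path_index = 0
            found = False
            for i in range(ud + 1):
                if fi[lev, i] == split:
                    path_index = i
                    found = True
                    break
            if found:
                iz = zf[lev, path_index]
                io = of[lev, path_index]
                _unwind(fi[lev], zf[lev], of[lev], w[lev], ud, path_index)
                ud -= 1
            # push cold then hot (order immaterial)
            st_node[top] = cold
            st_plev[top] = lev
            st_ud[top] = ud + 1
            st_pz[top] = cold_zf * iz
            st_po[top] = 0.0
            st_pi[top] = split
            top += 1
            st_node[top] = hot
            st_plev[top] = lev
            st_ud[top] = ud + 1
            st_pz[top] = hot_zf * iz
            st_po[top] = io
            st_pi[top] = split
            top += 1


@njit(cache=True)
def _forest_shap(lefts, rights, feats, thrs, vals, covers, n_nodes, max_depths, X, phi):
    n_trees = lefts.shape[0]
    n_samples = X.shape[0]
    for s in range(n_samples):
        for t in range(n_trees):
            _tree_shap_sample(
                lefts[t, : n_nodes[t]], rights[t, : n_nodes[t]], feats[t, : n_nodes[t]],
                thrs[t, : n_nodes[t]], vals[t, : n_nodes[t]], covers[t, : n_nodes[t]],
                X[s], phi[s], max_depths[t],
            )
    for s in range(n_samples):
        for j in range(phi.shape[1]):
            phi[s, j] /= n_trees


def _tree_arrays(tree):
    t = tree.tree_
    return (
        t.children_left.astype(np.int64),
        t.children_right.astype(np.int64),
        t.feature.astype(np.int64),
        t.threshold.astype(np.float64),
        t.value[:, 0, 0].astype(np.float64),
        t.weighted_n_node_samples.astype(np.float64),
        int(t.max_depth),
    )


def shap_values(model, X) -> tuple[np.ndarray, float]:
    """Per-sample Shapley attributions for a fitted tree regressor.

    Parameters
    ----------
    model
        A fitted ``DecisionTreeRegressor`` or forest of them (anything
        exposing ``estimators_``) whose prediction is the mean of its
        trees, e.g. ``RandomForestRegressor``.
    X : array-like of shape (n_samples, n_features)
        Points to explain, in the model's feature order.

    Returns
    -------
    phi : ndarray of shape (n_samples, n_features)
        Shapley attributions; ``phi[s].sum() + expected_value`` equals
        the model prediction for sample ``s``.
    expected_value : float
        Cover-weighted mean tree output (the attribution baseline).
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    trees = list(getattr(model, "estimators_", [model]))
    arrays = [_tree_arrays(t) for t in trees]
    n_trees = len(arrays)
    max_nodes = max(a[0].size for a in arrays)
    lefts = np.full((n_trees, max_nodes), -1, dtype=np.int64)
    rights = np.full((n_trees, max_nodes), -1, dtype=np.int64)
    feats = np.full((n_trees, max_nodes), -2, dtype=np.int64)
    thrs = np.zeros((n_trees, max_nodes), dtype=np.float64)
    vals = np.zeros((n_trees, max_nodes), dtype=np.float64)
    covers = np.ones((n_trees, max_nodes), dtype=np.float64)
    n_nodes = np.zeros(n_trees, dtype=np.int64)
    max_depths = np.zeros(n_trees, dtype=np.int64)
    for t, (l, r, f, th, v, c, d) in enumerate(arrays):
        k = l.size
        n_nodes[t] = k
        max_depths[t] = d
        lefts[t, :k] = l
        rights[t, :k] = r
        feats[t, :k] = f
        thrs[t, :k] = th
        vals[t, :k] = v
        covers[t, :k] = c

    phi = np.zeros((X.shape[0], X.shape[1]), dtype=np.float64)
    _forest_shap(lefts, rights, feats, thrs, vals, covers, n_nodes, max_depths, X, phi)
    if not np.isfinite(phi).all():
        raise FloatingPointError("non-finite Shapley attributions")
    expected = float(np.mean([a[4][0] for a in arrays]))
    return phi, expected
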