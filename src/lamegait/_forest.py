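"""Numba-compiled CART growth kernel for Gini-importance ranking.

One tree is grown on a bootstrap resample with Gini-impurity splits over
``mtry`` randomly chosen features, unlimited depth, and no pruning.  The
kernel accumulates, per feature, the node-size-weighted Gini decrease

    [n * G(node) - n_left * G(left) - n_right * G(right)] / n_root

summed over all splits on that feature, which averaged over trees is the
mean decrease in Gini.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _gini_from_counts(counts, m):
    if m <= 0:
        return 0.0
    acc = 0.0
    for c in counts:
        p = c / m
        acc += p * p
    return 1.0 - acc


@njit(cache=True)
def grow_tree(X, y, n_classes, boot_idx, mtry, min_node, seed, importance):
    """Grow one tree; add its per-feature Gini decreases into ``importance``.

    Returns the total decrease accumulated by this tree (conservation
    check: equals the sum of its importance contributions).
    """
    np.random.seed(seed)
    n = boot_idx.shape[0]
    d = X.shape[1]
    idx = boot_idx.copy()

    # explicit node stack: (start, end) index ranges into idx
    max_nodes = 2 * n + 2
    stack_lo = np.empty(max_nodes, dtype=np.int64)
    stack_hi = np.empty(max_nodes, dtype=np.int64)
    top = 0
    stack_lo[top] = 0
    stack_hi[top] = n
    top += 1

    feat_pool = np.empty(d, dtype=np.int64)
    counts = np.empty(n_classes, dtype=np.int64)
    left_counts = np.empty(n_classes, dtype=np.int64)
    best_left = np.empty(n_classes, dtype=np.int64)
    tmp = np.empty(n, dtype=np.int64)
    total_decrease = 0.0

    while top > 0:
        top -= 1
        lo = stack_lo[top]
        hi = stack_hi[top]
        m = hi - lo
        counts[:] = 0
        for i in range(lo, hi):
            counts[y[idx[i]]] += 1
        g_node = _gini_from_counts(counts, m)
        if m < 2 * min_node or g_node <= 0.0:
            continue

        # sample mtry distinct candidate features (partial Fisher-Yates)
        for f in range(d):
            feat_pool[f] = f
        k = mtry if mtry < d else d
        for j in range(k):
            r = j + np.random.randint(0, d - j)
            feat_pool[j], feat_pool[r] = feat_pool[r], feat_pool[j]

        best_dec = 0.0
        best_feat = -1
        best_thresh = 0.0
        best_ml = 0

        for j in range(k):
            f = feat_pool[j]
            vals = np.empty(m, dtype=np.float64)
            for i in range(m):
                vals[i] = X[idx[lo + i], f]
            order = np.argsort(vals)
            left_counts[:] = 0
            ml = 0
            for pos in range(m - 1):
                row = idx[lo + order[pos]]
                left_counts[y[row]] += 1
                ml += 1
                v_here = vals[order[pos]]
                v_next = vals[order[pos + 1]]
                if v_next <= v_here:
                    continue
                mr = m - ml
                if ml < min_node or mr < min_node:
                    continue
                gl = 0.0
                for c in range(n_classes):
                    p = left_counts[c] / ml
                    gl += p * p
                gl = 1.0 - gl
                gr = 0.0
                for c in range(n_classes):
                    p = (counts[c] - left_counts[c]) / mr
                    gr += p * p
                gr = 1.0 - gr
                dec = m * g_node - ml * gl - mr * gr
                if dec > best_dec + 1e-12:
                    best_dec = dec
                    best_feat = f
                    best_thresh = 0.5 * (v_here + v_next)
                    best_ml = ml
                    best_left[:] = left_counts

        if best_feat < 0:
            continue

        importance[best_feat] += best_dec / n
        total_decrease += best_dec / n

        # stable partition of idx[lo:hi] around the threshold
        nl = 0
        nr = 0
        for i in range(lo, hi):
            if X[idx[i], best_feat] <= best_thresh:
                tmp[nl] = idx[i]
                nl += 1
        for i in range(lo, hi):
            if X[idx[i], best_feat] > best_thresh:
                tmp[nl + nr] = idx[i]
                nr += 1
        for i in range(m):
            idx[lo + i] = tmp[i]

        stack_lo[top] = lo
        stack_hi[top] = lo + nl
        top += 1
        stack_lo[top] = lo + nl
        stack_hi[top] = hi
        top += 1

    return total_decrease


@njit(cache=True)
def grow_forest(X, y, n_classes, boot_all, mtry, min_node, tree_seeds):
    """Grow ``n_trees`` trees; return (per-tree importance matrix, per-tree totals)."""
    n_trees = boot_all.shape[0]
    d = X.shape[1]
    imp = np.zeros((n_trees, d), dtype=np.float64)
    totals = np.zeros(n_trees, dtype=np.float64)
    for t in range(n_trees):
        totals[t] = grow_tree(X, y, n_classes, boot_all[t], mtry, min_node,
                              tree_seeds[t], imp[t])
    return imp, totals
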