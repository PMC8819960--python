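"""Numba kernels for the random-forest out-of-bag machinery.

A single tree builder serves both tasks: trees are grown by maximizing
the variance reduction of the response, which for a 0/1 response selects
exactly the same splits as the Gini criterion (binary Gini impurity
2p(1-p) is proportional to the node variance p(1-p)). Leaf values are
response means, i.e. class-1 probabilities in classification — the
"probability forest" convention.

Everything is single-threaded and deterministic given the per-tree seed
array: each tree seeds the global numba RNG once and draws its bootstrap
sample and split-candidate subsets from that stream.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forest_oob_predictions"]


@njit(cache=True)
def _build_tree(X, y, boot, mtry, min_node, feat, thr, left, right, val, featbuf):
    n_total, d = X.shape
    work = boot.copy()
    max_nodes = feat.shape[0]
    stack_node = np.empty(max_nodes, np.int64)
    stack_lo = np.empty(max_nodes, np.int64)
    stack_hi = np.empty(max_nodes, np.int64)
    feat[:] = -1
    n_nodes = 1
    stack_node[0] = 0
    stack_lo[0] = 0
    stack_hi[0] = work.shape[0]
    sp = 1
    while sp > 0:
        sp -= 1
        node = stack_node[sp]
        lo = stack_lo[sp]
        hi = stack_hi[sp]
        m = hi - lo
        s = 0.0
        for i in range(lo, hi):
            s += y[work[i]]
        val[node] = s / m
        if m <= min_node:
            continue
        pure = True
        y0 = y[work[lo]]
        for i in range(lo + 1, hi):
            if y[work[i]] != y0:
                pure = False
                break
        if pure:
            continue
        best_gain = -1.0
        best_f = -1
        best_t = 0.0
        # sample mtry candidate features without replacement
        for k in range(mtry):
            j = k + np.random.randint(0, d - k)
            tmp = featbuf[k]
            featbuf[k] = featbuf[j]
            featbuf[j] = tmp
        for k in range(mtry):
            f = featbuf[k]
            order = np.argsort(X[work[lo:hi], f], kind="mergesort")
            vals = np.empty(m, np.float64)
            ys = np.empty(m, np.float64)
            for a in range(m):
                w = work[lo + order[a]]
                vals[a] = X[w, f]
                ys[a] = y[w]
            sl = 0.0
            for a in range(m - 1):
                sl += ys[a]
                if vals[a + 1] > vals[a]:
                    nl = a + 1
                    nr = m - nl
                    gain = sl * sl / nl + (s - sl) * (s - sl) / nr
                    if gain > best_gain:
                        best_gain = gain
                        best_f = f
                        best_t = 0.5 * (vals[a] + vals[a + 1])
        if best_f < 0:
            continue  # no valid split (all candidate features constant)
        i = lo
        jx = hi - 1
        while i <= jx:
            if X[work[i], best_f] <= best_t:
                i += 1
            else:
                tmpw = work[i]
                work[i] = work[jx]
                work[jx] = tmpw
                jx -= 1
        feat[node] = best_f
        thr[node] = best_t
        lc = n_nodes
        rc = n_nodes + 1
        n_nodes += 2
        left[node] = lc
        right[node] = rc
        stack_node[sp] = lc
        stack_lo[sp] = lo
        stack_hi[sp] = i
        sp += 1
        stack_node[sp] = rc
        stack_lo[sp] = i
        stack_hi[sp] = hi
        sp += 1
    return n_nodes


@njit(cache=True)
def forest_oob_predictions(X, y, n_trees, mtry, min_node, tree_seeds):
    """Grow a forest and return per-sample OOB prediction sums and counts.

    Returns (pred_sum, pred_count): for sample i, pred_sum[i] is the sum
    of leaf values over the trees whose bootstrap sample excluded i, and
    pred_count[i] the number of such trees. The OOB prediction is the
    ratio where the count is positive.
    """
    n, d = X.shape
    pred_sum = np.zeros(n, np.float64)
    pred_cnt = np.zeros(n, np.int64)
    max_nodes = 4 * n + 8
    feat = np.empty(max_nodes, np.int64)
    thr = np.empty(max_nodes, np.float64)
    left = np.empty(max_nodes, np.int64)
    right = np.empty(max_nodes, np.int64)
    val = np.empty(max_nodes, np.float64)
    featbuf = np.arange(d)
    inbag = np.empty(n, np.bool_)
    for t in range(n_trees):
        np.random.seed(tree_seeds[t])
        boot = np.random.randint(0, n, n)
        inbag[:] = False
        for i in range(n):
            inbag[boot[i]] = True
        _build_tree(X, y, boot, mtry, min_node, feat, thr, left, right, val, featbuf)
        for i in range(n):
            if not inbag[i]:
                node = 0
                while feat[node] >= 0:
                    if X[i, feat[node]] <= thr[node]:
                        node = left[node]
                    else:
                        node = right[node]
                pred_sum[i] += val[node]
                pred_cnt[i] += 1
    return pred_sum, pred_cnt
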