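"""Numba-jitted regression forest used by the missForest-style imputer.

Bagged CART regression trees: each tree is grown on a bootstrap sample of
the training rows, at every node ``mtry`` candidate features are drawn
without replacement, the split maximizes variance reduction, and leaves hold
at least ``min_leaf`` samples.

The kernel grows each tree *along the query paths only*: greedy CART picks a
split from the node's own samples alone, so subtrees that no query row
reaches can be skipped without changing any prediction.  With a single
missing cell per column (the leave-one-day-out design) this prunes most of
every tree.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def _insertion_sort_pair(v, y, n):
    """Sort v[:n] ascending, permuting y alongside."""
    for i in range(1, n):
        vi = v[i]
        yi = y[i]
        j = i - 1
        while j >= 0 and v[j] > vi:
            v[j + 1] = v[j]
            y[j + 1] = y[j]
            j -= 1
        v[j + 1] = vi
        y[j + 1] = yi


@njit(cache=False)
def forest_impute_column(X, col, train_rows, query_rows, n_trees, mtry, min_leaf, seed):
    """Predict column ``col`` for ``query_rows`` from all other columns.

    X is the current completed matrix (no NaNs); training targets are
    X[train_rows, col].  Returns forest-averaged predictions, one per query
    row.  Deterministic for a fixed seed.
    """
    n = train_rows.size
    nq = query_rows.size
    p = X.shape[1] - 1  # candidate features = all columns but `col`
    if mtry > p:
        mtry = p

    preds = np.zeros(nq)
    if n == 0 or nq == 0 or p < 1:
        return preds

    np.random.seed(seed)

    idx = np.empty(n, np.int64)    # bootstrap row ids, partitioned in place
    qpos = np.empty(nq, np.int64)  # query positions (into preds), partitioned
    off = n + nq  # right-half offset inside the partition scratch buffer
    tmp = np.empty(2 * off, np.int64)
    perm = np.arange(p)            # feature pool for partial Fisher-Yates
    sv = np.empty(n, np.float64)
    sy = np.empty(n, np.float64)
    stack = np.empty((4 * n + 8, 4), np.int64)  # rows: lo, hi, qlo, qhi

    for _tree in range(n_trees):
        for i in range(n):
            idx[i] = train_rows[np.random.randint(0, n)]
        for i in range(nq):
            qpos[i] = i

        top = 0
        stack[top, 0] = 0
        stack[top, 1] = n
        stack[top, 2] = 0
        stack[top, 3] = nq
        top = 1
        while top > 0:
            top -= 1
            lo = stack[top, 0]
            hi = stack[top, 1]
            qlo = stack[top, 2]
            qhi = stack[top, 3]
            if qhi <= qlo:
                continue  # no query reaches this subtree
            nn = hi - lo

            best_gain = -1.0
            best_feat = -1
            best_thr = 0.0
            if nn >= 2 * min_leaf:
                for t in range(mtry):
                    # partial Fisher-Yates draw without replacement
                    swap_j = t + np.random.randint(0, p - t)
                    f = perm[swap_j]
                    perm[swap_j] = perm[t]
                    perm[t] = f
                    feat = f if f < col else f + 1

                    for i in range(nn):
                        r = idx[lo + i]
                        sv[i] = X[r, feat]
                        sy[i] = X[r, col]
                    _insertion_sort_pair(sv, sy, nn)
                    if sv[0] == sv[nn - 1]:
                        continue  # constant feature at this node
                    total = 0.0
                    for i in range(nn):
                        total += sy[i]
                    left = 0.0
                    for i in range(min_leaf - 1):
                        left += sy[i]
                    for s in range(min_leaf, nn - min_leaf + 1):
                        left += sy[s - 1]
                        if sv[s - 1] == sv[s]:
                            continue  # can't split inside a tie block
                        right = total - left
                        gain = left * left / s + right * right / (nn - s)
                        if gain > best_gain:
                            best_gain = gain
                            best_feat = feat
                            best_thr = 0.5 * (sv[s - 1] + sv[s])

            if best_feat < 0:
                # leaf: mean of the bootstrap sample in this node
                m = 0.0
                for i in range(lo, hi):
                    m += X[idx[i], col]
                m /= nn
                for i in range(qlo, qhi):
                    preds[qpos[i]] += m
                continue

            # partition training rows by the split
            nl = 0
            nr = 0
            for i in range(lo, hi):
                if X[idx[i], best_feat] <= best_thr:
                    tmp[nl] = idx[i]
                    nl += 1
                else:
                    tmp[off + nr] = idx[i]
                    nr += 1
            for i in range(nl):
                idx[lo + i] = tmp[i]
            for i in range(nr):
                idx[lo + nl + i] = tmp[off + i]

            # partition query rows the same way
            ql = 0
            qr = 0
            for i in range(qlo, qhi):
                if X[query_rows[qpos[i]], best_feat] <= best_thr:
                    tmp[ql] = qpos[i]
                    ql += 1
                else:
                    tmp[off + qr] = qpos[i]
                    qr += 1
            for i in range(ql):
                qpos[qlo + i] = tmp[i]
            for i in range(qr):
                qpos[qlo + ql + i] = tmp[off + i]

            stack[top, 0] = lo
            stack[top, 1] = lo + nl
            stack[top, 2] = qlo
            stack[top, 3] = qlo + ql
            top += 1
            stack[top, 0] = lo + nl
            stack[top, 1] = hi
            stack[top, 2] = qlo + ql
            stack[top, 3] = qhi
            top += 1

    return preds / n_trees
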