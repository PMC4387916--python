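"""numba-compiled CART grower for all-numeric feature tables.

This is a speed twin of the pure-Python grower in :mod:`xrf.cart_forest`:
identical split search (exhaustive midpoint cuts, smallest weighted child
gini, ties broken by lowest feature index then smallest cut), identical
splitmix64 per-node subspace draws, identical pre-order node numbering.
Every intermediate count is integer-valued and exactly representable in
float64, so the two growers produce bit-identical trees; tests assert it.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_GOLD = np.uint64(0x9E3779B97F4A7C15)
_C1 = np.uint64(0xBF58476D1CE4E5B9)
_C2 = np.uint64(0x94D049BB133111EB)


@njit(inline="always")
def _mix(z):
    z = (z ^ (z >> np.uint64(30))) * _C1
    z = (z ^ (z >> np.uint64(27))) * _C2
    return z ^ (z >> np.uint64(31))


@njit(cache=True)
def grow_tree_numeric(X, y, n_classes, bag, strong, weak, k_s, k_w, n_min, tree_seed):
    """Grow one CART tree on ``bag`` (indices into X, with repeats).

    Candidate subspaces: ``k_s`` features drawn without replacement from
    ``strong`` and ``k_w`` from ``weak`` at every node (a plain forest
    passes all features as ``strong``).  Returns flat node arrays with
    pre-order ids.
    """
    n = bag.shape[0]
    max_nodes = 2 * n + 1

    feature = np.full(max_nodes, -1, np.int64)
    threshold = np.zeros(max_nodes, np.float64)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    leaf_class = np.full(max_nodes, -1, np.int64)
    n_node = np.zeros(max_nodes, np.int64)
    impurity = np.zeros(max_nodes, np.float64)
    class_counts = np.zeros((max_nodes, n_classes), np.int64)

    idx = bag.copy()
    tmp = np.empty(n, np.int64)
    vals = np.empty(n, np.float64)
    cnt = np.zeros(n_classes, np.int64)
    cl = np.zeros(n_classes, np.int64)

    n_cand = k_s + k_w
    cand = np.empty(n_cand, np.int64)
    swaps = np.empty(max(k_s, k_w, 1), np.int64)
    strong_l = strong.copy()
    weak_l = weak.copy()

    # explicit stack: (parent id, side [0=left,1=right], start, end)
    st_parent = np.empty(max_nodes, np.int64)
    st_side = np.empty(max_nodes, np.int64)
    st_start = np.empty(max_nodes, np.int64)
    st_end = np.empty(max_nodes, np.int64)
    sp = 0
    st_parent[sp] = -1
    st_side[sp] = 0
    st_start[sp] = 0
    st_end[sp] = n
    sp += 1

    n_nodes = 0
    while sp > 0:
        sp -= 1
        parent = st_parent[sp]
        side = st_side[sp]
        start = st_start[sp]
        end = st_end[sp]

        node = n_nodes
        n_nodes += 1
        if parent >= 0:
            if side == 0:
                left[parent] = node
            else:
                right[parent] = node

        n_t = end - start
        for j in range(n_classes):
            cnt[j] = 0
        for i in range(start, end):
            cnt[y[idx[i]]] += 1
        ss = 0.0
        for j in range(n_classes):
            ss += cnt[j] * cnt[j]
        impur = 1.0 - ss / (n_t * n_t)

        n_node[node] = n_t
        impurity[node] = impur
        for j in range(n_classes):
            class_counts[node, j] = cnt[j]

        make_leaf = impur <= 0.0 or n_t <= n_min
        if not make_leaf:
            # per-node splitmix64 stream seeded by (tree_seed, node id)
            s = np.uint64(tree_seed) + _GOLD * np.uint64(node + 1)

            # draw k_s from strong, then k_w from weak (partial
            # Fisher-Yates with undo so group arrays stay intact)
            m = strong_l.shape[0]
            for i in range(k_s):
                s = s + _GOLD
                r = _mix(s)
                j = i + np.int64(r % np.uint64(m - i))
                swaps[i] = j
                t = strong_l[i]
                strong_l[i] = strong_l[j]
                strong_l[j] = t
            for i in range(k_s):
                cand[i] = strong_l[i]
            for i in range(k_s - 1, -1, -1):
                j = swaps[i]
                t = strong_l[i]
                strong_l[i] = strong_l[j]
                strong_l[j] = t
            m = weak_l.shape[0]
            for i in range(k_w):
                s = s + _GOLD
                r = _mix(s)
                j = i + np.int64(r % np.uint64(m - i))
                swaps[i] = j
                t = weak_l[i]
                weak_l[i] = weak_l[j]
                weak_l[j] = t
            for i in range(k_w):
                cand[k_s + i] = weak_l[i]
            for i in range(k_w - 1, -1, -1):
                j = swaps[i]
                t = weak_l[i]
                weak_l[i] = weak_l[j]
                weak_l[j] = t
            cand.sort()

            best_g = np.inf
            best_f = np.int64(-1)
            best_thr = 0.0
            for ci in range(n_cand):
                f = cand[ci]
                for i in range(n_t):
                    vals[i] = X[idx[start + i], f]
                order = np.argsort(vals[:n_t])
                for j in range(n_classes):
                    cl[j] = 0
                for i in range(n_t - 1):
                    cl[y[idx[start + order[i]]]] += 1
                    v0 = vals[order[i]]
                    v1 = vals[order[i + 1]]
                    if v0 < v1:
                        nl = i + 1
                        nr = n_t - nl
                        ssl = 0.0
                        ssr = 0.0
                        for j in range(n_classes):
                            ssl += cl[j] * cl[j]
                            cr = cnt[j] - cl[j]
                            ssr += cr * cr
                        gl = 1.0 - ssl / (nl * nl)
                        gr = 1.0 - ssr / (nr * nr)
                        g = (nl * gl + nr * gr) / n_t
                        if g < best_g:
                            best_g = g
                            best_f = f
                            thr = 0.5 * (v0 + v1)
                            if thr >= v1:  # midpoint rounded up to v1
                                thr = v0
                            best_thr = thr

            if best_f < 0:
                make_leaf = True
            else:
                feature[node] = best_f
                threshold[node] = best_thr
                nl = 0
                for i in range(start, end):
                    if X[idx[i], best_f] <= best_thr:
                        tmp[nl] = idx[i]
                        nl += 1
                nr = nl
                for i in range(start, end):
                    if not (X[idx[i], best_f] <= best_thr):
                        tmp[nr] = idx[i]
                        nr += 1
                for i in range(n_t):
                    idx[start + i] = tmp[i]
                mid = start + nl
                # push right then left: left is processed next (pre-order)
                st_parent[sp] = node
                st_side[sp] = 1
                st_start[sp] = mid
                st_end[sp] = end
                sp += 1
                st_parent[sp] = node
                st_side[sp] = 0
                st_start[sp] = start
                st_end[sp] = mid
                sp += 1

        if make_leaf:
            best_c = np.int64(0)
            best_n = cnt[0]
            for j in range(1, n_classes):
                if cnt[j] > best_n:
                    best_n = cnt[j]
                    best_c = j
            leaf_class[node] = best_c

    return (
        feature[:n_nodes].copy(),
        threshold[:n_nodes].copy(),
        left[:n_nodes].copy(),
        right[:n_nodes].copy(),
        leaf_class[:n_nodes].copy(),
        n_node[:n_nodes].copy(),
        impurity[:n_nodes].copy(),
        class_counts[:n_nodes].copy(),
    )
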