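"""Numba kernels for growing, applying and mining feature-weighted trees.

Kept free of Python objects so the hot loops compile to machine code; the
public wrappers live in :mod:`multiview_irf.irf_core.forest` and
:mod:`multiview_irf.irf_core.rit`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Node encoding: feature[i] == -1 marks a leaf; left child takes values
# <= threshold, right child takes values > threshold.


@njit(cache=True, inline="always")
def _weighted_gini(n0: float, n1: float) -> float:
    n = n0 + n1
    if n <= 0.0:
        return 0.0
    return n - (n0 * n0 + n1 * n1) / n


@njit(cache=True)
def _sample_candidates(weights, cumw, mtry, cand, mark):
    """Weighted sampling without replacement (successive draws; falls back
    to exponential keys when rejection stalls on skewed weights).
    Returns the candidate count; chosen features are flagged in ``mark``."""
    p = weights.shape[0]
    total = cumw[p - 1]
    n_cand = 0
    attempts = 0
    max_attempts = 10 * mtry + 20
    while n_cand < mtry and attempts < max_attempts:
        attempts += 1
        u = np.random.random() * total
        f = np.searchsorted(cumw, u, side="right")
        if f >= p:
            f = p - 1
        if weights[f] <= 0.0:
            continue
        if mark[f] == 0:
            mark[f] = 1
            cand[n_cand] = f
            n_cand += 1
    if n_cand < mtry:
        # exponential-key ranking of the remaining positive-weight features
        rest_idx = np.empty(p, dtype=np.int64)
        rest_key = np.empty(p, dtype=np.float64)
        n_rest = 0
        for j in range(p):
            if mark[j] == 0 and weights[j] > 0.0:
                u = np.random.random()
                while u <= 0.0:
                    u = np.random.random()
                rest_idx[n_rest] = j
                rest_key[n_rest] = -np.log(u) / weights[j]
                n_rest += 1
        order = np.argsort(rest_key[:n_rest])
        take = min(mtry - n_cand, n_rest)
        for j in range(take):
            f = rest_idx[order[j]]
            mark[f] = 1
            cand[n_cand] = f
            n_cand += 1
    return n_cand


@njit(cache=True)
def grow_tree(X, y, weights, cumw, sort_idx, mtry, min_node, max_depth, bootstrap, seed):
    """Grow one tree; returns node arrays trimmed to the used length.

    Candidate features at every split are drawn without replacement with
    probability proportional to ``weights``; the best candidate maximizes
    the count-weighted Gini decrease ``n_p*G_p - n_L*G_L - n_R*G_R``.
    Ties resolve to the earliest-drawn candidate, then the lowest
    threshold (thresholds are scanned in ascending value order with a
    strict improvement test); both are deterministic under the seed but
    carry no systematic preference for low feature indices.
    """
    np.random.seed(seed)
    n, p = X.shape
    if bootstrap:
        samp = np.random.randint(0, n, n)
    else:
        samp = np.arange(n)

    cap = 2 * n + 1
    feature = np.full(cap, -1, dtype=np.int64)
    threshold = np.zeros(cap, dtype=np.float64)
    left = np.full(cap, -1, dtype=np.int64)
    right = np.full(cap, -1, dtype=np.int64)
    count0 = np.zeros(cap, dtype=np.int64)
    count1 = np.zeros(cap, dtype=np.int64)
    decrease = np.zeros(cap, dtype=np.float64)

    stack = np.zeros((cap, 4), dtype=np.int64)  # node_id, start, end, depth
    stack[0, 2] = n
    top = 1
    next_id = 1

    cand = np.empty(mtry, dtype=np.int64)
    mark = np.zeros(p, dtype=np.uint8)
    vals = np.empty(n, dtype=np.float64)
    labs = np.empty(n, dtype=np.int64)
    cnt = np.zeros(n, dtype=np.int64)  # in-node multiplicity per original row
    while top > 0:
        top -= 1
        nid = stack[top, 0]
        s = stack[top, 1]
        e = stack[top, 2]
        depth = stack[top, 3]
        m = e - s
        n1 = 0
        for i in range(s, e):
            n1 += y[samp[i]]
        n0 = m - n1
        count0[nid] = n0
        count1[nid] = n1
        if n0 == 0 or n1 == 0 or m < 2 * min_node or (max_depth > 0 and depth >= max_depth):
            continue
        imp_parent = _weighted_gini(n0, n1)

        n_cand = _sample_candidates(weights, cumw, mtry, cand, mark)
        for ci in range(n_cand):
            mark[cand[ci]] = 0
        if n_cand == 0:
            continue

        # large nodes scan each feature's forest-level presorted order in
        # O(n); small nodes gather and argsort their own values
        use_presort = m * 12 > n
        if use_presort:
            for i in range(s, e):
                cnt[samp[i]] += 1

        best_dec = 0.0
        best_feat = -1
        best_thr = 0.0
        for ci in range(n_cand):
            f = cand[ci]
            if use_presort:
                nl = 0
                left1 = 0
                prev_val = 0.0
                for k in range(n):
                    sid = sort_idx[f, k]
                    c = cnt[sid]
                    if c == 0:
                        continue
                    v = X[sid, f]
                    if nl > 0 and v > prev_val:
                        if nl >= min_node and m - nl >= min_node:
                            dec = (
                                imp_parent
                                - _weighted_gini(nl - left1, left1)
                                - _weighted_gini(n0 - (nl - left1), n1 - left1)
                            )
                            if dec > best_dec + 1e-12:
                                best_dec = dec
                                best_feat = f
                                best_thr = 0.5 * (prev_val + v)
                    nl += c
                    left1 += c * y[sid]
                    prev_val = v
            else:
                for i in range(m):
                    idx = samp[s + i]
                    vals[i] = X[idx, f]
                    labs[i] = y[idx]
                o = np.argsort(vals[:m])
                left1 = 0
                for i in range(m - 1):
                    left1 += labs[o[i]]
                    nl = i + 1
                    if nl < min_node or m - nl < min_node:
                        continue
                    vlo = vals[o[i]]
                    vhi = vals[o[i + 1]]
                    if vhi <= vlo:
                        continue
                    dec = (
                        imp_parent
                        - _weighted_gini(nl - left1, left1)
                        - _weighted_gini(n0 - (nl - left1), n1 - left1)
                    )
                    if dec > best_dec + 1e-12:
                        best_dec = dec
                        best_feat = f
                        best_thr = 0.5 * (vlo + vhi)
        if use_presort:
            for i in range(s, e):
                cnt[samp[i]] = 0
        if best_feat < 0:
            continue

        # partition samp[s:e] around the chosen split
        i = s
        j = e - 1
        while i <= j:
            if X[samp[i], best_feat] <= best_thr:
                i += 1
            else:
                tmp = samp[i]
                samp[i] = samp[j]
                samp[j] = tmp
                j -= 1
        mid = i
        if mid == s or mid == e:  # numerically degenerate split
            continue
        feature[nid] = best_feat
        threshold[nid] = best_thr
        decrease[nid] = best_dec
        lid = next_id
        rid = next_id + 1
        next_id += 2
        left[nid] = lid
        right[nid] = rid
        stack[top, 0] = lid
        stack[top, 1] = s
        stack[top, 2] = mid
        stack[top, 3] = depth + 1
        top += 1
        stack[top, 0] = rid
        stack[top, 1] = mid
        stack[top, 2] = e
        stack[top, 3] = depth + 1
        top += 1

    return (
        feature[:next_id],
        threshold[:next_id],
        left[:next_id],
        right[:next_id],
        count0[:next_id],
        count1[:next_id],
        decrease[:next_id],
    )


@njit(cache=True)
def apply_tree(feature, threshold, left, right, X):
    """Leaf node index for every row of X."""
    n = X.shape[0]
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = node
    return out


@njit(cache=True)
def tree_proba(feature, threshold, left, right, count0, count1, X):
    """Per-row class-1 fraction of the reached leaf."""
    n = X.shape[0]
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        tot = count0[node] + count1[node]
        out[i] = count1[node] / tot if tot > 0 else 0.5
    return out


@njit(cache=True)
def class1_leaf_paths(feature, threshold, left, right, Xpos):
    """Signed root-to-leaf paths for leaves reached by class-1 rows.

    ``Xpos`` holds the class-1 rows only.  Returns (items, offsets,
    weights): ``items[offsets[i]:offsets[i+1]]`` is the signed path set of
    the i-th hit leaf (encoded +-(f+1); a feature split twice keeps the
    sign of its deepest split) and ``weights[i]`` its class-1 row count.
    """
    n_nodes = feature.shape[0]
    leaf_of = apply_tree(feature, threshold, left, right, Xpos)
    counts = np.zeros(n_nodes, dtype=np.int64)
    for i in range(leaf_of.shape[0]):
        counts[leaf_of[i]] += 1

    parent = np.full(n_nodes, -1, dtype=np.int64)
    side = np.zeros(n_nodes, dtype=np.int64)
    depth = np.zeros(n_nodes, dtype=np.int64)
    max_depth = 0
    for i in range(n_nodes):
        if feature[i] >= 0:
            parent[left[i]] = i
            side[left[i]] = -1
            parent[right[i]] = i
            side[right[i]] = 1
            d = depth[i] + 1
            depth[left[i]] = d
            depth[right[i]] = d
            if d > max_depth:
                max_depth = d

    n_hit = 0
    for i in range(n_nodes):
        if counts[i] > 0:
            n_hit += 1
    offsets = np.zeros(n_hit + 1, dtype=np.int64)
    weights = np.zeros(n_hit, dtype=np.int64)
    items = np.zeros(n_hit * max(max_depth, 1), dtype=np.int64)
    buf = np.empty(max(max_depth, 1), dtype=np.int64)
    pos = 0
    k = 0
    for leaf in range(n_nodes):
        if counts[leaf] == 0:
            continue
        # walk to the root; first occurrence of a feature is its deepest split
        n_items = 0
        node = leaf
        while parent[node] >= 0:
            par = parent[node]
            f = feature[par]
            dup = False
            for j in range(n_items):
                if abs(buf[j]) - 1 == f:
                    dup = True
                    break
            if not dup:
                buf[n_items] = (f + 1) * side[node]
                n_items += 1
            node = par
        for j in range(n_items):
            items[pos + j] = buf[j]
        pos += n_items
        weights[k] = counts[leaf]
        k += 1
        offsets[k] = pos
    return items[:pos], offsets, weights
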