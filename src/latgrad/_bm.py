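"""Felsenstein pruning for Brownian motion with shared edge variances.

The kernel works on flattened tree arrays so it can be JIT-compiled with
numba when available; a pure-numpy fallback keeps the package importable
without it.  For p traits whose edge variances differ only by a per-trait
scalar s_j, one pass yields the per-trait quadratic forms, the common
log-determinant and the GLS (root) means, from which the independent-trait
BM log-likelihood is assembled in closed form.
"""

from __future__ import annotations

import numpy as np

__all__ = ["tree_arrays", "bm_pruning", "bm_loglik_parts"]


def _bm_pruning_impl(postorder, parent, child_ptr, child_idx, n_tips,
                     edge_var, X):
    """Returns (q per trait, logdet incl. root variance, mu per trait, ok).

    ``edge_var``: variance accumulated on each edge (indexed by node).
    ``X``: (n_tips, p) tip values.  ``ok`` is False if a combined variance
    hit zero (singular covariance).
    """
    n_nodes = parent.shape[0]
    p = X.shape[1]
    xhat = np.zeros((n_nodes, p))
    vhat = np.zeros(n_nodes)
    q = np.zeros(p)
    logdet = 0.0
    root = -1
    for oi in range(postorder.shape[0]):
        node = postorder[oi]
        if node < n_tips:
            for j in range(p):
                xhat[node, j] = X[node, j]
            vhat[node] = edge_var[node]
            continue
        first = True
        xv = np.zeros(p)
        vv = 0.0
        for ci in range(child_ptr[node], child_ptr[node + 1]):
            c = child_idx[ci]
            if first:
                for j in range(p):
                    xv[j] = xhat[c, j]
                vv = vhat[c]
                first = False
                continue
            vsum = vv + vhat[c]
            if vsum <= 0.0:
                return q, logdet, xv, False
            logdet += np.log(vsum)
            for j in range(p):
                d = xv[j] - xhat[c, j]
                q[j] += d * d / vsum
                xv[j] = (vhat[c] * xv[j] + vv * xhat[c, j]) / vsum
            vv = vv * vhat[c] / vsum
        for j in range(p):
            xhat[node, j] = xv[j]
        vhat[node] = vv + edge_var[node]
        root = node
    v_root = vhat[root] - edge_var[root]
    if v_root <= 0.0:
        return q, logdet, xhat[root], False
    logdet += np.log(v_root)
    return q, logdet, xhat[root].copy(), True


def _path_cumsum_impl(preorder, parent, x):
    """out[node] = sum of x along the root-to-node path."""
    out = np.zeros_like(x)
    for i in range(preorder.shape[0]):
        node = preorder[i]
        p = parent[node]
        out[node] = x[node] + (out[p] if p >= 0 else 0.0)
    return out


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    bm_pruning = njit(cache=True)(_bm_pruning_impl)
    path_cumsum = njit(cache=True)(_path_cumsum_impl)
except Exception:  # pragma: no cover
    bm_pruning = _bm_pruning_impl
    path_cumsum = _path_cumsum_impl


def tree_arrays(tree):
    """Flattened child lists for the kernel: (postorder, parent, ptr, idx)."""
    n = tree.n_nodes
    ptr = np.zeros(n + 1, dtype=np.int64)
    for node in range(n):
        ptr[node + 1] = ptr[node] + len(tree.children[node])
    idx = np.empty(ptr[-1], dtype=np.int64)
    for node in range(n):
        idx[ptr[node]:ptr[node + 1]] = tree.children[node]
    return tree.postorder.astype(np.int64), tree.parent.astype(np.int64), ptr, idx


def bm_loglik_parts(arrays, n_tips, edge_var, X):
    """(q, logdet, mu) for unit-scale edge variances; raises if singular."""
    postorder, parent, ptr, idx = arrays
    q, logdet, mu, ok = bm_pruning(postorder, parent, ptr, idx, n_tips,
                                   np.ascontiguousarray(edge_var, dtype=np.float64),
                                   np.ascontiguousarray(X, dtype=np.float64))
    if not ok:
        raise np.linalg.LinAlgError("singular Brownian covariance (zero variance)")
    return q, logdet, mu


def bm_loglik(arrays, n_tips, edge_var, X, scales):
    """Independent-trait BM log-likelihood at the GLS root means.

    Trait j has edge variances ``scales[j] * edge_var``; the root value is
    profiled out at its maximum-likelihood (GLS) estimate.
    """
    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0):
        raise ValueError("trait variance scales must be > 0")
    q, logdet, _ = bm_loglik_parts(arrays, n_tips, edge_var, X)
    n = n_tips
    return float(
        -0.5 * np.sum(q / scales + n * np.log(scales))
        - 0.5 * scales.size * (logdet + n * np.log(2.0 * np.pi))
    )
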