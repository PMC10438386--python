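"""Bootstrap regression forests with split-improvement recording.

This is the tree engine behind the gradient-forest stage.  Fitting allelic
turnover functions requires, for every SNP, a forest of hundreds of small
regression trees *and* access to the raw split records (feature, threshold,
impurity improvement) of every tree, which is what the turnover functions are
built from.  The engine is numba-compiled and keeps whole forests in flat
arrays, so fitting ~10^5 trees per dataset stays inexpensive on one core.

Trees are CART regression trees (variance reduction splits) grown on
bootstrap samples with `mtry` features considered per node, unlimited depth
and a minimum leaf size.  Out-of-bag predictions and Breiman-style
permutation importance (optionally stratified, for conditional permutation)
are computed from the stored forests.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["RegressionForest"]


@njit(cache=True)
def _fit_tree(X, y, idx, mtry, min_leaf, base, feat, thr, left, right, val, imp,
              stack_nd, stack_lo, stack_hi, feats, vals, tmp):
    n = idx.shape[0]
    p = X.shape[1]
    n_nodes = 1
    sp = 0
    stack_nd[sp] = 0
    stack_lo[sp] = 0
    stack_hi[sp] = n
    sp += 1
    while sp > 0:
        sp -= 1
        nd = stack_nd[sp]
        lo = stack_lo[sp]
        hi = stack_hi[sp]
        m = hi - lo
        s = 0.0
        ss = 0.0
        for i in range(lo, hi):
            v = y[idx[i]]
            s += v
            ss += v * v
        val[base + nd] = s / m
        feat[base + nd] = -1
        sse = ss - s * s / m
        if m < 2 * min_leaf or sse <= 1e-12:
            continue
        # sample mtry candidate features without replacement
        for j in range(mtry):
            k = j + np.random.randint(0, p - j)
            t = feats[j]
            feats[j] = feats[k]
            feats[k] = t
        best_gain = 1e-12
        best_f = -1
        best_thr = 0.0
        for jf in range(mtry):
            f = feats[jf]
            for i in range(m):
                vals[i] = X[idx[lo + i], f]
            order = np.argsort(vals[:m], kind="mergesort")
            cs = 0.0
            css = 0.0
            for i in range(m - 1):
                v = y[idx[lo + order[i]]]
                cs += v
                css += v * v
                ml = i + 1
                mr = m - ml
                if ml < min_leaf or mr < min_leaf:
                    continue
                if vals[order[i]] == vals[order[i + 1]]:
                    continue
                sse_l = css - cs * cs / ml
                rs = s - cs
                rss = ss - css
                sse_r = rss - rs * rs / mr
                gain = sse - sse_l - sse_r
                if gain > best_gain:
                    best_gain = gain
                    best_f = f
                    best_thr = 0.5 * (vals[order[i]] + vals[order[i + 1]])
        if best_f < 0:
            continue
        # stable partition of the index segment around the chosen threshold
        nl = 0
        for i in range(m):
            if X[idx[lo + i], best_f] <= best_thr:
                tmp[nl] = idx[lo + i]
                nl += 1
        nr = nl
        for i in range(m):
            if X[idx[lo + i], best_f] > best_thr:
                tmp[nr] = idx[lo + i]
                nr += 1
        if nl == 0 or nl == m:
            # adjacent floats: the midpoint threshold rounded onto one of
            # the two split values, leaving a child empty -> keep as leaf
            continue
        for i in range(m):
            idx[lo + i] = tmp[i]
        lid = n_nodes
        rid = n_nodes + 1
        n_nodes += 2
        feat[base + nd] = best_f
        thr[base + nd] = best_thr
        left[base + nd] = lid
        right[base + nd] = rid
        imp[base + nd] = best_gain
        stack_nd[sp] = lid
        stack_lo[sp] = lo
        stack_hi[sp] = lo + nl
        sp += 1
        stack_nd[sp] = rid
        stack_lo[sp] = lo + nl
        stack_hi[sp] = hi
        sp += 1
    return n_nodes


@njit(cache=True, inline="always")
def _predict_row(base, feat, thr, left, right, val, x):
    nd = 0
    while feat[base + nd] >= 0:
        if x[feat[base + nd]] <= thr[base + nd]:
            nd = left[base + nd]
        else:
            nd = right[base + nd]
    return val[base + nd]


@njit(cache=True)
def _fit_forest(X, y, n_trees, mtry, min_leaf, seed):
    n, p = X.shape
    stride = 2 * n + 1
    feat = np.full(n_trees * stride, -1, np.int32)
    thr = np.zeros(n_trees * stride)
    left = np.zeros(n_trees * stride, np.int32)
    right = np.zeros(n_trees * stride, np.int32)
    val = np.zeros(n_trees * stride)
    imp = np.zeros(n_trees * stride)
    inbag = np.zeros((n_trees, n), np.int16)
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n, np.int64)
    idx = np.empty(n, np.int64)
    stack_nd = np.empty(2 * n + 2, np.int64)
    stack_lo = np.empty(2 * n + 2, np.int64)
    stack_hi = np.empty(2 * n + 2, np.int64)
    feats = np.arange(p)
    vals = np.empty(n)
    tmp = np.empty(n, np.int64)
    for t in range(n_trees):
        np.random.seed(seed + t)
        for i in range(n):
            j = np.random.randint(0, n)
            idx[i] = j
            inbag[t, j] += 1
        _fit_tree(X, y, idx, mtry, min_leaf, t * stride, feat, thr, left, right,
                  val, imp, stack_nd, stack_lo, stack_hi, feats, vals, tmp)
        for i in range(n):
            if inbag[t, i] == 0:
                oob_sum[i] += _predict_row(t * stride, feat, thr, left, right, val, X[i])
                oob_cnt[i] += 1
    return feat, thr, left, right, val, imp, inbag, oob_sum, oob_cnt


@njit(cache=True)
def _predict_forest(X, n_trees, stride, feat, thr, left, right, val):
    n = X.shape[0]
    out = np.zeros(n)
    for i in range(n):
        s = 0.0
        for t in range(n_trees):
            s += _predict_row(t * stride, feat, thr, left, right, val, X[i])
        out[i] = s / n_trees
    return out


@njit(cache=True)
def _perm_importance(X, y, n_trees, stride, feat, thr, left, right, val, inbag, perms, var):
    n, p = X.shape
    xbuf = np.empty(p)
    total = 0.0
    used = 0
    for t in range(n_trees):
        base = t * stride
        mse_o = 0.0
        mse_p = 0.0
        m = 0
        for i in range(n):
            if inbag[t, i] == 0:
                pred = _predict_row(base, feat, thr, left, right, val, X[i])
                for k in range(p):
                    xbuf[k] = X[i, k]
                xbuf[var] = X[perms[t, i], var]
                pred_p = _predict_row(base, feat, thr, left, right, val, xbuf)
                d = y[i] - pred
                dp = y[i] - pred_p
                mse_o += d * d
                mse_p += dp * dp
                m += 1
        if m > 0:
            total += (mse_p - mse_o) / m
            used += 1
    if used == 0:
        return 0.0
    return total / used


class RegressionForest:
    """Random forest regressor recording per-split impurity improvements.

    Parameters
    ----------
    n_trees:
        Number of bootstrap trees.
    mtry:
        Features considered per split; default ``ceil(p / 3)``.
    min_leaf:
        Minimum samples per leaf (2 keeps at least two points per partition).
    seed:
        Base seed; tree ``t`` is grown from ``seed + t``, so forests are
        reproducible and independent of evaluation order.
    """

    def __init__(self, n_trees: int = 500, mtry: int | None = None,
                 min_leaf: int = 2, seed: int = 0):
        self.n_trees = int(n_trees)
        self.mtry = mtry
        self.min_leaf = int(min_leaf)
        self.seed = int(seed)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RegressionForest":
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.ascontiguousarray(y, dtype=np.float64)
        if X.ndim != 2 or y.shape[0] != X.shape[0]:
            raise ValueError("X must be (n_samples, n_features) matching y")
        n, p = X.shape
        mtry = self.mtry if self.mtry is not None else int(np.ceil(p / 3))
        mtry = max(1, min(mtry, p))
        (self._feat, self._thr, self._left, self._right, self._val,
         self._imp, self._inbag, oob_sum, oob_cnt) = _fit_forest(
            X, y, self.n_trees, mtry, self.min_leaf, self.seed)
        self._stride = 2 * n + 1
        self._X = X
        self._y = y
        with np.errstate(invalid="ignore"):
            self.oob_prediction_ = np.where(oob_cnt > 0, oob_sum / np.maximum(oob_cnt, 1), np.nan)
        covered = oob_cnt > 0
        if covered.sum() >= 2 and np.var(y[covered]) > 0:
            resid = y[covered] - self.oob_prediction_[covered]
            self.oob_r2_ = 1.0 - np.sum(resid ** 2) / np.sum((y[covered] - y[covered].mean()) ** 2)
        else:
            self.oob_r2_ = np.nan
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float64)
        return _predict_forest(X, self.n_trees, self._stride, self._feat,
                               self._thr, self._left, self._right, self._val)

    def permutation_importance(self, strata: dict[int, np.ndarray] | None = None,
                               seed: int | None = None,
                               n_perm_trees: int | None = None) -> np.ndarray:
        """Mean OOB MSE increase per feature under permutation.

        ``strata[v]``, when given, holds integer stratum labels per sample for
        feature ``v``; permutation is then performed within strata (a
        cluster-conditional stand-in for conditional permutation, which keeps
        correlated covariate patterns intact while breaking the focal
        feature's own association).  ``n_perm_trees`` estimates the importance
        on the first that many trees (an unbiased subsample of the forest).
        """
        n, p = self._X.shape
        T = self.n_trees if n_perm_trees is None else min(int(n_perm_trees), self.n_trees)
        rng = np.random.default_rng(self.seed + 10_000 if seed is None else seed)
        ar = np.arange(n)
        out = np.zeros(p)
        for v in range(p):
            labels = None if strata is None else strata.get(v)
            if labels is None:
                perms = rng.permuted(np.broadcast_to(ar, (T, n)), axis=1)
            else:
                perms = np.tile(ar, (T, 1))
                for g in np.unique(labels):
                    members = np.flatnonzero(labels == g)
                    sub = rng.permuted(
                        np.broadcast_to(np.arange(members.size), (T, members.size)), axis=1)
                    perms[:, members] = members[sub]
            out[v] = _perm_importance(self._X, self._y, T, self._stride,
                                      self._feat, self._thr, self._left, self._right,
                                      self._val, self._inbag, perms, v)
        return out

    def split_records(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All splits of the forest as (feature, threshold, improvement) arrays."""
        internal = self._feat >= 0
        return (self._feat[internal].astype(np.int64),
                self._thr[internal].copy(),
                self._imp[internal].copy())
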