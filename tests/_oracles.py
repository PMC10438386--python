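"""Independent reference implementations used as test oracles.

Everything here is deliberately written as direct, brute-force code —
double loops, dense linear algebra, textbook estimator formulas — and kept
independent of the package's implementation paths.
"""

import numpy as np


def wc_multilocus_fst(dosages: np.ndarray, pops) -> float:
    """Weir & Cockerham (1984) multilocus theta for biallelic dosages."""
    pops = np.asarray(pops)
    upops = np.unique(pops)
    r = len(upops)
    a_sum = b_sum = c_sum = 0.0
    for l in range(dosages.shape[1]):
        ni = np.array([np.sum(pops == p) for p in upops], float)
        pi = np.array([dosages[pops == p, l].mean() / 2 for p in upops])
        hi = np.array([np.mean(dosages[pops == p, l] == 1) for p in upops])
        nbar = ni.mean()
        nc = (r * nbar - np.sum(ni ** 2) / (r * nbar)) / (r - 1)
        pbar = np.sum(ni * pi) / (r * nbar)
        s2 = np.sum(ni * (pi - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(ni * hi) / (r * nbar)
        a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                         / (nbar - 1))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - (2 * nbar - 1) / (4 * nbar) * hbar)
        a_sum += a
        b_sum += b
        c_sum += hbar / 2
    return a_sum / (a_sum + b_sum + c_sum)


def brute_force_filter(dosages: np.ndarray, max_missing: float, min_maf: float):
    """Per-SNP double loop equivalent of the missingness + MAF filter."""
    n, l = dosages.shape
    keep = []
    for j in range(l):
        col = dosages[:, j]
        n_missing = sum(1 for v in col if np.isnan(v))
        if n_missing / n > max_missing:
            continue
        obs = [v for v in col if not np.isnan(v)]
        freq = sum(obs) / (2 * len(obs))
        if min(freq, 1 - freq) < min_maf:
            continue
        keep.append(j)
    return keep


def brute_force_ld_prune(dosages: np.ndarray, chrom, pos, r2_max: float,
                         window_bp: int):
    """Greedy left-to-right LD pruning by explicit pairwise scanning."""
    l = dosages.shape[1]
    dropped = set()
    for i in range(l):
        if i in dropped:
            continue
        for j in range(i + 1, l):
            if j in dropped or chrom[j] != chrom[i]:
                continue
            if pos[j] - pos[i] > window_bp:
                continue
            a, b = dosages[:, i], dosages[:, j]
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() < 2:
                continue
            x, y = a[ok], b[ok]
            if x.var() == 0 or y.var() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            if r * r > r2_max:
                dropped.add(j)
    return [j for j in range(l) if j not in dropped]


def greedy_prune_correlated(table, threshold: float):
    """Exhaustive re-implementation of the correlation-pruning rule."""
    import pandas as pd
    work = table.copy()
    removed = []
    while work.shape[1] >= 2:
        cols = list(work.columns)
        best = None
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                r = abs(np.corrcoef(work[cols[i]], work[cols[j]])[0, 1])
                if np.isnan(r):
                    r = 0.0
                if best is None or r > best[0]:
                    best = (r, i, j)
        if best is None or best[0] <= threshold:
            break
        _, i, j = best
        corr = work.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        corr = np.nan_to_num(corr)
        mean_abs = corr.sum(axis=0) / (corr.shape[0] - 1)
        if mean_abs[i] > mean_abs[j]:
            drop = i
        elif mean_abs[j] > mean_abs[i]:
            drop = j
        else:
            drop = max(i, j)
        removed.append(cols[drop])
        work = work.drop(columns=cols[drop])
    return list(work.columns), removed


def procrustes_closed_form(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residuals of superimposing y onto x via the closed-form SVD solution."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    u, s, vt = np.linalg.svd(yc.T @ xc)
    rot = u @ vt
    scale = s.sum() / np.sum(yc ** 2)
    return np.linalg.norm(xc - scale * yc @ rot, axis=1)


def simple_regression_t(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Per-column t-statistic of the slope in y_j ~ 1 + x (textbook OLS)."""
    n = len(x)
    out = np.empty(y.shape[1])
    for j in range(y.shape[1]):
        yy = y[:, j]
        b = np.cov(x, yy, ddof=1)[0, 1] / np.var(x, ddof=1)
        a = yy.mean() - b * x.mean()
        resid = yy - a - b * x
        s2 = np.sum(resid ** 2) / (n - 2)
        se = np.sqrt(s2 / np.sum((x - x.mean()) ** 2))
        out[j] = b / se
    return out


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up by the definition q(i) = min_{j>=i} p(j) m/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q
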