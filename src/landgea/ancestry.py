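"""Ancestry estimation by sparse nonnegative matrix factorization.

Genotypes are one-hot encoded over the three diploid classes and factorized
as ``X ~ Q F`` with ``Q`` the individuals x K admixture proportions (rows on
the probability simplex) and ``F`` the K x (loci x 3) ancestral genotype-
class frequencies.  The fit alternates projected least-squares updates of
``F`` and ``Q`` (with an L2 sparsity weight ``alpha`` on ``Q``), each
safeguarded by a backtracking step so the training loss never increases.

Model choice (K) uses masked cross-entropy: a random fraction of genotype
entries is held out of the fit, and the mean negative log-likelihood of the
held-out genotypes under Binomial(2, Q G) — with G the ancestral alt-allele
frequencies implied by F — scores each K; lower is better.

FST outlier scanning converts per-SNP FST over the ancestral components
(weighted by mean ancestry) into squared z-statistics, calibrates them with
a genomic inflation factor against chi-square with K-1 degrees of freedom,
and flags SNPs at Q-value < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gea import _chi2_lambda, _chi2_calibrate

__all__ = ["AncestryModel", "fit_snmf", "select_k", "SelectKResult", "fst_outliers"]

_EPS = 1e-9


@dataclass
class AncestryModel:
    """Fitted sNMF model."""

    Q: np.ndarray              # n_individuals x K, rows sum to 1
    G: np.ndarray              # K x n_snps ancestral alt-allele frequencies
    K: int
    alpha: float
    cross_entropy: float
    seed: int
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q rows must sum to 1")
        if (self.Q < -1e-12).any():
            raise ValueError("Q entries must be nonnegative")
        if (self.G < -1e-12).any() or (self.G > 1 + 1e-12).any():
            raise ValueError("G entries must lie in [0, 1]")
        if not np.isfinite(self.cross_entropy):
            raise ValueError("non-finite cross-entropy")


def _one_hot(geno: np.ndarray) -> np.ndarray:
    """(n, L, 3) one-hot encoding of dosage classes."""
    n, l = geno.shape
    x = np.zeros((n, l, 3))
    for c in range(3):
        x[:, :, c] = geno == c
    return x


def _loss(x: np.ndarray, w: np.ndarray, q: np.ndarray, f: np.ndarray,
          alpha: float) -> float:
    pred = np.einsum("ik,klc->ilc", q, f)
    return float(np.sum(w[:, :, None] * (x - pred) ** 2) + alpha * np.sum(q ** 2))


def _backtrack(x, w, q, f, alpha, prev_loss, new, which, max_halvings=30):
    """Accept ``new`` for factor ``which`` only along a loss-non-increasing
    segment toward the previous value (both endpoints are feasible, the loss
    is convex in each factor, so some step is always acceptable)."""
    old = q if which == "q" else f
    t = 1.0
    for _ in range(max_halvings):
        cand = old + t * (new - old)
        loss = (_loss(x, w, cand, f, alpha) if which == "q"
                else _loss(x, w, q, cand, alpha))
        if loss <= prev_loss + 1e-12:
            return cand, loss
        t *= 0.5
    return old, prev_loss


def _ancestral_freqs(f: np.ndarray) -> np.ndarray:
    """Alt-allele frequency per component from genotype-class weights."""
    tot = np.maximum(f.sum(axis=2), _EPS)
    return np.clip((f[:, :, 1] + 2.0 * f[:, :, 2]) / (2.0 * tot), _EPS, 1 - _EPS)


def _cross_entropy(geno, held, q, f):
    """Mean negative log Binomial(2, QG) probability of held-out genotypes."""
    g = _ancestral_freqs(f)
    p = np.clip(q @ g, _EPS, 1 - _EPS)
    d = geno
    loglik = (np.log(np.where(d == 1, 2.0, 1.0))
              + d * np.log(p) + (2 - d) * np.log1p(-p))
    return float(-loglik[held].mean())


def fit_snmf(gm, K: int, alpha: float = 10.0, max_iter: int = 200,
             mask_fraction: float = 0.05, seed: int = 0,
             tol: float = 1e-7) -> AncestryModel:
    """Fit the sNMF factorization at a given K.

    A random ``mask_fraction`` of genotype entries is held out of the
    training loss and scored by masked cross-entropy.  K=1 has the closed
    form Q = 1, G = global allele frequencies and is computed exactly.
    """
    d = gm.dosages if hasattr(gm, "dosages") else np.asarray(gm, float)
    if np.isnan(d).any():
        raise ValueError("genotype matrix contains missing calls; impute first")
    geno = d.astype(int)
    n, l = geno.shape
    if not 1 <= K <= n:
        raise ValueError(f"K must lie in [1, n_individuals={n}]")
    if not 0 <= mask_fraction < 1:
        raise ValueError("mask_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    held = rng.random((n, l)) < mask_fraction
    if held.all(axis=0).any():  # keep at least one training call per locus
        cols = np.flatnonzero(held.all(axis=0))
        held[rng.integers(0, n, cols.size), cols] = False
    w = (~held).astype(float)
    x = _one_hot(geno)

    if K == 1:
        denom = np.maximum(w.sum(axis=0), _EPS)
        f = (np.einsum("il,ilc->lc", w, x) / denom[:, None])[None, :, :]
        q = np.ones((n, 1))
        loss = _loss(x, w, q, f, alpha)
        ce = (_cross_entropy(geno, held, q, f) if held.any()
              else _cross_entropy(geno, np.ones_like(held, bool), q, f))
        return AncestryModel(q, _ancestral_freqs(f), 1, alpha, ce, seed,
                             np.array([loss]))

    q = rng.dirichlet(np.ones(K), size=n)
    f = rng.uniform(0.2, 0.8, size=(K, l, 3))
    f /= f.sum(axis=2, keepdims=True)
    prev = _loss(x, w, q, f, alpha)
    history = [prev]
    eye = 1e-8 * np.eye(K)
    for _ in range(max_iter):
        # F update: per-locus ridge-free least squares, projected to >= 0
        a = np.einsum("ik,il,im->lkm", q, w, q) + eye
        b = np.einsum("ik,il,ilc->lkc", q, w, x)
        f_new = np.clip(np.linalg.solve(a, b), 0.0, None).transpose(1, 0, 2)
        f, prev = _backtrack(x, w, q, f, alpha, prev, f_new, "f")
        # Q update: per-individual regularized least squares, projected to
        # the simplex by clipping and row renormalization
        m = np.einsum("klc,mlc->lkm", f, f)
        a_i = np.einsum("il,lkm->ikm", w, m) + alpha * np.eye(K)
        # gather F[k, l, geno[i, l]] -> (K, n, l)
        fg = f[:, np.arange(l)[None, :], geno]
        b_i = np.einsum("kil,il->ik", fg, w)
        q_new = np.linalg.solve(a_i, b_i[:, :, None])[:, :, 0]
        q_new = np.clip(q_new, 0.0, None)
        rows = q_new.sum(axis=1)
        bad = rows <= _EPS
        if bad.any():
            q_new[bad] = 1.0 / K
            rows[bad] = 1.0
        q_new /= rows[:, None]
        q, loss = _backtrack(x, w, q, f, alpha, prev, q_new, "q")
        history.append(loss)
        if prev - loss <= tol * max(prev, 1.0) and len(history) > 3:
            prev = loss
            break
        prev = loss
    if not np.isfinite(prev):
        raise ValueError("non-finite training loss in sNMF fit")
    held_eval = held if held.any() else np.ones_like(held, bool)
    ce = _cross_entropy(geno, held_eval, q, f)
    return AncestryModel(q, _ancestral_freqs(f), K, alpha, ce, seed,
                         np.asarray(history))


@dataclass
class SelectKResult:
    chosen_k: int
    curve: pd.DataFrame            # columns: K, cross_entropy (best over reps)
    best_models: dict[int, AncestryModel]


def _rep_seed(seed: int, k: int, rep: int) -> int:
    return (seed * 1009 + k * 101 + rep) % (2 ** 31)


def choose_k_from_curve(ks: list[int], ce: list[float],
                        plateau_tol: float = 0.01) -> int:
    """Argmin of the cross-entropy curve with a plateau rule.

    Scanning K in ascending order, the first relative decrease below
    ``plateau_tol`` marks the start of the plateau and the K just before it
    is chosen; a strictly worsening curve therefore returns the first K,
    and a curve that keeps improving returns the argmin.
    """
    if not ks:
        raise ValueError("empty K range")
    chosen = ks[int(np.argmin(ce))]
    for i in range(1, len(ks)):
        rel_drop = (ce[i - 1] - ce[i]) / max(abs(ce[i - 1]), _EPS)
        if rel_drop < plateau_tol:
            return ks[i - 1]
    return chosen


def select_k(gm, k_range=range(1, 16), reps: int = 10, alpha: float = 10.0,
             max_iter: int = 200, mask_fraction: float = 0.05, seed: int = 0,
             plateau_tol: float = 0.01) -> SelectKResult:
    """Choose K by masked cross-entropy with a plateau rule.

    Per K the best (lowest) cross-entropy over ``reps`` repetitions is kept.
    The chosen K is the argmin of the curve, unless the curve plateaus
    earlier: scanning K in ascending order, if the relative decrease from
    one K to the next falls below ``plateau_tol`` the K before that first
    negligible drop (the plateau entry) is chosen.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty K range")
    best_ce: dict[int, float] = {}
    best_models: dict[int, AncestryModel] = {}
    for k in ks:
        for rep in range(reps):
            model = fit_snmf(gm, k, alpha=alpha, max_iter=max_iter,
                             mask_fraction=mask_fraction,
                             seed=_rep_seed(seed, k, rep))
            if k not in best_ce or model.cross_entropy < best_ce[k]:
                best_ce[k] = model.cross_entropy
                best_models[k] = model
    curve = pd.DataFrame({"K": ks, "cross_entropy": [best_ce[k] for k in ks]})
    chosen = choose_k_from_curve(ks, [best_ce[k] for k in ks], plateau_tol)
    return SelectKResult(chosen_k=chosen, curve=curve, best_models=best_models)


def fst_outliers(model: AncestryModel, gm, q_thresh: float = 0.01) -> pd.DataFrame:
    """FST outlier scan from ancestry coefficients.

    Per SNP, FST is the variance of ancestral alt-allele frequencies around
    their mean-ancestry-weighted average over total heterozygosity
    p(1-p).  Following the sNMF outlier convention, the statistic
    z^2 = FST (n - K) / (1 - FST) is referred to chi-square with K-1 degrees
    of freedom after genomic-inflation calibration; BH Q-values below
    ``q_thresh`` flag outliers.
    """
    if model.K == 1:
        raise ValueError("FST is undefined for K=1")
    n = model.Q.shape[0]
    wk = model.Q.mean(axis=0)
    g = model.G
    pbar = wk @ g
    denom = pbar * (1 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.einsum("k,kl->l", wk, (g - pbar[None, :]) ** 2) / denom
    fst = np.clip(np.nan_to_num(fst), 0.0, 1.0 - 1e-12)
    z2 = fst * (n - model.K) / (1.0 - fst)
    lam = _chi2_lambda(z2, df=model.K - 1)
    if lam <= 0:
        lam = 1.0  # degenerate: all statistics zero
    p, q = _chi2_calibrate(z2, lam, df=model.K - 1)
    snp_ids = (gm.snp_meta["id"].to_numpy() if hasattr(gm, "snp_meta")
               else np.arange(g.shape[1]))
    return pd.DataFrame({"id": snp_ids, "fst": fst, "z2": z2,
                         "p_adj": p, "q": q, "outlier": q < q_thresh})
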