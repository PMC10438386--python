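"""Latent-factor gene-environment association with inflation calibration.

For each environmental variable, every SNP's dosage vector is regressed on
the variable while K latent factors absorb neutral population structure
(``Y ~ X b + U V' + E``).  The estimator is the deterministic least-squares
formulation: latent factors are the top-K left singular vectors of the
centred dosage matrix, and per-SNP effects come from ordinary least squares
on [intercept, env, factors], giving Z = b-hat / se(b-hat).

Test statistics are recalibrated with the genomic inflation factor

    lambda = median(Z^2) / median(chi-square_1)

and calibrated P-values are the upper-tail chi-square_1 probability of
Z^2 / lambda; Benjamini-Hochberg Q-values correct for multiple testing.
SNPs with |Z| above a threshold and Q below a threshold for at least one
variable are classified as putatively adaptive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["GeaResult", "fit_lfmm_z", "genomic_inflation", "calibrate_and_fdr",
           "classify_adaptive", "run_gea"]


def _as_dosage_matrix(gm) -> np.ndarray:
    d = gm.dosages if hasattr(gm, "dosages") else np.asarray(gm, float)
    if np.isnan(d).any():
        raise ValueError("genotype matrix contains missing calls; impute first")
    return np.asarray(d, float)


def _ridge_latent_factors(yc: np.ndarray, x: np.ndarray, k: int,
                          ridge: float) -> np.ndarray:
    """Latent factors of the ridge latent-factor model, by weighted SVD.

    The singular directions of the (centred) exposure design are shrunk by
    sqrt(ridge / (ridge + sigma_i^2)) before the rank-K SVD of the response
    matrix, then unshrunk in the recovered factors.  This keeps the factors
    from swallowing genuine exposure effects (a plain PCA of Y would absorb
    any widespread environmental signal into the structure term) while still
    letting them span the confounded directions.
    """
    n = yc.shape[0]
    xc = (x - x.mean())[:, None]
    xc = xc / xc.std()  # affine-invariant: shrinkage must not depend on units
    qx, sx, _ = np.linalg.svd(xc, full_matrices=False)
    shrink = np.sqrt(ridge / (ridge + sx ** 2))
    proj = qx.T @ yc                       # d x p components along X
    y_tilde = yc + qx @ ((shrink[:, None] - 1.0) * proj)
    u, s, _ = np.linalg.svd(y_tilde, full_matrices=False)
    uk = u[:, :k] * s[:k]
    # undo the shrinkage inside the recovered factors
    uk = uk + qx @ ((1.0 / shrink[:, None] - 1.0) * (qx.T @ uk))
    # orthonormalize for a well-conditioned downstream regression
    q, _ = np.linalg.qr(uk)
    return q[:, :k]


def fit_lfmm_z(gm, env, k_latent: int, reps: int = 3, seed: int = 0,
               ridge: float = 1.0) -> pd.DataFrame:
    """Per-SNP, per-variable association Z-scores under latent factors.

    ``env`` is a per-sample table (or array) of environmental variables; each
    is tested separately under the model ``Y ~ x b + U V' + E`` with
    ``k_latent`` factors.  Factors are estimated by the ridge-weighted SVD
    (see :func:`_ridge_latent_factors`); per-SNP effects and standard errors
    come from ordinary least squares on [1, x, U], so Z = b-hat / se.  The
    estimator is deterministic: the ``reps`` repetitions (kept for API
    compatibility with stochastic fits) return identical Z-scores and the
    per-SNP median equals the single fit.
    """
    y = _as_dosage_matrix(gm)
    n, n_snps = y.shape
    if isinstance(env, pd.DataFrame):
        env_df = env
    else:
        arr = np.asarray(env, float)
        if arr.ndim == 1:
            arr = arr[:, None]
        env_df = pd.DataFrame(arr, columns=[f"env{i + 1}"
                                            for i in range(arr.shape[1])])
    if len(env_df) != n:
        raise ValueError("env rows must match the number of individuals")
    if k_latent < 0 or k_latent >= min(n, n_snps):
        raise ValueError("k_latent must satisfy 0 <= K < min(n_individuals, n_snps)")
    yc = y - y.mean(axis=0)
    z = np.empty((n_snps, env_df.shape[1]))
    for j, name in enumerate(env_df.columns):
        x = env_df[name].to_numpy(float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"environmental variable {name!r} has non-finite values")
        if np.ptp(x) == 0:
            raise ValueError(f"environmental variable {name!r} is constant")
        factors = (_ridge_latent_factors(yc, x, k_latent, ridge)
                   if k_latent > 0 else np.empty((n, 0)))
        design = np.column_stack([np.ones(n), x, factors])
        q, r = np.linalg.qr(design)
        beta = np.linalg.solve(r, q.T @ y)
        resid = y - design @ beta
        dof = n - design.shape[1]
        if dof < 1:
            raise ValueError("not enough residual degrees of freedom")
        sigma2 = (resid ** 2).sum(axis=0) / dof
        xtx_inv = np.linalg.inv(r.T @ r)
        se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
        z[:, j] = beta[1] / se
        z[y.std(axis=0) == 0, j] = 0.0  # monomorphic SNPs carry no signal
    snp_ids = (gm.snp_meta["id"].to_numpy() if hasattr(gm, "snp_meta")
               else np.arange(n_snps))
    return pd.DataFrame(z, index=snp_ids, columns=env_df.columns)


def _chi2_lambda(stat: np.ndarray, df: int) -> float:
    """Genomic inflation: observed median statistic over the chi-square median."""
    stat = np.asarray(stat, float)
    if stat.size == 0:
        raise ValueError("empty statistic vector")
    if not np.all(np.isfinite(stat)):
        raise ValueError("non-finite statistics")
    return float(np.median(stat) / stats.chi2.ppf(0.5, df))


def _chi2_calibrate(stat: np.ndarray, lam: float, df: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Calibrated upper-tail P-values and BH Q-values."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    p = stats.chi2.sf(np.asarray(stat, float) / lam, df)
    q = multipletests(p, method="fdr_bh")[1]
    return p, q


def genomic_inflation(z: np.ndarray) -> float:
    """lambda = median(Z^2) divided by the median of chi-square with 1 d.f."""
    z = np.asarray(z, float)
    return _chi2_lambda(z ** 2, df=1)


def calibrate_and_fdr(z: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Calibrated P-values (chi-square_1 tail of Z^2/lambda) and BH Q-values."""
    z = np.asarray(z, float)
    return _chi2_calibrate(z ** 2, lam, df=1)


@dataclass
class GeaResult:
    """Per-SNP, per-variable association results.

    ``z``, ``p_adj``, ``q`` and ``flags`` are SNP x variable frames;
    ``lam`` maps each variable to its genomic inflation factor.
    """

    z: pd.DataFrame
    lam: pd.Series
    p_adj: pd.DataFrame
    q: pd.DataFrame
    k_latent: int
    flags: pd.DataFrame | None = None
    adaptive_any: pd.Series | None = None
    counts_per_variable: pd.Series | None = None
    counts_per_n_variables: pd.Series = field(default=None)

    @property
    def variables(self) -> list[str]:
        return list(self.z.columns)


def classify_adaptive(result: GeaResult, z_thresh: float = 2.0,
                      q_thresh: float = 0.01) -> GeaResult:
    """Flag SNPs with |Z| > z_thresh and Q < q_thresh per variable.

    ``adaptive_any`` is the union over variables; counts per variable and
    per number-of-variables summarise the classification.
    """
    flags = (result.z.abs() > z_thresh) & (result.q < q_thresh)
    result.flags = flags
    result.adaptive_any = flags.any(axis=1)
    result.counts_per_variable = flags.sum(axis=0)
    n_vars = flags.sum(axis=1)
    result.counts_per_n_variables = (n_vars[n_vars > 0]
                                     .value_counts().sort_index())
    return result


def run_gea(gm, env, k_latent: int, reps: int = 3, seed: int = 0,
            z_thresh: float = 2.0, q_thresh: float = 0.01) -> GeaResult:
    """Full association scan: Z-scores, per-variable lambda, calibrated
    P/Q-values, and adaptive classification."""
    z = fit_lfmm_z(gm, env, k_latent, reps=reps, seed=seed)
    lam = pd.Series({c: genomic_inflation(z[c].to_numpy()) for c in z.columns})
    p_adj = pd.DataFrame(index=z.index, columns=z.columns, dtype=float)
    q = pd.DataFrame(index=z.index, columns=z.columns, dtype=float)
    for c in z.columns:
        p_adj[c], q[c] = calibrate_and_fdr(z[c].to_numpy(), lam[c])
    result = GeaResult(z=z, lam=lam, p_adj=p_adj, q=q, k_latent=k_latent)
    return classify_adaptive(result, z_thresh=z_thresh, q_thresh=q_thresh)
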