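"""Gradient-forest allelic turnover: fitting, projection, and comparison.

Each SNP's allele frequency (individual dosage / 2) is regressed on the
environmental and spatial (PCNM) predictors with a random forest.  Forests
with positive out-of-bag R^2 contribute their split improvements, weighted by
R^2 and the per-SNP permutation importance of each predictor, to a cumulative
"allelic turnover" function along every predictor: a monotone map from a
predictor value to compositional genetic change, density-standardised so
data-dense parts of the gradient do not dominate.

Turnover functions are projected over raster grids cell-by-cell (linear
interpolation between split knots, clamped outside the training range); the
projected vectors are summarised by PCA, and adaptive versus neutral
projections are superimposed by orthogonal Procrustes rotation whose
per-cell residuals map where adaptive structure deviates from the neutral
expectation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

from .envlayers import EnvStack, GridSpec
from .forest import RegressionForest

__all__ = ["max_splits", "TurnoverModel", "TurnoverGrid", "fit_gradient_forest",
           "project_turnover", "procrustes_residuals", "pcnm_surfaces"]


def max_splits(p: int | float) -> float:
    """Density-binning control ``log2(0.368 p) / 2`` for p predictors.

    The 0.368 (~1/e) reflects the out-of-bag fraction of a bootstrap; the
    quantity controls the partition depth used when density-standardising
    split importances (ensuring at least two points per partition).
    """
    if p < 1 or 0.368 * p <= 1:
        raise ValueError("max_splits requires 0.368 * p > 1")
    return math.log2(0.368 * p) / 2.0


def _n_density_bins(p: int) -> int:
    """Bin count for density standardization, derived from max_splits."""
    try:
        return max(2, math.ceil(2 ** max_splits(p)))
    except ValueError:
        return 2


@dataclass
class TurnoverModel:
    """Aggregated allelic-turnover functions and importances.

    ``functions[var] = (knots, heights)``: a non-decreasing cumulative
    importance curve starting at 0 at the predictor minimum, with total
    height equal to the variable's R^2-weighted importance.
    """

    functions: dict[str, tuple[np.ndarray, np.ndarray]]
    importance: pd.Series
    snp_r2: pd.Series
    n_trees: int
    max_splits_bins: int
    snp_set_label: str = "adaptive"
    train_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def variables(self) -> list[str]:
        return list(self.functions)

    def evaluate(self, var: str, x: np.ndarray) -> np.ndarray:
        """Turnover value(s) for variable ``var``; clamped outside training
        range, linear between knots."""
        knots, heights = self.functions[var]
        return np.interp(np.asarray(x, float), knots, heights)

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        """Map a sites/cells x predictors table into turnover space."""
        missing = [v for v in self.variables if v not in table.columns]
        if missing:
            raise ValueError(f"missing predictor column(s): {missing}")
        return np.column_stack([self.evaluate(v, table[v].to_numpy())
                                for v in self.variables])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "snp_set_label": self.snp_set_label,
            "n_trees": self.n_trees,
            "max_splits_bins": self.max_splits_bins,
            "importance": self.importance.to_dict(),
            "functions": {v: {"knots": k.tolist(), "heights": h.tolist()}
                          for v, (k, h) in self.functions.items()},
            "train_ranges": {v: list(r) for v, r in self.train_ranges.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TurnoverModel":
        d = json.loads(Path(path).read_text())
        funcs = {v: (np.asarray(f["knots"]), np.asarray(f["heights"]))
                 for v, f in d["functions"].items()}
        return cls(functions=funcs, importance=pd.Series(d["importance"]),
                   snp_r2=pd.Series(dtype=float), n_trees=d["n_trees"],
                   max_splits_bins=d["max_splits_bins"],
                   snp_set_label=d["snp_set_label"],
                   train_ranges={v: tuple(r) for v, r in d["train_ranges"].items()})


def _correlation_clusters(pred: np.ndarray, threshold: float = 0.5
                          ) -> dict[int, np.ndarray]:
    """Conditional-permutation strata per predictor.

    Predictors joined by |r| > threshold form clusters; for a clustered
    predictor, samples are stratified into quantile bins of the mean of its
    standardized partners, and permutation later happens within bins.
    """
    p = pred.shape[1]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(pred, rowvar=False)
    corr = np.nan_to_num(corr)
    strata: dict[int, np.ndarray] = {}
    for v in range(p):
        partners = [u for u in range(p) if u != v and abs(corr[v, u]) > threshold]
        if not partners:
            continue
        z = pred[:, partners]
        sd = z.std(axis=0)
        sd[sd == 0] = 1.0
        score = ((z - z.mean(axis=0)) / sd).mean(axis=1)
        n_bins = min(4, max(2, len(np.unique(score))))
        edges = np.quantile(score, np.linspace(0, 1, n_bins + 1)[1:-1])
        strata[v] = np.searchsorted(edges, score)
    return strata


def fit_gradient_forest(gm, predictors: pd.DataFrame, n_trees: int = 500,
                        seed: int = 0, min_leaf: int = 2,
                        corr_threshold: float = 0.5,
                        n_perm_trees: int = 150,
                        snp_set_label: str = "adaptive") -> TurnoverModel:
    """Fit per-SNP forests and aggregate turnover functions.

    Per SNP with positive out-of-bag R^2, the conditional permutation
    importance distributes the SNP's R^2 across predictors, and the SNP's
    split improvements along each predictor (density-standardised over
    the observed gradient) build the cumulative turnover function.  SNPs
    with R^2 <= 0 are excluded from aggregation.
    """
    d = gm.dosages if hasattr(gm, "dosages") else np.asarray(gm, float)
    if np.isnan(d).any():
        raise ValueError("genotype matrix contains missing calls; impute first")
    pred = predictors.to_numpy(float)
    if not np.all(np.isfinite(pred)):
        raise ValueError("predictors must be complete and finite")
    n, p = pred.shape
    if d.shape[0] != n:
        raise ValueError("predictor rows must match individuals")
    degenerate = [c for c in predictors.columns
                  if predictors[c].nunique() < 2]
    if degenerate:
        raise ValueError(f"predictor(s) with < 2 distinct values: {degenerate}")
    var_names = list(predictors.columns)
    snp_ids = (gm.snp_meta["id"].tolist() if hasattr(gm, "snp_meta")
               else [f"snp{j}" for j in range(d.shape[1])])
    strata = _correlation_clusters(pred, corr_threshold)
    n_bins = _n_density_bins(p)

    r2 = {}
    split_pool: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {v: [] for v in range(p)}
    weighted_imp = np.zeros(p)
    n_used = 0
    for j, sid in enumerate(snp_ids):
        y = d[:, j] / 2.0
        if y.std() == 0:
            r2[sid] = np.nan
            continue
        forest = RegressionForest(n_trees=n_trees, min_leaf=min_leaf,
                                  seed=(seed + 1009 * j) % (2 ** 31)).fit(pred, y)
        r2[sid] = forest.oob_r2_
        if not np.isfinite(forest.oob_r2_) or forest.oob_r2_ <= 0:
            continue
        imp = np.clip(forest.permutation_importance(
            strata=strata, n_perm_trees=n_perm_trees), 0.0, None)
        feat, thr, gain = forest.split_records()
        if imp.sum() <= 0:
            # permutation uninformative: fall back to split-gain shares
            imp = np.bincount(feat, weights=gain, minlength=p)
        if imp.sum() <= 0:
            continue
        rel = imp / imp.sum()
        for v in range(p):
            mask_v = feat == v
            if not mask_v.any():
                continue
            g = gain[mask_v]
            # this SNP contributes importance r2 * rel_v on variable v
            split_pool[v].append((thr[mask_v], g / g.sum() * forest.oob_r2_ * rel[v]))
        weighted_imp += forest.oob_r2_ * rel
        n_used += 1
    if n_used == 0:
        raise ValueError("no SNP had positive out-of-bag R^2; "
                         "the responses carry no predictable signal")

    importance = pd.Series(weighted_imp / n_used, index=var_names)
    functions: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    train_ranges: dict[str, tuple[float, float]] = {}
    for v, name in enumerate(var_names):
        x = pred[:, v]
        lo, hi = float(x.min()), float(x.max())
        train_ranges[name] = (lo, hi)
        if split_pool[v]:
            thr = np.concatenate([t for t, _ in split_pool[v]])
            wgt = np.concatenate([w for _, w in split_pool[v]]) / n_used
            # density standardization: deflate importance in data-dense bins
            edges = np.linspace(lo, hi, n_bins + 1)
            dens = np.histogram(x, bins=edges)[0] / max(x.size, 1)
            which = np.clip(np.searchsorted(edges, thr, side="right") - 1, 0, n_bins - 1)
            std = wgt / np.maximum(dens[which], 1.0 / x.size)
            total = wgt.sum()
            if std.sum() > 0:
                std *= total / std.sum()
            order = np.argsort(thr, kind="mergesort")
            knots = np.concatenate([[lo], thr[order]])
            heights = np.concatenate([[0.0], np.cumsum(std[order])])
        else:
            knots = np.array([lo, hi])
            heights = np.array([0.0, 0.0])
        functions[name] = (knots, heights)
    return TurnoverModel(functions=functions, importance=importance,
                         snp_r2=pd.Series(r2), n_trees=n_trees,
                         max_splits_bins=n_bins, snp_set_label=snp_set_label,
                         train_ranges=train_ranges)


@dataclass
class TurnoverGrid:
    """Turnover-transformed predictor vectors over a raster grid."""

    transformed: np.ndarray       # n_mask_cells x p, row order = np.nonzero(mask)
    pcs: np.ndarray               # n_mask_cells x n_pc (centered scores)
    explained_variance_ratio: np.ndarray
    mask: np.ndarray
    grid: GridSpec
    var_names: list[str]

    def pc_grid(self, i: int) -> np.ndarray:
        """PC ``i`` (0-based) as a full grid with NaN off the mask."""
        out = np.full(self.mask.shape, np.nan)
        out[self.mask] = self.pcs[:, i]
        return out


def pcnm_surfaces(vectors: np.ndarray, site_coords: np.ndarray,
                  stack: EnvStack, power: float = 2.0) -> dict[str, np.ndarray]:
    """Interpolate site PCNM eigenvectors over a raster grid.

    Spatial eigenvectors are defined at the sampling sites only; projection
    over the landscape uses inverse-distance-weighted interpolation of each
    eigenvector (a cell at a site reproduces the site's value exactly).
    """
    vectors = np.asarray(vectors, float)
    site_coords = np.asarray(site_coords, float)
    gx, gy = stack.grid.cell_centers()
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    d = np.sqrt(((pts[:, None, :] - site_coords[None, :, :]) ** 2).sum(2))
    out: dict[str, np.ndarray] = {}
    w = 1.0 / np.maximum(d, 1e-12) ** power
    w /= w.sum(axis=1, keepdims=True)
    exact = d < 1e-9
    rows_exact = exact.any(axis=1)
    for k in range(vectors.shape[1]):
        vals = w @ vectors[:, k]
        if rows_exact.any():
            vals[rows_exact] = vectors[exact.argmax(axis=1)[rows_exact], k]
        out[f"pcnm{k + 1}"] = vals.reshape(stack.shape)
    return out


def project_turnover(model: TurnoverModel, stack: EnvStack,
                     extra_layers: dict[str, np.ndarray] | None = None,
                     n_pc: int = 3) -> TurnoverGrid:
    """Project the turnover model over every mask cell of a raster stack.

    ``extra_layers`` supplies predictor surfaces not in the stack (for
    example interpolated PCNM eigenvectors from :func:`pcnm_surfaces`).
    """
    layers = dict(stack.layers)
    if extra_layers:
        layers.update(extra_layers)
    missing = [v for v in model.variables if v not in layers]
    if missing:
        raise ValueError(f"stack lacks predictor layer(s): {missing}")
    mask = stack.mask
    table = pd.DataFrame({v: np.asarray(layers[v], float)[mask]
                          for v in model.variables})
    transformed = model.transform(table)
    centered = transformed - transformed.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive per component
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    k = min(n_pc, s.size)
    scores = u[:, :k] * s[:k]
    var = s ** 2
    evr = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
    return TurnoverGrid(transformed=transformed, pcs=scores,
                        explained_variance_ratio=evr, mask=mask.copy(),
                        grid=stack.grid, var_names=list(model.variables))


def procrustes_residuals(adaptive: TurnoverGrid, neutral: TurnoverGrid
                         ) -> np.ndarray:
    """Per-cell residual distance after Procrustes superposition.

    The neutral PCA scores are translated, rotated/reflected and uniformly
    scaled onto the adaptive scores; the residual at each cell is the
    Euclidean distance between the superimposed configurations.  Returned as
    a full grid with NaN off the mask.
    """
    if adaptive.mask.shape != neutral.mask.shape or not np.array_equal(
            adaptive.mask, neutral.mask):
        raise ValueError("adaptive and neutral grids must share one mask")
    x = adaptive.pcs
    y = neutral.pcs
    if x.shape != y.shape:
        raise ValueError("PCA dimensionality mismatch between grids")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    r, scale_num = orthogonal_procrustes(yc, xc)
    denom = np.sum(yc ** 2)
    s = scale_num / denom if denom > 0 else 0.0
    resid = np.sqrt(((xc - s * (yc @ r)) ** 2).sum(axis=1))
    out = np.full(adaptive.mask.shape, np.nan)
    out[adaptive.mask] = resid
    return out
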