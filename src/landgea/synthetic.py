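"""Synthetic landscapes, populations and genotypes with known ground truth.

Every downstream stage of the pipeline (filtering, ancestry, gene-environment
association, gradient forests, offset mapping) is exercised on data from this
module, so the generator targets exactly the statistical structure those
analyses assume:

* spatially autocorrelated, cross-correlated environmental layers
  (standardised Gaussian random fields), plus shifted "future" layers;
* populations at distinct localities on the landscape;
* neutral loci under a Balding-Nichols ancestral-frequency model with
  ``ancestral_K`` components, spatially smooth admixture proportions and a
  target multi-locus FST;
* adaptive loci whose population allele frequencies follow a logistic cline
  in one causal environmental layer, with a slope per environmental s.d.

The model is deliberately simple — no coalescent, recombination or realistic
LD decay — but it is fully seeded: identical seeds give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit, logit

from .envlayers import EnvStack, GridSpec
from .genotype import GenotypeMatrix

__all__ = ["LandscapeSpec", "TruthTable", "simulate_landscape",
           "simulate_samples", "simulate_genotypes"]


@dataclass
class LandscapeSpec:
    """Parameters of the synthetic environmental landscape.

    ``autocorr_range`` is the Gaussian smoothing scale in cells;
    ``env_cross_corr`` the target pairwise correlation matrix between layers
    (identity if omitted).
    """

    grid_rows: int
    grid_cols: int
    n_env: int = 3
    autocorr_range: float = 5.0
    env_cross_corr: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.grid_rows < 4 or self.grid_cols < 4:
            raise ValueError("grid must be at least 4x4")
        if self.n_env < 1:
            raise ValueError("need at least one environmental layer")
        if self.env_cross_corr is None:
            self.env_cross_corr = np.eye(self.n_env)
        self.env_cross_corr = np.asarray(self.env_cross_corr, float)
        c = self.env_cross_corr
        if c.shape != (self.n_env, self.n_env):
            raise ValueError("env_cross_corr must be n_env x n_env")
        if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("env_cross_corr must be symmetric with unit diagonal")
        if np.any(np.abs(c) > 1 + 1e-12):
            raise ValueError("env_cross_corr entries must lie in [-1, 1]")

    @property
    def layer_names(self) -> list[str]:
        return [f"env{i + 1}" for i in range(self.n_env)]


@dataclass
class TruthTable:
    """Ground truth of the planted adaptive signal.

    When used as an *input template* for :func:`simulate_genotypes`, the
    per-locus maps are keyed by adaptive-locus index (0..n_adaptive-1); the
    returned table carries the realised SNP ids instead.
    """

    adaptive_locus_ids: list = field(default_factory=list)
    causal_env_by_locus: dict = field(default_factory=dict)
    effect_size_by_locus: dict = field(default_factory=dict)
    ancestral_K: int = 3
    target_fst: float = 0.15

    def __post_init__(self):
        if not 0 <= self.target_fst <= 0.5:
            raise ValueError("target_fst must lie in [0, 0.5]")
        for v in self.effect_size_by_locus.values():
            if not np.isfinite(v):
                raise ValueError("effect sizes must be finite")

    @classmethod
    def template(cls, n_adaptive: int, env_names: list[str],
                 effect_size: float = 2.0, ancestral_K: int = 3,
                 target_fst: float = 0.15) -> "TruthTable":
        """Template assigning causal layers cyclically with one effect size."""
        return cls(adaptive_locus_ids=list(range(n_adaptive)),
                   causal_env_by_locus={i: env_names[i % len(env_names)]
                                        for i in range(n_adaptive)},
                   effect_size_by_locus={i: float(effect_size)
                                         for i in range(n_adaptive)},
                   ancestral_K=ancestral_K, target_fst=target_fst)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Standardised Gaussian random field via kernel-smoothed white noise."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def simulate_landscape(spec: LandscapeSpec,
                       future_shifts: dict[str, dict[str, float | np.ndarray]] | None = None
                       ) -> tuple[EnvStack, dict[str, EnvStack]]:
    """Simulate current layers and shifted future layers per scenario.

    Each layer is a standardised (zero-mean, unit-variance) autocorrelated
    field; cross-layer correlations follow ``spec.env_cross_corr`` (realised
    values approach the target as the grid grows).  ``future_shifts`` maps a
    scenario name to per-layer shift fields (scalars or grids, in layer
    s.d.); the default emulates directional climate change with a +1 s.d.
    shift of the first, temperature-like layer in one scenario.
    """
    try:
        chol = np.linalg.cholesky(spec.env_cross_corr)
    except np.linalg.LinAlgError as e:
        raise ValueError("env_cross_corr is not positive definite; "
                         "supply a valid correlation matrix") from e
    rng = np.random.default_rng(spec.seed)
    shape = (spec.grid_rows, spec.grid_cols)
    base = np.stack([_smooth_field(rng, shape, spec.autocorr_range).ravel()
                     for _ in range(spec.n_env)])
    mixed = chol @ base
    names = spec.layer_names
    layers = {}
    for i, name in enumerate(names):
        f = mixed[i]
        layers[name] = ((f - f.mean()) / f.std()).reshape(shape)
    grid = GridSpec(spec.grid_rows, spec.grid_cols)
    current = EnvStack(layers, grid)
    if future_shifts is None:
        future_shifts = {"ssp370_2081-2100": {names[0]: 1.0}}
    futures: dict[str, EnvStack] = {}
    for scenario, shifts in future_shifts.items():
        fut = {}
        for name in names:
            shift = np.asarray(shifts.get(name, 0.0), float)
            fut[name] = current.layers[name] + shift
        futures[scenario] = EnvStack(fut, grid, dict(current.kinds),
                                     current.mask.copy())
    return current, futures


def simulate_samples(n_pops: int, n_per_pop: int, landscape: EnvStack,
                     seed: int = 0) -> pd.DataFrame:
    """Place populations at distinct landscape cells and samples within them.

    Returns a table with sample id, locality label and cell-centre
    coordinates; all samples of a population share its locality.
    """
    if n_pops < 1 or n_per_pop < 1:
        raise ValueError("n_pops and n_per_pop must be positive")
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(landscape.mask)
    if n_pops > rows.size:
        raise ValueError(f"n_pops={n_pops} exceeds the {rows.size} available cells")
    pick = rng.choice(rows.size, size=n_pops, replace=False)
    grid = landscape.grid
    x = grid.xll + (cols[pick] + 0.5) * grid.cell
    y = grid.yll + (grid.nrows - rows[pick] - 0.5) * grid.cell
    recs = []
    for p in range(n_pops):
        loc = f"pop{p + 1:02d}"
        for i in range(n_per_pop):
            recs.append((f"{loc}_ind{i + 1:03d}", loc, x[p], y[p]))
    return pd.DataFrame(recs, columns=["id", "locality", "lon", "lat"])


def _admixture_proportions(pop_xy: np.ndarray, landscape: EnvStack, K: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Spatially smooth admixture: soft assignment to K ancestral centres.

    Centres are farthest-point sampled from the population locations (so the
    K ancestral components occupy distinct parts of the sampled landscape and
    each is anchored by at least one population), and the assignment kernel
    scale is tied to the inter-centre spacing: populations near a centre are
    dominated by its component while intermediate populations are admixed.
    """
    n_pops = pop_xy.shape[0]
    if K > n_pops:
        centers = pop_xy[rng.choice(n_pops, size=n_pops, replace=False)]
        extra = K - n_pops
        xmin, xmax, ymin, ymax = landscape.grid.extent
        centers = np.vstack([centers,
                             np.column_stack([rng.uniform(xmin, xmax, extra),
                                              rng.uniform(ymin, ymax, extra)])])
    else:
        picked = [int(rng.integers(n_pops))]
        for _ in range(K - 1):
            d2 = ((pop_xy[:, None, :] - pop_xy[picked][None, :, :]) ** 2).sum(2)
            picked.append(int(np.argmax(d2.min(axis=1))))
        centers = pop_xy[picked]
    dc = np.sqrt(((centers[:, None, :] - centers[None, :, :]) ** 2).sum(2))
    np.fill_diagonal(dc, np.inf)
    scale = max(dc.min() / 3.0, 1e-6)
    d2 = ((pop_xy[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    d2 -= d2.min(axis=1, keepdims=True)  # stabilize the softmax
    q = np.exp(-d2 / (2 * scale ** 2))
    return q / q.sum(axis=1, keepdims=True)


def _predicted_fst(Q: np.ndarray, f_bn: float, seed: int, n_loci: int = 600) -> float:
    """Monte-Carlo among-population FST implied by admixture Q and a
    Balding-Nichols concentration, as the multilocus ratio of among-population
    frequency variance to pooled heterozygosity (tracks Weir-Cockerham)."""
    r = np.random.default_rng(seed)
    c = (1 - f_bn) / f_bn
    p0 = r.uniform(0.05, 0.95, n_loci)
    comp = r.beta(p0[:, None] * c, (1 - p0[:, None]) * c, (n_loci, Q.shape[1]))
    pp = np.clip(comp @ Q.T, 1e-9, 1 - 1e-9)
    num = pp.var(axis=1, ddof=1).sum()
    pbar = pp.mean(axis=1)
    return float(num / (pbar * (1 - pbar)).sum())


def _calibrate_balding_nichols(Q: np.ndarray, target_fst: float, seed: int) -> float:
    """Bisect the Balding-Nichols F so the realised FST matches the target."""
    if target_fst <= 0:
        return 0.0
    lo, hi = 1e-4, 0.9
    if _predicted_fst(Q, hi, seed) <= target_fst:
        return hi
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if _predicted_fst(Q, mid, seed) < target_fst:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_genotypes(samples: pd.DataFrame, landscape: EnvStack,
                       n_neutral: int, n_adaptive: int,
                       truth: TruthTable | None = None,
                       missing_rate: float = 0.0, seed: int = 0,
                       n_chromosomes: int = 5, mean_spacing_bp: int = 1200
                       ) -> tuple[GenotypeMatrix, TruthTable]:
    """Simulate diploid dosages at neutral and adaptive loci.

    Neutral loci: ancestral frequency p0 ~ U(0.05, 0.95), per-component
    frequencies Balding-Nichols Beta around p0, population frequency the
    admixture mixture.  The Balding-Nichols concentration is rescaled by the
    admixture dispersion so the realised among-population FST matches
    ``truth.target_fst`` rather than being diluted by admixture.  Adaptive
    loci: population frequency ``expit(logit(p0) + slope * env)`` in the
    standardised causal layer.  Dosages are Binomial(2, p) per individual;
    missingness is completely at random.  SNP positions are laid out on
    synthetic chromosomes with ~``mean_spacing_bp`` spacing so windowed LD
    logic is exercisable.
    """
    if n_neutral + n_adaptive < 1:
        raise ValueError("need at least one locus")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    if truth is None:
        truth = TruthTable.template(n_adaptive, landscape.names)
    if len(truth.adaptive_locus_ids) != n_adaptive:
        raise ValueError("truth template must describe exactly n_adaptive loci")
    rng = np.random.default_rng(seed)
    n_loci = n_neutral + n_adaptive
    n_ind = len(samples)

    pops, pop_idx = np.unique(samples["locality"], return_inverse=True)
    pop_xy = (samples.groupby("locality", sort=True)[["lon", "lat"]]
              .first().loc[pops].to_numpy())
    K = truth.ancestral_K
    Q = _admixture_proportions(pop_xy, landscape, K, rng)

    # Admixture shrinks among-population frequency variance relative to the
    # ancestral components; calibrate the Balding-Nichols concentration by
    # bisection so the realised among-population FST tracks target_fst.
    f_bn = _calibrate_balding_nichols(Q, truth.target_fst,
                                      int(rng.integers(2 ** 31)))

    # interleave adaptive loci at random positions among the neutral ones
    adaptive_slots = rng.choice(n_loci, size=n_adaptive, replace=False)
    is_adaptive = np.zeros(n_loci, bool)
    is_adaptive[adaptive_slots] = True

    env_at_pop = {
        name: layer[landscape.grid.cell_index(pop_xy[:, 0], pop_xy[:, 1])]
        for name, layer in landscape.layers.items()
    }

    pop_freq = np.empty((len(pops), n_loci))
    slot_of = {int(s): i for i, s in enumerate(adaptive_slots)}
    for j in range(n_loci):
        if is_adaptive[j]:
            a = slot_of[j]
            key = truth.adaptive_locus_ids[a]
            env_name = truth.causal_env_by_locus[key]
            slope = truth.effect_size_by_locus[key]
            p0 = rng.uniform(0.3, 0.7)
            pop_freq[:, j] = expit(logit(p0) + slope * env_at_pop[env_name])
        else:
            p0 = rng.uniform(0.05, 0.95)
            if f_bn == 0:
                comp = np.full(K, p0)
            else:
                c = (1 - f_bn) / f_bn
                comp = rng.beta(p0 * c, (1 - p0) * c, size=K)
            pop_freq[:, j] = np.clip(Q @ comp, 1e-6, 1 - 1e-6)

    dosages = rng.binomial(2, pop_freq[pop_idx, :]).astype(float)
    if missing_rate > 0:
        dosages[rng.random(dosages.shape) < missing_rate] = np.nan

    # positions on synthetic chromosomes, strictly increasing
    chrom_of = np.sort(rng.integers(0, n_chromosomes, n_loci))
    spacing = rng.geometric(1.0 / mean_spacing_bp, n_loci)
    snp_ids = [f"snp_{j + 1:06d}" for j in range(n_loci)]
    chroms, positions = [], []
    last_chrom, cursor = -1, 0
    for j in range(n_loci):
        c = int(chrom_of[j])
        if c != last_chrom:
            cursor = 0
            last_chrom = c
        cursor += int(spacing[j])
        chroms.append(f"chr{c + 1}")
        positions.append(cursor)
    alleles = rng.choice(list("ACGT"), size=(n_loci, 2))
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")
    snp_meta = pd.DataFrame({"id": snp_ids, "chrom": chroms, "pos": positions,
                             "ref": alleles[:, 0], "alt": alleles[:, 1]})
    gm = GenotypeMatrix(dosages, snp_meta, samples.copy())

    realized = TruthTable(
        adaptive_locus_ids=[snp_ids[s] for s in adaptive_slots],
        causal_env_by_locus={snp_ids[s]: truth.causal_env_by_locus[k]
                             for s, k in zip(adaptive_slots,
                                             truth.adaptive_locus_ids)},
        effect_size_by_locus={snp_ids[s]: truth.effect_size_by_locus[k]
                              for s, k in zip(adaptive_slots,
                                              truth.adaptive_locus_ids)},
        ancestral_K=K, target_fst=truth.target_fst)
    return gm, realized
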