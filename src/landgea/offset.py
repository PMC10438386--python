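"""Genomic offset and seed-source genomic-similarity mapping.

The genomic offset of a grid cell is the Euclidean distance, in allelic-
turnover space, between the cell's current and future environments — a proxy
for the genomic change required to stay locally adapted under climate
change.  Offsets are computed per scenario (GCM x SSP x period), optionally
averaged over GCM members, and min-max scaled jointly across all scenarios
of a run so maps are visually comparable.

The similarity map inverts the question for assisted migration: the turnover
vector of a planned restoration site under the *future* scenario is compared
with every cell's *current* turnover vector; reversed min-max-scaled
distances (1 = most similar seed source, 0 = least) rank candidate seed
sources for that site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .envlayers import EnvStack
from .gradient import TurnoverModel, TurnoverGrid, project_turnover

logger = logging.getLogger(__name__)

__all__ = ["ScenarioSpec", "OffsetMap", "genomic_offset", "scale_offsets",
           "variable_contributions", "similarity_map", "aggregate_offsets"]

VALID_SSPS = (126, 245, 370, 585)
VALID_PERIODS = ("2021-2040", "2041-2060", "2061-2080", "2081-2100")


@dataclass(frozen=True)
class ScenarioSpec:
    """A future climate scenario: GCM member x SSP x 20-year period."""

    gcm: str
    ssp: int
    period: str

    def __post_init__(self):
        if not self.gcm:
            raise ValueError("gcm name must be non-empty")
        if self.ssp not in VALID_SSPS:
            raise ValueError(f"ssp must be one of {VALID_SSPS}")
        if self.period not in VALID_PERIODS:
            raise ValueError(f"period must be one of {VALID_PERIODS}")

    @property
    def label(self) -> str:
        return f"{self.gcm}_ssp{self.ssp}_{self.period}"


@dataclass
class OffsetMap:
    """Per-cell genomic offset for one scenario (NaN off the mask)."""

    raw: np.ndarray
    scenario: ScenarioSpec | None
    mask: np.ndarray
    scaled: np.ndarray | None = None

    def __post_init__(self):
        vals = self.raw[self.mask]
        if np.any(vals < -1e-12):
            raise ValueError("raw offsets must be nonnegative")


def _check_compatible(current: TurnoverGrid, future: TurnoverGrid) -> None:
    if current.var_names != future.var_names:
        raise ValueError("predictor sets of the two grids differ")
    if not np.array_equal(current.mask, future.mask):
        raise ValueError("grids must share one mask")


def genomic_offset(current: TurnoverGrid, future: TurnoverGrid,
                   scenario: ScenarioSpec | None = None,
                   sqrt: bool = True) -> OffsetMap:
    """Cell-wise distance between future and current turnover vectors.

    With ``sqrt=True`` (default) this is the Euclidean distance over the p
    predictors; ``sqrt=False`` keeps the raw sum of squared turnover
    differences (the two are monotonically related).
    """
    _check_compatible(current, future)
    d2 = ((future.transformed - current.transformed) ** 2).sum(axis=1)
    vals = np.sqrt(d2) if sqrt else d2
    raw = np.full(current.mask.shape, np.nan)
    raw[current.mask] = vals
    return OffsetMap(raw=raw, scenario=scenario, mask=current.mask.copy())


def scale_offsets(offsets: list[OffsetMap]) -> list[OffsetMap]:
    """Min-max scale raw offsets jointly across all scenarios.

    The global minimum and maximum pool every mask cell of every map, so a
    scaled value is comparable between SSPs and periods; a degenerate pool
    (max = min) yields all-zero scaled maps with a logged warning.
    """
    if not offsets:
        raise ValueError("no offset maps to scale")
    mask = offsets[0].mask
    for om in offsets[1:]:
        if not np.array_equal(om.mask, mask):
            raise ValueError("all offset maps must share one mask")
    pool = np.concatenate([om.raw[mask] for om in offsets])
    lo, hi = float(pool.min()), float(pool.max())
    span = hi - lo
    if span <= 0:
        logger.warning("degenerate offset scaling (max == min); "
                       "scaled offsets set to 0")
    for om in offsets:
        scaled = np.full(mask.shape, np.nan)
        scaled[mask] = 0.0 if span <= 0 else (om.raw[mask] - lo) / span
        om.scaled = scaled
    return offsets


def variable_contributions(current: TurnoverGrid, future: TurnoverGrid
                           ) -> tuple[dict[str, np.ndarray], pd.Series]:
    """Fraction of each cell's squared offset attributable to each variable.

    Cells with zero offset have undefined contributions (NaN).  The second
    return value is the range-wide mean fraction per variable over defined
    cells.
    """
    _check_compatible(current, future)
    d2 = (future.transformed - current.transformed) ** 2
    tot = d2.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot[:, None] > 0, d2 / tot[:, None], np.nan)
    grids: dict[str, np.ndarray] = {}
    for i, name in enumerate(current.var_names):
        g = np.full(current.mask.shape, np.nan)
        g[current.mask] = frac[:, i]
        grids[name] = g
    means = pd.Series(np.nanmean(frac, axis=0) if np.isfinite(frac).any()
                      else np.full(len(current.var_names), np.nan),
                      index=current.var_names)
    return grids, means


def similarity_map(site: tuple[float, float], model: TurnoverModel,
                   current_stack: EnvStack, future_stack: EnvStack,
                   scenario: ScenarioSpec | None = None,
                   extra_layers: dict[str, np.ndarray] | None = None,
                   sqrt: bool = True) -> np.ndarray:
    """Genomic similarity of every current cell to a site's future turnover.

    The restoration site's predictor vector under the future scenario is
    transformed through the turnover model; each current-landscape cell's
    turnover vector is compared with it by Euclidean distance, and distances
    are min-max scaled over the mask then reversed, so 1 marks the most
    genomically similar candidate seed source and 0 the least.
    """
    row, col = current_stack.grid.cell_index(np.array([site[0]]),
                                             np.array([site[1]]))
    row, col = int(row[0]), int(col[0])
    if not current_stack.mask[row, col]:
        raise ValueError(f"site {site} falls outside the mask")
    current = project_turnover(model, current_stack, extra_layers=extra_layers)
    future = project_turnover(model, future_stack, extra_layers=extra_layers)
    _check_compatible(current, future)
    cell_order = np.flatnonzero(current.mask.ravel())
    site_flat = row * current_stack.grid.ncols + col
    site_pos = int(np.searchsorted(cell_order, site_flat))
    site_vec = future.transformed[site_pos]
    d2 = ((current.transformed - site_vec[None, :]) ** 2).sum(axis=1)
    dist = np.sqrt(d2) if sqrt else d2
    lo, hi = dist.min(), dist.max()
    span = hi - lo
    if span <= 0:
        logger.warning("degenerate similarity scaling (all distances equal)")
        sim = np.ones_like(dist)
    else:
        sim = 1.0 - (dist - lo) / span
    out = np.full(current.mask.shape, np.nan)
    out[current.mask] = sim
    return out


def aggregate_offsets(offsets: list[OffsetMap], how: str = "mean"
                      ) -> dict[tuple[int, str], OffsetMap]:
    """Aggregate raw offsets over GCM members per SSP x period."""
    if how != "mean":
        raise ValueError("only mean aggregation is supported")
    groups: dict[tuple[int, str], list[OffsetMap]] = {}
    for om in offsets:
        if om.scenario is None:
            raise ValueError("aggregation requires scenario metadata")
        groups.setdefault((om.scenario.ssp, om.scenario.period), []).append(om)
    out = {}
    for key, members in groups.items():
        raw = np.nanmean(np.stack([m.raw for m in members]), axis=0)
        scen = ScenarioSpec(gcm="ensemble-mean", ssp=key[0], period=key[1])
        out[key] = OffsetMap(raw=raw, scenario=scen, mask=members[0].mask.copy())
    return out
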