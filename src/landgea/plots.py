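"""Plot helpers: association Manhattan plots and raster previews."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .gea import GeaResult

__all__ = ["manhattan", "raster_preview"]


def manhattan(result: GeaResult, snp_meta, variable: str,
              path: str | Path, q_thresh: float = 0.01) -> None:
    """Manhattan-style plot of -log10 calibrated P-values along the genome."""
    p = result.p_adj[variable].to_numpy()
    chroms = snp_meta["chrom"].to_numpy()
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    for i, chrom in enumerate(dict.fromkeys(chroms)):
        sel = chroms == chrom
        pos = snp_meta["pos"].to_numpy()[sel]
        ax.scatter(offset + pos, -np.log10(np.maximum(p[sel], 1e-300)),
                   s=6, color=f"C{i % 2}")
        offset += pos.max() + 1
    if result.flags is not None:
        n_hit = int(result.flags[variable].sum())
        ax.set_title(f"{variable}: {n_hit} adaptive SNP(s) at Q < {q_thresh}")
    ax.set_xlabel("genome position")
    ax.set_ylabel(r"$-\log_{10} P_{adj}$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def raster_preview(grid: np.ndarray, path: str | Path, title: str = "",
                   cmap: str = "viridis") -> None:
    """PNG preview of a raster grid (NaN cells transparent)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(grid, cmap=cmap)
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
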