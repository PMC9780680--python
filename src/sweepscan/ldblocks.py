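"""Pairwise linkage disequilibrium and haplotype-block segmentation.

From phased haplotypes of one population: D = p_AB - p_A p_B per site pair,
r^2 = D^2 / (p_A(1-p_A) p_B(1-p_B)), and D' = |D| / D_max with the usual
sign-dependent D_max.  Blocks are called with a deterministic solid-spine
rule: a run of consecutive sites is a block when every member is in strong
LD (r^2 >= r2_min) with both the first and the last site of the run; the
returned blocks are the maximal such runs.  A mean-r^2 summary over pairs
within a distance cap supports the swept-vs-neutral LD contrast between
populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genodata import HaplotypePanel, sites_in_window

log = logging.getLogger("sweepscan.ldblocks")


@dataclass
class LDMatrix:
    positions: np.ndarray  # 1-based bp of retained (polymorphic) sites
    r2: np.ndarray  # symmetric, diagonal 1
    dprime: np.ndarray  # symmetric, diagonal 1


def ld_matrix(panel: HaplotypePanel, pop=None, region=None) -> LDMatrix:
    """Pairwise r^2 and D' among polymorphic sites of a population.

    ``region`` is an optional (start, end) 0-based half-open interval.
    Monomorphic sites are excluded (logged).
    """
    rows = panel.hap_indices(pop) if pop is not None else slice(None)
    mat = panel.matrix[rows]
    pos = panel.positions
    if region is not None:
        sl = sites_in_window(pos, region[0], region[1])
        mat = mat[:, sl]
        pos = pos[sl]
    p = mat.mean(axis=0)
    poly = (p > 0) & (p < 1)
    n_mono = int((~poly).sum())
    if n_mono:
        log.info("ld_matrix: excluded %d monomorphic sites", n_mono)
    mat = mat[:, poly].astype(float)
    pos = pos[poly]
    p = p[poly]
    S = pos.size
    if S < 2:
        raise ValueError("need >= 2 polymorphic sites for LD")
    pab = mat.T @ mat / mat.shape[0]
    D = pab - np.outer(p, p)
    denom = np.outer(p * (1 - p), p * (1 - p))
    r2 = D * D / denom
    dmax_pos = np.minimum(np.outer(p, 1 - p), np.outer(1 - p, p))
    dmax_neg = np.minimum(np.outer(p, p), np.outer(1 - p, 1 - p))
    dmax = np.where(D > 0, dmax_pos, dmax_neg)
    with np.errstate(invalid="ignore", divide="ignore"):
        dprime = np.where(D == 0, 0.0, np.abs(D) / dmax)
    np.fill_diagonal(r2, 1.0)
    np.fill_diagonal(dprime, 1.0)
    return LDMatrix(positions=pos, r2=r2, dprime=dprime)


def blocks(matrix: LDMatrix, r2_min: float = 0.5) -> list:
    """Maximal solid-spine runs of sites; returns [start, end) bp intervals.

    A run [i..j] qualifies when r^2(i, k) >= r2_min and r^2(k, j) >= r2_min
    for every member k.  For each start the longest qualifying run is taken
    and runs contained in an earlier one are dropped; only runs of >= 2
    sites are blocks.
    """
    r2 = matrix.r2
    S = r2.shape[0]
    found = []
    for i in range(S - 1):
        for j in range(S - 1, i, -1):
            seg = slice(i, j + 1)
            if np.all(r2[i, seg] >= r2_min) and np.all(r2[seg, j] >= r2_min):
                found.append((i, j))
                break
    maximal = []
    for i, j in found:
        if any(i0 <= i and j <= j0 for i0, j0 in maximal):
            continue
        maximal.append((i, j))
    return [
        (int(matrix.positions[i]) - 1, int(matrix.positions[j]))
        for i, j in maximal
    ]


def mean_r2(matrix: LDMatrix, max_dist: float = None) -> float:
    """Mean r^2 over site pairs within max_dist bp (NaN if no pair)."""
    S = matrix.r2.shape[0]
    iu = np.triu_indices(S, k=1)
    vals = matrix.r2[iu]
    if max_dist is not None:
        dist = np.abs(matrix.positions[iu[0]] - matrix.positions[iu[1]])
        vals = vals[dist <= max_dist]
    return float(vals.mean()) if vals.size else float("nan")


def plot_ld_heatmap(matrix: LDMatrix, block_list=None, path=None, title=None):
    """r^2 heatmap with optional block overlays; saves to ``path`` if given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.r2, vmin=0, vmax=1, cmap="Reds", interpolation="nearest")
    fig.colorbar(im, ax=ax, label=r"$r^2$")
    if block_list:
        pos = matrix.positions
        for a, b in block_list:
            sl = sites_in_window(pos, a, b)
            lo, hi = sl.start - 0.5, sl.stop - 0.5
            ax.plot([lo, hi, hi, lo, lo], [lo, lo, hi, hi, lo], color="navy", lw=1.2)
    ax.set_xlabel("site index")
    ax.set_ylabel("site index")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
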