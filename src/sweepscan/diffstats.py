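"""Population differentiation and diversity: FST, PBS, nucleotide diversity.

Per-site FST comes in two estimators operating on haplotype allele counts:

* Hudson (Bhatia et al. form):
  num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
  den = p1(1-p2) + p2(1-p1)
* Weir-Cockerham (1984 ANOVA, haploid two-population form):
  num = MSP - MSG, den = MSP + (nc - 1) MSG, where
  MSP = sum_i n_i (p_i - pbar)^2 / (r-1),
  MSG = sum_i n_i p_i (1-p_i) / sum_i (n_i - 1),
  nc  = (sum n_i - sum n_i^2 / sum n_i) / (r-1).

Windowed values are ratios of sums ("weighted" FST, vcftools-style).  The
population branch statistic roots three pairwise FST values on an outgroup:
each FST is clamped to [0, 1), transformed T = -ln(1 - FST), and the focal
branch length is PBS = (T_S_L1 + T_S_L2 - T_L1_L2) / 2.  Raw FST keeps
negative values; clamping happens only inside the PBS transform.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genodata import HaplotypePanel, sites_in_window

_CLAMP_HI = 1.0 - 1e-9


def _pop_freqs(panel: HaplotypePanel, pop):
    rows = panel.hap_indices(pop)
    return panel.alt_freq(rows), rows.size


def fst_sites(
    panel: HaplotypePanel, popA, popB, estimator: str = "wc"
) -> pd.DataFrame:
    """Per-site FST components between two populations of one panel.

    Returns a DataFrame with columns pos, p1, p2, num, den, fst; sites
    monomorphic across both populations are excluded.  The per-site ratio
    is reported unclamped (negative values retained).
    """
    if estimator not in ("wc", "hudson"):
        raise ValueError("estimator must be 'wc' or 'hudson'")
    p1, n1 = _pop_freqs(panel, popA)
    p2, n2 = _pop_freqs(panel, popB)
    if min(n1, n2) < 2:
        raise ValueError("each population needs >= 2 haplotypes")
    keep = ~(((p1 == 0) & (p2 == 0)) | ((p1 == 1) & (p2 == 1)))
    p1, p2 = p1[keep], p2[keep]
    pos = panel.positions[keep]

    if estimator == "hudson":
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n1 - 1)
            - p2 * (1 - p2) / (n2 - 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    else:
        n_tot = n1 + n2
        pbar = (n1 * p1 + n2 * p2) / n_tot
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # r-1 = 1
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n_tot - 2)
        nc = n_tot - (n1 * n1 + n2 * n2) / n_tot
        num = msp - msg
        den = msp + (nc - 1) * msg
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(den > 0, num / den, np.nan)
    return pd.DataFrame(
        {"pos": pos, "p1": p1, "p2": p2, "num": num, "den": den, "fst": fst}
    )


def fst_windows(sites: pd.DataFrame, windows, chrom=None) -> pd.DataFrame:
    """Windowed FST as the ratio of summed numerators to summed denominators.

    ``windows`` is a list of (start, end) 0-based half-open intervals (or a
    scanner window DataFrame).  Empty windows get NaN, not zero.  Output
    mirrors the vcftools windowed-FST layout.
    """
    starts, ends = _window_bounds(windows)
    pos = sites["pos"].to_numpy()
    num = sites["num"].to_numpy()
    den = sites["den"].to_numpy()
    out = []
    for a, b in zip(starts, ends):
        sl = sites_in_window(pos, a, b)
        n = sl.stop - sl.start
        if n == 0 or den[sl].sum() <= 0:
            val = np.nan
        else:
            val = num[sl].sum() / den[sl].sum()
        out.append((chrom, a, b, n, val))
    return pd.DataFrame(
        out, columns=["CHROM", "BIN_START", "BIN_END", "N_VARIANTS", "WEIGHTED_FST"]
    )


def _window_bounds(windows):
    if isinstance(windows, pd.DataFrame):
        return windows["start"].to_numpy(), windows["end"].to_numpy()
    arr = np.asarray(list(windows))
    if arr.size == 0:
        return np.zeros(0, dtype=int), np.zeros(0, dtype=int)
    return arr[:, 0], arr[:, 1]


def pbs(fst_S_L1, fst_S_L2, fst_L1_L2):
    """Population branch statistic of the focal population S.

    Inputs are (possibly windowed) FST values in [-1, 1]; each is clamped to
    [0, 1 - 1e-9] before the log transform T = -ln(1 - FST).  The result can
    be negative (branch-length estimate).
    """
    t1, t2, t3 = (
        -np.log1p(-np.clip(f, 0.0, _CLAMP_HI)) for f in map(np.asarray, (fst_S_L1, fst_S_L2, fst_L1_L2))
    )
    return (t1 + t2 - t3) / 2.0


def pbs_windows(
    panel: HaplotypePanel,
    focal,
    low1,
    low2,
    windows,
    estimator: str = "wc",
) -> pd.DataFrame:
    """Windowed PBS of ``focal`` rooted by ``low1``/``low2``.

    Computes the three pairwise windowed FST tracks on a common window frame
    and applies the PBS transform per window.  ``low2`` is typically the
    outgroup.  Output columns carry the three FST, the three T values and
    pbs; windows empty in any comparison give NaN.
    """
    pairs = {
        "S_L1": (focal, low1),
        "S_L2": (focal, low2),
        "L1_L2": (low1, low2),
    }
    frames = {}
    for key, (a, b) in pairs.items():
        w = fst_windows(fst_sites(panel, a, b, estimator=estimator), windows,
                        chrom=panel.chrom)
        frames[key] = w["WEIGHTED_FST"].to_numpy()
    base = fst_windows(
        fst_sites(panel, focal, low1, estimator=estimator), windows, chrom=panel.chrom
    )[["CHROM", "BIN_START", "BIN_END", "N_VARIANTS"]]
    df = base.copy()
    for key in pairs:
        df[f"fst_{key}"] = frames[key]
        df[f"T_{key}"] = -np.log1p(-np.clip(frames[key], 0.0, _CLAMP_HI))
    df["pbs"] = pbs(frames["S_L1"], frames["S_L2"], frames["L1_L2"])
    return df


def pi_windows(panel: HaplotypePanel, pop, windows) -> pd.DataFrame:
    """Windowed nucleotide diversity of one population.

    Per segregating site the unbiased heterozygosity 2 p (1-p) n/(n-1) is
    summed over the window and divided by the window length in bp, so
    monomorphic positions contribute zero through the denominator.  Output
    mirrors the vcftools windowed-pi layout.
    """
    rows = panel.hap_indices(pop)
    n = rows.size
    if n < 2:
        raise ValueError("pi requires >= 2 haplotypes")
    p = panel.alt_freq(rows)
    h = 2.0 * p * (1 - p) * n / (n - 1)
    pos = panel.positions
    starts, ends = _window_bounds(windows)
    out = []
    for a, b in zip(starts, ends):
        sl = sites_in_window(pos, a, b)
        nv = sl.stop - sl.start
        out.append((panel.chrom, a, b, nv, h[sl].sum() / (b - a)))
    return pd.DataFrame(
        out, columns=["CHROM", "BIN_START", "BIN_END", "N_VARIANTS", "PI"]
    )
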