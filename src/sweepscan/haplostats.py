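"""Extended haplotype homozygosity (EHH) and the integrated haplotype score.

EHH at a flanking marker x is the probability that two randomly chosen
haplotypes carrying the core allele are identical at every site from the
core out to x (inclusive):

    EHH(x) = sum_h C(n_h, 2) / C(n_c, 2)

over the distinct extended haplotypes h among the n_c carriers.  iHH is the
trapezoidal integral of EHH over physical distance, summed over both sides
of the core, out to the first marker where EHH drops below a cutoff
(default 0.05).  The unstandardized score is ln(iHH_ancestral /
iHH_derived); standardization within derived-allele-frequency bins yields
iHS, and piHS = -log10 of the two-sided normal p-value of iHS.

No genetic map is used: integration is in physical bp, so iHH carries
bp*EHH units.  This cancels in the A/D ratio wherever the local
recombination environment is shared by the two allele classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import norm

from .genodata import ANCESTRAL_UNKNOWN, HaplotypePanel

log = logging.getLogger("sweepscan.haplostats")

DEFAULT_EHH_CUTOFF = 0.05
DEFAULT_MAX_GAP = 200_000
DEFAULT_BIN_WIDTH = 0.025

FLAG_BORDER = "border"
FLAG_GAP = "gap"
FLAG_FEW_CARRIERS = "few_carriers"
FLAG_SMALL_BIN = "small_bin"


@dataclass
class EHHCurve:
    """EHH values for one side of one core-allele class."""

    core_index: int
    side: str  # "left" | "right"
    points: list  # [(position, ehh)], starting at the core with ehh=1
    truncated_at_border: bool


@njit(cache=True)
def _ehh_walk_kernel(matT, carriers, core, step, cutoff, out_idx, out_ehh):
    """March outward from the core refining haplotype classes.

    matT is the site-major (n_sites, n_hap) matrix.  Writes visited marker
    indices and EHH values into the out arrays; returns (n_points,
    truncated_at_border).
    """
    n_c = carriers.size
    denom = n_c * (n_c - 1) / 2.0
    n_sites = matT.shape[0]
    out_idx[0] = core
    out_ehh[0] = 1.0
    npts = 1
    labels = np.zeros(n_c, dtype=np.int64)
    newlab = np.empty(n_c, dtype=np.int64)
    key_l = np.empty(n_c, dtype=np.int64)
    key_a = np.empty(n_c, dtype=np.uint8)
    cnt = np.empty(n_c, dtype=np.int64)
    truncated = True
    j = core + step
    while 0 <= j < n_sites:
        row = matT[j]
        n_classes = 0
        for i in range(n_c):
            li = labels[i]
            ai = row[carriers[i]]
            found = -1
            for t in range(n_classes):
                if key_l[t] == li and key_a[t] == ai:
                    found = t
                    break
            if found < 0:
                key_l[n_classes] = li
                key_a[n_classes] = ai
                cnt[n_classes] = 0
                found = n_classes
                n_classes += 1
            newlab[i] = found
            cnt[found] += 1
        labels, newlab = newlab, labels
        num = 0.0
        for t in range(n_classes):
            num += cnt[t] * (cnt[t] - 1)
        e = num / 2.0 / denom
        out_idx[npts] = j
        out_ehh[npts] = e
        npts += 1
        if e < cutoff:
            truncated = False
            break
        j += step
    return npts, truncated


def _ehh_walk(matT, carriers, core, step, cutoff):
    """Python-level wrapper over the kernel; returns (points, truncated)."""
    n_sites = matT.shape[0]
    out_idx = np.empty(n_sites, dtype=np.int64)
    out_ehh = np.empty(n_sites, dtype=np.float64)
    npts, truncated = _ehh_walk_kernel(
        matT, np.asarray(carriers, dtype=np.int64), core, step, cutoff,
        out_idx, out_ehh,
    )
    points = [(int(out_idx[k]), float(out_ehh[k])) for k in range(npts)]
    return points, bool(truncated)


def ehh(
    panel: HaplotypePanel,
    core: int,
    allele_class: str,
    cutoff: float = DEFAULT_EHH_CUTOFF,
):
    """EHH curves (left, right) for one core-allele class.

    ``allele_class`` is ``"ancestral"``/``"derived"`` (requires polarity at
    the core) or an explicit allele code 0/1.  The walk stops at the first
    marker where EHH < cutoff, or at the chromosome border (curve flagged
    ``truncated_at_border``).
    """
    if allele_class in ("ancestral", "derived"):
        anc = int(panel.ancestral[core])
        if anc == ANCESTRAL_UNKNOWN:
            raise ValueError(f"core site {core} has unknown ancestral allele")
        code = anc if allele_class == "ancestral" else 1 - anc
    else:
        code = int(allele_class)
    carriers = np.nonzero(panel.matrix[:, core] == code)[0]
    if carriers.size < 2:
        raise ValueError(
            f"core site {core}: <2 carriers of the {allele_class!r} allele"
        )
    matT = np.ascontiguousarray(panel.matrix.T)
    curves = []
    for side, step in (("left", -1), ("right", +1)):
        idx_points, truncated = _ehh_walk(matT, carriers, core, step, cutoff)
        pts = [(int(panel.positions[j]), e) for j, e in idx_points]
        curves.append(
            EHHCurve(
                core_index=core, side=side, points=pts, truncated_at_border=truncated
            )
        )
    return curves[0], curves[1]


def ihh(
    left: EHHCurve,
    right: EHHCurve,
    cutoff: float = DEFAULT_EHH_CUTOFF,
    max_gap: int = DEFAULT_MAX_GAP,
):
    """Integrate the EHH curve pair; returns (ihh in bp*EHH, flags).

    Each side is integrated with the trapezoid rule from the core out to the
    first marker where EHH < cutoff, including the crossing trapezoid.  If
    the chromosome ends first the side is flagged ``border``; a >max_gap bp
    jump between adjacent markers stops the integration with flag ``gap``.
    """
    total = 0.0
    flags = set()
    for curve in (left, right):
        pts = curve.points
        acc = 0.0
        stopped = False
        for (p0, e0), (p1, e1) in zip(pts, pts[1:]):
            if abs(p1 - p0) > max_gap:
                flags.add(FLAG_GAP)
                stopped = True
                break
            acc += 0.5 * (e0 + e1) * abs(p1 - p0)
            if e1 < cutoff:
                stopped = True
                break
        if not stopped and curve.truncated_at_border:
            flags.add(FLAG_BORDER)
        total += acc
    return total, flags


@njit(cache=True)
def _trapezoid_kernel(out_idx, out_ehh, npts, positions, cutoff, max_gap):
    """Integrate one walked side up to the cutoff crossing or a gap.

    Returns (area, crossed_cutoff, gap_stop).
    """
    acc = 0.0
    crossed = False
    gap = False
    for k in range(npts - 1):
        p0 = positions[out_idx[k]]
        p1 = positions[out_idx[k + 1]]
        d = p1 - p0 if p1 > p0 else p0 - p1
        if d > max_gap:
            gap = True
            break
        acc += 0.5 * (out_ehh[k] + out_ehh[k + 1]) * d
        if out_ehh[k + 1] < cutoff:
            crossed = True
            break
    return acc, crossed, gap


def _ihh_one_class(matT, positions, carriers, core, cutoff, max_gap, scratch):
    """iHH for one core-allele class; returns (value, flags set)."""
    out_idx, out_ehh = scratch
    total = 0.0
    flags = set()
    for step in (-1, 1):
        npts, truncated = _ehh_walk_kernel(
            matT, carriers, core, step, cutoff, out_idx, out_ehh
        )
        acc, crossed, gap = _trapezoid_kernel(
            out_idx, out_ehh, npts, positions, cutoff, max_gap
        )
        if gap:
            flags.add(FLAG_GAP)
        elif not crossed and truncated:
            flags.add(FLAG_BORDER)
        total += acc
    return total, flags


def _bin_index(freq, maf_min, bin_width, n_bins):
    """Equal-width frequency bins on [maf_min, 1-maf_min]; edge ties go to
    the lower bin."""
    idx = np.ceil((np.asarray(freq) - maf_min) / bin_width).astype(int) - 1
    return np.clip(idx, 0, n_bins - 1)


def ihs_unstandardized(
    panel: HaplotypePanel,
    maf_min: float = 0.05,
    cutoff: float = DEFAULT_EHH_CUTOFF,
    max_gap: int = DEFAULT_MAX_GAP,
    border_policy: str = "discard",
) -> pd.DataFrame:
    """Per-site iHH_A, iHH_D and uniHS = ln(iHH_A/iHH_D) for one panel.

    Sites are pooled-MAF filtered at ``maf_min`` (strict >) and must be
    polarized.  ``border_policy``: "discard" excludes sites whose EHH never
    drops below the cutoff before a chromosome border or a >max_gap gap;
    "keep" scores them from the truncated integral.  Excluded/unscorable
    sites are retained in the table with NaN uniHS and a reason flag.
    """
    if border_policy not in ("discard", "keep"):
        raise ValueError("border_policy must be 'discard' or 'keep'")
    p_alt = panel.alt_freq()
    maf = np.minimum(p_alt, 1 - p_alt)
    keep = maf > maf_min
    if not keep.all():
        panel = panel.take_sites(np.nonzero(keep)[0])
    if (panel.ancestral == ANCESTRAL_UNKNOWN).any():
        raise ValueError("panel must be polarized before iHS (see polarize_panel)")

    matT = np.ascontiguousarray(panel.matrix.T)
    n_sites = panel.n_sites
    positions = panel.positions
    scratch = (np.empty(n_sites, dtype=np.int64), np.empty(n_sites, dtype=np.float64))
    rows = []
    for j in range(n_sites):
        derived_code = 1 - int(panel.ancestral[j])
        col = matT[j]
        p_derived = float((col == derived_code).mean())
        rec = {
            "chrom": panel.chrom,
            "pos": int(positions[j]),
            "derived_freq": p_derived,
            "ihh_A": np.nan,
            "ihh_D": np.nan,
            "uniHS": np.nan,
            "flags": "",
        }
        carr_A = np.nonzero(col == 1 - derived_code)[0]
        carr_D = np.nonzero(col == derived_code)[0]
        if min(carr_A.size, carr_D.size) < 2:
            rec["flags"] = FLAG_FEW_CARRIERS
            rows.append(rec)
            continue
        ihh_A, flags_A = _ihh_one_class(matT, positions, carr_A, j, cutoff, max_gap, scratch)
        ihh_D, flags_D = _ihh_one_class(matT, positions, carr_D, j, cutoff, max_gap, scratch)
        flags = flags_A | flags_D
        rec["ihh_A"], rec["ihh_D"] = ihh_A, ihh_D
        rec["flags"] = ",".join(sorted(flags))
        usable = not (flags and border_policy == "discard")
        if usable and ihh_A > 0 and ihh_D > 0:
            rec["uniHS"] = float(np.log(ihh_A / ihh_D))
        rows.append(rec)
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "derived_freq", "ihh_A", "ihh_D", "uniHS", "flags"],
    )
    n_scored = int(df["uniHS"].notna().sum())
    log.info("ihs_unstandardized: %d/%d sites scored", n_scored, len(df))
    return df


def standardize_ihs(
    df: pd.DataFrame,
    maf_min: float = 0.05,
    bin_width: float = DEFAULT_BIN_WIDTH,
    reference: pd.DataFrame = None,
) -> pd.DataFrame:
    """Standardize uniHS within derived-allele-frequency bins.

    Adds ``iHS = (uniHS - bin mean)/bin sd`` and ``piHS = -log10 of the
    two-sided standard-normal p-value``.  Bins with fewer than two scored
    sites leave their sites unscored (flagged); a zero-variance bin raises.

    The bin means and standard deviations come from ``reference`` when
    given (an unstandardized table from data believed neutral — e.g. the
    genome-wide scan, or pooled neutral simulations), else from ``df``
    itself.  Apply across all chromosomes of a scan at once so the
    empirical null is genome-wide; self-standardizing a region that is
    largely swept deflates the scores of the sweep itself.
    """
    df = df.copy()
    n_bins = max(int(round((1 - 2 * maf_min) / bin_width)), 1)
    df["iHS"] = np.nan
    df["piHS"] = np.nan
    scored = df["uniHS"].notna()
    bins = _bin_index(df.loc[scored, "derived_freq"], maf_min, bin_width, n_bins)
    uni = df.loc[scored, "uniHS"].to_numpy()

    ref = df if reference is None else reference
    ref_scored = ref["uniHS"].notna()
    ref_bins = _bin_index(
        ref.loc[ref_scored, "derived_freq"], maf_min, bin_width, n_bins
    )
    ref_uni = ref.loc[ref_scored, "uniHS"].to_numpy()
    stats = {}
    for b in np.unique(ref_bins):
        sel = ref_bins == b
        if sel.sum() < 2:
            continue
        sd = ref_uni[sel].std(ddof=1)
        if sd == 0:
            raise ValueError(f"frequency bin {b} has zero uniHS variance")
        stats[b] = (ref_uni[sel].mean(), sd)

    ihs = np.full(uni.size, np.nan)
    small = np.zeros(uni.size, dtype=bool)
    for b in np.unique(bins):
        sel = bins == b
        if b not in stats:
            small |= sel
            continue
        mean, sd = stats[b]
        ihs[sel] = (uni[sel] - mean) / sd
    df.loc[scored, "iHS"] = ihs
    pihs = -np.log10(np.clip(2.0 * norm.sf(np.abs(ihs)), 1e-320, None))
    df.loc[scored, "piHS"] = pihs
    if small.any():
        idx = df.index[scored][small]
        df.loc[idx, "flags"] = df.loc[idx, "flags"].map(
            lambda f: ",".join(sorted(set(filter(None, f.split(","))) | {FLAG_SMALL_BIN}))
        )
    return df


def ihs_scan(
    panel: HaplotypePanel,
    maf_min: float = 0.05,
    cutoff: float = DEFAULT_EHH_CUTOFF,
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_gap: int = DEFAULT_MAX_GAP,
    border_policy: str = "discard",
) -> pd.DataFrame:
    """Full within-population iHS scan of one panel (one chromosome).

    Convenience wrapper: :func:`ihs_unstandardized` followed by
    :func:`standardize_ihs`.  For multi-chromosome scans, run the first step
    per chromosome, concatenate, then standardize once.
    """
    df = ihs_unstandardized(
        panel,
        maf_min=maf_min,
        cutoff=cutoff,
        max_gap=max_gap,
        border_policy=border_policy,
    )
    return standardize_ihs(df, maf_min=maf_min, bin_width=bin_width)
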