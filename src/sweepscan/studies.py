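"""Replicate simulation studies used for validation and calibration.

These functions encode the package's standard desk-scale experiments:

* :func:`run_drift_study` — neutral two-population drift calibration: after a
  clean split of ``t`` generations at haploid size ``N``, genome-mean Hudson
  FST is expected near 1 - exp(-t/N).
* :func:`run_sweep_study` — the sweep-vs-neutral localization experiment:
  paired replicates of a three-population design (highland/lowland/outgroup)
  with and without a conditioned hard sweep on the highland branch, scanned
  with iHS, XP-CLR and PBS, plus the three-method intersection.

Protocol notes for the sweep study (all deliberate, see the methods note):
the 1 Mb replicate is small enough that a sweep contaminates its own
empirical background, so iHS standardization bin statistics and the XP-CLR
drift scale omega are estimated from the pooled neutral replicates — the
desk-scale analog of genome-wide calibration; EHH border truncation uses
the keep policy because on a 1 Mb "chromosome" the discard policy deletes
exactly the long-haplotype sites a sweep creates; the sweep-PBS comparison
uses the same 100 kb / 50 kb windows as the other two scans; the sweep
position sits mid-window rather than on the 50 kb lattice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffstats import fst_sites, pbs_windows
from .genodata import concat_panels, subset_panel
from .haplostats import ihs_unstandardized, standardize_ihs
from .scanner import call_outliers, make_windows, merge_regions, summarize
from .wfsim import POP_HI, POP_LO, POP_OUT, SimConfig, SweepConfig, simulate
from .xpclr import estimate_omega, xpclr_scan

log = logging.getLogger("sweepscan.studies")

REGION_LENGTH = 1_000_000
SWEEP_POSITION = 475_000  # mid-window, off the 50 kb window lattice
SWEEP_S = 0.05
SWEEP_T_START = 170
#: sampled sweep stage: near fixation but still segregating, the regime the
#: within-population haplotype test targets
SWEEP_FREQ_RANGE = (0.85, 0.97)
LOCALIZE_TOL = 100_000  # bp

#: XP-CLR settings for the study: two-point completeness grid (fixed or
#: 85%-complete sweep), three candidate sweep positions per window, and a
#: 256-point quadrature (the scan is rank-based; halving the grid does not
#: move window ranks)
def _xpclr_params():
    from .xpclr import XpclrParams

    return XpclrParams(
        completeness_grid=(1.0, 0.85), n_center_points=3, n_quad=256
    )


def sweep_study_config(seed: int, sweep: bool) -> SimConfig:
    """Study conditions for one replicate of the sweep-vs-neutral design."""
    return SimConfig(
        region_length=REGION_LENGTH,
        N_anc=1000, N_out=1000, N_hi=1000, N_lo=1000,
        t_out_split=600, t_hilo_split=200,
        mu=3e-7, rho=2e-7,
        n_sample={"highland": 30, "lowland": 30, "outgroup": 10},
        burn_in_factor=5.0,
        seed=seed,
        sweep=SweepConfig(
            position=SWEEP_POSITION, s=SWEEP_S, t_start=SWEEP_T_START,
            final_freq_range=SWEEP_FREQ_RANGE,
        )
        if sweep else None,
    )


@dataclass
class SweepStudyResult:
    n_reps: int
    ihs_hit_rate: float          # max-|iHS| window within +-100 kb of sweep
    xpclr_hit_rate: float        # max-score window contains the sweep site
    pbs_hit_rate: float          # sweep-window PBS > neutral 99th percentile
    pbs_outgroup_hit_rate: float  # same test for the outgroup branch (control)
    intersect_hit_rate: float    # 3-way intersection recovers the sweep
    intersect_neutral_window_fraction: float
    neutral_pihs6_fraction: float  # share of pooled neutral SNPs at piHS >= 6
    n_neutral_scored: int
    bin_abs_mean_max: float      # worst-bin |mean| after pooled standardization
    bin_sd_dev_max: float        # worst-bin |sd - 1|
    pbs_neutral_q99: float
    final_frequencies: list = field(default_factory=list)


def _window_hits_position(start, end, pos, tol=0):
    return (start - tol) < pos <= (end + tol)


def _replicate(seed, sweep):
    """Simulate one replicate and compute its per-method raw tables."""
    panels, truth = simulate(sweep_study_config(seed, sweep))
    hi = subset_panel(panels[POP_HI], POP_HI, 0.05)
    raw_ihs = ihs_unstandardized(hi, border_policy="keep")
    joint = concat_panels([panels[p] for p in (POP_HI, POP_LO, POP_OUT)])
    return {"panels": panels, "truth": truth, "raw_ihs": raw_ihs, "joint": joint}


def _scan_replicate(rep, windows, ref_pool, omega):
    """iHS/XP-CLR/PBS window tracks for one replicate."""
    std = standardize_ihs(rep["raw_ihs"], reference=ref_pool)
    scored = std[std["iHS"].notna()]
    ihs_win = summarize(
        scored["pos"], scored["iHS"].abs(), windows, "max", chrom="1", method="ihs"
    )
    xp_win = xpclr_scan(
        rep["panels"][POP_LO], rep["panels"][POP_HI], windows,
        params=_xpclr_params(), omega=omega,
    )
    pbs_win = pbs_windows(
        rep["joint"], POP_HI, POP_LO, POP_OUT, windows, estimator="wc"
    )
    pbs_out = pbs_windows(
        rep["joint"], POP_OUT, POP_HI, POP_LO, windows, estimator="wc"
    )
    return {"std": std, "ihs_win": ihs_win, "xp_win": xp_win,
            "pbs_win": pbs_win, "pbs_outgroup_win": pbs_out}


def _intersection_regions(scans, pbs_threshold, min_snps=10):
    """Three-way intersection of per-method outlier regions for one
    replicate: top-quartile iHS windows (the weakest localizer gets the
    broadest candidate set), top-decile XP-CLR windows, and PBS windows
    above the neutral-calibrated threshold."""
    from .scanner import intersect

    ihs_out = call_outliers(scans["ihs_win"], ("top_fraction", 0.25), min_snps)
    xp_w = scans["xp_win"].rename(columns={"score": "value"})
    xp_out = call_outliers(xp_w, ("top_fraction", 0.10), min_snps)
    pbs_w = scans["pbs_win"].rename(
        columns={"CHROM": "chrom", "BIN_START": "start", "BIN_END": "end",
                 "N_VARIANTS": "n_snps", "pbs": "value"}
    )
    pbs_out = call_outliers(pbs_w, ("threshold", pbs_threshold), min_snps)
    r_ihs = merge_regions(ihs_out, "ihs")
    r_xp = merge_regions(xp_out, "xpclr")
    r_pbs = merge_regions(pbs_out, "pbs")
    return intersect(intersect(r_ihs, r_xp), r_pbs)


def run_sweep_study(seed: int, n_reps: int = 20) -> SweepStudyResult:
    """Run the paired sweep-vs-neutral localization experiment."""
    windows = make_windows(REGION_LENGTH)
    base = (seed * 100_003) % (2**31 - 100_000)  # keep replicate seeds < 2**31
    sweeps = [_replicate(base + k, True) for k in range(n_reps)]
    neuts = [_replicate(base + 50_000 + k, False) for k in range(n_reps)]

    ref_pool = pd.concat([r["raw_ihs"] for r in neuts], ignore_index=True)
    omega = float(np.mean([
        estimate_omega(r["panels"][POP_LO], r["panels"][POP_HI]) for r in neuts
    ]))

    neut_scans = [_scan_replicate(r, windows, ref_pool, omega) for r in neuts]
    sweep_scans = [_scan_replicate(r, windows, ref_pool, omega) for r in sweeps]

    pbs_pool = np.concatenate([s["pbs_win"]["pbs"].to_numpy() for s in neut_scans])
    pbs_q99 = float(np.nanquantile(pbs_pool, 0.99))
    # the outgroup branch is longer, so its rotated PBS needs its own null
    pbs_og_pool = np.concatenate(
        [s["pbs_outgroup_win"]["pbs"].to_numpy() for s in neut_scans]
    )
    pbs_og_q99 = float(np.nanquantile(pbs_og_pool, 0.99))

    pos = SWEEP_POSITION
    ihs_hits = xp_hits = pbs_hits = pbs_og_hits = int_hits = 0
    for s in sweep_scans:
        w = s["ihs_win"].dropna(subset=["value"])
        best = w.loc[w["value"].idxmax()]
        ihs_hits += _window_hits_position(best["start"], best["end"], pos, LOCALIZE_TOL)
        xw = s["xp_win"].dropna(subset=["score"])
        bx = xw.loc[xw["score"].idxmax()]
        xp_hits += _window_hits_position(bx["start"], bx["end"], pos)
        pbs_hits += _sweep_window_value(s["pbs_win"], pos) > pbs_q99
        pbs_og_hits += _sweep_window_value(s["pbs_outgroup_win"], pos) > pbs_og_q99
        regions = _intersection_regions(s, pbs_q99)
        int_hits += any(
            _window_hits_position(r.start, r.end, pos, LOCALIZE_TOL) for r in regions
        )

    # fraction of neutral windows swallowed by the 3-way intersection
    covered = total = 0
    for s in neut_scans:
        regions = _intersection_regions(s, pbs_q99)
        total += len(windows)
        covered += sum(
            any(r.start < b and r.end > a for r in regions) for a, b in windows
        )

    pooled_std = standardize_ihs(ref_pool)
    scored = pooled_std[pooled_std["iHS"].notna()]
    from .haplostats import _bin_index

    bins = _bin_index(scored["derived_freq"], 0.05, 0.025, 36)
    means, sds = [], []
    for b in np.unique(bins):
        sub = scored["iHS"].to_numpy()[bins == b]
        if sub.size >= 2:
            means.append(abs(sub.mean()))
            sds.append(abs(sub.std(ddof=1) - 1))

    return SweepStudyResult(
        n_reps=n_reps,
        ihs_hit_rate=ihs_hits / n_reps,
        xpclr_hit_rate=xp_hits / n_reps,
        pbs_hit_rate=pbs_hits / n_reps,
        pbs_outgroup_hit_rate=pbs_og_hits / n_reps,
        intersect_hit_rate=int_hits / n_reps,
        intersect_neutral_window_fraction=covered / total,
        neutral_pihs6_fraction=float((scored["piHS"] >= 6).mean()),
        n_neutral_scored=int(len(scored)),
        bin_abs_mean_max=float(max(means)),
        bin_sd_dev_max=float(max(sds)),
        pbs_neutral_q99=pbs_q99,
        final_frequencies=[
            r["truth"].beneficial_frequency.get(POP_HI, 0.0) for r in sweeps
        ],
    )


def _sweep_window_value(pbs_df, pos):
    """Strongest PBS among the (overlapping) windows containing ``pos``."""
    contain = pbs_df[(pbs_df["BIN_START"] < pos) & (pos <= pbs_df["BIN_END"])]
    return float(contain["pbs"].max())


def drift_study_config(seed: int) -> SimConfig:
    """Two-population neutral drift calibration conditions: N = 500 haploid,
    split 50 generations ago, 10 kb with theta*L = 2*N*mu*L = 100 so each
    sampled replicate carries several hundred SNPs.  Recombination is set
    equal to mutation so the ~500 sites of a replicate span many
    near-independent genealogies; with long-range linkage the
    ratio-of-sums FST estimator is visibly biased below the independent-
    site drift expectation it is compared against."""
    return SimConfig(
        region_length=10_000,
        N_anc=500, N_out=500, N_hi=500, N_lo=500,
        t_out_split=60, t_hilo_split=50,
        mu=1e-5, rho=1e-5,
        n_sample=10,
        seed=seed,
    )


def run_drift_study(seed: int, n_reps: int = 20) -> dict:
    """Mean Hudson FST across neutral split replicates vs 1 - exp(-t/N)."""
    vals = []
    n_snps = []
    base = (seed * 99_991) % (2**31 - 100_000)
    for k in range(n_reps):
        panels, _ = simulate(drift_study_config(base + k))
        joint = concat_panels([panels[POP_HI], panels[POP_LO]])
        df = fst_sites(joint, POP_HI, POP_LO, "hudson")
        vals.append(float(df["num"].sum() / df["den"].sum()))
        n_snps.append(len(df))
    cfg = drift_study_config(0)
    expected = 1.0 - np.exp(-cfg.t_hilo_split / cfg.N_hi)
    return {
        "mean_fst": float(np.mean(vals)),
        "expected": float(expected),
        "per_replicate": vals,
        "mean_snps": float(np.mean(n_snps)),
    }
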