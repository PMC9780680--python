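"""Windowing, outlier calling, region merging, intersection and gene overlap.

This is the bookkeeping layer that turns per-SNP score tracks into candidate
regions and gene lists: sliding windows (default 100 kb with 50 kb step),
window-level summaries of SNP scores, threshold or top-fraction outlier
rules with deterministic tie-breaking, union-merging of overlapping outlier
windows into regions, cross-method intersection (by base-pair overlap or by
gene name), and region -> gene annotation by >= 1 bp interval overlap.

All windows and regions are 0-based half-open intervals; SNP membership
follows the centralized rule in :func:`sweepscan.genodata.sites_in_window`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import GeneModel, sites_in_window

log = logging.getLogger("sweepscan.scanner")


@dataclass
class CandidateRegion:
    """A merged run of outlier windows with provenance."""

    chrom: str
    start: int
    end: int
    methods: dict = field(default_factory=dict)  # method -> peak value
    genes: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def make_windows(chrom_length: int, size: int = 100_000, step: int = 50_000):
    """Sliding windows [k*step, k*step + size) with start + size <= length."""
    if not (0 < step <= size):
        raise ValueError("need 0 < step <= size")
    if size > chrom_length:
        log.warning(
            "window size %d exceeds chromosome length %d: no windows",
            size, chrom_length,
        )
        return []
    return [
        (s, s + size) for s in range(0, chrom_length - size + 1, step)
    ]


def summarize(
    positions,
    values,
    windows,
    reducer="max",
    chrom=None,
    method=None,
) -> pd.DataFrame:
    """Aggregate a sorted per-SNP score track into window scores.

    ``reducer`` is ``"max"``, ``"mean"``, ``("count_above", t)`` or a
    callable over the window's value array.  NaN scores are ignored inside a
    window; windows with no scored SNP get NaN.
    """
    if isinstance(reducer, str):
        if reducer == "max":
            fn = np.max
        elif reducer == "mean":
            fn = np.mean
        else:
            raise ValueError(f"unknown reducer {reducer!r}")
    elif isinstance(reducer, tuple) and reducer[0] == "count_above":
        t = reducer[1]
        fn = lambda v: float((v >= t).sum())
    elif callable(reducer):
        fn = reducer
    else:
        raise ValueError(f"unknown reducer {reducer!r}")

    positions = np.asarray(positions)
    values = np.asarray(values, dtype=float)
    if positions.size and np.any(np.diff(positions) < 0):
        raise ValueError("track must be sorted by position")
    rows = []
    for a, b in _bounds_iter(windows):
        sl = sites_in_window(positions, a, b)
        v = values[sl]
        v = v[~np.isnan(v)]
        rows.append(
            (chrom, a, b, float(fn(v)) if v.size else np.nan, v.size, method)
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "value", "n_snps", "method"]
    )


def call_outliers(windows: pd.DataFrame, rule, min_snps: int = 0) -> pd.DataFrame:
    """Select outlier windows by an absolute threshold or a top fraction.

    ``rule`` is ``("threshold", v)`` (keep value >= v) or
    ``("top_fraction", q)`` (keep the ceil(q*M) highest of the M non-NA
    windows, ties broken by value desc, then chrom, then start).  Windows
    with fewer than ``min_snps`` SNPs are excluded first.
    """
    df = windows[(windows["n_snps"] >= min_snps) & windows["value"].notna()]
    if df.empty:
        raise ValueError("no scored windows to call outliers on")
    kind, arg = rule
    if kind == "threshold":
        return df[df["value"] >= arg].reset_index(drop=True)
    if kind == "top_fraction":
        if not (0 < arg < 1):
            raise ValueError("top fraction must be in (0, 1)")
        m = math.ceil(arg * len(df))
        ordered = df.sort_values(
            ["value", "chrom", "start"], ascending=[False, True, True],
            kind="mergesort",
        )
        return ordered.head(m).sort_values(["chrom", "start"]).reset_index(drop=True)
    raise ValueError(f"unknown outlier rule {kind!r}")


def merge_regions(outliers: pd.DataFrame, method=None) -> list:
    """Union overlapping or book-ended outlier windows into regions.

    Peak value per region is the max member value.  Idempotent and
    independent of input row order.
    """
    if outliers.empty:
        return []
    df = outliers.sort_values(["chrom", "start"])
    regions = []
    cur = None
    for row in df.itertuples(index=False):
        m = method or getattr(row, "method", None) or "score"
        if (
            cur is not None
            and row.chrom == cur.chrom
            and row.start <= cur.end
        ):
            cur.end = max(cur.end, int(row.end))
            cur.methods[m] = max(cur.methods.get(m, -np.inf), float(row.value))
        else:
            cur = CandidateRegion(
                chrom=row.chrom, start=int(row.start), end=int(row.end),
                methods={m: float(row.value)},
            )
            regions.append(cur)
    return regions


def intersect(regionsA, regionsB, mode: str = "region"):
    """Shared signal between two region lists.

    region mode: base-pair intersections of overlapping regions, with the
    provenance of both parents merged.  gene mode: the set of gene names
    present in both lists (regions must be annotated first).
    """
    if mode == "gene":
        gA = {g for r in regionsA for g in r.genes}
        gB = {g for r in regionsB for g in r.genes}
        return sorted(gA & gB)
    if mode != "region":
        raise ValueError("mode must be 'region' or 'gene'")
    out = []
    for ra in regionsA:
        for rb in regionsB:
            if ra.chrom != rb.chrom:
                continue
            a, b = max(ra.start, rb.start), min(ra.end, rb.end)
            if a < b:
                methods = dict(ra.methods)
                for k, v in rb.methods.items():
                    methods[k] = max(methods.get(k, -np.inf), v)
                out.append(
                    CandidateRegion(chrom=ra.chrom, start=a, end=b, methods=methods)
                )
    out.sort(key=lambda r: (r.chrom, r.start, r.end))
    return out


def annotate_genes(regions, genes) -> list:
    """Attach every gene overlapping each region by >= 1 bp (half-open)."""
    by_chrom = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for r in regions:
        r.genes = sorted(
            {
                g.name
                for g in by_chrom.get(r.chrom, [])
                if g.start < r.end and g.end > r.start
            }
        )
    return regions


def regions_to_frame(regions) -> pd.DataFrame:
    """Flatten regions into a Table-2-like DataFrame (one row per region)."""
    rows = []
    for r in regions:
        row = {"chrom": r.chrom, "start": r.start, "end": r.end,
               "length": r.length, "genes": ",".join(r.genes)}
        for m, v in sorted(r.methods.items()):
            row[f"peak_{m}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_bed(regions, path):
    with open(path, "w") as fh:
        for r in regions:
            name = ";".join(sorted(r.methods)) or "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")


def _bounds_iter(windows):
    if isinstance(windows, pd.DataFrame):
        return list(zip(windows["start"], windows["end"]))
    return list(windows)
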