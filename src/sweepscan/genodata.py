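"""Phased genotype data model and I/O.

The central container is :class:`HaplotypePanel`, a haplotype-by-site 0/1
allele matrix with physical positions, REF/ALT alleles, ancestral-allele
polarity and a sample->population map.  Every statistic in the package
(EHH/iHS, XP-CLR, FST/PBS, pi, LD) operates on this container.

Coordinate conventions
----------------------
Variant sites keep their 1-based VCF positions.  All windows and gene
intervals are 0-based half-open ``[start, end)``.  The single boundary rule —
a 1-based position ``p`` lies in window ``[a, b)`` iff ``a < p <= b`` — is
centralized in :func:`sites_in_window`; nothing else in the package compares
positions to window bounds directly.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
from cyvcf2 import VCF

log = logging.getLogger("sweepscan.genodata")

ANCESTRAL_UNKNOWN = -1

#: Policies for assigning ancestral alleles when the VCF carries no AA tag.
POLARIZE_POLICIES = ("ref", "outgroup-major", "skip")


class EmptyPanelError(ValueError):
    """Raised when ingestion or filtering leaves no usable sites."""


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes for one chromosome.

    Attributes
    ----------
    chrom : str
        Chromosome identifier.
    positions : ndarray of int64
        1-based physical coordinates, strictly increasing.
    alleles : list of (ref, alt)
        Per-site allele pair.
    matrix : ndarray of uint8, shape (n_haplotypes, n_sites)
        Allele codes in {0, 1}; rows 2k and 2k+1 are the two haplotypes of
        sample k.
    ancestral : ndarray of int8
        Per-site ancestral allele code: 0, 1, or -1 (unknown).
    sample_ids : list of str
        One entry per diploid sample (half the number of matrix rows).
    pop_of : dict
        Sample id -> population label.
    """

    chrom: str
    positions: np.ndarray
    alleles: list
    matrix: np.ndarray
    ancestral: np.ndarray
    sample_ids: list
    pop_of: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        self.ancestral = np.asarray(self.ancestral, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (haplotypes x sites)")
        if self.matrix.shape[0] % 2 != 0:
            raise ValueError("matrix must have an even number of haplotype rows")
        if len(self.sample_ids) * 2 != self.matrix.shape[0]:
            raise ValueError("sample_ids length must be half the haplotype count")
        if self.matrix.shape[1] != self.positions.size:
            raise ValueError("positions/matrix site-count mismatch")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.matrix.size and self.matrix.max() > 1:
            raise ValueError("matrix entries must be 0 or 1")
        if not np.all(np.isin(self.ancestral, (-1, 0, 1))):
            raise ValueError("ancestral codes must be in {-1, 0, 1}")

    # -- basic geometry -------------------------------------------------

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def populations(self):
        return sorted({self.pop_of[s] for s in self.sample_ids if s in self.pop_of})

    def hap_indices(self, pops) -> np.ndarray:
        """Row indices of haplotypes belonging to the named populations."""
        if isinstance(pops, str):
            pops = [pops]
        pops = set(pops)
        known = set(self.pop_of.get(s) for s in self.sample_ids)
        unknown = pops - known
        if unknown:
            raise KeyError(
                f"unknown population label(s) {sorted(unknown)}; "
                f"valid labels: {sorted(l for l in known if l is not None)}"
            )
        rows = []
        for k, s in enumerate(self.sample_ids):
            if self.pop_of.get(s) in pops:
                rows.extend((2 * k, 2 * k + 1))
        return np.asarray(rows, dtype=np.intp)

    # -- frequencies ----------------------------------------------------

    def alt_freq(self, rows=None) -> np.ndarray:
        """ALT (code-1) allele frequency per site over the given rows."""
        sub = self.matrix if rows is None else self.matrix[rows]
        if sub.shape[0] == 0:
            raise ValueError("no haplotypes selected")
        return sub.mean(axis=0)

    def derived_freq(self, rows=None) -> np.ndarray:
        """Derived-allele frequency; NaN where ancestral is unknown."""
        p_alt = self.alt_freq(rows)
        out = np.where(self.ancestral == 0, p_alt, 1.0 - p_alt)
        return np.where(self.ancestral == ANCESTRAL_UNKNOWN, np.nan, out)

    # -- subsetting -----------------------------------------------------

    def take_sites(self, idx) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return replace(
            self,
            positions=self.positions[idx],
            alleles=[self.alleles[i] for i in np.atleast_1d(idx)],
            matrix=self.matrix[:, idx],
            ancestral=self.ancestral[idx],
        )

    def take_samples(self, sample_idx) -> "HaplotypePanel":
        sample_idx = np.asarray(sample_idx)
        rows = np.stack([2 * sample_idx, 2 * sample_idx + 1], axis=1).ravel()
        ids = [self.sample_ids[i] for i in sample_idx]
        return replace(
            self,
            matrix=self.matrix[rows],
            sample_ids=ids,
            pop_of={s: self.pop_of[s] for s in ids if s in self.pop_of},
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene interval, stored 0-based half-open regardless of source format."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.name}: start must be < end")


# ---------------------------------------------------------------------------
# Centralized window/position boundary rule
# ---------------------------------------------------------------------------

def sites_in_window(positions: np.ndarray, start: int, end: int):
    """Slice of site indices whose 1-based position falls in [start, end).

    The window is 0-based half-open, positions are 1-based; position ``p``
    belongs iff ``start < p <= end``.  Assumes ``positions`` sorted.
    """
    lo = np.searchsorted(positions, start, side="right")
    hi = np.searchsorted(positions, end, side="right")
    return slice(lo, hi)


# ---------------------------------------------------------------------------
# VCF ingestion / export
# ---------------------------------------------------------------------------

_BASES = {"A", "C", "G", "T"}


def _parse_region(region):
    chrom, _, rng = region.partition(":")
    if not rng:
        return chrom, None, None
    a, _, b = rng.partition("-")
    return chrom, int(a), int(b)


def read_vcf(path, region=None, pop_of=None) -> HaplotypePanel:
    """Read phased biallelic SNPs from a VCF into a :class:`HaplotypePanel`.

    Records that are not biallelic SNPs, or that contain any unphased,
    half-called or missing genotype, are skipped (counts logged).  The
    ancestral code is set from the INFO ``AA`` tag when it matches REF or ALT
    case-insensitively, else left unknown.

    Parameters
    ----------
    region : str, optional
        ``chrom`` or ``chrom:start-end`` (1-based inclusive bounds, as in
        tabix region strings); filtering is positional, no index required.
    pop_of : dict, optional
        Sample -> population map to attach to the panel.
    """
    want_chrom = want_lo = want_hi = None
    if region is not None:
        want_chrom, want_lo, want_hi = _parse_region(region)

    vcf = VCF(os.fspath(path))
    samples = list(vcf.samples)
    positions, alleles, ancestral, columns = [], [], [], []
    chrom = None
    n_skip = {"multiallelic_or_not_snp": 0, "unphased_or_missing": 0, "bad_aa": 0}

    for var in vcf:
        if want_chrom is not None:
            if var.CHROM != want_chrom:
                continue
            if want_lo is not None and not (want_lo <= var.POS <= want_hi):
                continue
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            raise ValueError(
                "panel spans multiple chromosomes; pass region= to select one"
            )
        if (
            len(var.ALT) != 1
            or var.REF.upper() not in _BASES
            or var.ALT[0].upper() not in _BASES
        ):
            n_skip["multiallelic_or_not_snp"] += 1
            continue
        gts = var.genotypes  # [a, b, phased] per sample
        ok = all(len(g) == 3 and g[0] >= 0 and g[1] >= 0 and g[2] for g in gts)
        if not ok:
            n_skip["unphased_or_missing"] += 1
            continue
        col = np.fromiter(
            (a for g in gts for a in (g[0], g[1])), dtype=np.uint8, count=2 * len(gts)
        )
        aa_code = ANCESTRAL_UNKNOWN
        aa = var.INFO.get("AA")
        if aa is not None:
            aa = str(aa).upper()
            if aa == var.REF.upper():
                aa_code = 0
            elif aa == var.ALT[0].upper():
                aa_code = 1
            else:
                n_skip["bad_aa"] += 1
        positions.append(var.POS)
        alleles.append((var.REF.upper(), var.ALT[0].upper()))
        ancestral.append(aa_code)
        columns.append(col)
    vcf.close()

    dropped = {k: v for k, v in n_skip.items() if v}
    if dropped:
        log.info("read_vcf(%s): skipped records %s", path, dropped)
    if not positions:
        raise EmptyPanelError(f"no usable phased biallelic SNP records in {path}")

    matrix = np.stack(columns, axis=1)
    return HaplotypePanel(
        chrom=chrom,
        positions=np.asarray(positions, dtype=np.int64),
        alleles=alleles,
        matrix=matrix,
        ancestral=np.asarray(ancestral, dtype=np.int8),
        sample_ids=samples,
        pop_of=dict(pop_of or {}),
    )


def write_vcf(panel: HaplotypePanel, path) -> None:
    """Write a panel as VCF v4.2 text (gzip if path ends in .gz).

    AA INFO is emitted for sites with known ancestral polarity, so a
    write/read round-trip preserves positions, alleles, phased genotypes and
    polarity exactly.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral Allele">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        mat = panel.matrix
        for j in range(panel.n_sites):
            ref, alt = panel.alleles[j]
            anc = panel.ancestral[j]
            info = "." if anc == ANCESTRAL_UNKNOWN else f"AA={ref if anc == 0 else alt}"
            gts = "\t".join(
                f"{mat[2 * k, j]}|{mat[2 * k + 1, j]}"
                for k in range(len(panel.sample_ids))
            )
            fh.write(
                f"{panel.chrom}\t{panel.positions[j]}\t.\t{ref}\t{alt}\t.\t.\t"
                f"{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Population map, gene annotation
# ---------------------------------------------------------------------------

def _open_text(path):
    return gzip.open(path, "rt") if str(path).endswith(".gz") else open(path, "rt")


def read_pop_map(path) -> dict:
    """Two-column TSV ``sample<TAB>population`` -> dict; duplicates rejected."""
    out = {}
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected two columns")
            sample, pop = parts[0], parts[1]
            if sample in out:
                raise ValueError(f"{path}:{ln}: duplicated sample id {sample!r}")
            out[sample] = pop
    if not out:
        raise ValueError(f"{path}: empty population map")
    return out


def read_genes(path, fmt=None) -> list:
    """Read gene intervals from BED (0-based half-open) or GFF3 (1-based closed).

    GFF3 rows of type other than ``gene`` are ignored; names come from BED
    column 4 or the GFF3 ``ID``/``Name`` attribute.  Rows with end <= start
    after conversion are rejected with a logged warning.
    """
    if fmt is None:
        base = str(path).lower()
        if base.endswith(".gz"):
            base = base[:-3]
        fmt = "gff3" if base.endswith((".gff", ".gff3")) else "bed"
    if fmt not in ("bed", "gff3"):
        raise ValueError(f"format must be 'bed' or 'gff3', got {fmt!r}")

    genes, n_bad = [], 0
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            try:
                if fmt == "bed":
                    chrom, start, end = f[0], int(f[1]), int(f[2])
                    name = f[3] if len(f) > 3 else f"{chrom}:{start}-{end}"
                else:
                    if f[2] != "gene":
                        continue
                    chrom = f[0]
                    start, end = int(f[3]) - 1, int(f[4])  # to 0-based half-open
                    attrs = dict(
                        kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                    )
                    name = attrs.get("Name") or attrs.get("ID") or f"{chrom}:{start}"
                genes.append(GeneModel(name=name, chrom=chrom, start=start, end=end))
            except (ValueError, IndexError):
                n_bad += 1
                log.warning("read_genes(%s): rejected malformed row %d", path, ln)
    if n_bad:
        log.info("read_genes(%s): %d malformed rows rejected", path, n_bad)
    # de-duplicate on the full key
    seen, uniq = set(), []
    for g in genes:
        key = (g.name, g.chrom, g.start, g.end)
        if key not in seen:
            seen.add(key)
            uniq.append(g)
    return uniq


def read_chrom_lengths(path) -> dict:
    """Two-column TSV ``chrom<TAB>length_bp`` -> dict."""
    out = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            out[parts[0]] = int(parts[1])
    if not out:
        raise ValueError(f"{path}: empty chromosome-length table")
    return out


# ---------------------------------------------------------------------------
# Filtering / polarity
# ---------------------------------------------------------------------------

def subset_panel(panel: HaplotypePanel, pops, maf_min: float = 0.05) -> HaplotypePanel:
    """Restrict to populations and drop sites with pooled MAF <= maf_min.

    Retains sites whose pooled minor-allele frequency over the kept
    haplotypes is strictly greater than ``maf_min``; monomorphic sites are
    always removed for any ``maf_min >= 0``.  Idempotent for fixed arguments.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    if isinstance(pops, str):
        pops = [pops]
    if not pops:
        raise ValueError("pops must be non-empty")
    rows = panel.hap_indices(pops)
    sample_idx = np.unique(rows // 2)
    sub = panel.take_samples(sample_idx)
    p = sub.alt_freq()
    maf = np.minimum(p, 1.0 - p)
    keep = np.nonzero(maf > maf_min)[0]
    n_drop = sub.n_sites - keep.size
    if n_drop:
        log.info(
            "subset_panel: dropped %d/%d sites at MAF <= %g", n_drop, sub.n_sites, maf_min
        )
    if keep.size == 0:
        raise EmptyPanelError("no sites left after MAF filtering")
    return sub.take_sites(keep)


def polarize_panel(
    panel: HaplotypePanel, policy: str = "ref", outgroup_pop=None
) -> HaplotypePanel:
    """Fill unknown ancestral codes according to a fallback policy.

    policy='ref'             treat REF as ancestral (logged);
    policy='outgroup-major'  ancestral = major allele in ``outgroup_pop``;
    policy='skip'            drop sites with unknown polarity.
    Sites with known polarity are never altered.
    """
    if policy not in POLARIZE_POLICIES:
        raise ValueError(f"policy must be one of {POLARIZE_POLICIES}")
    unknown = panel.ancestral == ANCESTRAL_UNKNOWN
    if not unknown.any():
        return panel
    anc = panel.ancestral.copy()
    if policy == "ref":
        log.warning(
            "polarize_panel: assuming REF ancestral at %d unpolarized sites",
            int(unknown.sum()),
        )
        anc[unknown] = 0
        return replace(panel, ancestral=anc)
    if policy == "outgroup-major":
        if outgroup_pop is None:
            raise ValueError("outgroup-major policy needs outgroup_pop")
        rows = panel.hap_indices(outgroup_pop)
        p_alt = panel.alt_freq(rows)
        anc[unknown] = np.where(p_alt[unknown] <= 0.5, 0, 1)
        return replace(panel, ancestral=anc)
    # skip
    keep = np.nonzero(~unknown)[0]
    if keep.size == 0:
        raise EmptyPanelError("polarize_panel(skip): no polarized sites remain")
    return panel.take_sites(keep)


def concat_panels(panels) -> HaplotypePanel:
    """Join panels of disjoint sample sets on an identical site frame."""
    first = panels[0]
    for p in panels[1:]:
        if (
            p.chrom != first.chrom
            or not np.array_equal(p.positions, first.positions)
            or p.alleles != first.alleles
        ):
            raise ValueError("panels must share chrom/positions/alleles")
    ids = [s for p in panels for s in p.sample_ids]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids across panels")
    pop_of = {}
    for p in panels:
        pop_of.update(p.pop_of)
    return HaplotypePanel(
        chrom=first.chrom,
        positions=first.positions.copy(),
        alleles=list(first.alleles),
        matrix=np.vstack([p.matrix for p in panels]),
        ancestral=first.ancestral.copy(),
        sample_ids=ids,
        pop_of=pop_of,
    )
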