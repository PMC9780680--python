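"""Forward-time Wright-Fisher simulator of a three-population sweep design.

Simulates the demography implied by a highland/lowland/outgroup contrast: an
ancestral population burns in to mutation-drift equilibrium, an outgroup
splits off first, then two sister populations split, and an optional hard
selective sweep acts on the "highland" branch.  The simulator emits phased
:class:`~sweepscan.genodata.HaplotypePanel` objects (one per population, on a
shared site frame) plus a :class:`SimTruth` record of the sweep ground truth,
and can write them as a phased VCF with AA tags, a population map and a truth
TSV.

Model
-----
Haploid Wright-Fisher generations: each of N offspring picks a parent
(uniformly, or with probability proportional to fitness 1 + s for carriers
of the beneficial allele), recombines with a second parent through
Poisson(rho * L) uniformly placed crossovers, and receives Poisson(mu * L)
new infinite-sites mutations at distinct integer positions.  Populations
split by copying.  The sweep allele is injected as a single copy on the
highland branch ``t_start`` generations before present; with
``condition_on_establishment`` the highland branch is re-simulated from the
injection point until the allele establishes (and, optionally, lands in a
requested present-day frequency band), up to a retry cap.

All randomness flows from one integer-seeded ``numpy`` Generator, so a fixed
seed reproduces output bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .genodata import HaplotypePanel

log = logging.getLogger("sweepscan.wfsim")


@njit(cache=True)
def _build_children(mat, S, pos, pa, rec_rows, pb, bks, boff, mut_rows, child):
    """Assemble one offspring generation into child[:, :S+m].

    ``mat``/``child`` are full C-contiguous capacity buffers; only the first
    S (respectively S+m) columns are live.  Row i copies parent pa[i]; rows
    listed in rec_rows alternate between their two parents at the sorted
    breakpoints bks[boff[r]:boff[r+1]]; column S+j is a fresh mutation
    carried only by mut_rows[j].
    """
    N = mat.shape[0]
    m = mut_rows.size
    for i in range(N):
        src = mat[pa[i]]
        dst = child[i]
        for s in range(S):
            dst[s] = src[s]
        for j in range(m):
            dst[S + j] = 0
    for r in range(rec_rows.size):
        i = rec_rows[r]
        b = pb[r]
        lo, hi = boff[r], boff[r + 1]
        dst = child[i]
        src = mat[b]
        if hi - lo == 1:  # single crossover: branchless select (common case)
            b0 = bks[lo]
            for s in range(S):
                t = np.uint8(pos[s] > b0)
                dst[s] = dst[s] * (1 - t) + src[s] * t
        else:
            for s in range(S):
                parity = 0
                p = pos[s]
                for t in range(lo, hi):
                    if bks[t] < p:
                        parity += 1
                if parity % 2 == 1:
                    dst[s] = src[s]
    for j in range(m):
        child[mut_rows[j], S + j] = 1


@njit(cache=True)
def _gather_cols(mat, keep_idx, out):
    """out[:, j] = mat[:, keep_idx[j]] into the full scratch buffer."""
    N = mat.shape[0]
    K = keep_idx.size
    for i in range(N):
        src = mat[i]
        dst = out[i]
        for j in range(K):
            dst[j] = src[keep_idx[j]]


@njit(cache=True)
def _col_counts(mat, S, out):
    """Derived-allele count of each live column."""
    N = mat.shape[0]
    for j in range(S):
        out[j] = 0
    for i in range(N):
        src = mat[i]
        for j in range(S):
            out[j] += src[j]

_BASES = np.array(["A", "C", "G", "T"])

POP_HI, POP_LO, POP_OUT = "highland", "lowland", "outgroup"


class EstablishmentError(RuntimeError):
    """Sweep allele failed to establish within the retry cap."""


@dataclass
class SweepConfig:
    """Hard sweep on the highland branch.

    With ``condition_on_establishment`` the highland branch is re-simulated
    from the injection point until an attempt both escapes early stochastic
    loss (the allele reaches the branching-process establishment scale of
    ~1/s copies) and is still segregating or fixed at sampling time.
    """

    position: int
    s: float
    t_start: int
    condition_on_establishment: bool = True
    #: optional (low, high) bounds on the population frequency of the
    #: beneficial allele at sampling time; attempts outside the band are
    #: re-run (conditioning a simulated sweep on its present-day frequency
    #: is the standard way to study a chosen sweep stage)
    final_freq_range: Optional[tuple] = None
    max_retries: int = 200

    @property
    def establishment_copies(self) -> int:
        return max(2, int(np.ceil(1.0 / self.s)))


@dataclass
class SimConfig:
    """Simulation parameters.

    Haploid population sizes; times in generations before present; rates per
    bp per generation.  The scaled-down defaults (N = 1000 with mu and rho
    raised well above per-generation point rates) preserve the population
    scaled parameters that matter: theta = 2*N*mu = 6e-4/bp approaches
    cattle-like SNP density, and rho keeps the expected hard-sweep footprint
    s / (rho * ln(2Ns)) near 50 kb.
    """

    region_length: int = 1_000_000
    N_anc: int = 1000
    N_out: int = 1000
    N_hi: int = 1000
    N_lo: int = 1000
    t_out_split: int = 600
    t_hilo_split: int = 200
    mu: float = 3e-7
    rho: float = 2e-7
    sweep: Optional[SweepConfig] = None
    #: diploids sampled per population; either one int for all populations
    #: or a dict keyed by "highland"/"lowland"/"outgroup"
    n_sample: object = 10
    seed: int = 0
    burn_in_factor: float = 10.0
    chrom: str = "1"

    def samples_per_pop(self) -> dict:
        if isinstance(self.n_sample, dict):
            return {
                p: int(self.n_sample.get(p, 10)) for p in (POP_HI, POP_LO, POP_OUT)
            }
        return {p: int(self.n_sample) for p in (POP_HI, POP_LO, POP_OUT)}

    def validate(self):
        if not (self.t_out_split > self.t_hilo_split > 0):
            raise ValueError("need t_out_split > t_hilo_split > 0")
        for name in ("N_anc", "N_out", "N_hi", "N_lo"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if min(self.mu, self.rho) < 0:
            raise ValueError("mu and rho must be non-negative")
        for pop, n in self.samples_per_pop().items():
            N = {POP_HI: self.N_hi, POP_LO: self.N_lo, POP_OUT: self.N_out}[pop]
            if 2 * n > N:
                raise ValueError(
                    f"cannot sample {n} diploids from {pop} of haploid size {N}"
                )
        if self.sweep is not None:
            sw = self.sweep
            if not (0 < sw.s <= 1):
                raise ValueError("selection coefficient must be in (0, 1]")
            if not (1 <= sw.position <= self.region_length):
                raise ValueError(
                    f"sweep position {sw.position} outside region "
                    f"[1, {self.region_length}]"
                )
            if not (0 < sw.t_start <= self.t_hilo_split):
                raise ValueError(
                    "sweep t_start must lie on the highland branch "
                    "(0 < t_start <= t_hilo_split)"
                )


@dataclass
class SimTruth:
    """Ground truth of a run, for downstream acceptance checks."""

    sweep_position: Optional[int]
    s: Optional[float]
    beneficial_frequency: dict = field(default_factory=dict)  # pop -> freq
    fixation_generation: Optional[int] = None  # generations before present


class _Branch:
    """One evolving population: active segregating columns + fixed positions.

    Haplotypes live in a capacity buffer (``buf``) with ``S`` active columns
    and a scratch buffer (``alt``) of equal role, swapped every generation to
    avoid per-generation allocation.
    """

    __slots__ = ("buf", "alt", "S", "pos", "fixed")

    def __init__(self, N, cap, pos, fixed):
        self.buf = np.empty((N, cap), dtype=np.uint8)
        self.alt = np.empty((N, cap), dtype=np.uint8)
        self.S = 0
        self.pos = pos  # (S,) int64, unsorted
        self.fixed = fixed  # set of int positions fixed-derived on this lineage

    @property
    def mat(self):
        return self.buf[:, : self.S]

    def ensure_alt(self, need):
        if self.alt.shape[1] < need:
            self.alt = np.empty(
                (self.buf.shape[0], int(need * 1.3) + 64), dtype=np.uint8
            )

    def swap(self, new_S):
        self.buf, self.alt = self.alt, self.buf
        self.S = new_S

    def set_mat(self, mat):
        """Replace active columns with a dense (N, S) array."""
        S = mat.shape[1]
        if self.buf.shape[1] < S:
            self.buf = np.empty((mat.shape[0], int(S * 1.3) + 64), dtype=np.uint8)
        self.buf[:, :S] = mat
        self.S = S


class _Engine:
    def __init__(self, config: SimConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.L = config.region_length
        self.R = config.rho * self.L  # crossovers per offspring
        self.U = config.mu * self.L  # mutations per offspring
        self._refs: dict = {}  # position -> number of branches holding it

    # -- position registry (infinite sites) -----------------------------

    def _hold(self, p):
        self._refs[p] = self._refs.get(p, 0) + 1

    def _release(self, p):
        c = self._refs[p] - 1
        if c:
            self._refs[p] = c
        else:
            del self._refs[p]

    def _draw_positions(self, m):
        """m distinct fresh integer positions in [1, L], avoiding live sites."""
        out = []
        batch = set()
        while len(out) < m:
            for cand in self.rng.integers(1, self.L + 1, size=m - len(out)):
                cand = int(cand)
                if cand in self._refs or cand in batch:
                    continue
                batch.add(cand)
                out.append(cand)
        for p in out:
            self._hold(p)
        return np.asarray(out, dtype=np.int64)

    # -- branch bookkeeping ---------------------------------------------

    def new_branch(self, N):
        return _Branch(N, 256, np.zeros(0, dtype=np.int64), set())

    def copy_branch(self, br: _Branch, N) -> _Branch:
        """Split: daughter of size N founded from br (resampled if N differs)."""
        if N == br.buf.shape[0]:
            mat = br.mat
        else:
            rows = self.rng.integers(0, br.buf.shape[0], size=N)
            mat = br.mat[rows]
        for p in br.pos.tolist():
            self._hold(p)
        for p in br.fixed:
            self._hold(p)
        child = _Branch(N, br.S + 64, br.pos.copy(), set(br.fixed))
        child.set_mat(mat)
        return child

    def drop_branch(self, br: _Branch):
        for p in br.pos.tolist():
            self._release(p)
        for p in br.fixed:
            self._release(p)

    # -- one generation --------------------------------------------------

    COMPACT_EVERY = 4  # generations between lost/fixed column sweeps

    def _step(self, br: _Branch, sel_idx=None, s=0.0):
        """Advance one generation (no compaction; columns only appended)."""
        rng = self.rng
        mat, pos = br.mat, br.pos
        N, S = mat.shape
        if sel_idx is not None:
            w = 1.0 + s * mat[:, sel_idx]
            pw = w / w.sum()
            pa = rng.choice(N, size=N, p=pw).astype(np.int64)
        else:
            pw = None
            pa = rng.integers(0, N, size=N)
        # recombination plan
        n_rec = 0
        if self.R > 0:
            nx = rng.poisson(self.R, size=N)
            rec_rows = np.nonzero(nx)[0]
            n_rec = rec_rows.size
        if n_rec:
            ks = nx[rec_rows]
            if pw is None:
                pb = rng.integers(0, N, size=n_rec)
            else:
                pb = rng.choice(N, size=n_rec, p=pw).astype(np.int64)
            bks = rng.uniform(0.0, self.L, size=int(ks.sum()))
            boff = np.zeros(n_rec + 1, dtype=np.int64)
            np.cumsum(ks, out=boff[1:])
            for r in range(n_rec):  # sort each row's breakpoints
                bks[boff[r]:boff[r + 1]].sort()
        else:
            rec_rows = np.zeros(0, dtype=np.int64)
            pb = np.zeros(0, dtype=np.int64)
            bks = np.zeros(0)
            boff = np.zeros(1, dtype=np.int64)
        # mutation plan
        if self.U > 0:
            cnt = rng.poisson(self.U, size=N)
            mut_rows = np.repeat(np.arange(N), cnt)
        else:
            mut_rows = np.zeros(0, dtype=np.int64)
        m = mut_rows.size
        br.ensure_alt(S + m)
        _build_children(
            br.buf, S, pos, pa, rec_rows.astype(np.int64), pb, bks, boff,
            mut_rows.astype(np.int64), br.alt,
        )
        if m:
            pos = np.concatenate([pos, self._draw_positions(m)])
        br.swap(S + m)
        br.pos = pos

    def _compact(self, br: _Branch, absorb_fixed=False):
        """Drop lost columns; move fixed columns to the branch's fixed set
        (or absorb them into the reference during burn-in)."""
        pos = br.pos
        S = br.S
        if S == 0:
            return
        csum = np.empty(S, dtype=np.int64)
        _col_counts(br.buf, S, csum)
        lost = csum == 0
        fixd = csum == br.buf.shape[0]
        if not (lost.any() or fixd.any()):
            return
        for p in pos[lost].tolist():
            self._release(p)
        for p in pos[fixd].tolist():
            if absorb_fixed:
                self._release(p)
            else:
                br.fixed.add(p)
        keep_idx = np.nonzero(~(lost | fixd))[0]
        br.ensure_alt(keep_idx.size)
        _gather_cols(br.buf, keep_idx, br.alt)
        br.swap(keep_idx.size)
        br.pos = pos[keep_idx]

    def evolve(self, br: _Branch, gens: int, absorb_fixed=False):
        for g in range(gens):
            self._step(br)
            if (g + 1) % self.COMPACT_EVERY == 0:
                self._compact(br, absorb_fixed)
        self._compact(br, absorb_fixed)
        return br

    # -- sweep branch -----------------------------------------------------

    def run_sweep(self, br: _Branch, sweep: SweepConfig):
        """Inject the beneficial allele and evolve ``t_start`` generations.

        Returns (branch, injected position, fixation generation or None).
        Under condition_on_establishment the branch restarts from the
        injection point whenever the attempt fails to establish (allele lost,
        or never reaching ~1/s copies), up to the retry cap.
        """
        pos0 = sweep.position
        while pos0 in self._refs:
            pos0 += 1  # injection site occupied by a standing variant: nudge
        if pos0 != sweep.position:
            log.info("sweep position nudged %d -> %d (occupied)", sweep.position, pos0)
        if pos0 > self.L:
            raise ValueError("no free injection site at region end")

        N = br.buf.shape[0]
        snap = None
        if sweep.condition_on_establishment:
            snap = (br.mat.copy(), br.pos.copy(), set(br.fixed), dict(self._refs))

        attempts = sweep.max_retries if sweep.condition_on_establishment else 1
        for attempt in range(attempts):
            carrier = int(self.rng.integers(0, N))
            self._hold(pos0)
            if br.buf.shape[1] == br.S:  # grow in place for the new column
                br.set_mat(np.concatenate([br.mat, np.zeros((N, 1), np.uint8)], axis=1))
                br.S -= 1
            br.buf[:, br.S] = 0
            br.buf[carrier, br.S] = 1
            br.S += 1
            br.pos = np.concatenate([br.pos, [pos0]])
            sel_idx = br.S - 1
            fix_gen = None
            fate = "segregating"
            established = False
            for g in range(sweep.t_start, 0, -1):
                self._step(br, sel_idx=sel_idx, s=sweep.s)
                count = int(br.mat[:, sel_idx].sum())
                established = established or count >= sweep.establishment_copies
                if count == 0:
                    fate = "lost"
                    break
                if count == N:
                    fate = "fixed"
                    fix_gen = g - 1
                    self._compact(br)  # moves the allele into br.fixed
                    for gg in range(g - 1):
                        self._step(br)
                        if (gg + 1) % self.COMPACT_EVERY == 0:
                            self._compact(br)
                    break
                if (sweep.t_start - g) % self.COMPACT_EVERY == self.COMPACT_EVERY - 1:
                    self._compact(br)
                    sel_idx = int(np.nonzero(br.pos == pos0)[0][0])
            self._compact(br)
            ok = fate == "fixed" or (fate == "segregating" and established)
            if ok and sweep.final_freq_range is not None:
                if pos0 in br.fixed:
                    freq = 1.0
                else:
                    hit = np.nonzero(br.pos == pos0)[0]
                    freq = float(br.mat[:, hit[0]].mean()) if hit.size else 0.0
                lo_f, hi_f = sweep.final_freq_range
                ok = lo_f <= freq <= hi_f
            if not sweep.condition_on_establishment or ok:
                if fate == "lost":
                    log.info("sweep allele lost (unconditioned run)")
                return br, pos0, fix_gen
            if snap is not None and attempt + 1 < attempts:
                br.set_mat(snap[0])
                br.pos, br.fixed = snap[1].copy(), set(snap[2])
                self._refs = dict(snap[3])
        raise EstablishmentError(
            f"sweep allele failed to establish in {sweep.max_retries} attempts "
            "(retry cap reached)"
        )

    # -- sampling ---------------------------------------------------------

    def sample_panels(self, branches: dict, n_sample, sweep_pos=None):
        """Draw diploid samples and assemble per-population panels on a
        shared site frame restricted to sites polymorphic in the pooled
        sample.  ``n_sample`` maps population name to diploid count."""
        rng = self.rng
        cfg = self.cfg
        drawn = {}
        for pop, br in branches.items():
            rows = rng.choice(br.mat.shape[0], size=2 * n_sample[pop], replace=False)
            drawn[pop] = (br.mat[np.sort(rows)], br.pos, br.fixed)

        allpos = set()
        for sub, pos, fixed in drawn.values():
            allpos.update(pos.tolist())
            allpos.update(fixed)
        allpos = np.asarray(sorted(allpos), dtype=np.int64)
        M = allpos.size

        blocks = {}
        for pop, (sub, pos, fixed) in drawn.items():
            block = np.zeros((sub.shape[0], M), dtype=np.uint8)
            if pos.size:
                block[:, np.searchsorted(allpos, np.sort(pos))] = sub[
                    :, np.argsort(pos, kind="stable")
                ]
            if fixed:
                block[:, np.searchsorted(allpos, sorted(fixed))] = 1
            blocks[pop] = block

        total = sum(b.sum(axis=0, dtype=np.int64) for b in blocks.values())
        n_tot = sum(b.shape[0] for b in blocks.values())
        poly = (total > 0) & (total < n_tot)
        allpos = allpos[poly]
        blocks = {pop: b[:, poly] for pop, b in blocks.items()}

        # derived allele is always ALT; REF letter drawn per site for realism
        ref_idx = rng.integers(0, 4, size=allpos.size)
        alt_idx = (ref_idx + rng.integers(1, 4, size=allpos.size)) % 4
        alleles = list(zip(_BASES[ref_idx], _BASES[alt_idx]))
        ancestral = np.zeros(allpos.size, dtype=np.int8)

        panels = {}
        for pop, block in blocks.items():
            ids = [f"{pop}_{k}" for k in range(block.shape[0] // 2)]
            panels[pop] = HaplotypePanel(
                chrom=cfg.chrom,
                positions=allpos.copy(),
                alleles=list(alleles),
                matrix=block,
                ancestral=ancestral.copy(),
                sample_ids=ids,
                pop_of={s: pop for s in ids},
            )
        freqs = {}
        if sweep_pos is not None:
            for pop, br in branches.items():
                if sweep_pos in br.fixed:
                    freqs[pop] = 1.0
                else:
                    hit = np.nonzero(br.pos == sweep_pos)[0]
                    freqs[pop] = (
                        float(br.mat[:, hit[0]].mean()) if hit.size else 0.0
                    )
        return panels, freqs


def simulate(config: SimConfig):
    """Run the three-population simulation.

    Returns ``(panels, truth)`` where ``panels`` is a dict with keys
    ``"highland"``, ``"lowland"``, ``"outgroup"`` holding
    :class:`HaplotypePanel` objects on a common site frame, and ``truth`` is
    a :class:`SimTruth`.
    """
    config.validate()
    eng = _Engine(config)
    cfg = config

    anc = eng.new_branch(cfg.N_anc)
    burn = int(round(cfg.burn_in_factor * cfg.N_anc))
    eng.evolve(anc, burn, absorb_fixed=True)

    out = eng.copy_branch(anc, cfg.N_out)
    eng.evolve(out, cfg.t_out_split)

    # main (highland+lowland ancestor) branch down to the sister split
    if cfg.N_anc != max(cfg.N_hi, cfg.N_lo):
        pass  # ancestor keeps N_anc until the split; sizes change at splits
    eng.evolve(anc, cfg.t_out_split - cfg.t_hilo_split)

    lo = eng.copy_branch(anc, cfg.N_lo)
    eng.evolve(lo, cfg.t_hilo_split)

    hi = eng.copy_branch(anc, cfg.N_hi)
    eng.drop_branch(anc)
    sweep_pos = fix_gen = None
    if cfg.sweep is None:
        eng.evolve(hi, cfg.t_hilo_split)
    else:
        eng.evolve(hi, cfg.t_hilo_split - cfg.sweep.t_start)
        hi, sweep_pos, fix_gen = eng.run_sweep(hi, cfg.sweep)

    branches = {POP_HI: hi, POP_LO: lo, POP_OUT: out}
    panels, freqs = eng.sample_panels(
        branches, cfg.samples_per_pop(), sweep_pos=sweep_pos
    )
    truth = SimTruth(
        sweep_position=sweep_pos,
        s=cfg.sweep.s if cfg.sweep else None,
        beneficial_frequency=freqs,
        fixation_generation=fix_gen,
    )
    return panels, truth


# ---------------------------------------------------------------------------
# Truth / artifact I/O
# ---------------------------------------------------------------------------

def write_truth(truth: SimTruth, path) -> None:
    """One-row TSV with header; missing sweep fields are written as NA."""
    pops = sorted(truth.beneficial_frequency)
    cols = ["sweep_position", "s", "fixation_generation"] + [
        f"freq_{p}" for p in pops
    ]
    na = lambda v: "NA" if v is None else repr(v) if isinstance(v, float) else str(v)
    vals = [na(truth.sweep_position), na(truth.s), na(truth.fixation_generation)]
    vals += [repr(truth.beneficial_frequency[p]) for p in pops]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        fh.write("\t".join(vals) + "\n")


def read_truth(path) -> SimTruth:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        row = fh.readline().rstrip("\n").split("\t")
    d = dict(zip(header, row))
    get = lambda k, f: None if d[k] == "NA" else f(d[k])
    freqs = {
        k[len("freq_"):]: float(v) for k, v in d.items() if k.startswith("freq_")
    }
    return SimTruth(
        sweep_position=get("sweep_position", int),
        s=get("s", float),
        beneficial_frequency=freqs,
        fixation_generation=get("fixation_generation", int),
    )


def write_sim_outputs(panels: dict, truth: SimTruth, outdir, prefix="sim"):
    """Write one joint phased VCF (AA set), a pop-map TSV and the truth TSV."""
    import os

    from .genodata import concat_panels, write_vcf

    os.makedirs(outdir, exist_ok=True)
    joint = concat_panels([panels[p] for p in sorted(panels)])
    vcf_path = os.path.join(outdir, f"{prefix}.vcf")
    map_path = os.path.join(outdir, f"{prefix}.popmap.tsv")
    truth_path = os.path.join(outdir, f"{prefix}.truth.tsv")
    write_vcf(joint, vcf_path)
    with open(map_path, "w") as fh:
        for s in joint.sample_ids:
            fh.write(f"{s}\t{joint.pop_of[s]}\n")
    write_truth(truth, truth_path)
    return {"vcf": vcf_path, "popmap": map_path, "truth": truth_path}
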