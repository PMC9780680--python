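"""End-to-end orchestration: iHS -> XP-CLR -> PBS -> intersection -> tracks.

Reproduces the analysis order of an altitude-contrast selection study on
arbitrary (or simulated) phased input: within-group iHS on the focal
populations, XP-CLR of focal vs reference, outlier windows merged to
candidate regions, PBS of the focal group (rooted by the reference group
and an outgroup) on fine windows restricted to those candidates, three-way
intersection with gene annotation, and windowed FST / nucleotide diversity
plus LD matrices over the final candidate regions.

Every stage is a pure function of (inputs, config); the JSON manifest lists
each artifact with its SHA-256, so rerunning an identical configuration
yields a byte-identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import diffstats, genodata, haplostats, ldblocks, scanner, xpclr

log = logging.getLogger("sweepscan.pipeline")

GROUP_FOCAL, GROUP_REF, GROUP_OUT = "focal", "reference", "outgroup"


@dataclass
class PipelineConfig:
    vcf: str
    popmap: str
    outdir: str
    focal_pops: list
    reference_pops: list
    outgroup_pop: str = None
    genes: str = None
    chrom_lengths: str = None
    # stage parameters (defaults follow the package-wide conventions)
    maf_min: float = 0.05
    polarize_policy: str = "ref"
    window_size: int = 100_000
    window_step: int = 50_000
    fine_size: int = 10_000
    fine_step: int = 5_000
    min_snps: int = 10
    ihs_pihs_threshold: float = 6.0
    ihs_min_qualifying: int = 1
    ihs_border_policy: str = "discard"
    ihs_bin_width: float = 0.025
    xpclr_top_fraction: float = 0.005
    pbs_threshold: float = 0.2
    fst_estimator: str = "wc"
    ld_r2_min: float = 0.5
    scan_reference_ihs: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause} (partial manifest kept)")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dict (also written as JSON)."""
    os.makedirs(config.outdir, exist_ok=True)
    outputs = {}
    manifest = {
        "config": dataclasses.asdict(config),
        "outputs": outputs,
    }

    def emit(name, df_or_regions, kind="tsv"):
        path = os.path.join(config.outdir, name)
        if kind == "tsv":
            df_or_regions.to_csv(path, sep="\t", index=False, na_rep="NA")
        elif kind == "bed":
            scanner.write_bed(df_or_regions, path)
        outputs[name] = _sha256(path)
        return path

    stage = "load"
    try:
        pop_of = genodata.read_pop_map(config.popmap)
        groups = {
            GROUP_FOCAL: list(config.focal_pops),
            GROUP_REF: list(config.reference_pops),
        }
        if config.outgroup_pop:
            groups[GROUP_OUT] = [config.outgroup_pop]
        known = set(pop_of.values())
        for g, pops in groups.items():
            missing = set(pops) - known
            if missing:
                raise ValueError(
                    f"{g} population(s) {sorted(missing)} absent from pop map "
                    f"(valid: {sorted(known)})"
                )
        panel = genodata.read_vcf(config.vcf, pop_of=pop_of)
        # collapse populations to analysis groups
        pop_to_group = {p: g for g, pops in groups.items() for p in pops}
        grouped = dataclasses.replace(
            panel,
            pop_of={
                s: pop_to_group[pop_of[s]]
                for s in panel.sample_ids
                if pop_of.get(s) in pop_to_group
            },
        )
        if config.chrom_lengths:
            L = genodata.read_chrom_lengths(config.chrom_lengths)[panel.chrom]
        else:
            L = int(panel.positions.max())
        coarse = scanner.make_windows(L, config.window_size, config.window_step)
        fine = scanner.make_windows(L, config.fine_size, config.fine_step)

        stage = "ihs"
        focal = genodata.subset_panel(grouped, GROUP_FOCAL, config.maf_min)
        focal = genodata.polarize_panel(
            focal, config.polarize_policy,
            outgroup_pop=GROUP_OUT if config.polarize_policy == "outgroup-major" else None,
        )
        ihs_df = haplostats.ihs_scan(
            focal, maf_min=config.maf_min,
            border_policy=config.ihs_border_policy,
            bin_width=config.ihs_bin_width,
        )
        emit("ihs_focal.tsv", ihs_df)
        scored = ihs_df[ihs_df["piHS"].notna()]
        win_ihs = scanner.summarize(
            scored["pos"], scored["piHS"], coarse,
            reducer=("count_above", config.ihs_pihs_threshold),
            chrom=panel.chrom, method="ihs",
        )
        emit("ihs_windows.tsv", win_ihs)
        ihs_out = scanner.call_outliers(
            win_ihs, ("threshold", config.ihs_min_qualifying), config.min_snps
        )
        regions_ihs = scanner.merge_regions(ihs_out, "ihs")
        if config.scan_reference_ihs:
            ref_p = genodata.subset_panel(grouped, GROUP_REF, config.maf_min)
            ref_p = genodata.polarize_panel(ref_p, config.polarize_policy)
            emit("ihs_reference.tsv", haplostats.ihs_scan(
                ref_p, maf_min=config.maf_min,
                border_policy=config.ihs_border_policy,
                bin_width=config.ihs_bin_width,
            ))

        stage = "xpclr"
        both = genodata.subset_panel(grouped, [GROUP_FOCAL, GROUP_REF], 0.0)
        obj_rows = np.unique(both.hap_indices(GROUP_FOCAL) // 2)
        ref_rows = np.unique(both.hap_indices(GROUP_REF) // 2)
        panel_obj = both.take_samples(obj_rows)
        panel_ref = both.take_samples(ref_rows)
        xp_df = xpclr.xpclr_scan(panel_ref, panel_obj, coarse)
        emit("xpclr_windows.tsv", xp_df)
        xp_win = xp_df.rename(columns={"score": "value"}).assign(method="xpclr")
        xp_out = scanner.call_outliers(
            xp_win, ("top_fraction", config.xpclr_top_fraction), config.min_snps
        )
        regions_xpclr = scanner.merge_regions(xp_out, "xpclr")

        stage = "pbs"
        candidates = sorted(
            regions_ihs + regions_xpclr, key=lambda r: (r.chrom, r.start)
        )
        if config.outgroup_pop:
            fine_cand = [
                (a, b) for a, b in fine
                if any(r.start < b and r.end > a for r in candidates)
            ]
            gsub = genodata.subset_panel(
                grouped, [GROUP_FOCAL, GROUP_REF, GROUP_OUT], 0.0
            )
            pbs_df = diffstats.pbs_windows(
                gsub, GROUP_FOCAL, GROUP_REF, GROUP_OUT,
                fine_cand, estimator=config.fst_estimator,
            )
            emit("pbs_windows.tsv", pbs_df)
            pbs_win = pbs_df.rename(
                columns={"CHROM": "chrom", "BIN_START": "start", "BIN_END": "end",
                         "N_VARIANTS": "n_snps", "pbs": "value"}
            )
            pbs_win["method"] = "pbs"
            pbs_out = pbs_win[
                (pbs_win["value"] >= config.pbs_threshold)
                & (pbs_win["n_snps"] >= config.min_snps)
            ]
            regions_pbs = scanner.merge_regions(pbs_out, "pbs")
        else:
            regions_pbs = []

        stage = "intersect"
        genes = genodata.read_genes(config.genes) if config.genes else []
        for regs in (regions_ihs, regions_xpclr, regions_pbs):
            scanner.annotate_genes(regs, genes)
        emit("regions_ihs.bed", regions_ihs, kind="bed")
        emit("regions_xpclr.bed", regions_xpclr, kind="bed")
        if regions_pbs:
            emit("regions_pbs.bed", regions_pbs, kind="bed")
        two_way = scanner.intersect(regions_ihs, regions_xpclr, mode="region")
        final = (
            scanner.intersect(two_way, regions_pbs, mode="region")
            if regions_pbs else two_way
        )
        scanner.annotate_genes(final, genes)
        emit("candidates.tsv", scanner.regions_to_frame(final))
        emit("candidates.bed", final, kind="bed")
        if genes:
            shared = scanner.intersect(regions_ihs, regions_xpclr, mode="gene")
            with open(os.path.join(config.outdir, "shared_genes.txt"), "w") as fh:
                fh.write("\n".join(shared) + ("\n" if shared else ""))
            outputs["shared_genes.txt"] = _sha256(
                os.path.join(config.outdir, "shared_genes.txt")
            )

        stage = "tracks"
        fst_fine = diffstats.fst_windows(
            diffstats.fst_sites(both, GROUP_FOCAL, GROUP_REF,
                                estimator=config.fst_estimator),
            fine, chrom=panel.chrom,
        )
        emit("fst_fine.tsv", fst_fine)
        for grp in (GROUP_FOCAL, GROUP_REF):
            emit(f"pi_{grp}.tsv", diffstats.pi_windows(both, grp, fine))
        ld_rows = []
        for r in final:
            for grp in (GROUP_FOCAL, GROUP_REF):
                try:
                    m = ldblocks.ld_matrix(both, grp, region=(r.start, r.end))
                except ValueError:
                    continue
                ld_rows.append(
                    (r.chrom, r.start, r.end, grp,
                     ldblocks.mean_r2(m),
                     len(ldblocks.blocks(m, config.ld_r2_min)))
                )
        import pandas as pd

        emit("ld_regions.tsv", pd.DataFrame(
            ld_rows, columns=["chrom", "start", "end", "group", "mean_r2", "n_blocks"]
        ))
    except Exception as err:
        _write_manifest(manifest, config.outdir, partial=stage)
        if isinstance(err, PipelineError):
            raise
        raise PipelineError(stage, err) from err

    _write_manifest(manifest, config.outdir)
    return manifest


def _write_manifest(manifest, outdir, partial=None):
    if partial:
        manifest = dict(manifest, partial_failure_at_stage=partial)
    path = os.path.join(outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
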