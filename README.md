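# sweepscan

Selection-signature scans for phased population genomic data: the
within-population integrated haplotype score (iHS), the cross-population
composite likelihood ratio (XP-CLR), the population branch statistic (PBS),
windowed FST and nucleotide diversity, pairwise-LD block structure, and the
window/threshold/intersection bookkeeping that turns per-SNP statistics into
candidate regions and gene lists. A forward Wright–Fisher simulator of a
three-population design (two sister populations, one carrying a hard sweep,
plus an outgroup) makes every stage testable without any data download.

The package is aimed at the analysis design used to find
high-altitude-adaptation candidates in livestock: a group of populations
from a highland environment is contrasted with lowland relatives and an
outgroup breed, scanning for regions where the highland branch shows long
haplotypes (iHS), excess allele-frequency change (XP-CLR), and
lineage-specific differentiation (PBS = (T₁ + T₂ − T₃)/2 with
T = −ln(1 − F_ST)).

## Worked example

Simulate a sweep dataset and run the pipeline end to end:

```bash
sweepscan simulate --seed 7 --sweep-s 0.05 --outdir demo/
cat > demo/config.yaml <<'YAML'
vcf: demo/sim.vcf
popmap: demo/sim.popmap.tsv
outdir: demo/run
focal_pops: [highland]
reference_pops: [lowland]
outgroup_pop: outgroup
window_size: 100000
window_step: 50000
ihs_border_policy: keep   # 1 Mb region: keep border-truncated EHH integrals
ihs_bin_width: 0.1
ihs_pihs_threshold: 2.0   # single-region demo; genome scans keep 6.0
xpclr_top_fraction: 0.1
pbs_threshold: 0.05
YAML
sweepscan pipeline --config demo/config.yaml
```

The simulate step prints the artifact paths and the truth file records the
injected sweep, e.g.

```
sweep_position  s     fixation_generation  freq_highland  freq_lowland  freq_outgroup
500000          0.05  NA                   0.983          0.0           0.0
```

The pipeline writes per-SNP iHS (`ihs_focal.tsv`), XP-CLR window scores
(`xpclr_windows.tsv`), PBS on fine windows restricted to the iHS/XP-CLR
candidates (`pbs_windows.tsv`), merged outlier regions per method
(`regions_*.bed`), the intersected candidate regions with overlapping gene
names (`candidates.tsv`/`candidates.bed`), vcftools-style windowed FST and
π tracks, per-region LD summaries, and a `manifest.json` whose
per-artifact SHA-256 hashes are byte-identical across reruns of the same
configuration.  For the run above the merged XP-CLR outlier region is

```
$ cat demo/run/regions_xpclr.bed
1	450000	600000	xpclr
```

bracketing the injected sweep at 500 kb (its two best windows score 153.5
and 132.8), and the strongest PBS region (`regions_pbs.bed`) spans
450–605 kb.  The iHS outlier region on this run lies away from the sweep —
on a single 1 Mb region the haplotype statistic is the noisiest of the
three scans (see `docs/methods.md`), so the strict three-way intersection
can come back empty on a toy run even when the frequency-based scans pin
the sweep.

The same stages are available as library functions (`read_vcf`,
`subset_panel`, `ihs_scan`, `xpclr_scan`, `pbs_windows`, `pi_windows`,
`ld_matrix`, `make_windows`, `call_outliers`, `merge_regions`,
`intersect`, `annotate_genes`) and as individual subcommands
(`sweepscan ihs|xpclr|fst|pbs|pi|scan|ld|annotate`).

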