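"""Wright-Fisher simulator: contracts, determinism, and drift expectations."""

import numpy as np
import pytest
from scipy.stats import chisquare

from sweepscan.genodata import concat_panels, read_vcf, write_vcf
from sweepscan.wfsim import (
    SimConfig,
    SimTruth,
    SweepConfig,
    read_truth,
    simulate,
    write_sim_outputs,
    write_truth,
)

TINY = dict(
    region_length=50_000, N_anc=100, N_out=100, N_hi=100, N_lo=100,
    t_out_split=60, t_hilo_split=20, mu=1e-6, rho=1e-7, n_sample=8,
)


class TestContracts:
    def test_no_mutation_means_no_sites(self):
        cfg = SimConfig(**{**TINY, "mu": 0.0}, seed=5)
        panels, truth = simulate(cfg)
        for p in panels.values():
            assert p.n_sites == 0
        assert truth.sweep_position is None

    def test_same_seed_identical_vcf_bytes(self, tmp_path):
        outs = []
        for d in ("a", "b"):
            cfg = SimConfig(**TINY, seed=42,
                            sweep=SweepConfig(position=25_000, s=0.1, t_start=20))
            panels, truth = simulate(cfg)
            paths = write_sim_outputs(panels, truth, tmp_path / d)
            outs.append((tmp_path / d / "sim.vcf").read_bytes())
        assert outs[0] == outs[1]

    def test_different_seeds_differ(self):
        a, _ = simulate(SimConfig(**TINY, seed=1))
        b, _ = simulate(SimConfig(**TINY, seed=2))
        assert not np.array_equal(a["highland"].positions, b["highland"].positions)

    def test_sweep_position_outside_region_rejected(self):
        cfg = SimConfig(**TINY, sweep=SweepConfig(position=99_000_000, s=0.1, t_start=10))
        with pytest.raises(ValueError, match="outside region"):
            simulate(cfg)

    def test_sweep_must_lie_on_highland_branch(self):
        cfg = SimConfig(**TINY, sweep=SweepConfig(position=25_000, s=0.1, t_start=50))
        with pytest.raises(ValueError, match="highland branch"):
            simulate(cfg)

    def test_invalid_split_order_rejected(self):
        with pytest.raises(ValueError, match="t_out_split"):
            simulate(SimConfig(**{**TINY, "t_out_split": 10}))

    def test_panels_share_polymorphic_site_frame(self):
        panels, _ = simulate(SimConfig(**TINY, seed=7))
        hi, lo, out = panels["highland"], panels["lowland"], panels["outgroup"]
        assert np.array_equal(hi.positions, lo.positions)
        assert np.array_equal(hi.positions, out.positions)
        total = hi.matrix.sum(0) + lo.matrix.sum(0) + out.matrix.sum(0)
        n_tot = hi.n_haplotypes * 3
        assert np.all((total > 0) & (total < n_tot))
        # ancestral polarity is known exactly (derived = ALT)
        assert np.all(hi.ancestral == 0)

    def test_vcf_roundtrip_of_sim_output(self, tmp_path):
        cfg = SimConfig(**TINY, seed=3)
        panels, truth = simulate(cfg)
        paths = write_sim_outputs(panels, truth, tmp_path)
        panel = read_vcf(paths["vcf"])
        joint = concat_panels([panels[p] for p in sorted(panels)])
        assert np.array_equal(panel.matrix, joint.matrix)
        assert np.array_equal(panel.ancestral, joint.ancestral)


class TestSweep:
    def test_established_sweep_rises_well_above_injection_frequency(self):
        """Conditioned on establishment (s=0.2, 20 generations), the allele
        sits far above its 1/N injection frequency and only on the highland
        branch."""
        high = 0
        for seed in range(6):
            cfg = SimConfig(**TINY, seed=seed,
                            sweep=SweepConfig(position=25_000, s=0.2, t_start=20))
            _, truth = simulate(cfg)
            assert truth.beneficial_frequency["highland"] > 0
            assert truth.beneficial_frequency["lowland"] == 0.0
            assert truth.beneficial_frequency["outgroup"] == 0.0
            high += truth.beneficial_frequency["highland"] > 0.15
        assert high >= 4

    def test_retry_cap_raises(self):
        from sweepscan.wfsim import EstablishmentError

        cfg = SimConfig(**TINY, seed=11,
                        sweep=SweepConfig(position=25_000, s=1e-6, t_start=3,
                                          max_retries=2))
        with pytest.raises(EstablishmentError, match="retry cap"):
            simulate(cfg)


class TestTruthIO:
    def test_roundtrip(self, tmp_path):
        t = SimTruth(12345, 0.05, {"highland": 0.93, "lowland": 0.0}, 17)
        p = tmp_path / "truth.tsv"
        write_truth(t, p)
        assert read_truth(p) == t

    def test_no_sweep_writes_na(self, tmp_path):
        t = SimTruth(None, None, {"highland": 0.0}, None)
        p = tmp_path / "truth.tsv"
        write_truth(t, p)
        text = p.read_text().splitlines()[1].split("\t")
        assert text[:3] == ["NA", "NA", "NA"]
        assert read_truth(p) == t


class TestDriftExpectations:
    def test_neutral_sfs_close_to_one_over_i(self):
        """Aggregate unfolded SFS of sampled neutral panels follows the 1/i
        shape (chi-square goodness of fit).

        Recombination is set high relative to mutation so sites within a
        replicate are nearly genealogically independent; otherwise linked
        sites share one tree and the chi-square test over-rejects.
        """
        counts = np.zeros(15, dtype=float)  # sample of 16 haplotypes: 1..15
        total_sites = 0
        seeds = 0
        while total_sites < 10_000:
            cfg = SimConfig(
                region_length=10_000, N_anc=100, N_out=100, N_hi=100, N_lo=100,
                t_out_split=3, t_hilo_split=2, mu=2e-5, rho=2e-4, n_sample=8,
                seed=1500 + seeds,
            )
            panels, _ = simulate(cfg)
            hi = panels["highland"]
            k = hi.matrix.sum(axis=0)
            seg = (k > 0) & (k < 16)
            counts += np.bincount(k[seg], minlength=16)[1:16]
            total_sites += int(seg.sum())
            seeds += 1
        expected = (1 / np.arange(1, 16))
        expected = expected / expected.sum() * counts.sum()
        stat, p = chisquare(counts, expected)
        assert p > 0.01

    def test_two_population_fst_matches_drift_oracle(self):
        """Mean Hudson FST after a split of t generations is close to
        1 - exp(-t/N) (small, noisy version of the calibration study)."""
        from sweepscan.diffstats import fst_sites

        vals = []
        for seed in range(8):
            cfg = SimConfig(
                region_length=10_000, N_anc=200, N_out=200, N_hi=200, N_lo=200,
                t_out_split=25, t_hilo_split=20, mu=1e-5, rho=1e-7, n_sample=10,
                seed=900 + seed,
            )
            panels, _ = simulate(cfg)
            joint = concat_panels([panels["highland"], panels["lowland"]])
            df = fst_sites(joint, "highland", "lowland", "hudson")
            vals.append(df["num"].sum() / df["den"].sum())
        expect = 1 - np.exp(-20 / 200)
        assert np.mean(vals) == pytest.approx(expect, abs=0.05)


class TestEstablishmentConditioning:
    def test_established_sweeps_reach_high_frequency(self):
        """Given enough time (200 generations at s=0.05, N=1000),
        establishment-conditioned sweeps end above 90% frequency in most
        replicates.  A short neutral region keeps the run cheap: the
        trajectory depends only on (N, s, t)."""
        high = 0
        for seed in range(10):
            cfg = SimConfig(
                region_length=50_000, N_anc=1000, N_out=1000, N_hi=1000,
                N_lo=1000, t_out_split=210, t_hilo_split=200, mu=2e-8,
                rho=1e-8, n_sample=5, burn_in_factor=0.5, seed=600 + seed,
                sweep=SweepConfig(position=25_000, s=0.05, t_start=200),
            )
            _, truth = simulate(cfg)
            high += truth.beneficial_frequency["highland"] > 0.9
        assert high >= 8
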