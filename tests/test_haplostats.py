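"""EHH, iHH integration and iHS standardization against enumeration oracles."""

import itertools

import numpy as np
import pytest
from scipy.stats import norm

from sweepscan.haplostats import (
    EHHCurve,
    ehh,
    ihh,
    ihs_scan,
    ihs_unstandardized,
    standardize_ihs,
)

from conftest import make_panel, random_panel


def brute_ehh(matrix, carriers, core, marker):
    """EHH by enumerating all carrier pairs and checking identity core..marker."""
    lo, hi = min(core, marker), max(core, marker)
    pairs = list(itertools.combinations(carriers, 2))
    same = sum(
        1 for a, b in pairs if np.array_equal(matrix[a, lo:hi + 1], matrix[b, lo:hi + 1])
    )
    return same / len(pairs)


class TestEhh:
    def test_unity_at_core(self, rng):
        panel = random_panel(rng, n_hap=12, n_sites=9)
        left, right = ehh(panel, 4, 1)
        assert left.points[0][1] == 1.0 and right.points[0][1] == 1.0

    def test_identical_carriers_stay_at_one(self):
        mat = np.vstack([np.tile([1, 1, 0, 1, 0], (4, 1)),
                         np.tile([0, 0, 0, 0, 1], (4, 1))]).astype(np.uint8)
        panel = make_panel(mat)
        left, right = ehh(panel, 0, 1)
        assert all(e == 1.0 for _, e in left.points + right.points)

    def test_two_two_split_gives_one_third(self):
        # 4 carriers of allele 1 at core split 2/2 at the adjacent marker
        mat = np.array(
            [[1, 0], [1, 0], [1, 1], [1, 1], [0, 0], [0, 1]], dtype=np.uint8
        )
        panel = make_panel(mat)
        _, right = ehh(panel, 0, 1)
        assert right.points[1][1] == pytest.approx(1 / 3)

    def test_fewer_than_two_carriers_raises(self):
        mat = np.array([[1, 0], [0, 0], [0, 1], [0, 1]], dtype=np.uint8)
        with pytest.raises(ValueError, match="carriers"):
            ehh(make_panel(mat), 0, 1)

    def test_monotone_nonincreasing_outward(self, rng):
        for _ in range(10):
            panel = random_panel(rng, n_hap=16, n_sites=25)
            left, right = ehh(panel, 12, 1, cutoff=0.0)
            for curve in (left, right):
                e = [v for _, v in curve.points]
                assert all(b <= a + 1e-12 for a, b in zip(e, e[1:]))

    def test_matches_pair_enumeration_oracle(self, rng):
        """EHH at every walked marker equals brute-force pair counting."""
        checked = 0
        while checked < 1000:
            panel = random_panel(rng, n_hap=12, n_sites=12)
            core = int(rng.integers(0, 12))
            code = int(rng.integers(0, 2))
            carriers = np.nonzero(panel.matrix[:, core] == code)[0]
            if carriers.size < 2:
                continue
            left, right = ehh(panel, core, code, cutoff=0.0)
            pos_to_idx = {int(p): i for i, p in enumerate(panel.positions)}
            for curve in (left, right):
                for p, e in curve.points:
                    marker = pos_to_idx[p]
                    assert e == pytest.approx(
                        brute_ehh(panel.matrix, carriers, core, marker), abs=1e-12
                    )
                    checked += 1

    def test_label_invariance_under_row_permutation(self, rng):
        panel = random_panel(rng, n_hap=16, n_sites=20)
        perm = rng.permutation(8)
        shuffled = panel.take_samples(perm)
        a = ehh(panel, 10, 1, cutoff=0.0)
        b = ehh(shuffled, 10, 1, cutoff=0.0)
        for ca, cb in zip(a, b):
            assert ca.points == cb.points


class TestIhh:
    def test_rectangle(self):
        left = EHHCurve(0, "left", [(2000, 1.0), (1000, 1.0)], True)
        right = EHHCurve(0, "right", [(2000, 1.0), (3000, 1.0)], True)
        v, flags = ihh(left, right, cutoff=0.05)
        assert v == pytest.approx(2000.0)
        assert flags == {"border"}

    def test_hand_trapezoid(self):
        left = EHHCurve(0, "left", [(5000, 1.0)], True)
        right = EHHCurve(0, "right", [(5000, 1.0), (6000, 1 / 3)], True)
        v, flags = ihh(left, right, cutoff=0.05)
        assert v == pytest.approx((1 + 1 / 3) / 2 * 1000)

    def test_stops_at_first_subcutoff_marker(self):
        left = EHHCurve(0, "left", [(5000, 1.0)], True)
        right = EHHCurve(
            0, "right", [(5000, 1.0), (5100, 0.01), (5200, 0.001)], False
        )
        v, flags = ihh(left, right, cutoff=0.05)
        assert v == pytest.approx((1 + 0.01) / 2 * 100)
        assert "border" in flags  # left side never crossed the cutoff

    def test_gap_rule_stops_integration(self):
        left = EHHCurve(0, "left", [(500_000, 1.0)], True)
        right = EHHCurve(
            0, "right", [(500_000, 1.0), (800_000, 0.5)], False
        )
        v, flags = ihh(left, right, cutoff=0.05, max_gap=200_000)
        assert "gap" in flags
        assert v == pytest.approx(0.0)


class TestIhsScan:
    def test_pihs_transform_values(self, rng):
        mat = (rng.random((40, 120)) < 0.5).astype(np.uint8)
        panel = make_panel(mat, positions=np.arange(1, 121) * 997)
        df = ihs_scan(panel, border_policy="keep")
        scored = df[df["iHS"].notna()]
        assert len(scored) > 20
        expect = -np.log10(2 * norm.sf(np.abs(scored["iHS"])))
        np.testing.assert_allclose(scored["piHS"], expect, atol=1e-10)

    def test_pihs_six_matches_inverse_normal(self):
        # piHS = 6 is attained at |iHS| = Phi^-1(1 - 5e-7)
        z = norm.isf(5e-7)
        assert z == pytest.approx(4.8916, abs=1e-4)
        assert -np.log10(2 * norm.sf(z)) == pytest.approx(6.0, abs=1e-9)

    def test_standardized_bins_have_zero_mean_unit_sd(self, rng):
        mat = (rng.random((30, 300)) < rng.uniform(0.1, 0.9, 300)).astype(np.uint8)
        p = mat.mean(axis=0)
        mat = mat[:, (p > 0.05) & (p < 0.95)]
        panel = make_panel(mat, positions=np.arange(1, mat.shape[1] + 1) * 499)
        df = ihs_scan(panel, border_policy="keep", bin_width=0.25)
        scored = df[df["iHS"].notna()]
        from sweepscan.haplostats import _bin_index

        bins = _bin_index(scored["derived_freq"], 0.05, 0.25, 4)
        for b in np.unique(bins):
            sub = scored["iHS"].to_numpy()[bins == b]
            if sub.size >= 2:
                assert abs(sub.mean()) < 1e-10
                assert abs(sub.std(ddof=1) - 1) < 1e-10

    def test_requires_polarized_panel(self, rng):
        panel = random_panel(rng, n_hap=12, n_sites=10)
        panel.ancestral[3] = -1
        with pytest.raises(ValueError, match="polarized"):
            ihs_unstandardized(panel)

    def test_edge_tie_goes_to_lower_bin(self):
        from sweepscan.haplostats import _bin_index

        # 0.05 + k*0.025 boundaries: a freq exactly on the boundary joins
        # the bin below it
        assert _bin_index([0.075], 0.05, 0.025, 36)[0] == 0
        assert _bin_index([0.076], 0.05, 0.025, 36)[0] == 1

    def test_small_bin_left_unscored(self, rng):
        mat = (rng.random((20, 30)) < 0.5).astype(np.uint8)
        p = mat.mean(axis=0)
        mat = mat[:, (p > 0.05) & (p < 0.95)]
        panel = make_panel(mat, positions=np.arange(1, mat.shape[1] + 1) * 211)
        raw = ihs_unstandardized(panel, border_policy="keep")
        # bins of width 0.001 isolate nearly every site -> almost nothing scored
        df = standardize_ihs(raw, bin_width=0.001)
        flagged = df["flags"].str.contains("small_bin")
        assert (df.loc[flagged, "iHS"].isna()).all()

    def test_label_invariance_of_scan(self, rng):
        mat = (rng.random((24, 60)) < 0.5).astype(np.uint8)
        panel = make_panel(mat, positions=np.arange(1, 61) * 307)
        perm = rng.permutation(12)
        df1 = ihs_scan(panel, border_policy="keep")
        df2 = ihs_scan(panel.take_samples(perm), border_policy="keep")
        np.testing.assert_allclose(df1["uniHS"], df2["uniHS"], atol=1e-12)
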