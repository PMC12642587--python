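"""Arm-bias folding, distribution comparison, gamma interference and Lint_norm."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from meiopattern import patterning_stats as ps
from meiopattern import synthetic_data as sd


class TestFoldPositions:
    @pytest.mark.parametrize("s,L,expected", [(0.8, 1.0, 0.2), (0.5, 1.0, 0.5),
                                              (0.0, 1.0, 0.0), (2.0, 10.0, 0.2)])
    def test_fold_values(self, s, L, expected):
        out = ps.fold_positions([s], L)
        assert out.values[0] == pytest.approx(expected)

    def test_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            ps.fold_positions([1.5], 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 10.0), min_size=1, max_size=20))
    def test_idempotent_and_reflection_invariant(self, raw):
        s = np.asarray(raw)
        L = 10.0
        once = ps.fold_positions(s, L)
        twice = ps.fold_positions(once.values, 1.0)
        assert np.allclose(once.values, twice.values)
        mirrored = ps.fold_positions(L - s, L)
        assert np.allclose(np.sort(once.values), np.sort(mirrored.values))


class TestShiftCorrect:
    def test_identical_samples_zero_shift(self, rng):
        v = ps.FoldedPositions(rng.random(100) * 0.5)
        out = ps.shift_correct(v, v)
        assert out.shift == 0.0

    def test_known_offset_recovered(self, rng):
        ref = ps.FoldedPositions(0.1 + rng.random(200) * 0.3)
        target = ps.FoldedPositions(ref.values - 0.062)
        out = ps.shift_correct(target, ref)
        assert out.shift == pytest.approx(0.062, abs=1e-12)
        assert np.median(out.values) == pytest.approx(np.median(ref.values))

    def test_corrected_median_matches_reference(self, rng):
        ref = ps.FoldedPositions(rng.random(151) * 0.4 + 0.05)
        target = ps.FoldedPositions(rng.random(151) * 0.3)
        out = ps.shift_correct(target, ref)
        assert np.median(out.values) == pytest.approx(np.median(ref.values), abs=1e-9)


class TestCompareDistributions:
    def test_self_distance_zero(self, rng):
        v = ps.FoldedPositions(rng.random(50) * 0.5, label="a")
        w = ps.FoldedPositions(v.values.copy(), label="b")
        out = ps.compare_distributions([v, w])
        assert out["wasserstein"].iloc[0] == 0.0

    def test_point_masses_analytic(self):
        a = ps.FoldedPositions(np.full(10, 0.1), "a")
        b = ps.FoldedPositions(np.full(10, 0.3), "b")
        out = ps.compare_distributions([a, b])
        assert out["wasserstein"].iloc[0] == pytest.approx(0.2)

    def test_same_distribution_not_significant(self):
        rng = np.random.default_rng(11)
        a = ps.FoldedPositions(rng.random(1000) * 0.5, "a")
        b = ps.FoldedPositions(rng.random(1000) * 0.5, "b")
        out = ps.compare_distributions([a, b])
        assert out["ks_p_adj"].iloc[0] > 0.05

    def test_triangle_inequality(self, rng):
        xs = [ps.FoldedPositions(rng.random(200) * 0.5) for _ in range(2)]
        xs.append(ps.FoldedPositions(np.clip(rng.normal(0.1, 0.05, 200), 0, 0.5)))
        for s, lab in zip(xs, "abc"):
            s.label = lab
        out = ps.compare_distributions(xs).set_index(["sample_a", "sample_b"])
        w = out["wasserstein"]
        assert w[("a", "c")] <= w[("a", "b")] + w[("b", "c")] + 1e-12


class TestGammaShape:
    def test_poisson_spacing_gives_shape_one(self):
        d = np.random.default_rng(4).exponential(1.0, 5000)
        fit = ps.fit_gamma_shape(d, n_bootstrap=50, rng=0)
        assert 0.9 <= fit.shape <= 1.1

    def test_strong_interference_shape_recovered(self):
        d = np.random.default_rng(7).gamma(40.0, 1.0, 5000)
        fit = ps.fit_gamma_shape(d, n_bootstrap=50, rng=0)
        assert fit.shape == pytest.approx(40.0, rel=0.10)

    def test_shape_monotone_in_interference_strength(self):
        rng = np.random.default_rng(9)
        shapes = []
        for true in (1.0, 4.6, 40.0):
            d = rng.gamma(true, 1.0, 3000)
            shapes.append(ps.fit_gamma_shape(d, n_bootstrap=10, rng=0).shape)
        assert shapes[0] < shapes[1] < shapes[2]

    def test_constant_distances_degenerate(self):
        fit = ps.fit_gamma_shape(np.full(100, 0.3), n_bootstrap=10, rng=0)
        assert fit.degenerate and fit.shape >= ps.GAMMA_SHAPE_CAP

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            ps.fit_gamma_shape(np.array([0.1, 0.2, -0.1, 0.3, 0.2]))


class TestLintNorm:
    def test_poisson_placement_near_zero(self):
        rng = np.random.default_rng(6)
        chroms = [rng.random(rng.poisson(2.0)) for _ in range(1000)]
        out = ps.lint_norm(chroms, np.ones(1000))
        # bootstrap CI of the null statistic at n=1000 is a few percent wide
        assert abs(out["lint_norm"]) < 0.05

    def test_one_focus_per_chromosome_maximal(self):
        chroms = [np.array([0.3])] * 100
        out = ps.lint_norm(chroms, np.ones(100))
        assert out["lint_norm"] == 1.0

    def test_persistent_preset_exceeds_uniform_poisson(self):
        kin = sd.FocusKineticsConfig(persistent_per_chromosome=None,
                                     n_blinking_sites_per_chromosome=0)
        rng = np.random.default_rng(8)
        _, pl = sd.gen_sc_traces(kin, n_nuclei=34, rng=rng)   # ~200 chromosomes
        pers = pl[pl.label == "persistent"]
        chroms, nuclei = [], []
        for (nid, tid), grp in pers.groupby(["nucleus_id", "trace_id"]):
            chroms.append(grp["arc_frac"].to_numpy())
            nuclei.append(nid)
        structured = ps.lint_norm(chroms, np.ones(len(chroms)), nuclei)
        null_chroms = [rng.random(rng.poisson(1.7)) for _ in range(len(chroms))]
        null = ps.lint_norm(null_chroms, np.ones(len(chroms)),
                            np.repeat(np.arange(34), 6)[: len(chroms)])
        a = [v for v in structured["per_nucleus"].values() if np.isfinite(v)]
        b = [v for v in null["per_nucleus"].values() if np.isfinite(v)]
        assert stats.mannwhitneyu(a, b, alternative="greater").pvalue < 0.01

    def test_invariant_to_relabeling_and_rescaling(self):
        rng = np.random.default_rng(10)
        chroms = [rng.random(rng.integers(1, 4)) * 5.0 for _ in range(50)]
        base = ps.lint_norm(chroms, np.full(50, 5.0))["lint_norm"]
        perm = rng.permutation(50)
        shuffled = ps.lint_norm([chroms[i] for i in perm], np.full(50, 5.0))["lint_norm"]
        scaled = ps.lint_norm([c * 3.0 for c in chroms], np.full(50, 15.0))["lint_norm"]
        assert base == shuffled == scaled

    def test_no_foci_rejected(self):
        with pytest.raises(ValueError):
            ps.lint_norm([np.empty(0)] * 20, np.ones(20))


class TestNeighborIntensityCorrelation:
    def test_identical_series_perfectly_correlated(self, rng):
        pos = np.arange(6, dtype=float)
        base = rng.random((3, 20))
        inten = np.repeat(base, 2, axis=0)  # neighbors share a series
        r, p, pairs = ps.neighbor_intensity_correlation(pos, inten, mode="1D")
        assert r == pytest.approx(1.0)

    def test_complementary_series_anticorrelated(self, rng):
        pos = np.arange(6, dtype=float)
        x = rng.random((3, 30))
        inten = np.empty((6, 30))
        inten[0::2] = x
        inten[1::2] = 1.0 - x   # material conservation between neighbors
        r, _, _ = ps.neighbor_intensity_correlation(pos, inten, mode="1D")
        assert r == pytest.approx(-1.0)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(3)
        pos = rng.random((8, 3)) * 5
        inten = rng.random((8, 500))
        r, _, _ = ps.neighbor_intensity_correlation(pos, inten, mode="3D")
        assert abs(r) < 0.1

    def test_constant_series_flagged(self):
        pos = np.arange(6, dtype=float)
        with pytest.raises(ValueError):
            ps.neighbor_intensity_correlation(pos, np.ones((6, 10)))


class TestArmCenterContingency:
    def test_extreme_table_significant(self):
        a = ps.FoldedPositions(np.full(10, 0.1))
        b = ps.FoldedPositions(np.full(10, 0.45))
        _, p, table = ps.arm_center_contingency(a, b)
        assert p < 0.001
        assert table.tolist() == [[10, 0], [0, 10]]

    def test_identical_proportions_null(self):
        a = ps.FoldedPositions(np.concatenate([np.full(5, 0.1), np.full(5, 0.45)]))
        odds, p, _ = ps.arm_center_contingency(a, a)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_90_10_vs_50_50_matches_hypergeometric_enumeration(self):
        a = ps.FoldedPositions(np.concatenate([np.full(90, 0.1), np.full(10, 0.45)]))
        b = ps.FoldedPositions(np.concatenate([np.full(50, 0.1), np.full(50, 0.45)]))
        odds, p, table = ps.arm_center_contingency(a, b)
        assert odds == pytest.approx(9.0)
        # independent oracle: full hypergeometric enumeration of tables with
        # the same margins, summing probabilities <= that of the observed table
        n_row = table.sum(axis=1)
        n_col = table.sum(axis=0)
        n = table.sum()
        probs = []
        for k in range(max(0, n_col[0] - n_row[1]), min(n_row[0], n_col[0]) + 1):
            probs.append((k, stats.hypergeom.pmf(k, n, n_row[0], n_col[0])))
        p_obs = dict(probs)[table[0, 0]]
        p_exact = sum(pr for _, pr in probs if pr <= p_obs * (1 + 1e-9))
        assert p == pytest.approx(p_exact, rel=1e-6)
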