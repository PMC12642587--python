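"""SMLM localization filtering, clustering, ellipse fitting and contact classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from meiopattern import smlm_nodules as sn
from meiopattern import synthetic_data as sd


def _loc_table(xyz, pxy=10.0, pz=20.0):
    df = pd.DataFrame(np.atleast_2d(xyz), columns=["x", "y", "z"])
    df["precision_xy"] = pxy
    df["precision_z"] = pz
    df["channel"] = "nodule"
    return df


class TestQualityFilter:
    def test_out_of_focus_removed_boundaries_inclusive(self):
        df = _loc_table([[0, 0, 350], [0, 0, 300], [0, 0, -300], [0, 0, 0]])
        out = sn.quality_filter(df)
        assert len(out) == 3

    def test_precision_bounds_inclusive(self):
        df = _loc_table([[0, 0, 0]] * 3)
        df.loc[0, "precision_xy"] = 15.0   # kept
        df.loc[1, "precision_xy"] = 15.1   # removed
        df.loc[2, "precision_z"] = 26.0    # removed
        assert len(sn.quality_filter(df)) == 1

    def test_enumerated_mixed_table(self, rng):
        df = _loc_table(rng.normal(0, 50, size=(100, 3)))
        bad = rng.choice(100, 30, replace=False)
        df.loc[bad[:10], "z"] = 500.0
        df.loc[bad[10:20], "precision_xy"] = 20.0
        df.loc[bad[20:], "precision_z"] = 30.0
        assert len(sn.quality_filter(df)) == 70

    def test_idempotent(self, rng):
        df = _loc_table(rng.normal(0, 100, size=(50, 3)))
        once = sn.quality_filter(df)
        pd.testing.assert_frame_equal(once, sn.quality_filter(once))

    def test_missing_columns_error(self):
        with pytest.raises(ValueError):
            sn.quality_filter(pd.DataFrame({"x": [1.0]}))


class TestAxisCenterline:
    def test_two_parallel_lines_bisected(self):
        xs = np.linspace(0, 1500, 400)
        pts = np.vstack([
            np.column_stack([xs, np.full(400, 75.0), np.zeros(400)]),
            np.column_stack([xs, np.full(400, -75.0), np.zeros(400)]),
        ])
        out = sn.axis_centerline(_loc_table(pts))
        assert np.max(np.abs(out["midline"][:, 1])) < 5.0
        assert out["separation_nm"] == pytest.approx(150.0, abs=5.0)

    def test_generator_axis_pair_rmse_within_15nm(self):
        gt = sd.NoduleGroundTruth(axis_separation=150, precision_xy=10, precision_z=20)
        _, axis = sd.gen_smlm_nodule(gt, n_axis_localizations=3000, rng=5)
        out = sn.axis_centerline(axis)
        rmse = np.sqrt(np.mean(out["midline"][:, 1] ** 2))  # true midline is y=0
        assert rmse <= 15.0
        assert not out["degenerate"]

    def test_single_strand_flagged_degenerate(self, rng):
        xs = np.linspace(0, 1200, 500)
        pts = np.column_stack([xs, rng.normal(0, 8, 500), rng.normal(0, 8, 500)])
        out = sn.axis_centerline(_loc_table(pts))
        assert out["degenerate"]
        assert out["separation_nm"] < 40.0

    def test_short_cloud_rejected(self, rng):
        pts = rng.normal(0, 50, size=(100, 3))
        with pytest.raises(ValueError):
            sn.axis_centerline(_loc_table(pts))


def brute_force_dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Literal density-reachability enumeration (independent oracle)."""
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None], axis=-1)
    neighbors = [set(np.nonzero(d[i] <= eps)[0]) for i in range(n)]  # includes self
    core = [len(neighbors[i]) >= min_pts for i in range(n)]
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        # expand cluster from this core point
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    if core[k]:
                        stack.append(k)
        cluster += 1
    return labels


class TestClusterCandidates:
    def _centerline(self):
        xs = np.linspace(-1000, 1000, 100)
        return np.column_stack([xs, np.zeros(100), np.zeros(100)])

    def test_dense_blob_on_centerline_is_one_cluster(self, rng):
        pts = rng.normal(0, 30, size=(50, 3))
        out = sn.cluster_candidates(_loc_table(pts), self._centerline())
        assert len(out) == 1

    def test_below_min_pts_no_cluster(self, rng):
        pts = rng.normal(0, 10, size=(10, 3))
        assert sn.cluster_candidates(_loc_table(pts), self._centerline()) == []

    def test_offset_blob_clustered_but_not_retained(self, rng):
        pts = rng.normal(0, 20, size=(50, 3)) + [0, 200, 0]
        out = sn.cluster_candidates(_loc_table(pts), self._centerline())
        assert out == []

    def test_matches_brute_force_density_reachability(self):
        rng = np.random.default_rng(21)
        # three blobs + scatter, gated region only
        pts = np.vstack([
            rng.normal(0, 25, size=(60, 3)),
            rng.normal(0, 25, size=(60, 3)) + [600, 0, 0],
            rng.normal(0, 120, size=(60, 3)),
        ])
        from sklearn.cluster import DBSCAN

        skl = DBSCAN(eps=100.0, min_samples=20).fit_predict(pts)
        ours = brute_force_dbscan(pts, 100.0, 20)
        # same partition up to label permutation, identical noise set
        assert np.array_equal(skl == -1, ours == -1)
        for lab in set(skl) - {-1}:
            members = ours[skl == lab]
            assert len(set(members)) == 1


class TestEllipsePerimeter:
    def test_circle_closed_form(self):
        assert sn.ellipse_perimeter(100, 100) == pytest.approx(2 * np.pi * 100, abs=1e-9)

    def test_matches_quadrature_oracle(self):
        a, b = 150.0, 80.0
        oracle, _ = integrate.quad(
            lambda t: np.hypot(-a * np.sin(t), b * np.cos(t)), 0, 2 * np.pi
        )
        assert sn.ellipse_perimeter(a, b) == pytest.approx(oracle, rel=1e-4)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(80.0, 400.0), st.floats(80.0, 400.0))
    def test_monotone_in_major_span(self, a1, a2):
        b = 80.0
        lo, hi = sorted([a1, a2])
        assert sn.ellipse_perimeter(hi, b) >= sn.ellipse_perimeter(lo, b)


class TestFitEllipse:
    def test_circle_recovered_within_10pct(self):
        gt = sd.NoduleGroundTruth(kind="doublet", a=100, b=100,
                                  precision_xy=10, precision_z=20, n_localizations=300)
        nod, _ = sd.gen_smlm_nodule(gt, rng=13)
        fit = sn.fit_ellipse(nod)
        assert fit.a == pytest.approx(100, rel=0.10)
        assert fit.b == pytest.approx(100, rel=0.10)

    def test_ellipse_spans_and_rotation_recovered(self):
        gt = sd.NoduleGroundTruth(kind="doublet", a=150, b=80, rotation=(0, 0, 0.5),
                                  precision_xy=10, precision_z=20, n_localizations=300)
        nod, _ = sd.gen_smlm_nodule(gt, rng=11)
        fit = sn.fit_ellipse(nod)
        assert fit.a == pytest.approx(150, rel=0.15)
        assert fit.b == pytest.approx(80, rel=0.15)
        in_plane = fit.rotation[2] % np.pi
        assert min(abs(in_plane - 0.5), abs(in_plane - 0.5 - np.pi),
                   abs(in_plane - 0.5 + np.pi)) < np.deg2rad(10)
        assert not fit.degenerate

    def test_tight_blob_degenerates(self):
        gt = sd.NoduleGroundTruth(kind="singlet", n_localizations=120)
        nod, _ = sd.gen_smlm_nodule(gt, rng=14)
        fit = sn.fit_ellipse(nod)
        assert fit.degenerate

    def test_too_few_localizations_rejected(self, rng):
        with pytest.raises(ValueError):
            sn.fit_ellipse(_loc_table(rng.normal(size=(10, 3))))


class TestClassifyContact:
    def test_generator_doublet_contacts_both_axes(self):
        gt = sd.NoduleGroundTruth(kind="doublet", a=150, b=80, axis_separation=150,
                                  precision_xy=10, precision_z=20)
        nod, axis = sd.gen_smlm_nodule(gt, rng=2)
        cl = sn.axis_centerline(axis)
        cands = sn.cluster_candidates(nod, cl["midline"])
        assert len(cands) == 1
        assert sn.classify_contact(cands[0], cl["strand_a"], cl["strand_b"],
                                   cl["degenerate"]) == "both_axes"

    def test_generator_singlet_contacts_one_axis(self):
        gt = sd.NoduleGroundTruth(kind="singlet", axis_separation=150,
                                  precision_xy=10, precision_z=20)
        nod, axis = sd.gen_smlm_nodule(gt, rng=3)
        cl = sn.axis_centerline(axis)
        cands = sn.cluster_candidates(nod, cl["midline"])
        assert len(cands) == 1
        assert sn.classify_contact(cands[0], cl["strand_a"], cl["strand_b"],
                                   cl["degenerate"]) == "one_axis"

    def test_far_cluster_unclear(self, rng):
        xs = np.linspace(0, 1000, 50)
        strand_a = np.column_stack([xs, np.full(50, 75.0), np.zeros(50)])
        strand_b = np.column_stack([xs, np.full(50, -75.0), np.zeros(50)])
        members = _loc_table(rng.normal(0, 10, size=(30, 3)) + [500, 0, 375])
        cluster = sn.NoduleCluster(0, members, np.array([500, 0, 375.0]), 100.0)
        assert sn.classify_contact(cluster, strand_a, strand_b) == "unclear"


class TestComparePerimeters:
    def test_identical_groups_null(self, rng):
        v = rng.normal(700, 50, 30)
        out = sn.compare_perimeters({"a": v, "b": v.copy()})
        assert out["omnibus_p"] > 0.9

    def test_shifted_groups_all_significant(self):
        rng = np.random.default_rng(6)
        g = {
            "a": rng.normal(500, 30, 30),
            "b": rng.normal(590, 30, 30),
            "c": rng.normal(680, 30, 30),
        }
        out = sn.compare_perimeters(g)
        assert out["omnibus_p"] < 0.01
        assert (out["pairwise"]["p_adj"] < 0.01).all()

    def test_single_shifted_group_two_significant_pairs(self):
        rng = np.random.default_rng(8)
        g = {
            "a": rng.normal(500, 30, 30),
            "b": rng.normal(500, 30, 30),
            "c": rng.normal(650, 30, 30),
        }
        out = sn.compare_perimeters(g)
        sig = out["pairwise"][out["pairwise"]["p_adj"] < 0.01]
        assert len(sig) == 2
        assert set(sig["group_b"]) == {"c"}


class TestEquivariance:
    def test_rotating_localizations_leaves_spans_unchanged(self):
        from scipy.spatial.transform import Rotation

        gt = sd.NoduleGroundTruth(kind="doublet", a=150, b=80,
                                  precision_xy=10, precision_z=20, n_localizations=250)
        nod, _ = sd.gen_smlm_nodule(gt, rng=19)
        fit1 = sn.fit_ellipse(nod)
        r = Rotation.from_euler("z", 0.7).as_matrix()
        rotated = nod.copy()
        rotated[["x", "y", "z"]] = nod[["x", "y", "z"]].to_numpy() @ r.T
        fit2 = sn.fit_ellipse(rotated)
        assert fit2.a == pytest.approx(fit1.a, rel=0.10)
        assert fit2.b == pytest.approx(fit1.b, rel=0.10)
        assert fit2.perimeter == pytest.approx(fit1.perimeter, rel=0.10)
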