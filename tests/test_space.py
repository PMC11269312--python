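"""Acoustic-space statistics: PCA basis, maps, shrinkage test, discriminant,
trajectory correlations, and the rotation-vs-contraction control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import crysig.space as sp
from crysig.space import SpaceError


def _map_from_coords(coords_a, coords_b, babies=None):
    """Build an AcousticMap directly from 2D coordinates per condition."""
    n = len(coords_a)
    babies = babies or [f"B{i:02d}" for i in range(n)]
    rows = []
    for cond, pts in (("discomfort", coords_a), ("pain", coords_b)):
        for b, (x, y) in zip(babies, pts):
            rows.append({"baby_id": b, "condition": cond, "PC1": x, "PC2": y})
    df = pd.DataFrame(rows)
    centroids, dispersions = {}, {}
    for cond, sub in df.groupby("condition"):
        c = sub[["PC1", "PC2"]].to_numpy().mean(axis=0)
        centroids[cond] = c
        dispersions[cond] = float(
            np.linalg.norm(sub[["PC1", "PC2"]].to_numpy() - c, axis=1).mean()
        )
    return sp.AcousticMap(coords=df, centroids=centroids, dispersions=dispersions)


class TestPCA:
    def test_planar_data_two_components(self):
        rng = np.random.default_rng(0)
        basisvecs = rng.standard_normal((2, 30))
        X = rng.standard_normal((40, 2)) @ basisvecs
        b = sp.fit_mps_pca(X, 2)
        assert b.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_refit_deterministic_sign_convention(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 12))
        b1 = sp.fit_mps_pca(X, 4)
        b2 = sp.fit_mps_pca(X, 4)
        np.testing.assert_allclose(b1.components, b2.components)
        for comp in b1.components:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(SpaceError):
            sp.fit_mps_pca(np.zeros((5, 10)), 5)

    def test_projection_of_mean_is_origin(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 6))
        b = sp.fit_mps_pca(X, 3)
        np.testing.assert_allclose(sp.project(b, X.mean(axis=0)), 0.0, atol=1e-10)


class TestMap:
    def test_identical_cries_coincide(self):
        X = np.tile(np.arange(6.0), (8, 1)) + 0.0
        rng = np.random.default_rng(3)
        fitX = rng.standard_normal((10, 6))
        basis = sp.fit_mps_pca(fitX, 2)
        babies = ["A", "A", "B", "B", "C", "C", "D", "D"]
        conds = ["discomfort", "pain"] * 4
        amap = sp.map_babies(X, babies, conds, basis)
        assert np.allclose(amap.coords[["PC1", "PC2"]].std().to_numpy(), 0.0)

    def test_baby_missing_condition_excluded_with_warning(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((5, 6))
        basis = sp.fit_mps_pca(rng.standard_normal((10, 6)), 2)
        babies = ["A", "A", "B", "B", "C"]
        conds = ["discomfort", "pain", "discomfort", "pain", "discomfort"]
        with pytest.warns(UserWarning, match="C"):
            amap = sp.map_babies(X, babies, conds, basis)
        assert set(amap.coords.baby_id) == {"A", "B"}


class TestShrinkageTest:
    def test_identical_coordinates_null(self):
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((6, 2))
        res = sp.centroid_shrinkage_test(_map_from_coords(pts, pts))
        assert res.mean_difference == pytest.approx(0.0)
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_paired_t(self):
        """Distances (2,3,4) vs (1,1,1): t must equal the closed-form value."""
        a = np.array([[2.0, 0], [0, 3.0], [-4.0, 0]])
        b = np.array([[1.0, 0], [0, 1.0], [-1.0, 0]])
        amap = _map_from_coords(a, b)
        # recentre so the centroid is the origin for both conditions
        amap.centroids = {"discomfort": np.zeros(2), "pain": np.zeros(2)}
        res = sp.centroid_shrinkage_test(amap)
        d = np.array([2, 3, 4]) - np.array([1, 1, 1])
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert res.t_statistic == pytest.approx(t_hand)
        assert res.df == 2

    def test_distances_invariant_to_rotation(self):
        rng = np.random.default_rng(6)
        a, b = rng.standard_normal((8, 2)), 0.5 * rng.standard_normal((8, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        r1 = sp.centroid_shrinkage_test(_map_from_coords(a, b))
        r2 = sp.centroid_shrinkage_test(_map_from_coords(a @ R.T, b @ R.T))
        assert r1.t_statistic == pytest.approx(r2.t_statistic)
        np.testing.assert_allclose(np.sort(r1.distances_a), np.sort(r2.distances_a))

    def test_too_few_babies_rejected(self):
        pts = np.zeros((2, 2))
        with pytest.raises(SpaceError):
            sp.centroid_shrinkage_test(_map_from_coords(pts, pts))


class TestRotationVsContraction:
    """Shrinkage must appear in both bases only under true contraction.

    When pain signatures are merely rotated into other acoustic dimensions,
    the basis fitted on discomfort shows an apparent contraction, but the
    basis fitted on pain shows none (the mirror-image control); with a real
    contraction both bases agree.
    """

    @staticmethod
    def _run(case, seed=0):
        rng = np.random.default_rng(seed)
        n, d = 20, 12
        signatures = rng.standard_normal((n, 2)) * 4.0
        noise = 0.3
        disc = np.zeros((n, d))
        disc[:, 0:2] = signatures
        pain = np.zeros((n, d))
        if case == "rotated":
            pain[:, 2:4] = signatures  # same dispersion, different dimensions
        else:
            pain[:, 0:2] = 0.3 * signatures  # contracted in place
        disc += noise * rng.standard_normal((n, d))
        pain += noise * rng.standard_normal((n, d))
        out = {}
        for fit_on, name in ((disc, "discomfort-basis"), (pain, "pain-basis")):
            basis = sp.fit_mps_pca(fit_on, 2)
            X = np.vstack([disc, pain])
            babies = [f"B{i:02d}" for i in range(n)] * 2
            conds = ["discomfort"] * n + ["pain"] * n
            amap = sp.map_babies(X, babies, conds, basis)
            out[name] = sp.centroid_shrinkage_test(amap)
        return out

    def test_rotated_signatures_shrink_in_one_basis_only(self):
        res = self._run("rotated")
        assert res["discomfort-basis"].t_statistic > 2.0
        assert res["pain-basis"].t_statistic < 0  # expansion, not shrinkage

    def test_contracted_signatures_shrink_in_both_bases(self):
        res = self._run("contracted")
        assert res["discomfort-basis"].t_statistic > 2.0
        assert res["pain-basis"].t_statistic > 2.0


class TestDiscriminant:
    def test_recovers_known_direction(self):
        rng = np.random.default_rng(7)
        w_true = np.array([3.0, 4.0]) / 5.0
        X = rng.standard_normal((200, 2))
        labels = np.where(X @ w_true + 0.3 * rng.standard_normal(200) > 0, "pain", "discomfort")
        axis = sp.condition_discriminant(X, labels)
        angle = np.degrees(np.arccos(np.clip(np.abs(axis.loading @ w_true), 0, 1)))
        assert angle < 10.0
        assert axis.class_means["pain"] > axis.class_means["discomfort"]

    def test_null_distributions_overlap(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((300, 5))
        labels = np.array(["discomfort", "pain"] * 150)
        axis = sp.condition_discriminant(X, labels)
        pooled = axis.per_cry_projection.std()
        gap = abs(axis.class_means["pain"] - axis.class_means["discomfort"])
        assert gap < 0.1 * pooled + 0.2 * pooled  # no real separation

    def test_single_class_rejected(self):
        with pytest.raises(SpaceError):
            sp.condition_discriminant(np.zeros((10, 3)), ["pain"] * 10)


class TestTrajectoryCorrelation:
    @staticmethod
    def _axis_coords(babies, x_disc, x_pain):
        rows = []
        for b, xd, xp in zip(babies, x_disc, x_pain):
            rows.append({"baby_id": b, "condition": "discomfort", "projection": xd})
            rows.append({"baby_id": b, "condition": "pain", "projection": xp})
        return pd.DataFrame(rows)

    def test_perfect_correlation(self):
        n = 8
        babies = [f"B{i:02d}" for i in range(n)]
        x = np.arange(n, dtype=float)
        pts_d = np.column_stack([x, np.zeros(n)])
        pts_p = np.column_stack([x * 0.5, np.zeros(n)])
        amap = _map_from_coords(pts_d, pts_p, babies)
        traj = sp.trajectory_correlation(
            amap, self._axis_coords(babies, x, x * 0.5), pc_index=1
        )
        assert traj.r_discomfort == pytest.approx(1.0)
        assert traj.p_discomfort < 1e-6

    def test_null_correlation_stays_small(self):
        """Independent coordinates at n=22: |r| < 0.45 in >= 90% of seeds."""
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            n = 22
            babies = [f"B{i:02d}" for i in range(n)]
            amap = _map_from_coords(
                rng.standard_normal((n, 2)), rng.standard_normal((n, 2)), babies
            )
            traj = sp.trajectory_correlation(
                amap,
                self._axis_coords(babies, rng.standard_normal(n), rng.standard_normal(n)),
            )
            hits += abs(traj.r_discomfort) < 0.45
        assert hits >= 18

    def test_zero_variance_rejected(self):
        babies = [f"B{i:02d}" for i in range(6)]
        amap = _map_from_coords(np.zeros((6, 2)), np.zeros((6, 2)), babies)
        with pytest.raises(SpaceError):
            sp.trajectory_correlation(
                amap, self._axis_coords(babies, np.arange(6.0), np.arange(6.0))
            )

    def test_aligned_identity_and_condition_dimensions(self):
        """When the identity dimension coincides with the condition dimension,
        the per-baby axis projection correlates strongly with PC1."""
        rng = np.random.default_rng(9)
        n = 22
        babies = [f"B{i:02d}" for i in range(n)]
        sig = np.sort(rng.standard_normal(n)) * 3
        pts_d = np.column_stack([sig, 0.2 * rng.standard_normal(n)])
        pts_p = np.column_stack([0.4 * sig + 1.0, 0.2 * rng.standard_normal(n)])
        amap = _map_from_coords(pts_d, pts_p, babies)
        traj = sp.trajectory_correlation(
            amap,
            self._axis_coords(
                babies,
                sig + 0.3 * rng.standard_normal(n),
                0.4 * sig + 1 + 0.3 * rng.standard_normal(n),
            ),
        )
        assert traj.r_discomfort > 0.8
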