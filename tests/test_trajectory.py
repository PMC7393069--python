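"""Trajectory space, branch isolation, scaling, and smoothing."""

import numpy as np
import pandas as pd
import pytest

from becatlas import trajectory
from becatlas.core import BecatlasError, NormMatrix


def line_traj(n=10, spacing=1.0, k=2, L=None):
    pcs = (np.arange(n) * spacing)[:, None]
    ids = np.array([f"c{i:02d}" for i in range(n)], dtype=object)
    return trajectory.tspace(pcs, k=k, L=L or n, seed=0, cell_ids=ids), ids


class TestTspace:
    def test_path_graph_distances_are_index_differences(self):
        spacing = 2.5
        traj, ids = line_traj(n=10, spacing=spacing)
        # column ell holds distances from seed ell; geodesic on a path is
        # |i - seed| * spacing
        for col, seed in enumerate(traj.seed_indices):
            expected = np.abs(np.arange(10) - seed) * spacing
            assert np.allclose(traj.T[:, col], expected)

    def test_graph_metric_triangle_inequality(self, rng):
        pcs = rng.normal(size=(60, 4))
        traj = trajectory.tspace(pcs, k=5, L=20, seed=1)
        from scipy.sparse.csgraph import dijkstra

        pairs = rng.choice(60, size=(30, 2))
        geo = dijkstra(traj.graph, directed=False,
                       indices=np.unique(pairs[:, 0]))
        row_of = {c: i for i, c in enumerate(np.unique(pairs[:, 0]))}
        for i, j in pairs:
            g_ij = geo[row_of[i], j]
            assert (np.abs(traj.T[i] - traj.T[j]) <= g_ij + 1e-9).all()

    def test_seed_prefix_property(self, rng):
        pcs = rng.normal(size=(50, 3))
        ids = np.array([f"c{i:02d}" for i in range(50)], dtype=object)
        a = trajectory.tspace(pcs, k=5, L=10, seed=3, cell_ids=ids)
        b = trajectory.tspace(pcs, k=5, L=20, seed=3, cell_ids=ids)
        assert np.array_equal(a.seed_indices, b.seed_indices[:10])
        assert np.allclose(a.T, b.T[:, :10])

    def test_cell_order_invariance_up_to_sign(self, rng):
        pcs = rng.normal(size=(40, 3))
        ids = np.array([f"c{i:02d}" for i in range(40)], dtype=object)
        perm = rng.permutation(40)
        a = trajectory.tspace(pcs, k=5, L=12, seed=2, cell_ids=ids)
        b = trajectory.tspace(pcs[perm], k=5, L=12, seed=2, cell_ids=ids[perm])
        back = np.empty_like(b.T)
        back[perm] = b.T
        assert np.allclose(np.sort(a.T, axis=1), np.sort(back, axis=1))

    def test_too_many_seeds_rejected(self, rng):
        with pytest.raises(BecatlasError):
            trajectory.tspace(rng.normal(size=(10, 2)), k=3, L=11)


class TestIsolateBranch:
    def setup_line(self):
        traj, ids = line_traj(n=30, k=3, L=10)
        labels = pd.Series(
            np.where(np.arange(30) < 10, "root",
                     np.where(np.arange(30) < 20, "mid", "tip")),
            index=ids)
        return traj, labels

    def test_wide_gates_select_all_named_subsets(self):
        traj, labels = self.setup_line()
        path = trajectory.isolate_branch(
            traj, labels, ["mid", "tip"], ["root"],
            gates={0: (-np.inf, np.inf)})
        assert len(path.cell_indices) == 20

    def test_distances_non_decreasing_along_order(self):
        traj, labels = self.setup_line()
        path = trajectory.isolate_branch(traj, labels, ["mid", "tip"],
                                         ["root"])
        assert (np.diff(path.distance) >= -1e-12).all()

    def test_disjoint_gate_rejected(self):
        traj, labels = self.setup_line()
        with pytest.raises(BecatlasError):
            trajectory.isolate_branch(traj, labels, ["mid"], ["root"],
                                      gates={0: (1e9, 2e9)})


class TestScaleDistances:
    def make_path(self, dist, name="p"):
        n = len(dist)
        return trajectory.BranchPath(name, np.arange(n),
                                     np.array([f"c{i}" for i in range(n)]),
                                     np.asarray(dist, dtype=float))

    def test_single_path_max_is_one(self):
        out = trajectory.scale_distances([self.make_path([0, 1, 4])])
        assert out[0].scaled.max() == 1.0

    def test_two_paths_share_the_longest_scale(self):
        a = self.make_path([0, 2, 5], "a")
        b = self.make_path([0, 4, 10], "b")
        sa, sb = trajectory.scale_distances([a, b])
        assert sb.scaled.max() == 1.0
        assert sa.scaled.max() == pytest.approx(0.5)

    def test_ratios_preserved_exactly(self):
        p = self.make_path([0, 1, 3, 9])
        (s,) = trajectory.scale_distances([p])
        assert np.allclose(s.scaled / s.scaled[-1], p.distance / 9)

    def test_zero_length_rejected(self):
        with pytest.raises(BecatlasError):
            trajectory.scale_distances([self.make_path([0, 0])])


class TestSmoothAlong:
    def make_path(self):
        d = np.linspace(0, 1, 50)
        return trajectory.BranchPath("p", np.arange(50),
                                     np.array([f"c{i}" for i in range(50)]),
                                     d, scaled=d)

    def test_constant_signal_smooths_to_constant(self):
        path = self.make_path()
        _, sm = trajectory.smooth_along(path, np.full(50, 2.3), h=0.05)
        assert np.allclose(sm, 2.3, atol=1e-12)

    def test_tiny_bandwidth_recovers_samples(self, rng):
        path = self.make_path()
        y = rng.normal(size=50)
        _, sm = trajectory.smooth_along(path, y, h=1e-4,
                                        grid=path.scaled)
        assert np.allclose(sm.ravel(), y, atol=1e-8)

    def test_planted_logistic_ramp_recovered(self):
        path = self.make_path()
        s = path.scaled
        true = 1.0 / (1.0 + np.exp(-(s - 0.5) / 0.1))
        rng = np.random.default_rng(4)
        noisy = true + rng.normal(0, 0.1, size=50)
        gpos, sm = trajectory.smooth_along(path, noisy, h=0.05)
        ref = 1.0 / (1.0 + np.exp(-(gpos - 0.5) / 0.1))
        assert np.abs(sm.ravel() - ref).max() < 0.15

    def test_empty_path_rejected(self):
        p = trajectory.BranchPath("e", np.array([], dtype=int),
                                  np.array([]), np.array([]))
        with pytest.raises(BecatlasError):
            trajectory.smooth_along(p, np.array([]), h=0.05)


class TestHeatmapExport:
    def setup(self, rng):
        n = 60
        d = np.linspace(0, 1, n)
        path = trajectory.BranchPath("p", np.arange(n),
                                     np.array([f"c{i}" for i in range(n)]),
                                     d, scaled=d)
        X = rng.normal(1, 0.2, size=(6, n))
        X[0] += np.linspace(0, 2, n)
        X[5] = 0.0
        genes = [f"g{i}" for i in range(6)]
        norm = NormMatrix(X, genes, [f"c{i}" for i in range(n)], np.ones(n))
        return path, norm, X

    def test_rows_scaled_to_unit_max(self, rng):
        path, norm, X = self.setup(rng)
        hm, order, flagged = trajectory.export_trajectory_heatmap(
            path, {"grp": ["g0", "g1", "g2"]}, X, norm)
        assert np.allclose(hm.max(axis=1), 1.0)

    def test_all_zero_row_flagged_not_scaled(self, rng):
        path, norm, X = self.setup(rng)
        hm, order, flagged = trajectory.export_trajectory_heatmap(
            path, {"z": ["g5", "g1", "g0"]}, X, norm)
        assert "z:g5" in flagged
        assert np.allclose(hm.loc["z:g5"], 0.0)

    def test_duplicate_gene_in_two_groups_appears_twice(self, rng):
        path, norm, X = self.setup(rng)
        hm, order, _ = trajectory.export_trajectory_heatmap(
            path, {"a": ["g0", "g1", "g2"], "b": ["g0", "g3", "g4"]}, X, norm)
        assert "a:g0" in order and "b:g0" in order

    def test_absent_gene_dropped_with_rest_kept(self, rng):
        path, norm, X = self.setup(rng)
        hm, order, _ = trajectory.export_trajectory_heatmap(
            path, {"a": ["g0", "ghost", "g1"]}, X, norm)
        assert all(not r.endswith("ghost") for r in order)
        assert len(order) == 2
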