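"""Trajectory loading, trim/stride arithmetic, series, populations,
densities, clustering, replica pooling and sampling bookkeeping."""

import numpy as np
import pytest
from scipy.stats import norm

import polsensor as ps
from polsensor.trajectory_analysis import frames_per_system, total_sampling_us, \
    equilibration_total_ns


def small_traj(n_frames=6, interval=2.5, seed=0):
    t = ps.make_two_state_trajectory(
        ps.TwoStateParams(n_frames=n_frames, frame_interval=interval, seed=seed))
    return t, t.metadata["sitemap"]


class TestLoadTrajectory:
    def test_multi_model_pdb(self):
        t, _ = small_traj(5)
        text = ps.write_pdb_models([t.frame(i) for i in range(5)])
        loaded = ps.load_trajectory(text, 2.5)
        assert loaded.n_frames == 5
        assert np.allclose(loaded.times, [0, 2.5, 5.0, 7.5, 10.0])
        assert np.allclose(loaded.coords, t.coords, atol=5e-4)

    def test_roster_mismatch_rejected(self):
        t, _ = small_traj(4)
        frames = [t.frame(i) for i in range(4)]
        frames[2] = ps.Structure(frames[2].atoms[:-1], 1)
        with pytest.raises(ps.InconsistentTrajectoryError):
            ps.trajectory_from_structures(frames, 2.5)

    def test_single_frame_ok(self):
        t, _ = small_traj(1)
        loaded = ps.load_trajectory(ps.write_pdb_models([t.frame(0)]), 2.5)
        assert loaded.n_frames == 1

    def test_coordinate_table_input(self):
        import pandas as pd
        t, _ = small_traj(3)
        rows = [{"frame": f, "atom_id": i, "x": c[0], "y": c[1], "z": c[2]}
                for f in range(3) for i, c in enumerate(t.coords[f])]
        loaded = ps.trajectory_from_table(pd.DataFrame(rows), t.topology, 2.5)
        assert np.allclose(loaded.coords, t.coords)


class TestTrimAndSubsample:
    def test_analysis_window_frame_count(self):
        """A 130 ns replica stored every 2.5 ps, trimmed at 30 ns and strided
        to 12.5 ps, leaves 8000 analysis frames."""
        topo = ps.Structure([ps.AtomRecord(1, "CA", "", "GLY", "A", 1, "",
                                           np.zeros(3))])
        coords = np.zeros((52000, 1, 3))
        traj = ps.Trajectory(topo, coords, 2.5)
        out = ps.trim_and_subsample(traj, skip_ns=30.0, every_ps=12.5)
        assert out.n_frames == 8000
        assert out.times[0] == pytest.approx(30000.0)
        assert out.frame_interval == 12.5

    def test_identity_when_nothing_trimmed(self):
        t, _ = small_traj(6)
        out = ps.trim_and_subsample(t, skip_ns=0.0, every_ps=t.frame_interval)
        assert out.n_frames == 6
        assert np.array_equal(out.times, t.times)

    def test_stride_two(self):
        t, _ = small_traj(6, interval=2.5)
        out = ps.trim_and_subsample(t, 0.0, 5.0)
        assert np.allclose(out.times, [0.0, 5.0, 10.0])

    def test_timestamps_selected_never_interpolated(self):
        t, _ = small_traj(11, interval=2.5)
        out = ps.trim_and_subsample(t, skip_ns=0.005, every_ps=5.0)
        assert set(out.times) <= set(t.times)

    def test_errors(self):
        t, _ = small_traj(4, interval=2.5)
        with pytest.raises(ValueError, match="integer multiple"):
            ps.trim_and_subsample(t, 0.0, 4.0)
        with pytest.raises(ValueError, match="discards"):
            ps.trim_and_subsample(t, 1.0, 2.5)


class TestDescriptorSeries:
    def test_degenerate_mixture_limit_is_constant(self):
        t = ps.make_two_state_trajectory(
            ps.TwoStateParams(n_frames=50, p_locked=1.0, locked_sd=1e-9,
                              gate_sd=1e-9, seed=1))
        site = t.metadata["sitemap"]
        s = ps.descriptor_series(t, site, "sensor_angle")
        assert np.allclose(s.values, 160.0, atol=1e-6)

    def test_series_matches_frame_by_frame_oracle(self):
        """Vectorised series equal per-frame evaluation by the descriptors
        module, frame by frame."""
        t, site = small_traj(25, seed=5)
        for kind, fn in (("sensor_angle", ps.sensor_angle),
                         ("gate_distance", ps.gate_distance),
                         ("catalytic_gap", ps.catalytic_gap)):
            series = ps.descriptor_series(t, site, kind)
            oracle = [fn(t.frame(i), site) for i in range(t.n_frames)]
            assert np.allclose(series.values, oracle, atol=1e-9)

    def test_empty_trajectory_rejected(self):
        t, site = small_traj(2)
        empty = ps.Trajectory(t.topology, t.coords[:0], 2.5)
        with pytest.raises(ValueError):
            ps.descriptor_series(empty, site, "sensor_angle")


class TestStatePopulations:
    def test_all_locked(self):
        s = ps.DescriptorSeries("r1", np.arange(4.0), np.full(4, 160.0),
                                "sensor_angle")
        pop = ps.state_populations(s, 140.0)
        assert pop.p_locked == 1.0 and pop.p_unlocked == 0.0
        assert pop.locked_mean == pytest.approx(160.0)
        assert np.isnan(pop.unlocked_mean)

    def test_zero_threshold_boundary(self):
        s = ps.DescriptorSeries("r1", np.arange(3.0), np.array([10.0, 90.0, 170.0]),
                                "sensor_angle")
        assert ps.state_populations(s, 0.0).p_locked == 1.0

    def test_mixture_recovery_at_spec_conditions(self):
        """p_locked = 0.7 at n = 24000 is recovered within 3 binomial SE."""
        t = ps.make_two_state_trajectory(
            ps.TwoStateParams(n_frames=24000, p_locked=0.7, seed=42))
        site = t.metadata["sitemap"]
        pop = ps.state_populations(ps.descriptor_series(t, site, "sensor_angle"),
                                   140.0)
        se3 = 3 * np.sqrt(0.7 * 0.3 / 24000)
        assert abs(pop.p_locked - 0.7) <= se3

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_recovery_grid_against_binomial_oracle(self, p):
        """Across the population grid the threshold estimator matches the
        mixture's analytic exceedance probability at binomial precision,
        and that probability is within 0.006 of the mixing weight itself."""
        n = 24000
        params = ps.TwoStateParams(n_frames=n, p_locked=p, seed=int(1000 * p) + 3)
        q = (p * norm.sf(140.0, params.locked_mean, params.locked_sd)
             + (1 - p) * norm.sf(140.0, params.unlocked_mean, params.unlocked_sd))
        t = ps.make_two_state_trajectory(params)
        pop = ps.state_populations(
            ps.descriptor_series(t, t.metadata["sitemap"], "sensor_angle"), 140.0)
        assert abs(pop.p_locked - q) <= 3 * np.sqrt(q * (1 - q) / n)
        assert abs(q - p) <= 0.006

    def test_empty_series_rejected(self):
        s = ps.DescriptorSeries("r1", np.array([]), np.array([]), "sensor_angle")
        with pytest.raises(ValueError):
            ps.state_populations(s)


class TestDensity2D:
    def test_single_bin(self):
        x = ps.DescriptorSeries("r1", np.arange(5.0), np.full(5, 3.4), "gate_distance")
        y = ps.DescriptorSeries("r1", np.arange(5.0), np.full(5, 160.0), "sensor_angle")
        d = ps.density2d(x, y, [3.0, 3.5, 4.0], [150.0, 165.0, 180.0])
        assert d.counts.sum() == 5
        assert d.counts[0, 0] == 5

    def test_counts_conserved_and_marginals_match_1d(self, rng):
        n = 500
        xv = rng.normal(3.6, 0.4, n)
        yv = rng.uniform(80, 175, n)
        times = np.arange(float(n))
        x = ps.DescriptorSeries("r1", times, xv, "gate_distance")
        y = ps.DescriptorSeries("r1", times, yv, "sensor_angle")
        xe = np.linspace(2.5, 5.0, 11)
        ye = np.linspace(0.0, 180.0, 10)
        d = ps.density2d(x, y, xe, ye)
        assert d.n_frames == n
        np.testing.assert_array_equal(
            d.counts.sum(axis=1),
            np.histogram(np.clip(xv, xe[0], xe[-1] - 1e-9), bins=xe)[0])
        np.testing.assert_array_equal(
            d.counts.sum(axis=0),
            np.histogram(np.clip(yv, ye[0], ye[-1] - 1e-9), bins=ye)[0])

    def test_out_of_range_clipped_and_reported(self):
        times = np.arange(3.0)
        x = ps.DescriptorSeries("r1", times, np.array([0.1, 3.4, 99.0]), "gate_distance")
        y = ps.DescriptorSeries("r1", times, np.full(3, 100.0), "sensor_angle")
        d = ps.density2d(x, y, [3.0, 4.0], [0.0, 180.0])
        assert d.counts.sum() == 3
        assert d.n_clipped == 2

    def test_misaligned_series_rejected(self):
        x = ps.DescriptorSeries("r1", np.arange(3.0), np.zeros(3), "gate_distance")
        y = ps.DescriptorSeries("r1", np.arange(4.0), np.zeros(4), "sensor_angle")
        with pytest.raises(ValueError):
            ps.density2d(x, y, [0, 1], [0, 1])


# ---------------------------------------------------------------------------
# clustering


def brute_force_average_linkage(dm: np.ndarray, cutoff: float) -> list[set]:
    """Naive agglomerative clustering oracle: repeatedly merge the two
    clusters with the smallest average pairwise distance until it exceeds
    the cutoff."""
    clusters = [{i} for i in range(len(dm))]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dm[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        if best[0] > cutoff:
            break
        d, i, j = best
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return clusters


def two_family_trajectory(n_frames=20, seed=0):
    """Frames drawn from two internally tight conformer families."""
    rng = np.random.default_rng(seed)
    base = ps.make_two_state_trajectory(
        ps.TwoStateParams(n_frames=n_frames, seed=seed))
    coords = base.coords.copy()
    family = rng.random(n_frames) < 0.5
    # family B: large internal rearrangement of three sensor atoms
    site = base.metadata["sitemap"]
    idx = [site.atom_index(base.topology, "sensor", nm) for nm in ("CB", "CG")]
    o2b = site.atom_index(base.topology, "nucleotide", "O2B")
    for f in range(n_frames):
        jitter = rng.normal(0, 0.05, (len(base.topology), 3))
        coords[f] = base.coords[0] + jitter
        if family[f]:
            coords[f, idx] += np.array([12.0, -8.0, 10.0])
            coords[f, o2b] += np.array([-10.0, 12.0, 8.0])
    t = ps.Trajectory(base.topology, coords, 12.5, metadata={"family": family})
    return t, site


SENSOR_REGION = ps.AtomSelector(chain=None, res_nums=(), atom_names=())


class TestClusterFrames:
    def test_identical_frames_single_cluster(self):
        t, site = small_traj(10)
        const = ps.Trajectory(t.topology, np.repeat(t.coords[:1], 10, axis=0), 2.5)
        res = ps.cluster_frames(const, SENSOR_REGION, cutoff=2.0, sieve=1)
        assert res.n_clusters == 1
        assert np.all(res.assignments == 0)

    def test_two_conformer_families_recovered_exactly(self):
        t, site = two_family_trajectory(24, seed=2)
        res = ps.cluster_frames(t, SENSOR_REGION, cutoff=2.0, sieve=1)
        family = t.metadata["family"]
        assert res.n_clusters == 2
        # cluster labels must be a relabelling of the family partition
        lab_a = set(res.assignments[~family])
        lab_b = set(res.assignments[family])
        assert len(lab_a) == len(lab_b) == 1 and lab_a != lab_b

    def test_sieved_assignment_matches_families(self):
        t, site = two_family_trajectory(40, seed=9)
        res = ps.cluster_frames(t, SENSOR_REGION, cutoff=2.0, sieve=5)
        family = t.metadata["family"]
        assert res.n_clusters == 2
        assert len(set(res.assignments[family])) == 1
        assert len(set(res.assignments[~family])) == 1

    def test_agrees_with_brute_force_oracle(self):
        """Sieve-free clustering partitions frames exactly as a naive
        average-linkage agglomeration of the same RMSD matrix (≤50 frames)."""
        from polsensor.trajectory_analysis import _pairwise_rmsd

        for seed in (1, 2, 3):
            t, _ = two_family_trajectory(18, seed=seed)
            res = ps.cluster_frames(t, SENSOR_REGION, cutoff=2.0, sieve=1)
            dm = _pairwise_rmsd(t.coords)
            oracle = brute_force_average_linkage(dm, 2.0)
            ours = [set(np.where(res.assignments == c)[0])
                    for c in range(res.n_clusters)]
            assert sorted(map(sorted, ours)) == sorted(map(sorted, oracle))

    def test_single_sieved_frame_warns(self):
        t, _ = small_traj(3)
        with pytest.warns(UserWarning):
            res = ps.cluster_frames(t, SENSOR_REGION, cutoff=2.0, sieve=10)
        assert res.n_clusters == 1

    def test_parameter_validation(self):
        t, _ = small_traj(4)
        with pytest.raises(ValueError):
            ps.cluster_frames(t, SENSOR_REGION, cutoff=-1.0)
        with pytest.raises(ValueError):
            ps.cluster_frames(t, SENSOR_REGION, sieve=0)


class TestReplicaSummary:
    def _series(self, values, rid):
        return ps.DescriptorSeries(rid, np.arange(float(len(values))),
                                   np.asarray(values, float), "gate_distance")

    def test_identical_replicas_zero_sd(self):
        reps = [self._series([3.4] * 5, f"r{i}") for i in range(3)]
        out = ps.replica_summary(reps)
        assert out["sd_across_replicas"] == 0.0
        assert out["pooled_mean"] == pytest.approx(3.4)

    def test_equal_lengths_pooled_equals_mean_of_means(self):
        reps = [self._series([1.0, 2.0], "r1"), self._series([3.0, 4.0], "r2")]
        out = ps.replica_summary(reps)
        assert out["pooled_mean"] == pytest.approx(
            np.mean(list(out["per_replica_means"].values())))

    def test_unequal_lengths_pooled_is_frame_weighted(self):
        reps = [self._series([1.0], "r1"), self._series([2.0, 2.0, 2.0], "r2")]
        out = ps.replica_summary(reps)
        assert out["pooled_mean"] == pytest.approx(np.mean([1.0, 2.0, 2.0, 2.0]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ps.replica_summary([])


class TestSamplingBookkeeping:
    def test_frames_per_system(self):
        assert frames_per_system() == 24000
        assert frames_per_system(n_replicas=1) == 8000

    def test_total_sampling(self):
        assert total_sampling_us() == pytest.approx(1.56)

    def test_equilibration_schedule(self):
        assert equilibration_total_ns() == pytest.approx(3.0)
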