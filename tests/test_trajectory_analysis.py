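import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from titramap import (
    ParameterError,
    SimConfig,
    classify_trajectory,
    extract_trajectories,
    generate_titration,
)
from titramap.binding_model import BindingParams
from titramap.trajectory_analysis import (
    PeakTrajectory,
    TrajectoryPoint,
    max_perpendicular_deviation,
)


def traj(points):
    return PeakTrajectory(
        residue_index=1,
        points=[TrajectoryPoint(r, h, n, None) for r, h, n in points],
    )


def brute_force_deviation(xy, n_angles=10_000):
    """Oracle: exhaustive scan over line angles through the centroid.

    For each angle, the perpendicular distances to that line are computed; the
    TLS axis minimises the *sum of squares*, so the oracle evaluates the max
    deviation at the angle minimising the squared sum.  The coarse grid is
    refined by two zoomed re-scans so the result is angle-exact well below
    the comparison tolerance; no linear algebra is used anywhere.
    """
    center = xy.mean(axis=0)
    d = xy - center

    def scan(angles):
        best_sse, best_ang = math.inf, angles[0]
        for ang in angles:
            normal = np.array([-math.sin(ang), math.cos(ang)])
            sse = float(np.sum((d @ normal) ** 2))
            if sse < best_sse:
                best_sse, best_ang = sse, ang
        return best_ang

    ang = scan(np.linspace(0, math.pi, n_angles, endpoint=False))
    step = math.pi / n_angles
    for _ in range(2):
        ang = scan(np.linspace(ang - step, ang + step, 2001))
        step /= 1000
    normal = np.array([-math.sin(ang), math.cos(ang)])
    return float(np.abs(d @ normal).max())


class TestExtractTrajectories:
    def test_one_trajectory_per_free_residue(self, default_dataset):
        series, _ = default_dataset
        trajectories = extract_trajectories(series)
        free_idx = {e.residue_index for e in series.free.entries if e.has_amide}
        assert {t.residue_index for t in trajectories} == free_idx
        assert all(len(t.points) == len(series.points) for t in trajectories)

    def test_vanishing_residue_keeps_missing_point(self):
        # slower exchange: contact peaks stay broadened out at the top point
        cfg = SimConfig(seed=4, binding=BindingParams(kex=1500.0))
        series, gt = generate_titration(cfg)
        top_idx = {e.residue_index for e in series.points[-1].entries}
        gone = sorted(i for i in gt.broadened_out if i not in top_idx)
        assert gone, "this exchange regime must lose peaks at the top point"
        trajectories = {t.residue_index: t for t in extract_trajectories(series)}
        t = trajectories[gone[0]]
        assert not t.points[-1].observed
        assert t.n_observed < len(series.points)
        call = classify_trajectory(t, noise_sd=cfg.noise_shift_sd)
        assert call.label in ("broadened_out", "insufficient")


class TestClassifyTrajectory:
    def test_collinear_points_linear_zero_deviation(self):
        t = traj([(0.0, 8.0, 120.0), (1.0, 8.1, 120.5), (2.0, 8.2, 121.0)])
        call = classify_trajectory(t, noise_sd=0.001)
        assert call.label == "linear"
        assert call.max_deviation <= 1e-12

    def test_two_points_insufficient(self):
        t = traj([(0.0, 8.0, 120.0), (1.0, 8.1, 120.5)])
        assert classify_trajectory(t, noise_sd=0.001).label == "insufficient"

    def test_coincident_points_degenerate_linear(self):
        t = traj([(0.0, 8.0, 120.0)] * 4)
        call = classify_trajectory(t, noise_sd=0.001)
        assert call.label == "linear" and call.max_deviation == 0.0

    def test_final_point_missing_is_broadened_out(self):
        t = PeakTrajectory(
            residue_index=1,
            points=[
                TrajectoryPoint(0.0, 8.0, 120.0, None),
                TrajectoryPoint(0.5, 8.05, 120.2, None),
                TrajectoryPoint(1.0, 8.1, 120.4, None),
                TrajectoryPoint(2.0, None, None, None),
            ],
        )
        assert classify_trajectory(t, noise_sd=0.001).label == "broadened_out"

    def test_path_length_gate_blocks_noise_only_residues(self):
        # large relative deviation but tiny absolute trajectory: must stay linear
        t = traj([(0.0, 8.0, 120.0), (1.0, 8.0005, 120.0), (2.0, 8.0, 120.0007)])
        assert classify_trajectory(t, noise_sd=0.001).label == "linear"

    def test_noise_sd_must_be_positive(self):
        t = traj([(0.0, 8.0, 120.0), (1.0, 8.1, 120.5), (2.0, 8.2, 121.0)])
        with pytest.raises(ParameterError):
            classify_trajectory(t, noise_sd=0.0)

    @given(st.integers(0, 500))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_tls_matches_brute_force_angle_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 6))
        xy = rng.normal(0, 0.05, (n, 2))
        dev, _ = max_perpendicular_deviation(xy)
        assert dev == pytest.approx(brute_force_deviation(xy), abs=1e-6)

    @given(st.integers(0, 200), st.floats(0.5, 4.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_equivariance_and_rotation_invariance(self, seed, k):
        rng = np.random.default_rng(seed)
        xy = rng.normal(0, 0.05, (4, 2))
        dev, ext = max_perpendicular_deviation(xy)
        dev_k, ext_k = max_perpendicular_deviation(xy * k)
        assert dev_k == pytest.approx(k * dev, rel=1e-9, abs=1e-12)
        assert ext_k == pytest.approx(k * ext, rel=1e-9, abs=1e-12)
        ang = float(rng.uniform(0, 2 * math.pi))
        rot = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
        dev_r, _ = max_perpendicular_deviation(xy @ rot.T)
        assert dev_r == pytest.approx(dev, rel=1e-9, abs=1e-12)


class TestExchangeRegimeDiscrimination:
    @staticmethod
    def _rates(kd2, seed, noise_sd=0.001):
        cfg = SimConfig(
            seed=seed,
            n_residues=200,
            patches=((1, 200, 0.25),),
            proline_fraction=0.0,
            noise_shift_sd=noise_sd,
            binding=BindingParams(kd1=5.0, kd2=kd2),
        )
        series, _ = generate_titration(cfg)
        calls = [
            classify_trajectory(t, noise_sd=noise_sd, dev_factor=3.0)
            for t in extract_trajectories(series)
        ]
        labels = [c.label for c in calls if c.label in ("linear", "nonlinear")]
        return sum(l == "nonlinear" for l in labels) / len(labels)

    def test_two_site_residues_called_nonlinear(self):
        """Weak second site (Kd2 = 20x Kd1) with a rotated shift direction curves
        the trajectory; >= 90% of residues must be flagged nonlinear."""
        assert self._rates(kd2=100.0, seed=11) >= 0.90

    def test_single_site_false_nonlinear_rate_low(self):
        """Two-state data may be called nonlinear in at most 5% of residues."""
        assert self._rates(kd2=None, seed=12) <= 0.05
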