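"""Peak-trajectory extraction and linear/non-linear classification.

In a two-state fast-exchange titration every peak moves along the straight
segment connecting its free and bound positions, so deviation from a line
in the (δH, α_N·δN) plane is the geometric signature of additional states
— a second weak site, intermediate exchange with an on-pathway species, or
a conformational rearrangement.  No mechanism is assigned here; only the
geometry is reported.

Classification fits the principal axis (total least squares, via the
centered points' SVD) through the observed points and takes the largest
perpendicular distance to it.  A trajectory is called nonlinear when that
deviation exceeds ``dev_factor``·noise and the trajectory is long enough
(path extent > 4·noise) that the deviation cannot be a noise artifact of a
stationary peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .csp_core import DEFAULT_ALPHA_N
from .errors import ParameterError
from .peaklist_io import TitrationSeries


@dataclass
class TrajectoryPoint:
    molar_ratio: float
    shift_h: float | None
    shift_n: float | None
    intensity: float | None

    @property
    def observed(self) -> bool:
        return self.shift_h is not None and self.shift_n is not None


@dataclass
class PeakTrajectory:
    """One residue's peak positions across the titration, ratio-ordered."""

    residue_index: int
    points: list[TrajectoryPoint]

    def __post_init__(self) -> None:
        self.points.sort(key=lambda p: p.molar_ratio)

    @property
    def n_observed(self) -> int:
        return sum(1 for p in self.points if p.observed)


@dataclass
class TrajectoryCall:
    """Classification of one trajectory.

    ``max_deviation`` and ``path_length`` are in compound ppm (¹H scale).
    Labels: ``linear``, ``nonlinear``, ``broadened_out`` (final point lost),
    ``insufficient`` (fewer than 3 observed points — a line always fits 2).
    """

    residue_index: int
    label: str
    max_deviation: float
    path_length: float


def extract_trajectories(series: TitrationSeries) -> list[PeakTrajectory]:
    """One trajectory per residue appearing in the free spectrum.

    Points missing at some ratio (peak broadened out or unassigned) are kept
    as explicit missing entries so the titration order is preserved.
    """
    free_idx = [e.residue_index for e in series.free.entries if e.has_amide]
    maps = [(p.molar_ratio, p.by_index()) for p in series.points]
    out = []
    for idx in free_idx:
        pts = []
        for ratio, by in maps:
            e = by.get(idx)
            if e is not None and e.has_amide:
                pts.append(TrajectoryPoint(ratio, e.shift_h, e.shift_n, e.intensity))
            else:
                pts.append(TrajectoryPoint(ratio, None, None, None))
        out.append(PeakTrajectory(residue_index=idx, points=pts))
    return out


def _scaled_points(traj: PeakTrajectory, alpha_n: float) -> np.ndarray:
    return np.array(
        [[p.shift_h, alpha_n * p.shift_n] for p in traj.points if p.observed], dtype=float
    )


def max_perpendicular_deviation(xy: np.ndarray) -> tuple[float, float]:
    """TLS principal-axis fit: (max perpendicular distance, extent along axis).

    All-coincident points give (0, 0).
    """
    center = xy.mean(axis=0)
    d = xy - center
    if np.allclose(d, 0.0):
        return 0.0, 0.0
    # principal axis = top right-singular vector of the centered cloud
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    axis = vt[0]
    along = d @ axis
    perp = d - np.outer(along, axis)
    dev = float(np.max(np.linalg.norm(perp, axis=1)))
    extent = float(along.max() - along.min())
    return dev, extent


def classify_trajectory(
    traj: PeakTrajectory,
    noise_sd: float,
    dev_factor: float = 3.0,
    alpha_n: float = DEFAULT_ALPHA_N,
) -> TrajectoryCall:
    """Label a trajectory from its perpendicular deviation off the TLS axis.

    ``noise_sd`` is the per-point positional noise (ppm, compound scale);
    ``dev_factor`` sets the nonlinearity gate at dev_factor·noise_sd, and a
    path-extent gate of 4·noise_sd stops noise-only (unperturbed) residues
    from being called nonlinear.
    """
    if noise_sd <= 0:
        raise ParameterError("noise_sd must be positive")
    n_obs = traj.n_observed
    if n_obs < 3:
        return TrajectoryCall(traj.residue_index, "insufficient", 0.0, 0.0)
    xy = _scaled_points(traj, alpha_n)
    dev, extent = max_perpendicular_deviation(xy)
    if not traj.points[-1].observed:
        label = "broadened_out"
    elif dev > dev_factor * noise_sd and extent > 4.0 * noise_sd:
        label = "nonlinear"
    else:
        label = "linear"
    return TrajectoryCall(traj.residue_index, label, dev, extent)
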