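"""Movement features of keypoint trajectories: pixel distance and velocity.

Two families of per-frame quantities are derived from a keypoint trajectory
in image coordinates:

* **Pixel distance (PD)** — the Euclidean distance ``L_n`` of the keypoint
  from a fixed origin A (the centre of the table edge next to the child):

  ``L_n = sqrt(X_n^2 + Y_n^2)`` with ``X_n = x_n - A_x``, ``Y_n = y_n - A_y``.

* **Instantaneous pixel velocity (IPV)** — the Euclidean displacement
  ``dL_n`` between consecutive frames:

  ``dL_n = sqrt(dX_n^2 + dY_n^2)`` with ``dX_n = x_{n+1} - x_n``.

  Steps are defined only between frames whose indices differ by exactly 1;
  velocity across an occlusion gap is unobserved and excluded.

Each family is summarised by its mean and standard deviation over a named
activity segment, giving the four movement features ``L_mean``, ``L_std``,
``dL_mean`` and ``dL_std``.  Both standard deviations divide by the number of
contributing samples (population form), matching the defining formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ANALYSIS_KEYPOINTS, KEYPOINT_NAMES, Timeline
from .tracking import Trajectory

#: Below this many PD samples (or IPV steps) in a segment, the statistic is
#: noise-dominated and the feature is withheld rather than emitted as zero.
MIN_SAMPLES = 10

FEATURE_NAMES = ("L_mean", "L_std", "dL_mean", "dL_std")


@dataclass
class PDSeries:
    """Per-frame pixel distances from the origin, with their components."""

    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    l: np.ndarray
    origin: tuple[float, float]


@dataclass
class IPVSeries:
    """Per-step pixel displacements between consecutive frames."""

    frames: np.ndarray  # frame index of the step's first frame
    dx: np.ndarray
    dy: np.ndarray
    dl: np.ndarray


@dataclass
class MovementFeatureSet:
    """The four movement features for one (child, activity, keypoint).

    Features whose sample counts fall below :data:`MIN_SAMPLES` are ``None``
    (absent), never zero.
    """

    child_id: str
    activity: str
    keypoint: int
    L_mean: float | None
    L_std: float | None
    dL_mean: float | None
    dL_std: float | None
    n_pd_samples: int
    n_ipv_samples: int


def pd_series(traj: Trajectory, origin: tuple[float, float]) -> PDSeries:
    """Distances of every trajectory sample from the origin point."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    x = traj.xy[:, 0] - origin[0]
    y = traj.xy[:, 1] - origin[1]
    return PDSeries(frames=traj.frames.copy(), x=x, y=y, l=np.hypot(x, y), origin=tuple(origin))


def pd_features(series: PDSeries, min_samples: int = 1) -> tuple[float | None, float | None]:
    """(mean, SD) of the pixel distances; SD uses the population divisor n.

    Returns ``None`` in place of a statistic its sample count cannot support
    (mean needs >= max(1, min_samples), SD needs >= max(2, min_samples)).
    """
    n = series.l.size
    mean = float(np.mean(series.l)) if n >= max(1, min_samples) else None
    std = float(np.std(series.l)) if n >= max(2, min_samples) else None
    return mean, std


def ipv_series(traj: Trajectory) -> IPVSeries:
    """Per-frame displacements, only between consecutively indexed samples."""
    if len(traj) < 2:
        return IPVSeries(
            frames=np.empty(0, dtype=np.int64),
            dx=np.empty(0),
            dy=np.empty(0),
            dl=np.empty(0),
        )
    consecutive = np.diff(traj.frames) == 1
    dxy = np.diff(traj.xy, axis=0)[consecutive]
    return IPVSeries(
        frames=traj.frames[:-1][consecutive].copy(),
        dx=dxy[:, 0],
        dy=dxy[:, 1],
        dl=np.hypot(dxy[:, 0], dxy[:, 1]),
    )


def ipv_features(series: IPVSeries, min_samples: int = 1) -> tuple[float | None, float | None]:
    """(mean, SD) of the absolute step displacements, divisor = step count."""
    n = series.dl.size
    mean = float(np.mean(np.abs(series.dl))) if n >= max(1, min_samples) else None
    std = float(np.std(series.dl)) if n >= max(2, min_samples) else None
    return mean, std


def _restrict(traj: Trajectory, fps: float, start: float, end: float) -> Trajectory:
    """Samples whose frame times fall in the half-open window [start, end)."""
    times = traj.frames / fps
    mask = (times >= start) & (times < end)
    return Trajectory(keypoint=traj.keypoint, frames=traj.frames[mask], xy=traj.xy[mask])


def segment_features(
    trajectories: dict[int, Trajectory],
    timeline: Timeline,
    origin: tuple[float, float],
    fps: float,
    child_id: str = "",
    keypoints: tuple[int, ...] = ANALYSIS_KEYPOINTS,
    min_samples: int = MIN_SAMPLES,
) -> list[MovementFeatureSet]:
    """Movement features for every (activity-or-composite, keypoint) pair.

    Composite activities pool PD samples over all member segments and
    concatenate IPV steps computed within each member, so no step spans from
    one member segment into another.
    """
    results: list[MovementFeatureSet] = []
    for activity in timeline.activities():
        members = timeline.members(activity)
        for kp in keypoints:
            traj = trajectories[kp]
            pd_values: list[np.ndarray] = []
            ipv_values: list[np.ndarray] = []
            for seg in members:
                part = _restrict(traj, fps, seg.start, seg.end)
                if len(part) > 0:
                    pd_values.append(pd_series(part, origin).l)
                    ipv_values.append(ipv_series(part).dl)
            l = np.concatenate(pd_values) if pd_values else np.empty(0)
            dl = np.concatenate(ipv_values) if ipv_values else np.empty(0)
            l_mean = float(np.mean(l)) if l.size >= min_samples else None
            l_std = float(np.std(l)) if l.size >= min_samples else None
            dl_mean = float(np.mean(np.abs(dl))) if dl.size >= min_samples else None
            dl_std = float(np.std(dl)) if dl.size >= min_samples else None
            results.append(
                MovementFeatureSet(
                    child_id=child_id,
                    activity=activity,
                    keypoint=kp,
                    L_mean=l_mean,
                    L_std=l_std,
                    dL_mean=dl_mean,
                    dL_std=dl_std,
                    n_pd_samples=int(l.size),
                    n_ipv_samples=int(dl.size),
                )
            )
    return results


def features_to_frame(features: list[MovementFeatureSet]) -> pd.DataFrame:
    """Flatten feature sets into the long-form table written to CSV."""
    rows = []
    for f in features:
        rows.append(
            {
                "child_id": f.child_id,
                "activity": f.activity,
                "keypoint": KEYPOINT_NAMES.get(f.keypoint, str(f.keypoint)),
                "L_mean": f.L_mean,
                "L_std": f.L_std,
                "dL_mean": f.dL_mean,
                "dL_std": f.dL_std,
                "n_pd_samples": f.n_pd_samples,
                "n_ipv_samples": f.n_ipv_samples,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "child_id",
            "activity",
            "keypoint",
            "L_mean",
            "L_std",
            "dL_mean",
            "dL_std",
            "n_pd_samples",
            "n_ipv_samples",
        ],
    )


def feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long-form feature table into children x (activity, keypoint,
    feature) with missing cells preserved as NaN."""
    long = table.melt(
        id_vars=["child_id", "activity", "keypoint"],
        value_vars=list(FEATURE_NAMES),
        var_name="feature",
    )
    wide = long.pivot_table(
        index="child_id",
        columns=["activity", "keypoint", "feature"],
        values="value",
        dropna=False,
    )
    return wide.sort_index(axis=1)
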