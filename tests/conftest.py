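"""Shared fixtures: a small end-to-end pipeline result reused across tests."""

import numpy as np
import pytest

from playmotion import CohortSpec, PipelineConfig, Trajectory, run_pipeline


@pytest.fixture(scope="session")
def small_result():
    """One small synthetic pipeline run (8 children), shared read-only."""
    spec = CohortSpec(group_sizes={0: 3, 1: 3, 2: 2}, seed=7)
    return run_pipeline(PipelineConfig(cohort_spec=spec, seed=7))


def make_trajectory(xy, frames=None, keypoint=1):
    xy = np.asarray(xy, dtype=float)
    if frames is None:
        frames = np.arange(len(xy))
    return Trajectory(keypoint=keypoint, frames=np.asarray(frames), xy=xy)
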