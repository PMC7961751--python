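from __future__ import annotations

import numpy as np
import pytest

from physioconc import (
    CHANNELS,
    CohortSpec,
    Recording,
    build_dataset,
    make_cohort,
)


def make_recording(
    values: np.ndarray,
    *,
    rate: float = 10.0,
    subject_id: str = "s1",
    session_id: str = "a",
) -> Recording:
    return Recording(
        subject_id=subject_id,
        session_id=session_id,
        values=np.asarray(values, dtype=float),
        channel_names=CHANNELS[: values.shape[0]],
        sampling_rate_hz=rate,
    )


def constant_recording(n_frames: int, *, rate: float = 10.0) -> Recording:
    base = np.array([70.0, 15.0, 5.0, 33.0])
    return make_recording(np.tile(base[:, None], (1, n_frames)), rate=rate)


@pytest.fixture(scope="session")
def default_cohort():
    return make_cohort(CohortSpec(master_seed=7))


@pytest.fixture(scope="session")
def default_dataset(default_cohort):
    return build_dataset(default_cohort.sessions)


@pytest.fixture(scope="session")
def small_dataset():
    """Two subjects, two sessions each: cheap enough for sweep/CLI tests."""
    spec = CohortSpec(n_subjects=2, sessions_per_subject=2, master_seed=3)
    return build_dataset(make_cohort(spec).sessions)
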