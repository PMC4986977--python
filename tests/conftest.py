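"""Shared fixtures: small simulated sessions and hand-built epoch sets."""

import numpy as np
import pandas as pd
import pytest

from attnloc.synthdata import (
    CHANNELS, TaskDesign, GroundTruth, generate_schedule, synthesize_subject,
)
from attnloc.preprocess import (
    EpochSet, rereference, filter_recording, epoch_and_baseline,
    reject_artifacts,
)
from attnloc.pipeline import simulate_experiment


def make_epochs(
    data: np.ndarray,
    sfreq: float = 512.0,
    kind: str = "cue",
    locations=None,
    channels=CHANNELS,
    subject: str = "S00",
) -> EpochSet:
    """EpochSet straight from an (n_epochs, n_channels, n_times) array.

    The time axis is anchored with 0.2 s of pre-stimulus baseline, matching
    the pipeline's epoch window.
    """
    n_epochs, n_channels, n_times = data.shape
    assert n_channels == len(channels)
    locations = (np.ones(n_epochs, dtype=int) if locations is None
                 else np.asarray(locations))
    pre = int(round(0.2 * sfreq))
    metadata = pd.DataFrame({
        "epoch": np.arange(n_epochs),
        "kind": kind,
        "location": locations,
        "cued_location": locations,
        "event_sample": np.zeros(n_epochs, dtype=int),
    })
    return EpochSet(
        data=np.asarray(data, dtype=float),
        channels=tuple(channels),
        times=(np.arange(n_times) - pre) / sfreq,
        sfreq=sfreq,
        metadata=metadata,
        kept=np.ones(n_epochs, dtype=bool),
        reject_reason=np.array([""] * n_epochs, dtype=object),
        subject=subject,
    )


def mirror_schedule(schedule):
    """The same session with the location axis flipped (1↔4, 2↔3)."""
    mirrored = schedule.trials.copy()
    n_loc = schedule.design.n_locations
    mirrored["location"] = n_loc + 1 - mirrored["location"]
    rename = {}
    for k in range(1, n_loc + 1):
        rename[f"flash1_loc{k}_s"] = f"flash1_loc{n_loc + 1 - k}_s"
        rename[f"flash2_loc{k}_s"] = f"flash2_loc{n_loc + 1 - k}_s"
    mirrored = mirrored.rename(columns=rename)[list(schedule.trials.columns)]
    return type(schedule)(design=schedule.design, trials=mirrored)


@pytest.fixture(scope="session")
def small_design():
    return TaskDesign(n_blocks=1, trials_per_block=16)


@pytest.fixture(scope="session")
def clean_truth():
    """Strong graded components, no noise, no variability, no artifacts."""
    return GroundTruth.default(
        noise_sd_uv=0.0, subject_scale_sd=0.0,
        artifact_rates={"blink": 0.0, "saccade": 0.0},
    )


@pytest.fixture(scope="session")
def clean_epochs(small_design, clean_truth):
    """One noise-free subject, fully preprocessed."""
    schedule = generate_schedule(small_design, seed=7)
    rec = synthesize_subject(schedule, clean_truth, seed=11, subject="S01")
    rec = filter_recording(rereference(rec))
    return reject_artifacts(epoch_and_baseline(rec))


@pytest.fixture(scope="session")
def default_experiment():
    """The full study design: 15 subjects, 2 × 300 trials, default truth."""
    return simulate_experiment(n_subjects=15, seed=1)
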