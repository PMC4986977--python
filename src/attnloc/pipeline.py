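"""End-to-end drivers: simulate → preprocess → features for many subjects.

Each subject flows through: schedule (shared design, per-subject order),
signal synthesis with per-subject amplitude variability, artifact
injection, mastoid re-referencing, band-pass filtering, epoching of cue
and flash events, artifact rejection, and feature extraction.  Subjects
whose epoch-rejection rate reaches the exclusion criterion are dropped,
mirroring the study's participant-exclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from attnloc.synthdata import (
    TaskDesign, GroundTruth, generate_schedule, synthesize_subject,
    inject_artifacts,
)
from attnloc.preprocess import (
    RejectionCriteria, EpochSet, filter_recording, rereference,
    epoch_and_baseline, reject_artifacts, exclude_subjects,
)
from attnloc.features import FeatureSpec, extract_features, \
    extract_binary_features
from attnloc.evaluate import compute_heog_summary


@dataclass
class ExperimentData:
    """Products of a simulated multi-subject experiment."""

    features: pd.DataFrame            # (subject, location) × 12
    binary_features: pd.DataFrame     # (subject, cue, letter) × 6 + label
    heog_amplitude_uv: dict[str, float]
    rejection_rates: dict[str, float]
    kept_subjects: list[str]


def _subject_seed(seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=(index,))


def run_subject_pipeline(
    design: TaskDesign,
    truth: GroundTruth,
    seed: int,
    subject: str = "S00",
    criteria: RejectionCriteria | None = None,
    inject: bool = True,
) -> EpochSet:
    """One subject end-to-end, returning the rejected-and-flagged EpochSet."""
    criteria = criteria or RejectionCriteria()
    ss = np.random.SeedSequence(seed)
    sched_seed, synth_seed, art_seed = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3)]
    schedule = generate_schedule(design, sched_seed)
    rec = synthesize_subject(schedule, truth, synth_seed, subject=subject)
    if inject and any(r > 0 for r in truth.artifact_rates.values()):
        rec, _ = inject_artifacts(rec, truth.artifact_rates, art_seed)
    rec = rereference(rec)
    rec = filter_recording(rec)
    epochs = epoch_and_baseline(rec)
    return reject_artifacts(epochs, criteria)


def simulate_experiment(
    n_subjects: int = 15,
    design: TaskDesign | None = None,
    truth: GroundTruth | None = None,
    seed: int = 0,
    criteria: RejectionCriteria | None = None,
    spec: FeatureSpec | None = None,
    with_binary: bool = True,
) -> ExperimentData:
    """Simulate and preprocess ``n_subjects`` subjects; extract features.

    Subjects are processed one at a time (epochs are not retained) so the
    full study design fits comfortably in memory.
    """
    design = design or TaskDesign()
    truth = truth or GroundTruth.default()
    criteria = criteria or RejectionCriteria()
    spec = spec or FeatureSpec()

    epoch_sets: list[EpochSet] = []
    rates: dict[str, float] = {}
    heog: dict[str, float] = {}
    feat_frames, bin_frames = [], []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        sub_seed = int(_subject_seed(seed, i).generate_state(1)[0] % (2 ** 31))
        epochs = run_subject_pipeline(design, truth, sub_seed, subject=sid,
                                      criteria=criteria)
        rates[sid] = epochs.rejection_rate()
        heog[sid] = compute_heog_summary([epochs])[sid]
        feat_frames.append(extract_features(epochs, spec))
        if with_binary:
            bin_frames.append(extract_binary_features(epochs, spec))
        del epochs

    kept = exclude_subjects(rates, criteria)
    features = pd.concat(feat_frames, ignore_index=True)
    features = features[features["subject"].isin(kept)].reset_index(drop=True)
    if with_binary:
        binary = pd.concat(bin_frames, ignore_index=True)
        binary = binary[binary["subject"].isin(kept)].reset_index(drop=True)
    else:
        binary = pd.DataFrame()
    heog = {s: heog[s] for s in kept}
    return ExperimentData(
        features=features, binary_features=binary, heog_amplitude_uv=heog,
        rejection_rates=rates, kept_subjects=kept,
    )


def synthetic_feature_table(
    n_subjects: int,
    class_centroids: np.ndarray,
    noise_sd: float,
    seed: int,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Feature table drawn directly from per-class Gaussian centroids.

    A lightweight stand-in for the full EEG pipeline when only classifier
    behavior is under study: row (subject, location) gets
    ``class_centroids[location-1] + N(0, noise_sd)``.
    """
    centroids = np.asarray(class_centroids, dtype=float)
    n_classes, n_feat = centroids.shape
    names = feature_names or [f"f{k}" for k in range(n_feat)]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for i in range(n_subjects):
        for loc in range(1, n_classes + 1):
            vals = centroids[loc - 1] + rng.normal(0, noise_sd, size=n_feat)
            rows.append({"subject": f"S{i + 1:02d}", "location": loc,
                         **dict(zip(names, vals))})
    return pd.DataFrame(rows)
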