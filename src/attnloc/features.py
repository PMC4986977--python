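"""Lateralized ERP feature extraction.

Per subject and cued location, kept epochs are averaged time-locked either
to cue onset or to the onsets of the two flashes of the letter at the cued
location (both flashes pooled into one average).  For each posterior pair
(PO7/PO8, O1/O2, PO3/PO4) the left-minus-right difference wave is computed
and its mean amplitude taken over an early and a late window:

* cue-locked:    170–270 ms (N2pc range) and 650–840 ms (SPCN range)
* target-locked: 0–100 ms (P1 range) and 410–530 ms

giving 12 features per (subject, location): 2 locks × 3 pairs × 2 windows.
Window endpoints follow the same half-open convention as epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from attnloc.preprocess import EpochSet
from attnloc.synthdata import ELECTRODE_PAIRS

logger = logging.getLogger(__name__)

CUE_WINDOWS_MS = {"early": (170.0, 270.0), "late": (650.0, 840.0)}
TARGET_WINDOWS_MS = {"early": (0.0, 100.0), "late": (410.0, 530.0)}


@dataclass(frozen=True)
class FeatureSpec:
    """Electrode pairs, locks, and averaging windows defining the features."""

    pairs: tuple[tuple[str, str], ...] = ELECTRODE_PAIRS
    locks: tuple[str, ...] = ("cue", "target")
    cue_windows_ms: dict = field(default_factory=lambda: dict(CUE_WINDOWS_MS))
    target_windows_ms: dict = field(
        default_factory=lambda: dict(TARGET_WINDOWS_MS))
    n_locations: int = 4

    def windows(self, lock: str) -> dict:
        return self.cue_windows_ms if lock == "cue" else self.target_windows_ms

    def feature_names(self) -> list[str]:
        """Stable column order: lock (cue, target) × pair × window."""
        return [
            f"{lock}/{win}/{left}-{right}"
            for lock in self.locks
            for left, right in self.pairs
            for win in self.windows(lock)
        ]

    def jittered(self, shift_ms: float) -> "FeatureSpec":
        """Spec with every window endpoint shifted by ``shift_ms``."""
        shift = lambda d: {k: (a + shift_ms, b + shift_ms)
                           for k, (a, b) in d.items()}
        return FeatureSpec(
            pairs=self.pairs, locks=self.locks,
            cue_windows_ms=shift(self.cue_windows_ms),
            target_windows_ms=shift(self.target_windows_ms),
            n_locations=self.n_locations,
        )


def _lock_mask(epochs: EpochSet, lock: str, location: int) -> np.ndarray:
    md = epochs.metadata
    if lock == "cue":
        return (md["kind"] == "cue") & (md["cued_location"] == location)
    if lock == "target":
        # flashes of the letter at the cued location, both flashes pooled
        return ((md["kind"] == "flash") & (md["cued_location"] == location)
                & (md["location"] == location))
    raise ValueError(f"unknown lock {lock!r}")


def average_epochs(epochs: EpochSet, lock: str, location: int) -> np.ndarray:
    """Point-wise mean over kept epochs for one lock and cued location.

    Returns (n_channels, n_times).  Raises if no kept epoch matches.
    """
    mask = (_lock_mask(epochs, lock, location).to_numpy() & epochs.kept)
    if not mask.any():
        raise ValueError(
            f"no kept {lock}-locked epochs for subject {epochs.subject}, "
            f"location {location}")
    return epochs.data[mask].mean(axis=0)


def lateralized_wave(
    avg: np.ndarray, pair: tuple[str, str], channels: tuple[str, ...]
) -> np.ndarray:
    """Left-minus-right difference wave for one electrode pair."""
    left, right = pair
    if left not in channels or right not in channels:
        raise ValueError(f"unknown electrode pair {pair}")
    return avg[channels.index(left)] - avg[channels.index(right)]


def window_mean(
    wave: np.ndarray, window_ms: tuple[float, float], times_s: np.ndarray
) -> float:
    """Mean amplitude over [onset, offset) ms relative to the lock event."""
    lo, hi = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    mask = (times_s >= lo) & (times_s < hi)
    if not mask.any():
        raise ValueError(f"window {window_ms} ms is empty on this epoch grid")
    return float(wave[mask].mean())


def _subject_features(epochs: EpochSet, spec: FeatureSpec) -> pd.DataFrame:
    rows = []
    for loc in range(1, spec.n_locations + 1):
        values = {}
        for lock in spec.locks:
            avg = average_epochs(epochs, lock, loc)
            for pair in spec.pairs:
                wave = lateralized_wave(avg, pair, epochs.channels)
                for win_name, win in spec.windows(lock).items():
                    name = f"{lock}/{win_name}/{pair[0]}-{pair[1]}"
                    values[name] = window_mean(wave, win, epochs.times)
        rows.append({"subject": epochs.subject, "location": loc, **values})
    return pd.DataFrame(rows)


def extract_features(
    epoch_sets: EpochSet | list[EpochSet],
    spec: FeatureSpec | None = None,
) -> pd.DataFrame:
    """Feature table: one row per (subject, location), one named column per
    feature (12 under the default spec).

    A subject missing kept epochs for any location is dropped with a logged
    warning rather than producing a partial row set.
    """
    spec = spec or FeatureSpec()
    if isinstance(epoch_sets, EpochSet):
        epoch_sets = [epoch_sets]
    frames = []
    for es in epoch_sets:
        try:
            frames.append(_subject_features(es, spec))
        except ValueError as err:
            logger.warning("dropping subject %s: %s", es.subject, err)
    if not frames:
        raise ValueError("no subject yielded a complete feature row set")
    table = pd.concat(frames, ignore_index=True)
    assert list(table.columns) == ["subject", "location"] + spec.feature_names()
    return table


def extract_binary_features(
    epoch_sets: EpochSet | list[EpochSet],
    spec: FeatureSpec | None = None,
) -> pd.DataFrame:
    """Target-locked features for the attended/unattended binary task.

    One row per (subject, cued location, letter location): the average is
    locked to the two flashes of the letter at ``letter_location`` on trials
    cued at ``cued_location``, yielding the 6 target-locked features plus an
    ``attended`` label (True iff cue and letter coincide — 1/4 of rows).
    """
    spec = spec or FeatureSpec()
    if isinstance(epoch_sets, EpochSet):
        epoch_sets = [epoch_sets]
    names = [f"target/{win}/{l}-{r}"
             for l, r in spec.pairs for win in spec.target_windows_ms]
    rows = []
    for es in epoch_sets:
        md = es.metadata
        for cue_loc in range(1, spec.n_locations + 1):
            for letter_loc in range(1, spec.n_locations + 1):
                mask = ((md["kind"] == "flash").to_numpy()
                        & (md["cued_location"] == cue_loc).to_numpy()
                        & (md["location"] == letter_loc).to_numpy()
                        & es.kept)
                if not mask.any():
                    logger.warning(
                        "subject %s: no kept flash epochs for cue %d / "
                        "letter %d", es.subject, cue_loc, letter_loc)
                    continue
                avg = es.data[mask].mean(axis=0)
                values = {}
                for pair in spec.pairs:
                    wave = lateralized_wave(avg, pair, es.channels)
                    for win_name, win in spec.target_windows_ms.items():
                        values[f"target/{win_name}/{pair[0]}-{pair[1]}"] = (
                            window_mean(wave, win, es.times))
                rows.append({"subject": es.subject,
                             "cued_location": cue_loc,
                             "letter_location": letter_loc,
                             "attended": cue_loc == letter_loc,
                             **values})
    table = pd.DataFrame(rows)
    return table[["subject", "cued_location", "letter_location", "attended"]
                 + names]
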