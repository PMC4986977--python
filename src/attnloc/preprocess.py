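"""Filtering, re-referencing, epoching and artifact rejection.

Conventions (fixed throughout the package):

* Filters are zero-phase forward-backward 4th-order Butterworth band-passes
  (−3 dB at the stated cut-offs): 0.1–30 Hz for EEG and mastoids, 0.1–10 Hz
  for the EOG channels.
* Re-referencing subtracts the mastoid average (M1+M2)/2 from EEG channels
  only; EOG channels are bipolar derivations and stay untouched.
* Epochs span the half-open window [−200, 800) ms around the event sample
  (t = 0 is the event); the baseline is [−200, 0) ms and its per-channel
  mean is subtracted.  Events too close to a recording edge are dropped.
* "Deflection within a time window" is read as peak-to-peak (max − min)
  over a sliding window of the stated length, stepped one sample at a time;
  comparisons are strict (>) at the thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from attnloc.synthdata import (
    EEG_CHANNELS,
    EOG_CHANNELS,
    MASTOID_CHANNELS,
    Recording,
)

logger = logging.getLogger(__name__)

EEG_BAND_HZ = (0.1, 30.0)
EOG_BAND_HZ = (0.1, 10.0)
EPOCH_WINDOW_S = (-0.2, 0.8)


@dataclass(frozen=True)
class RejectionCriteria:
    """Artifact-rejection thresholds.

    Blinks: VEOG peak-to-peak > ``veog_threshold_uv`` within any
    ``veog_window_ms`` window.  Eye movements: HEOG peak-to-peak >
    ``heog_threshold_uv`` within any ``heog_window_ms`` window.  Any EEG
    sample beyond ±``absolute_limit_uv`` also rejects.  Subjects whose
    rejection rate reaches ``subject_exclusion_rate`` are excluded.
    """

    veog_threshold_uv: float = 50.0
    veog_window_ms: float = 150.0
    heog_threshold_uv: float = 35.0
    heog_window_ms: float = 300.0
    absolute_limit_uv: float = 100.0
    subject_exclusion_rate: float = 0.30

    def __post_init__(self) -> None:
        if min(self.veog_threshold_uv, self.heog_threshold_uv,
               self.absolute_limit_uv, self.veog_window_ms,
               self.heog_window_ms) <= 0:
            raise ValueError("all thresholds and windows must be positive")
        if not (0 < self.subject_exclusion_rate <= 1):
            raise ValueError("subject_exclusion_rate must be in (0, 1]")


@dataclass
class EpochSet:
    """Fixed-length baseline-corrected epochs with keep/reject state.

    ``data``: (n_epochs, n_channels, n_times) in μV; ``times``: seconds
    relative to the locking event; ``metadata`` columns: epoch, kind
    ("cue" | "flash"), location, cued_location, event_sample; ``kept`` and
    ``reject_reason`` mirror the rejection log.
    """

    data: np.ndarray
    channels: tuple[str, ...]
    times: np.ndarray
    sfreq: float
    metadata: pd.DataFrame
    kept: np.ndarray
    reject_reason: np.ndarray
    subject: str = "S00"

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)

    def select(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=self.data[mask],
            channels=self.channels,
            times=self.times,
            sfreq=self.sfreq,
            metadata=self.metadata.loc[mask].reset_index(drop=True),
            kept=self.kept[mask],
            reject_reason=self.reject_reason[mask],
            subject=self.subject,
        )

    def rejection_rate(self) -> float:
        return float(1.0 - self.kept.mean()) if self.n_epochs else 0.0

    def rejection_log(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": self.metadata["epoch"],
            "kept": self.kept,
            "reason": self.reject_reason,
        })


def bandpass_filter(
    x: np.ndarray, low_hz: float, high_hz: float, sfreq: float
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis."""
    nyq = sfreq / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyq} Hz")
    sos = signal.butter(4, (low_hz, high_hz), btype="bandpass",
                        fs=sfreq, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def filter_recording(recording: Recording) -> Recording:
    """Apply the EEG band to EEG+mastoids and the EOG band to EOG channels."""
    out = recording.copy()
    for name in recording.channels:
        i = recording.channels.index(name)
        band = EOG_BAND_HZ if name in EOG_CHANNELS else EEG_BAND_HZ
        out.data[i] = bandpass_filter(recording.data[i], *band,
                                      sfreq=recording.sfreq)
    return out


def rereference(recording: Recording) -> Recording:
    """Re-reference EEG channels to the mastoid average (M1+M2)/2."""
    for m in MASTOID_CHANNELS:
        if m not in recording.channels:
            raise ValueError(f"missing mastoid channel {m}")
    out = recording.copy()
    ref = 0.5 * (recording.channel("M1") + recording.channel("M2"))
    for name in EEG_CHANNELS:
        out.data[recording.channels.index(name)] -= ref
    return out


def epoch_and_baseline(
    recording: Recording,
    events: pd.DataFrame | None = None,
    window_s: tuple[float, float] = EPOCH_WINDOW_S,
) -> EpochSet:
    """Cut half-open [window_s) epochs around events and baseline-correct.

    The baseline is the pre-stimulus part [window start, 0) of each epoch;
    its per-channel mean is subtracted.  Events whose epoch would cross a
    recording edge are dropped with a logged warning.
    """
    if events is None:
        events = recording.events
    sfreq = recording.sfreq
    pre = int(round(-window_s[0] * sfreq))
    post = int(round(window_s[1] * sfreq))
    n_times = pre + post
    n_total = recording.data.shape[1]

    rows, chunks = [], []
    dropped = 0
    for idx, ev in enumerate(events.itertuples(index=False)):
        s = int(ev.sample)
        if s - pre < 0 or s + post > n_total:
            dropped += 1
            continue
        chunk = recording.data[:, s - pre:s + post].copy()
        chunk -= chunk[:, :pre].mean(axis=1, keepdims=True)
        chunks.append(chunk)
        rows.append((idx, ev.kind, int(ev.location), int(ev.cued_location), s))
    if dropped:
        logger.warning("dropped %d events too close to recording edge (%s)",
                       dropped, recording.subject)

    data = (np.stack(chunks) if chunks
            else np.empty((0, len(recording.channels), n_times)))
    metadata = pd.DataFrame(
        rows, columns=["epoch", "kind", "location", "cued_location",
                       "event_sample"])
    times = (np.arange(n_times) - pre) / sfreq
    n = len(rows)
    return EpochSet(
        data=data, channels=recording.channels, times=times, sfreq=sfreq,
        metadata=metadata, kept=np.ones(n, dtype=bool),
        reject_reason=np.array([""] * n, dtype=object),
        subject=recording.subject,
    )


def _sliding_ptp_exceeds(x: np.ndarray, window: int, threshold: float
                         ) -> np.ndarray:
    """Per epoch: does any length-``window`` sliding peak-to-peak exceed
    ``threshold``?  ``x`` is (n_epochs, n_times)."""
    if x.shape[-1] == 0:
        return np.zeros(x.shape[0], dtype=bool)
    window = min(window, x.shape[-1])
    ptp = (maximum_filter1d(x, size=window, axis=-1, mode="nearest")
           - minimum_filter1d(x, size=window, axis=-1, mode="nearest"))
    # restrict to windows fully inside the epoch
    half_lo = window // 2
    valid = ptp[..., half_lo:half_lo + (x.shape[-1] - window + 1)]
    return (valid > threshold).any(axis=-1)


def reject_artifacts(
    epochs: EpochSet, criteria: RejectionCriteria | None = None
) -> EpochSet:
    """Flag epochs containing blinks, eye movements, or over-range signal.

    Reasons, checked in order: "blink" (VEOG rule), "eye movement" (HEOG
    rule), "absolute limit" (any EEG channel beyond ±limit).  The first
    matching reason is recorded.  Already-rejected epochs keep their flag.
    """
    criteria = criteria or RejectionCriteria()
    out = epochs.select(np.ones(epochs.n_epochs, dtype=bool))
    if out.n_epochs == 0:
        return out

    sfreq = epochs.sfreq
    veog = out.data[:, out.channel_index("VEOG"), :]
    heog = out.data[:, out.channel_index("HEOG"), :]
    w_v = int(round(criteria.veog_window_ms * sfreq / 1000.0))
    w_h = int(round(criteria.heog_window_ms * sfreq / 1000.0))
    blink = _sliding_ptp_exceeds(veog, w_v, criteria.veog_threshold_uv)
    eyemove = _sliding_ptp_exceeds(heog, w_h, criteria.heog_threshold_uv)

    eeg_idx = [out.channel_index(c) for c in EEG_CHANNELS
               if c in out.channels]
    over = (np.abs(out.data[:, eeg_idx, :]) > criteria.absolute_limit_uv
            ).any(axis=(1, 2))

    for i in range(out.n_epochs):
        if not out.kept[i]:
            continue
        if blink[i]:
            out.kept[i], out.reject_reason[i] = False, "blink"
        elif eyemove[i]:
            out.kept[i], out.reject_reason[i] = False, "eye movement"
        elif over[i]:
            out.kept[i], out.reject_reason[i] = False, "absolute limit"
    return out


def exclude_subjects(
    rejection_rates: dict[str, float],
    criteria: RejectionCriteria | None = None,
) -> list[str]:
    """Drop subjects whose epoch-rejection rate reaches the exclusion rate.

    Returns the kept subject ids in input order; raises if nobody survives.
    """
    criteria = criteria or RejectionCriteria()
    if any(not (0 <= r <= 1) for r in rejection_rates.values()):
        raise ValueError("rejection rates must be in [0, 1]")
    kept, excluded = [], []
    for sid, rate in rejection_rates.items():
        if rate >= criteria.subject_exclusion_rate:
            excluded.append(sid)
        else:
            kept.append(sid)
    for sid in excluded:
        logger.warning("excluding subject %s (rejection rate %.0f%%)",
                       sid, 100 * rejection_rates[sid])
    if not kept:
        raise ValueError("all subjects excluded; cannot proceed")
    return kept
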