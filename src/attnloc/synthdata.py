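"""Synthetic EEG generator for a four-location covert-attention experiment.

Emulates the study design of a modified Posner cueing task: a 250 ms
endogenous cue at one of four horizontal letter locations (1–2 in the left
hemifield, 3–4 in the right), a 450–550 ms delay, then each of the four
letters flashed twice for 33 ms within a 200 ms presentation window.  The
generated recording carries lateralized ERP components (an early
N2pc-like and a sustained SPCN-like contralateral negativity locked to the
cue; P1-like and late contralateral positivities locked to each flash of the
cued letter) on three posterior electrode pairs, on top of 1/f background
noise, with optional ocular artifacts (blinks on VEOG, saccade steps on
HEOG) whose ground-truth times are returned for rejection-recall testing.

All randomness flows from explicit integer seeds through
``numpy.random.SeedSequence`` spawning, so every product is reproducible
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Channel order of every generated recording.
CHANNELS = ("PO7", "PO8", "O1", "O2", "PO3", "PO4", "HEOG", "VEOG", "M1", "M2")
EEG_CHANNELS = ("PO7", "PO8", "O1", "O2", "PO3", "PO4")
EOG_CHANNELS = ("HEOG", "VEOG")
MASTOID_CHANNELS = ("M1", "M2")
#: Left member first in every posterior pair (odd 10-10 labels are left).
ELECTRODE_PAIRS = (("PO7", "PO8"), ("O1", "O2"), ("PO3", "PO4"))

#: Hemifield of each cued location: +1 = left of fixation, -1 = right.
HEMIFIELD = {1: +1, 2: +1, 3: -1, 4: -1}
OUTER_LOCATIONS = (1, 4)


@dataclass(frozen=True)
class TaskDesign:
    """Trial structure and stimulus geometry of the cueing task.

    Defaults reproduce the study conditions: two blocks of 300 trials
    (600 total, 150 per location), 512 Hz sampling, 250 ms cue, uniform
    450–550 ms cue-offset-to-letters delay, letters flashed twice for 33 ms
    with a minimum 17 ms inter-flash gap inside a 200 ms window, letter
    locations separated horizontally by 0.88 degrees of visual angle.
    """

    n_blocks: int = 2
    trials_per_block: int = 300
    n_locations: int = 4
    cue_duration_ms: float = 250.0
    delay_range_ms: tuple[float, float] = (450.0, 550.0)
    flash_duration_ms: float = 33.0
    min_interflash_gap_ms: float = 17.0
    presentation_window_ms: float = 200.0
    horizontal_gap_deg: float = 0.88
    vertical_gap_deg: float = 2.05
    sampling_rate_hz: float = 512.0
    #: Time from one trial's cue onset to the next; sized so that the
    #: -200..+800 ms epochs of the latest possible flash never collide
    #: with the following trial's cue-locked epoch.
    trial_period_ms: float = 2400.0
    #: Lead-in before the first cue so the first baseline window exists.
    lead_in_ms: float = 500.0

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def validate(self) -> None:
        if self.n_trials % self.n_locations != 0:
            raise ValueError(
                f"unbalanced design: {self.n_trials} trials not divisible by "
                f"{self.n_locations} locations"
            )
        span = 2 * self.flash_duration_ms + self.min_interflash_gap_ms
        if span > self.presentation_window_ms:
            raise ValueError(
                "two flashes plus the minimum gap do not fit in the "
                f"presentation window ({span} > {self.presentation_window_ms} ms)"
            )
        if not (0 < self.delay_range_ms[0] <= self.delay_range_ms[1]):
            raise ValueError("invalid delay range")


@dataclass(frozen=True)
class GroundTruth:
    """Known lateralized-component amplitudes injected per cued location.

    Amplitudes are *contralateral minus ipsilateral* in microvolts: negative
    for the attention-related negativities (N2pc-like, SPCN-like), positive
    for the flash-evoked contralateral positivities.  Index 0 of each
    4-vector is location 1 (leftmost), index 3 location 4 (rightmost).
    Outer locations carry ``eccentricity_factor`` times the inner amplitude,
    mirroring the observation that the outermost locations decode best.

    ``component_latencies_ms`` maps component name to (onset, offset) in ms
    relative to its locking event (cue onset or flash onset).
    """

    cue_locked_amp_uv: tuple[float, ...] = ()
    cue_locked_early_amp_uv: tuple[float, ...] = ()
    target_locked_early_amp_uv: tuple[float, ...] = ()
    target_locked_late_amp_uv: tuple[float, ...] = ()
    component_latencies_ms: dict = field(
        default_factory=lambda: {
            "cue_early": (170.0, 270.0),
            "cue_late": (300.0, 840.0),
            "target_early": (0.0, 100.0),
            "target_late": (410.0, 530.0),
        }
    )
    noise_sd_uv: float = 10.0
    #: Per-subject multiplicative amplitude variability (lognormal sigma).
    subject_scale_sd: float = 0.3
    #: Expected artifact events per trial: {"blink": r, "saccade": r}.
    artifact_rates: dict = field(
        default_factory=lambda: {"blink": 0.05, "saccade": 0.03}
    )

    @staticmethod
    def default(
        cue_early: float = -1.0,
        cue_late: float = -2.0,
        target_early: float = 1.5,
        target_late: float = 1.0,
        eccentricity_factor: float = 1.5,
        noise_sd_uv: float = 10.0,
        subject_scale_sd: float = 0.3,
        artifact_rates: dict | None = None,
    ) -> "GroundTruth":
        """Build a graded ground truth from per-component base amplitudes.

        ``cue_early``/``cue_late``/``target_early``/``target_late`` are the
        contra-minus-ipsi amplitudes (μV) at the inner locations 2 and 3;
        outer locations 1 and 4 get the same value times
        ``eccentricity_factor``.
        """

        def grade(base: float) -> tuple[float, float, float, float]:
            return (base * eccentricity_factor, base, base,
                    base * eccentricity_factor)

        kwargs = {}
        if artifact_rates is not None:
            kwargs["artifact_rates"] = dict(artifact_rates)
        return GroundTruth(
            cue_locked_amp_uv=grade(cue_late),
            cue_locked_early_amp_uv=grade(cue_early),
            target_locked_early_amp_uv=grade(target_early),
            target_locked_late_amp_uv=grade(target_late),
            noise_sd_uv=noise_sd_uv,
            subject_scale_sd=subject_scale_sd,
            **kwargs,
        )

    def mirrored(self) -> "GroundTruth":
        """Ground truth with the location axis flipped (1↔4, 2↔3)."""
        flip = lambda t: tuple(reversed(t))
        return replace(
            self,
            cue_locked_amp_uv=flip(self.cue_locked_amp_uv),
            cue_locked_early_amp_uv=flip(self.cue_locked_early_amp_uv),
            target_locked_early_amp_uv=flip(self.target_locked_early_amp_uv),
            target_locked_late_amp_uv=flip(self.target_locked_late_amp_uv),
        )

    def validate(self) -> None:
        for name in ("cue_locked_amp_uv", "cue_locked_early_amp_uv",
                     "target_locked_early_amp_uv", "target_locked_late_amp_uv"):
            amps = getattr(self, name)
            if len(amps) != 4 or not np.all(np.isfinite(amps)):
                raise ValueError(f"{name} must hold 4 finite amplitudes")
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be >= 0")
        if any(r < 0 for r in self.artifact_rates.values()):
            raise ValueError("artifact rates must be >= 0")


@dataclass(frozen=True)
class TrialSchedule:
    """Per-trial cue locations and event times for one simulated session.

    ``trials`` columns: trial, block, location (1–4 cued), cue_onset_s,
    letters_onset_s (start of the 200 ms presentation window), and
    flash{1,2}_loc{1..4}_s — onsets of the two flashes of the letter at each
    location (every letter flashes at every location on every trial).
    """

    design: TaskDesign
    trials: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def duration_s(self) -> float:
        d = self.design
        return (d.lead_in_ms + d.trial_period_ms * self.n_trials) / 1000.0


def generate_schedule(design: TaskDesign, seed: int) -> TrialSchedule:
    """Draw a balanced, randomly ordered trial schedule.

    Each location is cued exactly ``n_trials / 4`` times.  Flash onsets are
    drawn uniformly subject to the timing constraints: each letter flashes
    twice for 33 ms, the second flash starts at least 17 ms after the first
    ends, and both flashes end inside the 200 ms presentation window.
    """
    design.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    d = design
    n = d.n_trials

    locations = np.repeat(np.arange(1, d.n_locations + 1), n // d.n_locations)
    rng.shuffle(locations)

    cue_onset = (d.lead_in_ms + d.trial_period_ms * np.arange(n)) / 1000.0
    delay = rng.uniform(*d.delay_range_ms, size=n)
    letters_onset = cue_onset + (d.cue_duration_ms + delay) / 1000.0

    # Latest admissible onsets (ms relative to window start).
    last2 = d.presentation_window_ms - d.flash_duration_ms          # 167
    last1 = last2 - d.flash_duration_ms - d.min_interflash_gap_ms   # 117
    cols = {"trial": np.arange(n), "block": np.arange(n) // d.trials_per_block,
            "location": locations, "cue_onset_s": cue_onset,
            "letters_onset_s": letters_onset}
    for loc in range(1, d.n_locations + 1):
        f1 = rng.uniform(0.0, last1, size=n)
        f2 = rng.uniform(f1 + d.flash_duration_ms + d.min_interflash_gap_ms,
                         last2, size=n)
        cols[f"flash1_loc{loc}_s"] = letters_onset + f1 / 1000.0
        cols[f"flash2_loc{loc}_s"] = letters_onset + f2 / 1000.0

    return TrialSchedule(design=design, trials=pd.DataFrame(cols))


@dataclass
class Recording:
    """Continuous multi-channel recording with labeled event markers.

    ``data`` is (n_channels, n_samples) in μV; ``events`` has columns
    sample, kind ("cue" | "flash"), location (cued location for cue events,
    the flashed letter's location for flash events) and cued_location.
    """

    data: np.ndarray
    channels: tuple[str, ...]
    sfreq: float
    events: pd.DataFrame
    subject: str = "S00"

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be (n_channels, n_samples)")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.events) and (
            self.events["sample"].min() < 0
            or self.events["sample"].max() >= self.data.shape[1]
        ):
            raise ValueError("event sample index outside recording bounds")

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.channels, self.sfreq,
                         self.events.copy(), self.subject)


def _half_cosine_envelope(n: int, ramp: int) -> np.ndarray:
    """Boxcar of length n with half-cosine on/off ramps of ``ramp`` samples."""
    env = np.ones(n)
    ramp = min(ramp, n // 2)
    if ramp > 0:
        up = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = up
        env[-ramp:] = up[::-1]
    return env


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """1/f-amplitude Gaussian noise, normalized to standard deviation sd."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0  # no DC offset
    pink = np.fft.irfft(spec * scale, n=n)
    return pink * (sd / pink.std())


def _add_lateralized(
    data: np.ndarray,
    channels: tuple[str, ...],
    onset_sample: int,
    amp_contra_uv: float,
    hemifield: int,
    window_ms: tuple[float, float],
    sfreq: float,
    ramp_ms: float = 20.0,
) -> None:
    """Add a lateralized component around ``onset_sample`` in place.

    ``amp_contra_uv`` is the contralateral-minus-ipsilateral amplitude; it is
    split symmetrically (±amp/2) over the two channels of every posterior
    pair so the left-minus-right difference equals −hemifield × amp.
    """
    start = onset_sample + int(round(window_ms[0] * sfreq / 1000.0))
    stop = onset_sample + int(round(window_ms[1] * sfreq / 1000.0))
    if stop > data.shape[1]:
        raise ValueError("component extends beyond recording end")
    n = stop - start
    env = _half_cosine_envelope(n, int(round(ramp_ms * sfreq / 1000.0)))
    # contra hemisphere channels get +amp/2, ipsi −amp/2
    half = 0.5 * amp_contra_uv * env
    for left, right in ELECTRODE_PAIRS:
        li, ri = channels.index(left), channels.index(right)
        if hemifield > 0:  # attending left: right hemisphere is contralateral
            data[ri, start:stop] += half
            data[li, start:stop] -= half
        else:
            data[li, start:stop] += half
            data[ri, start:stop] -= half


def synthesize_subject(
    schedule: TrialSchedule,
    truth: GroundTruth,
    seed: int,
    subject: str = "S00",
) -> Recording:
    """Render one subject's continuous recording from a schedule.

    Per trial, the cue-locked components are added time-locked to cue onset
    with the cued location's amplitude, and the target-locked components to
    each of the two flashes of the letter at the cued location.  Pink noise
    of ``truth.noise_sd_uv`` is added independently per EEG/EOG channel;
    mastoids get low-amplitude (0.05 × sd) noise so re-referencing is
    exercised without dominating.  A per-subject lognormal scale factor
    (sigma ``truth.subject_scale_sd``) multiplies all component amplitudes.
    """
    truth.validate()
    d = schedule.design
    sfreq = d.sampling_rate_hz
    n_samples = int(round(schedule.duration_s() * sfreq))
    data = np.zeros((len(CHANNELS), n_samples))

    ss = np.random.SeedSequence(entropy=seed, spawn_key=(0,))
    rng_scale, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]
    scale = (
        float(np.exp(rng_scale.normal(0.0, truth.subject_scale_sd)))
        if truth.subject_scale_sd > 0 else 1.0
    )

    lat = truth.component_latencies_ms
    events = []
    for row in schedule.trials.itertuples(index=False):
        loc = int(row.location)
        h = HEMIFIELD[loc]
        cue_sample = int(round(row.cue_onset_s * sfreq))
        events.append((cue_sample, "cue", loc, loc))
        _add_lateralized(data, CHANNELS, cue_sample,
                         scale * truth.cue_locked_early_amp_uv[loc - 1], h,
                         lat["cue_early"], sfreq)
        _add_lateralized(data, CHANNELS, cue_sample,
                         scale * truth.cue_locked_amp_uv[loc - 1], h,
                         lat["cue_late"], sfreq)
        for fl_loc in range(1, d.n_locations + 1):
            for k in (1, 2):
                fs = int(round(getattr(row, f"flash{k}_loc{fl_loc}_s") * sfreq))
                events.append((fs, "flash", fl_loc, loc))
                if fl_loc == loc:
                    _add_lateralized(
                        data, CHANNELS, fs,
                        scale * truth.target_locked_early_amp_uv[loc - 1], h,
                        lat["target_early"], sfreq)
                    _add_lateralized(
                        data, CHANNELS, fs,
                        scale * truth.target_locked_late_amp_uv[loc - 1], h,
                        lat["target_late"], sfreq)

    for name in EEG_CHANNELS + EOG_CHANNELS:
        data[CHANNELS.index(name)] += _pink_noise(
            rng_noise, n_samples, truth.noise_sd_uv)
    for name in MASTOID_CHANNELS:
        data[CHANNELS.index(name)] += _pink_noise(
            rng_noise, n_samples, 0.05 * truth.noise_sd_uv)

    events_df = pd.DataFrame(
        events, columns=["sample", "kind", "location", "cued_location"]
    ).sort_values("sample", kind="stable").reset_index(drop=True)
    return Recording(data=data, channels=CHANNELS, sfreq=sfreq,
                     events=events_df, subject=subject)


# Artifact templates: blink = half-cosine bump on VEOG with fractional
# leakage into posterior EEG; saccade = ramped step on HEOG.
BLINK_AMP_UV = 150.0
BLINK_DURATION_MS = 250.0
BLINK_EEG_LEAK = 0.10
SACCADE_AMP_UV = 60.0
SACCADE_DURATION_MS = 400.0
SACCADE_RAMP_MS = 30.0


def inject_artifacts(
    recording: Recording,
    rates: dict | None,
    seed: int,
    blink_amp_uv: float = BLINK_AMP_UV,
    saccade_amp_uv: float = SACCADE_AMP_UV,
) -> tuple[Recording, pd.DataFrame]:
    """Add blink and saccade artifacts at random times.

    ``rates`` maps {"blink": r, "saccade": r} in expected events per trial;
    counts are Poisson.  Returns the modified copy and a truth-label table
    (sample, kind, amplitude_uv).  Rate 0 (or None) leaves the recording
    untouched.
    """
    rates = rates or {}
    if any(r < 0 for r in rates.values()):
        raise ValueError("artifact rates must be >= 0")
    out = recording.copy()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(1,)))
    sfreq = out.sfreq
    n_samples = out.data.shape[1]
    n_trials = max(1, int((out.events["kind"] == "cue").sum()))
    labels = []

    def _times(kind: str, dur_ms: float) -> np.ndarray:
        count = rng.poisson(rates.get(kind, 0.0) * n_trials)
        hi = n_samples - int(round(dur_ms * sfreq / 1000.0)) - 1
        return rng.integers(0, max(hi, 1), size=count)

    veog = out.channels.index("VEOG")
    nb = int(round(BLINK_DURATION_MS * sfreq / 1000.0))
    bump = np.sin(np.pi * np.arange(nb) / nb) ** 2
    for s in _times("blink", BLINK_DURATION_MS):
        out.data[veog, s:s + nb] += blink_amp_uv * bump
        for name in EEG_CHANNELS:
            out.data[out.channels.index(name), s:s + nb] += (
                BLINK_EEG_LEAK * blink_amp_uv * bump)
        labels.append((int(s), "blink", blink_amp_uv))

    heog = out.channels.index("HEOG")
    ns = int(round(SACCADE_DURATION_MS * sfreq / 1000.0))
    ramp = int(round(SACCADE_RAMP_MS * sfreq / 1000.0))
    step = np.ones(ns)
    step[:ramp] = np.arange(ramp) / ramp
    step[-ramp:] = step[:ramp][::-1]
    for s in _times("saccade", SACCADE_DURATION_MS):
        sign = rng.choice([-1.0, 1.0])
        out.data[heog, s:s + ns] += sign * saccade_amp_uv * step
        labels.append((int(s), "saccade", sign * saccade_amp_uv))

    labels_df = pd.DataFrame(labels, columns=["sample", "kind", "amplitude_uv"])
    return out, labels_df
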