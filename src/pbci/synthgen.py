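"""Seeded synthetic dual-session physiological recordings.

Generates the eight-channel montage (five EEG sites Fz, F7, Pz, P7, O2;
bipolar VEOG, HEOG; bipolar ECG) at 200 Hz with the statistical structure the
workload analysis assumes:

* EEG as a sum of band-limited Gaussian oscillations whose per-band RMS
  amplitude is set per channel, so band power scales as amplitude squared;
* blinks as raised-cosine deflections in VEOG that propagate into the EEG
  channels with frontal-dominant gains;
* saccades as step-and-return deflections in HEOG;
* ECG as a train of biphasic QRS templates with Gaussian inter-beat gaps;
* a between-session "electrode replacement" perturbation (per-channel gain,
  additive sensor noise, small EEG cross-mixing, DC offset).

All generation is deterministic given the seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

SAMPLE_RATE = 200.0
EEG_CHANNELS = ("Fz", "F7", "Pz", "P7", "O2")
EOG_CHANNELS = ("VEOG", "HEOG")
ALL_CHANNELS = EEG_CHANNELS + EOG_CHANNELS + ("ECG",)

#: clinical band edges in Hz, shared with the feature module
BANDS = {
    "delta": (0.5, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (31.0, 42.0),
}

_IBI_MIN_MS = 300.0
_IBI_MAX_MS = 2000.0


@dataclass
class StateProfile:
    """Generative parameters for one workload state.

    band_amplitude maps channel -> band -> RMS amplitude in uV; blink and
    saccade rates are events/min; mean_ibi / ibi_sd are ms; blink_propagation
    is the unitless gain of the VEOG waveform into each EEG channel.
    """

    band_amplitude: dict[str, dict[str, float]]
    blink_rate: float
    saccade_rate: float
    mean_ibi: float
    ibi_sd: float
    blink_propagation: dict[str, float]
    blink_amplitude: float = 250.0
    saccade_amplitude: float = 60.0
    eeg_noise_sd: float = 1.0
    eog_noise_sd: float = 4.0
    ecg_noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.blink_rate < 0 or self.saccade_rate < 0:
            raise ValueError("event rates must be >= 0")
        if not (_IBI_MIN_MS <= self.mean_ibi <= _IBI_MAX_MS):
            raise ValueError(f"mean_ibi must lie in [{_IBI_MIN_MS}, {_IBI_MAX_MS}] ms")
        if self.ibi_sd < 0:
            raise ValueError("ibi_sd must be >= 0")
        if any(g < 0 for g in self.blink_propagation.values()):
            raise ValueError("blink propagation gains must be >= 0")
        frontal = min(self.blink_propagation["Fz"], self.blink_propagation["F7"])
        rest = max(self.blink_propagation[c] for c in ("Pz", "P7", "O2"))
        if frontal < rest:
            raise ValueError("blink propagation must be frontal-dominant")


@dataclass
class SessionPerturbation:
    """Electrode-replacement perturbation applied to a generated session.

    channel_gain and dc_offset cover all eight channels; mixing is a
    row-stochastic matrix over the five EEG channels only; noise_sd is
    additive white sensor noise in uV per channel.
    """

    channel_gain: dict[str, float]
    noise_sd: dict[str, float]
    mixing: np.ndarray
    dc_offset: dict[str, float]

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.channel_gain.values()):
            raise ValueError("channel gains must be > 0")
        m = np.asarray(self.mixing, dtype=float)
        if m.shape != (len(EEG_CHANNELS), len(EEG_CHANNELS)):
            raise ValueError("mixing must be square over the EEG channels")
        if (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0):
            raise ValueError("mixing rows must be non-negative and sum to 1")
        self.mixing = m

    @classmethod
    def identity(cls) -> "SessionPerturbation":
        return cls(
            channel_gain={c: 1.0 for c in ALL_CHANNELS},
            noise_sd={c: 0.0 for c in ALL_CHANNELS},
            mixing=np.eye(len(EEG_CHANNELS)),
            dc_offset={c: 0.0 for c in ALL_CHANNELS},
        )

    def is_identity(self) -> bool:
        return (
            all(g == 1.0 for g in self.channel_gain.values())
            and all(s == 0.0 for s in self.noise_sd.values())
            and np.array_equal(self.mixing, np.eye(len(EEG_CHANNELS)))
            and all(o == 0.0 for o in self.dc_offset.values())
        )


@dataclass
class Recording:
    """Fixed-rate multichannel uV time series with trial annotations.

    annotations is a list of (start_s, end_s, workload_label, session_label)
    tuples; trials must not overlap.
    """

    sample_rate: float
    channels: tuple[str, ...]
    samples: np.ndarray  # channels x time, uV
    annotations: list[tuple[float, float, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape[0] != len(self.channels):
            raise ValueError("one sample row per channel required")
        spans = sorted((a[0], a[1]) for a in self.annotations)
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError("annotations must not overlap")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.channels.index(name)]

    def trial_slices(self):
        """Yield (samples slice, workload, session) per annotated trial."""
        for start, end, workload, session in self.annotations:
            i0 = int(round(start * self.sample_rate))
            i1 = int(round(end * self.sample_rate))
            yield self.samples[:, i0:i1], workload, session


def default_workload_profiles(effect_scale: float = 1.0) -> tuple[StateProfile, StateProfile]:
    """Return (low, high) workload state profiles.

    The high-workload profile differs from low only in the four canonical
    signatures: Fz theta amplitude up, Pz alpha amplitude down, blink rate
    down, mean inter-beat interval down (heart rate up). ``effect_scale``
    scales all four differences; 0 gives identical profiles.
    """
    base_amp = {"delta": 3.0, "theta": 2.0, "alpha": 3.0, "beta": 1.5, "gamma": 0.8}
    posterior_alpha = {"Pz": 5.0, "P7": 4.5, "O2": 5.5}
    band_amplitude: dict[str, dict[str, float]] = {}
    for ch in EEG_CHANNELS:
        amps = dict(base_amp)
        if ch in posterior_alpha:
            amps["alpha"] = posterior_alpha[ch]
        band_amplitude[ch] = amps
    # EOG band content: broadband low-frequency dominance
    for ch in EOG_CHANNELS:
        band_amplitude[ch] = {"delta": 6.0, "theta": 3.0, "alpha": 2.0, "beta": 1.0, "gamma": 0.5}

    propagation = {"Fz": 0.35, "F7": 0.30, "Pz": 0.08, "P7": 0.06, "O2": 0.04}

    low = StateProfile(
        band_amplitude=band_amplitude,
        blink_rate=15.0,
        saccade_rate=8.0,
        mean_ibi=850.0,
        ibi_sd=40.0,
        blink_propagation=propagation,
    )
    high = copy.deepcopy(low)
    s = float(effect_scale)
    high.band_amplitude["Fz"]["theta"] = low.band_amplitude["Fz"]["theta"] * (1.0 + 0.5 * s)
    high.band_amplitude["Pz"]["alpha"] = low.band_amplitude["Pz"]["alpha"] * (1.0 - 0.3 * s)
    high.blink_rate = low.blink_rate - 5.0 * s
    high.mean_ibi = low.mean_ibi - 100.0 * s
    return low, high


def _band_noise(rng: np.random.Generator, n: int, lo: float, hi: float, fs: float) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise via 4th-order Butterworth."""
    nyq = fs / 2.0
    sos = signal.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    # pad so filter transients do not depress the RMS of short trials
    pad = int(4 * fs)
    x = signal.sosfilt(sos, rng.standard_normal(n + pad))[pad:]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def blink_template(fs: float = SAMPLE_RATE, width_s: float = 0.35) -> np.ndarray:
    """Raised-cosine positive deflection; unit peak, ~350 ms duration."""
    n = int(round(width_s * fs))
    t = np.arange(n) / n
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * t))


def qrs_template(fs: float = SAMPLE_RATE) -> np.ndarray:
    """Biphasic QRS complex, unit R peak, ~90 ms total width."""
    q = -0.15 * np.sin(np.pi * np.arange(int(0.02 * fs)) / int(0.02 * fs))
    nr = int(0.04 * fs)
    r = np.sin(np.pi * np.arange(nr) / nr)
    ns = int(0.03 * fs)
    s = -0.25 * np.sin(np.pi * np.arange(ns) / ns)
    return np.concatenate([q, r, s])


def _event_times(
    rng: np.random.Generator, rate_per_min: float, duration_s: float, mode: str
) -> np.ndarray:
    """Event onset times; jittered-regular mode has exactly rate*duration events."""
    if rate_per_min <= 0:
        return np.empty(0)
    if mode == "poisson":
        lam = rate_per_min / 60.0
        gaps = rng.exponential(1.0 / lam, size=int(np.ceil(lam * duration_s * 2)) + 10)
        times = np.cumsum(gaps)
        return times[times < duration_s]
    # jittered-regular: deterministic count round(rate * duration / 60)
    count = int(round(rate_per_min * duration_s / 60.0))
    spacing = duration_s / max(count, 1)
    centers = (np.arange(count) + 0.5) * spacing
    jitter = rng.uniform(-0.2, 0.2, size=count) * spacing
    return np.sort(np.clip(centers + jitter, 0.0, duration_s - 0.6))


def _inject(trace: np.ndarray, times: np.ndarray, template: np.ndarray, amps, fs: float) -> None:
    amps = np.broadcast_to(np.asarray(amps, dtype=float), times.shape)
    for t, a in zip(times, amps):
        i = int(round(t * fs))
        j = min(i + len(template), len(trace))
        trace[i:j] += a * template[: j - i]


def generate_trial(
    profile: StateProfile,
    duration_s: float,
    seed: int,
    perturbation: SessionPerturbation | None = None,
    event_mode: str = "jittered",
    sample_rate: float = SAMPLE_RATE,
) -> Recording:
    """Generate one unannotated trial Recording.

    Deterministic given all arguments. ``event_mode`` is "jittered"
    (deterministic event counts) or "poisson".
    """
    if duration_s < 60:
        raise ValueError(
            "duration_s must be >= 60 s: shorter trials cannot hold the "
            "30 s blink-rate feature window with headroom"
        )
    if perturbation is None:
        perturbation = SessionPerturbation.identity()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    samples = np.zeros((len(ALL_CHANNELS), n))

    # VEOG: blinks + broadband EOG background
    veog = np.zeros(n)
    for band, amp in profile.band_amplitude["VEOG"].items():
        if amp > 0:
            lo, hi = BANDS[band]
            veog += amp * _band_noise(rng, n, lo, hi, sample_rate)
    blink_times = _event_times(rng, profile.blink_rate, duration_s, event_mode)
    blink_amps = profile.blink_amplitude * rng.uniform(0.85, 1.15, size=len(blink_times))
    _inject(veog, blink_times, blink_template(sample_rate), blink_amps, sample_rate)
    if profile.eog_noise_sd > 0:
        veog += profile.eog_noise_sd * rng.standard_normal(n)

    # HEOG: saccade steps (rise, hold, return) + background
    heog = np.zeros(n)
    for band, amp in profile.band_amplitude["HEOG"].items():
        if amp > 0:
            lo, hi = BANDS[band]
            heog += amp * _band_noise(rng, n, lo, hi, sample_rate)
    sacc_times = _event_times(rng, profile.saccade_rate, duration_s, event_mode)
    step = _saccade_template(sample_rate)
    signs = np.where(np.arange(len(sacc_times)) % 2 == 0, 1.0, -1.0)
    _inject(heog, sacc_times, step, signs * profile.saccade_amplitude, sample_rate)
    if profile.eog_noise_sd > 0:
        heog += profile.eog_noise_sd * rng.standard_normal(n)

    # EEG: per-band oscillations + blink propagation + sensor noise
    for ci, ch in enumerate(EEG_CHANNELS):
        x = np.zeros(n)
        for band, amp in profile.band_amplitude[ch].items():
            if amp > 0:
                lo, hi = BANDS[band]
                x += amp * _band_noise(rng, n, lo, hi, sample_rate)
        x += profile.blink_propagation[ch] * veog
        if profile.eeg_noise_sd > 0:
            x += profile.eeg_noise_sd * rng.standard_normal(n)
        samples[ci] = x

    samples[ALL_CHANNELS.index("VEOG")] = veog
    samples[ALL_CHANNELS.index("HEOG")] = heog

    # ECG: QRS train with truncated-Gaussian inter-beat gaps
    ecg = np.zeros(n)
    beat_times = _beat_times(rng, profile.mean_ibi, profile.ibi_sd, duration_s)
    _inject(ecg, beat_times, qrs_template(sample_rate), 1000.0, sample_rate)
    if profile.ecg_noise_sd > 0:
        ecg += profile.ecg_noise_sd * rng.standard_normal(n)
    samples[ALL_CHANNELS.index("ECG")] = ecg

    if not perturbation.is_identity():
        _apply_perturbation(samples, perturbation, rng)

    return Recording(sample_rate=sample_rate, channels=ALL_CHANNELS, samples=samples)


def _saccade_template(fs: float) -> np.ndarray:
    """Step up over 20 ms, hold ~1 s, step back; no blink-like apex."""
    rise = np.linspace(0.0, 1.0, int(0.02 * fs))
    hold = np.ones(int(1.0 * fs))
    fall = np.linspace(1.0, 0.0, int(0.02 * fs))
    return np.concatenate([rise, hold, fall])


def _beat_times(
    rng: np.random.Generator, mean_ibi_ms: float, ibi_sd_ms: float, duration_s: float
) -> np.ndarray:
    times = []
    t = rng.uniform(0.0, mean_ibi_ms / 1000.0) if ibi_sd_ms > 0 else 0.05
    while t < duration_s - 0.1:
        times.append(t)
        gap = rng.normal(mean_ibi_ms, ibi_sd_ms) if ibi_sd_ms > 0 else mean_ibi_ms
        gap = float(np.clip(gap, _IBI_MIN_MS, _IBI_MAX_MS))
        t += gap / 1000.0
    return np.asarray(times)


def _apply_perturbation(
    samples: np.ndarray, p: SessionPerturbation, rng: np.random.Generator
) -> None:
    n_eeg = len(EEG_CHANNELS)
    samples[:n_eeg] = p.mixing @ samples[:n_eeg]
    for ci, ch in enumerate(ALL_CHANNELS):
        samples[ci] *= p.channel_gain[ch]
        if p.noise_sd[ch] > 0:
            samples[ci] += p.noise_sd[ch] * rng.standard_normal(samples.shape[1])
        samples[ci] += p.dc_offset[ch]


def generate_session(
    low: StateProfile,
    high: StateProfile,
    trial_order: tuple[str, str],
    trial_duration_s: float,
    seed: int,
    perturbation: SessionPerturbation | None = None,
    session_label: str = "S1",
    event_mode: str = "jittered",
) -> Recording:
    """Generate one session of two annotated trials (one low, one high).

    Each trial gets a child seed derived from (seed, trial index), so swapping
    ``trial_order`` with the same seed yields the label-swapped session.
    """
    if sorted(trial_order) != ["high", "low"]:
        raise ValueError("trial_order must be a permutation of ('low', 'high')")
    profiles = {"low": low, "high": high}
    pieces, annotations = [], []
    for i, label in enumerate(trial_order):
        child_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        rec = generate_trial(
            profiles[label], trial_duration_s, child_seed, perturbation, event_mode
        )
        pieces.append(rec.samples)
        annotations.append(
            (i * trial_duration_s, (i + 1) * trial_duration_s, label, session_label)
        )
    return Recording(
        sample_rate=SAMPLE_RATE,
        channels=ALL_CHANNELS,
        samples=np.concatenate(pieces, axis=1),
        annotations=annotations,
    )


def replacement_perturbation(severity: float, seed: int) -> SessionPerturbation:
    """Draw an electrode-replacement perturbation of the given severity.

    severity 0 returns the exact identity; gains are log-uniform in
    [1/(1+0.2*severity), 1+0.2*severity], sensor noise and EEG cross-mixing
    grow monotonically with severity, DC offsets up to +-5*severity uV.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    s = float(severity)
    gain_r = 0.2
    u = rng.uniform(-1.0, 1.0, size=len(ALL_CHANNELS))
    gains = np.exp(u * np.log1p(s * gain_r))
    noise = s * rng.uniform(0.5, 1.5, size=len(ALL_CHANNELS)) * 2.0
    offsets = s * rng.uniform(-5.0, 5.0, size=len(ALL_CHANNELS))
    n_eeg = len(EEG_CHANNELS)
    off = s * 0.05 * rng.uniform(0.0, 1.0, size=(n_eeg, n_eeg))
    np.fill_diagonal(off, 0.0)
    mixing = np.eye(n_eeg) + off
    if s > 0:
        mixing /= mixing.sum(axis=1, keepdims=True)
    else:
        mixing = np.eye(n_eeg)
        noise = np.zeros(n_eeg + 3)
        offsets = np.zeros(n_eeg + 3)
        gains = np.ones(n_eeg + 3)
    return SessionPerturbation(
        channel_gain=dict(zip(ALL_CHANNELS, gains.tolist())),
        noise_sd=dict(zip(ALL_CHANNELS, noise.tolist())),
        mixing=mixing,
        dc_offset=dict(zip(ALL_CHANNELS, offsets.tolist())),
    )


# ---------------------------------------------------------------------------
# Recording I/O: long-format CSV + annotation sidecar.

def write_recording_csv(rec: Recording, samples_path, annotations_path=None) -> None:
    n = rec.samples.shape[1]
    t = np.arange(n) / rec.sample_rate
    frames = [
        pd.DataFrame({"time_s": t, "channel": ch, "value_uV": rec.samples[i]})
        for i, ch in enumerate(rec.channels)
    ]
    pd.concat(frames, ignore_index=True).to_csv(samples_path, index=False)
    if annotations_path is not None:
        pd.DataFrame(
            rec.annotations, columns=["start_s", "end_s", "workload", "session"]
        ).to_csv(annotations_path, index=False)


def read_recording_csv(samples_path, annotations_path=None, sample_rate=SAMPLE_RATE) -> Recording:
    df = pd.read_csv(samples_path)
    channels = tuple(df["channel"].unique())
    samples = np.stack(
        [df.loc[df["channel"] == ch, "value_uV"].to_numpy() for ch in channels]
    )
    annotations = []
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path)
        annotations = [
            (row.start_s, row.end_s, row.workload, row.session)
            for row in ann.itertuples()
        ]
    return Recording(
        sample_rate=sample_rate, channels=channels, samples=samples, annotations=annotations
    )


def read_recording_edf(path) -> Recording:
    """Read a Recording from an EDF file (requires mne)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        sample_rate=raw.info["sfreq"],
        channels=tuple(raw.ch_names),
        samples=raw.get_data() * 1e6,  # mne returns volts
    )
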