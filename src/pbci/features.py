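"""The 37-feature, 1 Hz-synchronized workload feature stream.

Per trial the stream carries, at every elapsed second:

* 25 EEG log band powers (5 channels x 5 clinical bands), from Hanning
  periodograms of 1 s windows averaged over a trailing 10 s window and
  log10-transformed;
* 10 EOG log band powers (VEOG, HEOG x 5 bands), same pipeline on the raw
  ocular channels;
* blink rate (blinks/min) from a causal VEOG blink detector, counts summed
  over a trailing 30 s window;
* mean inter-beat interval (ms) from a Pan-Tompkins-family R-wave detector,
  averaged over a trailing 10 s window.

All windows are trailing (right-aligned at each 1 s tick), matching a
real-time implementation. Output seconds earlier than a full averaging window
use the expanding-window warm-up rule, so every trial of T whole seconds
yields exactly T feature rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import AdaptiveFilterConfig, correct_eeg_block
from .synthgen import ALL_CHANNELS, BANDS, EEG_CHANNELS, EOG_CHANNELS, Recording

LOG_POWER_FLOOR = 1e-12  # uV^2; clamps degenerate all-zero windows before log10

#: frozen public column order of the feature frame
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{ch}_{band}" for ch in EEG_CHANNELS + EOG_CHANNELS for band in BANDS
) + ("blink_rate", "ibi")

EEG_FEATURES = tuple(n for n in FEATURE_NAMES if n.split("_")[0] in EEG_CHANNELS)
PERIPHERAL_FEATURES = tuple(n for n in FEATURE_NAMES if n not in EEG_FEATURES)


@dataclass
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError("band edges must satisfy 0 < lo < hi")


DEFAULT_BANDS = tuple(BandDefinition(name, lo, hi) for name, (lo, hi) in BANDS.items())


@dataclass
class FeatureConfig:
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    psd_avg_window_s: int = 10
    blink_window_s: int = 30
    ibi_window_s: int = 10
    rls: AdaptiveFilterConfig = field(default_factory=AdaptiveFilterConfig)


@dataclass
class FeatureFrame:
    """n_seconds x 37 matrix of features at 1 Hz with canonical column order."""

    timestamps: np.ndarray
    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.timestamps), len(self.names)):
            raise ValueError("values shape must be (n_seconds, n_features)")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("features must be finite")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.names))
        df.insert(0, "time_s", self.timestamps)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureFrame":
        df = pd.read_csv(path)
        return cls(
            timestamps=df["time_s"].to_numpy(),
            values=df.drop(columns="time_s").to_numpy(),
            names=tuple(df.columns[1:]),
        )


def periodogram_1s(window: np.ndarray, sample_rate: float = 200.0) -> tuple[np.ndarray, np.ndarray]:
    """Hanning-window periodogram of one 1 s window.

    Returns (freqs, psd) with psd in uV^2/Hz at 1 Hz bin spacing; satisfies
    Parseval's relation: sum(psd) * df equals the window-compensated
    time-domain power of the segment.
    """
    window = np.asarray(window, dtype=float)
    if len(window) != int(sample_rate):
        raise ValueError("window must hold exactly one second of samples")
    freqs, psd = signal.periodogram(
        window, fs=sample_rate, window="hann", detrend=False, scaling="density"
    )
    return freqs, psd


def band_power(freqs: np.ndarray, psd: np.ndarray, band: BandDefinition) -> float:
    """Sum of PSD bins with lo <= f <= hi, times the bin width (uV^2).

    At 1 s windows the bin spacing is 1 Hz, so a 0.5 Hz band edge first
    captures the 1 Hz bin.
    """
    mask = (freqs >= band.lo) & (freqs <= band.hi)
    if not mask.any():
        raise ValueError(f"band {band.name} contains no PSD bins")
    df = freqs[1] - freqs[0]
    return float(np.sum(psd[mask]) * df)


def _second_band_powers(x: np.ndarray, bands, sample_rate: float) -> np.ndarray:
    """Per-second raw band powers: (n_seconds, n_bands), non-overlapping 1 s windows."""
    n_sec = int(len(x) // sample_rate)
    out = np.empty((n_sec, len(bands)))
    for s in range(n_sec):
        seg = x[int(s * sample_rate) : int((s + 1) * sample_rate)]
        freqs, psd = periodogram_1s(seg, sample_rate)
        for bi, band in enumerate(bands):
            out[s, bi] = band_power(freqs, psd, band)
    return out


def _trailing_mean(per_second: np.ndarray, window: int) -> np.ndarray:
    """Trailing mean over up to `window` most recent rows (expanding warm-up)."""
    csum = np.cumsum(per_second, axis=0)
    out = np.empty_like(per_second, dtype=float)
    for s in range(len(per_second)):
        lo = max(0, s - window + 1)
        total = csum[s] - (csum[lo - 1] if lo > 0 else 0.0)
        out[s] = total / (s - lo + 1)
    return out


def rolling_log_band_features(
    x: np.ndarray,
    bands=DEFAULT_BANDS,
    sample_rate: float = 200.0,
    window_s: int = 10,
) -> np.ndarray:
    """Per-second log10 band powers: trailing `window_s`-second mean of 1 s
    band-power estimates, then log10 with a floor. One row per elapsed second."""
    if len(x) < window_s * sample_rate:
        raise ValueError("channel shorter than one averaging window")
    per_second = _second_band_powers(np.asarray(x, dtype=float), bands, sample_rate)
    avg = _trailing_mean(per_second, window_s)
    return np.log10(np.maximum(avg, LOG_POWER_FLOOR))


# ---------------------------------------------------------------------------
# VEOG blink detection

def detect_blinks(
    veog: np.ndarray,
    sample_rate: float = 200.0,
    k_mad: float = 4.0,
    min_width_s: float = 0.1,
    max_width_s: float = 0.5,
    return_to_baseline_s: float = 1.0,
) -> np.ndarray:
    """Blink apex times (s) from the VEOG channel (blinks positive).

    A candidate apex must exceed baseline + k_mad robust SDs, have a
    half-amplitude width inside [min_width_s, max_width_s], and return below
    a quarter of its prominence within `return_to_baseline_s` — which rejects
    saccade-like steps that stay elevated.
    """
    v = np.asarray(veog, dtype=float)
    if len(v) == 0:
        return np.empty(0)
    baseline = float(np.median(v))
    mad = float(np.median(np.abs(v - baseline)))
    sigma = 1.4826 * mad if mad > 0 else float(np.std(v))
    if sigma == 0:
        return np.empty(0)
    thr = baseline + k_mad * sigma
    min_dist = max(1, int(0.2 * sample_rate))
    peaks, _ = signal.find_peaks(v, height=thr, distance=min_dist)
    apexes = []
    for p in peaks:
        prom = v[p] - baseline
        half = baseline + 0.5 * prom
        i = p
        while i > 0 and v[i] > half:
            i -= 1
        j = p
        while j < len(v) - 1 and v[j] > half:
            j += 1
        width = (j - i) / sample_rate
        if not (min_width_s <= width <= max_width_s):
            continue
        quarter = baseline + 0.25 * prom
        horizon = min(len(v), p + int(return_to_baseline_s * sample_rate))
        if not (v[p:horizon] < quarter).any():
            continue
        apexes.append(p / sample_rate)
    return np.asarray(apexes)


def blink_rate_feature(
    blink_times: np.ndarray, duration_s: float, window_s: int = 30
) -> np.ndarray:
    """Per-second blink rate (blinks/min): count in the trailing `window_s`
    seconds times 60/window_s. The window ends at the close of each second
    ([t+1-window, t+1) for output second t); seconds before the recording
    start contribute zero counts."""
    times = np.asarray(blink_times, dtype=float)
    n_sec = int(duration_s)
    out = np.empty(n_sec)
    scale = 60.0 / window_s
    for s in range(n_sec):
        end = s + 1.0
        start = end - window_s
        out[s] = np.count_nonzero((times >= start) & (times < end)) * scale
    return out


# ---------------------------------------------------------------------------
# ECG R-wave detection (Pan-Tompkins family)

def detect_rwaves(
    ecg: np.ndarray,
    sample_rate: float = 200.0,
    refractory_s: float = 0.2,
) -> np.ndarray:
    """R-wave times (s) via bandpass, derivative, squaring, moving-window
    integration and adaptive dual thresholds with a 200 ms refractory."""
    x = np.asarray(ecg, dtype=float)
    if len(x) < sample_rate:
        return np.empty(0)
    nyq = sample_rate / 2.0
    sos = signal.butter(2, [5.0 / nyq, 15.0 / nyq], btype="bandpass", output="sos")
    filt = signal.sosfilt(sos, x)
    deriv = np.diff(filt, prepend=filt[0])
    sq = deriv**2
    win = max(1, int(0.15 * sample_rate))
    integ = np.convolve(sq, np.ones(win) / win, mode="full")[: len(sq)]

    min_dist = max(1, int(refractory_s * sample_rate))
    peaks, props = signal.find_peaks(integ, distance=min_dist)
    if len(peaks) == 0:
        return np.empty(0)

    # adaptive signal/noise level estimates (Pan-Tompkins style)
    init = integ[: int(2 * sample_rate)]
    spki = float(np.max(init)) * 0.5 if init.size else 0.0
    npki = float(np.mean(init)) * 0.5 if init.size else 0.0
    accepted = []
    for p in peaks:
        threshold = npki + 0.25 * (spki - npki)
        if integ[p] >= threshold:
            if accepted and (p - accepted[-1]) < min_dist:
                continue
            accepted.append(p)
            spki = 0.125 * integ[p] + 0.875 * spki
        else:
            npki = 0.125 * integ[p] + 0.875 * npki

    # refine each detection to the raw R apex: the integrator peak trails the
    # R wave by roughly the integration window plus filter group delay
    back = int(0.20 * sample_rate)
    r_times = []
    for p in accepted:
        lo = max(0, p - back)
        hi = min(len(x), p + int(0.05 * sample_rate))
        r = lo + int(np.argmax(x[lo:hi]))
        r_times.append(r / sample_rate)
    r_times = np.asarray(sorted(set(r_times)))
    if len(r_times) > 1:
        keep = np.concatenate([[True], np.diff(r_times) >= refractory_s])
        r_times = r_times[keep]
    return r_times


def ibi_feature(
    r_times: np.ndarray, duration_s: float, window_s: int = 10
) -> np.ndarray:
    """Per-second mean inter-beat interval (ms).

    Averages the intervals whose terminating R-wave falls in the trailing
    `window_s` seconds; carries the last valid value when the window holds no
    interval, and back-fills leading seconds from the first valid value.
    """
    times = np.asarray(r_times, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least two R-waves to form an interval")
    intervals_ms = np.diff(times) * 1000.0
    ends = times[1:]
    n_sec = int(duration_s)
    out = np.full(n_sec, np.nan)
    last = np.nan
    for s in range(n_sec):
        end = s + 1.0
        mask = (ends >= end - window_s) & (ends < end)
        if mask.any():
            last = float(np.mean(intervals_ms[mask]))
        out[s] = last
    if np.isnan(out).any():
        first_valid = out[~np.isnan(out)][0]
        out = np.where(np.isnan(out), first_valid, out)
    return out


# ---------------------------------------------------------------------------
# Assembly

def assemble_features(
    recording: Recording, config: FeatureConfig | None = None
) -> list[tuple[FeatureFrame, str, str]]:
    """Per annotated trial, a (FeatureFrame, workload, session) triple.

    EEG band features are computed on RLS-corrected channels (filter state
    reset per trial); EOG band features on the raw VEOG/HEOG channels; blink
    rate from VEOG; IBI from ECG. Exactly one row per elapsed second and 37
    columns in the frozen canonical order.
    """
    if config is None:
        config = FeatureConfig()
    missing = [c for c in ALL_CHANNELS if c not in recording.channels]
    if missing:
        raise ValueError(f"recording lacks channels: {missing}")
    if not recording.annotations:
        raise ValueError("recording has no trial annotations")
    fs = recording.sample_rate
    results = []
    ch_index = {c: recording.channels.index(c) for c in ALL_CHANNELS}
    for trial, workload, session in recording.trial_slices():
        duration_s = trial.shape[1] / fs
        if duration_s < config.blink_window_s:
            raise ValueError("trial shorter than the longest feature window")
        veog = trial[ch_index["VEOG"]]
        heog = trial[ch_index["HEOG"]]
        eeg = np.stack([trial[ch_index[c]] for c in EEG_CHANNELS])
        eeg_corrected = correct_eeg_block(eeg, veog, heog, config.rls)

        cols = []
        for row in eeg_corrected:
            cols.append(
                rolling_log_band_features(row, config.bands, fs, config.psd_avg_window_s)
            )
        for eog in (veog, heog):
            cols.append(
                rolling_log_band_features(eog, config.bands, fs, config.psd_avg_window_s)
            )
        blink_times = detect_blinks(veog, fs)
        blink = blink_rate_feature(blink_times, duration_s, config.blink_window_s)
        r_times = detect_rwaves(trial[ch_index["ECG"]], fs)
        ibi = ibi_feature(r_times, duration_s, config.ibi_window_s)

        values = np.column_stack(cols + [blink, ibi])
        frame = FeatureFrame(
            timestamps=np.arange(1, int(duration_s) + 1, dtype=float), values=values
        )
        results.append((frame, workload, session))
    return results
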