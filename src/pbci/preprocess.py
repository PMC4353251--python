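"""Recursive-least-squares adaptive cancellation of ocular artifact.

Each EEG channel is treated as primary input to a noise-cancelling adaptive
filter whose reference inputs are the bipolar VEOG and HEOG channels. At each
sample the filter predicts the reference-correlated component of the EEG from
the M most recent samples of each reference and subtracts it; the prediction
weights are updated by exponentially-weighted recursive least squares. The
filter is causal, and with identically-zero references the output equals the
input exactly (the weight update never fires).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AdaptiveFilterConfig:
    """RLS parameters: M taps per reference, forgetting factor, P(0) = delta*I."""

    taps_per_reference: int = 3
    forgetting_factor: float = 0.9999
    init_regularization: float = 100.0

    def __post_init__(self) -> None:
        if self.taps_per_reference < 1:
            raise ValueError("taps_per_reference must be >= 1")
        if not 0.0 < self.forgetting_factor <= 1.0:
            raise ValueError("forgetting_factor must lie in (0, 1]")
        if self.init_regularization <= 0:
            raise ValueError("init_regularization must be > 0")


def rls_ocular_removal(
    eeg: np.ndarray,
    veog: np.ndarray,
    heog: np.ndarray,
    config: AdaptiveFilterConfig | None = None,
) -> np.ndarray:
    """Return the EEG channel with the reference-correlated component removed.

    All three inputs are 1-D uV series of equal length; the output has the
    same length. Sample t uses reference samples up to and including t only.
    """
    if config is None:
        config = AdaptiveFilterConfig()
    eeg = np.asarray(eeg, dtype=float)
    veog = np.asarray(veog, dtype=float)
    heog = np.asarray(heog, dtype=float)
    if not (eeg.shape == veog.shape == heog.shape) or eeg.ndim != 1:
        raise ValueError("eeg, veog, heog must be 1-D arrays of equal length")
    if not (np.isfinite(eeg).all() and np.isfinite(veog).all() and np.isfinite(heog).all()):
        raise ValueError("inputs must be finite")
    m = config.taps_per_reference
    if len(eeg) < m:
        raise ValueError("inputs shorter than the filter order")

    lam = config.forgetting_factor
    n_w = 2 * m
    w = np.zeros(n_w)
    p = config.init_regularization * np.eye(n_w)
    out = np.empty_like(eeg)
    u = np.zeros(n_w)

    for t in range(len(eeg)):
        lo = max(0, t - m + 1)
        u[:] = 0.0
        seg_v = veog[lo : t + 1][::-1]
        seg_h = heog[lo : t + 1][::-1]
        u[: len(seg_v)] = seg_v
        u[m : m + len(seg_h)] = seg_h
        y = w @ u
        e = eeg[t] - y
        out[t] = e
        pu = p @ u
        denom = lam + u @ pu
        k = pu / denom
        w += k * e
        p = (p - np.outer(k, pu)) / lam

    return out


def correct_eeg_block(
    eeg_block: np.ndarray,
    veog: np.ndarray,
    heog: np.ndarray,
    config: AdaptiveFilterConfig | None = None,
) -> np.ndarray:
    """Apply rls_ocular_removal to each row of a channels x time EEG block.

    Filter state is independent per channel; callers reset state at trial
    boundaries by invoking this per trial.
    """
    return np.stack([rls_ocular_removal(row, veog, heog, config) for row in eeg_block])
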