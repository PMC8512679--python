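"""Time-series preprocessing used throughout the gait pipeline.

The recipes mirror common gait-lab practice: marker and force-plate
channels are smoothed with a zero-lag (forward-backward) second-order
Butterworth low-pass at 8 Hz; surface EMG is high-pass filtered at
30 Hz, full-wave rectified and low-pass filtered at 6 Hz with zero-lag
fourth-order Butterworth filters to obtain the linear envelope, which
is then normalised to each subject's global peak; derivatives are
taken frame by frame; and every stance-phase series is resampled to
100 samples between heel strike (0%) and toe-off (100%).

"Second-order"/"fourth-order" refer to the one-pass filter design;
zero-lag application runs it forward and backward, doubling the
effective order (a 2nd-order zero-lag low-pass attenuates ~6 dB at
its cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

__all__ = [
    "FilterSpec",
    "butterworth_zero_lag",
    "process_emg",
    "normalise_emg",
    "differentiate",
    "resample_stance",
    "MARKER_FILTER",
    "EMG_HIGHPASS",
    "EMG_LOWPASS",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter specification.

    ``order`` is the order of the one-pass design; with ``zero_lag``
    the filter is applied forward and backward, giving zero phase
    shift and squared magnitude response.
    """

    kind: str  # "lowpass" | "highpass"
    order: int
    cutoff: float  # Hz
    zero_lag: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


#: 8 Hz zero-lag second-order low-pass for markers and force-plate channels.
MARKER_FILTER = FilterSpec("lowpass", 2, 8.0)
#: EMG envelope chain: 30 Hz high-pass then 6 Hz low-pass, both 4th order zero-lag.
EMG_HIGHPASS = FilterSpec("highpass", 4, 30.0)
EMG_LOWPASS = FilterSpec("lowpass", 4, 6.0)


def butterworth_zero_lag(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Apply a Butterworth filter with optional zero-lag (filtfilt) scheme.

    Edge transients are suppressed with reflective padding of length
    3 x filter order.
    """
    x = np.asarray(x, dtype=float)
    if spec.cutoff >= fs / 2:
        raise ValueError(
            f"cutoff {spec.cutoff} Hz is not below Nyquist {fs / 2} Hz (fs={fs} Hz)"
        )
    btype = "low" if spec.kind == "lowpass" else "high"
    b, a = _sig.butter(spec.order, spec.cutoff / (fs / 2), btype=btype)
    padlen = 3 * spec.order
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"series of length {x.shape[-1]} too short for edge padding ({padlen})"
        )
    if spec.zero_lag:
        return _sig.filtfilt(b, a, x, axis=-1, padtype="even", padlen=padlen)
    return _sig.lfilter(b, a, x, axis=-1)


def process_emg(raw: np.ndarray, fs: float) -> np.ndarray:
    """Raw EMG -> linear envelope (30 Hz HP, rectify, 6 Hz LP; zero-lag 4th order).

    The output is non-negative and the same length as the input; peak
    normalisation is a separate, subject-level step (:func:`normalise_emg`).
    """
    if fs <= 60:
        raise ValueError(f"fs={fs} Hz too low for a 30 Hz high-pass (need fs > 60)")
    hp = butterworth_zero_lag(raw, fs, EMG_HIGHPASS)
    rect = np.abs(hp)
    env = butterworth_zero_lag(rect, fs, EMG_LOWPASS)
    # the zero-lag low-pass can undershoot slightly near sharp transients
    return np.clip(env, 0.0, None)


def normalise_emg(envelopes: list[np.ndarray]) -> tuple[list[np.ndarray], np.ndarray]:
    """Normalise per-channel envelopes to the subject-global peak.

    Parameters
    ----------
    envelopes
        One ``(n_channels, n_samples)`` array per trial of a single
        subject.  The peak is taken per channel over *all* trials, so
        a channel's maximum over the subject's data set equals 1.

    Returns
    -------
    normalised trials (same shapes) and the per-channel peaks used.
    """
    if not envelopes:
        raise ValueError("no envelopes given")
    arrs = [np.atleast_2d(np.asarray(e, dtype=float)) for e in envelopes]
    n_ch = arrs[0].shape[0]
    for a in arrs:
        if a.shape[0] != n_ch:
            raise ValueError("inconsistent channel counts across trials")
    peaks = np.max([a.max(axis=1) for a in arrs], axis=0)
    dead = np.flatnonzero(peaks <= 0)
    if dead.size:
        raise ValueError(f"all-zero EMG channel(s) at index {dead.tolist()}")
    return [a / peaks[:, None] for a in arrs], peaks


def differentiate(x: np.ndarray, fs: float) -> np.ndarray:
    """Frame-by-frame derivative: central differences inside, one-sided at ends."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(x, 1.0 / fs, axis=-1, edge_order=1)


def resample_stance(x: np.ndarray, n_out: int = 100) -> np.ndarray:
    """Resample a stance-phase series to ``n_out`` samples by linear interpolation.

    0% and 100% of the output phase grid coincide with the first and
    last input samples (heel strike and toe-off), which are preserved
    exactly.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 samples to resample a stance phase")
    phase_in = np.linspace(0.0, 1.0, n)
    phase_out = np.linspace(0.0, 1.0, n_out)
    if x.ndim == 1:
        return np.interp(phase_out, phase_in, x)
    return np.stack([np.interp(phase_out, phase_in, row) for row in x])
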