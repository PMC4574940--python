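"""Signal conditioning: FIR band-pass, resampling, baselining, trial
averaging, and Morlet time-frequency decomposition.

Connectivity in a frequency band (e.g. low gamma, 30-45 Hz) is computed on
band-passed data, so the filter here is zero-phase by default: phase-based
coupling estimates must not inherit a filter group delay. The band-pass is
a windowed-sinc (Hamming) FIR applied forward-backward; a causal
forward-only variant (with group-delay compensation) is available via
``causal=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .data_io import Recording
from .errors import ParameterError, ShapeError

__all__ = [
    "fir_bandpass", "resample", "set_baseline", "average_trials",
    "morlet_tfr", "TimeFreqMap", "design_bandpass",
]


def design_bandpass(
    sfreq: float, f_lo: float, f_hi: float, order: int | None = None
) -> np.ndarray:
    """Hamming-window FIR band-pass taps.

    Default length from the Harris rule-of-thumb ``3.3 / normalized
    transition width``; the transition width is 25% of the lower band edge
    (the narrower of the two transitions), rounded up to an odd tap count.
    """
    nyq = sfreq / 2.0
    if not 0 < f_lo < f_hi < nyq:
        raise ParameterError(
            f"band ({f_lo}, {f_hi}) Hz must satisfy 0 < lo < hi < "
            f"Nyquist ({nyq} Hz)"
        )
    if order is None:
        trans = 0.25 * min(f_lo, nyq - f_hi)
        order = int(np.ceil(3.3 * sfreq / trans))
    if order < 3:
        raise ParameterError("filter order must be >= 3")
    numtaps = order + 1 if order % 2 == 0 else order
    return signal.firwin(
        numtaps, [f_lo, f_hi], fs=sfreq, pass_zero=False, window="hamming"
    )


def fir_bandpass(
    rec: Recording,
    f_lo: float,
    f_hi: float,
    order: int | None = None,
    causal: bool = False,
) -> Recording:
    """Band-pass every channel/trial with a linear-phase FIR filter.

    Zero-phase (forward-backward, squared magnitude response) unless
    ``causal=True``, in which case the filter runs forward once and the
    output is shifted by the group delay.
    """
    taps = design_bandpass(rec.sfreq, f_lo, f_hi, order=order)
    if rec.n_samples < 3 * len(taps):
        raise ParameterError(
            f"signal of {rec.n_samples} samples is too short for a "
            f"{len(taps)}-tap filter (need >= {3 * len(taps)})"
        )
    if causal:
        out = signal.lfilter(taps, 1.0, rec.data, axis=1)
        delay = (len(taps) - 1) // 2
        out = np.roll(out, -delay, axis=1)
        out[:, -delay:, :] = 0.0
    else:
        out = signal.filtfilt(taps, 1.0, rec.data, axis=1)
    return rec.with_data(out)


def resample(rec: Recording, new_sfreq: float) -> Recording:
    """Change the sampling rate with polyphase anti-aliased resampling."""
    if new_sfreq <= 0:
        raise ParameterError("new_sfreq must be > 0")
    frac = Fraction(new_sfreq / rec.sfreq).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    new_ns = int(np.ceil(rec.n_samples * up / down))
    if new_ns < 2:
        raise ParameterError(
            f"resampling to {new_sfreq} Hz leaves {new_ns} sample(s)"
        )
    out = signal.resample_poly(rec.data, up, down, axis=1)
    changes: dict = {"sfreq": rec.sfreq * up / down}
    if rec.onset_index is not None:
        changes["onset_index"] = min(
            int(round(rec.onset_index * up / down)), out.shape[1] - 1
        )
    if rec.baseline_span is not None:
        s, e = rec.baseline_span
        changes["baseline_span"] = (
            int(round(s * up / down)),
            max(int(round(e * up / down)), int(round(s * up / down)) + 1),
        )
    return rec.with_data(out, **changes)


def set_baseline(rec: Recording, start: int, end: int) -> Recording:
    """Mark ``[start, end)`` as the pre-stimulus baseline and subtract the
    per-channel baseline mean from every trial.

    The recorded span is what the noise-covariance estimator uses.
    """
    start, end = int(start), int(end)
    if not (0 <= start < end <= rec.n_samples):
        raise ParameterError(
            f"baseline span ({start}, {end}) outside [0, {rec.n_samples}]"
        )
    mean = rec.data[:, start:end, :].mean(axis=1, keepdims=True)
    return rec.with_data(rec.data - mean, baseline_span=(start, end))


def average_trials(rec: Recording) -> Recording:
    """Arithmetic mean across trials; the result has a single trial."""
    return rec.with_data(rec.data.mean(axis=2, keepdims=True))


@dataclass
class TimeFreqMap:
    """Complex Morlet coefficients, shape (Nc, Nf, Ns, Nt).

    ``power`` is |coeff|^2. Frequencies are strictly increasing and below
    Nyquist; ``n_cycles`` is the per-frequency cycle count of the Gaussian
    envelope.
    """

    coeffs: np.ndarray
    freqs: np.ndarray
    n_cycles: np.ndarray
    sfreq: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=complex)
        if self.coeffs.ndim != 4:
            raise ShapeError("coeffs must be (Nc, Nf, Ns, Nt)")
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.size < 1:
            raise ParameterError("need at least one frequency")
        if not (np.diff(self.freqs) > 0).all():
            raise ParameterError("freqs must be strictly increasing")
        if self.freqs[-1] >= self.sfreq / 2 or self.freqs[0] <= 0:
            raise ParameterError("freqs must lie in (0, Nyquist)")
        self.n_cycles = np.broadcast_to(
            np.asarray(self.n_cycles, dtype=float), self.freqs.shape
        ).copy()

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coeffs) ** 2


def _morlet_wavelet(sfreq: float, freq: float, n_cycles: float) -> np.ndarray:
    """L2-normalized complex Morlet: Gaussian-windowed complex exponential
    with sigma_t = n_cycles / (2 pi f), truncated at 5 sigma."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t ** 2) / (2 * sigma_t ** 2))
    w -= w.mean()  # zero-mean so a DC offset contributes no power
    return w / np.sqrt(0.5) / np.linalg.norm(w)


def morlet_tfr(
    rec: Recording, freqs, n_cycles: float | np.ndarray = 7.0
) -> TimeFreqMap:
    """Morlet wavelet transform of every channel and trial.

    Same-length complex convolution per frequency; the default seven-cycle
    wavelet trades time against frequency resolution symmetrically across
    the band. Raises if the longest wavelet exceeds the signal.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    cycles = np.broadcast_to(np.asarray(n_cycles, dtype=float), freqs.shape)
    if (cycles <= 0).any():
        raise ParameterError("n_cycles must be > 0")
    if freqs.min(initial=np.inf) <= 0 or freqs.max(initial=0) >= rec.sfreq / 2:
        raise ParameterError("freqs must lie in (0, Nyquist)")
    wavelets = [
        _morlet_wavelet(rec.sfreq, f, c) for f, c in zip(freqs, cycles)
    ]
    longest = max(len(w) for w in wavelets)
    if longest > rec.n_samples:
        raise ParameterError(
            f"wavelet of {longest} samples exceeds signal length "
            f"{rec.n_samples}; reduce n_cycles or the lowest frequency"
        )
    nc, ns, nt = rec.data.shape
    out = np.empty((nc, len(freqs), ns, nt), dtype=complex)
    for fi, w in enumerate(wavelets):
        for ti in range(nt):
            for ci in range(nc):
                out[ci, fi, :, ti] = np.convolve(
                    rec.data[ci, :, ti], w, mode="same"
                )
    return TimeFreqMap(
        out, freqs=freqs, n_cycles=cycles, sfreq=rec.sfreq,
        channel_labels=list(rec.channel_labels),
    )
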