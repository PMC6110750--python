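"""Complex Morlet decomposition and non-phase-locked (induced) power.

The speaker's preparatory spectral response is measured by convolving each
epoch with complex Morlet wavelets, psi(u) = (pi*fb)^(-1/2) *
exp(2*pi*i*fc*u) * exp(-u^2 / fb), at scales a = fc * fs / f for target
frequencies 2, 6, 8, 12, 20 and 40 Hz (fb = 0.5, fc = 1).  Power is the
variance of the complex coefficients *across trials*: subtracting the
across-trial mean removes every phase-locked (evoked) contribution, so what
remains is induced activity such as the preparatory alpha burst, whose phase
varies from trial to trial.  Complex variance is the mean squared absolute
deviation (a real, nonnegative number); taking its absolute value afterwards
is a documented no-op safeguard.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from .containers import EpochSet

log = logging.getLogger(__name__)

DEFAULT_FREQUENCIES = (2.0, 6.0, 8.0, 12.0, 20.0, 40.0)


@dataclass
class WaveletSpec:
    """Complex Morlet analysis parameters.

    ``scale = fc * fs / f`` maps a target frequency to a wavelet scale; this
    is the documented convention of the classic MATLAB ``cwt``/``cmor``
    wavelet family (and of PyWavelets' ``cmorB-C``).
    """

    center_frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    bandwidth_fb: float = 0.5
    center_freq_fc: float = 1.0

    def __post_init__(self) -> None:
        if self.bandwidth_fb <= 0:
            raise ValueError("fb must be positive")
        if any(f <= 0 for f in self.center_frequencies):
            raise ValueError("frequencies must be positive")

    def scale(self, f: float, sfreq: float) -> float:
        return self.center_freq_fc * sfreq / f

    def efold_s(self, f: float) -> float:
        """Temporal e-folding half-width of the envelope, in seconds."""
        return self.center_freq_fc * math.sqrt(self.bandwidth_fb) / f

    def kernel(self, f: float, sfreq: float) -> np.ndarray:
        """Sampled analytic Morlet at scale fc*fs/f, L1 gain ~ 1/sqrt(a)."""
        if f >= sfreq / 2:
            raise ValueError(f"{f} Hz is at or above Nyquist ({sfreq / 2} Hz)")
        a = self.scale(f, sfreq)
        half = int(math.ceil(4.0 * math.sqrt(self.bandwidth_fb) * a))
        u = np.arange(-half, half + 1) / a
        psi = ((np.pi * self.bandwidth_fb) ** -0.5 *
               np.exp(2j * np.pi * self.center_freq_fc * u) *
               np.exp(-u**2 / self.bandwidth_fb))
        return psi / math.sqrt(a)


@dataclass
class WaveletCube:
    """Complex coefficients: trials x channels x samples x frequencies."""

    coeffs: np.ndarray
    freqs: tuple[float, ...]
    sfreq: float
    channels: list[str]
    conditions: np.ndarray
    keep_mask: np.ndarray
    window_ms: tuple[float, float]
    coi_valid: np.ndarray = None       # (samples, freqs) bool, True = interior
    meta: dict = field(default_factory=dict)

    @property
    def times_ms(self) -> np.ndarray:
        step = 1000.0 / self.sfreq
        return self.window_ms[0] + step * np.arange(self.coeffs.shape[2])

    def channel_indices(self, names) -> np.ndarray:
        missing = [ch for ch in names if ch not in self.channels]
        if missing:
            raise KeyError(f"channel(s) not in cube: {missing}")
        return np.array([self.channels.index(ch) for ch in names])

    def freq_index(self, f: float) -> int:
        try:
            return self.freqs.index(f) if isinstance(self.freqs, list) \
                else list(self.freqs).index(f)
        except ValueError:
            raise KeyError(f"frequency {f} Hz not in cube") from None


@dataclass
class PowerTimecourse:
    """Non-phase-locked power, channels x samples x frequencies (or averaged).

    After :func:`average_over_electrodes` the channel axis is collapsed and
    ``electrode_set`` records which channels entered the mean.
    """

    power: np.ndarray
    freqs: tuple[float, ...]
    sfreq: float
    window_ms: tuple[float, float]
    condition: str | None = None
    channels: list[str] | None = None          # present while channel axis is
    electrode_set: tuple[str, ...] | None = None
    n_trials: int = 0
    coi_valid: np.ndarray = None

    @property
    def times_ms(self) -> np.ndarray:
        step = 1000.0 / self.sfreq
        n = self.power.shape[-2]
        return self.window_ms[0] + step * np.arange(n)

    def freq_index(self, f: float) -> int:
        try:
            return list(self.freqs).index(f)
        except ValueError:
            raise KeyError(f"frequency {f} Hz not available") from None


@dataclass
class PeakDef:
    """A peak sample chosen from condition-collapsed grand-average data."""

    peak_sample: int
    peak_time_ms: float
    frequency: float | None = None
    selection_window_ms: tuple[float, float] = (0.0, 1000.0)

    def __post_init__(self) -> None:
        lo, hi = self.selection_window_ms
        if not (lo <= self.peak_time_ms < hi):
            raise ValueError("peak lies outside its selection window")


# ---------------------------------------------------------------------------

def morlet_transform(ep: EpochSet, spec: WaveletSpec | None = None
                     ) -> WaveletCube:
    """FFT-based continuous wavelet transform of every epoch.

    Edge samples inside one e-folding width of either epoch boundary are
    flagged (cone of influence) but retained.
    """
    spec = spec or WaveletSpec()
    fs = ep.sfreq
    n_s = ep.n_samples
    lowest = min(spec.center_frequencies)
    if n_s / fs < 3.0 * spec.efold_s(lowest):
        raise ValueError("epoch shorter than 3 wavelet e-folding widths at "
                         f"{lowest} Hz")
    n_tr, n_ch = ep.data.shape[:2]
    coeffs = np.empty((n_tr, n_ch, n_s, len(spec.center_frequencies)),
                      dtype=complex)
    coi = np.ones((n_s, len(spec.center_frequencies)), dtype=bool)
    flat = ep.data.reshape(n_tr * n_ch, n_s)
    for j, f in enumerate(spec.center_frequencies):
        k = spec.kernel(f, fs)
        conv = fftconvolve(flat, k[None, :], mode="same", axes=1)
        coeffs[..., j] = conv.reshape(n_tr, n_ch, n_s)
        edge = int(math.ceil(spec.efold_s(f) * fs))
        coi[:edge, j] = False
        if edge > 0:
            coi[-edge:, j] = False
    return WaveletCube(coeffs, tuple(spec.center_frequencies), fs,
                       list(ep.channels), ep.conditions.copy(),
                       ep.keep_mask.copy(), ep.window_ms, coi_valid=coi,
                       meta=dict(ep.meta))


def morlet_transform_direct(ep: EpochSet, spec: WaveletSpec | None = None
                            ) -> WaveletCube:
    """Brute-force time-domain convolution; oracle for the FFT path."""
    spec = spec or WaveletSpec()
    out = morlet_transform(ep, spec)     # reuse shapes/COI
    n_tr, n_ch, n_s, _ = out.coeffs.shape
    for j, f in enumerate(spec.center_frequencies):
        k = spec.kernel(f, ep.sfreq)
        half = (k.size - 1) // 2
        for tr in range(n_tr):
            for ch in range(n_ch):
                full = np.convolve(ep.data[tr, ch], k, mode="full")
                out.coeffs[tr, ch, :, j] = full[half:half + n_s]
    return out


def nonphaselocked_power(cube: WaveletCube, condition: str | None = None
                         ) -> PowerTimecourse:
    """Across-trial complex variance (ddof=1) per channel/sample/frequency.

    Subtracting the across-trial mean removes the phase-locked response; the
    result is real and nonnegative, so the subsequent absolute value is the
    identity (kept as a safeguard).
    """
    sel = cube.keep_mask.copy()
    if condition is not None:
        sel &= cube.conditions == condition
    n = int(sel.sum())
    if n < 2:
        raise ValueError(f"need >= 2 kept trials (have {n}) for condition "
                         f"{condition!r}")
    var = np.abs(np.var(cube.coeffs[sel], axis=0, ddof=1))
    return PowerTimecourse(var, cube.freqs, cube.sfreq, cube.window_ms,
                           condition=condition, channels=list(cube.channels),
                           n_trials=n, coi_valid=cube.coi_valid)


def average_over_electrodes(tc: PowerTimecourse, electrodes) -> PowerTimecourse:
    """Unweighted mean over the listed channels; the set is recorded."""
    if tc.channels is None:
        raise ValueError("power timecourse already electrode-averaged")
    missing = [ch for ch in electrodes if ch not in tc.channels]
    if missing:
        raise KeyError(f"electrode(s) not present: {missing}")
    idx = [tc.channels.index(ch) for ch in electrodes]
    return replace(tc, power=tc.power[idx].mean(axis=0), channels=None,
                   electrode_set=tuple(electrodes))


def grand_average_power(timecourses: list[PowerTimecourse]) -> PowerTimecourse:
    """Mean over subjects/conditions of electrode-averaged power."""
    if not timecourses:
        raise ValueError("no timecourses to average")
    stack = np.stack([tc.power for tc in timecourses])
    first = timecourses[0]
    return replace(first, power=stack.mean(axis=0), condition=None,
                   n_trials=sum(tc.n_trials for tc in timecourses))


def find_peak_time(grand: PowerTimecourse, frequency: float,
                   window_ms: tuple[float, float] = (0.0, 1000.0),
                   exclude_coi: bool = True) -> PeakDef:
    """Sample of maximum grand-average power at `frequency` in `window_ms`.

    Ties break to the earliest sample; cone-of-influence edges are excluded
    from the search by default.
    """
    if grand.channels is not None:
        raise ValueError("collapse electrodes before peak search")
    j = grand.freq_index(frequency)
    t = grand.times_ms
    sel = (t >= window_ms[0]) & (t < window_ms[1])
    if exclude_coi and grand.coi_valid is not None:
        sel &= grand.coi_valid[:, j]
    if not sel.any():
        raise ValueError("empty peak-search window")
    trace = grand.power[:, j]
    candidates = np.flatnonzero(sel)
    if np.ptp(trace[candidates]) == 0:
        log.warning("flat power trace; returning earliest window sample")
    peak = int(candidates[np.argmax(trace[candidates])])
    return PeakDef(peak, float(t[peak]), frequency=frequency,
                   selection_window_ms=window_ms)


def subject_peak_power(tc_by_condition: dict[str, PowerTimecourse],
                       peak: PeakDef) -> dict[str, float]:
    """Power at the (condition-collapsed) peak sample, per condition."""
    out = {}
    for cond, tc in tc_by_condition.items():
        j = tc.freq_index(peak.frequency)
        out[cond] = float(tc.power[peak.peak_sample, j])
    return out


def percent_reduction(expected_mean: float, unexpected_mean: float) -> float:
    """100 * (expected - unexpected) / expected."""
    if expected_mean == 0:
        raise ZeroDivisionError("expected-condition mean is zero")
    return 100.0 * (expected_mean - unexpected_mean) / expected_mean
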