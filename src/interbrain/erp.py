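"""Listener event-related potentials and single-trial peak amplitudes.

ERPs are averaged over central-parietal electrodes; the negative (N400-range)
and positive (P600-range) peak samples are identified once, from the grand
average collapsed over subjects *and* conditions, so the choice of time point
cannot favour either condition.  Per-subject condition amplitudes and
per-trial amplitudes are then read at those fixed samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .containers import EpochSet
from .spectral import PeakDef

log = logging.getLogger(__name__)


@dataclass
class ErpTimecourse:
    """Mean amplitude per sample (uV) with a 95% CI half-width."""

    mean: np.ndarray                       # (n_samples,)
    ci95: np.ndarray                       # (n_samples,) half-width
    sfreq: float
    window_ms: tuple[float, float]
    electrode_set: tuple[str, ...]
    condition: str | None = None
    n_trials: int = 0

    @property
    def times_ms(self) -> np.ndarray:
        step = 1000.0 / self.sfreq
        return self.window_ms[0] + step * np.arange(self.mean.size)

    def sample_at(self, time_ms: float) -> int:
        lo, hi = self.window_ms
        if not (lo <= time_ms < hi):
            raise ValueError(f"{time_ms} ms outside window {self.window_ms}")
        return int(round((time_ms - lo) / 1000.0 * self.sfreq))


@dataclass
class ErpPeaks:
    """Negative and positive peak definitions from the collapsed average."""

    negative: PeakDef
    positive: PeakDef


def average_erp(ep: EpochSet, electrodes, condition: str | None = None
                ) -> ErpTimecourse:
    """Mean over kept trials (optionally one condition), then electrodes.

    The 95% band is the t-based CI of the across-trial mean of the
    electrode-averaged single-trial traces.
    """
    sel = ep.kept(condition)
    n = int(sel.sum())
    if n < 1:
        raise ValueError(f"no kept trials for condition {condition!r}")
    idx = ep.channel_indices(electrodes)
    traces = ep.data[sel][:, idx, :].mean(axis=1)       # trials x samples
    mean = traces.mean(axis=0)
    if n > 1:
        sem = traces.std(axis=0, ddof=1) / np.sqrt(n)
        ci = sem * stats.t.ppf(0.975, n - 1)
    else:
        ci = np.zeros_like(mean)
    return ErpTimecourse(mean, ci, ep.sfreq, ep.window_ms, tuple(electrodes),
                         condition=condition, n_trials=n)


def grand_average_erp(timecourses: list[ErpTimecourse]) -> ErpTimecourse:
    """Collapse subject/condition ERPs into one grand average."""
    if not timecourses:
        raise ValueError("nothing to average")
    stack = np.stack([tc.mean for tc in timecourses])
    first = timecourses[0]
    return replace(first, mean=stack.mean(axis=0),
                   ci95=np.zeros(stack.shape[1]), condition=None,
                   n_trials=sum(tc.n_trials for tc in timecourses))


def _window_extremum(trace: np.ndarray, times: np.ndarray,
                     window_ms: tuple[float, float], mode: str) -> int:
    sel = (times >= window_ms[0]) & (times < window_ms[1])
    if not sel.any():
        raise ValueError(f"search window {window_ms} outside the epoch")
    cand = np.flatnonzero(sel)
    seg = trace[cand]
    if np.ptp(seg) == 0:
        log.warning("flat ERP trace in %s; returning earliest sample", window_ms)
    pick = np.argmin(seg) if mode == "min" else np.argmax(seg)
    return int(cand[pick])


def find_erp_peaks(grand: ErpTimecourse,
                   negative_window_ms: tuple[float, float] = (150.0, 500.0),
                   positive_window_ms: tuple[float, float] = (450.0, 900.0)
                   ) -> ErpPeaks:
    """Negative (minimum) and positive (maximum) peaks of the grand average.

    Ties break to the earliest sample (np.argmin/argmax convention).
    """
    t = grand.times_ms
    ni = _window_extremum(grand.mean, t, negative_window_ms, "min")
    pi = _window_extremum(grand.mean, t, positive_window_ms, "max")
    return ErpPeaks(
        negative=PeakDef(ni, float(t[ni]),
                         selection_window_ms=negative_window_ms),
        positive=PeakDef(pi, float(t[pi]),
                         selection_window_ms=positive_window_ms))


def subject_peak_amplitude(tc_by_condition: dict[str, ErpTimecourse],
                           peaks: ErpPeaks) -> dict[str, tuple[float, float]]:
    """(negative, positive) peak-sample amplitude per condition, uV."""
    out = {}
    for cond, tc in tc_by_condition.items():
        out[cond] = (float(tc.mean[peaks.negative.peak_sample]),
                     float(tc.mean[peaks.positive.peak_sample]))
    return out


def single_trial_amplitude(ep: EpochSet, electrodes, peak: PeakDef,
                           half_window_ms: float = 0.0) -> np.ndarray:
    """Per-trial electrode-mean amplitude at the peak sample.

    Returns one value per trial (NaN for unkept trials, preserving indices
    for speaker/listener pairing).  ``half_window_ms > 0`` averages a small
    symmetric window around the peak instead of the single sample (off by
    default: the peak-sample reading is the primary definition).
    """
    idx = ep.channel_indices(electrodes)
    s = peak.peak_sample
    if not 0 <= s < ep.n_samples:
        raise ValueError("peak sample outside the epoch")
    if half_window_ms > 0:
        h = int(round(half_window_ms / 1000.0 * ep.sfreq))
        lo, hi = max(s - h, 0), min(s + h + 1, ep.n_samples)
        vals = ep.data[:, idx, lo:hi].mean(axis=(1, 2))
    else:
        vals = ep.data[:, idx, s].mean(axis=1)
    vals = vals.astype(float)
    vals[~ep.keep_mask] = np.nan
    return vals
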