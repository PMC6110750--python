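"""Cleaning of continuous recordings and synchronized epoch extraction.

The stage order mirrors standard mobile-EEG practice for this task: blink
attenuation on the individual continuous record (ICA with an automated
frontal/low-frequency component criterion, or a regression fallback), linear
detrend and re-reference to the mastoid average, bad-channel detection
(robust variance and kurtosis z-scores) with spherical-spline interpolation,
event-locked epoching on [-200, 1000) ms, automatic artifact-epoch rejection,
and finally synchronization of the rejections across the two members of a
dyad (an epoch dropped for the speaker is dropped for the listener and vice
versa).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.special import eval_legendre

from .containers import EPOCH_WINDOW_MS, EpochSet, EventTable, Recording
from . import montage

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Thresholds for every preprocessing stage (all configurable)."""

    mastoids: tuple[str, str] = montage.MASTOIDS
    # bad-channel detection (robust z of log-variance; z of kurtosis)
    z_var: float = 3.0
    z_kurt: float = 5.0
    # spherical spline interpolation
    spline_order_m: int = 4
    spline_n_terms: int = 50
    spline_reg: float = 1e-5
    # blink removal
    blink_method: str = "ica"          # "ica" | "template_regression"
    ica_seed: int = 0
    ica_subsample: int = 10            # fit ICA on every k-th sample
    ica_n_components: int = 6          # PCA subspace for the decomposition
    frontal_weight_ratio: float = 2.0  # frontal vs rest mixing-weight ratio
    lowfreq_power_frac: float = 0.55   # fraction of source power below 5 Hz
    # epoch rejection
    amp_threshold: float = 1000.0      # uV, absolute rejection
    z_epoch: float = 5.0
    frac_per_iter: float = 0.05
    # ERP baseline
    baseline_ms: tuple[float, float] | None = (-200.0, 0.0)

    log_prefix: str = ""


# ---------------------------------------------------------------------------

def detrend_and_rereference(rec: Recording,
                            mastoids: tuple[str, str] = montage.MASTOIDS
                            ) -> Recording:
    """Linearly detrend each channel, then subtract the mastoid average."""
    for m in mastoids:
        if m not in rec.channels:
            raise KeyError(f"mastoid channel {m!r} missing from recording")
    out = rec.copy()
    out.data = signal.detrend(out.data, axis=1, type="linear")
    idx = [out.index_of(m) for m in mastoids]
    reference = out.data[idx].mean(axis=0)
    out.data -= reference
    return out


def detect_bad_channels(rec: Recording, z_var: float = 3.0,
                        z_kurt: float = 5.0,
                        exclude: tuple[str, ...] = montage.MASTOIDS
                        ) -> list[str]:
    """Channels whose log-variance (robust z) or kurtosis (z) is an outlier.

    Robust z uses median/MAD so a handful of wild channels cannot mask each
    other.  Reference (mastoid) channels are excluded from screening.
    """
    names = [ch for ch in rec.channels if ch not in exclude]
    x = rec.data[[rec.index_of(ch) for ch in names]]

    logvar = np.log(np.maximum(x.var(axis=1), np.finfo(float).tiny))
    med = np.median(logvar)
    mad = np.median(np.abs(logvar - med))
    scale = 1.4826 * mad if mad > 0 else max(logvar.std(), np.finfo(float).eps)
    zv = (logvar - med) / scale

    centred = x - x.mean(axis=1, keepdims=True)
    sd = centred.std(axis=1)
    sd[sd == 0] = np.finfo(float).eps
    kurt = (centred**4).mean(axis=1) / sd**4 - 3.0
    ks = kurt.std()
    zk = (kurt - kurt.mean()) / (ks if ks > 0 else np.finfo(float).eps)

    flagged = [ch for ch, a, b in zip(names, zv, zk)
               if abs(a) > z_var or abs(b) > z_kurt]
    if len(rec.channels) - len(flagged) < 4:
        raise ValueError("fewer than 4 good channels would remain")
    if len(flagged) > len(rec.channels) / 3:
        log.warning("more than a third of channels flagged bad (%d of %d)",
                    len(flagged), len(rec.channels))
    return flagged


def _spline_g(cosang: np.ndarray, m: int, n_terms: int) -> np.ndarray:
    """Perrin g(cos angle): sum (2n+1) / (n(n+1))^m P_n(cos angle) / 4 pi."""
    out = np.zeros_like(cosang, dtype=float)
    for n in range(1, n_terms + 1):
        out += ((2 * n + 1) / (n * (n + 1)) ** m) * eval_legendre(n, cosang)
    return out / (4.0 * np.pi)


def interpolate_spherical(rec: Recording, bad: list[str],
                          m: int = 4, n_terms: int = 50,
                          reg: float = 1e-5) -> Recording:
    """Replace bad channels with spherical-spline estimates (Perrin 1989 form).

    Good channels are untouched bit-for-bit; an empty bad list is the
    identity.  Positions come from the montage's unit sphere.
    """
    if not bad:
        return rec.copy()
    missing = [ch for ch in bad if ch not in rec.channels]
    if missing:
        raise KeyError(f"bad channel(s) not in recording: {missing}")
    good = [ch for ch in rec.channels if ch not in bad]
    if len(good) < 4:
        raise ValueError("need at least 4 good channels to interpolate")
    pos_good = montage.positions_for(good)
    pos_bad = montage.positions_for(bad)

    G = _spline_g(np.clip(pos_good @ pos_good.T, -1.0, 1.0), m, n_terms)
    G = G + reg * np.eye(len(good))
    Gi = _spline_g(np.clip(pos_bad @ pos_good.T, -1.0, 1.0), m, n_terms)

    # Solve [G 1; 1' 0] [w; c] = [v; 0] per time point, vectorized over time.
    n = len(good)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    V = rec.data[[rec.index_of(ch) for ch in good]]
    rhs = np.vstack([V, np.zeros((1, V.shape[1]))])
    sol = np.linalg.solve(A, rhs)
    W, c = sol[:n], sol[n]
    est = Gi @ W + c           # (n_bad, n_samples)

    out = rec.copy()
    for k, ch in enumerate(bad):
        out.data[out.index_of(ch)] = est[k]
    out.meta = dict(out.meta, interpolated=list(bad))
    return out


# ---------------------------------------------------------------------------
# blink removal

def _frontal_weight_ratio(column: np.ndarray, channels: list[str]) -> float:
    frontal = [i for i, ch in enumerate(channels) if ch in ("Fp1", "Fp2")]
    rest = [i for i in range(len(channels)) if i not in frontal]
    num = np.abs(column[frontal]).mean()
    den = np.abs(column[rest]).mean()
    return float(num / den) if den > 0 else np.inf


def _lowfreq_fraction(source: np.ndarray, sfreq: float,
                      cutoff: float = 5.0) -> float:
    f, p = signal.welch(source, fs=sfreq, nperseg=min(4096, source.size))
    total = p.sum()
    return float(p[f < cutoff].sum() / total) if total > 0 else 0.0


def _blink_reference(rec: Recording) -> np.ndarray:
    """Low-pass-filtered frontal average as a blink regressor."""
    idx = [rec.index_of(ch) for ch in ("Fp1", "Fp2") if ch in rec.channels]
    if not idx:
        raise KeyError("no frontal (Fp1/Fp2) channel for blink template")
    ref = rec.data[idx].mean(axis=0)
    sos = signal.butter(4, 8.0, btype="low", fs=rec.sfreq, output="sos")
    return signal.sosfiltfilt(sos, ref)


def remove_blink_component(rec: Recording,
                           method: str = "ica",
                           config: PreprocessConfig | None = None
                           ) -> tuple[Recording, int]:
    """Attenuate blinks; returns the cleaned record and a component count.

    ``ica``: FastICA on the (temporally subsampled) record; components whose
    mixing weights are frontal-dominant *and* whose source power is mostly
    below 5 Hz are zeroed before back-reconstruction.  Non-convergence falls
    back to ``template_regression``, which subtracts the least-squares
    projection of each channel onto a low-passed frontal blink reference.
    """
    config = config or PreprocessConfig()
    if method == "template_regression":
        ref = _blink_reference(rec)
        ref = ref - ref.mean()
        denom = ref @ ref
        out = rec.copy()
        if denom > 0:
            beta = (out.data - out.data.mean(axis=1, keepdims=True)) @ ref / denom
            out.data -= np.outer(beta, ref)
        return out, 1

    if method != "ica":
        raise ValueError(f"unknown blink-removal method {method!r}")
    if rec.n_samples / rec.sfreq < 60.0:
        raise ValueError("record shorter than 60 s; use template_regression")

    from sklearn.decomposition import FastICA
    import warnings

    X = rec.data - rec.data.mean(axis=1, keepdims=True)
    sub = X[:, ::config.ica_subsample].T       # samples x channels
    # Small PCA subspace: blink/artifact sources carry most variance and are
    # the only strongly non-Gaussian directions, so a compact decomposition
    # converges where a full-rank one cannot.
    ica = FastICA(n_components=min(rec.n_channels, config.ica_n_components),
                  whiten="unit-variance",
                  random_state=config.ica_seed, max_iter=300, tol=1e-2)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            ica.fit(sub)
        except Exception:
            log.warning("ICA failed; falling back to template regression")
            return remove_blink_component(rec, "template_regression", config)
        if any("did not converge" in str(w.message) for w in caught):
            log.warning("ICA did not converge; falling back to "
                        "template regression")
            return remove_blink_component(rec, "template_regression", config)

    sources = ica.transform(X.T).T             # components x samples
    mixing = ica.mixing_                       # channels x components
    flagged = []
    for k in range(mixing.shape[1]):
        ratio = _frontal_weight_ratio(mixing[:, k], rec.channels)
        lf = _lowfreq_fraction(sources[k], rec.sfreq)
        if ratio >= config.frontal_weight_ratio and lf >= config.lowfreq_power_frac:
            flagged.append(k)

    out = rec.copy()
    if flagged:
        removed = mixing[:, flagged] @ sources[flagged]
        out.data = rec.data - removed
    out.meta = dict(out.meta, blink_components_removed=len(flagged))
    return out, len(flagged)


# ---------------------------------------------------------------------------
# epoching and rejection

def epoch(rec: Recording, events: EventTable, lock: str,
          window_ms: tuple[float, float] = EPOCH_WINDOW_MS,
          baseline_ms: tuple[float, float] | None = None) -> EpochSet:
    """Cut one epoch per trial around `lock` on the half-open window.

    Trials whose window leaves the record, or overlaps any invalid sample
    (lost packet), are kept in the cube but flagged ``keep_mask = False``.
    """
    fs = rec.sfreq
    lo = int(round(window_ms[0] / 1000.0 * fs))
    hi = int(round(window_ms[1] / 1000.0 * fs))      # exclusive
    n_s = hi - lo
    onsets = events.onsets(lock)
    n_tr = len(onsets)
    data = np.zeros((n_tr, rec.n_channels, n_s))
    keep = np.ones(n_tr, dtype=bool)
    for i, ev in enumerate(onsets):
        a, b = ev + lo, ev + hi
        if a < 0 or b > rec.n_samples:
            keep[i] = False
            log.warning("trial %d: window outside record, dropped", i)
            continue
        data[i] = rec.data[:, a:b]
        if not rec.validity_mask[a:b].all():
            keep[i] = False
    ep = EpochSet(data, fs, list(rec.channels), events.conditions, keep,
                  window_ms=window_ms, lock_event=lock,
                  baseline_ms=baseline_ms,
                  meta={"role": rec.role, "pair_id": rec.pair_id,
                        "block_id": rec.block_id, "subject_id": rec.subject_id})
    if baseline_ms is not None:
        ep = apply_baseline(ep, baseline_ms)
    return ep


def apply_baseline(ep: EpochSet,
                   baseline_ms: tuple[float, float] = (-200.0, 0.0)
                   ) -> EpochSet:
    """Subtract each epoch's mean over the baseline interval, per channel."""
    t = ep.times_ms
    sel = (t >= baseline_ms[0]) & (t < baseline_ms[1])
    if not sel.any():
        raise ValueError("baseline interval outside the epoch window")
    out = ep.copy()
    out.data -= out.data[:, :, sel].mean(axis=2, keepdims=True)
    out.baseline_ms = baseline_ms
    return out


def reject_artifact_epochs(ep: EpochSet, amp_threshold: float = 1000.0,
                           z_epoch: float = 5.0,
                           frac_per_iter: float = 0.05) -> EpochSet:
    """Automatic artifact-epoch rejection.

    Two criteria: (a) any sample exceeding `amp_threshold` uV in magnitude;
    (b) an iterative deviation rule -- per epoch, the maximum across channels
    of |z| of the epoch's peak-to-peak deviation relative to the surviving
    epochs; epochs exceeding `z_epoch` are rejected, at most `frac_per_iter`
    of the surviving count per iteration (worst first), and the z-scores are
    recomputed until no survivor exceeds the threshold.
    """
    if not ep.keep_mask.any():
        raise ValueError("no kept epochs to screen")
    out = ep.copy()
    keep = out.keep_mask

    amp_bad = np.abs(out.data).max(axis=(1, 2)) > amp_threshold
    keep &= ~amp_bad

    # per-epoch, per-channel peak-to-peak deviation
    ptp = out.data.max(axis=2) - out.data.min(axis=2)     # trials x channels
    while keep.sum() >= 2:
        mu = ptp[keep].mean(axis=0)
        sd = ptp[keep].std(axis=0, ddof=1)
        sd[sd == 0] = np.finfo(float).eps
        zmax = (np.abs(ptp - mu) / sd).max(axis=1)
        zmax[~keep] = 0.0
        offenders = np.flatnonzero(zmax > z_epoch)
        if offenders.size == 0:
            break
        n_drop = max(1, int(math.floor(frac_per_iter * keep.sum())))
        worst = offenders[np.argsort(zmax[offenders])[::-1][:n_drop]]
        keep[worst] = False

    if not keep.any():
        raise ValueError("all epochs rejected")
    out.keep_mask = keep
    return out


def synchronize_rejections(speaker_ep: EpochSet, listener_ep: EpochSet
                           ) -> tuple[EpochSet, EpochSet]:
    """Joint keep mask: a trial survives only if both members keep it."""
    if speaker_ep.n_trials != listener_ep.n_trials:
        raise ValueError("trial counts differ between members")
    joint = speaker_ep.keep_mask & listener_ep.keep_mask
    a, b = speaker_ep.copy(), listener_ep.copy()
    a.keep_mask = joint.copy()
    b.keep_mask = joint.copy()
    return a, b


# ---------------------------------------------------------------------------

@dataclass
class PreprocessReport:
    """Per-stage counts for one recording."""

    bad_channels: list[str] = field(default_factory=list)
    blink_components_removed: int = 0
    epochs_rejected: int = 0
    epochs_total: int = 0


def preprocess_recording(rec: Recording, events: EventTable, lock: str,
                         config: PreprocessConfig | None = None,
                         baseline: bool | None = None
                         ) -> tuple[EpochSet, PreprocessReport]:
    """Full single-recording chain: blinks -> detrend/re-ref -> bad channels
    -> interpolation -> epoching -> artifact rejection."""
    config = config or PreprocessConfig()
    report = PreprocessReport()

    cleaned, n_removed = remove_blink_component(rec, config.blink_method, config)
    report.blink_components_removed = n_removed

    cleaned = detrend_and_rereference(cleaned, config.mastoids)

    bad = detect_bad_channels(cleaned, config.z_var, config.z_kurt,
                              exclude=config.mastoids)
    report.bad_channels = bad
    cleaned = interpolate_spherical(cleaned, bad, config.spline_order_m,
                                    config.spline_n_terms, config.spline_reg)

    use_baseline = (baseline if baseline is not None
                    else (lock == "word" and config.baseline_ms is not None))
    ep = epoch(cleaned, events, lock,
               baseline_ms=config.baseline_ms if use_baseline else None)
    before = int(ep.keep_mask.sum())
    ep = reject_artifact_epochs(ep, config.amp_threshold, config.z_epoch,
                                config.frac_per_iter)
    report.epochs_total = ep.n_trials
    report.epochs_rejected = ep.n_trials - int(ep.keep_mask.sum())
    log.info("%s%s: %d bad channel(s), %d blink component(s), "
             "%d/%d epochs rejected (%d pre-screen kept)",
             config.log_prefix, rec.subject_id or rec.role,
             len(bad), n_removed, report.epochs_rejected, ep.n_trials, before)
    return ep, report
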