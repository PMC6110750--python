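"""Synthetic paired speaker/listener EEG sessions with known ground truth.

The generator emulates a dyadic sentence-completion experiment recorded with a
24-channel 10-20 cap at 500 Hz: on each trial the speaker sees an instruction
("serious" -> expected ending, "humorous" -> unexpected ending), prepares a
sentence ending while the incomplete sentence is shown, and reads it aloud
once the sentence turns green; the listener simply listens.  Each block holds
80 trials (40 per condition) and the fixed trial timeline
(200 ms fixation + 2000 ms prompt + 4000 ms sentence + 4000 ms green) makes a
block exactly 13 min 36 s long.

What the generator injects, per trial:

* speaker parietal channels - an 8 Hz burst with a Gaussian temporal envelope
  peaking ~402 ms after the prompt.  The single-trial envelope amplitude
  ``a_i`` is a truncated-normal draw whose condition means are calibrated so
  the *unexpected* condition carries ~9.7% less non-phase-locked power;
  the carrier phase is uniform per trial, so none of the burst energy is
  phase-locked.
* listener central-parietal channels - a negative deflection (N400) 270 ms
  after the spoken-word onset with amplitude ``b_i`` and a positive deflection
  (P600) at 680 ms.  On coupled trials (unexpected, by default)
  ``b_i = mean(cond) + sd * (gamma * z(a_i) + eps) / sqrt(1 + gamma^2)``
  so that corr(a, b) = gamma / sqrt(1 + gamma^2) regardless of the noise
  scale; the P600 amplitude is independent of ``a_i``.
* both members - 1/f background noise, frontal-dominant blink transients,
  optional bad channels (variance inflated x20), and per-trial lost-packet
  gaps in the validity mask.

The per-trial ``a_i``/``b_i`` values and the coupling coefficient are returned
as a :class:`GroundTruth` record for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import CONDITIONS, EventTable, Recording
from . import montage

# ---------------------------------------------------------------------------
# timing constants (ms) -- fixed trial timeline of the task
FIXATION_MS = 200.0
PROMPT_TO_SENTENCE_MS = 2000.0
SENTENCE_TO_GO_MS = 4000.0
GO_DURATION_MS = 4000.0
TRIAL_MS = FIXATION_MS + PROMPT_TO_SENTENCE_MS + SENTENCE_TO_GO_MS + GO_DURATION_MS
LEAD_IN_MS = 2000.0
TAIL_MS = 2000.0

#: Relative channel gain of the speaker alpha burst.
ALPHA_TOPOGRAPHY = {
    "P3": 1.0, "Pz": 1.0, "P4": 1.0, "PO2": 0.9, "P7": 0.7, "P8": 0.7,
    "O1": 0.5, "Oz": 0.55, "O2": 0.5, "CPz": 0.45,
}

#: Relative channel gain of the listener ERP deflections.
ERP_TOPOGRAPHY = {
    "Cz": 1.0, "CPz": 1.0, "Pz": 0.95, "C3": 0.8, "C4": 0.85,
    "P3": 0.8, "P4": 0.85, "PO2": 0.65, "P7": 0.5, "P8": 0.55,
    "Fz": 0.5, "Oz": 0.35, "O1": 0.3, "O2": 0.3,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic dyad generator.

    Defaults reproduce the design of the emulated experiment: 9 dyads, two
    blocks with roles swapped, 40 trials per condition per block, 500 Hz,
    24 channels.  Amplitude parameters are in microvolts.
    """

    n_pairs: int = 9
    n_trials_per_condition: int = 40
    sample_rate: float = 500.0
    channel_labels: tuple[str, ...] = montage.DEFAULT_CHANNELS
    mastoids: tuple[str, str] = montage.MASTOIDS

    # speaker alpha burst
    alpha_freq: float = 8.0
    alpha_peak_latency_ms: float = 402.0
    alpha_envelope_sd_ms: float = 150.0
    alpha_latency_jitter_ms: float = 20.0
    # Condition means calibrated so the *measured* peak power (burst E[a^2]
    # times the wavelet gain, plus the 1/f background's in-band floor) drops
    # by ~9.7% in the unexpected condition.
    alpha_mean_expected: float = 10.0
    alpha_mean_unexpected: float = 9.47
    alpha_sd: float = 2.5

    # listener ERP
    n400_latency_ms: float = 270.0
    n400_width_ms: float = 60.0
    p600_latency_ms: float = 680.0
    p600_width_ms: float = 100.0
    n400_mean_expected: float = -0.22
    n400_mean_unexpected: float = -0.69
    n400_sd: float = 2.5
    p600_mean: float = 1.2
    p600_sd: float = 2.5

    # inter-brain coupling: corr(a, b) = gamma / sqrt(1 + gamma^2)
    coupling_gamma: float = 0.3145      # target r ~ 0.30
    couple_expected: bool = False       # couple only unexpected trials

    # nuisance structure
    noise_rms: float = 2.0              # 1/f background RMS per channel, uV
    noise_exponent: float = 1.0         # PSD ~ 1/f^exponent
    noise_length_scale: float = 1.0     # spatial corr e-folding, chord units
    blink_rate_per_min: float = 8.0
    blink_amplitude: float = 100.0
    blink_duration_ms: float = 200.0
    artifact_rate_per_min: float = 2.0  # large movement/muscle transients
    artifact_amplitude: float = 250.0
    bad_channel_prob: float = 0.08
    packet_loss_prob: float = 0.03      # per epoch, per member
    word_onset_after_go_ms: float = 500.0

    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trials_per_condition < 2:
            raise ValueError("need at least 2 trials per condition")
        if self.sample_rate <= 2 * max(40.0, self.alpha_freq):
            raise ValueError("sample rate must exceed twice the highest "
                             "analysis frequency")
        for p in (self.bad_channel_prob, self.packet_loss_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for lat in (self.n400_latency_ms, self.p600_latency_ms,
                    self.alpha_peak_latency_ms):
            if not 0.0 <= lat < 1000.0:
                raise ValueError("peak latencies must lie inside the "
                                 "[0, 1000) ms epoch window")
        for m in self.mastoids:
            if m not in self.channel_labels:
                raise ValueError(f"mastoid {m!r} not among channel labels")

    @property
    def n_trials(self) -> int:
        return 2 * self.n_trials_per_condition

    def alpha_mean(self, condition: str) -> float:
        return (self.alpha_mean_expected if condition == "expected"
                else self.alpha_mean_unexpected)

    def n400_mean(self, condition: str) -> float:
        return (self.n400_mean_expected if condition == "expected"
                else self.n400_mean_unexpected)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_labels"] = list(self.channel_labels)
        d["mastoids"] = list(self.mastoids)
        return d


def gamma_for_target_r(r: float) -> float:
    """Coupling slope that yields a population trial-level correlation `r`."""
    if not -1.0 < r < 1.0:
        raise ValueError("target correlation must lie in (-1, 1)")
    return r / math.sqrt(1.0 - r * r)


def target_r_for_gamma(gamma: float) -> float:
    return gamma / math.sqrt(1.0 + gamma * gamma)


@dataclass
class GroundTruth:
    """Per-trial generative amplitudes and the coupling that produced them."""

    frame: pd.DataFrame        # trial, condition, alpha_envelope,
                               # n400_amplitude, p600_amplitude
    coupling_gamma: float
    realized_r_unexpected: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.realized_r_unexpected <= 1.0:
            raise ValueError("realized correlation outside [-1, 1]")

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        f = self.frame.copy()
        f["coupling_gamma"] = self.coupling_gamma
        f["realized_r_unexpected"] = self.realized_r_unexpected
        f.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_csv(cls, path) -> "GroundTruth":
        f = pd.read_csv(path, sep="\t")
        gamma = float(f.pop("coupling_gamma").iloc[0])
        r = float(f.pop("realized_r_unexpected").iloc[0])
        return cls(f, gamma, r)


@dataclass
class BlockSession:
    """One block of a dyad: synchronized speaker and listener recordings."""

    speaker: Recording
    listener: Recording
    events: EventTable
    ground_truth: GroundTruth
    pair_id: int = 0
    block_id: int = 1
    speaker_subject: str = ""
    listener_subject: str = ""


@dataclass
class PairSession:
    """Both blocks of one dyad; roles swap between blocks."""

    pair_id: int
    blocks: list[BlockSession] = field(default_factory=list)


# ---------------------------------------------------------------------------
# elementary draws (shared with the amplitude-level cohort simulations)

def draw_alpha_envelopes(rng: np.random.Generator, condition: str,
                         n: int, config: SimConfig) -> np.ndarray:
    """Truncated-normal (>= 0) single-trial alpha envelope amplitudes, uV.

    Sampled by rejection (exact for the truncation at zero; at the default
    mean/sd the rejection rate is negligible).
    """
    mu, sd = config.alpha_mean(condition), config.alpha_sd
    if mu == 0.0 and sd < 1e-12:
        return np.zeros(n)
    a = rng.normal(mu, sd, size=n)
    bad = a < 0
    while bad.any():
        a[bad] = rng.normal(mu, sd, size=int(bad.sum()))
        bad = a < 0
    return a


def draw_n400_amplitudes(rng: np.random.Generator, condition: str,
                         alpha: np.ndarray, config: SimConfig) -> np.ndarray:
    """Single-trial N400 amplitudes, coupled to the alpha envelopes.

    On coupled trials the standardized envelope enters with slope ``gamma``
    while the marginal SD stays at ``n400_sd`` for every gamma.
    """
    alpha = np.asarray(alpha, dtype=float)
    n = alpha.size
    eps = rng.standard_normal(n)
    coupled = config.couple_expected or condition == "unexpected"
    g = config.coupling_gamma if coupled else 0.0
    if g != 0.0 and config.alpha_sd > 0:
        # standardize by the population moments (truncation correction is
        # negligible at the default mean/sd ratio) so the population
        # correlation is exactly gamma / sqrt(1 + gamma^2)
        z = (alpha - config.alpha_mean(condition)) / config.alpha_sd
    else:
        z, g = np.zeros(n), 0.0
    mix = (g * z + eps) / math.sqrt(1.0 + g * g)
    return config.n400_mean(condition) + config.n400_sd * mix


def draw_trial_amplitudes(rng: np.random.Generator,
                          config: SimConfig) -> pd.DataFrame:
    """Per-trial ground-truth amplitudes for one block (both conditions).

    The condition sequence is a random interleave of the two 40-trial sets.
    """
    conds = np.array([CONDITIONS[0]] * config.n_trials_per_condition +
                     [CONDITIONS[1]] * config.n_trials_per_condition)
    rng.shuffle(conds)
    a = np.empty(config.n_trials)
    b = np.empty(config.n_trials)
    for cond in CONDITIONS:
        sel = conds == cond
        a[sel] = draw_alpha_envelopes(rng, cond, int(sel.sum()), config)
        b[sel] = draw_n400_amplitudes(rng, cond, a[sel], config)
    c = config.p600_mean + config.p600_sd * rng.standard_normal(config.n_trials)
    return pd.DataFrame({
        "trial": np.arange(config.n_trials),
        "condition": conds,
        "alpha_envelope": a,
        "n400_amplitude": b,
        "p600_amplitude": c,
    })


# ---------------------------------------------------------------------------
# waveform synthesis

def one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                     sfreq: float, rms: float, exponent: float) -> np.ndarray:
    """Spectrally shaped white noise with PSD ~ 1/f^exponent, zero DC."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    noise = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    scale = noise.std(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    return noise * (rms / scale)


def spatial_mixing(channels, length_scale: float) -> np.ndarray:
    """Cholesky factor of an exponential spatial correlation over the scalp.

    Volume conduction makes EEG background strongly correlated between
    nearby electrodes; corr(i, j) = exp(-d_ij / length_scale) with d the
    chord distance on the unit sphere reproduces that, and in particular
    makes mastoid re-referencing cancel shared background rather than inject
    independent mastoid noise.
    """
    pos = montage.positions_for(channels)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    corr = np.exp(-d / length_scale)
    return np.linalg.cholesky(corr + 1e-9 * np.eye(len(channels)))


def background_noise(rng: np.random.Generator, channels, n_samples: int,
                     sfreq: float, rms: float, exponent: float,
                     length_scale: float) -> np.ndarray:
    """Spatially correlated 1/f background, `rms` uV per channel."""
    z = one_over_f_noise(rng, len(channels), n_samples, sfreq, 1.0, exponent)
    mixed = spatial_mixing(channels, length_scale) @ z
    scale = mixed.std(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    return mixed * (rms / scale)


def build_event_table(config: SimConfig,
                      conditions: np.ndarray) -> EventTable:
    """Trigger samples for one block under the fixed trial timeline."""
    fs = config.sample_rate

    def ms2samp(ms: float) -> int:
        return int(round(ms / 1000.0 * fs))

    rows = []
    for i, cond in enumerate(conditions):
        start = LEAD_IN_MS + i * TRIAL_MS
        prompt = start + FIXATION_MS
        sentence = prompt + PROMPT_TO_SENTENCE_MS
        go = sentence + SENTENCE_TO_GO_MS
        word = go + config.word_onset_after_go_ms
        rows.append((i, cond, ms2samp(prompt), ms2samp(sentence),
                     ms2samp(go), ms2samp(word)))
    return EventTable(pd.DataFrame(
        rows, columns=["trial", "condition", "prompt_onset", "sentence_onset",
                       "go_onset", "word_onset"]))


def _block_n_samples(config: SimConfig) -> int:
    total_ms = LEAD_IN_MS + config.n_trials * TRIAL_MS + TAIL_MS
    return int(round(total_ms / 1000.0 * config.sample_rate))


def _gaussian_bump(t: np.ndarray, center: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sd) ** 2)


def _add_alpha_bursts(data: np.ndarray, channels: list[str],
                      events: EventTable, gt: pd.DataFrame,
                      config: SimConfig, rng: np.random.Generator) -> None:
    fs = config.sample_rate
    half = int(round(0.6 * fs))            # +-600 ms support around the peak
    t_rel = np.arange(-half, half + 1) / fs
    ch_gain = [(channels.index(ch), g) for ch, g in ALPHA_TOPOGRAPHY.items()
               if ch in channels]
    prompts = events.onsets("prompt")
    sd_s = config.alpha_envelope_sd_ms / 1000.0
    for i in range(len(gt)):
        jitter = rng.normal(0.0, config.alpha_latency_jitter_ms / 1000.0)
        center = prompts[i] + (config.alpha_peak_latency_ms / 1000.0 + jitter) * fs
        phase = rng.uniform(0.0, 2.0 * np.pi)
        env = _gaussian_bump(t_rel, 0.0, sd_s)
        burst = gt["alpha_envelope"].iloc[i] * env * np.cos(
            2.0 * np.pi * config.alpha_freq * t_rel + phase)
        s0 = int(round(center)) - half
        sl = slice(max(s0, 0), min(s0 + burst.size, data.shape[1]))
        seg = burst[sl.start - s0: sl.stop - s0]
        for idx, g in ch_gain:
            data[idx, sl] += g * seg


def _add_listener_erps(data: np.ndarray, channels: list[str],
                       events: EventTable, gt: pd.DataFrame,
                       config: SimConfig) -> None:
    fs = config.sample_rate
    n = data.shape[1]
    t = np.arange(n) / fs
    ch_gain = [(channels.index(ch), g) for ch, g in ERP_TOPOGRAPHY.items()
               if ch in channels]
    words = events.onsets("word")
    for i in range(len(gt)):
        w = words[i] / fs
        lo = max(int(words[i] - fs), 0)
        hi = min(int(words[i] + 1.5 * fs), n)
        tt = t[lo:hi]
        shape = (gt["n400_amplitude"].iloc[i] *
                 _gaussian_bump(tt, w + config.n400_latency_ms / 1000.0,
                                config.n400_width_ms / 1000.0) +
                 gt["p600_amplitude"].iloc[i] *
                 _gaussian_bump(tt, w + config.p600_latency_ms / 1000.0,
                                config.p600_width_ms / 1000.0))
        for idx, g in ch_gain:
            data[idx, lo:hi] += g * shape


def _add_blinks(data: np.ndarray, channels: list[str],
                config: SimConfig, rng: np.random.Generator) -> None:
    """Frontal raised-cosine blink transients at Poisson times."""
    fs = config.sample_rate
    n = data.shape[1]
    duration_s = n / fs
    n_blinks = rng.poisson(config.blink_rate_per_min * duration_s / 60.0)
    if n_blinks == 0:
        return
    width = int(round(config.blink_duration_ms / 1000.0 * fs))
    template = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(width) / width))
    pos = montage.positions_for(channels)
    frontal = montage.positions_for(["Fp1", "Fp2"]).mean(axis=0)
    frontal /= np.linalg.norm(frontal)
    d = np.linalg.norm(pos - frontal, axis=1)
    gains = np.exp(-d / 0.5)
    gains /= gains.max()
    starts = rng.integers(0, n - width, size=n_blinks)
    for s in starts:
        amp = config.blink_amplitude * rng.uniform(0.8, 1.2)
        data[:, s:s + width] += amp * np.outer(gains, template)


def _add_movement_artifacts(data: np.ndarray, config: SimConfig,
                            rng: np.random.Generator) -> None:
    """Occasional large slow transients with irregular topography.

    These emulate motion/muscle artifacts: the epochs they land in are what
    the automatic artifact-rejection stage is meant to remove.
    """
    fs = config.sample_rate
    n = data.shape[1]
    n_events = rng.poisson(config.artifact_rate_per_min * (n / fs) / 60.0)
    for _ in range(n_events):
        width = int(rng.uniform(0.3, 0.8) * fs)
        start = int(rng.integers(0, max(n - width, 1)))
        env = np.hanning(width)
        amp = config.artifact_amplitude * rng.uniform(0.5, 1.5)
        sign = rng.choice([-1.0, 1.0])
        weights = rng.uniform(0.2, 1.0, size=data.shape[0])
        data[:, start:start + width] += sign * amp * np.outer(weights, env)


def _inject_bad_channels(data: np.ndarray, channels: list[str],
                         config: SimConfig,
                         rng: np.random.Generator) -> list[str]:
    """Inflate the variance of randomly chosen scalp channels x20."""
    bad = []
    for i, ch in enumerate(channels):
        if ch in montage.MASTOIDS:
            continue
        if rng.uniform() < config.bad_channel_prob:
            sd = data[i].std()
            data[i] += rng.standard_normal(data.shape[1]) * (math.sqrt(19.0) * sd)
            bad.append(ch)
    return bad


def _packet_loss_mask(n_samples: int, events: EventTable, config: SimConfig,
                      rng: np.random.Generator, role: str) -> np.ndarray:
    """Per-epoch dropout gaps (40-200 ms) inside the role's analysis window.

    The speaker is epoched on the prompt and the listener on the spoken-word
    onset, so `packet_loss_prob` is the probability that a given trial's
    [-200, 1000) ms epoch overlaps a lost-packet run for that member.
    """
    mask = np.ones(n_samples, dtype=bool)
    fs = config.sample_rate
    lock = "prompt" if role == "speaker" else "word"
    for onset in events.onsets(lock):
        if rng.uniform() >= config.packet_loss_prob:
            continue
        span_lo = int(onset - 0.2 * fs)
        span_hi = int(onset + 1.0 * fs)
        gap = int(rng.uniform(0.04, 0.2) * fs)
        start = int(rng.integers(span_lo, max(span_hi - gap, span_lo + 1)))
        mask[max(start, 0):min(start + gap, n_samples)] = False
    return mask


# ---------------------------------------------------------------------------
# session-level generation

def simulate_pair_session(config: SimConfig, seed: int | None = None, *,
                          pair_id: int = 0, block_id: int = 1,
                          speaker_subject: str = "",
                          listener_subject: str = "") -> BlockSession:
    """Generate one synchronized speaker/listener block with ground truth.

    `seed` is mandatory (falling back to the config's seed): every run must be
    reproducible.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required; reproducibility is mandatory")

    epoch_span_ms = 1200.0
    if epoch_span_ms > TRIAL_MS:
        raise ValueError("epoch window exceeds inter-trial spacing")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    channels = list(config.channel_labels)
    n_samples = _block_n_samples(config)

    gt_frame = draw_trial_amplitudes(rng, config)
    events = build_event_table(config, gt_frame["condition"].to_numpy())

    recordings = {}
    bad_injected = {}
    masks = {}
    for role in ("speaker", "listener"):
        data = background_noise(rng, channels, n_samples,
                                config.sample_rate, config.noise_rms,
                                config.noise_exponent,
                                config.noise_length_scale)
        if role == "speaker":
            _add_alpha_bursts(data, channels, events, gt_frame, config, rng)
        else:
            _add_listener_erps(data, channels, events, gt_frame, config)
        _add_blinks(data, channels, config, rng)
        _add_movement_artifacts(data, config, rng)
        bad_injected[role] = _inject_bad_channels(data, channels, config, rng)
        masks[role] = _packet_loss_mask(n_samples, events, config, rng, role)
        recordings[role] = data

    unexp = gt_frame["condition"] == "unexpected"
    r = float(np.corrcoef(gt_frame.loc[unexp, "alpha_envelope"],
                          gt_frame.loc[unexp, "n400_amplitude"])[0, 1])
    gt = GroundTruth(gt_frame, config.coupling_gamma, r)

    def mk(role: str, subject: str) -> Recording:
        return Recording(recordings[role], config.sample_rate, list(channels),
                         validity_mask=masks[role], role=role, pair_id=pair_id,
                         block_id=block_id, subject_id=subject,
                         meta={"injected_bad_channels": bad_injected[role]})

    return BlockSession(
        speaker=mk("speaker", speaker_subject),
        listener=mk("listener", listener_subject),
        events=events, ground_truth=gt, pair_id=pair_id, block_id=block_id,
        speaker_subject=speaker_subject, listener_subject=listener_subject)


def cohort_block_seeds(master_seed: int, n_pairs: int) -> np.ndarray:
    """Deterministic per-(pair, block) seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return np.array([s.generate_state(1)[0] % (2**31)
                     for s in ss.spawn(2 * n_pairs)]).reshape(n_pairs, 2)


def simulate_cohort(config: SimConfig,
                    master_seed: int | None = None) -> list[PairSession]:
    """Generate the full cohort: one :class:`PairSession` per dyad.

    Subject A speaks in block 1 and listens in block 2 (roles reversed), so a
    default cohort of 9 pairs yields 18 distinct speaker-listener role
    assignments -- the units of the group analysis.
    """
    if master_seed is None:
        master_seed = config.seed
    if master_seed is None:
        raise ValueError("a master seed is required")
    if config.n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    seeds = cohort_block_seeds(master_seed, config.n_pairs)
    cohort = []
    for p in range(config.n_pairs):
        subj = (f"P{p + 1:02d}A", f"P{p + 1:02d}B")
        blocks = []
        for b in (1, 2):
            spk, lst = subj if b == 1 else subj[::-1]
            blocks.append(simulate_pair_session(
                config, int(seeds[p, b - 1]), pair_id=p + 1, block_id=b,
                speaker_subject=spk, listener_subject=lst))
        cohort.append(PairSession(pair_id=p + 1, blocks=blocks))
    return cohort


def iter_blocks(config: SimConfig, master_seed: int):
    """Yield the cohort's blocks one at a time (memory-friendly)."""
    seeds = cohort_block_seeds(master_seed, config.n_pairs)
    for p in range(config.n_pairs):
        subj = (f"P{p + 1:02d}A", f"P{p + 1:02d}B")
        for b in (1, 2):
            spk, lst = subj if b == 1 else subj[::-1]
            yield simulate_pair_session(
                config, int(seeds[p, b - 1]), pair_id=p + 1, block_id=b,
                speaker_subject=spk, listener_subject=lst)
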