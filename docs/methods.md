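# Methods

`interbrain` implements a dual-EEG ("hyperscanning") analysis of a sentence-
completion task: a speaker prepares an expected or unexpected sentence ending
while a listener waits for the spoken word. The package measures (i) the
speaker's preparatory lower-alpha (8 Hz) non-phase-locked power, (ii) the
listener's single-trial N400/P600 amplitudes to the spoken word, and (iii)
their trial-by-trial coupling across the dyad, with group inference over
speaker-listener role assignments. Because no public dataset accompanies the
design, a synthetic paired-session generator with recorded ground truth is a
first-class part of the package; every statistical guarantee quoted below is
computed, not assumed.

## The model

Per analysis unit (one speaker-listener role assignment; a dyad contributes
two, one per block) and per trial *i*:

* the speaker's parietal channels carry an 8 Hz burst with Gaussian temporal
  envelope peaking ~402 ms after the instruction prompt, with single-trial
  envelope amplitude *a_i* ≥ 0;
* the listener's central-parietal channels carry a negative deflection
  (N400 range, ~270 ms post word onset) with amplitude *b_i* and a positive
  deflection (P600 range, ~680 ms) with amplitude *c_i*;
* on coupled trials (the unexpected condition, by default)

      b_i = mu_cond + sd_b * (gamma * z(a_i) + eps_i) / sqrt(1 + gamma^2),

  where `z(a_i)` standardizes the envelope by its population moments and
  `eps_i` is standard normal. The marginal SD of *b* is `sd_b` for every
  `gamma`, and the population trial-level correlation is
  `r = gamma / sqrt(1 + gamma^2)` (`gamma_for_target_r` inverts this).
  *c_i* is independent of *a_i* throughout.

The inference chain estimates, per unit, the Pearson correlation between the
speaker's single-trial wavelet amplitude and the listener's single-trial ERP
amplitude over kept trials of one condition, Fisher-transforms it
(z = atanh r), and tests the population mean z against zero with a one-sample
t-test (df = units − 1). The full family is 6 frequencies × 2 ERP peaks = 12
tests, corrected by the Holm–Bonferroni step-down at alpha = 0.05 (the k-th
smallest p is significant iff every j ≤ k satisfies p_(j) < alpha/(m−j+1)).
Two-sided p-values are the default: the published family layout this mirrors
reports two-sided-sized p-values even though the hypothesis is directional;
`alternative="greater"` is available and logged when used.

## Signal processing

**Wavelet.** Complex Morlet, psi(u) = (pi·fb)^(−1/2) · exp(2·pi·i·fc·u) ·
exp(−u²/fb), with fb = 0.5, fc = 1, and scale = fc·fs/f for target
frequencies {2, 6, 8, 12, 20, 40} Hz — the convention of the classic MATLAB
`cwt` `cmor` family and of PyWavelets' `cmorB-C`, against which the
implementation is cross-checked. The transform is FFT-based convolution; a
brute-force time-domain convolution serves as the oracle (rms agreement
< 1e−6). Samples within one envelope e-folding width of an epoch edge are
flagged (cone of influence) and excluded from peak searches.

**Non-phase-locked power** is the across-trial variance of the complex
coefficients, Var(c) = Σ|c_i − mean|²/(n−1) — real and nonnegative, so the
conventional trailing "absolute value" is implemented as a documented no-op.
Subtracting the across-trial mean removes every phase-locked (evoked)
contribution; the generator's bursts carry uniform random phase per trial,
so their energy is entirely non-phase-locked.

**Peak selection.** All peak time points (per-frequency power peaks in
[0, 1000) ms post-prompt; negative ERP peak in [150, 500) ms and positive in
[450, 900) ms post word onset) are identified once from grand averages
collapsed over units *and* conditions, so the chosen samples cannot favour a
condition. Ties break to the earliest sample. Single-trial speaker power is
|mean over parietal electrodes of the complex coefficient| at the peak
sample — the complex mean precedes the modulus, deliberately distinct from a
mean of moduli. Single-trial listener amplitudes are electrode means at the
peak sample (a ±10 ms window mean is available but off by default).

**Preprocessing order** (per continuous recording): blink attenuation →
linear detrend → re-reference to the mastoid (M1/M2) average → bad-channel
detection and spherical-spline interpolation → epoching on [−200, 1000) ms
(half-open, 600 samples at 500 Hz, lock sample at t = 0) → automatic
artifact-epoch rejection → synchronization of rejections across the dyad
(joint keep mask = elementwise AND).

* *Blink removal:* FastICA on a temporally subsampled copy (every 10th
  sample) restricted to a 6-component PCA subspace; components are removed
  when their mixing column is frontal-dominant (Fp1/Fp2 weight ratio ≥ 2)
  and their source power is mostly below 5 Hz (fraction ≥ 0.55). The small
  subspace is deliberate: ocular sources carry most variance and are the
  only strongly non-Gaussian directions, so a compact decomposition
  converges where a full-rank one cannot. Non-convergence falls back to
  regressing out a low-passed frontal reference (logged).
* *Bad channels:* robust z of log-variance (median/MAD, threshold 3) or
  kurtosis z (threshold 5), mastoids excluded; interpolation uses the Perrin
  spherical spline (order m = 4, 50 Legendre terms, ridge 1e−5) on the
  montage's unit sphere. Good channels pass through bit-identical.
* *Epoch rejection:* absolute threshold 1000 µV, then an iterative
  peak-to-peak deviation rule (max channel |z| > 5, at most 5% of survivors
  dropped per iteration, statistics recomputed until stable).
* *Baseline:* listener epochs are baseline-corrected by the mean of
  [−200, 0) ms (configurable, off for speaker epochs before the wavelet
  stage).

The thresholds above are documented package defaults in the spirit of the
standard EEGLAB/FASTER tooling, not values taken from any dataset.

## The synthetic generator

Defaults encode the study conditions: 9 dyads × 2 blocks with roles swapped
(18 analysis units), 40 expected + 40 unexpected trials per block in random
interleave, 500 Hz, 24-channel 10–20 montage including CPz, Pz, mastoids and
the nonstandard label "PO2" (placed at the normalized POz/PO4 midpoint — a
choice this montage owns; the label is carried verbatim). The fixed trial
timeline (200 ms fixation, 2000 ms prompt, 4000 ms sentence, 4000 ms green
reading period; word onset 500 ms after the go signal) makes a block exactly
13 min 36 s.

Amplitude parameters (µV): envelope mean 10.0 (expected) with SD 2.5,
truncated at zero; N400 condition means −0.22 / −0.69 with single-trial SD
2.5 (chosen so the condition contrast lands at a group effect size a cohort
of 18 units detects with high power); P600 mean 1.2, SD 2.5, no condition
effect; default coupling gamma 0.3145 (target trial-level r = 0.30). The
unexpected envelope mean (9.47) is calibrated so the *measured* peak
non-phase-locked power — burst E[a²] times the wavelet gain plus the in-band
1/f floor — drops by ~9.7%.

Nuisance structure: spatially correlated 1/f background (exponential spatial
correlation with e-folding one chord unit; RMS 2 µV per channel), frontal
raised-cosine blinks (200 ms, ~100 µV, 8/min), occasional large movement
transients (2/min, 0.3–0.8 s, ~250 µV, irregular topography) that give the
epoch-rejection stage genuine targets, bad channels (probability 0.08,
variance ×20), and per-epoch lost-packet gaps (probability 0.03 per member,
40–200 ms, placed in the member's own analysis window).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: physiological source geometry (no forward model;
topographies are fixed gain maps), heartbeat/muscle tone/line noise,
between-subject variability in latencies and topographies, non-stationary
alpha (the background is stationary 1/f), and real ocular dynamics. The
default background RMS (2 µV) is optimistic relative to typical scalp EEG;
it is set so that single-trial amplitude extraction tracks the generative
amplitudes at reliability ≥ 0.7, which is the regime the recovery tests are
designed around. Real single-trial reliabilities are lower, which attenuates
observable trial-level correlations — the reason measured inter-brain r
values in practice sit well below the generative coupling.

Wavelet bandwidth is a physical caveat in the other direction: fb = 0.5 at
fc = 1 is a very short wavelet (envelope e-folding of ~0.7 carrier periods),
so its frequency response is broad and the 6, 12 and 20 Hz bands — at high
SNR even 40 Hz — partially inherit the 8 Hz burst. At strong coupling the
full-pipeline family therefore shows Holm-significant neighbours of the
8 Hz × negative-peak cell. The amplitude-level specificity simulations are
leak-free by construction (independent envelope draws per frequency); the
waveform-level family is reported as computed.

## Statistical guarantees (computed, not assumed)

`interbrain.recover` replicates cohorts at the generator's amplitude level —
per-trial a_i/b_i/c_i draws from exactly the distributions the waveform
generator uses, fed through the package's own correlation → Fisher z →
t-test → Holm chain; speaker metrics at the five uncoupled frequencies are
independent envelope draws, and kept-trial counts are drawn from 26–40 to
emulate post-rejection attrition. This isolates the inference guarantees
from waveform synthesis (validated separately by injection–recovery tests
and an end-to-end cohort):

* with gamma = 0, the familywise Holm rejection rate over 200 cohorts stays
  at alpha;
* with target r = 0.3, the 8 Hz × negative-peak cell is Holm-significant in
  well over 80% of cohorts, usually alone, and mean recovered z matches
  atanh(0.3) within Monte-Carlo error plus the known small-sample bias
  r/(2(n−1));
* the injected alpha-power reduction and the printed N400 condition gap are
  each detected by paired t-tests (18 units, 40 trials/condition) in well
  over 80% of cohorts.

Problem sizes (200/100 cohorts, 18 units, 26–40 trials) are the package's
chosen simulation sizes; they keep Monte-Carlo standard errors below ~0.02
on the reported rates.

## Numerical choices and degenerate inputs

* Epoch arithmetic is 0-based and half-open: window [−200, 1000) ms at
  500 Hz → samples event−100 … event+499.
* Complex variance uses ddof = 1 (two coefficients +1/−1 → power 2).
* `pair_correlation` needs ≥ 3 common trials (default family minimum 10);
  zero variance in either vector yields a logged missing r; |r| = 1 raises
  (no finite Fisher z). Units with missing r are dropped from the affected
  cell with a logged count.
* A group test on all-zero z values returns t = 0, p = 1 (the 0/0 limit at
  the null); constant nonzero z raises.
* Flat traces in peak searches return the earliest window sample with a
  warning; ties break early.
* Holm uses strict `<` against alpha/(m−k) ("below" the threshold), which
  differs from some libraries' `<=` only on exact ties.
* EDF files are written with per-channel symmetric physical ranges sized to
  the data, so round-trips are exact to the 16-bit quantization step;
  validity masks and events travel in TSV sidecars because EDF carries
  neither.

## Reproducibility

Every generator entry point requires a seed; cohorts derive per-block
substreams from one master seed via `SeedSequence` spawning, so partial
reruns reproduce per-block data exactly. The CLI (`interbrain simulate |
analyze | recover`) writes the fully resolved configuration next to its
outputs; a run is reproducible from its artifacts alone.
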