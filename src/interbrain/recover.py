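"""Statistical-guarantee simulations: type-I error, power, recovery.

These simulations run at the generator's amplitude level: per-trial envelope
and ERP amplitudes are drawn from exactly the distributions the waveform
generator uses (the same functions), and fed through the package's own
correlation / Fisher-z / t-test / Holm chain.  This isolates the inference
guarantees (familywise error control, detection power, parameter recovery)
from waveform synthesis, which is validated separately by injection-recovery
tests on full recordings.  A replicate cohort is 18 analysis units with a
random 26-40 kept unexpected trials each, emulating post-rejection counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .containers import CONDITIONS
from .coupling import group_onesample_test, holm_bonferroni, pair_correlation
from .simulate import (SimConfig, draw_alpha_envelopes, draw_n400_amplitudes,
                       target_r_for_gamma)

FREQS = (2.0, 6.0, 8.0, 12.0, 20.0, 40.0)
KEPT_TRIALS = (26, 40)      # post-rejection unexpected-trial counts


def _unit_cell_r(rng: np.random.Generator, config: SimConfig,
                 n_trials: int) -> dict:
    """Per-unit Fisher z for all 12 family cells, amplitude level.

    The 8 Hz speaker metric is the alpha envelope that drives the listener
    N400; the other five frequencies are independent envelope draws; the
    positive-peak listener metric is independent of everything.
    """
    a8 = draw_alpha_envelopes(rng, "unexpected", n_trials, config)
    b = draw_n400_amplitudes(rng, "unexpected", a8, config)
    c = config.p600_mean + config.p600_sd * rng.standard_normal(n_trials)
    out = {}
    for f in FREQS:
        sp = a8 if f == 8.0 else draw_alpha_envelopes(rng, "unexpected",
                                                      n_trials, config)
        for pk, amp in (("negative", b), ("positive", c)):
            out[(f, pk)] = pair_correlation(sp, amp, unit=None, frequency=f,
                                            peak_kind=pk).z
    return out


@dataclass
class FamilySimResult:
    n_cohorts: int
    any_significant_rate: float          # familywise rejection rate
    target_cell_rate: float              # 8 Hz x negative-peak Holm rate
    only_target_rate: float              # target and nothing else
    mean_z_target: float
    se_mean_z_target: float
    true_z: float


def simulate_family(config: SimConfig, n_cohorts: int, master_seed: int,
                    n_units: int = 18,
                    alternative: str = "two-sided") -> FamilySimResult:
    """Replicate the 12-cell Holm-corrected family over simulated cohorts."""
    rng = np.random.default_rng(np.random.SeedSequence(master_seed))
    cells = [(f, pk) for f in FREQS for pk in ("negative", "positive")]
    target = (8.0, "negative")
    any_sig = np.zeros(n_cohorts, dtype=bool)
    tgt_sig = np.zeros(n_cohorts, dtype=bool)
    only_tgt = np.zeros(n_cohorts, dtype=bool)
    mean_z = np.zeros(n_cohorts)
    for i in range(n_cohorts):
        z = {cell: np.empty(n_units) for cell in cells}
        for u in range(n_units):
            n_tr = int(rng.integers(KEPT_TRIALS[0], KEPT_TRIALS[1] + 1))
            for cell, zu in _unit_cell_r(rng, config, n_tr).items():
                z[cell][u] = zu
        p = np.array([group_onesample_test(z[cell], alternative).p
                      for cell in cells])
        flags = holm_bonferroni(p, 0.05)
        any_sig[i] = flags.any()
        k = cells.index(target)
        tgt_sig[i] = flags[k]
        only_tgt[i] = flags[k] and flags.sum() == 1
        mean_z[i] = z[target].mean()
    return FamilySimResult(
        n_cohorts, float(any_sig.mean()), float(tgt_sig.mean()),
        float(only_tgt.mean()), float(mean_z.mean()),
        float(mean_z.std(ddof=1) / np.sqrt(n_cohorts)),
        float(np.arctanh(target_r_for_gamma(config.coupling_gamma))))


@dataclass
class ContrastSimResult:
    n_cohorts: int
    alpha_detection_rate: float
    n400_detection_rate: float
    mean_percent_reduction: float


def _subject_alpha_power(rng: np.random.Generator, config: SimConfig,
                         condition: str, n_trials: int) -> float:
    """Amplitude-level non-phase-locked power: across-trial complex variance
    of the enveloped carrier at its peak (random phase per trial)."""
    a = draw_alpha_envelopes(rng, condition, n_trials, config)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=n_trials)
    coeff = a * np.exp(1j * phase)
    return float(np.abs(np.var(coeff, ddof=1)))


def simulate_contrasts(config: SimConfig, n_cohorts: int, master_seed: int,
                       n_units: int = 18, alpha: float = 0.05
                       ) -> ContrastSimResult:
    """Detection rates of the condition contrasts by paired t-tests."""
    rng = np.random.default_rng(np.random.SeedSequence(master_seed))
    n_tr = config.n_trials_per_condition
    alpha_hits = np.zeros(n_cohorts, dtype=bool)
    n400_hits = np.zeros(n_cohorts, dtype=bool)
    reductions = np.zeros(n_cohorts)
    for i in range(n_cohorts):
        pw = {c: np.empty(n_units) for c in CONDITIONS}
        nn = {c: np.empty(n_units) for c in CONDITIONS}
        for u in range(n_units):
            for cond in CONDITIONS:
                pw[cond][u] = _subject_alpha_power(rng, config, cond, n_tr)
                a = draw_alpha_envelopes(rng, cond, n_tr, config)
                nn[cond][u] = draw_n400_amplitudes(rng, cond, a,
                                                   config).mean()
        alpha_hits[i] = stats.ttest_rel(pw["expected"],
                                        pw["unexpected"]).pvalue < alpha
        n400_hits[i] = stats.ttest_rel(nn["expected"],
                                       nn["unexpected"]).pvalue < alpha
        e, ue = pw["expected"].mean(), pw["unexpected"].mean()
        reductions[i] = 100.0 * (e - ue) / e
    return ContrastSimResult(n_cohorts, float(alpha_hits.mean()),
                             float(n400_hits.mean()),
                             float(reductions.mean()))


def gamma_sweep(config: SimConfig, gammas, n_cohorts: int,
                master_seed: int, n_units: int = 18) -> list[dict]:
    """Mean recovered Fisher z per coupling level (monotonicity check)."""
    out = []
    for k, g in enumerate(gammas):
        cfg = replace(config, coupling_gamma=float(g))
        res = simulate_family(cfg, n_cohorts, master_seed + 1000 * k, n_units)
        out.append({"gamma": float(g),
                    "target_r": target_r_for_gamma(float(g)),
                    "mean_z": res.mean_z_target,
                    "detection_rate": res.target_cell_rate})
    return out
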