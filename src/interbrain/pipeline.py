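"""End-to-end cohort analysis: preprocess -> spectral/ERP -> coupling.

The analysis unit is one speaker-listener role assignment (a dyad contributes
two, since roles swap between blocks).  Per block the speaker is epoched on
the instruction prompt and the listener on the spoken-word onset; artifact
rejections are synchronized across the two members.  Peak time points (the
preparatory power peak per frequency, the negative/positive ERP peaks) are
identified once from grand averages collapsed over units and conditions, and
all per-unit and single-trial quantities are read at those fixed samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import erp as erpmod
from . import montage
from . import spectral
from .containers import CONDITIONS
from .coupling import CouplingResults, InterBrainCoupling
from .preprocess import (PreprocessConfig, PreprocessReport,
                         preprocess_recording, synchronize_rejections)
from .simulate import BlockSession
from .spectral import WaveletSpec

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Every analysis parameter in one serializable place."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    parietal: tuple[str, ...] = montage.PARIETAL
    central_parietal: tuple[str, ...] = montage.CENTRAL_PARIETAL
    alpha_freq: float = 8.0
    power_peak_window_ms: tuple[float, float] = (0.0, 1000.0)
    negative_window_ms: tuple[float, float] = (150.0, 500.0)
    positive_window_ms: tuple[float, float] = (450.0, 900.0)
    alpha_level: float = 0.05
    min_trials: int = 10
    alternative: str = "two-sided"


@dataclass
class BlockFeatures:
    """Reduced per-unit quantities kept in memory during a cohort run."""

    unit: str
    pair_id: int
    block_id: int
    conditions: np.ndarray
    keep_mask: np.ndarray
    # electrode-averaged non-phase-locked power per condition (samples x freqs)
    power: dict
    # parietal-mean complex coefficients per trial (trials x samples x freqs)
    trial_coeffs: np.ndarray
    # ERP timecourses per condition and single-trial electrode-mean traces
    erp: dict
    erp_traces: np.ndarray
    freqs: tuple
    sfreq: float
    window_ms: tuple
    coi_valid: np.ndarray
    reports: dict


def extract_block_features(block: BlockSession,
                           cfg: AnalysisConfig | None = None
                           ) -> BlockFeatures:
    """Preprocess one block and reduce it to the quantities the group-level
    analysis needs."""
    cfg = cfg or AnalysisConfig()
    sp_ep, sp_rep = preprocess_recording(block.speaker, block.events,
                                         "prompt", cfg.preprocess,
                                         baseline=False)
    ls_ep, ls_rep = preprocess_recording(block.listener, block.events,
                                         "word", cfg.preprocess)
    sp_ep, ls_ep = synchronize_rejections(sp_ep, ls_ep)

    cube = spectral.morlet_transform(sp_ep, cfg.wavelet)
    power = {}
    for cond in CONDITIONS:
        tc = spectral.nonphaselocked_power(cube, cond)
        power[cond] = spectral.average_over_electrodes(tc, cfg.parietal)
    idx = cube.channel_indices(cfg.parietal)
    trial_coeffs = cube.coeffs[:, idx].mean(axis=1)
    trial_coeffs[~cube.keep_mask] = np.nan

    erp = {cond: erpmod.average_erp(ls_ep, cfg.central_parietal, cond)
           for cond in CONDITIONS}
    eidx = ls_ep.channel_indices(cfg.central_parietal)
    erp_traces = ls_ep.data[:, eidx, :].mean(axis=1)
    erp_traces[~ls_ep.keep_mask] = np.nan

    unit = f"p{block.pair_id:02d}b{block.block_id}"
    return BlockFeatures(unit, block.pair_id, block.block_id,
                         sp_ep.conditions.copy(), sp_ep.keep_mask.copy(),
                         power, trial_coeffs, erp, erp_traces,
                         cube.freqs, cube.sfreq, cube.window_ms,
                         cube.coi_valid,
                         {"speaker": sp_rep, "listener": ls_rep})


@dataclass
class PairedContrast:
    """Paired t-test of per-unit expected vs unexpected values."""

    name: str
    mean_expected: float
    mean_unexpected: float
    t: float
    df: int
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class CohortResults:
    """Everything the cohort-level analysis produces."""

    config: AnalysisConfig
    power_peaks: dict                     # frequency -> PeakDef
    erp_peaks: erpmod.ErpPeaks
    subject_power: pd.DataFrame           # unit, condition, frequency, power
    subject_erp: pd.DataFrame             # unit, condition, neg_amp, pos_amp
    single_trial: pd.DataFrame            # model input table
    alpha_contrast: PairedContrast
    n400_contrast: PairedContrast
    p600_contrast: PairedContrast
    percent_alpha_reduction: float
    coupling: CouplingResults
    coupling_expected: CouplingResults
    reports: dict

    @property
    def alpha_peak(self) -> spectral.PeakDef:
        return self.power_peaks[self.config.alpha_freq]

    def summary(self) -> str:
        a, n, p = self.alpha_contrast, self.n400_contrast, self.p600_contrast
        lines = [
            "Cohort analysis summary",
            "=======================",
            f"units (speaker-listener role assignments): "
            f"{self.subject_erp['unit'].nunique()}",
            f"alpha ({self.config.alpha_freq:g} Hz) power peak: "
            f"{self.alpha_peak.peak_time_ms:.0f} ms post-prompt",
            f"ERP peaks: negative {self.erp_peaks.negative.peak_time_ms:.0f} "
            f"ms, positive {self.erp_peaks.positive.peak_time_ms:.0f} ms "
            "post-word",
            "",
            f"alpha peak power  expected {a.mean_expected:8.2f}  "
            f"unexpected {a.mean_unexpected:8.2f}  "
            f"({self.percent_alpha_reduction:.2f}% reduction; "
            f"T = {a.t:.2f}, p = {a.p:.3f}, df = {a.df})",
            f"negative ERP peak expected {n.mean_expected:8.2f}  "
            f"unexpected {n.mean_unexpected:8.2f} uV "
            f"(T = {n.t:.2f}, p = {n.p:.3f}, df = {n.df})",
            f"positive ERP peak expected {p.mean_expected:8.2f}  "
            f"unexpected {p.mean_unexpected:8.2f} uV "
            f"(T = {p.t:.2f}, p = {p.p:.3f}, df = {p.df})",
            "",
            self.coupling.summary(),
        ]
        cell = self.coupling_expected.cell(self.config.alpha_freq, "negative")
        lines.append("")
        lines.append(
            f"expected-trial coupling at {self.config.alpha_freq:g} Hz x "
            f"negative peak (uncorrected): T = {cell.t:.2f}, p = {cell.p:.4f}")
        return "\n".join(lines)


def _paired(name: str, expected: np.ndarray,
            unexpected: np.ndarray) -> PairedContrast:
    res = stats.ttest_rel(unexpected, expected)
    return PairedContrast(name, float(np.mean(expected)),
                          float(np.mean(unexpected)), float(res.statistic),
                          expected.size - 1, float(res.pvalue))


def analyze_cohort(blocks, cfg: AnalysisConfig | None = None) -> CohortResults:
    """Run the full group analysis over an iterable of blocks.

    Blocks are consumed one at a time; only reduced features are retained, so
    a full cohort fits comfortably in memory.
    """
    cfg = cfg or AnalysisConfig()
    features = [b if isinstance(b, BlockFeatures)
                else extract_block_features(b, cfg) for b in blocks]
    if not features:
        raise ValueError("no blocks to analyze")

    # grand-average power, collapsed over units and conditions
    all_power = [f.power[c] for f in features for c in CONDITIONS]
    grand_power = spectral.grand_average_power(all_power)
    power_peaks = {f: spectral.find_peak_time(grand_power, f,
                                              cfg.power_peak_window_ms)
                   for f in grand_power.freqs}

    # grand-average ERP, collapsed over units and conditions
    grand_erp = erpmod.grand_average_erp(
        [f.erp[c] for f in features for c in CONDITIONS])
    erp_peaks = erpmod.find_erp_peaks(grand_erp, cfg.negative_window_ms,
                                      cfg.positive_window_ms)

    sp_rows, erp_rows, st_rows = [], [], []
    for f in features:
        for cond in CONDITIONS:
            peaks_power = spectral.subject_peak_power(
                {cond: f.power[cond]}, power_peaks[cfg.alpha_freq])[cond]
            sp_rows.append({"unit": f.unit, "condition": cond,
                            "frequency": cfg.alpha_freq,
                            "power": peaks_power})
            amp = erpmod.subject_peak_amplitude({cond: f.erp[cond]},
                                                erp_peaks)[cond]
            erp_rows.append({"unit": f.unit, "condition": cond,
                             "neg_amp": amp[0], "pos_amp": amp[1]})
        listener_amp = {
            "negative": f.erp_traces[:, erp_peaks.negative.peak_sample],
            "positive": f.erp_traces[:, erp_peaks.positive.peak_sample]}
        for j, freq in enumerate(f.freqs):
            sp_power = np.abs(f.trial_coeffs[:, power_peaks[freq].peak_sample,
                                             j])
            for pk in ("negative", "positive"):
                for tr in range(f.conditions.size):
                    st_rows.append({
                        "unit": f.unit, "trial": tr,
                        "condition": f.conditions[tr], "frequency": freq,
                        "peak": pk, "speaker_power": sp_power[tr],
                        "listener_amp": listener_amp[pk][tr]})

    subject_power = pd.DataFrame(sp_rows)
    subject_erp = pd.DataFrame(erp_rows)
    single_trial = pd.DataFrame(st_rows)

    def pivot(frame, col):
        w = frame.pivot(index="unit", columns="condition", values=col)
        return w["expected"].to_numpy(), w["unexpected"].to_numpy()

    a_e, a_u = pivot(subject_power, "power")
    n_e, n_u = pivot(subject_erp, "neg_amp")
    p_e, p_u = pivot(subject_erp, "pos_amp")
    alpha_contrast = _paired("alpha_peak_power", a_e, a_u)
    n400_contrast = _paired("negative_peak_amplitude", n_e, n_u)
    p600_contrast = _paired("positive_peak_amplitude", p_e, p_u)
    pct = spectral.percent_reduction(float(a_e.mean()), float(a_u.mean()))

    model = InterBrainCoupling.from_dataframe(single_trial)
    coupling = model.fit(condition="unexpected", alpha=cfg.alpha_level,
                         alternative=cfg.alternative,
                         min_trials=cfg.min_trials)
    coupling_expected = model.fit(condition="expected", alpha=cfg.alpha_level,
                                  alternative=cfg.alternative,
                                  min_trials=max(3, cfg.min_trials // 2),
                                  correct=False)

    reports = {f.unit: f.reports for f in features}
    return CohortResults(cfg, power_peaks, erp_peaks, subject_power,
                         subject_erp, single_trial, alpha_contrast,
                         n400_contrast, p600_contrast, pct, coupling,
                         coupling_expected, reports)
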