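"""Single-trial inter-brain coupling: the core inference of the pipeline.

For every speaker-listener role assignment (the analysis unit; a dyad
contributes two, one per block) the speaker's single-trial wavelet amplitude
at the preparatory peak is correlated with the listener's single-trial ERP
amplitude at the word-locked peak, across the kept trials of one condition.
The per-unit Pearson r values are Fisher z-transformed (z = atanh r) and a
one-sample t-test asks whether the population mean z differs from zero.  The
full family is 6 frequencies x 2 ERP peaks = 12 tests, corrected with the
Holm-Bonferroni step-down at alpha = 0.05.

The module exposes both the elementary operations and a statsmodels-style
model: build :class:`InterBrainCoupling` from a tidy single-trial table, call
``fit()``, and read estimates, tests and the Holm decisions off the returned
:class:`CouplingResults` (``summary()`` prints the 12-cell family table).

Two-sided p-values are the default for the family; the direction of interest
(mean z > 0) can be requested via ``alternative="greater"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .spectral import PeakDef, WaveletCube

log = logging.getLogger(__name__)

PEAK_KINDS = ("negative", "positive")


# ---------------------------------------------------------------------------
# elementary operations

def speaker_single_trial_power(cube: WaveletCube, electrodes,
                               peak: PeakDef, frequency: float) -> np.ndarray:
    """|mean over electrodes of the complex coefficient| per trial.

    The electrode mean is taken on the *complex* coefficients before the
    modulus (phase cancellation across electrodes is intended and distinct
    from averaging moduli).  Unkept trials return NaN, preserving indices.
    """
    electrodes = list(electrodes)
    if not electrodes:
        raise ValueError("empty electrode set")
    idx = cube.channel_indices(electrodes)
    j = cube.freq_index(frequency)
    vals = np.abs(cube.coeffs[:, idx, peak.peak_sample, j].mean(axis=1))
    vals = vals.astype(float)
    vals[~cube.keep_mask] = np.nan
    return vals


def fisher_z(r: float) -> float:
    """Variance-stabilizing transform z = atanh(r) = 0.5 ln((1+r)/(1-r))."""
    if abs(r) >= 1.0:
        raise ValueError("|r| must be < 1 for the Fisher transform")
    return math.atanh(r)


@dataclass
class PairCoupling:
    """One unit's correlation in one family cell."""

    unit: object
    frequency: float
    peak_kind: str
    condition: str
    n_trials: int
    r: float
    z: float


def pair_correlation(speaker_amps: np.ndarray, listener_amps: np.ndarray,
                     conditions: np.ndarray | None = None,
                     condition_filter: str | None = None,
                     min_trials: int = 3, *, unit=None,
                     frequency: float = np.nan,
                     peak_kind: str = "") -> PairCoupling:
    """Pearson r (and Fisher z) over the common valid trials of one condition.

    Inputs are aligned per-trial vectors with NaN at rejected trials; a trial
    enters only if both members have it.  Zero variance in either vector
    makes r undefined (returned as NaN with a warning); |r| = 1 has no finite
    z and raises.
    """
    a = np.asarray(speaker_amps, dtype=float)
    b = np.asarray(listener_amps, dtype=float)
    if a.shape != b.shape:
        raise ValueError("speaker and listener trial vectors differ in length")
    sel = ~(np.isnan(a) | np.isnan(b))
    if conditions is not None and condition_filter is not None:
        sel &= np.asarray(conditions) == condition_filter
    n = int(sel.sum())
    if n < max(min_trials, 3):
        raise ValueError(f"only {n} common trials; need >= {max(min_trials, 3)}")
    x, y = a[sel], b[sel]
    if x.std() == 0 or y.std() == 0:
        log.warning("zero variance in a trial vector; correlation undefined")
        return PairCoupling(unit, frequency, peak_kind,
                            condition_filter or "all", n, np.nan, np.nan)
    r = float(np.corrcoef(x, y)[0, 1])
    if 1.0 - abs(r) < 1e-12:
        raise ValueError("|r| = 1: Fisher z is infinite; inputs are "
                         "perfectly collinear")
    return PairCoupling(unit, frequency, peak_kind, condition_filter or "all",
                        n, r, fisher_z(r))


@dataclass
class GroupTestResult:
    """One-sample t-test of per-unit Fisher z values against zero."""

    frequency: float
    peak_kind: str
    n_units: int
    mean_z: float
    sd_z: float
    t: float
    df: int
    p: float
    holm_significant: bool = False
    family_size: int = 12


def group_onesample_test(z_values, alternative: str = "two-sided",
                         frequency: float = np.nan,
                         peak_kind: str = "") -> GroupTestResult:
    """One-sample t of the per-unit z values against zero (df = n - 1)."""
    z = np.asarray(z_values, dtype=float)
    z = z[~np.isnan(z)]
    n = z.size
    if n < 2:
        raise ValueError("need at least 2 units for the group test")
    sd = z.std(ddof=1)
    if sd == 0:
        if z.mean() == 0.0:
            # all units exactly at the null: t = 0/0 resolved as no evidence
            return GroupTestResult(frequency, peak_kind, n, 0.0, 0.0, 0.0,
                                   n - 1, 1.0)
        raise ValueError("zero variance across units with nonzero mean; "
                         "t undefined")
    res = stats.ttest_1samp(z, 0.0, alternative=alternative)
    return GroupTestResult(frequency, peak_kind, n, float(z.mean()),
                           float(sd), float(res.statistic), n - 1,
                           float(res.pvalue))


def holm_thresholds(m: int, alpha: float = 0.05) -> np.ndarray:
    """Step-down thresholds alpha/(m - k) for the k-th smallest p (k=0..)."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return alpha / (m - np.arange(m))


def holm_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Step-down Holm correction; returns a boolean flag per input p-value.

    The k-th smallest p is significant iff every j <= k satisfies
    p_(j) < alpha / (m - j + 1); the step-down stops at the first failure.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for k, idx in enumerate(order):
        if p[idx] < alpha / (m - k):
            flags[idx] = True
        else:
            break
    return flags


# ---------------------------------------------------------------------------
# model / results

class InterBrainCoupling:
    """Group-level inter-brain coupling model over a single-trial table.

    Parameters
    ----------
    data : pandas.DataFrame
        Tidy single-trial table with one row per
        (unit, trial, frequency, peak) cell and columns ``unit``, ``trial``,
        ``condition``, ``frequency``, ``peak`` ("negative"/"positive"),
        ``speaker_power`` and ``listener_amp``.  Rejected trials carry NaN.
    frequencies, peaks : sequences, optional
        The family layout; defaults to the frequencies present in the data
        and both peak kinds.

    Examples
    --------
    >>> model = InterBrainCoupling.from_dataframe(table)   # doctest: +SKIP
    >>> res = model.fit(condition="unexpected")            # doctest: +SKIP
    >>> print(res.summary())                               # doctest: +SKIP
    """

    REQUIRED = ("unit", "trial", "condition", "frequency", "peak",
                "speaker_power", "listener_amp")

    def __init__(self, data: pd.DataFrame, frequencies=None, peaks=PEAK_KINDS):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"single-trial table missing columns: {missing}")
        self.data = data
        self.frequencies = (tuple(sorted(data["frequency"].unique()))
                            if frequencies is None else tuple(frequencies))
        self.peaks = tuple(peaks)
        self.units = tuple(pd.unique(data["unit"]))

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kw) -> "InterBrainCoupling":
        return cls(data, **kw)

    @property
    def family_size(self) -> int:
        return len(self.frequencies) * len(self.peaks)

    def fit(self, condition: str = "unexpected", alpha: float = 0.05,
            alternative: str = "two-sided", min_trials: int = 10,
            correct: bool = True) -> "CouplingResults":
        """Estimate per-unit correlations and run the corrected family.

        Units with undefined r (zero variance) are dropped from the affected
        cell's group test with a logged count; every cell must retain at
        least two units.
        """
        rows = []
        for (unit, f, pk), g in self.data.groupby(["unit", "frequency", "peak"],
                                                  sort=False):
            if f not in self.frequencies or pk not in self.peaks:
                continue
            g = g.sort_values("trial")
            try:
                pc = pair_correlation(
                    g["speaker_power"].to_numpy(),
                    g["listener_amp"].to_numpy(),
                    g["condition"].to_numpy(), condition,
                    min_trials=min_trials, unit=unit, frequency=f,
                    peak_kind=pk)
            except ValueError as err:
                raise ValueError(f"unit {unit!r}, {f} Hz, {pk} peak: {err}"
                                 ) from err
            rows.append(pc)
        pair_table = pd.DataFrame([vars(pc) for pc in rows])
        if pair_table.empty:
            raise ValueError("no family cells could be computed")

        missing_cells = [(f, pk) for f in self.frequencies for pk in self.peaks
                         if pair_table[(pair_table.frequency == f) &
                                       (pair_table.peak_kind == pk)].empty]
        if missing_cells:
            raise ValueError(f"family cells missing entirely: {missing_cells}")

        tests = []
        for f in self.frequencies:
            for pk in self.peaks:
                cell = pair_table[(pair_table.frequency == f) &
                                  (pair_table.peak_kind == pk)]
                z = cell["z"].to_numpy()
                n_dropped = int(np.isnan(z).sum())
                if n_dropped:
                    log.warning("%s Hz / %s peak: %d unit(s) with undefined r "
                                "dropped", f, pk, n_dropped)
                tests.append(group_onesample_test(z, alternative,
                                                  frequency=f, peak_kind=pk))
        if correct:
            flags = holm_bonferroni([t.p for t in tests], alpha)
            for t, fl in zip(tests, flags):
                t.holm_significant = bool(fl)
                t.family_size = len(tests)
        else:
            for t in tests:
                t.family_size = 1
        return CouplingResults(self, condition, alpha, alternative,
                               min_trials, pair_table, tests,
                               corrected=correct)


@dataclass
class CouplingResults:
    """Fitted inter-brain coupling family.

    ``pair_table`` holds one row per (unit, frequency, peak) with n, r, z;
    ``tests`` the 12 group tests in (frequency-major, negative-first) order.
    """

    model: InterBrainCoupling
    condition: str
    alpha: float
    alternative: str
    min_trials: int
    pair_table: pd.DataFrame
    tests: list[GroupTestResult]
    corrected: bool = True

    def family_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.tests])

    def cell(self, frequency: float, peak_kind: str) -> GroupTestResult:
        for t in self.tests:
            if t.frequency == frequency and t.peak_kind == peak_kind:
                return t
        raise KeyError(f"no cell ({frequency} Hz, {peak_kind})")

    def mean_r(self, frequency: float, peak_kind: str) -> float:
        cell = self.pair_table[(self.pair_table.frequency == frequency) &
                               (self.pair_table.peak_kind == peak_kind)]
        return float(cell["r"].mean())

    @property
    def n_significant(self) -> int:
        return sum(t.holm_significant for t in self.tests)

    def summary(self) -> str:
        """Family table in the conventional layout: rows = frequency,
        columns = Min./Max. ERP peak p-values, '*' = Holm-significant."""
        lines = [
            "Inter-brain coupling: one-sample t-tests on Fisher z "
            f"({self.condition} trials)",
            f"units = {len(self.model.units)}, alternative = "
            f"{self.alternative}, "
            + (f"Holm-Bonferroni over {len(self.tests)} tests at alpha = "
               f"{self.alpha}" if self.corrected else "uncorrected"),
            "",
            f"{'Speaker':>8}  {'Min. ERP peak':>16}  {'Max. ERP peak':>16}",
        ]
        for f in self.model.frequencies:
            cells = []
            for pk in ("negative", "positive"):
                t = self.cell(f, pk)
                cells.append(f"{t.p:.4f}{'*' if t.holm_significant else ' '}")
            lines.append(f"{f:>6g}Hz  {cells[0]:>16}  {cells[1]:>16}")
        lines.append("")
        for pk, label in (("negative", "negative (N400-range)"),
                          ("positive", "positive (P600-range)")):
            for f in self.model.frequencies:
                t = self.cell(f, pk)
                if t.holm_significant:
                    lines.append(
                        f"  {f:g} Hz x {label} peak: mean z = {t.mean_z:.4f} "
                        f"(mean r = {self.mean_r(f, pk):.4f}), "
                        f"T = {t.t:.2f}, df = {t.df}, p = {t.p:.4f}")
        return "\n".join(lines)

    def plot(self, frequency: float = 8.0, peak_kind: str = "negative",
             ax=None):
        """Box/strip plot of the per-unit correlations in one family cell."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(3, 4))
        cell = self.pair_table[(self.pair_table.frequency == frequency) &
                               (self.pair_table.peak_kind == peak_kind)]
        r = cell["r"].dropna().to_numpy()
        ax.boxplot(r, tick_labels=[f"{frequency:g} Hz / {peak_kind}"])
        ax.scatter(np.ones_like(r) + 0.08, r, s=12, alpha=0.7)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_ylabel("per-unit Pearson r")
        return ax
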