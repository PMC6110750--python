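"""In-memory containers shared across the pipeline.

A :class:`Recording` is a continuous multichannel EEG record in microvolts
with a per-sample validity mask (``False`` marks samples lost in transmission,
e.g. dropped Bluetooth packets).  An :class:`EventTable` holds the per-trial
trigger samples (prompt, sentence, go, spoken-word onset) plus the condition
label, and an :class:`EpochSet` is the trials x channels x samples cube cut
around a lock event on the half-open window [-200, 1000) ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONDITIONS = ("expected", "unexpected")

#: Epoch window in ms, half-open.  At 500 Hz this is exactly 600 samples with
#: the lock event at t = 0 included.
EPOCH_WINDOW_MS = (-200.0, 1000.0)


@dataclass
class Recording:
    """Continuous EEG: channels x time in microvolts."""

    data: np.ndarray                  # (n_channels, n_samples) float
    sfreq: float                      # Hz
    channels: list[str]
    validity_mask: np.ndarray | None = None   # (n_samples,) bool, False = lost
    role: str | None = None           # "speaker" | "listener"
    pair_id: int | None = None
    block_id: int | None = None
    subject_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel label count does not match data rows")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.validity_mask is None:
            self.validity_mask = np.ones(self.data.shape[1], dtype=bool)
        else:
            self.validity_mask = np.asarray(self.validity_mask, dtype=bool)
            if self.validity_mask.shape != (self.data.shape[1],):
                raise ValueError("validity_mask length must equal n_samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def index_of(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"channel {channel!r} not in recording") from None

    def copy(self) -> "Recording":
        return replace(
            self,
            data=self.data.copy(),
            channels=list(self.channels),
            validity_mask=self.validity_mask.copy(),
            meta=dict(self.meta),
        )


@dataclass
class EventTable:
    """Per-trial trigger samples (0-based) and condition labels."""

    frame: pd.DataFrame   # columns: trial, condition, prompt_onset,
                          # sentence_onset, go_onset, word_onset

    REQUIRED = ("trial", "condition", "prompt_onset", "sentence_onset",
                "go_onset", "word_onset")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        f = self.frame
        onsets = f[["prompt_onset", "sentence_onset", "go_onset", "word_onset"]]
        if not (onsets.diff(axis=1).iloc[:, 1:] > 0).all().all():
            raise ValueError("trigger samples must be strictly increasing "
                             "within each trial")
        bad = set(f["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def conditions(self) -> np.ndarray:
        return self.frame["condition"].to_numpy()

    def onsets(self, lock: str) -> np.ndarray:
        col = f"{lock}_onset" if not lock.endswith("_onset") else lock
        if col not in self.frame.columns:
            raise KeyError(f"unknown lock event {lock!r}")
        return self.frame[col].to_numpy(dtype=int)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_csv(cls, path) -> "EventTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class EpochSet:
    """Event-locked trials x channels x samples cube."""

    data: np.ndarray                 # (n_trials, n_channels, n_samples), uV
    sfreq: float
    channels: list[str]
    conditions: np.ndarray           # (n_trials,) str
    keep_mask: np.ndarray            # (n_trials,) bool
    window_ms: tuple[float, float] = EPOCH_WINDOW_MS
    lock_event: str = ""
    baseline_ms: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.conditions = np.asarray(self.conditions)
        self.keep_mask = np.asarray(self.keep_mask, dtype=bool)
        n_tr, n_ch, n_s = self.data.shape
        if len(self.channels) != n_ch:
            raise ValueError("channel labels do not match data")
        if self.conditions.shape != (n_tr,) or self.keep_mask.shape != (n_tr,):
            raise ValueError("conditions/keep_mask must have one entry per trial")
        expect = round((self.window_ms[1] - self.window_ms[0]) / 1000 * self.sfreq)
        if n_s != expect:
            raise ValueError(
                f"epoch has {n_s} samples; window {self.window_ms} at "
                f"{self.sfreq} Hz requires {expect}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Time of each sample in ms relative to the lock event."""
        step = 1000.0 / self.sfreq
        return self.window_ms[0] + step * np.arange(self.n_samples)

    def sample_at(self, time_ms: float) -> int:
        """Index of the sample at `time_ms` (nearest, within the window)."""
        lo, hi = self.window_ms
        if not (lo <= time_ms < hi):
            raise ValueError(f"{time_ms} ms outside epoch window {self.window_ms}")
        return int(round((time_ms - lo) / 1000.0 * self.sfreq))

    def kept(self, condition: str | None = None) -> np.ndarray:
        """Boolean trial selector: kept trials, optionally of one condition."""
        sel = self.keep_mask.copy()
        if condition is not None:
            sel &= self.conditions == condition
        return sel

    def channel_indices(self, names) -> np.ndarray:
        missing = [ch for ch in names if ch not in self.channels]
        if missing:
            raise KeyError(f"channel(s) not in epochs: {missing}")
        return np.array([self.channels.index(ch) for ch in names])

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            channels=list(self.channels),
            conditions=self.conditions.copy(),
            keep_mask=self.keep_mask.copy(),
            meta=dict(self.meta),
        )
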