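"""24-channel 10-20 montage used by the synthetic dyad recordings.

The channel set mirrors a 24-electrode mobile EEG cap: the classic 10-20
positions plus CPz and Pz, linked-mastoid reference electrodes M1/M2, and the
label ``PO2``.  ``PO2`` is not a standard 10-20/10-05 label; this montage
defines its scalp position as the normalized midpoint of POz and PO4.  All
positions are unit vectors on a best-fit sphere centred inside the head, which
is the geometry the spherical-spline interpolation operates on.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np

#: Default montage, in cap order.  Parietal and central-parietal analysis sets
#: are subsets of these labels.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "CPz", "P7", "P3", "Pz", "P4", "P8",
    "PO2", "O1", "Oz", "O2", "M1", "M2",
)

#: Mastoid reference pair.
MASTOIDS: tuple[str, str] = ("M1", "M2")

#: Parietal electrodes over which speaker alpha power is averaged.
PARIETAL: tuple[str, ...] = ("P7", "P3", "Pz", "PO2", "P4", "P8")

#: Central-parietal electrodes over which listener ERPs are averaged.
CENTRAL_PARIETAL: tuple[str, ...] = (
    "P7", "P3", "Pz", "PO2", "P4", "P8", "CPz", "C3", "Cz", "C4",
)


@lru_cache(maxsize=1)
def _standard_positions() -> dict[str, np.ndarray]:
    """Raw 3-D electrode positions (metres, head frame) from the 10-05 set."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = mne.channels.make_standard_montage("standard_1005")
    pos = m.get_positions()["ch_pos"]
    return {k: np.asarray(v, dtype=float) for k, v in pos.items()}


@lru_cache(maxsize=1)
def channel_positions() -> dict[str, np.ndarray]:
    """Unit-sphere positions for every channel in :data:`DEFAULT_CHANNELS`.

    A sphere is least-squares fitted to the standard electrode cloud; each
    electrode is then projected radially onto that sphere.  PO2 is synthesised
    from POz/PO4 as documented in the module docstring.
    """
    std = _standard_positions()
    labels = [ch for ch in DEFAULT_CHANNELS if ch != "PO2"] + ["POz", "PO4"]
    xyz = np.array([std[ch] for ch in labels])

    # Algebraic sphere fit: |p - c|^2 = r^2  =>  2 p.c + (r^2 - |c|^2) = |p|^2
    A = np.hstack([2 * xyz, np.ones((len(xyz), 1))])
    b = (xyz**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]

    def unit(p: np.ndarray) -> np.ndarray:
        v = p - center
        return v / np.linalg.norm(v)

    out = {ch: unit(std[ch]) for ch in DEFAULT_CHANNELS if ch != "PO2"}
    po2 = unit(std["POz"]) + unit(std["PO4"])
    out["PO2"] = po2 / np.linalg.norm(po2)
    return out


def positions_for(channels) -> np.ndarray:
    """Stack unit-sphere positions for `channels` into an (n, 3) array."""
    table = channel_positions()
    missing = [ch for ch in channels if ch not in table]
    if missing:
        raise KeyError(f"no montage position for channel(s): {missing}")
    return np.array([table[ch] for ch in channels])
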