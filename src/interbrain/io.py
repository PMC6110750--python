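"""Reading and writing datasets on disk.

A simulated cohort is laid out as one EDF file per subject per block plus
plain-text sidecars: a tab-separated event table (0-based sample indices), a
lost-packet table (invalid sample spans, half-open), the per-block ground
truth, and a ``dataset.json`` with the generator configuration and the
role-assignment index.  External recordings in EDF or BrainVision format can
be loaded through MNE into the same :class:`~interbrain.containers.Recording`
container.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import edf as edfmod
from .containers import EventTable, Recording
from .simulate import BlockSession, GroundTruth, SimConfig


def _mask_to_spans(mask: np.ndarray) -> list[tuple[int, int]]:
    """Invalid (False) runs of the validity mask as half-open spans."""
    invalid = ~np.asarray(mask, dtype=bool)
    edges = np.flatnonzero(np.diff(np.r_[0, invalid.astype(int), 0]))
    return [(int(edges[i]), int(edges[i + 1]))
            for i in range(0, edges.size, 2)]


def _spans_to_mask(spans, n: int) -> np.ndarray:
    mask = np.ones(n, dtype=bool)
    for a, b in spans:
        mask[a:b] = False
    return mask


def _stem(pair_id: int, block_id: int) -> str:
    return f"pair{pair_id:02d}_block{block_id}"


def write_block(outdir: Path, block: BlockSession) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = _stem(block.pair_id, block.block_id)
    for role in ("speaker", "listener"):
        rec: Recording = getattr(block, role)
        edfmod.write_edf(outdir / f"{stem}_{role}.edf", rec.data, rec.sfreq,
                         rec.channels, patient_id=rec.subject_id or "X",
                         recording_id=f"{stem} {role}")
        pd.DataFrame(_mask_to_spans(rec.validity_mask),
                     columns=["start", "stop"]).to_csv(
            outdir / f"{stem}_{role}_lost.tsv", sep="\t", index=False)
    block.events.to_csv(outdir / f"{stem}_events.tsv")
    block.ground_truth.to_csv(outdir / f"{stem}_groundtruth.tsv")
    meta = {"pair_id": block.pair_id, "block_id": block.block_id,
            "speaker_subject": block.speaker_subject,
            "listener_subject": block.listener_subject,
            "n_samples": int(block.speaker.n_samples),
            "sfreq": block.speaker.sfreq}
    (outdir / f"{stem}_meta.json").write_text(json.dumps(meta, indent=1))


def read_block(outdir: Path, pair_id: int, block_id: int) -> BlockSession:
    outdir = Path(outdir)
    stem = _stem(pair_id, block_id)
    meta = json.loads((outdir / f"{stem}_meta.json").read_text())
    events = EventTable.from_csv(outdir / f"{stem}_events.tsv")
    gt = GroundTruth.from_csv(outdir / f"{stem}_groundtruth.tsv")
    recs = {}
    for role in ("speaker", "listener"):
        data, sfreq, labels = edfmod.read_edf(outdir / f"{stem}_{role}.edf",
                                              n_samples=meta["n_samples"])
        spans = pd.read_csv(outdir / f"{stem}_{role}_lost.tsv", sep="\t")
        mask = _spans_to_mask(spans.to_numpy(), data.shape[1])
        subj = meta[f"{role}_subject"]
        recs[role] = Recording(data, sfreq, labels, validity_mask=mask,
                               role=role, pair_id=pair_id, block_id=block_id,
                               subject_id=subj)
    return BlockSession(recs["speaker"], recs["listener"], events, gt,
                        pair_id=pair_id, block_id=block_id,
                        speaker_subject=meta["speaker_subject"],
                        listener_subject=meta["listener_subject"])


def write_dataset(outdir: Path, config: SimConfig, master_seed: int,
                  blocks) -> None:
    """Write an iterable of blocks plus the dataset index."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index = []
    for block in blocks:
        write_block(outdir, block)
        index.append({"pair_id": block.pair_id, "block_id": block.block_id})
    (outdir / "dataset.json").write_text(json.dumps(
        {"master_seed": master_seed, "config": config.to_dict(),
         "blocks": index}, indent=1))


def dataset_index(outdir: Path) -> dict:
    path = Path(outdir) / "dataset.json"
    if not path.exists():
        raise FileNotFoundError(f"no dataset.json under {outdir}")
    return json.loads(path.read_text())


def iter_dataset(outdir: Path):
    """Yield BlockSessions of a written dataset, one at a time."""
    for entry in dataset_index(outdir)["blocks"]:
        yield read_block(outdir, entry["pair_id"], entry["block_id"])


def read_raw(path, role: str | None = None) -> Recording:
    """Load an external EDF or BrainVision recording via MNE."""
    import warnings

    import mne

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if path.suffix.lower() == ".edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        elif path.suffix.lower() == ".vhdr":
            raw = mne.io.read_raw_brainvision(path, preload=True,
                                              verbose="error")
        else:
            raise ValueError(f"unsupported raw format: {path.suffix}")
    data = raw.get_data() * 1e6          # MNE uses volts internally
    return Recording(data, raw.info["sfreq"], list(raw.ch_names), role=role)
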