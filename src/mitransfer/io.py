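"""Pool serialization: epochs in an HDF5 container with a JSON metadata
sidecar (one entry per subject/condition block)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .synthetic import EpochSet


def _key(subject_id: int, condition: str) -> str:
    return f"subject_{subject_id:03d}/{condition}"


def save_pool(path, pool: dict) -> None:
    """Write {subject_id: {condition: EpochSet}} to `path` (.h5) plus a
    `<path>.json` sidecar holding the per-block metadata."""
    path = Path(path)
    meta = []
    with h5py.File(path, "w") as f:
        for sid, conds in pool.items():
            for cond, eset in conds.items():
                g = f.create_group(_key(sid, cond))
                g.create_dataset("data", data=eset.data, compression="gzip",
                                 compression_opts=1)
                g.create_dataset("labels", data=np.asarray(eset.labels))
                g.attrs.update(sfreq=eset.sfreq, t0=eset.t0,
                               condition=cond, modality=eset.modality,
                               subject_id=sid)
                meta.append({"subject_id": int(sid), "condition": cond,
                             "modality": eset.modality,
                             "sfreq": float(eset.sfreq), "t0": float(eset.t0),
                             "n_epochs": int(eset.n_epochs),
                             "n_channels": int(eset.n_channels),
                             "n_samples": int(eset.n_samples)})
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2))


def load_pool(path) -> dict:
    pool: dict = {}
    with h5py.File(path, "r") as f:
        for skey in sorted(f):
            for cond in f[skey]:
                g = f[skey][cond]
                eset = EpochSet(data=g["data"][()], labels=g["labels"][()],
                                condition=g.attrs["condition"],
                                modality=g.attrs["modality"],
                                subject_id=int(g.attrs["subject_id"]),
                                sfreq=float(g.attrs["sfreq"]),
                                t0=float(g.attrs["t0"]))
                pool.setdefault(eset.subject_id, {})[cond] = eset
    return pool
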