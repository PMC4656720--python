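"""Checkpointing and trial-log export.

Checkpoints store the affordance-map weights, every learned and fixed
premotor weight matrix, stage/epoch counters and the full RNG substream
states in HDF5, so a restored model continues bit-identically to an
uninterrupted run.  Trial logs export to HDF5 (activity arrays) plus a
tidy CSV summary.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence

import h5py
import numpy as np
import pandas as pd

from .config import ModelConfig
from .training import GraspModel, TrialRecord

FORMAT_VERSION = 1


class CheckpointError(RuntimeError):
    pass


def checkpoint(model: GraspModel, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["config"] = json.dumps(model.config.to_dict(), sort_keys=True)
        f.attrs["trial_count"] = model.trial_count
        f.attrs["stages_done"] = json.dumps(model.stages_done)
        f.attrs["som_epoch"] = model.som.epoch
        f.attrs["rng_state"] = json.dumps(model.rng.state())
        f.create_dataset("som/weights", data=model.som.weights,
                         compression="gzip")
        g = f.create_group("premotor")
        for name, w in model.premotor.learned.items():
            g.create_dataset(name, data=w, compression="gzip")


def restore(path: str | Path, config: ModelConfig | None = None) -> GraspModel:
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("format_version", -1))
            if version != FORMAT_VERSION:
                raise CheckpointError(
                    f"checkpoint format {version} unsupported "
                    f"(expected {FORMAT_VERSION})")
            cfg = config or ModelConfig.model_validate(
                json.loads(f.attrs["config"]))
            model = GraspModel(cfg)
            model.som.weights[...] = f["som/weights"][...]
            model.som.epoch = int(f.attrs["som_epoch"])
            model.trial_count = int(f.attrs["trial_count"])
            model.stages_done = list(json.loads(f.attrs["stages_done"]))
            for name, w in model.premotor.learned.items():
                w[...] = f["premotor"][name][...]
            model.rng.set_state(json.loads(f.attrs["rng_state"]))
    except (OSError, KeyError) as exc:
        raise CheckpointError(f"unreadable checkpoint {path}: {exc}") from exc
    return model


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "trial": r.trial, "stage": r.stage, "shape": r.object["shape"],
            "novel": r.novel, "decoded": r.decoded,
            "palm_contact": r.palm_contact, "success": r.success,
            "rs": r.rs, "rs_sum": r.rs_sum,
            "vf": r.plan.vf_combination if r.plan else "",
            "aperture": r.plan.max_aperture if r.plan else np.nan,
        })
    return pd.DataFrame(rows)


def save_log(records: Sequence[TrialRecord], h5_path: str | Path,
             csv_path: str | Path | None = None) -> None:
    h5_path = Path(h5_path)
    h5_path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(h5_path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.create_dataset("aip", data=np.stack([r.aip for r in records]),
                         compression="gzip")
        meta = records_to_frame(records)
        for col in meta.columns:
            data = meta[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            f.create_dataset(f"meta/{col}", data=data)
        objs = json.dumps([r.object for r in records])
        f.attrs["objects"] = objs
    if csv_path is not None:
        records_to_frame(records).to_csv(csv_path, index=False)


def load_log(h5_path: str | Path) -> List[TrialRecord]:
    with h5py.File(h5_path, "r") as f:
        aip = f["aip"][...]
        meta = {k: f[f"meta/{k}"][...] for k in f["meta"]}
        objects = json.loads(f.attrs["objects"])
    records = []
    for i in range(len(objects)):
        records.append(TrialRecord(
            trial=int(meta["trial"][i]),
            stage=meta["stage"][i].decode(),
            object=objects[i], novel=bool(meta["novel"][i]),
            aip=aip[i], plan=None,
            palm_contact=bool(meta["palm_contact"][i]),
            success=bool(meta["success"][i]), rs=float(meta["rs"][i]),
            rs_sum=float(meta["rs_sum"][i]),
            decoded=bool(meta["decoded"][i])))
    return records
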