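"""Plain-file readers and writers for the pipeline's data products.

BOLD: TSV (header = region labels, one row per volume) + JSON sidecar.
EEG: HDF5 (channels x samples) + JSON sidecar, or TSV for small arrays.
Intensity, partitions and receptor maps: 2-column TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    EEGRecording,
    IntensityTrace,
    NetworkPartition,
    ParcelTimeSeries,
    ReceptorMap,
)


def write_bold(ts: ParcelTimeSeries, path) -> None:
    path = Path(path)
    pd.DataFrame(ts.data, columns=ts.region_labels).to_csv(path, sep="\t", index=False)
    sidecar = {
        "tr_seconds": ts.tr_seconds, "subject": ts.subject,
        "condition": ts.condition, "injection_index": int(ts.injection_index),
        "censor_mask": ts.censor_mask.astype(int).tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_bold(path) -> ParcelTimeSeries:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    return ParcelTimeSeries(
        data=frame.to_numpy(), tr_seconds=meta["tr_seconds"],
        region_labels=list(frame.columns), subject=meta["subject"],
        condition=meta["condition"], injection_index=meta["injection_index"],
        censor_mask=np.asarray(meta["censor_mask"], dtype=bool),
    )


def write_eeg(rec: EEGRecording, path) -> None:
    """HDF5 for .h5 paths, TSV otherwise (TSV is large; prefer .h5)."""
    path = Path(path)
    if path.suffix == ".h5":
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=rec.data, compression="gzip")
    else:
        np.savetxt(path, rec.data.T, delimiter="\t")
    sidecar = {
        "fs": rec.fs, "channel_names": rec.channel_names,
        "epoch_seconds": rec.epoch_seconds,
        "bad_epochs": sorted(int(e) for e in rec.bad_epochs),
        "midline_chain": list(rec.midline_chain),
        "injection_sample": int(rec.injection_sample),
        "subject": rec.subject, "condition": rec.condition,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_eeg(path) -> EEGRecording:
    path = Path(path)
    if path.suffix == ".h5":
        import h5py

        with h5py.File(path, "r") as f:
            data = f["data"][()]
    else:
        data = np.loadtxt(path, delimiter="\t").T
    meta = json.loads(path.with_suffix(".json").read_text())
    return EEGRecording(
        data=data, fs=meta["fs"], channel_names=meta["channel_names"],
        epoch_seconds=meta["epoch_seconds"], bad_epochs=set(meta["bad_epochs"]),
        midline_chain=tuple(meta["midline_chain"]),
        injection_sample=meta["injection_sample"],
        subject=meta["subject"], condition=meta["condition"],
    )


def write_intensity(trace: IntensityTrace, path) -> None:
    pd.DataFrame({"minute": trace.times, "rating": trace.ratings}).to_csv(
        path, sep="\t", index=False
    )


def read_intensity(path) -> IntensityTrace:
    frame = pd.read_csv(path, sep="\t")
    return IntensityTrace(frame["minute"].to_numpy(), frame["rating"].to_numpy())


def write_partition(part: NetworkPartition, path) -> None:
    pd.DataFrame({"region": part.region_labels, "network": part.networks}).to_csv(
        path, sep="\t", index=False
    )


def read_partition(path) -> NetworkPartition:
    frame = pd.read_csv(path, sep="\t")
    return NetworkPartition(frame["region"].tolist(), frame["network"].tolist())


def write_receptor_map(rmap: ReceptorMap, path) -> None:
    pd.DataFrame({"region": rmap.region_labels, "density": rmap.density}).to_csv(
        path, sep="\t", index=False
    )


def read_receptor_map(path) -> ReceptorMap:
    frame = pd.read_csv(path, sep="\t")
    return ReceptorMap(frame["region"].tolist(), frame["density"].to_numpy())
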