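"""Reading and writing the standard on-disk formats.

BOLD series and label volumes travel as NIfTI (via nibabel); LFP
recordings as HDF5 (channels x samples dataset with sampling-rate
attribute and a geometry table) with a CSV fallback; spike trains and
connectivity tables as CSV; protocols and generator configs as key=value
text files.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .core import LABELS, BoldSeries, LabelVolume, LfpRecording, SpikeTrain
from .protocols import StimulusProtocol


def _affine(voxel_size) -> np.ndarray:
    return np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])


def save_bold(series: BoldSeries, path: str | Path) -> None:
    img = nib.Nifti1Image(series.data.astype(np.float32), _affine(series.voxel_size))
    img.header["pixdim"][4] = series.tr_seconds
    nib.save(img, str(path))


def load_bold(path: str | Path) -> BoldSeries:
    img = nib.load(str(path))
    tr = float(img.header["pixdim"][4]) or 3.0
    vx = tuple(float(v) for v in img.header.get_zooms()[:3])
    return BoldSeries(np.asarray(img.dataobj, dtype=float), tr, vx)


def save_labels(vol: LabelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.labels.astype(np.int16), _affine(vol.voxel_size))
    nib.save(img, str(path))


def load_labels(path: str | Path, igm_depth_row: int = 0) -> LabelVolume:
    img = nib.load(str(path))
    vx = tuple(float(v) for v in img.header.get_zooms()[:3])
    return LabelVolume(np.asarray(img.dataobj, dtype=np.int16), vx, dict(LABELS),
                       igm_depth_row)


def save_lfp(rec: LfpRecording, path: str | Path) -> None:
    with h5py.File(str(path), "w") as f:
        d = f.create_dataset("voltages", data=rec.voltages.astype(np.float32))
        d.attrs["fs_hz"] = rec.fs_hz
        g = f.create_group("geometry")
        for col in rec.geometry.columns:
            g.create_dataset(col, data=rec.geometry[col].to_numpy())
        lab = f.create_group("labels")
        for ch, name in rec.labels.items():
            lab.attrs[str(ch)] = name


def load_lfp(path: str | Path) -> LfpRecording:
    with h5py.File(str(path), "r") as f:
        v = f["voltages"][...]
        fs = float(f["voltages"].attrs["fs_hz"])
        geom = pd.DataFrame({c: f["geometry"][c][...] for c in f["geometry"]})
        labels = {int(k): str(val) for k, val in f["labels"].attrs.items()}
    return LfpRecording(v, fs, geom, labels)


def save_lfp_csv(rec: LfpRecording, path: str | Path) -> None:
    """CSV fallback: one column per channel, sampling rate in the header."""
    df = pd.DataFrame(rec.voltages.T,
                      columns=[f"ch{c}" for c in rec.geometry["channel"]])
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={rec.fs_hz}\n")
        df.to_csv(fh, index=False)


def save_spikes(trains: list[SpikeTrain], path: str | Path) -> None:
    rows = [{"channel": t.channel, "timestamp_s": ts}
            for t in trains for ts in t.timestamps]
    pd.DataFrame(rows, columns=["channel", "timestamp_s"]).to_csv(path, index=False)


def load_spikes(path: str | Path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    return [SpikeTrain(np.sort(g["timestamp_s"].to_numpy()), channel=int(ch))
            for ch, g in df.groupby("channel")]


def save_protocol(protocol: StimulusProtocol, path: str | Path) -> None:
    Path(path).write_text(protocol.to_text())


def load_protocol(path: str | Path) -> StimulusProtocol:
    return StimulusProtocol.from_text(Path(path).read_text())


def save_config(cfg, path: str | Path) -> None:
    """Key=value dump of a generator config dataclass."""
    lines = []
    for f in dataclasses.fields(cfg):
        val = getattr(cfg, f.name)
        if isinstance(val, (tuple, list)):
            val = ",".join(str(v) for v in val)
        elif isinstance(val, dict):
            val = ";".join(f"{k}:{v}" for k, v in val.items())
        lines.append(f"{f.name}={val}")
    Path(path).write_text("\n".join(lines) + "\n")
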