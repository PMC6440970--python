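"""Core data containers shared across the fMRI and electrophysiology pipelines.

The package analyses two kinds of recordings from the cervical spinal cord:

* 4D BOLD image time series (axial slices through the cord, the gray-matter
  "butterfly" visible in-plane), together with an integer label volume that
  assigns every voxel to one anatomical compartment (dorsal horn, intermediate
  gray matter, ventral horn — each left/right — plus white matter, CSF and
  surrounding muscle).
* Multi-shank linear-array electrophysiology: local field potential (LFP)
  voltage series sampled at 500 Hz with contact geometry (depth below the
  dorsal surface), and spike timestamp trains.

All containers are plain dataclasses holding numpy arrays plus the metadata
the analysis operations need (sampling intervals, voxel sizes, geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Integer codes for the cord-phantom compartments.  Left/right refer to the
#: animal's left and right hemi-cord (columns of the in-plane grid).
LABELS: dict[str, int] = {
    "DH_L": 1,
    "DH_R": 2,
    "IGM_L": 3,
    "IGM_R": 4,
    "VH_L": 5,
    "VH_R": 6,
    "WM": 7,
    "CSF": 8,
    "MUSCLE": 9,
}

GRAY_MATTER = ("DH_L", "DH_R", "IGM_L", "IGM_R", "VH_L", "VH_R")


@dataclass
class LabelVolume:
    """Integer compartment map of the cord cross-section.

    Parameters
    ----------
    labels : ndarray, shape (ny, nx, n_slices)
        Integer label per voxel; values are those of :data:`LABELS`.
        Axis 0 runs dorsal (row 0) to ventral, axis 1 left to right,
        axis 2 along the cord (one slice per spinal segment).
    voxel_size : tuple of float
        Voxel dimensions in mm, default 0.25 x 0.25 x 3 mm (the upsampled
        in-plane resolution used for ROI analysis).
    label_dictionary : dict
        Name -> integer code mapping.
    igm_depth_row : int
        In-plane row index of the central canal / intermediate-gray-matter
        depth, used as the anatomical fallback when a functional
        intermediate-GM seed cannot be defined.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (0.25, 0.25, 3.0)
    label_dictionary: dict[str, int] = field(default_factory=lambda: dict(LABELS))
    igm_depth_row: int = 0

    @property
    def n_slices(self) -> int:
        return self.labels.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, *names: str) -> np.ndarray:
        """Boolean mask of the union of the named compartments."""
        codes = [self.label_dictionary[n] for n in names]
        return np.isin(self.labels, codes)

    def gm_mask(self) -> np.ndarray:
        return self.mask(*GRAY_MATTER)

    def noise_mask(self) -> np.ndarray:
        """Muscle + CSF voxels, the nuisance-PCA source compartments."""
        return self.mask("MUSCLE", "CSF")

    def validate(self) -> None:
        """Raise if the compartment invariants are violated."""
        for s in range(self.n_slices):
            sl = self.labels[:, :, s]
            for name in GRAY_MATTER:
                if not np.any(sl == self.label_dictionary[name]):
                    raise ValueError(f"compartment {name} empty on slice {s}")
        # left/right mirror symmetry of the gray matter compartments
        for left, right in (("DH_L", "DH_R"), ("IGM_L", "IGM_R"), ("VH_L", "VH_R")):
            lm = self.mask(left)
            rm = self.mask(right)
            if np.any(lm & rm):
                raise ValueError(f"{left}/{right} overlap")
            if abs(int(lm.sum()) - int(rm.sum())) > self.n_slices:
                raise ValueError(f"{left}/{right} not mirror symmetric")


@dataclass
class BoldSeries:
    """4D BOLD image time series.

    ``data`` has shape (ny, nx, n_slices, n_volumes); ``tr_seconds`` is the
    volume repetition time.  Operations in :mod:`cordfc.fmri` never introduce
    non-finite values into ``data``.
    """

    data: np.ndarray
    tr_seconds: float = 3.0
    voxel_size: tuple[float, float, float] = (0.25, 0.25, 3.0)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "BoldSeries":
        return BoldSeries(self.data.copy(), self.tr_seconds, self.voxel_size)


@dataclass
class MotionParams:
    """Per-slice, per-volume in-plane rigid alignment parameters.

    ``dx``, ``dy`` (voxels) and ``theta`` (degrees) have shape
    (n_slices, n_volumes) and hold the correction applied to each slice to
    align it with the reference volume (identity for the reference itself).
    """

    dx: np.ndarray
    dy: np.ndarray
    theta: np.ndarray
    reference_index: int = 0

    def as_design(self, slice_index: int, expand: bool = True) -> np.ndarray:
        """Time x k regressor matrix for one slice (zero-mean columns).

        With ``expand`` the squared parameters are appended (a Friston-style
        expansion): resampling artifacts scale nonlinearly with the applied
        displacement, and the quadratic terms absorb that component.
        """
        cols = np.column_stack(
            [self.dx[slice_index], self.dy[slice_index], self.theta[slice_index]]
        )
        if expand:
            cols = np.column_stack([cols, cols**2])
        return cols - cols.mean(axis=0, keepdims=True)


@dataclass
class LfpRecording:
    """Multi-channel LFP recording.

    ``voltages`` has shape (n_channels, n_samples) in microvolts; ``geometry``
    is a DataFrame with columns ``channel``, ``shank``, ``contact``,
    ``depth_um`` (contact index x pitch below the most superficial contact).
    ``labels`` maps channel -> coarse region guess ("dorsal", "intermediate",
    "ventral").
    """

    voltages: np.ndarray
    fs_hz: float
    geometry: pd.DataFrame
    labels: dict[int, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.voltages.shape[0]

    @property
    def duration_s(self) -> float:
        return self.voltages.shape[1] / self.fs_hz

    def channel_depth(self, channel: int) -> float:
        row = self.geometry.loc[self.geometry["channel"] == channel]
        return float(row["depth_um"].iloc[0])

    def shank_channels(self, shank: int) -> list[int]:
        g = self.geometry
        return [int(c) for c in g.loc[g["shank"] == shank, "channel"]]


@dataclass
class SpikeTrain:
    """Sorted spike timestamps (seconds) from one channel."""

    timestamps: np.ndarray
    channel: int = 0
    duration_s: float | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.size and np.any(np.diff(self.timestamps) < 0):
            raise ValueError("spike timestamps must be non-decreasing")
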