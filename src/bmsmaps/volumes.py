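"""Scalp-time voxel volumes: interpolation, containers, and NIfTI I/O.

Epoched M/EEG data (trials x channels x time) are converted into per-trial
3-D images whose first two axes are interpolated scalp position and whose
third axis is peristimulus time.  The same containers also hold
source-space volumes read from disk; downstream stages never care which
space they are in.

Out-of-mask voxels are represented as NaN on disk and as an explicit
boolean mask in memory, so that zeros are never silently read as data.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .errors import DataError, GridError

log = logging.getLogger(__name__)


@dataclass
class GridMeta:
    """Geometry of a voxel grid.

    voxel_sizes are in physical units per axis: for scalp-time volumes the
    first two are normalised scalp units and the third is the sampling
    interval in milliseconds; for source volumes all three are mm.
    """

    voxel_sizes: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_names: tuple[str, str, str] = ("scalp-x", "scalp-y", "time-ms")

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_sizes) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_dict(self) -> dict:
        return {
            "voxel_sizes": list(self.voxel_sizes),
            "origin": list(self.origin),
            "axis_names": list(self.axis_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridMeta":
        return cls(
            voxel_sizes=tuple(d["voxel_sizes"]),
            origin=tuple(d.get("origin", (0.0, 0.0, 0.0))),
            axis_names=tuple(d.get("axis_names", ("scalp-x", "scalp-y", "time-ms"))),
        )


@dataclass
class EpochedDataset:
    """Per-subject epoched data: trials x channels x time, labelled by condition."""

    data: np.ndarray
    channel_positions: np.ndarray
    time_axis: np.ndarray
    condition_labels: list[str]
    subject_id: str = "sub-00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_positions = np.asarray(self.channel_positions, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.data.ndim != 3:
            raise DataError("data must be trials x channels x time (3-D)")
        n_tr, n_ch, n_t = self.data.shape
        if self.channel_positions.shape != (n_ch, 2):
            raise DataError(
                f"channel_positions shape {self.channel_positions.shape} "
                f"inconsistent with {n_ch} channels"
            )
        if len(self.time_axis) != n_t:
            raise DataError(
                f"time_axis length {len(self.time_axis)} != {n_t} samples"
            )
        if len(self.condition_labels) != n_tr:
            raise DataError(
                f"{len(self.condition_labels)} condition labels for {n_tr} trials"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.condition_labels))


@dataclass
class VoxelImageSet:
    """Per-trial 3-D volumes on a shared grid with an explicit validity mask."""

    volumes: np.ndarray  # (n_volumes, nx, ny, nz)
    mask: np.ndarray  # (nx, ny, nz) bool
    grid_meta: GridMeta
    condition_labels: list[str]
    subject_id: str = "sub-00"

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.volumes.ndim != 4:
            raise GridError("volumes must be (n_volumes, nx, ny, nz)")
        if self.mask.shape != self.volumes.shape[1:]:
            raise GridError(
                f"mask shape {self.mask.shape} != volume shape {self.volumes.shape[1:]}"
            )
        if len(self.condition_labels) != self.volumes.shape[0]:
            raise GridError("one condition label required per volume")

    @property
    def n_volumes(self) -> int:
        return self.volumes.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.mask.shape


class ScalpInterpolator:
    """Piecewise-linear barycentric interpolation from channels to a 2-D grid.

    The channel positions are triangulated (Delaunay) once; each grid node
    inside the convex hull receives a fixed convex-weight combination of the
    three vertices of its enclosing triangle.  Nodes outside the hull are
    masked out — no extrapolation.
    """

    def __init__(self, channel_positions: np.ndarray, grid_size: tuple[int, int]):
        pos = np.asarray(channel_positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise DataError("channel_positions must be (n_channels, 2)")
        if pos.shape[0] < 3:
            raise DataError("at least 3 channel positions required for interpolation")
        uniq = np.unique(pos, axis=0)
        if uniq.shape[0] != pos.shape[0]:
            raise DataError("duplicate channel positions are not allowed")
        try:
            self.tri = Delaunay(pos)
        except QhullError as e:  # collinear channels have no 2-D hull
            raise DataError(f"channel positions are degenerate (collinear?): {e}")
        self.positions = pos
        self.grid_size = tuple(grid_size)
        nx, ny = self.grid_size
        self.x = np.linspace(pos[:, 0].min(), pos[:, 0].max(), nx)
        self.y = np.linspace(pos[:, 1].min(), pos[:, 1].max(), ny)
        gx, gy = np.meshgrid(self.x, self.y, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        simplex = self.tri.find_simplex(pts)
        inside = simplex >= 0
        # barycentric weights of each inside grid node w.r.t. its triangle
        n_grid = pts.shape[0]
        n_ch = pos.shape[0]
        W = np.zeros((n_grid, n_ch))
        if inside.any():
            s = simplex[inside]
            T = self.tri.transform[s]  # (m, 3, 2) affine to barycentric
            delta = pts[inside] - T[:, 2]
            bary2 = np.einsum("mij,mj->mi", T[:, :2], delta)
            bary = np.column_stack([bary2, 1.0 - bary2.sum(axis=1)])
            verts = self.tri.simplices[s]  # (m, 3)
            rows = np.repeat(np.flatnonzero(inside), 3)
            W[rows, verts.ravel()] = bary.ravel()
        self.weights = W
        self.mask2d = inside.reshape(nx, ny)

    def __call__(self, channel_values: np.ndarray) -> np.ndarray:
        """Interpolate values of shape (..., n_channels) to (..., nx, ny).

        Out-of-hull nodes are NaN.
        """
        vals = np.asarray(channel_values, dtype=float)
        if vals.shape[-1] != self.positions.shape[0]:
            raise DataError(
                f"expected {self.positions.shape[0]} channel values, "
                f"got {vals.shape[-1]}"
            )
        flat = vals @ self.weights.T  # (..., n_grid)
        out = flat.reshape(vals.shape[:-1] + self.grid_size)
        out[..., ~self.mask2d] = np.nan
        return out

    def vertex_channels(self, voxel_index: tuple[int, int]) -> np.ndarray:
        """Indices of channels with non-zero weight at a grid node."""
        i, j = voxel_index
        flat = i * self.grid_size[1] + j
        return np.flatnonzero(self.weights[flat] > 0)


def interpolate_scalp(
    channel_values: np.ndarray,
    channel_positions: np.ndarray,
    grid_size: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate one vector of per-channel amplitudes onto a 2-D scalp grid.

    Returns ``(grid, mask)`` where ``grid`` is (nx, ny) with NaN outside the
    convex hull of the channels and ``mask`` marks valid cells.
    """
    interp = ScalpInterpolator(channel_positions, grid_size)
    grid = interp(np.asarray(channel_values, dtype=float))
    return grid, interp.mask2d.copy()


def build_scalp_time_volumes(
    dataset: EpochedDataset,
    grid_size: tuple[int, int] = (32, 32),
    interpolator: ScalpInterpolator | None = None,
) -> VoxelImageSet:
    """Build one scalp-time volume per trial: shape (nx, ny, n_time).

    The third axis is time ordered from the earliest to the latest sample;
    its voxel size is the sampling interval in ms.  The mask is the 2-D
    convex-hull mask repeated along time, identical for every trial.
    """
    if dataset.n_trials == 0:
        raise DataError("dataset has no trials")
    interp = interpolator or ScalpInterpolator(dataset.channel_positions, grid_size)
    order = np.argsort(dataset.time_axis, kind="stable")
    data = dataset.data[:, :, order]  # (T, C, S) earliest first
    # interpolate all trials and samples at once: (T, S, C) -> (T, S, nx, ny)
    vols = interp(np.moveaxis(data, 1, 2))
    vols = np.moveaxis(vols, 1, 3)  # (T, nx, ny, S)
    mask3d = np.repeat(interp.mask2d[:, :, None], data.shape[2], axis=2)
    dt = float(np.median(np.diff(np.sort(dataset.time_axis)))) if len(
        dataset.time_axis
    ) > 1 else 1.0
    dx = float(interp.x[1] - interp.x[0]) if grid_size[0] > 1 else 1.0
    dy = float(interp.y[1] - interp.y[0]) if grid_size[1] > 1 else 1.0
    meta = GridMeta(
        voxel_sizes=(dx, dy, dt),
        origin=(float(interp.x[0]), float(interp.y[0]), float(np.min(dataset.time_axis))),
        axis_names=("scalp-x", "scalp-y", "time-ms"),
    )
    return VoxelImageSet(
        volumes=vols,
        mask=mask3d,
        grid_meta=meta,
        condition_labels=list(dataset.condition_labels),
        subject_id=dataset.subject_id,
    )


def write_volumes(image_set: VoxelImageSet, out_dir: str | Path) -> list[Path]:
    """Write one NIfTI-1 file per volume plus sidecars; NaN codes out-of-mask.

    Emits ``vol_<i>.nii`` (float32), ``grid_meta.json`` and ``trials.tsv``
    (volume index, condition label).  Returns the image paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = image_set.grid_meta.affine()
    paths = []
    for i in range(image_set.n_volumes):
        vol = image_set.volumes[i].astype(np.float32).copy()
        vol[~image_set.mask] = np.nan
        img = nib.Nifti1Image(vol, affine)
        p = out / f"vol_{i:04d}.nii"
        nib.save(img, str(p))
        paths.append(p)
    (out / "grid_meta.json").write_text(
        json.dumps(image_set.grid_meta.to_dict(), indent=2)
    )
    pd.DataFrame(
        {
            "volume": np.arange(image_set.n_volumes),
            "condition": image_set.condition_labels,
        }
    ).to_csv(out / "trials.tsv", sep="\t", index=False)
    return paths


def read_volumes(
    source: str | Path | Sequence[str | Path],
    condition_labels: list[str] | None = None,
    subject_id: str = "sub-00",
) -> VoxelImageSet:
    """Read NIfTI volumes (a directory written by :func:`write_volumes` or an
    explicit list of paths) back into a :class:`VoxelImageSet`.

    NaN voxels become out-of-mask; the mask is the intersection of finite
    voxels across all volumes.
    """
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        d = Path(source)
        paths = sorted(d.glob("vol_*.nii"))
        if not paths:
            paths = sorted(p for p in d.glob("*.nii"))
        meta_path = d / "grid_meta.json"
        meta = (
            GridMeta.from_dict(json.loads(meta_path.read_text()))
            if meta_path.exists()
            else None
        )
        trial_path = d / "trials.tsv"
        if condition_labels is None and trial_path.exists():
            condition_labels = list(
                pd.read_csv(trial_path, sep="\t")["condition"].astype(str)
            )
    else:
        paths = [Path(p) for p in source]
        meta = None
    if not paths:
        raise DataError("no NIfTI volumes found to read")
    arrays = []
    shape = None
    for p in paths:
        img = nib.load(str(p))
        arr = np.asarray(img.dataobj, dtype=float)
        if arr.ndim != 3:
            raise GridError(f"{p}: expected a 3-D volume, got shape {arr.shape}")
        if shape is None:
            shape = arr.shape
            affine = img.affine
        elif arr.shape != shape:
            raise GridError(
                f"shape mismatch across files: {p} has {arr.shape}, expected {shape}"
            )
        arrays.append(arr)
    vols = np.stack(arrays)
    mask = np.all(np.isfinite(vols), axis=0)
    if meta is None:
        vs = tuple(float(v) for v in np.abs(np.diag(affine)[:3]))
        meta = GridMeta(voxel_sizes=vs, origin=tuple(float(v) for v in affine[:3, 3]))
    if condition_labels is None:
        condition_labels = ["n/a"] * vols.shape[0]
    if len(condition_labels) != vols.shape[0]:
        raise DataError("condition label count does not match volume count")
    return VoxelImageSet(
        volumes=vols,
        mask=mask,
        grid_meta=meta,
        condition_labels=condition_labels,
        subject_id=subject_id,
    )


def sanitize_source_map(
    volume: np.ndarray, return_count: bool = False
) -> np.ndarray | tuple[np.ndarray, int]:
    """Replace NaNs with zeros (the convention for source-space evidence maps).

    Finite values are untouched.  The number of replacements is logged; an
    all-NaN volume triggers a warning.
    """
    vol = np.asarray(volume, dtype=float)
    nan_mask = np.isnan(vol)
    n = int(nan_mask.sum())
    out = np.where(nan_mask, 0.0, vol)
    if n:
        log.info("sanitize_source_map: replaced %d NaN voxel(s) with zero", n)
    if n == vol.size and vol.size > 0:
        warnings.warn("sanitize_source_map: volume was entirely NaN", stacklevel=2)
    if return_count:
        return out, n
    return out
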