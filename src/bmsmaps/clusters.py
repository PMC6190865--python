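"""Thresholding, cluster extraction and reporting for probability maps.

A probability volume (PPM or EPM) is binarised at a strict threshold
(voxel kept iff p > threshold and in-mask), connected components are
labelled under a chosen neighbourhood scheme, components smaller than a
minimum size are dropped, and each surviving cluster is summarised by its
extent K_E, peak probability and peak coordinates.
"""

from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING

import nibabel as nib
import numpy as np
import pandas as pd
from skimage import measure

from .errors import DataError

if TYPE_CHECKING:  # pragma: no cover
    from .rfx import BMSResult

#: neighbourhood scheme -> skimage connectivity order (3-D)
CONNECTIVITY = {"face": 1, "face+edge": 2, "face+edge+corner": 3}

CLUSTER_COLUMNS = [
    "model",
    "size",
    "peak_probability",
    "peak_i",
    "peak_j",
    "peak_k",
    "peak_x",
    "peak_y",
    "peak_z",
]


def threshold_map(
    prob_volume: np.ndarray,
    threshold: float,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Binarise a probability volume: true iff p > threshold and in-mask.

    NaN voxels (the out-of-mask convention) never pass.
    """
    if not (0.0 <= threshold <= 1.0):
        raise DataError(f"threshold must lie in [0, 1], got {threshold}")
    vol = np.asarray(prob_volume, dtype=float)
    out = np.zeros(vol.shape, dtype=bool)
    finite = np.isfinite(vol)
    out[finite] = vol[finite] > threshold
    if mask is not None:
        out &= np.asarray(mask, dtype=bool)
    return out


def extract_clusters(
    binary_volume: np.ndarray,
    connectivity: str = "face",
    min_size: int = 0,
    prob_volume: np.ndarray | None = None,
    affine: np.ndarray | None = None,
    model: str = "",
) -> pd.DataFrame:
    """Label connected components and tabulate clusters of size >= min_size.

    The table is sorted by size descending, ties broken by lexicographic
    peak index.  The peak is the voxel with the highest probability inside
    the cluster (first in lexicographic order if no probability volume is
    given); physical peak coordinates come from the affine when provided.
    """
    if connectivity not in CONNECTIVITY:
        raise DataError(
            f"connectivity must be one of {sorted(CONNECTIVITY)}, got {connectivity!r}"
        )
    binary = np.asarray(binary_volume, dtype=bool)
    labelled = measure.label(binary, connectivity=CONNECTIVITY[connectivity])
    rows = []
    for lab in range(1, labelled.max() + 1):
        idx = np.argwhere(labelled == lab)
        size = idx.shape[0]
        if size < min_size:
            continue
        if prob_volume is not None:
            probs = np.asarray(prob_volume, dtype=float)[tuple(idx.T)]
            # lexicographically-first argmax: stable tie-break
            best = int(np.argmax(probs))
            peak = idx[best]
            peak_p = float(probs[best])
        else:
            peak = idx[0]  # argwhere is already lexicographic
            peak_p = np.nan
        if affine is not None:
            xyz = (np.asarray(affine) @ np.append(peak, 1.0))[:3]
        else:
            xyz = peak.astype(float)
        rows.append(
            {
                "model": model,
                "size": int(size),
                "peak_probability": peak_p,
                "peak_i": int(peak[0]),
                "peak_j": int(peak[1]),
                "peak_k": int(peak[2]),
                "peak_x": float(xyz[0]),
                "peak_y": float(xyz[1]),
                "peak_z": float(xyz[2]),
            }
        )
    table = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    if len(table):
        table = table.sort_values(
            ["size", "peak_i", "peak_j", "peak_k"],
            ascending=[False, True, True, True],
            kind="stable",
        ).reset_index(drop=True)
    return table


def report(
    result: "BMSResult",
    thresholds: float | dict[str, float] = 0.75,
    min_size: int = 0,
    connectivity: str = "face",
    out_dir: str | Path | None = None,
    use_epm: bool = False,
    n_time_panels: int = 8,
) -> dict[str, pd.DataFrame]:
    """Per-model cluster tables (and, if out_dir is given, files).

    Thresholds the chosen probability volumes (PPM by default, EPM with
    ``use_epm``), extracts clusters and, when ``out_dir`` is set, writes a
    delimited cluster table, a thresholded NIfTI mask and a small panel of
    2-D time slices per model.
    """
    from .rfx import BMSResult  # noqa: F401  (runtime type only)

    volumes = result.epm if use_epm else result.ppm
    tables: dict[str, pd.DataFrame] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    affine = result.grid_meta.affine()
    for k, name in enumerate(result.model_names):
        thr = thresholds[name] if isinstance(thresholds, dict) else float(thresholds)
        binary = threshold_map(volumes[k], thr, mask=result.mask)
        table = extract_clusters(
            binary,
            connectivity=connectivity,
            min_size=min_size,
            prob_volume=volumes[k],
            affine=affine,
            model=name,
        )
        tables[name] = table
        if out is not None:
            table.to_csv(out / f"clusters_{name}.tsv", sep="\t", index=False)
            nib.save(
                nib.Nifti1Image(binary.astype(np.uint8), affine),
                str(out / f"thresholded_{name}.nii"),
            )
            _render_time_panels(
                volumes[k], binary, out / f"panels_{name}.png", thr, n_time_panels
            )
    return tables


def _render_time_panels(
    prob_volume: np.ndarray,
    binary: np.ndarray,
    path: Path,
    threshold: float,
    n_panels: int,
) -> None:
    """PNG of evenly spaced time slices with supra-threshold voxels outlined."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nt = prob_volume.shape[2]
    slices = np.unique(np.linspace(0, nt - 1, min(n_panels, nt)).astype(int))
    fig, axes = plt.subplots(1, len(slices), figsize=(2.2 * len(slices), 2.6))
    axes = np.atleast_1d(axes)
    for ax, t in zip(axes, slices):
        ax.imshow(
            prob_volume[:, :, t].T,
            origin="lower",
            vmin=0.0,
            vmax=1.0,
            cmap="viridis",
        )
        if binary[:, :, t].any():
            ax.contour(binary[:, :, t].T, levels=[0.5], colors="red", linewidths=0.8)
        ax.set_title(f"t={t}", fontsize=8)
        ax.axis("off")
    fig.suptitle(f"posterior probability, threshold > {threshold:g}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
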