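"""Synthetic group datasets with known ground truth.

Emulates a heterogeneous group in a four-condition attention x prediction
design: each subject's trial amplitudes are generated under one of K
condition-weight models.  A spatially contiguous "effect" blob of scalp
channels carries, during a fixed peristimulus window,

    amplitude = intercept + effect_size * weight_k(condition) + N(0, noise_sd^2)

while everything else is pure Gaussian noise.  Because the image-building
stage interpolates linearly between channels, the voxels whose
interpolation stencil draws only on signal channels inherit the stated
mean exactly; those are recorded as the ground-truth effect region, and
the partially-influenced fringe is recorded separately as the halo.

One root seed spawns independent per-subject streams, so adding a subject
never changes earlier subjects' data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DesignError
from .vbglm import INTERACTION, OPPOSITION, LogEvidenceMaps, ModelSpec
from .volumes import EpochedDataset, GridMeta, ScalpInterpolator


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream verification.

    ``subject_assignments`` are 1-based model indices (subject n was
    generated by model ``subject_assignments[n-1]``).  ``effect_region``
    holds flat voxel indices (into the nx*ny*nt grid) whose expected
    amplitude is exactly intercept + effect_size * weight; ``halo_region``
    voxels receive a partial, interpolation-attenuated effect and belong to
    neither the effect nor the null set.
    """

    subject_assignments: list[int]
    effect_region: set[int]
    effect_size: float
    noise_sd: float
    seed: int
    intercept: float = 0.0
    halo_region: set[int] = field(default_factory=set)
    grid_shape: tuple[int, int, int] = (32, 32, 80)
    effect_time_window: tuple[int, int] = (30, 40)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise DataError("noise_sd must be non-negative")

    def validate(self, n_models: int) -> None:
        if any(not (1 <= a <= n_models) for a in self.subject_assignments):
            raise DataError(
                f"subject assignments must lie in 1..{n_models}"
            )

    def effect_voxel_indices(self) -> np.ndarray:
        """Effect-region voxels as (n, 3) grid indices."""
        flat = np.array(sorted(self.effect_region), dtype=int)
        return np.column_stack(np.unravel_index(flat, self.grid_shape))

    def to_json(self) -> str:
        return json.dumps(
            {
                "subject_assignments": self.subject_assignments,
                "effect_region": sorted(self.effect_region),
                "halo_region": sorted(self.halo_region),
                "effect_size": self.effect_size,
                "noise_sd": self.noise_sd,
                "intercept": self.intercept,
                "seed": self.seed,
                "grid_shape": list(self.grid_shape),
                "effect_time_window": list(self.effect_time_window),
            }
        )


@dataclass
class SimulatedGroup:
    """One epoched dataset per subject plus the generating ground truth."""

    datasets: list[EpochedDataset]
    truth: GroundTruth
    model_specs: list[ModelSpec]

    def __post_init__(self) -> None:
        shapes = {d.data.shape[1:] for d in self.datasets}
        if len(shapes) > 1:
            raise DataError("all subjects must share channel and sample counts")
        labels = {frozenset(d.condition_labels) for d in self.datasets}
        if len(labels) > 1:
            raise DataError("all subjects must share the condition label set")

    @property
    def n_subjects(self) -> int:
        return len(self.datasets)


def grid_channel_layout(n_side: int = 8) -> np.ndarray:
    """A regular n_side x n_side electrode raster on the unit square.

    A stand-in for a real cap montage: dense enough that linear
    interpolation onto a 32 x 32 raster is well conditioned everywhere.
    """
    u = np.linspace(0.0, 1.0, n_side)
    gx, gy = np.meshgrid(u, u, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def _signal_channels(
    positions: np.ndarray,
    centre: tuple[float, float],
    half_extent: float,
    spacing: float,
) -> np.ndarray:
    """Channels inside the effect square expanded by one electrode spacing.

    The expansion guarantees that every grid node inside the nominal square
    interpolates exclusively from signal channels, so the planted mean
    survives interpolation exactly.
    """
    lo_x = centre[0] - half_extent - spacing - 1e-9
    hi_x = centre[0] + half_extent + spacing + 1e-9
    lo_y = centre[1] - half_extent - spacing - 1e-9
    hi_y = centre[1] + half_extent + spacing + 1e-9
    return np.flatnonzero(
        (positions[:, 0] >= lo_x)
        & (positions[:, 0] <= hi_x)
        & (positions[:, 1] >= lo_y)
        & (positions[:, 1] <= hi_y)
    )


def simulate_group(
    n_subjects: int = 21,
    n_trials_per_condition: int = 30,
    conditions: Sequence[str] = ("UP", "AP", "UU", "AU"),
    model_specs: Sequence[ModelSpec] = (OPPOSITION, INTERACTION),
    effect_size: float = 1.0,
    noise_sd: float = 1.0,
    intercept: float = 0.0,
    subject_assignments: Sequence[int] | None = None,
    grid_size: tuple[int, int] = (32, 32),
    n_time: int = 80,
    sample_interval_ms: float = 5.0,
    effect_extent: int = 5,
    effect_time_window: tuple[int, int] = (30, 40),
    channel_grid_side: int = 8,
    seed: int = 0,
) -> SimulatedGroup:
    """Simulate an epoched group with a planted spatiotemporal effect.

    Subject n (assigned model k) has, at signal channels during the effect
    window, mean ``intercept + effect_size * weight_k(condition)``; all
    other channel/time samples are zero-mean noise.  Defaults mirror a
    21-subject cohort, four conditions at 200 Hz over 0-395 ms, and a
    5 x 5 x 10-voxel effect blob centred in a 32 x 32 x 80 grid.
    """
    if len(conditions) < 2:
        raise DesignError("need at least two conditions")
    if len(set(conditions)) != len(conditions):
        raise DesignError("condition labels must be unique")
    if len(model_specs) < 1:
        raise DesignError("need at least one model spec")
    if n_trials_per_condition < 1:
        raise DataError("n_trials_per_condition must be >= 1")
    for spec in model_specs:
        missing = [c for c in conditions if c not in spec.weights]
        if missing:
            raise DesignError(
                f"model {spec.name!r} has no weight for condition(s) {missing}"
            )
    K = len(model_specs)
    if subject_assignments is None:
        # deterministic near-even split, model 1 first
        subject_assignments = [(i % K) + 1 for i in range(n_subjects)]
    assignments = list(int(a) for a in subject_assignments)
    if len(assignments) != n_subjects:
        raise DataError("one model assignment required per subject")

    positions = grid_channel_layout(channel_grid_side)
    spacing = 1.0 / (channel_grid_side - 1)
    interp = ScalpInterpolator(positions, grid_size)
    nx, ny = grid_size

    # effect square in normalised scalp coordinates, centred on the grid
    half_extent = 0.5 * (effect_extent - 1) * (
        (interp.x[1] - interp.x[0]) if nx > 1 else 1.0
    )
    # centre on a grid node so an odd-extent square covers exactly
    # effect_extent nodes per axis
    centre = (float(interp.x[nx // 2]), float(interp.y[ny // 2]))
    sig_ch = _signal_channels(positions, centre, half_extent, spacing)

    # voxels fully determined by signal channels (exact planted mean) ...
    full = np.all(
        interp.weights[:, np.setdiff1d(np.arange(positions.shape[0]), sig_ch)] == 0,
        axis=1,
    ) & interp.mask2d.ravel()
    # ... restricted to the nominal effect square
    ix = np.arange(nx)[np.abs(interp.x - centre[0]) <= half_extent + 1e-9]
    iy = np.arange(ny)[np.abs(interp.y - centre[1]) <= half_extent + 1e-9]
    square = np.zeros(nx * ny, dtype=bool)
    square[(ix[:, None] * ny + iy[None, :]).ravel()] = True
    spatial_effect = full & square
    touched = (interp.weights[:, sig_ch].sum(axis=1) > 0) & interp.mask2d.ravel()
    spatial_halo = touched & ~spatial_effect

    t0, t1 = effect_time_window
    if not (0 <= t0 < t1 <= n_time):
        raise DataError("effect_time_window must lie within the sample range")
    grid_shape = (nx, ny, n_time)
    effect_region = {
        int(v * n_time + t)
        for v in np.flatnonzero(spatial_effect)
        for t in range(t0, t1)
    }
    halo_region = {
        int(v * n_time + t)
        for v in np.flatnonzero(spatial_halo)
        for t in range(t0, t1)
    }

    time_axis = np.arange(n_time) * sample_interval_ms
    labels = [c for c in conditions for _ in range(n_trials_per_condition)]
    n_trials = len(labels)
    n_ch = positions.shape[0]

    root = np.random.SeedSequence(seed)
    children = root.spawn(n_subjects)
    datasets = []
    for n in range(n_subjects):
        rng = np.random.default_rng(children[n])
        data = rng.normal(0.0, noise_sd, size=(n_trials, n_ch, n_time))
        spec = model_specs[assignments[n] - 1]
        w = np.array([float(spec.weights[c]) for c in labels])
        signal = intercept + effect_size * w  # (n_trials,)
        data[np.ix_(np.arange(n_trials), sig_ch, np.arange(t0, t1))] += signal[
            :, None, None
        ]
        datasets.append(
            EpochedDataset(
                data=data,
                channel_positions=positions,
                time_axis=time_axis,
                condition_labels=list(labels),
                subject_id=f"sub-{n + 1:02d}",
            )
        )

    truth = GroundTruth(
        subject_assignments=assignments,
        effect_region=effect_region,
        halo_region=halo_region,
        effect_size=effect_size,
        noise_sd=noise_sd,
        intercept=intercept,
        seed=seed,
        grid_shape=grid_shape,
        effect_time_window=(t0, t1),
    )
    truth.validate(K)
    return SimulatedGroup(
        datasets=datasets, truth=truth, model_specs=list(model_specs)
    )


def simulate_log_evidences(
    n_subjects: int,
    true_frequencies: Sequence[float],
    evidence_scale: float,
    seed: int = 0,
    noise_sd: float = 1.0,
    return_truth: bool = False,
):
    """Draw a single-voxel subjects x models log-evidence matrix.

    Each subject's generating model is drawn from ``true_frequencies``;
    its log evidence exceeds the others by draws centred on
    ``evidence_scale`` (every entry gets independent N(0, noise_sd^2)
    jitter, so ``evidence_scale = 0`` rows carry no systematic
    information).  Returns a single-voxel :class:`LogEvidenceMaps`;
    with ``return_truth=True`` also the 1-based assignment list.
    """
    freqs = np.asarray(true_frequencies, dtype=float)
    if np.any(freqs < 0):
        raise DataError("true_frequencies must be non-negative")
    if not np.isclose(freqs.sum(), 1.0):
        raise DataError("true_frequencies must sum to 1")
    K = freqs.size
    rng = np.random.default_rng(seed)
    gen = rng.choice(K, size=n_subjects, p=freqs)
    lev = rng.normal(0.0, noise_sd, size=(n_subjects, K))
    lev[np.arange(n_subjects), gen] += evidence_scale
    maps = LogEvidenceMaps(
        evidences=lev[:, :, None],
        mask=np.ones((1, 1, 1), dtype=bool),
        grid_meta=GridMeta(voxel_sizes=(1.0, 1.0, 1.0)),
        model_names=[f"model-{k + 1}" for k in range(K)],
        subject_ids=[f"sub-{n + 1:02d}" for n in range(n_subjects)],
    )
    if return_truth:
        return maps, [int(g) + 1 for g in gen]
    return maps


def write_group(group: SimulatedGroup, out_dir: str | Path) -> Path:
    """Write a simulated group: one array file + trial table per subject,
    plus a ground-truth JSON sidecar and a channel-position table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ds in group.datasets:
        np.save(out / f"{ds.subject_id}_data.npy", ds.data)
        pd.DataFrame(
            {"trial": np.arange(ds.n_trials), "condition": ds.condition_labels}
        ).to_csv(out / f"{ds.subject_id}_trials.tsv", sep="\t", index=False)
    np.savetxt(out / "channel_positions.tsv", group.datasets[0].channel_positions,
               delimiter="\t", header="x\ty", comments="")
    np.savetxt(out / "time_axis.tsv", group.datasets[0].time_axis,
               delimiter="\t", header="time_ms", comments="")
    (out / "ground_truth.json").write_text(group.truth.to_json())
    (out / "models.json").write_text(
        json.dumps({s.name: dict(s.weights) for s in group.model_specs}, indent=2)
    )
    return out


def read_group(in_dir: str | Path) -> SimulatedGroup:
    """Read a group previously written by :func:`write_group`."""
    d = Path(in_dir)
    positions = np.loadtxt(d / "channel_positions.tsv", skiprows=1)
    time_axis = np.loadtxt(d / "time_axis.tsv", skiprows=1)
    gt = json.loads((d / "ground_truth.json").read_text())
    truth = GroundTruth(
        subject_assignments=gt["subject_assignments"],
        effect_region=set(gt["effect_region"]),
        halo_region=set(gt.get("halo_region", [])),
        effect_size=gt["effect_size"],
        noise_sd=gt["noise_sd"],
        intercept=gt.get("intercept", 0.0),
        seed=gt["seed"],
        grid_shape=tuple(gt["grid_shape"]),
        effect_time_window=tuple(gt["effect_time_window"]),
    )
    models = json.loads((d / "models.json").read_text())
    specs = [ModelSpec(name, w) for name, w in models.items()]
    datasets = []
    for p in sorted(d.glob("sub-*_data.npy")):
        sid = p.name.replace("_data.npy", "")
        data = np.load(p)
        labels = list(
            pd.read_csv(d / f"{sid}_trials.tsv", sep="\t")["condition"].astype(str)
        )
        datasets.append(
            EpochedDataset(
                data=data,
                channel_positions=positions,
                time_axis=time_axis,
                condition_labels=labels,
                subject_id=sid,
            )
        )
    return SimulatedGroup(datasets=datasets, truth=truth, model_specs=specs)
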