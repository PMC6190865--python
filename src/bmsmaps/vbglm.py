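"""Per-voxel Bayesian GLM fitted by variational Bayes (VB).

Each voxel's trial amplitudes ``y`` are modelled as

    y = X w + e,     e ~ N(0, 1/lambda)

with a zero-mean Gaussian prior on the coefficients ``w`` (precision
``coeff_precision`` per regressor) and a Gamma(shape, rate) prior on the
noise precision ``lambda``.  The posterior is approximated by the
mean-field factorisation ``q(w) q(lambda)`` optimised by coordinate
ascent; the converged variational free energy ``F`` is the lower bound on
the log model evidence ``ln p(y | m)`` used for model comparison.

The design matrix encodes a model as a single centred condition-covariate
regressor plus an intercept, so two models differ only in how their
covariate weights order the conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import digamma, gammaln

from .errors import DataError, DesignError, GridError
from .volumes import GridMeta, VoxelImageSet

LN2PI = float(np.log(2.0 * np.pi))
#: FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian kernel
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class ModelSpec:
    """A named hypothesis: a mapping from condition label to covariate weight.

    Example: the Opposition model over (unattended-predicted,
    attended-predicted, unattended-unpredicted, attended-unpredicted) uses
    weights 1, 2, 2, 3 — attention boosts responses to predicted and
    unpredicted tones alike.
    """

    name: str
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(self.weights) < 1:
            raise DesignError(f"model {self.name!r} has no condition weights")
        if len(set(float(v) for v in self.weights.values())) < 2:
            raise DesignError(
                f"model {self.name!r} needs at least two distinct weights "
                "(otherwise it is a pure intercept)"
            )

    @property
    def conditions(self) -> list[str]:
        return list(self.weights)


# The two competing hypotheses about attention x prediction over the
# conditions (UP, AP, UU, AU) = (unattended predicted, attended predicted,
# unattended unpredicted, attended unpredicted).
OPPOSITION = ModelSpec("opposition", {"UP": 1.0, "AP": 2.0, "UU": 2.0, "AU": 3.0})
INTERACTION = ModelSpec("interaction", {"UP": 1.0, "AP": 4.0, "UU": 2.0, "AU": 3.0})


@dataclass
class DesignMatrix:
    """Trials x regressors design: column 1 centred covariate, column 2 ones."""

    matrix: np.ndarray
    regressor_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise DesignError("design matrix must be 2-D (trials x regressors)")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise DesignError("design matrix is rank deficient")

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class Priors:
    """Hyperparameters of the VB-GLM: weakly informative by default."""

    coeff_precision: float = 1e-3
    noise_shape: float = 1e-3
    noise_rate: float = 1e-3

    def __post_init__(self) -> None:
        if min(self.coeff_precision, self.noise_shape, self.noise_rate) <= 0:
            raise DesignError("prior precisions/shape/rate must be positive")


@dataclass
class GLMPosterior:
    """Factorised posterior: q(w) = N(mean, diag var), q(lambda) = Gamma."""

    coeff_mean: np.ndarray
    coeff_precision: np.ndarray  # marginal posterior precision per regressor
    noise_shape: float
    noise_rate: float

    @property
    def noise_precision_mean(self) -> float:
        return self.noise_shape / self.noise_rate


@dataclass
class FreeEnergyTrace:
    """Per-iteration free energy; coordinate ascent makes it non-decreasing."""

    values: np.ndarray
    converged: bool
    n_iter: int


@dataclass
class LogEvidenceMaps:
    """Subjects x models x voxels array of free energies (nats)."""

    evidences: np.ndarray  # (N, K, n_voxels) flat voxel order
    mask: np.ndarray  # grid-shaped bool
    grid_meta: GridMeta
    model_names: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.evidences = np.asarray(self.evidences, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.evidences.ndim != 3:
            raise GridError("evidences must be (subjects, models, voxels)")
        if self.evidences.shape[2] != self.mask.size:
            raise GridError("voxel axis inconsistent with mask size")
        if self.evidences.shape[1] != len(self.model_names):
            raise GridError("model axis inconsistent with model_names")

    @property
    def n_subjects(self) -> int:
        return self.evidences.shape[0]

    @property
    def n_models(self) -> int:
        return self.evidences.shape[1]

    def in_mask_matrix(self) -> np.ndarray:
        """Evidence restricted to in-mask voxels: (N, K, n_in_mask)."""
        return self.evidences[:, :, self.mask.ravel()]


def build_design(
    condition_labels: Sequence[str], spec: ModelSpec, normalise: bool = True
) -> DesignMatrix:
    """Map per-trial condition labels to the model's covariate and centre it.

    Column 1 is the mean-centred covariate, column 2 the intercept; centring
    makes the effect regressor orthogonal to the baseline.  By default the
    centred covariate is also scaled to unit Euclidean norm: competing
    models then carry identical Occam penalties under the shared coefficient
    prior, so pure-noise voxels yield ln BF centred on zero.  (Scaling does
    not change the model's explanatory subspace, only the units of its
    coefficient.)
    """
    labels = list(condition_labels)
    missing = sorted({c for c in labels if c not in spec.weights})
    if missing:
        raise DesignError(
            f"model {spec.name!r} has no weight for condition(s): {missing}"
        )
    cov = np.array([float(spec.weights[c]) for c in labels])
    centred = cov - cov.mean()
    norm = np.linalg.norm(centred)
    if norm < 1e-12 * max(1.0, np.abs(cov).max()):
        raise DesignError(
            f"covariate for model {spec.name!r} is constant across trials "
            "(design would be rank deficient)"
        )
    if normalise:
        centred = centred / norm
    X = np.column_stack([centred, np.ones(len(labels))])
    return DesignMatrix(matrix=X, regressor_names=[spec.name, "intercept"])


def _vb_fit_batch(
    Y: np.ndarray,
    X: np.ndarray,
    priors: Priors,
    tol: float,
    max_iter: int,
    keep_trace: bool = False,
) -> dict:
    """Coordinate-ascent VB for many voxels sharing one design.

    Y is (n_trials, n_voxels).  The coefficient update is diagonalised in
    the eigenbasis of X'X so every voxel costs O(d) per iteration despite
    having its own posterior noise precision.
    """
    n, V = Y.shape
    d = X.shape[1]
    p0 = priors.coeff_precision
    a0, b0 = priors.noise_shape, priors.noise_rate

    G = X.T @ X
    evals, Q = np.linalg.eigh(G)
    Xty = Q.T @ (X.T @ Y)  # (d, V) in eigenbasis
    yty = np.einsum("nv,nv->v", Y, Y)

    a_n = a0 + 0.5 * n  # shape is fixed across iterations
    e_lam = np.full(V, a0 / b0)
    F_prev = np.full(V, -np.inf)
    converged = np.zeros(V, dtype=bool)
    n_iter = np.zeros(V, dtype=int)
    trace = [] if keep_trace else None

    const = (
        -0.5 * n * LN2PI
        + 0.5 * d * (np.log(p0) - LN2PI)
        + a0 * np.log(b0)
        - gammaln(a0)
        + 0.5 * d * (1.0 + LN2PI)
    )

    for it in range(max_iter):
        # --- q(w) update: S = (p0 I + E[lam] X'X)^-1, m = E[lam] S X'y
        denom = p0 + e_lam[None, :] * evals[:, None]  # (d, V)
        m_eig = e_lam[None, :] * Xty / denom
        tr_S = (1.0 / denom).sum(axis=0)
        tr_GS = (evals[:, None] / denom).sum(axis=0)
        logdet_S = -np.log(denom).sum(axis=0)
        mm = np.einsum("dv,dv->v", m_eig, m_eig)
        mGm = np.einsum("d,dv,dv->v", evals, m_eig, m_eig)
        mXty = np.einsum("dv,dv->v", m_eig, Xty)
        resid = yty - 2.0 * mXty + mGm
        exp_sq = resid + tr_GS  # E_q ||y - Xw||^2

        # --- q(lambda) update
        b_n = b0 + 0.5 * exp_sq
        e_lam = a_n / b_n
        e_lnlam = digamma(a_n) - np.log(b_n)

        # --- free energy with the freshly updated factors
        F = (
            const
            + 0.5 * n * e_lnlam
            - 0.5 * e_lam * exp_sq
            - 0.5 * p0 * (mm + tr_S)
            + (a0 - 1.0) * e_lnlam
            - b0 * e_lam
            + 0.5 * logdet_S
            + a_n
            - np.log(b_n)
            + gammaln(a_n)
            + (1.0 - a_n) * digamma(a_n)
        )
        if keep_trace:
            trace.append(F.copy())
        newly = (~converged) & (np.abs(F - F_prev) < tol)
        n_iter[newly] = it + 1
        converged |= newly
        F_prev = F
        if converged.all():
            break
    n_iter[~converged] = max_iter

    coeff_mean = Q @ m_eig  # back to regressor basis
    # marginal variances: diag(Q S_eig Q')
    S_diag = np.einsum("di,iv,di->dv", Q, 1.0 / denom, Q)
    return {
        "F": F_prev,
        "coeff_mean": coeff_mean,
        "coeff_precision": 1.0 / S_diag,
        "noise_shape": a_n,
        "noise_rate": b_n,
        "converged": converged,
        "n_iter": n_iter,
        "trace": np.array(trace).T if keep_trace else None,  # (V, n_it)
    }


def vb_fit(
    y: np.ndarray,
    X: DesignMatrix | np.ndarray,
    priors: Priors = Priors(),
    tol: float = 1e-4,
    max_iter: int = 128,
) -> tuple[GLMPosterior, FreeEnergyTrace]:
    """Fit the VB-GLM to one voxel's trial amplitudes.

    Returns the factorised posterior and the free-energy trace, which is
    non-decreasing up to numerical tolerance; ``converged`` records whether
    successive improvements fell below ``tol`` nats within ``max_iter``.
    """
    Xm = X.matrix if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if tol <= 0:
        raise DataError("tol must be positive")
    if not np.all(np.isfinite(y)):
        raise DataError("y contains non-finite values")
    if not np.all(np.isfinite(Xm)):
        raise DataError("design matrix contains non-finite values")
    if len(y) != Xm.shape[0]:
        raise DataError(f"len(y)={len(y)} does not match {Xm.shape[0]} design rows")
    if len(y) < 3:
        raise DataError("need at least 3 trials to fit the VB-GLM")
    res = _vb_fit_batch(y[:, None], Xm, priors, tol, max_iter, keep_trace=True)
    if not res["converged"][0]:
        import warnings

        warnings.warn(
            f"VB did not converge within {max_iter} iterations "
            f"(last dF={np.diff(res['trace'][0])[-1]:.3g} nats)",
            stacklevel=2,
        )
    post = GLMPosterior(
        coeff_mean=res["coeff_mean"][:, 0],
        coeff_precision=res["coeff_precision"][:, 0],
        noise_shape=float(res["noise_shape"]),
        noise_rate=float(res["noise_rate"][0]),
    )
    trace = FreeEnergyTrace(
        values=res["trace"][0],
        converged=bool(res["converged"][0]),
        n_iter=int(res["n_iter"][0]),
    )
    return post, trace


def log_bayes_factor(evidence_a: float, evidence_b: float) -> float:
    """Log Bayes factor ln BF = ln p(y|a) - ln p(y|b)."""
    if not (np.isfinite(evidence_a) and np.isfinite(evidence_b)):
        raise DataError("log evidences must be finite")
    return float(evidence_a) - float(evidence_b)


def kl_gaussian(q_mean: float, q_var: float, p_mean: float, p_var: float) -> float:
    """KL(q || p) between univariate Gaussians, in nats; zero iff q == p."""
    if q_var <= 0 or p_var <= 0:
        raise DataError("variances must be positive")
    return float(
        0.5
        * (
            np.log(p_var / q_var)
            + (q_var + (q_mean - p_mean) ** 2) / p_var
            - 1.0
        )
    )


def evidence_maps(
    images: Sequence[VoxelImageSet],
    specs: Sequence[ModelSpec],
    priors: Priors = Priors(),
    tol: float = 1e-4,
    max_iter: int = 128,
) -> LogEvidenceMaps:
    """Fit every model at every in-mask voxel of every subject.

    ``evidences[n, k, v]`` is the converged free energy of model ``k`` for
    subject ``n`` at voxel ``v``; out-of-mask voxels are NaN.
    """
    if len(images) == 0:
        raise DataError("no subjects provided")
    if len(specs) == 0:
        raise DesignError("no model specs provided")
    ref = images[0]
    for s in images[1:]:
        if s.grid_shape != ref.grid_shape:
            raise GridError(
                f"grid mismatch: {s.subject_id} has {s.grid_shape}, "
                f"expected {ref.grid_shape}"
            )
        if not np.array_equal(s.mask, ref.mask):
            raise GridError(f"mask differs for subject {s.subject_id}")
        if set(s.condition_labels) != set(ref.condition_labels):
            raise DataError(f"condition set differs for subject {s.subject_id}")
    flat_mask = ref.mask.ravel()
    n_vox = flat_mask.size
    ev = np.full((len(images), len(specs), n_vox), np.nan)
    for n, subj in enumerate(images):
        Y = subj.volumes.reshape(subj.n_volumes, -1)[:, flat_mask]
        for k, spec in enumerate(specs):
            X = build_design(subj.condition_labels, spec)
            res = _vb_fit_batch(Y, X.matrix, priors, tol, max_iter)
            ev[n, k, flat_mask] = res["F"]
    return LogEvidenceMaps(
        evidences=ev,
        mask=ref.mask,
        grid_meta=ref.grid_meta,
        model_names=[s.name for s in specs],
        subject_ids=[s.subject_id for s in images],
    )


def write_evidence_maps(maps: LogEvidenceMaps, out_dir) -> list:
    """Write one log-evidence NIfTI per subject per model plus a JSON index."""
    import json
    from pathlib import Path

    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = maps.grid_meta.affine()
    grid = maps.mask.shape
    paths = []
    for n, sid in enumerate(maps.subject_ids):
        for k, model in enumerate(maps.model_names):
            vol = maps.evidences[n, k].reshape(grid).astype(np.float32)
            p = out / f"LogEv_{sid}_{model}.nii"
            nib.save(nib.Nifti1Image(vol, affine), str(p))
            paths.append(p)
    (out / "evidence_meta.json").write_text(
        json.dumps(
            {
                "subject_ids": maps.subject_ids,
                "model_names": maps.model_names,
                "grid_meta": maps.grid_meta.to_dict(),
            },
            indent=2,
        )
    )
    return paths


def read_evidence_maps(in_dir) -> LogEvidenceMaps:
    """Read a directory written by :func:`write_evidence_maps`."""
    import json
    from pathlib import Path

    import nibabel as nib

    d = Path(in_dir)
    meta = json.loads((d / "evidence_meta.json").read_text())
    subject_ids = meta["subject_ids"]
    model_names = meta["model_names"]
    grid_meta = GridMeta.from_dict(meta["grid_meta"])
    vols = []
    for sid in subject_ids:
        row = []
        for model in model_names:
            img = nib.load(str(d / f"LogEv_{sid}_{model}.nii"))
            row.append(np.asarray(img.dataobj, dtype=float).ravel())
        vols.append(row)
    ev = np.asarray(vols)
    mask = np.all(np.isfinite(ev), axis=(0, 1)).reshape(
        nib.load(str(d / f"LogEv_{subject_ids[0]}_{model_names[0]}.nii")).shape
    )
    return LogEvidenceMaps(
        evidences=ev,
        mask=mask,
        grid_meta=grid_meta,
        model_names=model_names,
        subject_ids=subject_ids,
    )


def smooth_map(
    volume: np.ndarray,
    fwhm: float | Sequence[float],
    voxel_sizes: Sequence[float] | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mask-aware Gaussian smoothing with per-axis FWHM in physical units.

    sigma = fwhm / (2 sqrt(2 ln 2)) per axis, converted to voxels through
    ``voxel_sizes`` (unit voxels if omitted).  Inside the mask the kernel is
    renormalised by the smoothed mask so edge voxels are not pulled toward
    zero; fwhm = 0 on every axis is the identity.
    """
    vol = np.asarray(volume, dtype=float)
    fwhm_arr = np.broadcast_to(np.asarray(fwhm, dtype=float), (vol.ndim,)).copy()
    if np.any(fwhm_arr < 0):
        raise DataError("fwhm must be non-negative")
    if voxel_sizes is None:
        voxel_sizes = np.ones(vol.ndim)
    sigma = fwhm_arr * FWHM_TO_SIGMA / np.asarray(voxel_sizes, dtype=float)
    if mask is None:
        mask = np.isfinite(vol)
    mask = np.asarray(mask, dtype=bool)
    if np.all(sigma == 0):
        out = np.where(mask, vol, np.nan)
        return out
    filled = np.where(mask, vol, 0.0)
    num = ndimage.gaussian_filter(filled, sigma=sigma, mode="constant")
    den = ndimage.gaussian_filter(mask.astype(float), sigma=sigma, mode="constant")
    out = np.full_like(vol, np.nan)
    inside = mask & (den > 0)
    out[inside] = num[inside] / den[inside]
    return out
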