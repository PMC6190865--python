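"""Random-effects Bayesian model selection over a group of subjects.

Model identity is treated as a random effect: each subject's data may have
been generated by a different model, and the group-level model frequencies
``r = (r_1 .. r_K)`` carry a Dirichlet distribution.  Given per-subject
log model evidences, a variational fixed-point iteration returns the
posterior Dirichlet ``Dir(r; alpha)``:

    u_nk  = exp( ln p(y_n | m_nk) + psi(alpha_k) - psi(sum_j alpha_j) )
    beta_k = sum_n u_nk / sum_j u_nj
    alpha  = alpha_0 + beta

``alpha_0 = 1`` for every model means no model has been "seen" a priori.
From ``alpha`` follow the posterior model probability ``<r_k> =
alpha_k / sum(alpha)`` (the PPM value) and the exceedance probability
``phi_k = P(r_k > r_j for all j != k)`` (the EPM value).  Fixed-effects
alternatives (Bayes factors and the Group Bayes Factor) are provided for
comparison; they assume one model generated every subject's data and are
not robust to outliers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import digamma

from .errors import DataError, GridError
from .vbglm import LogEvidenceMaps
from .volumes import GridMeta

log = logging.getLogger(__name__)


@dataclass
class DirichletPosterior:
    """Posterior Dirichlet over group model frequencies at one voxel.

    ``alpha`` = prior counts plus expected data counts ``beta``; by
    construction ``sum(alpha) == sum(alpha0) + n_subjects``.
    """

    alpha: np.ndarray
    alpha0: np.ndarray
    beta: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.alpha0 = np.asarray(self.alpha0, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if np.any(self.alpha <= 0) or np.any(self.alpha0 <= 0):
            raise DataError("Dirichlet parameters must be positive")

    @property
    def n_models(self) -> int:
        return self.alpha.size


@dataclass
class SubjectModelPosterior:
    """Normalised per-subject model assignment beliefs (rows sum to 1)."""

    u_normalised: np.ndarray

    def __post_init__(self) -> None:
        self.u_normalised = np.asarray(self.u_normalised, dtype=float)
        sums = self.u_normalised.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise DataError("subject posterior rows must sum to 1")


@dataclass
class BMSResult:
    """Voxel-wise group BMS output: alpha, PPM and EPM volumes per model."""

    alpha: np.ndarray  # (K, *grid)
    ppm: np.ndarray  # (K, *grid)
    epm: np.ndarray  # (K, *grid)
    mask: np.ndarray
    grid_meta: GridMeta
    model_names: list[str]
    n_subjects: int
    alpha0: np.ndarray
    subject_posteriors: np.ndarray | None = None  # (N, K, *grid), memory-gated


def write_bms_result(result: BMSResult, out_dir, run_info: dict | None = None):
    """Write PPM/EPM/alpha volumes per model plus a JSON run report."""
    import json
    from pathlib import Path

    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = result.grid_meta.affine()
    for k, name in enumerate(result.model_names):
        for stem, arr in (("PPM", result.ppm), ("EPM", result.epm), ("alpha", result.alpha)):
            nib.save(
                nib.Nifti1Image(arr[k].astype(np.float32), affine),
                str(out / f"{stem}_{name}.nii"),
            )
    report = {
        "model_names": result.model_names,
        "n_subjects": result.n_subjects,
        "alpha0": list(map(float, result.alpha0)),
        "grid_meta": result.grid_meta.to_dict(),
    }
    report.update(run_info or {})
    (out / "bms_report.json").write_text(json.dumps(report, indent=2))
    return out


def read_bms_result(in_dir) -> BMSResult:
    """Read a directory written by :func:`write_bms_result`."""
    import json
    from pathlib import Path

    import nibabel as nib

    d = Path(in_dir)
    report = json.loads((d / "bms_report.json").read_text())
    names = report["model_names"]

    def _stack(stem):
        return np.stack(
            [
                np.asarray(nib.load(str(d / f"{stem}_{n}.nii")).dataobj, dtype=float)
                for n in names
            ]
        )

    alpha = _stack("alpha")
    ppm = _stack("PPM")
    epm = _stack("EPM")
    mask = np.all(np.isfinite(ppm), axis=0)
    return BMSResult(
        alpha=alpha,
        ppm=ppm,
        epm=epm,
        mask=mask,
        grid_meta=GridMeta.from_dict(report["grid_meta"]),
        model_names=names,
        n_subjects=int(report["n_subjects"]),
        alpha0=np.asarray(report["alpha0"], dtype=float),
    )


def _rfx_update_batch(
    log_ev: np.ndarray,
    alpha0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed-point iteration for a stack of voxels.

    log_ev is (V, N, K); returns (alpha (V,K), beta (V,K), u (V,N,K)).
    The u update is done in the log domain with the per-row maximum
    subtracted before exponentiation — exact, because only within-row
    differences enter the normalised belief.
    """
    V, N, K = log_ev.shape
    alpha = np.tile(alpha0, (V, 1)).astype(float)
    g = np.full((V, N, K), 1.0 / K)
    for _ in range(max_iter):
        w = (
            log_ev
            + digamma(alpha)[:, None, :]
            - digamma(alpha.sum(axis=1))[:, None, None]
        )
        w -= w.max(axis=2, keepdims=True)
        u = np.exp(w)
        g = u / u.sum(axis=2, keepdims=True)
        beta = g.sum(axis=1)
        alpha_new = alpha0[None, :] + beta
        delta = np.abs(alpha_new - alpha).max()
        alpha = alpha_new
        if delta < tol:
            break
    return alpha, alpha - alpha0[None, :], g


def rfx_update(
    log_evidences: np.ndarray,
    alpha0: Sequence[float] | None = None,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> tuple[DirichletPosterior, SubjectModelPosterior]:
    """Invert the Dirichlet-multinomial hierarchy for one voxel.

    ``log_evidences`` is subjects x models.  Only within-row evidence
    differences matter (adding a constant to a subject's row leaves the
    result unchanged).
    """
    lev = np.asarray(log_evidences, dtype=float)
    if lev.ndim != 2:
        raise DataError("log_evidences must be a subjects x models matrix")
    N, K = lev.shape
    if N < 1 or K < 2:
        raise DataError("need at least 1 subject and 2 models")
    if not np.all(np.isfinite(lev)):
        raise DataError("log evidences must be finite")
    a0 = np.ones(K) if alpha0 is None else np.asarray(alpha0, dtype=float)
    if a0.shape != (K,):
        raise DataError(f"alpha0 must have length {K}")
    if np.any(a0 <= 0):
        raise DataError("alpha0 must be positive elementwise")
    alpha, beta, g = _rfx_update_batch(lev[None], a0, tol, max_iter)
    dp = DirichletPosterior(alpha=alpha[0], alpha0=a0, beta=beta[0], n_subjects=N)
    return dp, SubjectModelPosterior(u_normalised=g[0])


def posterior_model_probabilities(dp: DirichletPosterior) -> np.ndarray:
    """Expected model frequencies <r_k> = alpha_k / sum(alpha) (PPM values)."""
    return dp.alpha / dp.alpha.sum()


def exceedance_probabilities(
    dp: DirichletPosterior,
    n_samples: int = 1_000_000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """phi_k = P(r_k > r_j for all j != k | alpha) (EPM values).

    For two models this is exact via the Beta marginal,
    phi_1 = P(Beta(alpha_1, alpha_2) > 1/2); for K > 2 it is estimated by
    Monte-Carlo Dirichlet sampling with a fixed seed.
    """
    K = dp.n_models
    if K == 2:
        phi1 = float(stats.beta.sf(0.5, dp.alpha[0], dp.alpha[1]))
        return np.array([phi1, 1.0 - phi1])
    if n_samples < 10_000:
        warnings.warn(
            f"n_samples={n_samples} is small for K={K}; attained MC s.e. "
            f"~{0.5 / np.sqrt(max(n_samples, 1)):.2g}",
            stacklevel=2,
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    draws = rng.dirichlet(dp.alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    phi = np.bincount(winners, minlength=K) / n_samples
    se = np.sqrt(phi * (1 - phi) / n_samples)
    log.debug(
        "exceedance MC: sum(phi)=%.6f, max s.e.=%.2g", phi.sum(), se.max()
    )
    return phi


def bayes_factor_to_posterior(bf: float) -> float:
    """Two-model posterior probability under uniform model priors.

    bf/(1+bf): the strong-evidence landmark BF = 20 maps to 20/21 > 0.95.
    """
    if not np.isfinite(bf) or bf <= 0:
        raise DataError("Bayes factor must be positive and finite")
    return float(bf / (1.0 + bf))


def group_bayes_factor(log_evidences: np.ndarray, k_a: int, k_b: int) -> float:
    """Log Group Bayes Factor: fixed-effects sum of per-subject log BFs."""
    lev = np.asarray(log_evidences, dtype=float)
    if lev.ndim != 2:
        raise DataError("log_evidences must be a subjects x models matrix")
    return float(np.sum(lev[:, k_a] - lev[:, k_b]))


def voxelwise_bms(
    maps: LogEvidenceMaps,
    alpha0: Sequence[float] | None = None,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    n_samples: int = 1_000_000,
    seed: int | None = 0,
    keep_subject_posteriors: bool = False,
) -> BMSResult:
    """Run the RFX inversion independently at every in-mask voxel.

    Fills K posterior-probability volumes (PPMs), K exceedance volumes
    (EPMs) and K alpha volumes; out-of-mask voxels are NaN.  Masked-out
    evidence at an in-mask voxel is an error — nothing is imputed.
    """
    K = maps.n_models
    N = maps.n_subjects
    if K < 2:
        raise DataError("voxelwise BMS needs at least two models")
    flat_mask = maps.mask.ravel()
    if not flat_mask.any():
        raise GridError("no in-mask voxels")
    a0 = np.ones(K) if alpha0 is None else np.asarray(alpha0, dtype=float)
    if np.any(a0 <= 0):
        raise DataError("alpha0 must be positive elementwise")
    lev = maps.evidences[:, :, flat_mask]  # (N, K, Vin)
    if not np.all(np.isfinite(lev)):
        bad = np.flatnonzero(~np.isfinite(lev).all(axis=(0, 1)))
        raise DataError(
            f"non-finite log evidence inside the mask at {bad.size} voxel(s); "
            "sanitize or re-mask before group inference"
        )
    stack = np.moveaxis(lev, 2, 0)  # (Vin, N, K)
    alpha, beta, g = _rfx_update_batch(stack, a0, tol, max_iter)
    ppm_in = alpha / alpha.sum(axis=1, keepdims=True)

    if K == 2:
        phi1 = stats.beta.sf(0.5, alpha[:, 0], alpha[:, 1])
        epm_in = np.column_stack([phi1, 1.0 - phi1])
    else:
        rng = np.random.default_rng(seed)
        epm_in = np.empty_like(alpha)
        for v in range(alpha.shape[0]):
            dp = DirichletPosterior(
                alpha=alpha[v], alpha0=a0, beta=beta[v], n_subjects=N
            )
            epm_in[v] = exceedance_probabilities(dp, n_samples=n_samples, seed=rng)

    grid = maps.mask.shape

    def _fill(values_in: np.ndarray) -> np.ndarray:
        out = np.full((values_in.shape[1],) + (flat_mask.size,), np.nan)
        out[:, flat_mask] = values_in.T
        return out.reshape((values_in.shape[1],) + grid)

    subject_post = None
    if keep_subject_posteriors:
        subject_post = np.full((N, K, flat_mask.size), np.nan)
        subject_post[:, :, flat_mask] = np.moveaxis(g, 0, 2)
        subject_post = subject_post.reshape((N, K) + grid)

    return BMSResult(
        alpha=_fill(alpha),
        ppm=_fill(ppm_in),
        epm=_fill(epm_in),
        mask=maps.mask,
        grid_meta=maps.grid_meta,
        model_names=list(maps.model_names),
        n_subjects=N,
        alpha0=a0,
        subject_posteriors=subject_post,
    )
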