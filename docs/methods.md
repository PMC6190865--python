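# Methods

## Model

### Per-voxel GLM and variational evidence

At one voxel, the trial amplitudes `y` (length = number of trials) under
model *m* follow

    y = X w + e,    e ~ N(0, λ⁻¹ I)

where `X` has two columns: the model's condition covariate (one weight
per condition, mapped to trials, mean-centred) and an intercept. Priors:
`w ~ N(0, p₀⁻¹ I)` and `λ ~ Gamma(a₀, b₀)`. The posterior is
approximated by the mean-field factorisation `q(w) q(λ)` optimised by
coordinate ascent; each sweep updates `q(w)` (Gaussian, diagonalised in
the eigenbasis of `X'X` so a whole volume of voxels is updated at once),
then `q(λ)` (Gamma), then evaluates the variational free energy

    F = E_q[ln p(y, w, λ)] − E_q[ln q(w, λ)] ≤ ln p(y | m).

`F` is non-decreasing over sweeps (tested to 1e-8) and the converged
value is the log-evidence surrogate used for model comparison. On a
20-trial single-regressor toy, the gap between converged `F` and the
exact log evidence (2-D quadrature over slope and log noise precision)
is ≈ 0.026 nat.

**Covariate scaling.** The centred covariate is scaled to unit Euclidean
norm by default. Competing condition-weight models span different raw
covariate norms (`[1,2,2,3]` centred has squared norm 2 per condition
block; `[1,4,2,3]` has 5), and under a shared fixed-precision coefficient
prior the larger-norm model would pay a systematically larger Occam
penalty: measured on pure noise, ln BF would be biased by ≈ +0.46
nat/subject toward the smaller model, dragging null-voxel PPMs to ≈ 0.88.
Unit-norm scaling equalises the complexity penalty without changing any
model's explanatory subspace (it only rescales the coefficient's units);
with it, null-voxel ln BF is centred on zero (measured mean 0.003) and
null PPMs on 0.5. Disable with `build_design(..., normalise=False)`.

### Random-effects group stage

Group model frequencies `r = (r₁..r_K)` carry a Dirichlet prior
`Dir(α₀)`, each subject's generating model is multinomial given `r`, and
the subject's data enter only through the per-model log evidences. The
variational fixed point is

    u_nk = exp(ln p(y_n|m_nk) + ψ(α_k) − ψ(Σ_j α_j))
    β_k  = Σ_n u_nk / Σ_j u_nj
    α    = α₀ + β

iterated until `max |Δα| < tol`. Per-subject rows are normalised before
summation; the exponent is computed in the log domain with the row
maximum subtracted (exact, because only within-row differences enter).
`Σα = Σα₀ + N` holds identically and is asserted after every run.

From `α` follow the PPM value `⟨r_k⟩ = α_k/Σα` and the exceedance
probability `φ_k = P(r_k > r_j ∀ j≠k | α)` — for `K = 2` exactly
`φ₁ = P(Beta(α₁, α₂) > ½)`, for `K > 2` by Dirichlet Monte-Carlo
(default 10⁶ draws, seeded). Note that for two models the PPM and EPM
are related but *not* equal (α = [3,1] gives ⟨r₁⟩ = 0.75 but
φ₁ = 1 − 0.5³ = 0.875); claims that they coincide for K = 2 conflate
the two quantities, and both maps are produced literally.

Fixed-effects operations (log Bayes factor, log Group Bayes Factor =
sum of per-subject log BFs, and the BF → posterior map `bf/(1+bf)`, under
which BF = 20 ↦ 20/21 > 0.95) are provided for comparison; the test
suite demonstrates the standard outlier failure of the GBF that the
random-effects stage avoids.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `coeff_precision` p₀ | 1e-3 | 1/amplitude² | weakly informative; evidence dominated by data |
| `noise_shape`, `noise_rate` | 1e-3, 1e-3 | — | Jeffreys-like vague Gamma |
| VB `tol` / `max_iter` | 1e-4 nat / 128 | — | iterate until F improvements are negligible |
| smoothing FWHM | 1 voxel-unit/axis | physical units | the conventional small evidence-image kernel; "half-width" specifications are read as FWHM |
| `α₀` | all ones | counts | no model seen a priori |
| RFX `tol` / `max_iter` | 1e-6 / 10⁴ | — | fixed-point convergence on α |
| MC draws (K>2 EPM) | 10⁶ | — | s.e. ≤ 5e-4 |
| threshold | 0.75 scalp / 0.5 source | probability | strict `>`, adjustable |
| connectivity | face (6-neighbour) | — | conservative, deterministic |
| min cluster size | 0 | voxels | keep all clusters; 16 is the conventional fMRI default |

## The synthetic world

`simulate_group` emulates a heterogeneous cohort (default 21 subjects,
near-even model split unless assignments are given): per trial,

    amplitude = intercept + effect_size · weight_k(condition) + N(0, noise_sd²)

on a block of "signal" channels during a fixed peristimulus window, pure
noise elsewhere. Channels sit on a regular 8×8 raster; the signal block
is the nominal effect square **expanded by one electrode spacing**, so
every grid voxel inside the square interpolates exclusively from signal
channels and inherits the planted mean exactly (with `noise_sd = 0`,
condition means at effect voxels are exactly `intercept +
effect_size·weight`). Voxels partially influenced by signal channels are
recorded as a *halo* — neither effect nor null — and excluded from both
sides of calibration checks. One root seed spawns per-subject
substreams, so adding a subject never changes earlier subjects' data.

Defaults (`effect_size = 1`, `noise_sd = 1`, 30 trials/condition) are
chosen for test power: they give per-subject effect-voxel |ln BF| ≈ 30–50
nats, i.e. decisive single-subject model identification, which is what
the group stage needs to show its behaviour cleanly. The generator makes
no attempt at realistic ERP waveforms, volume conduction, artifacts, or
realistic inter-subject variability — a green end-to-end test
establishes the pipeline's statistical machinery, not its performance on
real recordings.

`simulate_log_evidences` is a direct fixture for the group stage: each
subject's generating model is drawn from the given frequencies, every
entry receives independent N(0, 1) jitter and the generating model's
entry is raised by `evidence_scale`.

## Numerical choices

- Scalp interpolation is piecewise-linear barycentric on a Delaunay
  triangulation of channel positions; no extrapolation outside the
  convex hull (masked). Exact at channel locations and for affine
  fields; bounded by the channel value range.
- Out-of-mask voxels are NaN on disk (NIfTI) and an explicit boolean
  mask in memory; volumes are stored float32. Source-space evidence
  volumes can be NaN-sanitised to zeros (`sanitize_source_map`), with
  the replacement count logged.
- Smoothing is mask-aware: the volume is zero-filled, filtered, and
  renormalised by the filtered mask, so edge voxels are not pulled
  toward zero. FWHM→σ uses `σ = FWHM / (2√(2 ln 2))`.
- Cluster peak ties break to the lexicographically first voxel; tables
  sort by size descending, then peak index.
- Cluster thresholding is strict (`p > threshold`), never `≥`.

## Known limitations

- **VB overconfidence at small N and weak evidence.** Against an exact
  (quadrature) inversion of the two-model hierarchy, the Dirichlet fixed
  point's posterior mean deviates by < 1e-3 when per-subject evidence is
  decisive (≥ ~2 nats) or flat, but by up to ~0.08 when all subjects
  carry ~0.5–1 nat, N ≤ 4: the digamma term feeds back on itself
  ("rich get richer"). This is a property of the approximation, not of
  the implementation.
- **Null-voxel PPM dispersion.** At pure-noise voxels, per-subject
  ln BF is χ²-difference distributed (sd ≈ 0.8 nat regardless of trial
  count), and at N = 21 the fixed-point feedback is near-critical, so
  null PPMs spread widely (sd ≈ 0.19) around their correct mean 0.5.
  Consequently a moderately heterogeneous effect (14/7 split: PPM capped
  at 15/23 = 0.652) cannot be separated from upper-tail noise voxels by
  any single-voxel threshold: suprathreshold noise occupancy exceeds the
  percolation limit and noise components merge. The planted blob is
  still recovered as one connected suprathreshold cluster at its true
  location; a homogeneous effect (PPM → (1+N)/(2+N)) separates cleanly.
  Practical implication: threshold choices for PPMs should anticipate
  heavy-tailed null fluctuation, and heterogeneous-effect extents are
  better read from EPMs/PPMs jointly than from cluster counts.
- **Frequency-recovery precision is sampling-limited.** With N = 50
  subjects drawn from frequencies (0.7, 0.3), the binomial spread of the
  realised assignment counts alone means even an oracle estimator lands
  within ±0.1 of the true frequency in only ≈ 87–91% of replications;
  the implemented estimator achieves 80/100 (unbiased: mean recovered
  frequency 0.718).
- Errors are assumed independent across trials (no autoregressive
  modelling) and voxels are fitted independently (no spatial coefficient
  priors); smoothing of evidence images is the only spatial
  regularisation.
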