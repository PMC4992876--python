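# Methods

`fmisopk` quantifies tumor hypoxia from dynamic PET of a nitroimidazole
tracer (¹⁸F-FMISO) using compartmental and graphical pharmacokinetic
analysis. This note records the models, the conventions the package fixes
where the field leaves them open, and the limitations of validating against
synthetic data.

## Kinetic model

Tissue tracer kinetics follow a two-tissue serial compartment model driven
by arterial plasma:

    dC_d/dt = K1·C_p − (k2 + k3)·C_d + k4·C_a
    dC_a/dt = k3·C_d − k4·C_a

`C_d` is the non-specific diffusive pool, `C_a` the specific accumulative
pool (reduced nitroimidazole adducts retained in viable hypoxic cells).
Transport is purely diffusive — no active-transport terms. `K1`
(mL/g/min) is plasma→tissue delivery, `k2` (1/min) efflux, `k3` (1/min)
the hypoxia-specific trapping rate, and `k4` (1/min) the reverse rate,
zero in the irreversible variant that is the package default. The measured
ROI signal is the convex mixture

    C_ROI(t) = w_p·C_p(t) + w_d·C_d(t) + w_a·C_a(t),  w_p + w_d + w_a = 1,

with `w_p` the fractional blood volume. The macro (net influx) rate of the
irreversible model is `Ki = K1·k3/(k2+k3)` (mL/g/min), equal to the
late-time Patlak slope of the tissue concentration.

Rates are stored per minute (the field's convention) and converted to per
second at evaluation; all timelines are seconds post injection, and
injection coincides with acquisition start.

### Solver

`C_p` is treated as piecewise linear between samples (ramped from (0, 0)
before the first sample). Because the system is linear time-invariant, the
solution is an exact linear combination of exponential convolutions
`h_λ(t) = ∫₀ᵗ e^{λ(t−s)} C_p(s) ds` over the two eigenvalues of the rate
matrix — always real and nonpositive, since the discriminant
`(k2+k3−k4)² + 4·k3·k4` is nonnegative. Each convolution obeys an exact
one-step recurrence per `C_p` segment (coefficients from the stable
`φ₁(z) = (e^z−1)/z` and `φ₂(z) = (e^z−1−z)/z²` forms), evaluated as a
first-order IIR filter on uniform grids. There is no ODE step size to
tune; results are exact for the piecewise-linear input up to round-off,
and tests confirm agreement with stiff `solve_ivp` integration to well
below 0.1%. A near-defective eigenvalue pair (possible only when
`k3·k4 ≈ 0` with `k2+k3 ≈ k4`) is split by a relative 1e−9 nudge, far
below fit noise.

Model predictions compared with measured TACs are **frame averages**
`(1/Δt)∫ C_ROI dt`, not midpoint samples, because PET frames integrate
counts; frame integrals come in closed form from `h_λ` at frame boundaries
via `∫ h_λ = (h_λ − ∫C_p)/λ`.

## Identifiability and the weight convention

With both `w_p` and `w_d` free, the weighted model is structurally
unidentifiable. For the irreversible variant the signal is

    C_ROI = w_p·C_p + [K1·w_d − K1·w_a·k3/α]·h_{−α} + [K1·w_a·k3/α]·P,

with `α = k2+k3` and `P = ∫C_p`: four observable features
(`w_p`, `α`, two amplitudes) determine five parameters, so a
one-parameter family of rate/weight combinations reproduces any noiseless
TAC exactly and the fitted rates depend on the optimizer's starting point.
The same count applies to the reversible variant.

The package therefore fits, by default, with a **fixed diffusive split**:
the extravascular volume `1 − w_p` is divided `w_d : w_a` at a fixed ratio
(default 0.60 : 0.35, i.e. split 0.632), leaving `K1, k2, k3, (k4), w_p`
free — an exactly identifiable parameterization under which noiseless
fits recover all rates to better than 0.1% across the realistic parameter
range. The historical procedure with `w_d` free is available as
`FitConfig(weight_mode="free")`; it reaches the same residuals but its
rate estimates carry the gauge freedom above and should be interpreted
only through identifiable combinations (e.g. `α`, `Ki`-type amplitudes).

## Fitting

Bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`, `trf`) with box bounds [0, 1] on every
rate and weight coordinate; `w_a` is eliminated by the sum-to-one
constraint (internally `w_d = (1−w_p)·θ`, `θ ∈ [0,1]`, so bounds alone
keep weights admissible). The default single initialization is
`K1 = k2 = k3 = 0.01, w_p = w_d = 0.1`; when it fails to converge or
leaves the residual above the acceptance threshold, up to four additional
log-normally jittered starts (fixed internal seed, deterministic) are
tried and the best SSE kept. Residual weighting is uniform by default
with an optional `sqrt(frame duration)` weighting, which is closer to
inverse-variance under counting noise.

Goodness of fit is the residual percentage

    ε = 100 · mean_i |tac_i − model_i| / max_i tac_i,

scale-free and robust to near-zero early frames; ε < 5% is the
conventional acceptance threshold. A pointwise-relative alternative
(frames above 10% of the maximum) is selectable. The exact formula behind
published ε tables is not standardized, so cross-study ε comparisons are
qualitative (ordering), not numeric.

TACs indistinguishable from background are refused rather than
noise-fitted (mirroring the convention of reporting zero rates for tumors
with no visible uptake): the refusal triggers when the TAC maximum is
below 3× a robust per-frame noise scale estimated from second differences
(zero for noiseless curves, ≈ the frame SD for pure background). Ratio
and switch are configurable.

### k4 under noise

On data simulated without reversibility, the reversible fit's `k4`
collapses to ~1e−6/min on noiseless TACs — the nesting degeneracy. Under
counting noise, however, the profile likelihood in `k4` is nearly flat
and its estimate is set by the noise floor: at 0.2–0.7% frame noise,
fitted `k4` is typically 1e−3–1e−2/min even though the generating model
has `k4 = 0`, and the nonzero-`k4` optimum genuinely lowers the SSE. A
small fitted `k4` is therefore evidence about the model only when the fit
is essentially noise-free; otherwise it measures noise, not efflux.

## Patlak analysis

The transform plots `y = C_t(t)/C_p(t)` against normalized time
`x = ∫₀ᵗC_p/C_p(t)` (minutes) at frame midpoints, with `∫C_p` trapezoidal
on the input grid; frames where `C_p` falls below 1% of its peak are
flagged invalid. The line is ordinary least squares over valid points
with `t ≥ t*`; `t* = 30 min` by default — past the fast exponentials
implied by observed tumor rate constants (1/(k2+k3) ≈ 14–28 min), and the
slope then matches `Ki` within 5% (2% at `t* = 60 min`) on noiseless
tissue curves. A weighting option exists but is off by default.

Two caveats the package makes explicit:

* The Patlak slope of the **weighted ROI signal** is `w_a·Ki`, not `Ki`:
  only the trapped pool contributes slope, the `w_p` and `w_d` terms feed
  the intercept. Slope = `Ki` holds for the blood-free total tissue
  concentration `C_d + C_a` (`tissue_concentration_tac`). Voxelwise `Ki`
  maps computed from measured images are therefore *apparent* influx maps
  (scaled by the local `w_a`); phantom ground truth records both `Ki` and
  `w_a·Ki`.
* With `k3 = 0` the slope is a transient that decays only as `t*` grows
  past `1/(k2+k3)`; "no trapping ⇒ zero slope" is an asymptotic
  statement.

`reference_patlak` substitutes a reference-tissue TAC (muscle) for the
plasma curve, yielding a relative slope in 1/min — used for whole-body
mapping when no reliable plasma curve exists.

## ROI analysis

Tumor ROIs are defined by fractional-maximum thresholding (default 50% of
the in-box maximum — the threshold value is a package convention; the
source protocols rarely state theirs) with largest-6-connected-component
cleanup to drop speckle and necrotic fragments. The dynamic-analysis
tumor ROI is conventionally drawn on the last frame; the blood ROI on the
mean of frames fully inside the first minute, where the vascular bolus is
the hottest structure. The image-derived input function is that ROI's
TAC sampled at frame midpoints, with the final value held through the
last half-frame. Static uptake is scored by the tumor-to-blood ratio;
T/B strictly above 1.2 is called hypoxic.

Inputs are assumed decay-corrected (the standard output of PET
reconstruction); an F-18 (half-life 109.77 min) correction utility is
provided but off by default, keeping the model radionuclide-agnostic.

## Parametric mapping

`ki_map` runs the Patlak regression per voxel over a body mask — cheap
because all voxels share one normalized-time axis — clamping negative
slopes to zero; `k3_map` fits the irreversible model per voxel inside the
tumor, warm-started from the whole-ROI fit (single start, which cuts
wall time and non-convergence). Failed voxels are carried as NaN in a
validity mask. The "map volume" overlap statistic is the percent of
tumor voxels at or above a level, by default 20% of the within-tumor map
maximum; overlap percentages are threshold-dependent and should be read
qualitatively. No smoothing is applied.

Known estimator behavior: voxel k3 estimates in low-k3 (normoxic) tissue
have a heavy right tail under noise — at sub-percent frame noise, of
order 10% of rim voxels can exceed a level midway between rim and core
k3. The phantom mapping validation therefore runs at the noiseless
default; quantitative overlap under realistic voxel noise requires a
more conservative level (e.g. 50% of maximum) or spatial regularization,
which the package deliberately does not apply by default.

## Synthetic data

The generator emulates a 2 h, 52-frame small-animal acquisition
(10×30 s, 10×60 s, 10×120 s, 10×150 s, 12×300 s). The plasma input is a
bolus: linear rise to a peak (default 30 s, 1000 Bq/mL — an arbitrary
scale, since the model is linear in activity) followed by a
tri-exponential washout (decay constants 3.0, 0.25, 0.003 /min; weights
0.6/0.25/0.15), giving the long circulation and slow late plateau
characteristic of this tracer, sampled at 1 s.

Noise is zero-mean Gaussian per frame with SD `σ₀·sqrt(value/Δt)` — the
counting-statistics surrogate for reconstructed-PET noise. Named levels
`low/moderate/high` (σ₀ = 2/5/15) correspond at the default scale to
whole-ROI, small-ROI and single-voxel noise respectively (≈0.7%, 1.7%,
5% relative SD in late 300 s frames; several-fold worse in the first
30 s frames).

The default phantom is 32³ voxels (0.8 mm): a muscle body sphere, a pure
blood pool (the left-ventricle stand-in, `w_p = 1`), and a tumor sphere
whose hypoxic core is exactly `round(f·n_tumor)` voxels nearest the
tumor center (so the designed hypoxic fraction is exact by
construction), the rest a normoxic rim (k3 = 0.002/min). Tissue presets
encode the published whole-tumor rate-constant means for the two
xenograft scenarios at each imaging time point, with weights
`w_p = 0.05, w_d = 0.60, w_a = 0.35` (fitted weights are never published;
these are plausible conventions, and recovery tests treat weights as
nuisance parameters). The phantom includes no scanner PSF, attenuation,
scatter, motion, or partial-volume effects — passing its tests
demonstrates correctness of the estimators under the model's own
assumptions, not robustness to real-scanner physics.

All simulator outputs are bit-reproducible given (spec, seed).

## Problem sizes and determinism

Validation runs use the 52-frame schedule with the 1 s input grid
(7201 samples), 20-point parameter-recovery grids, 50 noisy replicates
for the stochastic k3 recovery check, and the 32³ phantom (~900 tumor
voxels) for mapping — sizes chosen so the whole suite completes in a few
minutes on one CPU. Every stochastic path takes an explicit seed;
optimizer multi-starts use a fixed internal seed, so all results are
deterministic.

## Limitations

* The left-ventricle image curve is used as plasma input without
  plasma/whole-blood, metabolite or delay/dispersion correction,
  following common small-animal practice.
* ε is a package-defined convention; published ε values from other
  implementations are comparable only in ordering.
* The free-weight fit variant is unidentifiable (see above); its rate
  output is initialization-dependent by nature.
* Apparent-vs-true `Ki` in voxel maps differs by the local `w_a`; absolute
  voxel `Ki` calibration would require knowing the compartment volume
  fractions.
* Patlak assumes effectively irreversible trapping; no Logan/reversible
  graphical variant is provided.
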