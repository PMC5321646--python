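# Methods

## Models

### Compartment models with plasma input

Tissue concentration follows linear compartmental kinetics driven by the
metabolite-corrected parent plasma curve `C_p(t)`:

* **1T**: `dC1/dt = K1·C_p − k2·C1`
* **2T**: adds a specific compartment, `dC2/dt = k3·C1 − k4·C2`
* **3T**: adds a non-specific compartment in *parallel* off the free
  compartment, `dC3/dt = k5·C1 − k6·C3`

The parallel topology is forced by the closed-form total distribution
volume used throughout, `V_T = (K1/k2)(1 + k3/k4 + k5/k6)`; a serial
third compartment would give a different expression. Macro parameters:
`BP_ND = k3/k4` and `DVR − 1 = V_T/V_T,ref − 1`.

The measured PET signal is the frame average of
`(1 − vB)·C_tissue(t) + vB·C_blood(t)` with whole-blood activity
`C_blood` and fractional blood volume `vB = 0.05` (fixed, not fitted).

### Spectral analysis

The TAC (after optional subtraction of the blood term) is decomposed as a
non-negative sum of `C_p ⊗ exp(−β t)` over 50 log-spaced `β` in
[0.001, 1] s⁻¹, solved by NNLS on column-normalised bases;
`V_T = Σ αᵢ/βᵢ`. Components are counted as adjacency clusters of
coefficients above 1% of the spectrum maximum. A three-tissue TAC has
three eigen-rates and, noiselessly, the spectrum resolves all three.

### Reference-tissue models

All reference models eliminate the plasma input in the Laplace domain:

* **SRTM** (both regions 1T): solved by the basis-function method — a log
  grid of 100 apparent-efflux values `θ = k2/(1 + BP_ND)` in
  [0.006, 6] min⁻¹ with an exact linear subproblem in `(R1, φ)` per `θ`,
  followed by bounded scalar refinement of `θ` between the neighbours of
  the best grid point so the estimate is not quantised to the grid.
* **FRTM** (2T target, 1T reference): 4-parameter nonlinear fit of
  `(R1, k2, k3, k4)` with `BP_ND = k3/k4`. The transfer function is
  `R1 (s + k3 + k4)(s + k2/R1) / ((s + a)(s + b))` with `a, b` the
  two-tissue eigen-rates.
* **SRTM-2C** (1T target, 2T reference): 5-parameter fit of
  `(R1, k2a, k2r, k3r, k4r)`; under a shared non-displaceable volume,
  `BP_ND = R1·k2r/k2a − 1`. It is seeded from the SRTM solution so the
  one-tissue-reference limit is always reachable.

Nonlinear reference fits run multistart (5 starts) bounded least squares in
log-parameter space.

## Parameters and defaults

| Quantity | Default | Units |
|---|---|---|
| Frame schedule | 6×10, 4×30, 2×60, 1×120, 1×180, 4×300, 3×600 s | 60 min total |
| Simulation grid | k3 = 0.20 … 2.60 step 0.15 (17 configs) | min⁻¹ |
| Fixed rates | K1 = 0.8 ml·cm⁻³·min⁻¹; k2 = 2.25, k4 = 0.17, k5 = 0.15, k6 = 0.08 min⁻¹ | |
| Blood volume | vB = 0.05 | unitless |
| Plasma input | tri-exponential bolus (A = 80, 1.2, 0.9; λ = 4.5, 0.4, 0.02 min⁻¹; τ = 0.25 min) | |
| Parent fraction | 0.15 + 0.85·exp(−0.06 t) | t in min |
| Plasma/blood ratio | 1.25 | |
| Fit bounds | K1 ∈ [0.01, 5]; k2–k6 ∈ [0.001, 5] | min⁻¹ |
| Noise levels | 5% and 10% of late-scan uptake, 25 replicates | |

## Numerical methods

* **Convolution.** `u ⊗ exp(−λt)` for piecewise-linear `u` obeys an exact
  one-step recursion, run as an IIR filter (`scipy.signal.lfilter`); the
  coefficient `1 − e^{−x}(1+x)` is evaluated by series for small `x` to
  avoid cancellation. This makes every model evaluation exact for the
  sampled input, not an ODE approximation (verified against a stiff LSODA
  integration at rtol 1e-11).
* **Impulse response.** Tissue responses come from the eigendecomposition
  of the rate matrix; (near-)degenerate eigenvalues are split by a relative
  1e-7 diagonal perturbation.
* **Grids and frame averaging.** Model curves are evaluated on a uniform
  0.5 s grid aligned with the frame boundaries; frame averages are a
  precomputed trapezoid weight matrix, normalised over the span the
  weights actually cover so constants average exactly.
* **Reference-curve reconstruction.** The reference region is only known
  as frame averages. Naive linear interpolation through frame midpoints
  does not average back to the measured values (it clips the early peak)
  and biases any convolution built from it, so reference fitters use a
  piecewise-linear curve whose node values are iterated until the
  frame-average operator reproduces the measurements (fixed point,
  converges to 1e-12 in a few iterations).
* **Residual weighting.** Reference-tissue fits weight residuals by
  √(frame duration) — the usual weighting for framed PET data. This
  matters beyond noise propagation: the reference models are structurally
  mis-specified against three-tissue data, so their fitted parameters
  depend on how the deterministic misfit is weighted. Duration weighting
  makes the discrete objective a quadrature of the continuous-time
  least-squares criterion, so estimates do not depend on how the
  acquisition happens to be framed (verified against dense-grid fits).
  Plasma-input fits stay uniform-weighted, matching the constant-variance
  synthetic noise model.
* **Optimisation.** Plasma-input fits are multistart bounded least squares
  in log space; the 2T model is additionally seeded from the 1T solution,
  which guarantees the nested-model RSS inequality. AIC is
  `n·ln(RSS/n) + 2k`.
* **Benchmark table comparison.** Several published macro values are
  truncated rather than rounded, so each cell is compared to one unit in
  its last printed digit.

## Synthetic generator: realism and limits

The generator is deterministic given a seed: a smooth tri-exponential
bolus input, a mono-exponential-plus-offset parent fraction, a constant
plasma-to-blood ratio, and zero-mean Gaussian frame noise with per-TAC
constant SD equal to `level ×` the mean of the last two noiseless frames
("percent of late uptake"). This is a deliberately simple stand-in for
count statistics: real frame noise scales with frame duration and decay,
is non-negative, and arterial samples carry their own measurement and
metabolite-model error, none of which are modelled. An optional
duration-scaled noise variant is provided. The input function is not fitted
to any measured plasma data, so absolute activity levels are arbitrary;
only ratios (V_T, BP_ND, DVR) are meaningful.

## Limitations

* The pseudo-reference analysis is noiseless; with noise, reference-model
  bias acquires variance not characterised here.
* Blood delay estimation is a 1D grid-plus-parabolic search on the 2T
  model; dispersion of the input function is not modelled.
* The spectral component count is a heuristic (threshold + adjacency) and
  is sensitive to the β grid at low SNR.
* `vB` is fixed, not estimated; misspecified blood volume propagates into
  all plasma-input estimates.
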