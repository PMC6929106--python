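# Methods

## Model

A nucleus of DNA content `DNA_c` (default 6000 Mbp) is divided into
`N_gl = DNA_c / DNA_gl` equal chromatin loops of `DNA_gl` (default 2 Mbp).
The ratio is treated as exact: it is rounded to the nearest integer and a
relative mismatch above 1e-6 is a configuration error.

Damage induction for photons is homogeneous ("low LET"): the total DSB
count is Poisson with mean `α_DSB · D · DNA_c` (`α_DSB` = 5e-3 DSB/(Mbp·Gy),
cell-line independent, constant over the clinical dose range), and each DSB
is assigned to a loop uniformly at random. Loops with exactly one DSB carry
an isolated lesion, loops with two or more a complex lesion. Survival of a
single cell is `(1 − RSF·K_iDSB)^N_iDSB · (1 − K_cDSB)^N_cDSB`; survival of
a population is the arithmetic (linear-space) mean of per-cell values.

No DSB rejoining kinetics, track structure/LET dependence, cell-cycle
structure, or intracellular oxygen diffusion is modeled. Oxygen enters only
through the induction rate (`α_DSB / HRF`); repair impairment enters only
through the isolated-lesion lethality (`RSF · K_iDSB`, with `K_cDSB` held
fixed — complex lesions are taken as maximally challenging regardless of
repair capacity). Consequences used throughout:

* HRF is exactly a dose rescaling: survival at rate `α/h`, dose `D` equals
  survival at rate `α`, dose `D/h` (asserted as an exact identity in tests).
* HRF and RSF compose in either order and the combined condition is a
  prediction with no free parameters.

## Evaluators

`mc_mean_survival` implements the two-step sampling literally (Poisson
total, uniform assignment, counting pass over loop occupancies), vectorized
over iterations in chunks; identical seeds give bit-identical results. The
default iteration count is 1e5 (configurable). A statistical test verifies
the chunked counting pass draws from the same distribution as the
one-nucleus-at-a-time routine.

Because a Poisson total distributed uniformly over `N_gl` loops makes the
per-loop counts i.i.d. Poisson(`λ = α_DSB·D·DNA_gl`), the population mean
has the exact closed form

    E[S] = (e^{−λ} + λe^{−λ}(1 − RSF·K_iDSB) + (1 − e^{−λ} − λe^{−λ})(1 − K_cDSB))^{N_gl},

used as the deterministic evaluator for all fitting and as the oracle the
Monte Carlo routine is tested against (agreement within 3 standard errors
across a randomized parameter sweep).

## LQ correspondence

Expanding `−ln E[S]` to second order in dose gives, with
`λ₁ = α_DSB·DNA_gl` (per-loop DSBs per Gy) and `k′ = RSF·K_iDSB`:

    α = k′ · α_DSB · DNA_c                      [Gy⁻¹]
    β = N_gl · λ₁² · (K_cDSB/2 − k′ + k′²/2)    [Gy⁻²]

Both coefficients are verified against numerical low-dose derivatives of
the closed form (1e-4 relative) for every bundled reference parameter set,
and the quadratic approximation tracks the model within 1 % up to 0.5 Gy.

## Fitting

The staged protocol fits, per cell line:

1. `(K_iDSB, K_cDSB)` to the normoxic untreated curve (bounds [1e-6, 1];
   5 optimizer starts, log-uniform over the bounds with a fixed seed, to
   guard the two-parameter objective against local minima);
2. one `HRF ∈ [1, 10]` per hypoxic oxygen level, lethalities frozen;
3. one `RSF ∈ [1, 1/K_iDSB]` per impairment label from normoxic impaired
   data, lethalities frozen.

The objective is unweighted least squares on `ln SF` (all decades of a
curve spanning 3–4 orders of magnitude contribute comparably); measurement
SEMs can optionally weight residuals as 1/σ² in log space (off by default).
Zero-dose records are excluded — after plating-efficiency normalization
they carry no information. Surviving fractions of exactly 0 are rejected at
validation with the offending row named. Solver: bounded trust-region
least squares (tolerances 1e-14); non-convergence is flagged on the result
rather than raised; an estimate pinned at a bound raises a warning.

Uncertainties are 1σ from the Jacobian-based covariance at the optimum
(residual variance estimated with the appropriate degrees of freedom). For
the staged single-factor fits this conditional covariance is additionally
augmented, to first order via the implicit-function sensitivity of the
optimum, with the covariance of the frozen stage-1 lethality estimates:
the RSF in particular trades off directly against `K_iDSB` through
`RSF·K_iDSB`, and the purely conditional error would understate its
uncertainty several-fold. Normoxia is encoded as `HRF = 1` exactly (the
reference of the fitting protocol), not as the parameterization value at
20 % O₂ (≈ 1.0006); `HRF < 1` (hyperoxia) is rejected unless explicitly
flagged. All fits use the closed-form evaluator, so results are
bit-reproducible for identical inputs and settings.

## Synthetic data

The generator emulates the triplicate clonogenic design the model is used
with: 1/2/4/8 Gy dose points per condition, conditions spanning normoxia,
hypoxia levels and impairment labels, multiplicative log-normal noise on
the surviving fraction (default σ = 0.1 on ln SF, a typical clonogenic
scatter), truncated at SF ≤ 1. By default each replicate is emitted as its
own record, so fits retain the full residual degrees of freedom; mean ± SEM
aggregation is available for display. Identical seeds give identical
datasets, and a test checks the empirical log-residual SD against the
nominal σ.

`benchmark_campaign` draws ground truth inside the published ranges
(`K_iDSB ∈ [1.5, 5]·10⁻³`, `K_cDSB ∈ [0.13, 0.26]`, `HRF ∈ [1.1, 2.5]`,
`RSF ∈ [1.7, 15]`) across a panel shaped like the published benchmarks:
five lines × three O₂ levels, a wild type with two repair-deficient
mutants, and two lines × three inhibitor concentrations including the
combined hypoxia + drug arms.

What the generator does *not* emulate: colony-counting/plating-efficiency
statistics, cell-cycle or dose-rate effects, or systematic model
misspecification. Passing recovery studies therefore demonstrate
identifiability of the model under its own error assumptions on this
design — not robustness on real data.

## Study sizes and numerical choices

The recovery study runs 200 simulated campaigns (one line, three
conditions, triplicate 4-dose curves, σ = 0.1), checking median relative
bias < 5 % for every parameter and pooled ±3σ coverage ≥ 90 %; the Monte
Carlo/closed-form comparison uses 50 randomized parameter/dose
combinations at 1e5 iterations each. These sizes keep each statistical
check's sampling error well below the margins it asserts. Seeds are fixed
everywhere; Monte Carlo chunking changes neither distributions nor seeded
results.

## Known limitations

* The lethality fit has only two parameters but survival curves are
  smooth; with few distinct doses the (K_iDSB, K_cDSB) estimates are
  strongly correlated, and uncertainties from 4-point curves are wide.
* First-order uncertainty propagation can understate strongly nonlinear
  cases (e.g. RSF near its saturation bound `1/K_iDSB`).
* The oxygen parameterization constants (m, K) are taken as given and are
  not refit.
* HRF values for conditions labeled only "< 1 % O₂" must be fitted, not
  parameterized — the exact oxygen level is unknown.
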