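# Methods

This note records the models, estimators, numerical choices and known
limitations of `isruq`, in the order the pipeline runs them.

## Uncertain inputs

Four independent uniform inputs (`isruq.params.default_space`): endothelium
regeneration time 10–20 days, maximum blood flow velocity 0.133–0.399 m/s,
relative threshold strain 0.446–0.785 (dimensionless), and fenestration
percentage of the internal elastic lamina 2–10%. The strain bounds come from
stretch experiments on unstrained tissue (first intimal rupture near 110%
strain, ±20% uncertainty) re-expressed relative to a vessel pre-strained by
30%: `σ_rel = (σ_abs + 1)/1.3 − 1`. The coefficient of variation of a
Uniform(a, b) input is `((b−a)/√12)/((a+b)/2)`; the four CVs round to 0.19,
0.29, 0.16 and 0.38.

Sampling uses Owen-scrambled Sobol sequences (`scipy.stats.qmc`) with an
explicit scramble seed; replicated estimates differ only by that seed. With
scrambling disabled the degenerate all-zeros first point is skipped.
Inputs are modelled as independent; correlated or non-uniform input
distributions are out of scope.

## Growth emulator (synthetic-data generator)

`isruq.emulator` stands in for the cluster-scale multiscale ISR simulator.
The vessel is `n_slices = 100` independent cross-sections with initial lumen
areas `A_i(0) ~ N(3.17, 0.04²)` mm² (the post-deployment lumen of a 2 mm
vessel). Per slice the neointimal area obeys

    dN_i/dt = G · S_i(t) · (1 − E(t)·I(v, A_i)) · (1 − N_i/(N_max · A_i(0)))

with `A_i(t) = A_i(0) − N_i(t)` and

* endothelium coverage `E(t)`: linear to 59% over the first 3 days, then
  linear to 100% at the uncertain regeneration time `T_regen`, constant 1
  afterwards;
* shear inhibition `I = logistic(k_tau (τ − τ0))` with the Poiseuille-type
  wall-shear surrogate `τ = v / r³`, `r = √(A/π)`: fast flow, or a lumen
  already narrowed, suppresses growth once the endothelium has healed;
* seeding factor
  `S_i(t) = (1 − e^{−t/0.5}) (1 + β_f φ e^{−t/t_f}) (1 + β_ε max(0, ε_dep − ε_thr)) (1 + η_i)`:
  a half-day activation ramp, an exponentially decaying fenestration burst
  (φ in %), a strain-excess gain active when the fixed deployment strain
  exceeds the bond-breaking threshold, and per-slice multiplicative noise
  `η_i ~ N(0, 0.08²)` frozen per run.

Integration is explicit Euler at `dt = 0.1` day on a daily output grid of
31 points (day 0 = post-deployment state). QoIs: ACSA is the slice mean of
`A_i(t)`; MRAL is the slice maximum of `1 − A_i(t)/A_i(0)`.

### Calibration of the kinetic constants

The constants have no counterpart measurements; they are calibration knobs
fixed once by a coarse grid search against distribution-level behaviour on
512-run Sobol designs and then frozen:

| constant | value | role |
|---|---|---|
| G | 0.33 mm²/day | peak growth rate |
| τ0, k_tau | 0.42, 1200 | shear-switch threshold and steepness |
| N_frac_max | 0.68 | saturation cap (fraction of initial slice area) |
| β_f, t_f | 0.13 /%, 2.5 day | fenestration burst gain and decay |
| β_ε, ε_dep | 0.25, 0.55 | strain gain and deployment strain |
| noise, initial-area SD | 0.08, 0.04 mm² | slice-level heterogeneity |

The search criteria: day-30 mean MRAL in [0.35, 0.50] with day-30 CVs of
the same order as the reference study (ACSA ≈ 0.10, MRAL ≈ 0.11, MRAL CV >
ACSA CV); growth arrest (per-day ACSA drift < 10⁻³ mm²) within 3 days of
`T_regen` for every sample; monotone day-30 responses (less lumen with
longer regeneration, more fenestration, slower flow) with strain by far the
weakest input; a fenestration influence that peaks at day 2 and is
negligible (first-order index < 0.05) from day 10; and a nearly additive
response at day 30. Verified on three independent 512-run designs (worst
per-day drift 4.4×10⁻⁴ mm²/day, zero violations).

Two mechanisms matter. The steep shear switch makes `A* (v) = π (v/τ0)^{2/3}`
an effective per-velocity floor; trajectories overshoot it during the
endothelium-healing phase, which drives the inhibition factor to 1 in
floating point and produces exact growth arrest. The early fenestration
burst only changes how fast trajectories descend to this floor, not where
it lies, which is what makes the fenestration influence transient.

Numerics: with `k_tau = 1200` the ODE is stiff near the floor, so explicit
Euler is first-order-accurate but not tightly converged: halving `dt`
moves day-30 ACSA by ~1–3×10⁻³ mm². That is two orders below every
statistic we report; the halved-step self-check in the test suite bounds it
at 10⁻² mm². A smoother switch would integrate more accurately but loses
the growth-arrest property.

What the emulator does **not** model: agent-based cell mechanics and cell
cycles, resolved blood flow, stent geometry, inflammation, or any
run-for-run match to the full simulator. Passing tests therefore certify
the surrogate/UQ machinery on a mapping with the right structure — smooth,
monotone, near-additive, heteroscedastic across QoIs — not fidelity to real
restenosis data.

## POD

Snapshot matrices are built from 100 responses drawn uniformly without
replacement (seeded; indices logged). The SVD basis is truncated at the
smallest rank reaching 99.9% relative energy. No mean-centering is applied:
the energy ratio is defined on raw responses, and centering would change
it. On the emulator data this keeps k small (2 for ACSA, 1 for MRAL at 512
runs; the retained rank is always recomputed from the energy rule, never
hard-coded). The error metric is the relative L2 norm per response; the
cross-validation report stores the fold mean (and the unaveraged sum, since
both conventions appear in the literature).

## Gaussian-process regression

Zero-mean GP with ARD-RBF kernel plus independent noise; hyperparameters
`{σ_f, σ_n, ℓ_1..ℓ_d}` fitted by L-BFGS-B on the log marginal likelihood
with analytic gradients, in log-space, 10 restarts (first start fixed,
others drawn log-uniformly: lengthscales in [10⁻², 10], signal SD in
[0.1, 10], noise SD in [10⁻⁴, 1]). Inputs are scaled to the unit hypercube
and targets standardised; constants live in the model. Conditioning policy:
noise variance floored at 10⁻¹⁰ and Cholesky jitter escalating
0 → 10⁻¹⁰ → 10⁻⁸ → 10⁻⁶. Lengthscales are bounded below by 0.05 (unit-cube
units): below the resolution of any design used here, short-lengthscale
interpolation of noise is likelihood-equivalent to a noise fit, and the
bound resolves that degeneracy toward the noise explanation.

The coefficient GPs are treated as independent; the predictive variance of
a reconstructed series sums per-coefficient variances through the squared
basis (`Var(y_t) = Σ_j Var(α_j) φ_jt²`), an approximation that ignores
cross-coefficient covariance. Predicted series may violate monotonicity by
small amounts; where physically required the series is projected onto the
monotone cone (pool-adjacent-violators) and MRAL clipped to [0, 1); the raw
prediction remains available.

Cross-validation is k-fold (default 4) with seeded random folds, POD basis
and GPs refitted inside every fold (strict held-out protocol).

## Uncertainty propagation

Scrambled-Sobol designs through the surrogate; point statistics are pooled
over replicates, and the across-replicate SD of each per-day estimate is
reported as estimator spread (the per-day "SD" itself is always across qMC
samples). Percentile bands are central coverage intervals — symmetric
quantile pairs with linear interpolation between order statistics.
Densities: 50-bin histograms plus Gaussian KDE with Scott bandwidth.
Restenosis fraction: share of samples with MRAL ≥ 0.5 at each day. CVs are
fractions internally, percentages in written tables.

## Sensitivity analysis

Saltelli design from a 2d-dimensional scrambled Sobol draw split into base
matrices A and B plus the d column-swapped hybrids, (d+2)N evaluations
total. Estimators: `S_i = mean(f_B (f_ABi − f_A))/V` (Saltelli-2010) and
`S_Ti = mean((f_A − f_ABi)²)/(2V)` (Jansen), with V from the pooled (f_A,
f_B) sample. Negative estimates are reported as-is (Monte Carlo noise
around small indices); indices are computed on the reconstructed QoI, not
on POD coefficients. Confidence intervals are across-replicate 2.5/97.5
percentiles. The reference interpretation of the study's quoted sample
size is the base N, not the total evaluation count; both are configurable.

Note a rank-1 artifact: when a QoI retains a single POD mode (MRAL here),
all days share one coefficient up to scaling, so its sensitivity indices
are constant over time. The ACSA indices carry the time structure.

## Problem sizes

Defaults in the analysis scripts and acceptance run: 512 training runs, 100
snapshots, fourfold cross-validation, 10⁴ qMC samples × 10 scramble
replicates, and Saltelli base 2¹² × 10 replicates. These desk-scale sizes
keep the full pipeline to a few CPU-minutes while leaving every estimator
in its asymptotic regime; the config exposes the study-scale values (10⁵
and 100 replicates) unchanged.

## Seeds and reproducibility

One master seed derives per-stage seeds (dataset, training, CV, UQ,
sensitivity) through `numpy.random.SeedSequence` spawning, reduced to 31
bits. Every artifact records the seeds and configuration needed to
regenerate it bitwise; CSV floats are written with 17 significant digits
and parsed with round-trip precision.

## Known limitations

* The emulator is phenomenological; its constants are calibrated to
  distribution-level behaviour, not fitted to simulation or clinical data.
* The reconstruction variance ignores cross-coefficient covariance.
* Explicit Euler near the steep shear switch limits trajectory-level
  accuracy to ~10⁻³ mm² (see above).
* Day-0 surrogate statistics inherit a little variance from later days
  through the global POD modes (day-0 CV ≈ 0.02 versus ≈ 0.10 at day 30).
* Higher-order interaction indices beyond first/total are not estimated.
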