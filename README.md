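# isruq — uncertainty quantification of in-stent restenosis with a POD + GP surrogate

In-stent restenosis (ISR) is the renarrowing of a stented coronary artery by
neointimal tissue growth; clinically it is called restenosis once more than
50% of the lumen area is lost. High-fidelity multiscale ISR simulators cost
hundreds of core-hours per run, which rules out direct Monte Carlo
uncertainty quantification. `isruq` implements the standard remedy for
time-dependent outputs: a surrogate that combines **proper orthogonal
decomposition (POD)** of the response with **Gaussian-process (GP)
regression** of the projection coefficients, then drives quasi-Monte Carlo
uncertainty estimation and variance-based sensitivity analysis through the
cheap surrogate.

The package targets the four uncertain inputs of a porcine-vessel stenting
scenario, each uniform on its range:

| parameter | range | unit | CV |
|---|---|---|---|
| endothelium regeneration time | 10–20 | day | 0.19 |
| blood flow velocity | 0.133–0.399 | m/s | 0.29 |
| relative threshold strain | 0.446–0.785 | – | 0.16 |
| IEL fenestration percentage | 2–10 | % | 0.38 |

and two daily quantities of interest over 30 days: the average
cross-sectional lumen area (ACSA, mm²) and the maximum relative area loss
(MRAL, dimensionless).

Because the original cluster-scale simulator is far outside desk budgets,
the package ships a **phenomenological growth emulator**
(`isruq.emulator`): a per-slice logistic-inhibition ODE whose drivers are
the re-endothelialisation schedule, a wall-shear feedback `tau = v / r^3`,
an early fenestration burst and a strain-excess term. It reproduces the
qualitative structure of the full model (slow start, near-linear growth,
growth arrest shortly after the regeneration time, noisier MRAL than ACSA)
and serves as the training-data generator for the whole pipeline.

## The method

Given training pairs `(x_i, y_i)` with `y_i ∈ R^{Nt}`:

1. **POD.** Stack a random subset of responses into a snapshot matrix
   `S = [y_1 | … | y_Ns]`, take its SVD `S = U Σ Vᵀ`, and keep the smallest
   rank `k` whose relative energy `Σ_{i≤k} σ_i² / Σ σ_i²` reaches 99.9%.
2. **GP regression.** Project every training response onto the basis,
   `α(x_i) = Φᵀ y_i`, and fit one single-output GP per coefficient with an
   ARD squared-exponential kernel
   `k(x,x') = σ_f² exp(−½ Σ_d (x_d−x'_d)²/ℓ_d²)` plus independent noise,
   hyperparameters by multi-start maximisation of the log marginal
   likelihood.
3. **Prediction.** `ŷ(x*) = Σ_j α̂_j(x*) φ_j`, with variance propagated per
   coefficient.
4. **UQ.** Push scrambled-Sobol input designs through the surrogate:
   per-day moments, CV, central 50/75/95% bands, densities, restenosis
   fraction (MRAL ≥ 0.5), replicated over scramblings.
5. **Sensitivity.** Saltelli designs and the Saltelli-2010/Jansen
   estimators give per-day first-order (`S_i`) and total (`S_Ti`) Sobol
   indices with replication confidence intervals.

## Worked example

```sh
python analysis/01_generate_training_data.py --seed 0
python analysis/02_train_surrogate.py --seed 0
python analysis/03_cross_validate.py --seed 0
python analysis/04_uncertainty_propagation.py --seed 0
python analysis/05_sensitivity_analysis.py --seed 0
```

prints (abridged):

```
512 emulator runs -> results/dataset
  day-30 mean lumen area 1.812 mm^2 (CV 10.4%)
  day-30 mean max relative area loss 46.1% (CV 11.3%)
acsa: retained rank k=2 (relative energy 0.999767)
mral: retained rank k=1 (relative energy 0.999345)
acsa: e_POD = 1.4085%, e_GP = 1.4360%
mral: e_POD = 2.5881%, e_GP = 2.8920%
  day 15: ACSA 1.820 mm^2 (CV 10.4%), MRAL 45.9% (CV 11.3%), restenosis 23.6%
acsa first-order indices (regen, velocity, strain, fenestration)
  day  2: [0.025 0.438 0.001 0.525] (sum 0.989)
  day 10: [0.089 0.858 0.    0.041] (sum 0.988)
  day 30: [0.094 0.858 0.    0.036] (sum 0.988)
```

Reading: the surrogate reconstructs held-out growth curves to ~1.4% (ACSA)
and ~2.9% (MRAL) relative L2 error; roughly a quarter of simulated vessels
reach the 50% restenosis threshold; fenestration dominates the output
variance only in the first days (smooth muscle cells quickly cover the
lamina), after which flow velocity — and increasingly the regeneration
time — take over; first-order indices sum to ≈1, so the response is nearly
additive in the inputs.

The same pipeline is available as a CLI (`isruq emulate|train|validate|uq|
sensitivity|report`) driven by one YAML config and a single master seed.

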