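# Methods

`gradret` models the retention times of ionizable solutes (amino-acid
derivatives) in reversed-phase HPLC under linear organic-modifier (φ)
gradients, pH gradients, and double pH/φ gradients. It has two halves: a
physical gradient-elution simulator that generates retention data, and an
ensemble neural-network regressor that learns retention directly from
gradient descriptors. This note records the models, their assumptions, the
parameters that matter, and the design choices that were genuinely open.

## Gradient programs and descriptors

A run is a single-segment linear ramp: φ and/or pH move from initial to
final value over the gradient time `t_g` (minutes), after which the final
composition is held (the universal instrument convention; the hold is not
itself a modeled choice). Three packaged designs cover the study
conditions:

* **A** — 19 φ gradients, φ 0.20 → 0.50, `t_g` 5–40 min, at six fixed pH
  values between 2.8 and 7.8; splits 10 train / 3 val / 6 test.
* **B** — 22 pH up-ramps at fixed φ (0.25–0.35) covering pH 2.8–10.7
  (runs 1B–10B) or 3.2–9 (11B–22B); splits 12/4/6.
* **C** — a three-level full factorial in (pH_f, φ_f, t_g) with levels
  (4.68, 5.86, 7.86) × (0.35, 0.40, 0.50) × (10, 20, 30) min and fixed
  φ_i = 0.25, pH_i = 3.21; 27 runs, splits 17/4/6.

Designs A and B are stored *slope-first*: the printed descriptors (pH_i,
ΔpH/t_g, φ_i, Δφ/t_g) are the authoritative fields, and endpoints/`t_g`
are reconstructed only when a simulation needs them. This guarantees the
descriptors fed to the models are exactly the published ones, at the cost
of reconstructed gradient times that are only as precise as the printed
slopes (e.g. a slope of 0.263 pH/min implies t_g ≈ 30.04 min rather than a
round 30).

Model inputs per context are the *non-constant* descriptors only: (pH_i,
Δφ/t_g) for A, (pH_i, ΔpH/t_g, φ_i) for B, all four for the fused A+B
set, and the raw factorial factors (pH_f, φ_f, t_g) for C. Dataset C's
validation/test membership is not published as a table; the packaged
assignment (`gradients.C_SPLIT`) spreads the six test runs over four
corners and two mid-edge points of the factor cube and the four validation
runs over face centres, and can be overridden through the `split` column of
any design CSV.

The pump-to-column dwell time is exposed (`SimulatorConfig.dwell_time`) but
defaults to 0 — the study conditions never state one.

## The retention surface and the elution solver

The simulator is the package's synthetic data source; its functional form
is a deliberate package choice, not a literature fit. Each solute carries a
two-species surface

    ln k_neutral(φ) = ln k_w,n − S_n φ
    ln k_ion(φ)     = ln k_w,i − S_i φ
    k(φ, pH) = k_n + (k_i − k_n) · f_ion,
    f_ion = 1 / (1 + 10^(−(pH − pKa_eff)))   (acids; sign flipped for bases)
    pKa_eff = pKa + (dpKa/dφ) · φ

i.e. the log-linear solvent-strength law per protonation state, the
standard sigmoidal acid–base mixing rule, and a linear apparent-pKa drift
with organic content. Constraints enforced at construction: S > 0 for both
species and k_ion ≤ k_neutral at every φ ∈ [0, 1], so retention falls
monotonically as φ rises and as the solute ionizes. Amino acids are
ampholytes; one apparent pKa per solute models the dominant transition in
the scanned pH window (a known simplification — no zwitterion equilibria,
no buffer-specific effects).

Retention times solve the fundamental equation of gradient elution

    ∫₀^(t_R − t0) dt / (t0 · k(φ(t), pH(t))) = 1,

with hold-up time `t0` defaulting to 2.0 min (plausible for a 250 × 4.6 mm
column at ordinary flow; a free choice, configurable). The migration
integral F is strictly increasing, so the root is unique: F is evaluated by
adaptive quadrature (`scipy.integrate.quad`, relative tolerance 1e-9,
breakpoints at the composition kinks at the dwell arrival and the ramp
end), bracketed geometrically starting from the isocratic guess
t0·(1 + k₀), and refined by Brent's method to 1e-10 min. A solute that has
not eluted by ten times the run's natural horizon, 10·(t_g + t0·(1 + k₀)),
raises a non-elution error; dataset generation logs and omits such pairs.
The solver is validated against two independent closed forms: the
constant-composition limit t_R = t0(1 + k) and the linear-solvent-strength
gradient solution t_R = t0 + ln(1 + b·t0·k₀)/b, b = S·Δφ/t_g (agreement
≲ 1e-11 relative).

The packaged 16-solute library (Arg … Leu, Glu excluded) ramps ln k_w from
2.2 to 7.9 and S from 8.0 to 14.75 across the roster, so elution order
matches the roster on a steep φ gradient, while pKa (4.3–7.4) and its φ
drift vary non-monotonically as real ionization constants would. All
library members are acids (pH up-ramps reduce retention). Under the three
designs the simulated retention window is ≈ 2.3–47 min. Measurement noise
is multiplicative lognormal with a configurable coefficient of variation
(mean-one; retention errors scale with magnitude); the headline exercises
are run noise-free so residuals isolate the regressor.

**What the generator does and does not emulate.** It reproduces the
qualitative physics (monotone retention responses, gradient compression,
ionization-driven elution on pH ramps, realistic elution windows) but its
data are smoother and more self-consistent than chromatographic
measurements: no peak-shape effects, no buffer capacity or ionic-strength
drift, no column aging, no inter-run variability beyond the optional
lognormal factor. Passing the end-to-end tests therefore shows the pipeline
can recover a retention surface of this smoothness class from the published
design sizes — not that real data would yield the same error levels.

## Feature pipeline

A row is `[active descriptors ‖ 16-bit one-hot solute code]`; the target is
`ln t_R` (natural log — any fixed base is equivalent after range scaling;
the log keeps relative errors of early eluters comparable to late ones).
Inputs and target are range-scaled to [0, 1] on statistics of the
**training rows only** (leakage hygiene; which split defined the published
ranges is unstated, so the package takes the conservative choice).
Validation/test rows may scale outside [0, 1]; they are passed through
untouched — extrapolated gradients (e.g. the pH-gradient test run whose φ_i
and pH_i both sit at the edge of the training ranges) are part of the
exercise. Columns constant on the training rows are dropped with a warning;
with the context-specific active descriptors this is only a safety net.

## Network, training, ensembling

The regressor is a three-layer perceptron: `n_in` inputs, one hidden layer
of tanh units, one linear output. Initial weights are i.i.d. uniform on
[−0.1, 0.1], seeded. Training minimizes full-batch MSE on the scaled log
target by BFGS (`scipy.optimize.minimize`) with the analytic
backpropagation gradient; one *epoch* is one quasi-Newton iteration.
Early stopping monitors validation MSE every iteration and keeps the best
snapshot; training halts after `patience` iterations without improvement or
at `max_epochs`, and the returned model is the validation argmin, never the
final iterate.

Defaults: `max_epochs = 2000`, `gtol = 1e-8`, `patience = 200`. The
patience value matters and was chosen deliberately: on noise-free synthetic
data the validation error improves in long shallow stretches, and a short
patience window (tens of iterations) systematically stops training an order
of magnitude above the reachable validation minimum. A patience of 200 lets
runs reach their minimum (typically 400–1200 epochs) while still cutting
off genuinely stalled runs.

Because the converged network depends on its random start, predictions are
averaged over an ensemble of restarts (member *i* seeded `base_seed + i`,
default base seed 12345, default 100 members); the ensemble prediction is
the arithmetic mean of member outputs on the scaled log-target scale,
inverted to minutes at the end. Members that diverge (non-finite loss) are
dropped; the ensemble is valid only if ≥ 90% of restarts succeed. Hidden
widths default to 14 (A), 21 (B), 23 (A+B), 18 (C); the
`architecture_scan` utility re-derives such choices by scanning N−6 … N+6
hidden units (N = input count, 13 candidates, no early exit) with a
10-restart ensemble per candidate and picking the validation-MSE argmin,
ties to the narrower net.

## Statistics

All reported statistics are computed on unscaled retention times in
minutes. R² (training) is the ordinary determination coefficient; for
validation/test the external form Q²_F1 is used — total sum of squares
about the *training-set* mean — so Q² measures gain over the naive
"predict the training mean" baseline on outside data. Alternates (F2/F3)
would only change the SST anchor and can be swapped inside
`compute_metrics`. SEC/SEP use an (n − 1) denominator. Percentage errors
are signed, 100·(pred − obs)/obs; Table-style summaries aggregate their
absolute values, per-solute/per-gradient profiles keep the sign (on data
with homogeneous absolute errors the relative errors fall from the least to
the most retained solute, which the error-profile tests exercise).

## Problem sizes and reproducibility

The end-to-end exercises train the full 100-restart ensemble for the
φ-gradient context and 10-restart ensembles for the pH, fused and
factorial contexts (the package's desk-scale problem sizes; ensemble means
stabilize well below 100 members on this data). Every stochastic component
— simulator noise, weight initialization, restart seeds — is driven by
explicit integer seeds, and training itself is deterministic given the
start, so every number in the README and the acceptance output is exactly
reproducible.

## Known limitations

* The simulator's k(φ, pH) surface is synthetic; its parameters are not
  fits to any published amino-acid dataset, and simulator accuracy claims
  must not be read as claims about the original measurements.
* Single-segment linear gradients only; no multilinear programs, ternary
  eluents, temperature effects, or peak widths.
* One apparent pKa per solute; strongly multiprotic behavior inside the
  scanned pH window is not representable.
* The pH delivered by the pump is assumed to be the pH experienced by the
  solute (no buffer-equilibration lag beyond the optional dwell offset).
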