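# Methods

## Model

Every system is a network of elementary reaction steps over integer copy
numbers in a cell of volume Ω (default 1 fL, so copies and molecules/fL
coincide). Time is in seconds. Gene expression for each of two genes A and B
follows the standard two-stage cascade — transcription at `k_tx` per active
promoter, first-order mRNA decay `delta_m`, translation at `k_tl` per
transcript, first-order protein dilution/degradation `k_deg` — optionally
gated by a two-state promoter (transcriptional bursting) with measured
switching rates `k_goff = 2.8e-3 s^-1` (on→off) and `k_gon = 4.5e-4 s^-1`
(off→on), i.e. a duty cycle of ≈ 0.139. Three coupling configurations share
identical per-gene rates and therefore identical protein means and marginal
noise; they differ only in topology:

* **cotranslated** — one promoter, one transcript, one translation channel
  producing A and B together;
* **cotranscribed, separate RBS** — one promoter and transcript, independent
  translation events;
* **uncoupled** — two independent promoters and transcripts.

Posttranslational interaction modules are appended on top: successive
metabolic steps (A then B), redundant catalysis, a branch point, two OR-gate
transcriptional regulators, heterodimerization, covalent modification of A
by B, and a reduced lac-like cascade (permease-mediated import, conversion
to an inducer that sequesters a repressor gating the shared or split
promoter). Michaelis–Menten and Hill/OR propensities are used as single-step
rates (no explicit enzyme–substrate complexes); the covalent module also has
a saturating (zero-order) variant used for threshold analysis.

## Stochastic simulation

Exact trajectories come from the Gillespie direct method (numba-compiled
inner loop); ensembles derive per-run RNG streams from a master seed as
`SeedSequence((master, run_index))`, so results are independent of execution
order. Tau-leaping uses the standard bounded-relative-propensity-change step
selection (ε ≤ 0.1, default 0.03) with Poisson firing, rejecting and halving
any leap that would drive a count negative, and falls back to exact SSA
steps whenever a consumed species is below 10 copies.

Module comparisons initialize each run at the rounded mean-field steady
state, with promoter states Bernoulli-sampled at their stationary occupancy,
and run to `t_end = 16,000 s` sampled at 100 points, discarding the first
half as burn-in (protein relaxation time 1/k_deg ≈ 2,600 s, so the retained
window spans ≈ 3 protein lifetimes after a stationary start). Default
ensembles are 2,000 runs per configuration — a desk-scale choice; ensemble
sizes are configurable upward. Statistics pool per-trajectory time averages
of the needed moments (one sample per trajectory avoids autocorrelation
bias) and error bars bootstrap whole trajectories (1,000 resamples).
Summaries with |skewness| > 2 carry a `skewed` flag, since CV estimates for
highly skewed distributions are fragile.

## Linear noise approximation

At a stable mean-field fixed point `x*` (damped Newton in the stoichiometric
subspace with an ODE-relaxation fallback; flux-imbalanced systems raise an
explicit no-finite-steady-state error), fluctuations obey
`M Σ + Σ Mᵀ + Ω N = 0` with `M` the Jacobian of `S f(x)` (central
differences, relative step 1e-6 — uniform across rate-law kinds) and
`N = S diag(f) Sᵀ / Ω`. Conservation pools (promoter states, clamped
reservoirs) make `M` singular in the full space, so the equation is solved
on the stoichiometric subspace and lifted back; the residual must stay below
`1e-8·‖ΩN‖`. Noise is reported as `η_ij = σ_ij/(⟨x_i⟩⟨x_j⟩)`, with CV² the
diagonal.

For pure two-gene expression without bursting the normalized covariance has
the closed form `η_AB = (1/⟨m⟩)·τ_mRNA/(τ_mRNA+τ_protein)` for a shared
transcript with separate RBS, plus `1/(2⟨A⟩)` under cotranslation (the
shared translation event contributes a Poisson pair term); the Lyapunov
solver is the arbiter of this formula and agrees to better than 1e-8
relative. Analytical comparisons are run without promoter bursting — the
regime of the linearized theory — while stochastic comparisons default to
bursting on; the signs agree.

Predicted signs of `ΔCV² = CV²(uncoupled) − CV²(cotranscribed)` per class
readout (positive = operon quieter): linear-pathway intermediate positive,
linear product small/either; redundant product negative; branch substrate
negative; OR-regulated output negative (same-sign regulators); physical
monomers positive, heterodimer small negative; covalent unmodified form
positive, modified form small/either. The `small_either` categories are
never hard-asserted; they are only checked to be smaller in magnitude than
the module's dominant readout.

## Ultrasensitive thresholds

Non-redundant modules hide a zero-order ultrasensitive switch: enzymatic
consumption saturates, so the steady-state readout responds sharply when
the production/consumption capacity ratio V⁺/V⁻ crosses 1 (for the linear
pathway the Michaelis–Menten balance gives `I* = K_m·r/(1−r)` and local
logarithmic sensitivity `1/(1−r)`); the heterodimer and covalent modules
reach thresholds by molecular titration instead. Ratio traces use capacity
(V_max-type) fluxes computed from copy numbers — not instantaneous realized
fluxes — so the threshold at 1 is meaningful; the covalent ratio uses the
saturating-variant parameters, since mass-action modification has no finite
capacity. Spikes are defined as excursions above 5× the ensemble median
lasting at least 60 s (the sampling interval in ensemble analyses), an
artifact convention.

## Kinetic parameter fixtures

Exact interaction-module rate constants are recorded in the versioned
fixture file `src/operonoise/data/module_fixtures.json`. Design principles:
expression presets put stationary protein levels at 53/529/5285 copies per
gene (the regulator module uses 1/53/529), mRNA mean 10, mRNA lifetime
200 s, protein dilution ln2/1800 s⁻¹ (30-minute doubling); with bursting,
`k_tx` is divided by the duty cycle to preserve means. Metabolic modules
are parameterized near enzyme saturation (reservoir S at 10·K_m; flux-ratio
target 0.85 for the linear pathway) so the ultrasensitive regime is
reachable; binding is strong (K_d ≈ 1 copy ≪ means) for titration; covalent
modification flux is ≈ 10× the degradation flux.

Two deliberate regime choices: (1) the **branch point** defaults to the
translational-bursting-only regime with flux-ratio target 0.75. With the
slow promoter switching above, the branch substrate becomes bimodal and
spike-dominated in *both* configurations, and the CV then misrepresents the
variability (rarer spikes paradoxically give the smaller CV because the
mean inflates with spike frequency); without promoter bursting, only
coordinated (cotranscribed) enzyme dips cross the saturation threshold and
the CV ordering reflects the actual variability. (2) the **covalent**
stochastic default is mass-action modification; the saturating variant
exists for threshold analysis where a capacity is required.

The reduced lac-like cascade preserves the import → conversion → inducer
feedback topology on a shared or split promoter, with conversion near
saturation (flux-ratio ≈ 0.9 at full induction) so that permease/enzyme
imbalance amplifies inducer fluctuations; it is not a reparameterization of
any published full-scale lac model. Inducer presets are 1.39/83.0/5000 µM
external lactose (≈ 837/50,000/3.0×10⁶ molecules/fL via the Avogadro
constant).

## Synthetic bioinformatic data

The generators emulate curated-dataset *structure*, not any real genome:
operon sizes are truncated-geometric; interacting pairs are drawn
within-operon with probability `f_target` (or uniformly for null datasets);
single-cell copy numbers are log-normal spanning ~1–10⁴ copies; the
probability that a gene's interaction is same-operon follows
`logistic(baseline + β·log10(copies))`, so β < 0 plants excess coupling at
low expression. Real datasets differ in ways the generators do not model —
operon-size/function correlations, chromosomal clustering, measurement
noise in copy numbers — so passing tests demonstrate correctness and
calibration of the statistical machinery, not genomic conclusions.

The randomization null flattens the pair list into its gene multiset,
permutes and re-pairs consecutive entries (operon identity travels with the
gene), redrawing any replicate containing a self-pair; the replicate
distribution is treated as normal for a one-sided parametric p (direction
supplied by the caller), with a half-lattice-step continuity correction
(0.5/n_pairs) since the same-operon fraction is lattice-valued and the raw
normal tail is otherwise liberal at small expected counts. Calibration universes (3,000 genes, geometric
operon sizes mean 10 capped at 25, 1,500 unbiased pairs) are sized so the
null same-operon count is large enough for that normal tail to be accurate
while gene duplication stays low enough for the self-pair redraw to be
tractable. The median split sends ties to the low-expression subset
(deterministic, conservative for the `f_low > f_high` alternative); the
bootstrap difference test resamples rows, recomputes the split per
replicate and reports a mid-p (replicates at exactly zero counted half —
the replicate difference is mildly discrete and the mid-p keeps the test at
nominal level). Per-bin error bars resample each bin with replacement to
its own size, 1,000 times.

## Numerical conventions and limitations

* Mass-action propensities use falling factorials (`k·a·b/Ω`,
  `k·a(a−1)/(2Ω)`); macroscopic rates replace them with plain powers.
* Degenerate steady states at zero copies and unstable Jacobians are
  rejected, not regularized; LNA failures near thresholds are expected and
  reported, never silently patched — the LNA systematically underestimates
  nonlinear spike amplification, which is why stochastic ensembles remain
  the primary comparison.
* The degree of decorrelation is implemented as `1 − Pearson r(A,B)` — a
  stand-in definition; related assertions are trend-level only.
* The `small_either` sign categories, read-through/partial translational
  coupling, SBML I/O, spatial/delay models and higher-order system-size
  corrections are out of scope.
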