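# operonoise

Bacterial genes are organized into operons: one promoter drives a
polycistronic mRNA encoding several proteins, so interacting partners are
produced in correlated stochastic bursts. `operonoise` asks what that
correlation does to intrinsic biochemical noise. It provides, as a tested
Python library plus a thin CLI:

* an elementary-step reaction engine (exact Gillespie SSA with a
  numba-compiled core, tau-leaping with exact fallback, mean-field steady
  states),
* builders for two-gene expression systems under three coupling
  configurations — cotranslated (one ribosome binding site), cotranscribed
  with separate ribosome binding sites, and transcriptionally uncoupled —
  composed with six posttranslational interaction-module classes (linear
  metabolic pathway, redundant enzymes, metabolic branch point, redundant
  OR-gate gene regulators, heterodimer formation, covalent modification)
  and a reduced lac-like import/conversion cascade,
* a linear noise approximation (LNA) engine solving the stationary
  fluctuation–dissipation equation `M Σ + Σ Mᵀ + Ω N = 0` and the
  closed-form normalized protein covariance
  `η_AB = σ_AB/(⟨A⟩⟨B⟩) = (1/⟨m⟩)·τ_mRNA/(τ_mRNA+τ_protein)` (+ `1/(2⟨A⟩)`
  under cotranslation) for operon-expressed genes,
* ultrasensitive-threshold analysis: mean-field response curves of module
  readouts versus the production/consumption capacity ratio V⁺/V⁻,
  logarithmic sensitivities, flux-ratio traces and spike statistics on
  stochastic trajectories,
* enrichment statistics for gene tables: same-operon fractions, a
  flatten–permute–re-pair randomization null with parametric p-values, an
  expression-level median split with a bootstrap difference test, and
  synthetic-data generators (operon universes, pair lists with controlled
  enrichment, log-normal single-cell copy-number tables with a planted
  expression–coupling slope) that stand in for curated database extractions.

The noise measure throughout is the coefficient of variation CV = σ/μ of a
species' stationary copy-number distribution (CV² = η_ii); comparisons
report ΔCV² = CV²(uncoupled) − CV²(cotranscribed), positive when the operon
configuration is the quieter one.

## Worked example

```python
from operonoise.pipeline import RunConfig, run_comparison

report = run_comparison(RunConfig(module_class="linear_pathway",
                                  n_runs=400, seed=7))
print(report.verdict)
print(f"CV^2(I) cotranslated {report.cv2_coupled:.3f}  "
      f"uncoupled {report.cv2_uncoupled:.3f}  "
      f"delta {report.delta_cv2_ssa:+.3f} +- {report.delta_cv2_se:.3f}")
print(f"time above flux threshold: coupled {report.crossing_coupled:.3f}  "
      f"uncoupled {report.crossing_uncoupled:.3f}")
```

prints (seed 7, 400 runs per configuration):

```
cotranscribed lower CV(I)
CV^2(I) cotranslated 0.267  uncoupled 1.823  delta +1.556 +- 0.136
time above flux threshold: coupled 0.035  uncoupled 0.475
```

i.e. the metabolic intermediate of a linear pathway is far noisier when its
two enzymes are expressed from independent promoters: the production/
consumption capacity ratio V⁺/V⁻ then fluctuates past 1 almost half of the
time, and each crossing drives a spike in the intermediate. When the
enzymes are cotranslated from one transcript the ratio barely moves and the
threshold is rarely crossed.

The same entry point runs the other classes; the redundant-enzyme and
OR-regulator modules come out with the opposite sign (the uncoupled
configuration is quieter, because uncorrelated enzymes rarely dip
simultaneously), as does the branch-point substrate.

Shell equivalents: `operonoise compare --cls linear_pathway`,
`operonoise build|simulate|lna|ultra|synth|enrich|split`.

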