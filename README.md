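# ecocompare

Cross-structure comparison of marine ecosystem models at desk scale.

Ecosystem-based fisheries management increasingly leans on suites of
models of very different complexity — from spatially resolved
end-to-end simulators down to mass-balance food-web models and
trait-based size-spectrum models.  Before trusting any of them for
scenario work, modellers ask: do structurally different models of the
*same* system tell the same story about diets, trophic structure,
influence of species, diversity, and responses to fishing?  This
package implements that comparison workflow end to end for two simple
community simulators evaluated against a common synthetic "source"
ecosystem:

* a **multispecies size-spectrum model** — abundance density N_i(w)
  per species over body mass w, lognormal prey-preference kernel
  (preferred predator:prey mass ratio β, width σ), Holling type-II
  feeding level f = E/(E + h wⁿ), von Bertalanffy-consistent
  physiology, Beverton–Holt recruitment R = R_max·R_p/(R_p + R_max),
  a background resource spectrum at 70 % of its reference capacity,
  and knife-edge fishing at the size of maturity;
* a **mass-balanced biomass-pool model** — Ecopath-style balance
  B₀·P/B·EE = Σ consumption + catch solved for the ecotrophic
  efficiency EE, foraging-arena consumption
  Q = a·v·B_prey·B_pred / (2v + a·B_pred) through time;
* the **indicator and skill suite** used to compare them: trophic
  levels solved from diet matrices (bacteria pinned at 0.01), the
  modified Kempton's Q diversity index, keystoneness
  KS_i = log₁₀(√Σ_{j≠i} m_ij² × drank_i) from press-perturbation
  experiments, Spearman diet correlations (−1 for zero-overlap diets),
  Pearson skill against rescaled survey/CPUE indices, between-run CV
  envelopes from initial-condition and forcing-year-bootstrap
  ensembles, and representative-forcing-year selection.

Everything runs from seeds — the synthetic source module generates the
species roster's traits, diets, overlaps, catch histories, forcing
years and noisy observation indices, so no download is needed.

## Worked example

The analysis is a sequence of numbered scripts (each a thin driver over
the `ecocompare` library; outputs land under `results/baseline/`):

```
python analysis/01_generate_source.py
python analysis/02_derive_parameters.py
python analysis/03_calibrate_sizespectrum.py
python analysis/04_run_models.py
python analysis/05_sensitivity.py
python analysis/06_indicators_comparison.py
```

Selected output from a run with the default seed (42):

```
derived parameters written to results/baseline/derived
  size-based filter retained 22 dynamic groups
  beta: median 18.2 (range 5.4-100.0)
  meatweight check: 100 t greenweight mussels -> 25 t
calibration written to results/baseline/calibrated
  converged: True in 10 iterations
  log-biomass Pearson r vs targets: 0.9997
  unfished hindcast max per-group biomass CV: 6.21 % (criterion: <= 20 %)
sensitivity outputs written to results/baseline/perturb
  keystone top 3 (pool): Tarakihi, Red gurnard, School shark
  keystone top 3 (size spectrum): Barracouta, Elasmobranch pisc, Cephalopod
  rank-third agreement: {'same_third': 7, 'opposite_thirds': 3, 'other': 12}
  diet Spearman by model pair (mean):
pair
pool_vs_source    0.55
pool_vs_ss       -0.25
  diversity change (late minus early mean, scaled units):
source    -9.789
pool     -13.196
ss       -18.046
```

Reading these numbers: the species filter keeps the 22 groups that feed
in a size-based way; R_max calibration reproduces the source model's
virgin biomasses almost exactly (r = 0.9997) and the calibrated
community is stable unfished (max CV 6.2 %, against the ≤ 20 %
criterion).  The two simulators *disagree* about which species are most
influential (only 7 of 22 groups land in the same keystone-rank third),
pool-model diets track the source diets (mean Spearman 0.55) while
size-spectrum diets anti-correlate with both (plankton and small fish
dominate all its diets — a structural feature of size-spectrum models),
and all three models agree that historical fishing lowered
upper-trophic-level diversity.

The same functionality is exposed as a CLI
(`ecocompare synth|calibrate|run|perturb|compare|indicators`, with
`--seed`, `--config`, `--out`, `--force`, `--log-level`).

## Layout

```
src/ecocompare/     library: synthetic source, size-spectrum and pool
                    simulators, parameter derivation, indicators,
                    pipeline stages, CLI
analysis/           numbered narrative drivers (01 ... 06)
scripts/            acceptance script
tests/              pytest suite (unit, property and acceptance tests)
docs/methods.md     model descriptions, defaults and numerical choices
```
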