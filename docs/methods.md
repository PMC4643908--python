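# Methods

## Model

Chemical mapping measures a per-nucleotide modification rate that is higher
at conformationally flexible (unpaired) positions.  For an RNA populating
several secondary structures, a measurement is an ensemble average, and a
mutate-and-map (M²) experiment — the wild type plus every single-nucleotide
complement mutant — yields a matrix of such averages under systematically
perturbed ensembles.  `m2fit` treats this matrix as a blind-source
separation problem with structural side information:

```
D_obs[j,i] = Σ_s W[j,s] (D[s,i] + C[s,j,i]) + ε_i,  ε_i ~ N(0, Ψ_i)
```

* `W[j,·]` — population fractions of the candidate structures in variant
  `j`; each row lies on the probability simplex.
* `D[s,i]` — hidden reactivity of structure `s` at position `i`, with
  exponential priors `Exp(λ_P)` at paired and `Exp(λ_U)` at unpaired
  positions.
* `C[s,j,i]` — mutation-local perturbations, nonzero only within one
  nucleotide of variant `j`'s mutation or of a base pair of `s` that the
  mutation disrupts; prior `N(0, 1/λ_perturbed)`.
* `Ψ_i` — position-wise noise variance (noise is independent across
  measurements: separate capillaries / separate sequencing reads).

Weight priors: a ridge `N(0, 1/λ_R)` ("smooth sparsity" — unimportant
structures are driven to small, typically nonzero weights; an l1 prior is
unavailable because rows are constrained to sum to one), and an anchor
`|W_WT,s − W[j,s]| ~ N(|W0_WT,s − W0[j,s]|, 1/λ_Δ)` tying wild-type/mutant
weight *differences* to the Boltzmann-weight differences `W0` computed from
the folding backend's energies.  Throughout, every Gaussian λ is a
precision (variance `1/λ`).

Candidate structures are the union of each variant's suboptimal ensemble
(default: at most 200 structures within 5% of the variant's minimum free
energy), deduplicated by base-pair set, with every retained structure
scored on every variant's sequence.  Pairs rendered non-canonical by a
mutation are removed before scoring; the perturbation variables, not the
energy function, absorb the local disruption.

### Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `λ_P` | 0.5 | paired-reactivity rate; prior mean 2.0 reactivity units |
| `λ_U` | 0.2 | unpaired rate; prior mean 5.0 |
| `λ_perturbed` | 2.0 | perturbation precision (sd ≈ 0.71) |
| `λ_R` | 0.26 | weight ridge precision (cross-validated) |
| `λ_Δ` | 5.0 | ΔΔG-anchor precision (cross-validated) |
| `kT` | 0.6156 kcal/mol | 37 °C, the convention of the energy backends |
| bp tolerance | 0.01 | EM convergence: max change of any weighted base-pair probability |
| bootstrap | 100 | column-resampling replicates |

The exponential rates follow the literal rate convention (mean = 1/λ), so
the *paired* prior mean (2.0) is high relative to raw RMDB reactivity
units; both rates are configurable per dataset/modifier.

## Inference

Hard EM on the joint log-posterior.

**E-step.** At each position the stationarity conditions in `(D, C)` form
one linear system: one equation per collapsed motif variable active there
plus one per masked `(structure, variant)` pair.  The masked block is
rank-one per measurement row and is eliminated analytically
(Sherman–Morrison), shrinking row `j`'s residual by
`γ_j = Ψλ_perturbed / (Ψλ_perturbed + Σ_s W[j,s]²)` and leaving a small
system in the collapsed variables, which is solved exactly under the
`D ≥ 0` constraint by an active-set method.  Two numerical guards:
variables carried by ~zero total weight (squared column norm ≤ 1e-8) are
unidentifiable at that position and are skipped (their values persist), and
solutions are capped at 1.5× the data maximum — the exponential prior is
linear, so a weakly-identified variable's MAP would otherwise be finite but
enormous; the cap binds only such variables.  The derivative of the
log-posterior puts the prior terms on the right-hand side with a *minus*
sign (`−Ψ λ_si`, shrinking `D` toward zero) and the perturbation precision
on the left with a *plus* sign; both steps are verified against a generic
constrained optimizer of the full log-posterior.

**M-step.** One simplex-constrained QP per measurement row, solved by a
primal active-set method with closed forms for r ≤ 2 (SLSQP fallback).
The wild-type row is solved first (its anchor couples it to every mutant's
current weights), then the mutant rows with the wild type fixed.  The
absolute values in the anchor make each row's objective piecewise
quadratic; when the sign-pattern space is small (≤ 2¹⁰ patterns) the
regions are enumerated exactly, otherwise the pattern is re-derived from
each pass's solution until self-consistent (≤ 4 passes).  `Ψ` is then the
per-position mean squared residual, floored at 1e-6.

**Initialization and convergence.** `W` starts at the Boltzmann weights of
the energy table; `Ψ` at the empirical per-position variance across all
measurements.  Iteration stops when no entry of any variant's weighted
base-pair probability matrix moves by more than the tolerance (default 1%),
usually within 10–25 iterations.  The posterior is not concave, so the fit
is a local MAP sensitive to initialization; the log-posterior trace is
recorded and is non-decreasing whenever the `D ≥ 0` projection is inactive.

**Bootstrap.** Sequence positions (columns) are resampled with
replacement; variant rows never are.  Duplicated columns receive duplicated
equations and independent per-column hidden variables, matching
resampling-with-replacement semantics.  Replicates warm-start from the
full-data fit, run the full EM loop with a doubled iteration cap (resampled
problems hover near the tolerance longer), and draw their resampling
indices from independent child streams of the master seed, so results do
not depend on execution order.  Replicates that fail to converge are
excluded and counted; more than 20% failures is an error.  The reported
weights are replicate means with bootstrap standard deviations.

## Landscape summaries

Helix populations: a maximal stack's population in variant `j` is the
summed weight of structures containing *every* one of its pairs; shifted
registers are distinct helices, and a bulge always breaks a helix (no
merging across bulges).  Uncertainty is the standard deviation of that sum
recomputed per bootstrap replicate; `detected` means population > sd
(SNR > 1).  Coarse states come from weighted k-medoids on the base-pair
symmetric-difference distance using wild-type weights, with k chosen by
silhouette over 2–6 when not given; each state is represented by its
medioid (the member minimizing population-weighted distance within the
cluster).

## Synthetic M² data

The generator reproduces the in-silico benchmark protocol: sample each
variant's suboptimal ensemble, perturb every `ΔG[j,s]` with `N(0, 1 kcal/mol)`
noise (mimicking the inaccuracy of nearest-neighbor models), Boltzmann
reweight to obtain true populations, draw reactivity profiles from the
`Exp(λ_P)` / `Exp(λ_U)` distributions, mix, add `N(0, 0.1)` measurement
noise (the benchmark default; the protocol source does not state a value),
and clamp at zero.  Two profile-draw schemes:

* `positional` (default): one paired and one unpaired value per position,
  shared across structures.  This is consistent with the model's premise
  that identical motifs react identically, and is the regime in which the
  benchmark behaves like the published experience with the method.
* `structural`: every structure's profile drawn independently.  Because
  the exponential sd equals its mean, this violates the motif-collapse
  premise strongly (fit residuals ~15× the measurement noise) and is kept
  as a deliberate robustness probe.

What the generator does *not* emulate: attenuation and normalization
artifacts of capillary electrophoresis, heavy-tailed outlier reactivities,
correlated noise across positions, position-specific modifier biases, and
ligand-dependent reactivity of a single motif.  Tests passing on synthetic
data therefore demonstrate correctness of the inference machinery under
the model's own assumptions plus Boltzmann-level energy misspecification —
not robustness to every artifact of real traces.

## Benchmark scoring

A *true* helix in a variant: ground-truth population ≥ 25% and ≥ 3 base
pairs.  A *detection*: fitted population ≥ 25% *and* greater than its
bootstrap sd.  TP/FP are counted per variant; sensitivity, FNR and FDR are
pooled over all variants of all benchmark RNAs.  The no-data baseline
scores Boltzmann weights with the same population threshold (no bootstrap
error exists without data).  The scaled-down benchmark shipped with the
package uses five 30–44 nt two-register sequences (the toy backend's
exhaustive enumeration is exact there) with 20 bootstrap replicates —
sizes chosen so the whole pipeline, including scoring, runs in about a
minute per seed.

Regularization selection uses structured k-fold cross-validation: test
fold `i` is the strided position set `{i, i+k, i+2k, …}` (the splitting
used for spline-type smoothers on structured data), weights are fitted on
training columns, held-out columns are predicted by re-running the E-step
with the fitted weights fixed, and the mean squared prediction error is
minimized over the `(λ_Δ, λ_R)` grid.

## Known limitations

* Population estimates carry a systematic component the column bootstrap
  cannot see: perturbation variables absorb part of the mutation-induced
  reweighting signal, the ΔΔG anchor pulls toward the unnoised Boltzmann
  differences, and simplex-boundary shrinkage biases dominant states
  downward.  On clean two-state simulations the major-state weight is
  recovered to ~0.04 on average, but ±2 bootstrap-sd intervals undercover
  because the sd (~0.01) reflects only column-sampling variance.  Treat
  bootstrap sds as precision, not total error.
* Hard EM finds a local MAP; differently initialized fits can differ,
  particularly for near-collinear structures (sub-registers), whose
  individual weights are not identifiable — helix-level populations are
  the meaningful output.
* Pseudoknots are out of scope end to end (parser, sampler, model).
* The toy folding backend is a stacking-score enumerator for ≤ ~40 nt
  fixtures, not an energy model; real analyses should use the ViennaRNA or
  external backend.
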