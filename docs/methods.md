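# Methods

This note documents the models, the numerical choices, and the synthetic data
generators behind `alfe`, and what passing its tests does and does not show.

## Thermodynamic integration with convergence control

The free energy of one alchemical leg (complex or solvent) is the integral of
the ensemble-averaged coupling-potential derivative over the coupling
parameter, ΔG = ∫₀¹ ⟨dU/dλ⟩ dλ, approximated by the n-point Gauss–Legendre
rule mapped to [0, 1] (default n = 9; exact for polynomials up to degree
2n − 1). The relative binding free energy of a transformation is
ΔΔG = ΔG_complex − ΔG_solvent, with window standard errors propagated through
the quadrature in quadrature: σ² = Σ wᵢ² σᵢ².

Each λ-window's gradient time series is processed as follows.

- **Equilibration detection.** Candidate truncation points t₀ are scanned on a
  grid of 50 evenly spaced integers over the first half of the series; for
  each, the statistical inefficiency g(t₀) of the remaining samples is
  computed as g = 1 + 2 Σₜ (1 − t/N)·ρ(t), with the autocorrelation ρ
  evaluated by FFT and the sum truncated at the first negative value. The t₀
  maximizing N_eff = (N − t₀)/g wins. A constant series is the degenerate
  case (t₀ = 0, g = 1). The grid-scan-with-N_eff-maximization scheme is the
  standard "automatic equilibration detection" approach for molecular
  simulation time series; the test suite cross-checks it against an
  explicit-loop oracle using a direct O(N²) autocorrelation.
- **Decorrelation.** Post-t₀ samples are thinned with stride ⌈g⌉.
- **Convergence test.** The equilibrated portion is split into two
  chronological halves; both are histogrammed on shared equal-width bins
  spanning the pooled range with n_bins = max(10, ⌈√N⌉), and the
  Jensen–Shannon distance (square root of the JS divergence, base-2 logs so
  the distance lies in [0, 1], 0·log 0 = 0) is compared against the
  criterion, default 0.1. Base-2 logs make the criterion scale-free. Fewer
  than four equilibrated samples count as not converged.
- **Extension policy.** A window starts at 2.5 ns; an unconverged window
  requests one 0.5 ns increment at a time while the total stays within the
  configured budget (default max_total = 10 ns — the budget is a
  configuration choice with no canonical value), after which it gives up and
  carries an unconverged flag into the transformation result. A `fast`
  preset (1.0 ns initial, 0.25 ns increments) mirrors the accelerated
  variant used late in a campaign.
- **Replicates.** Each replicate of a window is equilibrated and decorrelated
  independently; the pooled decorrelated values give the window mean and
  stderr = sd/√n_pooled. A pooled window counts as converged only if every
  replicate passes the halves test.

## Perturbation-map thermodynamics

RBFE edges form a directed graph; anchoring nodes with known absolute binding
free energies converts every reachable node by summing signed edge values
along the breadth-first path from its nearest anchor (edges traversed against
their direction contribute −ΔΔG), with stderr accumulated in quadrature.
Multi-anchor disagreements beyond 3σ are reported as warnings rather than
averaged (the production map is a tree, so a weighted least-squares refit
would be over-engineering); cycle closure sums are available as a consistency
diagnostic. Dissociation constants convert via ΔG = RT ln(K_D/c°) with
R = 1.987204×10⁻³ kcal/(mol·K), T = 298 K (the binding-assay temperature) and
c° = 1 M.

## Surrogate models and the acquisition loop

Labels are absolute binding free energies (kcal/mol, more negative = tighter).
Three algorithm families are available on binary-fingerprint inputs:

- **Linear/ridge regression.** Solved in dual (kernel) form with an appended
  constant bias feature; hyperparameter grid α ∈ {0 (plain least squares), 1}.
  For α > 0 the exact leave-one-out residual eᵢ/(1 − hᵢᵢ) is used; plain
  least squares falls back to explicit refits because the hat-matrix identity
  fails for interpolating fits.
- **Random forest.** scikit-learn, grid over {100, 500} trees × depth
  {∞, 10}.
- **Tanimoto-kernel GP.** k(x, y) = ⟨x, y⟩/(‖x‖² + ‖y‖² − ⟨x, y⟩) plus a
  constant component (prior variance 10) that absorbs the overall affinity
  level, plus diagonal noise from the grid {10⁻⁴, 10⁻², 10⁻¹}. The exact GP
  leave-one-out identity μ₋ᵢ = yᵢ − αᵢ/(K⁻¹)ᵢᵢ makes model selection O(n³)
  instead of n refits; the closed form is verified against explicit refits in
  the tests.

Model selection scores every (representation × algorithm) cell: an inner
5-fold grid search tunes the cell's hyperparameters, then the tuned cell is
scored by leave-one-out cross-validated R² = 1 − SSE/SST over held-out
predictions. Zero label variance yields a −∞ sentinel so a degenerate cell
can never win; ties keep the first cell in declared grid order. The winner is
refit on all data and screens the unlabelled pool; acquisition takes the
`batch` most negative predictions, ties broken lexicographically by id, and
ids are never re-queried (oracle failures are recorded and not retried,
mirroring failed simulations).

The default loop grid is ECFP6-2048 with the linear and Tanimoto-GP cells:
on the additive synthetic landscape these are the informative cells, and the
reduced grid keeps a full seven-iteration campaign to a couple of seconds.
The full zoo (five fingerprint kinds, three algorithms) is available through
`ALConfig`. Scope control trains and screens only the first hit series until
a configurable switch iteration, then widens to both — mirroring a campaign
that optimizes one chemotype first.

Final selection takes the 70 most negative scores overall plus 5 molecules
chosen for chemical diversity among eligible candidates (negative score,
passing a caller-supplied predicate) by max–min Tanimoto picking seeded with
the most negative eligible molecule; shortfalls fill greedily with a warning.

## Synthetic generators: what they emulate, and what they do not

- **Analog libraries** decorate a SMILES scaffold with marked attachment
  points by fragment products (sampled without replacement above `n_max`).
  The default library is an oxamide scaffold with 33 × 33 substituent pairs.
- **The affinity oracle** is additive: ΔG = base + Σ group contributions +
  N(0, noise_sd²), with the noise drawn once per molecule id (repeat queries
  return identical values, like re-reading a completed simulation). Defaults:
  base −5.5 kcal/mol, per-site contributions uniform in [−1.5, +1.0], noise
  0.5 kcal/mol — a dynamic range and label noise comparable to a real
  hit-optimization series with TI-level uncertainty. Additivity gives the
  surrogate learnable structure; real structure–activity landscapes contain
  non-additive cliffs this generator deliberately omits, so enrichment
  results bound what the loop can do when its modelling assumptions hold,
  not what it will do on arbitrary chemistry.
- **Mock docking** emits three poses per molecule; scores are an affine
  function of true affinity (offset −2 keeps typical scores below the −6
  retention gate without disturbing the ranking), while geometry columns
  (RMSDs, clash) are drawn to pass or violate the filter thresholds with a
  configurable fraction. Scores therefore carry signal, geometry carries the
  filter behaviour.
- **Gradient series** are AR(1) processes around a polynomial mean curve in
  λ whose constant term is shifted so the schedule quadrature equals the
  requested leg free energy exactly; an optional exponentially decaying
  transient (amplitude in σ units, decay constant = transient_length·N/2)
  exercises equilibration detection. AR(1) is the right null model for
  short-memory gradient noise; it does not emulate slow conformational
  switching, which is the regime where the JS halves test earns its keep in
  production.

All generators are bit-reproducible under fixed seeds.

## Problem sizes

The validation experiments use: TI recovery — 200 transformations, two
9-window legs, 500 samples/window, noise 1 kcal/mol, correlation time 5
samples, 5σ transients over 20% of the series; AL enrichment — 1000-molecule
library, 30-molecule initial set, 7 iterations × batch 20, scored on the true
top 5%; the end-to-end pipeline — 1000 molecules, 60-molecule pre-AL set,
75-candidate budget. These sizes make every suite a desk-scale computation
while keeping the statistics informative (binomial error on a 95% coverage
check at n = 200 is ±1.5%).

## Known limitations

- Fingerprint bits are deterministic within an RDKit build but not promised
  identical across cheminformatics toolkits; the `e3fp_default` kind is
  declared but has no implementation here and raises a clear error.
- The MCS atom mapper enumerates substructure embeddings (capped) and keeps
  the distance-feasible pair set of the best embedding; for molecules with
  high symmetry counts beyond the cap a feasible but suboptimal embedding
  could win. Production-size ligands are far below the cap.
- The stderr of a TI window assumes the decorrelated samples are effectively
  independent; residual correlation beyond the ⌈g⌉ stride would shrink error
  bars. The 3σ-coverage experiment is the guard on this.
- `combine_replicates` reports the first replicate's t₀ and the mean g as
  summary metadata; only the pooled mean/stderr/convergence flags feed the
  free energies.
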