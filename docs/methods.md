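# Methods

This note records the models, numerical choices and open design decisions
behind `pathshap`, in the spirit of a package reference manual: what is
computed, under which assumptions, and what the synthetic experiments do
and do not establish.

## Synthetic cohorts

The generator emulates the measurement chain *downstream* of ICA: it does
not synthesize volumes or unmixing matrices, only per-subject IC
time-course matrices (485 volumes × 125 ICs, TR 2.5 s) plus the event
schedule that produced them.

**Paradigm.** Four categories (BP, BI, O, P), 40 events per category per
subject, 20 of each statement valence; each event occupies a 7.5 s slot
(4.0 s stimulus + 3.5 s fixation), back to back, in a per-subject seeded
random order (the presentation order of the real paradigm is not public).
The first onset defaults to 6.0 s, which places every onset 1.0 s after a
volume acquisition so that the three post-onset samples fall at +1.5, +4.0
and +6.5 s. A `drop_events` hook removes events by position, emulating
discarded acquisitions (the real instance counts imply one missing P event
per split: 600+600+600+599 train, 280+280+280+279 test).

**Hemodynamic response.** Canonical double gamma: difference of two gamma
densities with modes at `peak_delay` = 6 s and `undershoot_delay` = 16 s
(dispersions 1 s, undershoot ratio 1/6), peak-normalized to 1. The mode
parameterization (shape = delay/dispersion + 1) makes the stated delays
exact lobe modes; the BOLD literature constrains the peak only to the
5–7 s window, so all parameters are configurable. `SampledHRF.normalization`
is the analytic gamma-CDF integral of the kernel over the sampled window;
tests confirm it against trapezoid quadrature.

**Signal model.** An informative IC for category c is
Σ_events(c) effect_size · HRF(t − onset) + N(0, noise_sd²); every other IC
is pure noise. Defaults: two informative ICs per category (disjoint across
categories, 8 of 125), effect_size 1.0, noise_sd 0.5. With these values the
selected-volume signal-to-noise per event is ≈ 2:1 — a deliberately clear
regime: the synthetic cohort exists to verify that the pipeline recovers
known structure, not to mimic the difficulty of real fMRI. Noise is i.i.d.
Gaussian per IC per volume; there is no autocorrelation, drift,
physiological noise, inter-subject spatial variability, or secondary-task
structure. Consequently, passing the recovery tests shows the chain is
*correct* (it finds what is there, through training, pruning and
attribution), not that real-data accuracies of any particular magnitude are
attainable; synthetic accuracies (≈ 0.9) are far above what the real,
noisy, overlapping-network data support (≈ 0.55).

An optional per-subject effect-size jitter was considered and left out:
no empirical value is available to calibrate it, and the recovery
experiments do not need it.

**Ratings.** The screening generator draws each stimulus's screening class
first (probabilities 0.35 / 0.35 / 0.30 for preferred / indifferent /
discarded) and then a (pleasure, arousal) pair uniformly within that
class's region of the 5×5 rating grid. This guarantees the two retained
classes are comfortably above the 40 stimuli the selection step needs for
the default 200 stimuli.

## Feature extraction

One instance per event: the 125 IC values at the third volume acquired
strictly after onset. Under the default onset alignment this is onset
+ 6.5 s, near the response peak; both the volume offset and the schedule
alignment are configurable. Volume indices are 0-based internally and all
CSV artifacts carry explicit onset time stamps.

Standardization defaults to `train_stats`: both splits are z-scored with
the training set's per-feature mean and population SD — the leakage-safe
reading of a protocol that states only that both datasets are
standardized. An `independent` mode (each split with its own statistics)
is provided for comparison. Zero-variance features raise by name rather than propagating
NaNs. Splits are by subject, and the split-disjointness guard runs on
every extraction.

## The shallow network

125-10-4, tanh hidden units, logistic-sigmoid outputs, one-hot {0,1}
targets, per-pattern error E = ½ Σ (t − y)² (the ½ is a convention choice;
it cancels in the delta rule). "Adaptive gradient descent with momentum"
is implemented as per-pattern (online) updates,
Δw ← momentum·Δw_prev − lr·∂E/∂w, with a fixed per-run learning rate — the
named method of the training package the original analysis used — and no
learning-rate schedule, because none is described. Presentation order is
reshuffled each epoch with the run seed (switchable off). Binary masks M1,
M2 multiply the weights in the forward pass and the gradients in the
backward pass, so masked connections are exactly zero forever; biases are
never masked. Non-finite weights raise a divergence error naming the
epoch. Training is bitwise reproducible given the seed.

**Search spaces.** The documented training grids are learning rates
log10-spaced 1e−07..1e−01 plus 0.9, and momenta 0.05..1.00 in 0.05 steps
with a finer 0.95..1.00 band; the fine step is not stated in the source
material, so 0.005 was chosen (it contains the selected 0.975).
Retraining grids: learning rates 1e−09..1e−04 log10, momenta 0.700..1.000
in 0.025 steps. Whether the retraining phase's "tested 1,000 times
(epochs)" means epochs or restarts is ambiguous; both are configurable and
the ambiguity is left unresolved. Model selection maximizes accuracy on
the out-of-sample cohort, replicating the original protocol; ties keep the
first-visited combination.

**Desk scale.** The original search (50,000 random restarts × full grids ×
500 epochs) is cluster-scale. The pipeline's default configuration uses a
1×1 grid with 2 restarts and 30 epochs for training, a 2×1 retraining grid,
a 40-row background, 64 sampled permutations and 48 explained test
instances — sizes chosen so a full run takes ~15 s on one CPU while the
synthetic signal remains comfortably recoverable. `paper_scale: true`
restores the printed settings. The retraining grid always contains a
near-zero learning rate, so the retrained network can never do
meaningfully worse than the pruned one on the selection set.

## Path-weights and pruning

pw[i,j,k] = W1[i,j] · W2[j,k], computed on the masked weights; 1,250 paths
per output for the default architecture. Per output, the 1,250 values are
sorted ascending and the elbow search runs separately on the strictly
negative prefix and strictly positive suffix. Zero-valued paths belong to
neither branch and never survive: they carry no signal (the product
cancels it).

**Elbow point.** Points (rank, value) are min-max normalized to the unit
square on both axes before measuring perpendicular distance to the chord
joining the branch endpoints — without normalization the value axis
dominates the rank axis by orders of magnitude. The original analysis
delegates to an external elbow routine whose normalization is not stated,
so this is flagged as a potential source of divergence from any published
elbow ranks (which are in any case not recomputable without the original
trained weights). Ties (distances within 1e−12 of the maximum) break to
the smallest index; an all-equal branch raises a degenerate-curve error;
a branch with fewer than 3 points has no elbow and survives whole (pruning
targets the near-zero bulk, and a 1–2 point branch is all extremes).
Internally indices are 0-based; reported ranks are 1-based.

**From paths to connections.** A path (i,j,k) survives iff its rank on
output k's curve is ≤ the negative elbow or ≥ the positive elbow. The
connection masks keep M2[j,k] iff any surviving path uses it and M1[i,j]
iff any surviving path through j starts at i — the minimal-removal
reading. A masked network can re-create non-surviving paths through shared
kept connections; `surviving_paths` therefore also reports the exact
survivor sets per output for strict path-level tables. Retraining starts
from the pruned weights with masks frozen and reports accuracy before
pruning, after pruning, and after retraining.

## Shapley values

The attribution is the interventional Shapley value: the coalition value
v(S) is the model output averaged over a background set with the features
in S fixed to the instance's values and the rest taken from the background
rows. Two estimators:

- **Exact subset enumeration** (≤ 20 features): all 2^n coalitions with the
  combinatorial weights |S|!(n−|S|−1)!/n!. Used by default for the 10
  hidden nodes (2¹⁰ coalitions). Additivity Σφ + base = f(x) holds to
  machine precision, and tests enforce the null-player and symmetry axioms
  and equivalence with an independently coded all-permutations average.
- **Antithetic permutation sampling** (the 125 inputs): each sampled
  feature ordering is paired with its reverse; marginal contributions
  telescope within an ordering, so additivity holds up to the Monte-Carlo
  average, and per-feature standard errors are reported. All explained
  instances share the same orderings (a vectorization choice; each
  instance's estimate remains unbiased).

The original analysis used an enhanced-DeepLIFT explainer. This package
instead implements the quantity that explainer approximates — the
interventional Shapley value — because it is precisely defined and
oracle-checkable: the exact enumerator and the sampling estimator
cross-validate each other in the test suite. Results need not coincide
with DeepLIFT multipliers instance by instance.

The background set defaults to 100 training instances drawn without
replacement (the original reference set is not documented; this is a
package choice). Hidden-node attribution uses the output layer as a
sub-model over hidden activations, with the background mapped through the
same hidden layer, so the composition identity g(h(x)) = f(x) is exact.

**Summaries.** Per output: features ranked by mean |φ| (top 20 by
default), dominant polarity (sign of mean φ, 0 when all-zero), bar data of
mean |φ| (polarity-free), beeswarm pairs (feature value, φ), and a partial
dependence slope — the OLS slope of φ against feature value, a
quantitative stand-in for reading a "positive gradient" off a dependence
scatter.

## Metrics

Confusion matrices are tallied with scikit-learn behind a thin surface.
Local precision = diagonal / column total; local accuracy = diagonal / row
total; global accuracy = trace / grand total. Percentages print to one
decimal with half-up rounding. Undefined ratios (empty row/column) return
explicit `None` sentinels. The row-weighted mean of local accuracies
equals global accuracy exactly, which the tests enforce. The published
best-network panel is embedded as a frozen benchmark table; the test suite
and acceptance script recompute its precisions (41.3/44.1/59.0/68.9%),
local accuracies (37.1/38.6/63.2/79.6%), global accuracy (54.6%) and
correct-prediction count (611) from the raw cells.

## Orchestration

One validated YAML (pydantic, unknown keys rejected) drives
simulate → screen → extract → train → prune → retrain → explain →
evaluate → report. Every stage seed is spawned from the single top-level
seed via `numpy.random.SeedSequence`, so a run is a pure function of its
configuration; the manifest records the configuration, derived seeds and
SHA-256 of every artifact, and identical configs reproduce identical
manifests. The CLI exposes each stage and a `run` command; exit codes
separate configuration (2), data (3) and numerical (4) failures.

## Known limitations

- The synthetic noise model is white Gaussian; conclusions about temporal
  autocorrelation, drift or motion artifacts are out of reach.
- Elbow ranks depend on the axis normalization noted above.
- Sampling-based input attributions carry Monte-Carlo error; the reported
  standard errors should be consulted before interpreting small |φ|
  differences.
- The desk-scale defaults are sized for a laptop CPU; reproducing the
  original cluster-scale search is a configuration change, not a code
  change, but takes correspondingly long.
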