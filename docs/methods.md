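# Methods

## The model

`bnec` models the effective connectivity (EC) of a set of brain regions as
a linear Gaussian Bayesian network. Given regions
X₁…X_k and a directed acyclic graph (DAG) with parent sets Pa(·), each
region is conditionally Gaussian:

    X_i | Pa(X_i) = pa  ~  N( m_i + Σ_j b_ij (x_j − m_j),  v_i )

with unconditional mean m_i, conditional variance v_i and linear
connectivity coefficients b_ij from each parent. The joint distribution is
multivariate Gaussian: writing W for the parent-to-child weight matrix,
the centred covariance is (I − Wᵀ)⁻¹ diag(v) (I − Wᵀ)⁻ᵀ, which the package
exposes as `implied_joint` and uses as an internal consistency oracle
(the factorized log-likelihood must equal the dense Gaussian log-density;
tested to 1e-8).

Maximum-likelihood estimation is per-node linear regression with
intercept; variances are the ML (divide-by-N) residual variances. Model
selection maximizes the Schwarz score

    BIC = log L̂ − (d/2)·ln N,   d = Σ_i (|Pa(i)| + 2),

which decomposes over nodes. The sign convention is "larger is better";
any monotone variant selects the same structure. BIC is score-equivalent
on Markov-equivalent DAGs (same skeleton and v-structures), so edge
directionality is only identified up to the equivalence class — every
report the pipeline writes carries a caution to that effect.

## Structure search

1. **Candidate parents.** For each node, the LARS-lasso regularization
   path of its penalized regression on all other (standardized) nodes is
   computed from sufficient statistics by a homotopy written for this
   package (cross-checked against `sklearn.linear_model.lars_path` in the
   test suite). Candidate parent sets are the unions-so-far of the active
   sets, nested from ∅ upward, truncated at `max_parents` (default 8).
2. **Order-based greedy search.** Node orderings (the identity plus
   seeded random restarts, default 50) are hill-climbed by adjacent
   swaps; under a fixed ordering each node takes its best-scoring
   candidate subset among its path sets intersected with its
   predecessors. Ties — which occur systematically for Markov-equivalent
   structures — are broken lexicographically on the sorted edge list, so
   results are deterministic given data and seed.
3. **Polish.** Each restart's result is refined twice: per-node greedy
   add/drop of single parents within the candidate union (non-prefix
   subsets the nested path sets cannot express), then a DAG-space
   steepest-ascent stage with add / delete / reverse-and-prune moves.
   The compound reversal move (reverse an edge, then greedily prune both
   endpoints' parents) matters: a score-neutral reversal alone can never
   be accepted by a strict hill climber, yet crossing to another member
   of the equivalence class is sometimes the only way to reach a
   higher-scoring neighborhood.

An exhaustive enumerator over all labeled DAGs (25 at 3 nodes, 543 at 4,
29,281 at 5) provides the exact optimum for small systems and is the
oracle for the search's acceptance test (≥ 90/100 exact matches on 4-node
data; measured 100/100).

All scoring runs off the pair (N, ML covariance). Group fits pool
per-subject Gram matrices of standardized series, so a permutation
re-fit costs one 9×9 matrix sum plus the search itself (~20 ms); this is
what makes 200-permutation × 500-replicate calibration studies feasible
on one CPU.

## Group analysis

A group network is learned from subjects' series standardized per column
per subject (making the fit invariant to per-subject affine rescaling)
and concatenated along time; how to pool subjects into one group model is
not uniquely determined by the study description, and this concatenation
construction is the package's choice. Subject-level networks are learned
independently per subject to give per-subject convergence-index (CI)
distributions.

**Convergence index.** CI(region) = number of parents (in-degree).
Regions are classified `high` iff CI is strictly above the mean CI over
regions; ties at the mean are `low` (with all regions tied there are no
hubs).

**Permutation test on directed weights.** The statistic for an ordered
pair (parent, child) is the group-A minus group-B fitted weight, with 0
when the learned network lacks the edge — so edges that disappear or
reverse between groups are handled by the same statistic. The null
distribution re-learns both group networks for each of B seeded
relabelings that preserve group sizes. P-values are one-sided in both
directions with add-one smoothing, p = (#{extreme} + 1)/(B + 1), ties
counted as extreme (conservative, never zero). The permutation permutes
the label vector itself, and all fits (observed and permuted) share one
fitting stream, so relabeling the two groups swaps the two p-value
matrices exactly — a tested invariant.

Permutation re-fits use 10 restarts by default (`permutation_restarts`):
measured on study-scale mixtures, fewer restarts let the search drop or
reorient contrast-carrying edges in permuted mixed groups, which fattens
the null's tails and destroys power; 10 restarts stabilize the fits at
~20 ms each. The same setting applies to the observed and permuted fits,
which is what the test's exchangeability argument requires.

**Classical layers.** Two-sample t-tests (pooled variance by default;
Welch available) compare FC z-scores and subject-level CI between groups.
Pearson correlations relate CI to FC within a group; Spearman (mid-rank)
correlations relate CI to cognitive domain scores. No multiple-testing
correction is applied by default, matching the exploratory design; a
Benjamini–Hochberg column is available behind a flag.

## Preprocessing

Spheres are defined in world (MNI) millimetre coordinates; a voxel
belongs to an ROI when its center, mapped through the image affine, lies
within the radius, boundary inclusive. ROI series are voxel means; FC is
quantified as the mean z-score within the sphere.

The temporal chain removes (1) each column's least-squares line, (2) DFT
bins outside the pass band (default 0.01–0.08 Hz, the conventional
resting-state band — a convention, not a reported value; inclusive
edges, frequency-domain masking for exact testability), and (3) the span
of the provided confound columns (six motion profiles, global, white
matter, CSF — accepted as columns; computing them from segmentations is
out of scope). `preprocess_series` removes the union of the three
subspaces in a single least-squares projection: the individual operations
do not commute (the trend line is not spanned by the retained Fourier
modes), so sequential application is only approximately idempotent,
whereas the joint projection is exactly idempotent and reduces to each
single operation when used alone. Column variance never increases under
any of these projections.

## Synthetic cohorts

The generator emulates the study design end-to-end: two groups of 17
subjects, 190 timepoints at TR = 2 s, nine default-mode-network regions
(PCC, dorsal/ventral MPFC, bilateral IPL, LTC and hippocampus). The
default ground-truth network has 13 edges arranged so that PCC, MPFC and
IPL are high-CI hubs fed by the network while LTC/HC form a peripheral
pairwise subsystem, echoing the hub/periphery dichotomy reported for the
DMN; the contrast-carrying edges sit in colliders so their orientations
are identifiable from data. Conditional variances are solved so that all
marginal variances equal 1 (`unit_variance_parameters`): group fits
standardize per subject, so only on the unit-variance scale does a
planted weight difference equal the difference the group statistic
actually measures.

Group B (the patient-like group) is derived by editing weights:
a weakened fronto-parietal edge (dMPFC→lIPL 0.55→0.15), a removed
parietal edge (PCC→rIPL, so rIPL loses one parent and its CI drops), a
weakened temporo-frontal edge and a strengthened temporo-parietal edge.
The magnitudes are a calibration choice — no effect sizes are reported
for the original contrasts — fixed once at a planted difference of
0.3–0.4 on the standardized scale.

Per-subject series are ancestral samples from the group's network;
optional AR(1) coloring (filter, then restore each column's mean and
variance) mimics fMRI temporal autocorrelation, which the iid model
ignores — the default is 0 so that generated data match the model
assumptions, and the option exists to quantify robustness. FC z-scores
are baseline + 0.2 × (true regional CI) + N(0, 0.3) noise, giving
hub regions higher simulated FC. Covariates (MMSE/MoCA-like global
scores and four domain scores, in standardized units rather than raw
test points) mix the standardized linked metric with independent noise
at a configured correlation. All randomness descends from one integer
seed through `numpy.random.SeedSequence` entropy lists; the two groups
draw from separate streams so regenerating one group leaves the other
byte-identical.

What the generator does **not** emulate: volumetric artifacts, motion,
ICA mixing, scanner noise spectra, non-Gaussian or nonstationary
dynamics, and between-subject heterogeneity of the true network within a
group. Passing tests therefore demonstrate correctness and calibration
of the estimation machinery under the model's own assumptions at the
study's scale — not robustness to everything real fMRI does.

## Numerical choices

- Degenerate (zero-variance) ML fits are representable and flagged;
  likelihood evaluation on them raises a named error rather than
  propagating ±∞.
- Collinear parent sets raise a rank error naming the node; inside the
  search they score −∞ and are never selected.
- Score ties are detected at 1e-9 absolute tolerance and resolved
  lexicographically on the sorted edge list.
- Local scores are computed from covariance algebra with a small
  hand-rolled Cholesky (the matrices are at most `max_parents` square;
  library call overhead dominates at that size inside permutation loops).

## Problem sizes used by the checks

Calibration of the permutation test runs 500 replicate null cohorts at a
reduced 5-node scale with B = 200 permutations (measured one-sided
rejection rate ≈ 0.046 at α = 0.05); power uses 50 study-scale replicates
with a single planted 0.4 weight difference (detected in ≥ 80%); the
structure-recovery study uses 20 random 9-node networks at 17 × 190
samples (skeleton recall ≈ 0.99, false-adjacency rate ≈ 0.03, exact
equivalence-class match ≈ 0.7–0.9 depending on the truth's density — the
misses trace to single borderline edges the BIC genuinely prefers at
N = 3230, not to search failures). `scripts/acceptance.py` re-measures
these quantities with 200 null replicates and 25 power replicates.

## Known limitations

- The model is a single static snapshot: no temporal dependence between
  successive volumes is modeled (AR(1) coloring in the generator breaks
  the iid assumption mildly and is off by default), and the acyclicity
  constraint rules out reciprocal connections.
- Orientation of individual edges is meaningful only up to the Markov
  equivalence class; between-group weight comparisons for a directed pair
  implicitly condition on the learned orientation being stable across
  fits. The permutation machinery handles instability conservatively
  (absent edge ⇒ weight 0) but loses power when orientations flap.
- The heuristic search has no optimality guarantee beyond 5 nodes; the
  exhaustive oracle bounds it only on small systems.
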