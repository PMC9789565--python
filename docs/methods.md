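# Methods

`microcf` implements a two-part analysis for cross-cohort gut-microbiome
studies of obesity: (1) discovery of *regional shared biomarkers* — species
that discriminate obese from healthy individuals in every cohort — by a
heterogeneous ensemble of filter, embedded and wrapper feature selection;
and (2) *counterfactual modulation analysis* — for each obese individual, a
minimal change of biomarker abundances that flips a trained classifier's
prediction to healthy, found with a deep-deterministic-policy-gradient
(DDPG) actor-critic operating in the latent space of an autoencoder.

## Input model

The package consumes species-level relative-abundance tables in the
MetaPhlAn2 merged dialect (TSV of clade lineages x samples, percent scale)
plus per-sample metadata (cohort and either an obese/healthy group label or
BMI, binarised as obese ≥ 30, healthy < 25, 25–30 excluded).  All analyses
run on abundance *fractions*.  Low-prevalence species are removed before
selection: a species is dropped iff its prevalence (fraction of samples
with abundance > 0) is ≤ 10% in **every** cohort x group cell; surviving in
any single cell suffices.  Per-cohort-only cells are available by option
(`per_group=False`) because the two readings cannot be distinguished from
published species counts.

## Synthetic study generator

Real multi-cohort metagenomes are not redistributable, so the testbed is a
zero-inflated compositional simulator whose defaults mirror a five-country
discovery design: per-species baseline log-intensities ~ N(0, 2.0), additive
cohort effects ~ N(0, `cohort_effect_size`), an obese-vs-healthy log-scale
shift of exactly `effect_size` for planted biomarkers (direction drawn once
per species), per-sample log-normal noise (SD 1.0), Bernoulli structural
zeros (`zero_inflation`, default 0.3), and closure to relative abundances.
The pinned evaluation testbed is 5 cohorts x 2 groups x 100 samples, 200
species, 20 planted shared biomarkers, effect 1.0, seed 1 — chosen as a
desk-scale analogue of a multi-hundred-sample cohort study with weak-to-
moderate per-species effects.

What the generator does *not* emulate: taxonomic correlation structure
(species are conditionally independent given the design), sequencing depth
variation, compositional bias from closure of a much larger community, or
batch effects beyond a mean cohort shift.  Passing recovery tests therefore
demonstrates that the pipeline machinery is correct and calibrated, not
that it would attain the same operating characteristics on real data.

## Ecology statistics

Shannon diversity (−Σ p log p over renormalised nonzero entries; natural
log by default, log2 by option), Bray–Curtis distance (Σ|u−v|/Σ(u+v)),
classical-scaling PCoA (negative eigenvalues dropped and reported, no
Cailliez correction), and one-way PERMANOVA (pseudo-F from the
within/between squared-distance decomposition, free label permutation,
`p = (1+#{F* ≥ F})/(1+n_perm)`, 999 permutations by default) are
implemented from first principles and cross-checked against scikit-bio and
scipy in the test suite.  For tiny samples an exact mode enumerates all
distinct group assignments.  The Wilcoxon rank-sum test enumerates the
exact null over index subsets (with midranks, so ties are handled exactly)
when the pooled size is ≤ 12, and uses the tie-corrected normal
approximation otherwise.

## Filter selection

Seven association statistics are computed per species against the binary
group label: Pearson, Spearman, Kendall tau-b, the maximal information
coefficient (MIC), and the three corresponding partial correlations.

*MIC.*  The characteristic-matrix definition with grid budget
B(n) = max(4, n^0.6) (the floor admits 2x2 grids at the smallest allowed
n).  When the number of admissible grids is small the search is exhaustive
(cuts fall only between distinct sorted values), so small-sample values are
exact; otherwise the equipartition-seeded dynamic programme over tie-clumps
is used in both axis orientations.  Against a binary label every admissible
grid is (l columns x 2 rows) and a single clump DP is optimal, which makes
label-permutation nulls cheap (a numba kernel with an integer `k log k`
lookup table).

*Partial correlations.*  Each species' association with the label given all
other species comes from the inverse of the bordered association matrix
(mid-ranks for Spearman, pairwise tau-b for Kendall).  Because p can exceed
n, the whole bordered correlation matrix is shrunk toward the identity —
feature block (1−γ)R + γI, target column (1−γ)s — with γ chosen
analytically (Schäfer–Strimmer estimate from standardised products for
Pearson/Spearman; the asymptotic null variance of tau-b for Kendall) or set
explicitly.  With a single feature γ_auto = 0 and the partial reduces to
the plain statistic.  A Schur-complement identity lets the inverted feature
block be reused across all label permutations.

*Consensus.*  Significance is a label-permutation p-value (999 permutations
by default, one shared permutation set across species and methods, two-
sided via |statistic|), BH-adjusted across species within each method.  A
method votes for a species at q < 0.05 and a species is selected at ≥ 4 of
7 votes; both knobs are exposed.  Note a discreteness consequence of the
strict `q < alpha` rule: with 999 permutations the smallest attainable p is
1/1000, so a cohort with exactly `m·p_min/alpha` top hits yields q exactly
at alpha and no votes from that method; raising `n_permutations` sharpens
the granularity.  The per-cohort selections are intersected across cohorts
into the filter family's regional set.

## Embedded selection and stability screening

Seven tree-ensemble learners (decision tree, random forest, gradient-
boosted trees, XGBoost, the XGBoost random-forest variant, AdaBoost,
LightGBM; library-default hyperparameters, seeds pinned) are fitted per
cohort; species with normalised impurity/gain importance ≥ 1/p (the uniform
share) are selected.  This rule reproduces the qualitative failure modes
that motivate screening: single trees concentrate importance on few
features and their cross-cohort intersection often empties, while bagged
forests spread importance and saturate.

The stability screen repeats the cross-cohort regional intersection over 10
seeds and rejects a learner whose regional set is ever empty (`empty`),
whose mean regional set exceeds 90% of the species (`saturated`), or whose
cumulative intersection still decays — by more than 10% relative between
the last two repeats, or all the way to the empty set — (`unstable`).
An accepted learner contributes the regional intersection of its base-seed
selection; the repeated runs only judge stability.  (The cumulative
intersection of all repeats, the learner's "stable core", is retained in
the report for inspection but is deliberately not the contribution — it
shrinks with the number of repeats and would make the selected set depend
on a screening knob.)

## Wrapper selection and aggregation

Per cohort, each learner ranks species by its own importances; sequential
forward selection evaluates the mean stratified 5-fold cross-validated AUC
of every ranking prefix (AUC by the Mann–Whitney rank statistic, ties
counted half) up to `sfs_max_features` (default 25 — AUC curves on the
testbed plateau well below this), and the best prefix wins, the smallest k
on exact ties.  The best (learner, prefix) pair per cohort is kept and the
pairs are pooled across cohorts by union.  The final biomarkers are
`(filter_regional ∪ accepted embedded regionals) ∩ wrapper_pool`; an empty
final set warns rather than fails.

## Counterfactual engine

A classifier M (default: XGBoost on the final biomarkers) defines the
prediction to flip.  An autoencoder (2 hidden layers, widths scaled to the
feature count, tanh; trained with Adam on reconstruction MSE with a held-
out split) embeds profiles as z = enc(x).  The actor maps the state
(z, the model's positive-class probability of x, the target class, an
optional conditioning vector) to a latent action z_CF; the decoded
counterfactual is x_CF = clip(dec(z_CF), [0, per-feature observed max]),
and delta is defined so that x_CF = x + delta holds bit-exactly.  Rows are
not renormalised: the biomarkers are a sub-composition treated feature-wise.

Training is one-step DDPG: the critic Q(state, action) regresses on the
immediate reward R = f(M(x_CF), y_T) (indicator of a flipped argmax by
default; target-class probability by option) over a replay buffer of
noise-explored actions, and the actor descends the combined gradient of
L_max = −mean Q, λ_s · L_sparsity (mean L1 between x and x_CF, via a
straight-through mask at the clipping boundary) and λ_c · L_consist (mean
squared error between enc(x_CF) and z_CF, keeping actions on the decoder
manifold).  λ_s = λ_c = 0.5 by default; increasing λ_s trades validity for
sparser edits (monotone on the toy benchmark).  All networks are small
fully-connected numpy models with hand-written backpropagation and Adam;
one seeded generator drives initialisation, batching and exploration noise,
so trajectories are exactly reproducible.  Because the episode is one step,
no bootstrapped target or target networks are needed.

## Modulation analysis

Per species and cohort, the shift between the median abundance of original
obese samples and of their counterfactuals is called `up`/`down` when
|shift| ≥ 0.1 (the table's native abundance scale; the dead band is
configurable) and `unchanged` otherwise.  A species is a broad-spectrum
target when every cohort calls the same non-unchanged direction
(a majority-without-opposition mode exists but is off by default).
Co-abundance networks connect biomarkers with |Pearson r| > 0.3 (absolute
value: the published threshold does not mention sign); comparing edge sets
counts common associations, sign-agnostic by default.

## Numerical and degenerate-input conventions

Constant species get statistic 0 and p 1 in the cohort screen (the public
`correlation` raises on constant input); all-zero abundance rows are
errors; empty selected sets give precision 0 by convention; permutation
p-values use the add-one estimator and so are never 0; BH q-values are
clipped at 1.  Samples in simulated tables are protected against total
zero-inflation by always keeping each sample's largest intensity.

## Problem sizes used in the shipped evaluation

The shipped tests and the acceptance script evaluate at desk scale chosen
as defaults of the package: the pinned 1000-sample testbed for pipeline
recovery and networks; 200-replicate null studies (30 species, 30 samples
per group, 199 permutations) for selection-rate and type-I calibration; a
200-sample two-feature toy task for the counterfactual engine; and a
250-sample stratified subsample for the PERMANOVA / geography figures in
the acceptance script.

## Known limitations

- The filter consensus loses power at permutation-p granularity boundaries
  (see above); on weak effects the embedded family dominates discovery.
- Kendall partial correlations invert a tau-b matrix that is not guaranteed
  positive semi-definite; shrinkage makes inversion stable but extreme
  cases fall back to a clamped Schur complement.
- The DDPG reward is the classifier's verdict, so counterfactual quality is
  bounded by classifier quality; probabilities are not calibrated.
- PCoA drops negative eigenvalues rather than correcting them; for strongly
  non-Euclidean distances the reported eigenvalue mass understates stress.
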