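# Methods

This note documents the models implemented in `phenoview`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not establish.

## Task and data model

One row per person; four feature groups — demographics `D`, clinical `C`,
lifestyle `S_lif`, genetic family history `S_gen` — and a three-level
outcome `Y` ∈ {non-MAFLD, nondiabetic MAFLD, diabetic MAFLD}, encoded
0/1/2.  Obese and lean MAFLD are merged into "nondiabetic" because both are
distinguished from each other purely by BMI.  Missingness is tracked in an
explicit boolean mask, which is the single source of truth; on disk a
missing cell is an empty field or the literal `NA`.  By default only the
survey groups may be missing: demographics and laboratory values come from
structured records, surveys from self-report.

## Graph representation learning

Each survey view becomes an undirected bipartite graph with person nodes
and one node per (feature, coded level) pair; an edge marks an observed
response.  All Σᵢ Jᵢ feature-value nodes exist even if unobserved, so the
graph's shape depends only on the schema.  Numeric survey features (none in
the default schema) are quantile-binned into 4 coded levels first.  Edge
weights are 1 for coded categorical values: a "value" on a one-hot category
carries no magnitude, so weighted aggregation reduces to the plain mean.

Initial node features are fixed and injective: feature-value node *k* gets
the one-hot of its own identity (Σᵢ Jᵢ dims); person nodes get zeros there
plus two summary coordinates, normalized degree and the mean of the
person's normalized response codes.  After one round of neighbor
aggregation a person's representation already contains its full normalized
response histogram, so no information is lost by the simple person
initialization.

The encoder is two layers of h ← W·[h; mean of neighbor h] with ReLU
between layers.  Training minimizes the mean margin triplet loss
max(0, d(a,p) − d(a,n) + α) with Euclidean d, α = 0.5, positives drawn
uniformly from neighbors (the anchor itself when isolated — exactly how
fully missing survey rows stay trainable), negatives uniformly from
non-neighbors.  A printed form of this objective elsewhere is syntactically
garbled; the standard margin form above is the only reading consistent
with an anchor/positive/negative triplet and a margin parameter.

Defaults: d_g = 96, 100 epochs, 2 negatives per anchor, Adam lr 0.01.
These are larger than a first-guess configuration (32/50/1) because linear
probes showed the narrower encoder discards a measurable part of the
surveys' aggregate class signal (probe macro AUC ≈ 0.79 vs ≈ 0.84); the
embedding must preserve signal it cannot see the labels for, so capacity is
the only lever.  Graphs are built over all persons without using labels;
the construction is transductive, which we flag openly: no outcome
information can leak, but embeddings of test persons do use their survey
responses.

## Multiview contrastive pretraining

The clinical teacher is the encoder half of a 3-layer autoencoder
(in→64→64→d_z and mirror) trained on the standardized clinical matrix by
mean squared reconstruction error, then frozen ("anchoring" the learners);
joint fine-tuning exists behind a flag but is off by default.  Learners for
lifestyle and genetics share the 3-layer MLP architecture (d_g→64→64→d_z)
and consume the graph embeddings, per the architecture's data flow.

The loss is one-directional InfoNCE per learner view — positives are the
same person across views, negatives the rest of the batch, similarity is
cosine — summed over the two views.  No symmetric (teacher→learner) term is
added because the objective is defined one-directionally.

The adaptive temperature network maps the batch-mean clinical embedding
through ReLU and a linear read-out to a scalar.  The raw linear form can
emit zero or negative temperatures, which the InfoNCE softmax cannot
accept, so the implementation uses τ = softplus(w·ReLU(V_batch)) + τ_min
with τ_min = 0.05: strictly positive, smooth, and still batch-adaptive.
The ATN trains jointly with the learners (the alternative — a separately
trained ATN — has no training signal of its own).  The teacher bottleneck
z_b is used directly as the clinical embedding downstream; no projection
head is added.

Defaults: d_z = 64, batch 256, 100 epochs, Adam lr 1e-3.  d_z mirrors the
graph-capacity argument above.

## Two-stage risk estimation

A shared trunk (one hidden layer of 64, ReLU) feeds a binary stage-1 head
(softmax over {no MAFLD, any MAFLD}) and an H=2 stage-2 head (softmax over
{nondiabetic, diabetic}).  The composed distribution is
(1−p, p·q₁, p·q₂), which sums to one by construction.  The training loss is

    L = Σᵢ w₃[yᵢ]·NLL(composed) + γ·Σᵢ w₂[bᵢ]·BCE(stage 1)
        + λ·Σ_{i: yᵢ>0} w_ph[yᵢ−1]·CE(stage 2)

with balanced inverse-frequency weights N/(K·n_c) in every term and
γ = λ = 1 by default (a {0.5, 1, 2}² grid is exposed through the CV
harness; measured sensitivity is small).  Stage 2's population is the
*true*-MAFLD rows (teacher forcing) rather than predicted-MAFLD rows:
conditioning on a hard prediction is non-differentiable and unstable early
in training, while teacher forcing trains the same conditional
distribution.  Log-probabilities are clamped at 1e-12.

The trunk is intentionally shallow: with ~3.5% prevalence in the rarest
class, a 2×64 trunk memorizes the minority rows (training AUC 1.0) and
loses 0.02–0.03 held-out macro AUC relative to the single hidden layer.

The classifier input concatenates the same preprocessed dense matrix every
benchmark sees (z-scored numerics, one-hot categoricals, kNN-imputed) with
the contrastive embeddings z_a and z_c; the teacher embedding z_b can be
appended behind a flag but is redundant with the raw clinical block and off
by default.  The method's graph/contrastive components are what consume
the raw, non-imputed survey responses.

Hard labels take the argmax of the composed distribution with ties broken
toward the lower class index (the less severe call).

## Preprocessing

z-scoring uses the population (divide-by-n) standard deviation from
training rows only; a zero-variance feature gets sd 1 with a warning, so
its transform is identically zero.  One-hot blocks follow declared level
order; unseen levels at transform time become all-zero blocks with a
warning.  kNN imputation (k = 5) fills the dense path only: Euclidean
distance over mutually observed features, neighbor mean for numerics, and
one-hot blocks snapped to the modal indicator so imputed categories remain
valid; at test time the neighbor pool is the training rows.  Imputation
runs after encoding — distances over encoded columns treat all features on
comparable scales, and the block-snapping step restores categorical
validity.

## Evaluation protocol

Repeated trials: stratified 80/20 splits (round(f·n) train rows;
stratification by class with largest-remainder allocation keeps the 3.5%
class in every test set), one model fit per trial, per-class and macro
precision/recall/F1, and one-vs-rest AUC via the rank (Mann–Whitney)
statistic with mid-rank ties.  Macro (unweighted) averaging is used
throughout — it is the only averaging rule under which a per-class AUC
triple like (0.859, 0.878, 0.957) reproduces an overall 0.898 exactly.
Paired two-tailed t-tests compare methods on shared splits;
zero-variance differences are reported as an explicit degenerate case,
never as a number.  The ablation ladder fixes the split seeds across
modes so every comparison is paired.

## Synthetic cohort generator

The generator plants the structure the method is designed to exploit and
nothing else; it makes no attempt to match real marginal distributions of
any study's 112 variables.

* **Outcome**: multinomial with priors (0.850, 0.115, 0.035).
* **Intraphenotype variability**: 2 latent subclusters per class; each
  (class, subcluster) pair owns a mean in a q=6-dimensional latent space
  (spread `class_sep` = 0.85); persons scatter around their pair's mean
  with unit sd.
* **Views**: clinical variables are noisy linear read-outs of the first 4
  latent dims (the "metabolic state"; noise sd 3.0); surveys are softmax
  draws over all 6 dims scaled by ρ·0.8, so behavioral/hereditary dims 5–6
  reach the observer only through the surveys, and at ρ = 0 surveys are
  exactly uniform noise.  This overlapping-but-distinct view structure is
  the generator's core design decision: if every view read the same
  factors, survey-derived representations would be redundant with the
  clinical block and no multiview method could add value even in
  principle.
* **Definitive diabetic markers**: two clinical variables with unit noise
  shifted +3.0/+2.5 in the diabetic class only, mirroring how definitive
  disease markers dominate diabetic-MAFLD prediction.
* **Demographics**: age ~ N(58.18, 12.94²) with a +2-year any-MAFLD shift;
  sex 68.1% female — the reported cohort marginals.
* **Missingness**: MCAR at rate m = 0.3 on survey cells only (a typical
  self-report incompleteness level; mechanism and rate are configurable,
  and MCAR is an acknowledged simplification — no MAR/MNAR structure).

Noise scales were calibrated once so that the dense MLP baseline lands
near the realistic difficulty regime (macro AUC ≈ 0.83–0.85 at n = 2000)
rather than saturating, and then frozen.

### What the synthetic experiments show — and don't

On planted-signal cohorts (ρ = 0.8, n = 2000) the ablation ladder orders
as designed and the full method beats the dense MLP baseline, but the
margin is small (per-trial macro-AUC difference ≈ +0.01, trial sd ≈ 0.013),
so paired significance at 5 trials depends on the cohort realization;
larger trial counts make it stable.  The generator's low-dimensional
latent structure is ultimately learnable by any flexible dense model, so
it cannot reproduce large real-data gaps — passing these tests shows the
components extract survey structure correctly and compose correctly, not
that the method will dominate baselines on real cohorts.  At ρ = 0 the
modes are statistically indistinguishable, as they must be.

## Numerical choices

All training runs on a vectorized NumPy reverse-mode autodiff core
(`phenoview.nn`) with float64, Glorot-normal initialization, and Adam;
every stochastic step draws from a `numpy.random.Generator` seeded from
the config, so identical seeds give identical results.  Distances inside
the differentiable triplet loss add 1e-12 under the square root to stay
differentiable when positive = anchor.  Softmaxes subtract the row max;
InfoNCE operates on cosine similarities, which are bounded, so no further
stabilization is needed at τ ≥ 0.05.  Problem sizes in the test suite and
acceptance script (n = 2000 cohorts, 5 trials; one n = 4408 end-to-end
run) are the package's chosen demonstration scale.

## Known limitations

* Transductive graph embeddings: persons must be present at graph-build
  time; no inductive embedding of new persons in this version.
* MCAR-only missingness in the generator's default path.
* The two-stage composition supervises the phenotype head only on MAFLD
  rows, so its outputs on confident non-MAFLD rows are unconstrained
  (they are multiplied by p ≈ 0 in composition).
* No probability calibration; the stage-1 threshold sweep is the supported
  decision-support tool.
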