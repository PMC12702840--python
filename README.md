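# phenoview

Two-stage multiview contrastive learning for predicting MAFLD (metabolic
dysfunction–associated fatty liver disease) phenotypes from mixed clinical
and survey-based patient data.

## The problem

MAFLD screening is a three-class risk prediction task: given a person's
demographics (D), clinical measurements (C), and self-reported lifestyle and
genetic family-history surveys (S), predict whether they will remain
MAFLD-free, develop nondiabetic MAFLD, or develop diabetic MAFLD.  Two
things make this hard in practice: the outcome is heavily imbalanced
(roughly 85% / 11.5% / 3.5%), and the survey data — which carries signal
about behavioral and hereditary predisposition not visible in laboratory
values — is incomplete and weakly informative item by item.

`phenoview` is for methodologists and applied biostatisticians who want a
tested, reproducible implementation of this modeling approach, together
with a synthetic cohort generator that plants the relevant structure so
every component can be validated without access to any patient data.

## The method

1. **Bipartite graph representation learning.**  For each survey view
   (lifestyle, genetics) build a bipartite graph: person nodes on one side,
   *feature-value* nodes F<sub>ij</sub> (feature *i*, coded level *j*) on
   the other; an edge marks an observed response, so missing answers need
   no imputation.  A two-layer mean-aggregation neighborhood encoder
   (GraphSAGE-style) is trained with the margin (triplet) objective

       L = max(0, d(f(a), f(p)) − d(f(a), f(n)) + α)

   where the positive *p* is a uniformly drawn neighbor of the anchor
   person *a* (or *a* itself when isolated) and *n* a uniformly drawn
   non-neighbor, yielding per-person embeddings A<sup>Lif</sup>,
   A<sup>Gen</sup>.

2. **Teacher-guided multiview contrastive pretraining.**  The clinical
   matrix is encoded by the frozen encoder half of a pretrained autoencoder
   (the *teacher*, z_b).  Lifestyle and genetics *learner* encoders map the
   graph embeddings to z_a, z_c and are trained with one-directional
   InfoNCE: for person *i*, −log softmax over in-batch candidates *k* of
   cos(z_x(i), z_b(k))/τ, summed over both learner views.  The temperature
   is produced per batch by an adaptive temperature network,
   τ = softplus(w·ReLU(mean z_b)) + τ_min, trained jointly.

3. **Two-stage risk estimation.**  A shared trunk feeds two heads: stage 1
   yields p = P(any MAFLD); stage 2 a phenotype distribution
   (q₁, q₂) over {nondiabetic, diabetic}.  The composed three-class
   distribution is (1 − p, p·q₁, p·q₂), and training minimizes the sum of a
   class-weighted NLL on the composed distribution, γ× a binary
   cross-entropy on stage 1, and λ× a phenotype cross-entropy on the
   true-MAFLD rows, with balanced inverse-frequency weights N/(K·n_c)
   throughout.

Evaluation follows repeated stratified 80/20 trials with per-class and
macro precision/recall/F1 and one-vs-rest AUC, a four-mode ablation ladder
(MLP / +graph / +contrastive / full) over shared splits, and paired
two-tailed t-tests.

All neural components run on a small NumPy reverse-mode autodiff core
(`phenoview.nn`); results are bit-for-bit reproducible under a fixed seed.

## Worked example

```python
import phenoview as pv
from phenoview.pipeline import PipelineConfig, fit_full_pipeline
from phenoview.twostage import threshold_report

table, _ = pv.generate_cohort(pv.SyntheticConfig(n=1200, seed=3))
split = pv.trial_split(table.n, seed=0, f=0.8, y=table.y)
fitted = fit_full_pipeline(table, split, PipelineConfig().fast().reseed(0))
pred = fitted.predict(split.test)
```

Running `python examples/04_two_stage_prediction.py` (which is exactly this)
prints:

```
held-out macro F1:  0.623
held-out macro AUC: 0.861
  non_MAFLD              F1=0.891  AUC=0.825
  nondiabetic_MAFLD      F1=0.432  AUC=0.811
  diabetic_MAFLD         F1=0.545  AUC=0.947
```

Macro averaging weights all three classes equally, so the 0.861 reflects
minority-phenotype discrimination, not just the easy majority class; the
diabetic class scores highest because the generator plants two definitive
diabetic markers.  The stage-1 threshold sweep that follows shows the
screening trade-off: raising the flagging threshold from 0.3 to 0.7 drops
the flagged count from 62 to 39 while precision rises from 0.35 to 0.49 and
recall falls from 0.61 to 0.53 — the dial a clinician would tune between
catching every at-risk person and avoiding false alarms.

The other scripts in `examples/` each demonstrate one capability:
cohort simulation, graph embedding, contrastive pretraining, and the
ablation ladder with its paired t-test.

A thin CLI mirrors the pipeline: `phenoview simulate | train | evaluate |
ablate | thresholds` (see `phenoview --help`).

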