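# Methods

This note records the models, defaults and numerical choices behind
`hfphenomap`, and what the synthetic experiments do and do not demonstrate.

## Synthetic cohort generator

The generator emulates a pooled cohort of nine double-blind
placebo-controlled β-blocker trials in HFrEF. Its defaults are the study
conditions used throughout the tests and the acceptance script:

* **Size and composition.** Nine trials totalling 15 659 patients with an
  expected 12 822 in sinus rhythm and 2 837 in atrial fibrillation (atrial
  flutter is generated as AF). Trial sizes range from ~380 to ~3830 and each
  trial has its own AF fraction (0.10–0.35) and follow-up scale.
* **Covariate marginals.** Continuous covariates are location–scale
  distributions matched to the published baseline table per stratum: normal
  for age, heart rate, systolic blood pressure and LVEF; log-normal for BMI
  and creatinine (right-skewed in practice); all truncated to physiologic
  ranges. The scale is IQR/1.349. Binary covariates are Bernoulli at the
  published proportions. At full size the generated medians match the
  configured medians within IQR/10 (tested).
* **Planted phenotypes.** Each rhythm stratum is a finite mixture: 6 SR
  clusters with prevalences 433/1001/1414/2537/3497/3940 out of 12 822, and
  5 AF clusters with 608/659/696/403/471 out of 2 837. A cluster shifts a
  handful of covariates by a fixed pattern (in standardised units,
  multiplied by a `separation` knob) and perturbs some binary proportions.
  Patterns are centred by their prevalence-weighted mean so the cohort
  marginals are invariant to `separation`. Default separation 1.5 gives
  overlapping, realistic phenotypes; 3.5 is the "strong separation" regime
  used for recovery testing, where the minimum pairwise centroid distance
  (~3.5 standardised units) comfortably exceeds the within-cluster spread
  (~2.1).
* **Outcome model.** Death is Bernoulli with logit
  `baseline_death_logit + treatment_log_or·1[bb] + Σ βⱼ(zⱼ − E[zⱼ])`, where
  the per-cluster baseline logits reproduce the published placebo death
  fractions (6.3%…28.5% in SR; 14.8%…40.3% in AF) and the treatment log
  odds ratios the published cluster ORs (0.59, 0.79, 0.54, 0.86, 0.69, 0.74
  in SR; 1.25, 0.57, 1.02, 0.75, 1.00 in AF). Covariate coefficients are
  small (|β| ≤ 0.1) and centred within cluster, so the marginal
  within-cluster OR stays within Monte-Carlo error of
  `exp(treatment_log_or)` despite the non-collapsibility of the odds ratio
  (verified at three million SR patients: worst deviation ~0.011).
* **Follow-up** is exponential per trial with overall median 1.3 years. It
  feeds only the annualised-mortality column; the outcome itself is binary,
  not time-to-event.
* The hidden assignment is emitted as a `true_cluster` column used only by
  tests; the pipeline drops it.

What the generator does **not** emulate: trial-specific inclusion criteria,
covariate correlation beyond what the mixture induces, informative
missingness (`inject_missingness` is MCAR by construction), competing risks
or censoring-informed outcomes. Passing recovery tests therefore shows the
pipeline recovers mixture-type phenotype structure under randomisation; it
cannot certify behaviour on real IPD.

## Variational autoencoder

Amortised-inference VAE with diagonal-Gaussian posterior, standard-normal
prior, and per-column likelihoods: Gaussian with a learned per-column
variance (floored at 1e-4) for continuous inputs, Bernoulli-with-logit for
binary inputs. Encoder and decoder are two tanh layers of width 64
(configurable); with 13 inputs nothing larger is warranted. Training is
mini-batch Adam (lr 1e-3, batch 256, 120 epochs by default) on the negative
ELBO with a linear KL warm-up over the first 20% of epochs to avoid
posterior collapse on tabular data. Implementation is pure numpy with
analytic gradients (verified against central finite differences to ~1e-7
relative error) and is exactly reproducible for a fixed seed on a single
thread. Early stopping is deliberately absent: a fixed epoch budget keeps
runs bit-reproducible.

Clustering consumes posterior means, never latent samples, for determinism.
The per-epoch log records the reconstruction term, the KL term and their
weighted sum; the identity `objective = recon + weight·KL` is asserted in
tests.

## Gap-statistic model selection

`W_k = Σ_r (1/(2 n_r)) Σ_{i,i'∈C_r} ‖x_i − x_i'‖²` over ordered pairs —
algebraically the within-cluster sum of squares about the centroids.
`Gap(k) = (1/B) Σ_b log W*_kb − log W_k` with B = 50 reference datasets by
default (B = 20 in the scaled-down tests), drawn uniformly on the
principal-axis-aligned bounding box of the embedded data; the standard
error is the reference-set SD scaled by √(1 + 1/B). Selection maximises the
gap over the (d, k) grid (default d ∈ 2…12, k ∈ 2…10); ties break toward
smaller k, then smaller d. A weak-structure flag is raised when the maximal
gap is within 2 SE of the smallest-k gap. Two caveats are inherent to this
reference model: for isotropic data the principal axes are arbitrary, so
the rotated bounding box overestimates the support and shifts all gaps
upward uniformly (harmless for selection, visible in absolute values); and
for Ward the same linkage tree is cut at every k, which is what makes the
(d, k) sweep affordable.

Internal indices (silhouette, Calinski–Harabasz, Davies–Bouldin) are
attached to the winning solution as descriptive diagnostics only. Cluster
labels are renumbered by ascending observed mortality so that reported
cluster 1 is always the lowest-risk phenotype.

## Stability and external validation

**Weighted Jaccard.** Each cluster of partition A is matched to the cluster
of B maximising |∩|/|∪|; the best overlaps are averaged weighted by cluster
size. This best-match definition is asymmetric; a symmetrised variant
(mean of both directions) is available via `symmetric=True`. For k
equal-size clusters and proportion-preserving random labels the score
concentrates near 1/(2k−1) (tested), which for k = 6 gives ~0.12 — the same
magnitude as published random-assignment baselines.

**Bootstrap protocol.** 100 replicates of an 80% subset without
replacement; the embedding is refitted per replicate by default
(`refit_embedding=False` freezes it for speed). The random null draws
labels i.i.d. with the reference cluster-size proportions. Observed and
null score vectors are compared by the asymptotic two-sample KS test.
A property of this design worth knowing: because each replicate is
compared against the reference partition of the *same* sample, any
deterministic spatial clustering aligns with itself far better than random
labels even on data with no cluster structure at all (isotropic Gaussian
data give observed ~0.22 vs null ~0.13 with KS D ≈ 1). The protocol
therefore certifies *stability*, not the *existence* of structure — the gap
statistic's weak-structure flag covers the latter.

**Leave-one-trial-out.** With (d*, k*) frozen at the full-data selection,
each trial in turn is held out; the pipeline is refitted on the remainder
(including the stratum's scaling parameters), the refit partition is scored
against the full-data partition on shared patients (iteration ARI), and the
held-out trial is scored after nearest-centroid assignment in the fold's
latent space (prediction ARI). Equidistant ties go to the lowest canonical
label. The permutation p compares the observed mean prediction ARI with
label-permuted nulls (1000 permutations by default). Membership prediction
by nearest latent centroid is a design choice; re-clustering plus
Jaccard-matching would be a heavier alternative and is not implemented.

## Treatment effects

Crude 2×2 estimates by intention to treat. OR with Woolf CI
`exp(ln OR ± 1.96·√(Σ 1/cell))`; RR with the log-RR interval; ARR with the
Wald interval; NNT = 1/ARR reported only when the ARR interval excludes
zero (otherwise marked not applicable); p from Pearson χ² without
continuity correction, two-tailed at α = 0.05. A Haldane–Anscombe 0.5 is
added to all cells if and only if some cell is zero; a table with zero
deaths in both arms yields an undefined, flagged OR. Annualised mortality
is deaths per 100 person-years of summed follow-up. Crude ORs reproduce the
published per-cluster ORs from the published counts at two decimals (one
printed value, 0.54, is the truncation of the crude 0.5454 rather than its
rounding). The published risk-ratio column is *not* reproducible from the
printed counts by any standard estimator we tested (e.g. SR-cohort crude RR
0.776 vs printed 0.86) and is excluded from checks; the same applies to the
published annualised-mortality percentages, which need unpublished
person-time.

## Problem sizes in tests and the acceptance script

The shipped experiments are scaled to run on one CPU core in minutes, as
the package's own choice of problem size: planted-recovery runs use ~4000
patients (strong separation 3.5, d fixed at its published value 9, k swept
2…9, B = 20, VAE 60 epochs, 10 seeds); stability uses ~2000 patients with
100 bootstrap replicates; LOTO uses the nine-trial ~4000-patient cohort
with 500 permutations; the generator calibration check uses three million
SR patients (cheap — generation is vectorised). Full-scale runs
(15 659 patients, d ∈ 2…12, B = 50) use the same code paths.

## Known limitations

* The published VAE-vs-PCA comparison (best gap 1.447 vs 0.812 on real
  data) does not reproduce on synthetic data, and the package makes no such
  claim: across every synthetic structure we tried (linear blobs,
  saturating nonlinear maps, covariance-only clusters), PCA's best gap
  matched or exceeded the VAE's. The KL term regularises the aggregate
  posterior toward an isotropic Gaussian — which is essentially the gap
  statistic's null — so a well-trained VAE tends to *lower* the gap unless
  the data hide genuinely nonlinear structure that a linear projection
  destroys. The VAE remains the default embedding for fidelity to the
  analysis design, and its cluster-recovery quality is tested directly via
  ARI against planted labels.
* Real-data quantities that depend on the unavailable IPD (cluster
  demographics, published Jaccard/ARI magnitudes, annualised mortality) are
  emulated only directionally by the synthetic experiments.
* No covariate-adjusted or time-to-event effect models; mortality is the
  only outcome.
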