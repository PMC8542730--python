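# hfphenomap

Phenotype clustering and β-blocker treatment-effect heterogeneity in pooled
heart-failure trial data.

## The problem

β blockers are a cornerstone therapy in heart failure with reduced ejection
fraction (HFrEF), yet their mortality benefit is not uniform: patients in
atrial fibrillation (AF) show no overall benefit, while even in sinus rhythm
(SR) some phenotypes respond poorly. Single-covariate subgroup analysis has
failed to explain this heterogeneity. This package implements an unsupervised
pipeline that discovers multivariate patient phenotypes in pooled randomised
placebo-controlled trial data and estimates the randomised treatment effect
within each phenotype — together with the stability and external-validation
protocols needed to trust unsupervised clusters.

It is written for biostatisticians and ML researchers working with individual
patient data (IPD) meta-analyses. Because real IPD of this kind cannot be
shared, the package ships a calibrated synthetic cohort generator that
emulates a nine-trial pooled HFrEF cohort (15 659 patients, 12 822 SR /
2 837 AF) with planted latent phenotypes carrying cluster-specific treatment
effects, so that every stage of the pipeline is testable end to end.

## The method

1. **Cohort preparation** — exclude LVEF ≥ 50% and paced/uninterpretable
   rhythms, pool atrial flutter with AF, keep complete cases only, stratify
   by baseline ECG rhythm, and encode 13 prespecified baseline variables
   (6 continuous, standardised per stratum; 7 binary, including NYHA III–IV
   and female sex).
2. **Embedding** — a mixed-likelihood variational autoencoder (VAE) with
   per-column likelihoods: Gaussian with learned variance for continuous
   columns, Bernoulli for binary columns. The training objective is the
   evidence lower bound

   ELBO = Σⱼ E_q[log p(xⱼ | z)] − KL(q(z | x) ‖ N(0, I)),

   maximised by Adam with a linear KL warm-up. Clustering uses the
   posterior means E_q[z | x]; a PCA baseline is available behind the same
   interface. (The VAE is implemented in pure numpy with analytic gradients;
   it trains in seconds at p = 13.)
3. **Cluster/model selection** — Ward hierarchical clustering (k-means++ as
   an alternative backend) on the latent coordinates; the latent dimension
   d and cluster count k are chosen by maximising the gap statistic

   Gap(d, k) = (1/B) Σ_b log W*_kb − log W_k,

   with W_k the pooled within-cluster dispersion and W*_kb from B reference
   datasets drawn uniformly on the principal-axis-aligned bounding box.
   Silhouette, Calinski–Harabasz and Davies–Bouldin indices are reported but
   never used for selection. Clusters are numbered by ascending mortality.
4. **Validation** — (a) bootstrap stability: re-embed and re-cluster random
   80% subsets (k = 100 replicates), score each against the reference
   partition with the size-weighted best-match Jaccard overlap, and compare
   with proportion-preserving random labels by a two-sample
   Kolmogorov–Smirnov test; (b) leave-one-trial-out (LOTO): refit on eight
   trials, predict the held-out trial by nearest latent centroid, and score
   agreement with the Adjusted Rand Index against a permutation null.
5. **Treatment effects** — per-cluster intention-to-treat 2×2 tables of
   all-cause mortality: odds ratio with Woolf (log-OR) 95% CI and Pearson
   χ² p, risk ratio, absolute risk reduction (ARR) with Wald CI, number
   needed to treat NNT = 1/ARR (reported only when the ARR interval
   excludes 0), and annualised mortality per 100 person-years.

## Worked example

```python
import hfphenomap as hp

# synthetic nine-trial cohort, ~4000 patients, strongly separated phenotypes
spec = hp.default_cohort_spec(seed=11, separation=3.5, n_scale=4000 / 15659)
cohort = hp.generate_cohort(spec).drop(columns=["true_cluster"])

model = hp.PhenomapModel(
    cohort, stratum="SR", d_grid=[9], k_grid=range(2, 10),
    method="hierarchical", embedding="vae",
    vae_config=hp.VaeConfig(epochs=60), B=20,
)
res = model.fit(seed=1)
res.bootstrap_stability(n_boot=50, seed=2)
res.leave_one_trial_out(seed=3, n_perm=500)
print(res.summary())
```

prints

```
Phenotype clustering of beta-blocker trial cohort
==========================================================
Stratum: SR    patients: 3264
Embedding: vae    clustering: hierarchical
Selected latent dimension d* = 9, clusters k* = 6  (gap = 1.509, B = 20)
Internal indices: silhouette=0.354  Calinski-Harabasz=1615.4  Davies-Bouldin=1.104

Per-cluster all-cause mortality (intention to treat):
cluster  deaths_placebo  n_placebo  deaths_bb  n_bb    or  or_lo  or_hi  p_value    nnt
    SR1              11        135          9   148 0.730  0.293  1.820    0.498    NaN
    SR2              27        253         23   230 0.930  0.517  1.673    0.809    NaN
    SR3              42        340         37   344 0.855  0.535  1.368    0.513    NaN
    SR4              29        179         11   156 0.392  0.189  0.815    0.010 10.929
    SR5              28        207         37   257 1.075  0.633  1.825    0.788    NaN
    SR6             152        498        102   517 0.559  0.419  0.747    0.000  9.265
    all             289       1612        219  1652 0.700  0.578  0.847    0.000 21.407

Bootstrap stability: mean weighted Jaccard 0.814 (SD 0.065) vs random 0.135 (SD 0.002); KS p = 0
LOTO validation: iteration ARI 0.825 (SD 0.033); prediction ARI 0.848 (SD 0.026); permutation p = 0.0020
```

Reading the output: the gap statistic selected six clusters (the number
planted by the generator); clusters are numbered SR1…SR6 by ascending
mortality. Each row is a randomised 2×2 comparison inside one phenotype —
e.g. in cluster SR6, 102/517 patients died on β blockers vs 152/498 on
placebo (OR 0.56, 95% CI 0.42–0.75), and NNT ≈ 9 means one death is averted
per nine patients treated. NaN NNTs mark clusters whose ARR interval
includes zero. The bootstrap Jaccard far above its random-assignment null
and the LOTO prediction ARI of 0.85 (permutation p = 0.002) say the
partition is stable under resampling and transports across trials.

A thin CLI wraps the same library (`hfphenomap simulate / prepare / select /
cluster / validate / effects / report`), configured by a YAML `RunConfig`;
`hfphenomap report --config run.yaml` writes effect tables, radar-plot
figures per cluster, stability/LOTO summaries and a reproducibility
manifest.

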