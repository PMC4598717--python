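# plastimap

Desk-scale analysis of **tutoring-induced neural normalization** in
mathematical learning disability (MLD), built around a fully synthetic
cohort generator.

Children with MLD over-engage a distributed set of prefrontal, parietal and
ventral temporal–occipital regions during arithmetic problem solving.
After an intensive 1:1 tutoring intervention, three questions arise:

1. **Do activation levels normalize?** Voxelwise group *t*-tests
   (MLD vs typically developing, TD, at each session) with
   family-wise-error correction at the cluster level via Monte-Carlo
   simulation: null fields smoothed to the data's estimated FWHM are
   thresholded at voxel height *p* < 0.01, and a cluster survives only if
   its extent exceeds the null's max-cluster-size α = 0.01 quantile
   (*k*min). A robust Bayesian two-group model (Student-*t* likelihoods,
   95% highest-density intervals) quantifies how large any remaining
   post-tutoring difference could credibly be.
2. **Do activation *patterns* normalize?** Multivariate pattern
   classification: *t*-maps are masked with the pre-tutoring
   group-difference regions, *z*-transformed per subject (so group
   differences are independent of overall activity level), and fed to a
   linear SVM under leave-one-out cross-validation (LOOCV). Significance
   comes from a permutation null: labels are reshuffled and the full LOOCV
   is recomputed, *p* = (1 + #{null ≥ observed}) / (1 + n_perm).
   Normalization = discriminable before tutoring, chance after.
3. **Does more brain change mean more improvement?** The **Brain
   Plasticity Index**, BPI = 1 − *r*(pre, post), the in-mask spatial
   correlation between a child's *z*-transformed pre- and post-tutoring
   patterns subtracted from 1, correlated with each child's accuracy gain
   (post − pre proportion correct).

Because the underlying study deposited no raw data, every analysis here is
exercised on a **synthetic cohort generator** that emulates the design:
2 groups × 15 children × 2 sessions, 2 runs/session, 12 Addition + 12
Control trials per run (TR = 2 s, 9.5 s trial window, six jittered 10 s
rests), group overactivation in designated aberrant regions that shrinks
post-tutoring by a per-subject retention factor, and a latent normalization
magnitude coupled to the accuracy gain. The generator stores its ground
truth, so every stage has a recovery oracle. The package also includes the
study's supporting machinery: event-related GLM with a canonical
double-gamma HRF and temporal derivative, AFNI-style volume despiking
(displacement > 1.562 mm or global-signal excursions > 5% repaired by
interpolation), and the behavioural statistics (two-sided *t*-tests with
Cohen's *d* = *t*/√n paired or *t*·√(1/n₁+1/n₂) independent, Lilliefors
normality checks, Pearson correlations).

## Worked example

```bash
python examples/04_mvpa_normalization.py
```

```
group-difference mask: 2936 voxels
 pre-tutoring: LOOCV accuracy 96.7%, permutation p = 0.001
post-tutoring: LOOCV accuracy 33.3%, permutation p = 0.914

(accuracy near 50% with p > 0.05 means the groups are
indistinguishable — the normalization signature)
```

Before tutoring the synthetic MLD children's masked activation patterns are
almost perfectly separable from their TD peers' (29/30 correct, a result
seen once per thousand label shuffles); after tutoring the classifier does
no better than coin flipping — the groups' patterns have converged. The
other examples (`examples/01…06`) walk through cohort generation,
behavioural scoring, cluster-corrected group maps, the BPI–gain
correlation, and Bayesian group estimation, each printing a few annotated
numbers.

A thin CLI wraps the same library calls:

```bash
plastimap simulate --out cohort/ --seed 7
plastimap run-all --out results/ --seed 7
```

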