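# Methods

`teasl` is a synthetic-data re-implementation of a perfusion-MRI analysis
chain: Hadamard time-encoded pseudo-continuous ASL (te-ASL) is decoded into
per-sub-bolus perfusion-weighted signals, fitted with the single-compartment
kinetic model to give CBF and ATT maps, compared head-to-head with the
consensus single-PLD quantification derived from the same acquisition, and
fed into the covariate-adjusted group statistics used to ask whether CBF
reductions are detectable in cognitively unimpaired amyloid-positive
individuals. No real data ship with the package; a digital phantom cohort
generator provides ground truth against which every stage is validated.

## Acquisition model

The simulated protocol uses seven labeling sub-boluses played back to back
(durations 1800/600/400/300/200/150/150 ms, earliest first) with chained
effective post-labeling delays 2000/1400/1000/700/500/350/200 ms, a 3600 ms
total label train, and an order-8 Sylvester-Hadamard encoding (+1 control,
−1 label; column 0 static). Decoding multiplies the acquisition vector by a
matrix column and scales by `2/order`, so one decoded value equals one
control-minus-label difference ΔM. Independent acquisition noise of SD σ
propagates to decoded SD `σ·√order·(2/order)` = σ/√2 at order 8; the codec
round-trip is exact to machine precision.

The longest sub-bolus (1800 ms, PLD 2000 ms) is the "perfusion block"; its
decoded ΔM alone, quantified with the consensus single-PLD formula, is the
single-PLD comparison arm. The single-PLD difference is taken from the
decoded block rather than a raw acquisition pair: the construction of a
two-acquisition subtraction from Hadamard-encoded volumes is ambiguous, and
the decoded block has the same expectation (its noise differs from a true
pairwise subtraction; the comparison is therefore of estimators applied to
identical inputs).

## Kinetic model

The forward model is the standard single-compartment (Buxton) pCASL kinetic
model with plug flow: for label duration `ld`, arrival at `att`, perfusion
`f = CBF/6000` s⁻¹,

    ΔM(t) = 0                                                   t < att
    ΔM(t) = A · (1 − e^{−(t−att)/T1'})                          att ≤ t < att+ld
    ΔM(t) = A · (1 − e^{−ld/T1'}) · e^{−(t−att−ld)/T1'}          t ≥ att+ld

with `A = 2 α_eff (M0/λ) f T1' e^{−att/T1b}` and the apparent relaxation
`1/T1' = 1/T1_tissue + f/λ`. Defaults follow the ASL consensus values:
T1_blood 1.65 s, T1_tissue 1.3 s, λ = 0.9 mL/g, α = 0.85; background
suppression is a single multiplicative efficiency (default 1, i.e. ideal)
because no pulse timings are modeled. Both the simulator and the te-ASL
fitter use the full `T1'` (including the `f/λ` term), so te-ASL fitting is a
matched-model estimator; the single-PLD formula keeps the consensus
blood-T1-only decay,

    CBF = 6000 λ ΔM e^{PLD/T1b} / (2 α_eff T1b M0 (1 − e^{−ld/T1b})),

and the divergence between the two decay assumptions plus the unknown ATT is
exactly the mechanism the method comparison probes. The single-PLD formula
inverts the kinetic model exactly only in the matched-decay limit
`T1' = T1b` (i.e. tissue T1 = 1/(1/T1b − f/λ)) with att ≤ PLD; setting
tissue T1 merely *equal* to blood T1 leaves a residual ≈2–3 % error at
CBF = 60 because of the `f/λ` term. Tests use the matched-`T1'`
construction.

## CBF/ATT estimation

Per voxel the estimator is bounded least squares over CBF ∈ [0, 300]
mL/100g/min and ATT ∈ [0.1, 3.0] s against the seven decoded sub-bolus
signals. Rather than generic per-voxel NLS iterations, the implementation
profiles CBF out: at fixed ATT the model is linear in CBF up to the weak
`f/λ` dependence of `T1'`, so the optimal CBF follows from a fixed-point
linear projection (a few iterations); ATT is then minimized on a 0.1 s grid
followed by golden-section refinement of the profiled residual. This is
deterministic, has no starting-value sensitivity, vectorizes across voxels
(which is what makes the replicated Monte-Carlo studies feasible), and on
noiseless data recovers CBF and ATT to ~1e−6 relative error across a
20–100 CBF × 0.5–2.0 s ATT grid.

Degenerate geometry matters at late arrival: once ATT reaches the
second-longest readout (2.0 s here), only the perfusion block carries
signal, and any (CBF′, ATT′ ≥ 2.0) pair on a zero-residual ridge fits the
data. Near-ties are broken toward the smallest ATT, pinning the ridge at
its physical lower edge — a minimal-transit-time convention, conservative in
the same direction as the variational-Bayes shrinkage priors of the toolbox
the study itself used. That toolbox's spatial priors are deliberately not
reproduced (its exact settings are unreported); the substitution is a known
fidelity gap, adequate here because all validation is against synthetic
ground truth.

All-zero inputs return CBF = 0 with ATT at the lower bound and a degenerate
flag. The estimator is unbiased to within 1 % of CBF at per-sample SNR ≳ 5;
at very low SNR the CBF ≥ 0 bound induces the usual positive truncation
bias.

## Phantom and cohort generator

The phantom is a labeled voxel grid (default 32×32×20 at 2.29×2.29×6 mm,
matching the acquisition resolution; a 12×12×6 variant runs the Monte-Carlo
studies) with white matter, cortical gray matter, a cerebellar gray-matter
reference region, and an "AD-vulnerable" gray-matter mask of an exact voxel
count standing in for the temporo-parietal/hippocampal a-priori mask.
Baselines: GM CBF 50, WM CBF 20 mL/100g/min; GM ATT 1.3 s, WM 1.6 s,
cerebellum 0.8 s; M0 1000/700 a.u. Geometry is boxes plus a
nearest-to-center mask — anatomy is irrelevant to the statistics being
validated, and all subjects share one grid, so template registration is out
of scope by construction.

A cohort draws three groups (CU Aβ−, CU Aβ+, CI Aβ+; n = 24/18/17) with the
study's age and sex distributions (67.4 (4.2) / 66.1 (2.9) / 73.1 (6.5)
years; 66.7/83.3/47.1 % female). Group CBF effects inside the AD mask
default to the reported adjusted reductions, −8.55 % (CU Aβ+) and −18.03 %
(CI Aβ+); a tau-stage split (52.9 % of CU Aβ+ T-positive) with
stage-specific effects supports the A/T-stage trend analysis.
Between-subject variability has two parts: a global multiplicative scale
(CV 0.10) that cerebellar normalization removes, and an AD-mask-specific
regional component (CV 0.08) that it cannot. The regional value is set so
that the *total* dispersion of normalized ROI values — biology plus ATT
effects plus acquisition noise — is ≈10 %, the level the study's reported
confidence intervals imply; assigning the full 10 % to biology alone would
double-count the simulated measurement variance.

Subject ATT follows `1.3 + 0.01·(age−70) + 0.10·male + ε` s (positive age
slope and higher male ATT, as the voxelwise covariate analysis reports), or
a Uniform(0.8, 2.2) s draw in the sensitivity experiments, which is the ATT
heterogeneity condition those experiments are defined under. The cerebellar
region receives an independent per-subject offset (SD 0.15 s): transit
through the posterior circulation does not track cortical transit, so ATT
effects do not artificially cancel in the normalization. Voxel-level ATT
jitter (SD 0.25 s in the sensitivity study) represents intracerebral
transit-time spread.

Acquisition noise is i.i.d. Gaussian per encoded volume with SD 2 a.u.
against M0 = 1000 a.u. — the effective noise of the *averaged* series (the
5.5-minute scan accommodates roughly nine Hadamard cycles; raw volume noise
≈0.6 % of M0), giving per-voxel decoded ΔM SNR ≈ 4, consistent with usable
single-subject maps. The paper reports no noise level; this is a package
choice.

What the generator does **not** emulate: realistic anatomy and partial
volume, motion and physiological noise, background-suppression pulse
timing, dispersion of the labeled bolus, macrovascular signal, and any
registration step. Passing tests therefore demonstrate correctness of the
decoding/fitting/statistics chain under the stated generative model, not
robustness to those real-data effects.

## Biomarker generator

Each biomarker is `μ(subject) + b·z + e`, where `z` is the standardized
residual of true AD-mask CBF on age and sex within the CU sample; `b` and
the noise variance are calibrated analytically so the population partial
correlation (age and sex regressed out) equals the target — the reported CU
associations (Aβ42/40 +0.53, Centiloid −0.41, pTau181/217/231/235 −0.43/
−0.49/−0.45/−0.51, GAP43 −0.46, neurogranin −0.47, SNAP25 −0.42,
synaptotagmin-1 −0.36, NfL −0.45; imaging/cognition covariates ≈0). The
calibration subtracts the covariance contributed by group-mean structure,
so group-defining markers (Aβ42/40, Centiloid, pTau181 with Table-1-style
group/stage means) still hit their pooled targets; their marginal SDs are
set slightly above the values the group separation alone would imply so the
residual variance stays positive. Values of group-defining markers are kept
on their group's side of the positivity thresholds (Aβ42/40 ≤ 0.071;
pTau181 > 24 pg/mL in CU, > 69.9 pg/mL in CI) — rare 3σ stragglers are
clipped. CI-group biomarkers carry no CBF link (they are excluded from the
correlation analysis, mirroring the study's data availability).

## Statistical layer

* **Adjusted percent change.** OLS of the ROI value on group (treatment
  coding), age, and sex; percent change is `100·β_g / (adjusted reference
  mean at covariate grand means)`; the 95 % CI scales the contrast SE by
  the same reference mean, ignoring the reference mean's own uncertainty
  (the study does not state its CI construction; this simplest choice gives
  94–97 % empirical coverage in the recovery experiments).
* **Voxelwise GLM.** Per-voxel OLS with [intercept, group dummies, age,
  sex]; one-sided reduction contrasts (matching the directional hypothesis);
  cluster-extent thresholding at p < 0.001 uncorrected, k ≥ 100 voxels,
  with 18-neighbour connectivity (the common SPM convention). Voxels whose
  residual variance is pure round-off get t = 0.
* **Partial Pearson.** Both variables residualized on [1, age, sex];
  p from `t = r·√((n−2−k)/(1−r²))` with k the number of covariates — the
  dof adjustment avoids anti-conservative p after residualization.
* **BH-FDR** via the statsmodels step-up implementation (verified against a
  brute-force implementation of the definition).
* **Outliers**: one pass, per variable, |value − mean| > 3 SD on the full
  sample, before each test; not iterated.
* **Chi-square** for 2×2 tables without continuity correction (this
  reproduces the reported p = 0.024 for the female proportions; Yates'
  correction would not).

## Replicated experiments and problem sizes

* *Effect recovery*: 500 cohorts at n = 24/18/17; the adjusted contrast on
  true-mask CBF recovers the injected −8.55 %/−18.03 % within ±2 points in
  the mean with CI coverage inside [90, 98] %. The imaging stages are
  validated separately by exact noiseless end-to-end recovery, so this
  experiment replicates the statistics layer at full speed.
* *Sensitivity comparison*: 200 cohorts; per subject the full image chain
  runs on the reduced phantom (encode → noise → decode → te fit /
  white-paper single-PLD → cerebellar normalization → ROI mean), then the
  CU Aβ+ vs CU Aβ− adjusted contrast is tested at α = 0.05 on both methods'
  values. Under Uniform(0.8, 2.2) s subject ATT the te-ASL rejection rate
  exceeds the single-PLD rate by ≈7 points (measured 0.740 vs 0.668 over
  400 cohorts at these conditions) — the qualitative pattern of the study,
  where the CU Aβ+ reduction was significant with te-ASL but not with
  single-PLD ASL. The gap is modest because a 2000 ms PLD protects
  single-PLD until ATT approaches it; only the late-ATT tail and the
  independent cerebellar transit variation degrade it.
* *Biomarker recovery*: 30 cohorts at study size (±0.15 tolerance on the
  mean partial r) and 4 cohorts at n = 1000 (±0.05).

## Known limitations

Per-voxel profile least squares replaces spatially regularized Bayesian
fitting; CBF/ATT are unidentifiable at ATT beyond the second-longest
readout and resolved by a smallest-ATT convention; the single-PLD arm is a
decoded-block estimator, not a literal two-acquisition subtraction; phantom
geometry is schematic; biomarkers are conditionally Gaussian (the partial
Pearson correlation is the estimand, so heavier tails are out of scope);
and no spatial normalization, partial-volume correction, or motion is
modeled.
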