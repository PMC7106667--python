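# Methods

## The problem

NIRS age-grading treats each mosquito's absorbance spectrum — log10(1/R)
over 700–2350 nm — as a high-dimensional predictor of its calendar age in
days, or of a binary young/old status at the 8-day extrinsic-incubation
boundary. The package implements the calibration procedures, their model
selection rules, the classification machinery and the spectral diagnostics
needed to study both the within-population accuracy of such models and
their failure to transfer across rearing environments.

## Partial least squares core

The regression engine is NIPALS PLS1. Spectra columns are mean-centred but
not variance-scaled (all channels share absorbance units; autoscaling is
available behind a flag but off by default). For a single response the
NIPALS weight per component is computed directly as w ∝ Xᵀy on the deflated
matrix — no inner iteration — so fitting is fully deterministic:
identical inputs give bit-identical models. Components are extracted by
deflation X ← X − tpᵀ, y ← y − qt, and the coefficient function
b = W(PᵀW)⁻¹q is stored alongside the factors. Since PᵀW is triangular,
the coefficient (and score) vectors of every truncated model K′ < K are
nested inside one K-component fit; the cross-validation loops exploit this
to score a whole component grid from a single deflation per fit.

Degenerate inputs: the component loop aborts with "rank exhausted" when
the weight norm falls below 1e-12 of the first component's — requesting
more components than the centred matrix's rank is an error, not silently
truncated. Predicted ages are never clipped: negative or >15-day
predictions are reported as-is, because clipping would bias RMSD.

## Model selection

*Standard PLS* mirrors classical chemometrics practice: leave-one-out
cross-validation over K = 1..Kmax, then the smallest K whose LOOCV RMSD is
within a relative tolerance (default 2%) of the curve minimum. The
traditional choice is made by eye; the 2% rule is our algorithmic
replacement and the tolerance is exposed as a parameter.

*Resampling PLS* draws R = 100 random splits into 50% train / 25%
validation / 25% test. Splits are stratified by age group by default
(every group present in all three partitions; an unstratified mode exists
for sensitivity analysis); within a stratum of size m, validation and test
each take ⌊m/4⌋ samples and the remainder trains. The component count is
chosen once — the smallest K whose mean validation RMSD across
randomisations is within 0.5 days of the best — and used in all R models.
Each sample's reported prediction is the mean of its predictions from the
randomisations where it fell in the *test* partition only, keeping the
estimate blinded; the overall RMSD is computed on these averaged
predictions. All R coefficient functions and their mean are retained for
inspection.

Transfer evaluation applies either the single standard-PLS model or the
mean prediction of the R resampling models to a second population on the
identical channel grid, and emits the same per-group summary (mean
predicted age, SEM, % classed old) used within-population.

## Classification

Direct young/old classification replaces the regression response with the
centred 0/1 class: PLS scores are extracted against it, and a binomial
logistic regression (IRLS, 25 iterations, coefficient norm capped at 10³ so
perfectly separable partitions still yield a finite, rank-preserving linear
predictor) maps the K training scores to η(x) = α + scores(x)ᵀβ. The
component count is again chosen once, from the mean validation AUC curve:
the smallest K within 0.01 of the best. Per randomisation, the cut-point τ
minimising misclassification over all midpoints of consecutive sorted η
values (ties broken by maximal tpr+tnr, then smallest τ) is estimated on
the *validation* partition — the test partition stays blinded. Final
calls compare each sample's test-averaged η̄ to the average cut-point, with
η̄ ≥ τ̄ read as old. ROC curves sweep all distinct η values; AUC is the
trapezoidal area and equals Mann–Whitney pairwise concordance with ties
counted ½ (asserted in tests against a brute-force oracle and
scikit-learn). Per-randomisation test AUCs are summarised at the
5/15/25/50/75/85/95 percentiles.

One terminological note: sensitivity is tp/(tp+fn) (true-positive rate,
"old" positive) and specificity tn/(tn+fp) throughout. Some published
figure captions in this literature label fnr as "specificity"; we follow
the standard definitions.

## PCA and outlier screening

PCA operates on the same pre-processed absorbance matrix fed to PLS
(configurable), via SVD of the column-centred matrix; explained fractions
are σ²ₖ over the total. The Hotelling statistic of sample i is
T²ᵢ = Σₖ t²ᵢₖ/λₖ over the A retained components (λₖ the score variances,
i.e. the squared Mahalanobis distance in score space), with the 95% limit
A(n−1)/(n−A)·F₀.₉₅(A, n−A). A defaults to 4. Screening is single-pass:
flagged samples are removed once, with no re-fit-and-repeat, since
iterating the screen can cascade. The limit converges to the χ²₀.₉₅(A)
quantile as n grows (verified numerically), and on clean Gaussian data the
flag rate sits near the nominal 5%.

## The synthetic-data generator

No public spectral dataset exists for this problem, so the generator is a
first-class, tested module encoding the study conditions: a laboratory
cohort aged 2/5/8/12/15 days (41/42/42/42/44 mosquitoes) and a
field-derived cohort aged 1/7/14 days (50/50/100), on a 350–2498 nm grid
at 3 nm spacing (717 channels).

Each spectrum is a superposition of Gaussian absorbance bands plus a random
additive offset, a random linear scatter ramp across the window, and iid
channel noise (sd 0.01 absorbance). Band amplitudes are linear in age.
Defaults:

| band | centre | width (sd) | base | age slope /day | role |
|------|--------|-----------|------|----------------|------|
| C-H overtone | 1170 nm | 30 nm | 0.12 | +0.0045 | age signal, jitter sd 0.025 |
| C-H overtone | 1400 nm | 40 nm | 0.15 | +0.0055 | age signal, jitter sd 0.025 |
| water | 1450 nm | 35 nm | 0.45 | −0.006 | hydration, +0.03 in field |
| water | 1930 nm | 45 nm | 0.55 | −0.007 | hydration, +0.04 in field |

The negative water slopes encode that younger insects are wetter. The two
water bands share a per-sample hydration factor with cohort-dependent
spread: sd 0.008 (laboratory) vs 0.15 (field). This single asymmetry *is*
the domain shift: in the laboratory, water tracks age tightly and is the
most precise age channel, so a laboratory-trained model loads on it; in
field material hydration is erratic, which both relocates (via the mean
excess) and re-ranks (via the spread) the model's predictions. A purely
additive cohort offset could shift predictions but never degrade AUC,
since ranking is invariant to monotone shifts — per-sample variability is
required for the transfer failure to appear in both RMSD and AUC, which is
exactly the observed phenomenon. The magnitudes were chosen so that the
within-cohort age signal survives (within-lab RMSD ≈ 1.4 days against a
4.7-day baseline, within-field ≈ 2.8 days) while the lab→field transfer
collapses (RMSD ratio ≈ 10, AUC drop ≈ 0.25–0.3), robustly across seeds.

What the generator does **not** model: Beer–Lambert radiative physics,
reflectance probe geometry, real cuticular chemistry (band positions and
linear-in-age amplitudes are stylised), instrument drift, or
non-Gaussian band shapes. Passing tests therefore demonstrate that the
*procedures* behave correctly and that the transfer-failure mechanism is
reproduced structurally — not that real mosquito spectra have these effect
sizes.

## Numerical and design choices

- Absorbance uses log base 10 (spectroscopy convention).
- The analysis window [700, 2350] nm is closed on both ends.
- SNV uses the sample (n−1) standard deviation; detrend-SNV applies SNV
  first, then subtracts a degree-2 (default) least-squares polynomial in
  wavelength; Savitzky–Golay defaults to window 17 channels (≈51 nm),
  polynomial order 3, derivative 2, with edge channels dropped rather than
  padded (no fabricated boundary data). Pre-treatments are mutually
  exclusive options, applied to raw absorbance.
- Splits, simulations and all stochastic steps flow from explicit integer
  seeds; reported results carry the seed and a config hash.
- Problem sizes in the test-suite and acceptance script: the full default
  designs (211 lab + 200 field samples, 550 channels after trimming),
  R = 100 randomisations for the headline runs and R = 15–25 in unit tests,
  Kmax = 20.

## Known limitations

- Resampling PLS stores all R fitted models; for very large R or channel
  counts this is memory-proportional to R·p.
- The IRLS coefficient cap keeps separable fits finite but means reported
  logistic coefficients are not MLEs under perfect separation (the linear
  predictor ordering, which is what classification uses, is unaffected).
- The standard-PLS LOOCV loop refits n models per component grid and is
  O(n²p·Kmax); fine for hundreds of samples, slow for thousands.
- Group SEM is reported as NaN for singleton groups.
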