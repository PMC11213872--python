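# Methods

This note documents the models and procedures `xenomet` implements, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## Scope and data model

The pipeline starts at an aligned feature table — peak areas for samples ×
features, with sample metadata (role: pooled QC / study / solvent control /
medium control, group, timepoint, replicate pairing, injection order) and
feature metadata (m/z, retention time, preferred ion, polarity, optional
per-sample vendor peak rating). Raw spectral peak picking and retention-time
alignment are out of scope; the vendor "peak rating" is treated as supplied
metadata because no public definition of it exists.

Positive- and negative-mode features live in one table distinguished by a
polarity column; no cross-polarity deduplication is attempted.

## Exact-mass arithmetic

Monoisotopic masses use CODATA/IUPAC values for {C, H, N, O, S, P, Cl, Na,
K}. Ion m/z is computed as

    m/z = (M + Δ_adduct − z·m_e) / |z|

with the electron mass always included; at 3 decimals the correction is
invisible, but 4-decimal fragment work requires it. The ten supported adducts
([M+H]+, [M+NH4]+, [M+Na]+, [M+K]+, [M+MeCN+H]+, [M+Cl]−, [M+MeOH+H]+,
[M+H−H2O]+, [M+H−NH3]+, [M−H]−) are a data table, extensible without code
changes.

Biotransformation screening is formula algebra only: a transformation is an
(atoms added, atoms removed) delta, and products are enumerated breadth-first
to a default chain depth of 2, deduplicated by formula (positional isomers
are separated downstream by retention time, never here). The default reaction
set — demethylation (−CH2), desaturation (−H2), oxidation (+O), di-oxidation
(+2O), reduction (+H2), hydration (+H2O), two composite deamination-to-acid
deltas (−NH+O and −N+H+O, ring-opening surrogates for keto and hydroxy
acids), glycine conjugation (+C2H3NO) and acetylation (+C2H2O) — covers the
reaction classes reported for pyridine-alkaloid metabolism. Matching against
observed features uses a signed ppm error, 5 ppm tolerance by default, and
returns every (candidate, ion, feature) pair within tolerance.

## Feature-table processing

Stage order and defaults:

1. **Peak-rating filter** — keep features rated strictly above 5 (scale of
   10) in ≥ 5 samples ("above" read as strict; the RSD "maximum allowed"
   bounds below read as inclusive — literal wording of the source settings).
2. **Missing-value imputation** — missForest-style: per sweep, each feature
   with missing entries is regressed (random forest, 100 trees, mtry = √p,
   10 most-correlated predictor features) on the others and its missing
   entries re-predicted; sweeps stop at 10 or when the relative change in
   imputed values increases. Imputation runs on the log scale because
   intensities are log-normal and censoring is intensity-dependent. Observed
   entries are never modified; features > 50% missing are flagged,
   all-missing features are rejected.
3. **QC drift correction (SERRF-style)** — per feature, a 200-tree random
   forest regresses the QC-pool intensities on injection order plus the 10
   most QC-correlated other features (samples as one batch); the fitted
   drift is interpolated at every injection order with a monotone piecewise
   cubic (PCHIP) and intensities are divided by it, rescaled so the QC
   median of every corrected feature is preserved exactly.

   *Overfitting guard.* A forest fitted to ~10 QC points interpolates
   analytical noise, and its out-of-bag score cannot detect this here
   because the correlated predictors were themselves selected on the same QC
   data. A feature is therefore corrected only when (a) its QC intensities
   show a Spearman rank association with injection order at α = 0.01 — a
   selection-free test, so ~1% of drift-free features are falsely corrected
   — and (b) the forest beats the mean out-of-bag. Limitation: drift with
   zero net monotone trend across the run is left uncorrected; the RSD
   filter then removes such features, which is the safe failure mode.
4. **RSD filter** — drop features with QC RSD (100·sd/mean over QC
   injections) > 50% before correction or > 25% after.
5. **Usable-hits filter** — keep features detected, before imputation, in
   ≥ 80% of the samples of at least one group × timepoint cell. The
   detection mask is the pre-imputation one; whether the original workflow
   applied this pre- or post-imputation is unstated, and pre-imputation is
   the conservative reading.
6. **Median normalization** — every sample is scaled so its median feature
   area equals the maximum of the per-sample medians ("maximum peak-area
   median" read as max-of-medians; a median-of-medians reference is
   selectable). Blank/solvent/medium controls are excluded from the
   reference pool but still scaled; they take no part in any statistics.
7. **Log + Pareto** — natural log, then per-feature centering and division
   by √sd. Features constant after the log are dropped with a warning.
   After scaling, each feature's variance equals its pre-scaling sd, which
   the tests assert.

## OPLS-DA

`OplsDa(X, y).fit()` implements orthogonal signal correction for a single
binary response: predictive weights w ∝ X'y; each orthogonal component
removes from X the part of the loading p orthogonal to w; exactly one
predictive component remains, as in the standard O-PLS formulation. Reported
statistics: cumulative R2X, R2Y, and 7-fold cross-validated Q2.

* **Folds** are contiguous blocks of a seeded permutation (the fold scheme of
  the original software is proprietary; the seed is logged).
* **Orthogonal components** are added while each raises Q2 by > 0.01, capped
  at 3 — chosen to reproduce the "1 + 1"/"1 + 2" component patterns of
  typical reports qualitatively; exact auto-fit rules of commercial software
  are proprietary, so component counts on real data may differ.
* **VIP** over the single predictive component reduces to √p·|w_j| (unit-norm
  w), so mean(VIP²) = 1 identically — asserted for every fit.
* **p(corr)** is the Pearson correlation of each processed feature with the
  predictive score vector t, clipped to [−1, 1]; zero-variance features get
  0.
* **CV-ANOVA**: F = ((SS_tot − PRESS)/A) / (PRESS/(N−1−A)) with A = 1 + K
  components, p from the F(A, N−1−A) tail. Models with PRESS ≥ SS_tot get
  p = 1. *Known property:* this test is conservative — under the null the
  cross-validated predictions are worse than the class mean, so the
  rejection rate at α = 0.05 is far below 5% at small n (measured ≈ 0/400
  at n = 8). It buys a very low false-model rate at the price of power;
  the validation suite documents this rather than recalibrating the test.

Discriminant features are the intersection of VIP ≥ 1.5, |p(corr)| ≥ 0.50
and paired-t p ≤ 0.05, computed only when the model itself passes CV-ANOVA at
0.05, sorted by descending VIP. No multiple-testing correction is applied by
default — the triple criterion is the filter; Benjamini–Hochberg is available
as an option. The paired t-test runs on processed (log-scale) values; the
direction of change (↑/↓) is read from normalized pre-log areas so the arrows
carry relative-concentration semantics. Metabolite-ratio tests (e.g.
arginine/ornithine) are paired t-tests on per-sample log ratios of normalized
areas, which makes them invariant to any global sample scaling.

## MS2 similarity and molecular networking

Spectra are read and written as MGF and NIST-style .msp text (round-trip
tested). The similarity score is a modified cosine scaled to 0–100: fragment
pairs match within 2.5 mmu either directly or after shifting by the
precursor mass difference, accepted greedily in descending intensity-product
order with one-to-one use and first-come tie-breaking. "Coverage" is
interpreted as the percentage of total fragment intensity of the less
intense spectrum explained by matched peaks — the vendor's exact definitions
of its score and coverage are not public, so the numeric thresholds (score
≥ 50, ≥ 3 matched fragments, coverage ≥ 70) are honored on this documented
scale. Nodes without a qualifying edge stay in the network as singletons;
the edge set is independent of input order, and tightening any threshold
can only remove edges (asserted).

Network nodes matching a theoretical biotransformation product within 5 ppm
are labelled with its formula and chain; edges whose precursor shift matches
a transformation delta within 5 mDa are labelled with the reaction name.

## Annotation levels

Evidence types accumulate independently per library candidate: accurate m/z
(5 ppm), retention time (±0.2 min), MS2 similarity (≥ 85). Levels follow the
Metabolomics Standards Initiative convention: level 1 needs ≥ 2 orthogonal
properties against an authentic in-house standard; level 2 is an MS2-only
match; level 3 a class label only (class prediction itself is out of scope
and accepted as an input column); level 4 unknown. An isotope check
(observed M+1/M against 1.07% per carbon, ±20% relative) counts as
supporting, not orthogonal, evidence — no published tolerance exists, so it
never changes a level on its own. Verification against an authentic
standard's spectrum demotes a refuted annotation to level 3/4 and flags it.

The bundled ~40-entry demo library (parent-alkaloid series plus common polar
metabolites) carries synthetic reference spectra generated deterministically
per compound name; they are stand-ins that exercise the matching machinery
and carry no measured fragment information.

## Synthetic-study generator

The generator emits the stated design: 2 groups × 2 timepoints × 4 paired
replicates, a 6-injection QC lead-in then a QC every 8th injection plus a
closing QC, and 3 + 3 solvent/medium controls. Defaults chosen as realistic
for cell-extract HILIC work where unstated: log-normal baselines (ln-sd 1.5
across features), 25% biological CV, 6% analytical CV, multiplicative
injection-order drift (amplitude 0 by default; 0.5 spans factor 0.5→1.5),
logistic intensity censoring at the 5% baseline quantile (≈12% missing
entries overall at the defaults — verified ±2% at 10,000 features;
`censor_quantile=0` disables censoring), and a saturating peak-rating model
calibrated so low-intensity features fail the rating filter at roughly the
attrition scale seen in real studies. Differential effects are injected on
the log scale *before* drift, so drift correction and differential analysis
remain separable failure modes.

The spiked biotransformation series has 17 products (one feature each, at
exact theoretical [M+H]+ m/z, exposed samples only; repeated formulas model
positional isomers at distinct retention times; the lactam product dominates
the abundance profile). Their MS2 spectra share ≥ 60% of scaffold fragments
shifted by the product−parent mass difference, so networking can recover the
family; decoys get unrelated fragment sets.

What a green synthetic test does **not** establish: real peak ratings,
matrix effects, correlated censoring, retention-time drift, chimeric MS2
spectra and real fragmentation chemistry are all absent, so recovery rates
here are upper bounds on real-data performance, and component counts or Q2
values from real studies are not expected to be reproduced numerically.

## Numerical and degenerate-input policies

Zero-variance differences in a paired t-test return p = 1 (zero mean) or a
p-underflow floor of 1e-300 (nonzero mean). Zero-variance features get
p(corr) = 0. A sample with non-positive median area rejects normalization by
name; non-positive entries reject the log transform with a count. Constant
QC features pass through drift correction unchanged. Seeds: every stochastic
step (generator, imputation, forest fits, fold assignment) takes an explicit
seed and is bit-reproducible; per-feature forest seeds derive from one
generator so results do not depend on feature iteration order.
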