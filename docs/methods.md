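# Methods

## The study design being modelled

A 2 × 2 crossover: 16 lactating does each experience thermoneutral (TN)
and heat-stress (HS) conditions in successive periods, half in each order,
giving 32 urine samples. The crossover makes every animal its own control,
which the univariate screen exploits through paired within-animal
differences; the multivariate model ignores pairing and classifies samples
by treatment, as is conventional for PLS-DA.

## Synthetic spectra

The generator emulates processed (Fourier-transformed, phased, referenced)
600-MHz ¹H spectra, not free-induction decays: acquisition physics, solvent
suppression and phasing are out of scope. Each spectrum is a sum of
Lorentzian peaks (the natural lineshape after exponential apodization; a
Gaussian option exists behind `SimConfig.lineshape`) over a descending ppm
axis, 32,768 points from 9.5 to −0.5 ppm by default — wide enough to cover
the analysed 9.0–0.5 ppm window with margin.

Concentration model for metabolite *m* in sample *i* (animal *a*,
treatment *g*):

    c[i,m] = base[m] · animal[a,m] · effect[m]^[g = HS] · dilution[i]

* `animal` — log-normal, sd 0.15 (log scale). The crossover pairing must
  have between-animal variance to remove; the study reports none for urine
  metabolites, so this is a plausible default, not an estimate.
* `dilution` — log-normal, sd 0.3: urinary dilution varies severalfold
  between micturitions. Creatinine carries *only* this factor (base 5×
  the unit metabolite baseline, as the dominant urine resonance), so
  reference normalization cancels dilution exactly.
* `effect` — HS/TN concentration ratios; the default map injects the
  fifteen candidate-biomarker fold changes (hippurate 2.74 down to
  histamine 1/2.64), under-excreted metabolites as reciprocals.
* Chemical-shift jitter: N(0, 0.003 ppm) per sample × metabolite,
  mimicking pH/ionic-strength sensitivity; it stays well under the
  ~0.007 ppm bin width, which is the point of binning.
* A smooth background (four broad Gaussian humps + pedestal, one shape per
  cohort, amplitude 0.1 × the median peak height) scaled by dilution. Real
  urine spectra have signal nearly everywhere; without a background, empty
  bins sit at the log₂ floor and their flooring noise dominates the
  feature variance, which no real spectrum shows. Because the background
  scales with dilution, normalization still cancels dilution to machine
  precision.
* Additive Gaussian noise, sd = 0.01 × the median peak height.

What the generator does **not** emulate: J-coupling fine structure (below
the bin width), peak-shape distortions, baseline roll, inter-spectrometer
shift drift beyond jitter, and any correlation structure between
metabolites beyond the shared animal/dilution factors. Passing tests
therefore demonstrate that the *pipeline* recovers known truth under
realistic noise — not that the biological effect sizes are re-estimated
from real animals.

## Pre-processing

Fixed order, tested end-to-end: bin → reference integral → exclusion →
normalization → log₂.

* Binning sums the intensities of consecutive groups of 20 points
  ("integration" on a uniform grid is proportional to the sum); the
  trailing remainder is dropped rather than kept as a short bin, keeping
  bin variance uniform. 32,768 points → 1,638 bins (8 points dropped).
* Window membership is half-open [low, high) on bin centers: a center at
  exactly 7.87 falls in the 8.17–7.87 histidine exclusion, 7.83
  (hippurate) survives. Deterministic boundary behaviour is the goal.
* The creatinine reference is the integral over 3.02–3.08 ppm, not a
  single bin: shift jitter makes single-bin lookup fragile. The reference
  is computed before exclusion removes bins (creatinine lies in no default
  exclusion window, so both orders agree for the defaults).
* log₂ flooring at 1e-12 (on the normalized scale where the reference
  window sums to 1) keeps noise-negative bins finite.
* No inter-sample peak alignment beyond the common grid: all cohort
  spectra share an axis, and binning absorbs the jitter. Segment-wise
  alignment (icoshift/COW) and probabilistic-quotient normalization are
  non-goals.

## Chemometrics

PCA is computed by SVD of the column-centered matrix — deterministic, and
identical to converged NIPALS — with component signs fixed by making the
largest-magnitude loading positive. The Hotelling screen uses
T²ᵢ = Σₐ tᵢₐ²/var(tₐ) against the F-based limit
A(n−1)(n+1)/(n(n−A)) · F(1−α; A, n−A). That limit is calibrated for a new
observation from the fitted population (verified by simulation in the test
suite); applied in-model it is slightly conservative, which suits an
outlier screen.

PLS-DA is NIPALS PLS1 against the centered 0/1 coding (TN → 0, HS → 1).
Mean-centering is the only scaling: the features are already log₂
intensities, and unit-variance or Pareto scaling would re-weight the
flooring noise of near-empty bins. With a univariate response the weight
update w ∝ Xᵀy is the NIPALS fixed point, so each component is exact in
one pass. R²X is the fraction of centered X sum-of-squares captured by the
score/loading reconstruction, computed on the retained matrix. Component 1
is oriented so the HS mean score is positive, making loading signs
reproducible ("positive = higher in HS").

Leave-one-out Q² refits from scratch per fold, re-centering X and y inside
the training fold (no leakage); TSS uses the full-data centered y. For
speed, cross-validation and permutation loops first project X onto an
orthonormal basis of its row space (U·S from the SVD): every reported
statistic depends on X only through row inner products, and fold-centered
rows stay inside the original row span, so the compression is exact (a
dedicated test checks equality to 1e-10 against the uncompressed route).

The permutation test supports two null schemes. Free label permutation is
the behaviour when no design is supplied, but it is *not* exchangeable for
a crossover with per-animal random effects: the true labeling is perfectly
balanced within animals, whereas free permutations can align both of an
animal's samples with one class and exploit the animal-correlation
structure, inflating the permuted Q² null — measured type-I error falls to
roughly 0.01–0.02 at the nominal 0.045 level. Passing the crossover
`design=` restricts permutations to within-animal swaps, whose orbit
contains the true labeling, making the test exact (measured rejection
≈ 0.03–0.045 at the same level); the pipeline and all replicate studies
therefore use the animal-blocked scheme. The p-value uses the add-one
formula (count + 1)/(n + 1), so it is never zero, and with 199
permutations "p < 0.05" corresponds to an exact level of 9/200 = 0.045.

Biomarker selection takes component-1 loadings over |0.0005|, ranked by
magnitude. Loadings are scale-dependent; the threshold is meaningful only
on the normalized/log₂ matrix.

## Volcano screen

Paired differences (HS − TN per animal, log₂ scale) feed a two-sided
one-sample t (df = n−1; zero-variance bins get p = 1 with a warning), BH
step-up adjustment over the retained bins only (excluded bins were never
tested), and the conjunctive gate |log₂ FC| ≥ 1.5 ∧ p < 0.01 ∧
BH-p < 0.05 — applied jointly rather than sequentially, same final set.
Both fold-change conventions are emitted: the mean log₂ difference and the
signed ratio 2^|mean| carrying the mean's sign (negative = higher under
TN). Note an intentional consequence of injecting effects on the ratio
scale: the largest injected ratio, 2.74, is log₂ = 1.45, *below* the 1.5
log₂ gate, so the default cohort produces a near-empty volcano; the screen
is validated with stronger injected effects, and model-based selection
(loadings) carries the discovery role at study-magnitude effects.

## Assignment

Bins match every library resonance within ±0.01 ppm (≈ 1.4 bin widths,
matching the jitter scale); overlapping candidates — trimethylamine
N-oxide at 3.27 vs histamine at 3.28 — are all reported, ordered by
|Δppm|. A metabolite is "supported" when at least half of its resonances
are matched, a documented choice where the field has no fixed rule. The
library ships as a versioned TSV so results are reproducible offline; live
HMDB/KEGG queries are out of scope.

## Performance arithmetic

`thi` implements the dry-bulb/relative-humidity NRC-1971 approximation
(1.8T + 32) − (0.55 − 0.0055·RH)(1.8T − 26) and reports the variant in
its metadata: the 1971 source lists several THI formulas (wet-bulb and
dew-point based), and the published band endpoints are not exactly
reproducible from the dry-bulb form at the stated chamber corners, so the
operation does not hard-code them. `fcm` evaluates
L·(0.432 + 0.162·fat%), exact at the 3.5 %-fat design point
(factor 0.999). `crossover_means` computes treatment means over
animal × period cells, which in a balanced crossover equal the
least-squares means; the full repeated-measures mixed model is
deliberately not reimplemented — the derived contrasts (differences,
ratios, percent changes) need only the means. Rounding follows reporting
precision: temperatures and ratios to 0.1, percent changes to the integer.
Applying the FCM formula to the mean yield/fat gives 2.02 L/d where the
published table prints 2.17; the table averaged per-animal FCM, not FCM of
averages, and the percent-change contrast uses the printed means.

## Problem sizes and numerical choices

The showcase cohort runs at full resolution (32 × 32,768 points,
1,163 retained bins). Replicate studies — 50 recovery cohorts and 200
permutation-null cohorts of 199 permutations each — use 8,192-point
spectra (≈ 0.024 ppm bins): bins remain far wider than the 0.002 ppm
linewidth and far narrower than any exclusion window, so the pipeline's
behaviour is unchanged while hundreds of cohorts stay cheap. Seeds derive
from a single `SeedSequence`, and identical configuration (including seed)
reproduces outputs bit-for-bit.

## Known limitations

* Effect sizes, variance components and the background shape are design
  choices, not estimates from the original animals; absolute Q²/R² values
  on synthetic cohorts characterise the pipeline, not the goats.
* PLS-DA R²/Q² conventions differ across implementations (fold
  re-centering, TSS definition); values reproduce exactly only under the
  conventions stated above.
* The assignment step is shift-matching, not identification: 2D-NMR
  confirmation and absolute quantification are out of scope.
* `crossover_means` gives no standard errors or P-values; those require
  the day-level raw records and the mixed model, both out of scope.
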