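# Methods

## The model

A patient's ex vivo drug response is modelled as a full second-order
polynomial in normalized doses.  Each of the k panel drugs is tested at
three levels — absent, low, high — coded 0/1/2 and mapped to regression
inputs x ∈ {0, 0.5, 1}, so coefficients are comparable across drugs
regardless of their molar concentrations.  The response is normalized cell
viability (NCV), the ratio of a treated well's luminescence signal to the
mean of the plate's untreated negative-control wells.  The surface

ŷ(x) = β₀ + Σ βᵢxᵢ + Σ βᵢᵢxᵢ² + Σᵢ<ⱼ βᵢⱼxᵢxⱼ

has 1 + 2k + k(k−1)/2 coefficients (91 at k = 12): βᵢ capture single-drug
efficacy, βᵢᵢ curvature of the dose response, and βᵢⱼ pairwise interaction
(negative = synergy, positive = antagonism).  The model is deliberately
mechanism-agnostic; higher-order interactions are assumed negligible.

Fitting is plain ordinary least squares on the coded design (no term
selection, no regularization), which the composite design supports with 155
observations against 91 coefficients.  An optional ridge penalty
(`alpha > 0`, intercept unpenalized) is available for rank-deficient or
reduced designs but is never the default.  Model quality is summarized by
the adjusted R², adj R² = 1 − (1 − R²)(n − 1)/(n − p − 1) with p = 90
non-intercept terms.

## The experimental design

The test points form an orthogonal-array composite design: a two-level
fractional factorial on the extreme levels {0, 2} concatenated with a
three-level orthogonal array contributing the mid-dose level.

- Two-level portion: full factorial for k ≤ 4; for larger k a stored
  regular fraction of resolution ≥ IV.  Generator words for k = 5..10 are
  the standard minimum-aberration sets; k = 11 and 13..16 use subsets of
  the 32-run fold-over family (factors on odd-length words, resolution IV
  by construction); k = 12 uses a 2^(12−5) set of 128 runs
  (H=ABFG, J=ABCD, K=ADEFG, L=ACDG, M=ABEG) chosen, by randomized search
  over generator words, to be resolution IV *and* to give the combined
  155-point design a full-rank quadratic model matrix.  Resolution is
  never assumed: the defining contrast subgroup is recomputed from the
  built matrix (all column subsets whose product is constant) and its
  minimum word length asserted ≥ 4 in the tests.
- Three-level portion: the 9-run array for k ≤ 4 and the 27-run array for
  k ≤ 13, generated over GF(3) (columns are dot products with projective
  representatives), which guarantees strength 2: every level pair occurs
  equally often in every column pair.

No additional center replicates are added beyond the orthogonal-array
portion.  Dose caps are enforced at panel construction: the top tested
concentration must not exceed min(10% of Cmax, IC10) where those are
provided, keeping tested doses clinically achievable.

## Plate processing and QC

Replicate wells sharing a design row are averaged (arithmetic mean of
per-well NCV; replicate SD retained for reporting).  NCV values above 1
(growth relative to control) are retained, not clipped.  Assay quality uses
raw signals with sample (n−1) SDs: Z′ = 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋| and
SSMD = (μ₋ − μ₊)/√(σ₋² + σ₊²), where + denotes the cytotoxic positive
controls declared in the layout.  A run is excluded when Z′ < 0.7,
strictly — Z′ = 0.7 passes.  When both control variances are exactly zero
(a noiseless simulation), SSMD is reported as infinite rather than failing
the run, since the separation is perfect.

## Ranking and report

The fitted surface is evaluated at all 3^k level assignments (chunked
matrix products; enumeration refuses k > 13) and sorted ascending by
predicted NCV with lexicographic tie-breaking on the coded vector, making
reports byte-reproducible.  Patient reports list the top 10 combinations
with exactly two and exactly three active drugs.  The pairwise-interaction
("polygonogram") score of drugs i, j is the minimum predicted NCV over the
four assignments with both drugs at levels {1, 2} and all other drugs
absent — a projection, not a marginalization, matching how two-drug
interactions are displayed in isolation.  A clinical regimen is scored with
each administered drug at its highest tested level (code 2) and others
absent; regimens containing drugs outside the panel are excluded from
concordance with an explicit log entry.

## Concordance statistics

Predicted NCV < 0.65 classifies a regimen as predicted responder; the
boundary value 0.65 is assigned to non-response.  Clinical CR/CRi/PR
collapse to response, NR to no response.  The 2×2 summary reports
sensitivity, specificity, PPV, NPV and accuracy with metrics left undefined
(None) when their denominator class is empty.  Binomial intervals are
Clopper–Pearson (default) or continuity-corrected Wilson — both are
provided because published concordance tables are not always consistent
with a single method, and intervals are audit output rather than decision
quantities here.  Fisher's exact test uses the two-sided
minimum-likelihood rule (total probability of all tables with the observed
margins no more likely than the observed table); degenerate margins give
p = 1 with a warning.  ROC analysis fixes the orientation lower-score =
more responder-like, computes AUC as the tie-corrected Mann–Whitney
statistic, and reports the optimal cutoff as the Youden-J maximizer over
thresholds midway between adjacent distinct scores.  Paired combination
comparisons use the two-sided paired t-test per subgroup; zero-variance
differences are flagged degenerate rather than given a spurious p-value.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
AML biology.  Per patient a ground-truth surface is drawn with β₀ = 1,
single-drug effects βᵢ ~ −U(0.05, 0.35) (modest kill at screening doses),
small curvature βᵢᵢ ~ N(0, 0.01), and pairwise terms βᵢⱼ = βᵢβⱼ + N(0, 0.01)
— the second-order expansion of multiplicative (Bliss-independent)
viability, so combined kill saturates instead of driving the surface
negative — plus configured synergy offsets (defaults: fludarabine–
cytarabine −0.12, fludarabine–venetoclax −0.08, giving the cohort a shared
dominant doublet).  A final safeguard rescales the non-intercept
coefficients (an affine map in kill space, so the surface stays exactly
quadratic) whenever the surface would dip below 0.02 at any design point;
with the defaults this triggers for ~0.3% of draws.

Plates place each design row in `n_replicates = 2` wells plus 12 negative
and 12 positive control wells (334 wells of a 384-well plate), with raw
signal = 10,000 RLU × (surface value + Gaussian noise, sd `noise_sd`,
truncated at 0).  Default noise sd 0.05 NCV units is a realistic replicate
CV for luminescence viability screens; a multiplicative log-normal model is
available by flag.  At zero noise the pipeline identities are exact:
normalization returns the truth surface at every design row, Z′ = 1, OLS
recovers every coefficient to numerical precision, and the fitted ranking
equals the truth ranking entry for entry.

Cohorts assign each patient a regimen from a weighted list (the
hypomethylating-agent + venetoclax doublet most frequent), disease status
ND/R-R at 0.69/0.31 and ELN risk favorable/intermediate/adverse at
0.25/0.40/0.35, mirroring a real-world screening cohort's mix.  The
clinical label is the truth-surface prediction (regimen NCV < 0.65) XOR a
flip with probability ε (`label_flip_eps`, default 0.1).  Patients
alternate between true responders and true non-responders, redrawing the
surface until the target class is hit (`balance_true_classes`, default
on): with balanced classes, estimated sensitivity and specificity share
the calibration target 1 − ε, whereas in an unbalanced cohort they would
converge to class-prevalence-weighted quantities instead.  Serial
resistance scenarios hold one patient's surface fixed except the named
drug's linear coefficient, which moves toward 0 by `resistance_drift` per
run, so single-drug predicted NCV rises strictly across runs.

What passing synthetic tests do *not* show: real screens have spatial
plate effects, heteroscedastic and non-Gaussian noise, imperfect blast
purity, and clinical outcomes driven by far more than ex vivo viability;
the label mechanism deliberately ties outcomes to the same 0.65 rule the
classifier uses, so calibration results certify pipeline correctness, not
clinical validity.

## Numerical choices and problem sizes

OLS is solved by `numpy.linalg.lstsq` after an explicit rank check (rank
deficiency raises with a pointer to the design, never a silent
pseudo-inverse fit).  Enumeration at k = 12 scores 531,441 × 91 terms in
~2 s in 65,536-row chunks.  Validation experiments use problem sizes that
keep the full suite fast while leaving no statistical ambiguity: exact
recovery is asserted at three zero-noise seeds; estimator unbiasedness
averages 200 independent screens at noise sd 0.05 (mean absolute
coefficient bias ≈ 0.002, bound 0.01 — OLS is unbiased, so the measured
value is Monte-Carlo noise of the mean); concordance calibration uses one
2000-patient cohort at ε = 0.1, zero plate noise (binomial SE ≈ 0.009 per
metric against the ±0.02 band).

## Known limitations

- The quadratic surface cannot represent three-way or higher synergies and
  extrapolates poorly outside the tested dose cube; predicted NCV can be
  negative for many-drug combinations and is reported unclipped.
- The two-level portion aliases some pairwise interactions with each other
  within that portion; identifiability of the full model rests on the
  combined design (rank 91 is asserted, but interaction estimates are not
  all equally precise).
- Regimen scoring uses the top tested level for every administered drug —
  a convention, since clinical dosing does not map onto the tested
  concentrations.
- The 27-run array supports at most 13 drugs; larger panels need a
  different composite design.
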