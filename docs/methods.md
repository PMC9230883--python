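# Methods

## The total-error model

`apval` treats validation as a prediction problem: a method is fit for use
when a single future measurement can be expected, with probability β, to
fall within ±λ of the true value.  At each concentration level *j* the
back-calculated concentration of a validation standard measured in series
(day) *i*, replicate *k* is modelled as a balanced one-way random-effects
draw

    x_ik = μ_j + α_i + ε_ik,   α_i ~ N(0, σ²_B),  ε_ik ~ N(0, σ²_W),

with *p* series and *n* replicates per series.  The components are
estimated by the ANOVA method of moments: σ̂²_W is the pooled within-series
mean square and σ̂²_B = max(0, (MS_between − MS_within)/n).  Negative
moment estimates are truncated at zero (R = 0, B = 1); the downstream
formulas remain well defined and the truncation matches universal practice
for this estimator.

The β-expectation tolerance interval on the relative-error (%) scale is

    bias_j ± t(ν; (1+β)/2) · sqrt(1 + 1/(p·n·B²_j)) · s_R,j

with R = σ̂²_B/σ̂²_W, B²_j = (R+1)/(nR+1), s_R,j the intermediate-precision
RSD (100·√(σ̂²_W+σ̂²_B)/μ̂_j), and Satterthwaite degrees of freedom

    ν = (R+1)² / [ (R + 1/n)²/(p−1) + (1 − 1/n)/(pn) ].

Two identities justify the construction.  First,
(1 + 1/(pnB²))·s_R² = s_R² + (σ̂²_B/p + σ̂²_W/(pn)), i.e. the estimated
variance of (new observation − grand mean), so the interval is a
Satterthwaite-approximate prediction interval for one future result.
Second, ν → p−1 as R → ∞ and stays finite and positive at R = 0, the two
regimes the design can produce.  The defining property — the expected
fraction of future observations inside the interval equals β — is checked
empirically by `coverage_experiment`, which re-estimates the interval from
each simulated dataset and scores fresh draws from the same model; under
the default conditions the mean coverage is ~94.8% at β = 0.95 (the small
deficit is the known cost of the Satterthwaite plug-in at p = 3).

Conventions: the t quantile uses fractional ν (no rounding); bias and RSDs
are computed on the relative scale with μ̂_j in the denominator; variance
components are computed on the absolute concentration scale and converted
once.  When both components are exactly zero the interval degenerates to
[bias, bias] without evaluating ν, avoiding 0/0.

## Profile decisions

A level passes when its interval lies inside [−λ, +λ] (default λ = 15%).
LLOQ is the lowest passing concentration if the lowest level passes;
otherwise the offending bound is interpolated linearly on the concentration
axis against ±λ between the last failing and first passing level.  ULOQ is
symmetric from the top.  No interpolation rule is canonical in the
literature; linear-on-concentration was chosen for transparency.  When
passing levels are non-contiguous the profile is reported invalid and the
extreme passing concentrations are still shown — inspection of the plot is
then mandatory.  The detection limit can be derived either as LLOQ/3.3 or
from the S/N = 3 route in `chrom_metrics.lod_from_sn`; the two answer
different questions (quantitation-anchored vs noise-anchored) and neither
is privileged.

## Response functions and inverse prediction

Four candidate calibration models are supported: unweighted linear,
through-origin single-point at the 120% level (mean of the top-level
replicates — with replicates, "fitted only at the highest level" implies
averaging), 1/X-weighted linear (weights 1/concentration, read literally),
and linear after square-root transformation of BOTH axes (the common
variance-stabilising choice; transforming only the response is a plausible
alternative and is deliberately not offered to keep one semantics).
r² is reported on the fitting scale and is undefined (NaN) for the
single-point model.  Back-calculation always uses the calibration fit of
the sample's own series: day is the blocking unit, and per-day fits are
what a routine laboratory would apply.  A negative back-calculated
concentration under a linear model is returned as-is — it is a meaningful
extreme-bias observation, not an error.

`select_response_function` ranks candidates by (all levels pass, then the
smallest maximum absolute interval bound), flags ties, and breaks them in
favour of the simplest model (unweighted linear first).

## Synthetic data: what it emulates and what it does not

`TruthSpec` defaults encode the validated assay's published operating
point: per-level true biases (+1.1, +3.9, −1.2, −3.0, −4.5)% and
within-series CVs (2.1, 2.7, 1.9, 1.5, 1.4)% with between-series CVs
derived as √(s_R² − s_r²) from the intermediate-precision RSDs
(2.6, 3.0, 3.1, 2.4, 2.5)%.  Errors are multiplicative Gaussian on
concentration (matching RSD-denominated reporting); an additive variant is
available via `error_scale="absolute"`.

Calibration standards are generated bias-free with their **own** precision:
aqueous serial dilutions are far tighter than matrix-matched validation
standards, and giving them the validation CVs would corrupt the unweighted
intercept enough to inflate the low-level intermediate RSD several-fold,
contradicting the reported per-day fit quality.  The defaults —
`cal_cv_within_pct = 0.3`, `day_effect_cv_pct = 0.2` — reproduce the
reported day-to-day slope spread (RSD ≈ 0.26%) and per-day r² (≥ 0.9997).
The day effect is a sensitivity factor multiplying the response slope of
both roles on a given day; it cancels in back-calculation, exactly as a
drifting detector would on a real instrument.

Not emulated: response drift within a run, carry-over, heteroscedastic
detector noise beyond the relative model, day effects on bias (the truth
spec allows per-level bias only, constant across days), and non-Gaussian
outliers.  Passing tests therefore demonstrate correctness of the
*computations* under the stated error model, not robustness of the assay
to artefacts the model excludes.

Replication note: under these defaults roughly a third of simulated
campaigns yield an all-levels-pass profile.  That is not a defect — the
600 µg/mL operating point (bias −4.5%, s_R 2.5%) sits close to the −15%
acceptance limit, so its interval legitimately crosses it in a substantial
fraction of replications.  A single real campaign passing says little about
the replication rate; the simulation makes that explicit.

## Chromatographic metrics

Peak metrics follow compendial definitions: N = 5.54·(t_R/W₀.₅)²
(half-height formula), USP tailing T_f = W₀.₀₅/(2f) at 5% height, and
S/N = 2H/h with h the peak-to-peak noise of a linearly detrended
analyte-free window (an RMS convention is available).  The within-window
baseline is the straight line through the window endpoints; widths are
linearly interpolated between samples; the apex is the sampled maximum, so
fixtures should be sampled densely (≥ ~1000 points per minute) when
sub-percent width accuracy matters.  Simulated peaks are exponentially
modified Gaussians (scipy's exponnorm density, unit-max normalised on a
dense internal grid so amplitude is sampling-independent); τ = 0 gives a
pure Gaussian with T_f = 1.

System suitability gates default to N > 5000, RSD ≤ 2% for retention time
and area over replicate injections, and T_f ≤ 1.5.

## Dissolution reduction

Cumulative release uses the standard sampling correction
%_i = 100·(C_i·V(t_i) + V_s·Σ_{j<i} C_j)/dose, with V(t) the
stage-appropriate vessel volume (100 mL gastric stage; 200 mL after the
60-min addition of an equal volume of double-concentrated intestinal
medium, analyte mass conserved).  On noiseless data the correction is
exact for any schedule — the aliquot mass balance telescopes — which the
tests verify to 1e−9.  The sample taken exactly at the change time is
treated as drawn before the addition (configurable), and the correction
can be disabled to reproduce uncorrected reductions.  Cumulative curves
are not forced monotone; decreases beyond 5% (about the 3σ of adjacent
differences at 2% sampling noise) raise a warning instead.

## Problem sizes

Default experiment sizes were chosen so Monte-Carlo error is comfortably
below the tolerances being checked: 500 datasets × 200 future draws per
level for coverage (MC SE ≈ 0.17 points on ~95%), and 1000 datasets for
parameter recovery (SE ≈ 0.04 points on the 600 µg/mL bias, ≈ 0.03 points
on the 50 µg/mL repeatability RSD).

## Known limitations

* β-content/γ-confidence tolerance intervals, outlier rejection and
  uncertainty on the LLOQ itself are out of scope.
* The accuracy-profile stage requires a balanced design; readers accept
  unbalanced tables but `validate_design` reports every hole and the
  profile stage refuses them (the closed-form ANOVA assumes balance).
* Weighted regression supports only 1/X; no quadratic or 4PL models.
* Peak handling assumes one analyte peak per window; co-elution only
  triggers a warning, not deconvolution.
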