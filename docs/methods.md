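# Methods

## The LMS model

A growth reference describes how an anthropometric measurement x is
distributed at each age and sex.  The LMS representation uses three curves:
the Box-Cox power L(age) capturing skewness, the median M(age), and the
coefficient of variation S(age).  The standard deviation score of a
measurement is

    z = ((x/M)^L - 1) / (L * S)   for |L| >= eps
    z = ln(x/M) / S               for |L| <  eps

with eps = 1e-7: well below the resolution at which L is ever tabulated,
well above floating-point noise, and the two branches agree to < 1e-6 over
x/M in [0.5, 2].  The inverse transform x = M*(1 + L*S*z)^(1/L) (or
M*exp(S*z) in the log limit) requires 1 + L*S*z > 0; violations raise
rather than extrapolate.  Centiles are 100*Phi(z).

References are tabulated at discrete ages and evaluated by piecewise-linear
interpolation applied independently to L, M and S — exact at the knots, no
overshoot, and no extrapolation beyond the tabulated span (out-of-span
children are flagged and excluded from tallies, never silently scored).
Spline interpolation was rejected because monotonicity of M between knots
is not guaranteed and tabulated references are dense enough that the
difference is negligible.

A reduced scorer is provided for references published only as centile
curves: SDS ~ (x - P50) / (0.5 * (P50 - P3)).  It is exact at the median
and maps the 3rd centile to -2 by construction, whereas the exact score
there is Phi^-1(0.03) = -1.8808, so it overstates |SDS| by a factor of
about 1.063 near the lower tail.  It exists as a documented fallback; the
pipeline always scores with the full LMS transform.

## Band schemes

The five-band clinical scheme uses the conventional printed SDS cutoffs
-1.88, -1.66, +1.66, +1.88 with the printed inclusivities (z = -1.88 is in
the 3rd-10th band and therefore "normal"; z = +1.88 in the 90th-97th).
Note the convention equates the 10th/90th centile with SDS +/-1.66 although
the exact normal quantile is +/-1.2816; the scheme is applied as
conventionally defined, and an `exact_quantiles` switch substitutes the
true quantiles for sensitivity analyses.  The headline chart comparison
uses the three-band screening scheme (<3rd, 3rd-97th, >97th centile);
overweight flagging above the 90th centile is available through the
five-band labels.

## Dual-chart comparison

Each child is standardized against both charts; per measure the three-band
counts form a band x chart contingency.  For a given band the two charts
are compared by the percentage-point difference of their shares and a
Pearson chi-squared test (no continuity correction) on the 2x2 table
(in band / out of band) x (chart).  This mirrors common practice even
though the two classifications are of the *same* children; a paired
McNemar test on the discordant pairs is provided (`mcnemar_test`) as the
statistically preferable alternative, but requires child-level data,
which published contingency tables do not give.  Display percentages are
rounded half-up to integers; differences and tests always use full
precision, and percentage-point gaps quoted as integers are differences of
the displayed percentages (that is how such figures are printed).
Degenerate tables (a zero margin) skip the test with a warning and still
report the difference.  Spearman correlations (mid-rank) and Mann-Whitney
U (U = min of the two one-sided statistics; exact enumeration for
tie-free samples up to n = 20, tie-corrected normal approximation
otherwise) cover the covariate analyses; all three tests are scipy.stats
wrappers whose contracts (margins, ties, empty groups) are enforced at the
package surface.

Adults are excluded at age >= 18.0 years — pediatric references end at 18.
No gestational-age correction of postnatal age is applied; a premature
subgroup can be excluded for sensitivity runs.  Missing covariates are
handled by pairwise deletion with the effective n reported per analysis.

## Synthetic references and cohorts

No copyrighted reference values are distributed.  The base ("standard")
chart is analytic: logistic-like median growth curves from birth to 18 y
at 0.1-y knots (height 50 -> 177/164 cm, weight 3.5 -> 70/58 kg for
boys/girls), L = 1, constant S (0.04 for height, 0.12 for weight).  The
BMI reference is made coherent with these: M_bmi = M_w / (M_h/100)^2 and
S_bmi by delta-method propagation sqrt(S_w^2 + 4 S_h^2 - 4 rho S_w S_h)
for latent weight/height scores correlated at rho (default 0.7), so that
BMI derived from simulated weight and height is approximately standard
normal against it.

The "specialized" partner chart shifts each median by a per-measure SDS
offset delta (M_spec = lms_value(delta, L, M, S), S scaled by an optional
ratio, L unchanged): a child at specialized-z 0 then sits at standard-z
delta exactly.  For nonzero latent z with L = 1 and unit S-ratio the
induced standard score is z*(1 + S*delta) + delta, so the under-3rd share
on the standard chart is Phi((-1.88 - delta)/(1 + S*delta)) — for
delta = -1 on the height chart (S = 0.04) that is 17.96%, within a point
of the naive Phi(-0.88) = 18.9% that ignores the variance contraction.
Recovery tests assert the exact form.  Default scenario offsets are
delta = -1.2 (weight), -1.5 (height), -0.5 (BMI): chosen once to realize,
through the closed form above, under-3rd standard-chart shares of the
order the motivating study observed (27%/35%/~10%); the BMI offset is an
independent scenario parameter and is deliberately not constrained to be
coherent with the weight/height offsets, so BMI truth scores are exactly
standard only under the base chart.

Cohorts draw sex ~ Bernoulli(0.54 male), age log-uniform on [0.1, 18] y
(a young-skewed sample; median 1.34 y, younger than a typical clinic
cohort — the distribution is configurable), latent (z_height, z_weight)
bivariate standard normal with correlation rho, and measurements through
the inverse LMS transform of a designated truth chart; BMI is derived as
weight/(height in m)^2, never drawn.  Covariates use the motivating
study's marginals: birth weight 2898 +/- 513 g (truncated positive),
gestation 37.7 +/- 2.17 wk (truncated to [22, 43]; the truncated-normal
mean, 37.66, is the recovery target), 78% breastfed, 64% on L-thyroxine.
Optionally the treated/untreated height-z standard deviations are set to
0.8/1.2, reproducing the finding that treated children sit inside the wide
norm band more often.  All randomness flows from a single integer seed;
identical configurations produce byte-identical output files.

What the generator does **not** emulate: longitudinal trajectories,
age-dependent offsets between the charts (delta is constant in age),
comorbidity co-occurrence structure, measurement digit preference, and the
age distribution of any particular clinic.  Passing recovery tests
therefore demonstrate that the pipeline's arithmetic and bookkeeping are
correct under the stated model, not that any particular real cohort would
show these effect sizes.

## Numerical and design choices

* Percent display rounding is half-up (26.5 -> 27), matching how such
  tables are conventionally printed; internal values are never rounded.
* Reference files are delimited text (comma or tab, sniffed) with columns
  sex/age/L/M/S; sex codes F/M or 1/2; an age-in-months flag divides by
  12.  Validation errors name the offending row and column.
* Cohort loading collects malformed rows as per-line errors and fails only
  when no valid row remains.
* Problem sizes: recovery checks use cohorts of 10^4 (proportions within
  ~0.5 percentage point at 3 Monte-Carlo SEs) and replicate studies use
  50-100 seeded replicates of 500-1000 children; all complete in seconds.
* CLI exit codes: 0 success, 1 validation failure, 2 internal error;
  logs to stderr, results to files; every run writes a manifest.

## Known limitations

The chi-squared independence test on chart-vs-chart tables ignores the
pairing of classifications (conservative here; the McNemar mode addresses
it when child-level data exist).  The linearized P3/P50 scorer is biased
in the tails by design.  Constant-S analytic references understate the
age-dependence of real S curves; they are stand-ins for structure, not
estimates of any population.
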