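# Methods

This note documents the models, algorithms and design choices behind
`mfbia`: what is fitted, how the synthetic cohorts are calibrated, which
statistical conventions are used, and what the package's tests do and do
not demonstrate about real recordings.

## The Cole model and the eight muscle parameters

A muscle segment measured with a tetra-polar electrode pair behaves, over
4–1000 kHz, like an extracellular resistance in parallel with an
intracellular path behind the cell membranes' capacitance.  `mfbia` uses
the single-dispersion Cole model

Z(f) = R∞ + (R0 − R∞) / (1 + (j·f/fc)^α)

with four parameters: R0 (zero-frequency resistance, Ω), R∞
(infinite-frequency resistance, Ω), fc (center frequency, kHz) and the
dispersion exponent α ∈ (0, 1].  In the complex plane (reactance taken
as the negated imaginary part, plotted upward) the model traces a
circular arc from (R0, 0) to (R∞, 0); for α = 1 it is a semicircle
centred on the real axis with apex (R0+R∞)/2 + j(R0−R∞)/2 at f = fc, and
for α < 1 the center drops below the axis by (ΔR/2)·cot(απ/2), where
ΔR = R0 − R∞, so the apex reactance (ΔR/2)·tan(απ/4) is strictly below
ΔR/2.

The eight derived parameters follow in closed form: R and Xc are model
values at 50 kHz (computed from the fitted model rather than
interpolated from raw samples — the model readout is noise-robust and
well-defined even when 50 kHz falls between grid points); Z = √(R²+Xc²);
PA = arctan(Xc/R) in degrees; Re = R0; Ri = Re·R∞/(Re − R∞); and Mc from
fc = 1/(2π·Mc·(Re+Ri)), with fc converted from kHz to Hz so Mc comes out
in farads.  Ri diverges as R∞ → Re; that geometry is rejected as a
degenerate-geometry error rather than returned as a huge number.

Although classical Cole-plot software often works with α = 1 implicitly,
the normative table is internally inconsistent with a semicircle: at the
male biceps means (Re 114.0, Ri 140.8 ⇒ R∞ 63.0, fc 42.3 kHz) a
semicircle predicts Xc(50 kHz) ≈ 25.1 Ω where the table lists
18.1 ± 3.7 Ω.  The model therefore carries α as a free parameter
(estimable or fixed by `alpha_fixed=1.0` for semicircle analysis).

### Units of Mc

The normative table labels Mc "pF", but evaluating the defining relation
on the table's own fc/Re/Ri means gives values of order 10⁻⁸ F (tens of
nF) — e.g. 1/(2π·42300·254.8) = 14.8 nF for the male biceps, against a
tabulated Mc of 17.5.  The tabulated numbers coincide numerically with
the nF scale (the residual gap is a Jensen effect: the mean of
per-subject 1/(fc·(Re+Ri)) exceeds the value at the means).  `mfbia`
stores Mc in farads, displays nF, and uses the tabulated Mc values only
in dimensionless comparisons (percent change, z-scores), where the scale
ambiguity cancels.  The "pF" label is preserved verbatim in the shipped
table.

## Fitting

`ColeModel.fit()` is deterministic (no random restarts):

1. **Initializer** — an algebraic (Kåsa) least-squares circle fit to the
   (R, Xc) points.  The real-axis intercepts of the circle give R0 and
   R∞ (half-chord h = √(r² − c²) for center offset c and radius r), the
   depression gives α = (2/π)·arcsin(h/r), and the frequency of maximal
   measured reactance seeds fc.  The circle fit is exact on noiseless
   arcs and rejects collinear input.
2. **Refinement** — bounded nonlinear least squares
   (`scipy.optimize.least_squares`, trust-region reflective) on the
   stacked real/imaginary residuals, parameterised as (R∞, ΔR, fc, α)
   with ΔR > 0 so R∞ < R0 holds throughout.  Residuals are equally
   weighted per frequency by default; proportional (relative) weighting
   is available.  Approximate standard errors come from the
   Gauss–Newton covariance s²(JᵀJ)⁻¹ at the optimum.

fc is constrained to the swept frequency range.  An arc apex beyond the
sweep is pure extrapolation: in pathological corners of the synthetic
cohorts (see below) a handful of recordings have ΔR < 1 Ω, and an
unconstrained fc can rail to absurd values (10⁵–10⁶ kHz) that dominate
any cell mean.  The quality screen still reports fc at or outside the
sweep edges.  Noiseless spectra on 256 log-spaced points are recovered
to machine precision; at 1% proportional noise the median relative error
of all four parameters is below 1% (measured over 100 replicates by the
acceptance suite).

### Quality screen

Mirroring the operator's check of the live R/Xc plots, `quality_check`
rejects a fitted recording when (defaults, all configurable):

* rms complex-plane residual exceeds 5% of ΔR;
* the data span less than 50% of the fitted arc (arc coverage is the
  angle subtended by the model points at the sweep extremes over the
  full arc angle απ);
* fc falls outside the swept range, or the optimizer failed to converge.

The rmse criterion is scaled to ΔR while measurement noise scales with
|Z|, so recordings of muscles with small arcs relative to their
impedance (high-Ri cells, mostly women's) are screened more aggressively
at a given noise level.  That is a property of the screen, not of the
recordings; analyses of cohort means in the test suite therefore run on
all fits, and the screen is applied in the reporting pipeline where a
clinician would want conservative per-recording flags.

## Normative reference and contrasts

The package ships the normative table (8 muscles × 2 genders × 8
parameters; mean, SD, n = 25, unit) as a TSV resource, loaded verbatim —
a fixture test compares every cell against an independently embedded
copy.  Two cells have SD > mean (women triceps fc 63.3 ± 95.4, women
rectus femoris fc 53.7 ± 69.3); they are stored verbatim and flagged.

Z-scores for a new recording are (value − mean)/SD per parameter with a
|z| > 2 flag.  The women-vs-men contrast table recomputes
100·(women − men)/men from the packaged means, rounding half away from
zero to match the published integer style.  33 of the 52 published
percent-change cells are reproduced exactly; the remainder differ by ±1
because the source computed percentages from unrounded subject-level
data before rounding the means.  Both numbers are stored — the published
integer for display, the recomputed one for exact tests — and mismatched
cells carry an explicit flag.

## Cohort statistics

* **Normality screen**: Shapiro–Wilk (the procedure's named screen is
  generic; Shapiro–Wilk has the best small-n power).  Constant samples
  are non-testable and routed nonparametric.
* **Equal variance**: two-sided F ratio at α = 0.05.
* **Age contrasts** (within gender, 20s+30s pooled vs 50s+60s pooled,
  40s excluded): pooled-variance two-tailed unpaired t-test when both
  samples pass both screens, else Mann–Whitney.  Pooled rather than
  Welch variance matches the classical textbook form the original
  procedure cites; Welch is available by flag.
* **Gender contrasts**: always Mann–Whitney, because some of the
  original data sets were non-normal; each subject contributes one
  side-averaged value per muscle (n = 25 per gender at the reference
  design), matching the normative cells.
* **Mann–Whitney p**: exact (full permutation distribution) for pooled
  n ≤ 16 without ties, tie-corrected normal approximation with
  continuity correction otherwise.  The exact branch is verified
  exhaustively against a brute-force enumeration oracle for all tie-free
  configurations with pooled n ≤ 10.
* **Significance**: p ≤ 0.05, no multiple-testing correction (matching
  the source procedure).  Percent change always uses group means with
  group a (men, or the younger pool) as baseline, even when the routed
  test is nonparametric, because the published percentages align with
  the means.

The bilateral gastrocnemius contributes both sides to the age contrast
("20 recordings per group" at the reference design) but only the
side-average to gender/reference summaries.  Note that the two sides are
correlated within subject (ρ = 0.8 in the generator), so treating them
as independent observations — as the pooled-age design does — inflates
the age contrast's type-I rate (~19% measured at α = 0.05 instead of
5%).  This is a faithful reproduction of the design, not a defect of the
tests; the type-I calibration checks therefore use a unilateral muscle,
where the measured null rejection rate is 4–6% over 1000 simulations.

## Synthetic cohorts

The generator emulates the reference study design: 5 men and 5 women per
age decade (20s–60s; 50 subjects), eight muscles each, gastrocnemius
bilateral, 256 log-spaced frequencies over 4–1000 kHz, with proportional
complex Gaussian noise (default SD 1% of |Z(f)| per quadrature
component).  Demographics (weight, height) are sampled around the
published per-decade cells; age is uniform within the decade.

**Calibration** is an inverse problem over the normative table, solved
once per muscle × gender cell:

* mean R0 = tabulated Re; mean Ri = tabulated Ri; mean R∞ follows as
  Re·Ri/(Re+Ri); mean fc = tabulated fc;
* α is solved by 1-D root finding (Brent) so that the model reactance at
  50 kHz equals the tabulated Xc mean.  The solved α lies in 0.59–0.84
  across cells; a target above the α = 1 ceiling would be geometrically
  unreachable and raises a calibration error naming the cell (this does
  not occur for the shipped table).

**Sampling** draws (r0, ri, fc) per subject from truncated normals with
the tabulated SDs and constructs rinf = r0·ri/(r0+ri) per draw — the
only cross-parameter correlation is the structural one this induces,
since the table publishes no covariances.  Sampling ri directly (rather
than rinf with a propagated SD) was a deliberate choice: Ri is a convex
function of (r0, rinf), so sampling in the (r0, rinf) basis biases the
cohort-mean Ri upward by tens of ohms in high-variance cells, whereas
sampling ri makes the Re/Ri/fc cell means exact by construction.
Truncation is symmetric about the mean, [t·μ, (2−t)·μ] with t = 0.1 by
default, which preserves the cell mean exactly while enforcing
positivity; the cost is a compressed SD in high-CV cells.  SDs exceeding
their mean (the two flagged fc cells) are capped at the mean and the
cell is flagged in the calibration record.  Bilateral gastrocnemius
draws are correlated across sides (ρ = 0.8, configurable) — side-to-side
similarity is implied by the design but unquantified, so the value is an
assumption isolated behind config.

`age_effect` multiplies the sampled parameter means for subjects in the
50s/60s decades (1.0 = null, the default study condition, under which
the pooled age contrast should and does reject at ≈5% on unilateral
muscles).

**Emergent cross-check.** R, Z and PA at 50 kHz are *not* calibrated;
their agreement with the tabulated means tests whether a single-
dispersion Cole model is consistent with the table's structure.  At the
calibrated cell means, R(50) and Z(50) land within ~4% of the tabulated
values for 15 of 16 cells.  The exception is the women-triceps cell
(+12.8%), the same cell whose tabulated SDs are of the order of, or
larger than, their means — the tabulated Re 195.9 ± 116.0 and
fc 63.3 ± 95.4 are hard to reconcile with its R 153.5 ± 31.4 under any
single-dispersion geometry, pointing at either extreme skew or a
data-entry problem in the source.  The property test encodes 10% for all
other cells and 15% for this flagged one.

### What the synthetic cohorts do not model

Electrode-contact artifacts, inductive (positive-imaginary) segments,
frequency-dependent noise, multi-dispersion tissue behaviour,
inter-parameter correlations beyond the structural one, disease or
exercise effects, and any real left/right asymmetry.  Passing tests
demonstrate internal consistency of the pipeline under the stated noise
model and that the analysis reproduces the published summary statistics;
they do not validate the instrument or the physiology.

## Numerical conventions

* Reactance is stored and reported as a positive magnitude (negated
  imaginary part); small negative excursions from noise at sweep edges
  are tolerated in spectra.
* Percent changes round half away from zero to integers; report files
  render Ω/kHz/degrees to 0.1.
* All simulation randomness flows from explicit integer seeds through
  `numpy.random.Generator`/`SeedSequence`; fits contain no randomness.
* Spectrum CSVs are comma-separated, dot-decimal, UTF-8 with `#key=value`
  metadata lines; tables are TSV; reports are JSON validated against the
  shipped schema (`mfbia/data/report.schema.json`, generated from the
  pydantic report model).

## Problem sizes used by the verification suites

The acceptance suite fits 256-point spectra; recovery statistics use 100
noise replicates; the null-age calibration uses 1000 simulated cohorts
at the reference design size (n_per_cell = 5) without spectrum
rendering (the contrast consumes closed-form derived parameters, and
rendering+refitting is exercised by the recovery suites); the
end-to-end mean-recovery run uses n_per_cell = 100 (1000 subjects, 9000
spectra, every one fitted), judged against 2 standard errors of the
normative means (SE = SD/√25).

## Known limitations

* The women-triceps cell is reproduced verbatim but is internally
  inconsistent (see above); z-scores against its fc and Re are
  correspondingly weak.
* The pooled-age contrast on the bilateral muscle inherits the design's
  independence violation; its p-values are anti-conservative.
* Published significance bands are stored metadata, not recomputed —
  subject-level source data are unavailable.
* The quality screen's rmse criterion couples to ΔR, not to |Z|; at
  fixed proportional noise it screens high-Ri muscles harder.
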