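# Methods

## Imaging model and coordinate conventions

A B-scan is a depth × lateral raster of non-negative reflectivity.  The
depth axis stores **optical path length**; with the default calibration
(1365 px over 2.01 mm, 2048 px over 8.41 mm) one depth pixel is
2010/1365 ≈ 1.4725 optical µm and one column is 8410/2048 ≈ 4.106 µm.
Whether an OCT vendor's quoted "scan depth" is optical or geometric is
often ambiguous; this package fixes one convention — depth pixels are
optical path, and geometric thickness is optical distance divided by
the corneal group index n = 1.376 — and uses it consistently in both
the generator and the segmenter, so the two can never disagree by a
factor of n.  Indices are 0-based, depth increases downward, and an
interface "depth" is the sub-pixel row coordinate of its ridge centre.

## Synthetic B-scan generator

Each corneal interface (air–epithelium, epithelium–Bowman's,
Bowman's–stroma, optional post-operative flap, endothelium–aqueous) is
rendered as a curved ridge whose axial cross-section is a Gaussian with
the instrument's PSF width (FWHM 3 µm by default, i.e. σ ≈ 0.87 px —
the peaks are only ~2 px wide, which drives several numerical choices
below).  The anterior surface follows a circle of radius 7.8 mm (a
typical human anterior corneal curvature; the value is configurable and
infinity gives a flat cornea), deeper interfaces are offset by
n × cumulative geometric thickness (paraxial model: no refraction
bending, no motion, no peripheral limbus).  Microdistortion — the fine
post-operative wrinkling of Bowman's layer — is modelled as a sinusoidal
lateral perturbation applied to both Bowman's boundaries together
(amplitude in µm, 0 disables), so the layer wrinkles without changing
thickness.

Artifacts and noise reproduce the qualitative content of clinical
UHR-OCT frames:

- **specular reflex**: a bright vertical streak with a Gaussian lateral
  footprint (σ = 4 columns) at the apex column;
- **horizontal bands**: three thin constant rows at random depths;
- **speckle**: multiplicative single-look exponential speckle (the
  standard fully-developed caricature) blended by `noise_level`
  (1.0 = fully developed, 0 = noiseless), plus additive Gaussian
  background (σ = 0.02 of the surface-peak amplitude at level 1).

No quantitative SNR for the instrument is available, so the default
noise level is the most pessimistic single-look case; what validates it
is that segmentation accuracy under it stays an order of magnitude
below the 3 µm axial resolution.  Relative interface reflectivities
default to 1.0 / 0.5 / 0.4 / 0.35 / 0.7 (surface brightest, intrastromal
flap faintest) and are configurable per interface.

Every generated image carries exact per-column interface depths in
pixels — the ground truth that all accuracy claims are scored against.
Images whose central ±900 µm would place any interface outside the
raster are rejected with a geometry error; outside that span ridges are
silently clipped (the cornea legitimately exits the frame laterally).

### Cohort simulator

The default design emulates a two-group thin-flap SBK study: 20
microkeratome ("Moria") and 21 femtosecond ("FEMTO") subjects, five
visits (PRE, 1D, 1W, 2W, 1M), two scans per visit.  Per layer the model

```
thickness(subject, visit, scan) = visit_mean
                                + subject_intercept   ~ N(0, sqrt(between² − visit_sd²))
                                + visit_deviation     ~ N(0, visit_sd)
                                + scan_noise          ~ N(0, pair_sd / √2)
```

keeps the cross-sectional SD at any visit equal to the configured
between-subject SD while the difference of a visit's two scans has SD
exactly `pair_sd`.  Default visit means and between-subject SDs follow
typical published post-SBK trajectories (epithelium ~53→56 µm with a
day-1 jump, Bowman's ~17 µm thickening by ~1.6 µm at day 1, flaps of
~96 µm vs ~106 µm, an ~80 µm post-ablation drop in total thickness);
default scan-pair difference SDs are 1.22/0.61/1.80/4.29 µm
(microkeratome group) and 1.02/0.48/2.00/4.71 µm (femtosecond group)
for epithelium/Bowman's/flap/total.  Within-subject visit-to-visit
biological SDs (1.8/0.9/1.8/4.0 µm) are set so consecutive-visit change
SDs land in the few-µm range typical of such studies.  Non-physical
draws (negative thickness, or epithelium + Bowman's ≥ flap ≥ total
violated) are resampled with a warning; a pathological subject-level
intercept triggers a full subject redraw, and exhaustion raises an
error.  The per-layer noise draws are independent, so the simulated
layers are additive only in expectation — adequate for the statistics,
and each rendered scan still satisfies the ordering invariant exactly.

What the simulator does **not** model: real speckle correlation between
the two scans of a visit, eye motion, tilt and decentration, refraction
at the surfaces, epithelial maps/peripheral pachymetry, and operator
behaviour in manual override.  Passing tests therefore demonstrate the
pipeline's correctness under the stated noise model, not clinical
performance.

## Segmentation

1. **Preprocess.**  A lateral-only median filter (3 A-scans) suppresses
   impulsive noise — filtering axially would distort the 2-px-wide
   peaks being localised.  Horizontal bands are removed by subtracting
   each row's median computed over columns *outside* ridge support
   (support = laterally smoothed intensity above 15 % of its maximum);
   rows with more than 80 % support (a flat cornea's own ridge) are
   left untouched so the cornea cannot subtract itself.  The specular
   reflex is the column of maximal total energy when that energy
   exceeds 5× the median column; exactly 128 columns centred on it
   (left-biased for the even count) are excluded, and two
   round(500 µm / 4.106 µm) = 122-column flanking regions are recorded.
   Without a detectable reflex the exclusion centres on the apex — the
   shallowest point of the anterior-surface trace, ties resolved to the
   midmost column.
2. **Profiles.**  Within each flanking region the anterior surface is
   traced per column (first half-maximum crossing of a laterally
   smoothed copy, validity judged against the median column maximum so
   a single speckle spike cannot skew it), refined to sub-pixel by
   argmax + parabola near the trace, and each A-scan is shifted by the
   rounded offset to a common surface row before averaging.  Rounding
   leaves ~0.3 px of alignment jitter, which broadens the averaged peak
   by ≲6 % of the PSF width — within the 10 % budget the tests enforce.
   Averaging ~122 A-scans attenuates fully developed speckle by ~11×,
   which is what makes single-profile peak detection reliable.
3. **Interfaces.**  Local maxima of each profile are detected with a
   prominence threshold of 3× the robust noise SD of the profile's deep
   tail, floored at 8 % of the profile maximum (residual speckle
   shoulders scale with signal, not with the noise floor).  The
   air–epithelium interface is the shallowest *strong* peak (≥ 40 % of
   the tallest); each later interface is the shallowest remaining peak
   inside an anatomical plausibility window — epithelium 35–75 µm and
   Bowman's 8–30 µm beyond the previous interface, flap 70–140 µm and
   total 350–700 µm from the surface (geometric µm, bracketing
   published anatomy: epithelium ~50 µm, Bowman's ~8–20 µm, thin SBK
   flaps ~90–110 µm).  Windows make the ordered-peak rule robust to
   spurious peaks; ordering alone is ambiguous once extra maxima
   appear.  Sub-pixel positions come from a parabolic fit through the
   peak and its two neighbours (worst-case bias ≈ 0.07 px at σ ≈ 0.87
   px, i.e. ≈ 0.07 µm geometric).  Failures raise a segmentation error
   carrying per-interface QC flags; `apply_manual_override` replaces
   flagged depths with operator values (marked `"manual"`, strict
   monotonicity enforced).  The two region-level interface sets are
   averaged into one central measurement per scan, mirroring the single
   central thickness a study reports per acquisition.

## Thickness and cohort assembly

Geometric thickness = Δpx × 1.4725 µm / 1.376.  Epithelium and Bowman's
are adjacent-peak distances; flap and total are measured from the
surface.  The two scan repetitions of a visit are averaged
element-wise.  Failed scans are excluded from the cohort table and
enumerated in a QC report; repeatability analysis then drops incomplete
pairs pairwise (a subject contributes to agreement statistics only with
both scans of the visit).

## Statistics

- **CoR** = 2 × sample SD (ddof = 1) of paired differences; CoR% uses
  the mean of all first and second measurements as denominator.
- **LoA** = mean difference ± 1.96 × SD; the multiplier is the
  conventional fixed 1.96, not a t quantile.
- **ICC** defaults to the two-way random, absolute-agreement,
  single-measures estimator ICC(2,1), computed from the paired
  two-way ANOVA decomposition (a systematic offset between the two
  scans counts against agreement, matching what test–retest
  repeatability is meant to measure); the consistency variant ICC(3,1)
  is available.  The estimator is validated against
  `pingouin.intraclass_corr` in the test suite.
- **Longitudinal changes**: per-subject scan-averaged thickness feeds a
  one-way repeated-measures ANOVA over visits (via `pingouin.rm_anova`,
  cross-checked against `statsmodels.AnovaRM`; Greenhouse–Geisser
  correction available by flag, off by default) plus paired t-tests on
  the four consecutive-visit intervals, Bonferroni-corrected over the
  number of intervals the layer supports (four, or three for the flap,
  which has no pre-operative value).
- **Group comparison**: pooled-variance Student t interval by default
  (Welch optional) on the difference of group means, from either raw
  cohorts or published summary statistics.
- **Sample size**: smallest n whose exact noncentral-t power reaches
  the target, for one-sample/paired or two-sample families, one- or
  two-tailed (validated against `statsmodels` power solvers; noncen-
  trality beyond the reach of `scipy.stats.nct` short-circuits to
  power 1).  At d = 1.0, α = 0.05, power 0.95 the paired one-tailed
  configuration gives n = 13; the two-sample two-tailed one gives 27
  per group — worth knowing, because published planning statements
  often omit the family.

## Numerical choices and degenerate inputs

- Sample SDs use ddof = 1 throughout.
- Apex ties (flat cornea) resolve to the midmost tied column; the even
  128-column exclusion is left-biased around its centre.
- Zero total variance makes the ICC undefined (error); fewer than two
  differences, three subjects, or three visits raise insufficient-data
  errors rather than returning NaNs.
- A blank or corneless image fails at surface tracing or peak
  assignment with explicit QC flags, feeding the pipeline's QC report;
  by default the analysis excludes such scans and reports them, and a
  strict mode halts after writing QC.
- Identical design + seed reproduces cohorts, rasters, and every CSV
  byte-for-byte (a single NumPy `default_rng` stream per artefact).

## Problem sizes used in validation

The accuracy study segments 50 native-geometry B-scans (alternating
pre/post-operative, randomized study-plausible thicknesses, full
speckle and artifacts) and pools absolute thickness errors over all
layers; Monte-Carlo recovery of the agreement statistics uses 200
replicate study-sized cohorts, and the null-rejection study of the post
hoc test uses 250 replicates at n = 15 — sizes chosen so each check's
Monte-Carlo standard error is small against the tolerance it enforces.

## Known limitations

Segmentation operates on averaged regional profiles, not per A-scan, so
it yields one central measurement per scan rather than a thickness map;
microdistortion can be simulated but no distortion-counting statistic
is implemented; no mixed-effects modelling of the longitudinal data;
the synthetic-to-real gap listed under the cohort simulator applies to
every accuracy figure.
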