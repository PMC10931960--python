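# Methods

## Coordinate conventions and geometry

All inputs are pixel coordinates with the origin at the top-left image
corner, x along columns and y increasing downward.  The gravity line is
the image vertical, which assumes a standing, plumb acquisition.  PT is a
pure angle, so no mm-per-pixel calibration is needed and every output is
invariant under translation and uniform scaling of the coordinates;
rotating the image by θ shifts every PT by −θ under the default sign
convention (a property the tests assert).

Posterior tilt is positive.  Radiographs may face either direction, so
the x direction that is anatomically posterior is a per-dataset flag
(`neg_x` default).  The signed angle of a body line is computed with
`atan2` of the (sign-adjusted) horizontal run over the vertical rise from
the inferior to the superior endpoint; the superior endpoint must be
strictly above the inferior one, otherwise an orientation error is
raised rather than returning an angle outside (−90°, 90°).

The femoral-head centre under the calculation method is the exact
circumcentre of each 3-point contour — three points determine the circle,
so a least-squares fit would return the identical point with more
machinery — and the bicoxofemoral centre is the midpoint of the two head
centres, the symmetric choice matching spinopelvic convention.
Collinearity is judged scale-free: a contour triangle whose area is below
1e−6 × (longest side)² raises a degenerate-geometry error naming the
landmark.  The anatomical (ASIS–pubis) line uses the pubic tubercle as
the inferior and the ASIS centre as the superior endpoint and exists only
from clicked points.

## Majority-rule review semantics

Reviews are recorded per (image, assessor, review-level landmark), where
review-level landmarks are the six derived quantities that feed the
parameters (ASIS centre, pubic tubercle, femoral centre cal/est, sacral
midpoint cal/est).  The calculated femoral centre stands for both head
contours: flagging it excludes the calculated PT_m without recording
which head's contour was at fault.

Resolution applies three *independent* clauses at a configurable k-of-n
majority (default 2-of-3, where ties are impossible):

- landmark-wise: ≥k assessors flagged ≥1 annotation of the landmark;
- reason-wise: ≥k assessors cited the same reason for the landmark,
  counted at landmark level regardless of which annotator each assessor
  attached the reason to;
- exclusion: ≥k assessors flagged the same annotator, regardless of
  reason agreement.

Because the clauses are independent, no ordering between the landmark-wise
and reason-wise tables is guaranteed (two assessors citing the same reason
for different annotators trip the reason clause but exclude nobody); the
tests construct such a case deliberately.  A flag attached to a landmark
excludes only that landmark's parameter, not the whole image, even for
image-level reasons such as axial rotation filed under "other".

## Comparison statistics

Case series are per-image means over included annotators; an image whose
annotators are all excluded for a parameter is dropped from both series
for that parameter (pairwise deletion).  The paired statistics are
Pearson r (with verbal bands poor < 0.3 ≤ fair < 0.5 ≤ moderate < 0.6 ≤
moderate-strong < 0.8 < very strong; the cut-points are open intervals in
the convention they come from, so exact boundary values are assigned to
the lower band), mean and maximum absolute difference, a 95% interval,
and a two-sided paired t-test.  The interval defaults to Bland–Altman
limits of agreement, mean ± 1.96·SD(diff): reported intervals of roughly
±2° around a near-zero mean difference of ~0.4° are consistent with
limits of agreement and not with a standard-error CI at n ≈ 115.  The
SE-based CI (t critical value) is available via `ci="sem"`.  Identical
series (zero-variance differences) report p = 1 and a zero-width
interval rather than NaN.

ICC uses the two-way ANOVA mean squares directly: ICC(2,1) =
(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n), the absolute-agreement
single-measurement form appropriate for comparing a measurement series
against an external reference; ICC(3,1) (consistency) is available by
flag.  The implementation is cross-checked in the tests against
pingouin's `intraclass_corr` and against hand-looped ANOVA sums.

## Synthetic studies

The generator builds a 2-D stick-figure pelvis per image — no pixel
rendering, since the pipeline consumes coordinates.  Template distances
are pixels at an EOS-like sagittal scale of roughly 0.36 mm/px: femoral
head radius 70 px (~25 mm), head separation 30 px, femoral-centre to
sacral-midpoint distance 300 px (~110 mm), endplate half-width 70 px,
ASIS and pubic distances 160 px each along the anterior-pelvic-plane
line.  These magnitudes are configuration, not science; they matter only
through the lever-arm lengths that convert pixel noise into angular
noise.  Default true tilts are PT_m 13°, PT_a 6°, with a per-image
uniform jitter of ±5° — a plausible adult spread.  Contour points sit at
fixed, well-spread angles (20°, 140°, 260°) on each head circle so the
circumcentre does not amplify noise through a narrow arc.  The noiseless
landmark set inverts the measurement exactly (round-trip to 1e−9°,
asserted per variant).

Corruption follows the reason taxonomy the assessors use:

- Gaussian jitter, σ = 1 px per landmark by default;
- outliers, per (annotator, image, landmark) with landmark-specific
  probabilities (defaults weighted toward the clicked ASIS and femoral
  centre, where single-click failures dominate in practice), displacing
  the whole landmark by 30–60 px; the ASIS outlier is purely lateral,
  emulating the overlooked-contralateral-side failure;
- bad-quality images (p = 0.15) multiply every σ by 3;
- anomalous images (p = 0.07, near the reported prevalence of
  lumbosacral transitional anatomy) shift the apparent sacral endplate
  25 px so every annotator marks the offset plate.

Every injected corruption is written to a ledger keyed by image,
annotator and review-level landmark.  Assessors are modelled as a
distance threshold (default 15 px) on the *derived* review-level
positions relative to truth, with an independent verdict-flip
probability (default 0.05); flag reasons are looked up in the ledger
(outlier → outlier, anomalous image's sacral landmarks → anomaly,
bad-quality image → bad quality, otherwise → other).  Setting the flip
probability to 1 exactly complements every verdict at a fixed seed, which
the tests use as a determinism check.

What the generator does *not* emulate: real bone-contour appearance,
annotator experience effects, correlated errors across landmarks of one
image, BMI or implant covariates, and any 3D→2D projection.  Passing
tests therefore demonstrate that the pipeline's arithmetic and logic are
correct and that exclusion improves accuracy under the stated noise
model — not that the noise model matches any particular clinic's error
distribution, about which no claim is made.

## Problem sizes and determinism

The simulated studies in the tests and the acceptance script use 100–200
images × 5 annotators × 3 assessors, matching the scale of a real
single-centre series while keeping runs in seconds.  All randomness flows
from a single integer seed through `numpy.random.SeedSequence`, which
derives independent sub-seeds for truth generation, corruption and
assessment; identical seeds give byte-identical CSV outputs.

## Known limitations

- The sign of PT_a relative to a neutral anterior pelvic plane is not
  standardised here; only the generic signed angle is exposed.
- Reason-wise majorities are counted at landmark level; a stricter
  annotation-level reading would attach the reason to the flagged
  annotator and can give smaller counts.
- The exclusion rule never removes a whole image, even when a flagged
  reason (e.g. axial rotation) plausibly affects every landmark.
- `compare` requires ≥3 aligned pairs and refuses smaller inputs rather
  than returning unstable statistics.
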