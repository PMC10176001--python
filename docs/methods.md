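# Methods

This note documents the models, parameters and numerical choices behind
`mapresponder`, in enough detail to judge what a passing test suite does and
does not establish.

## Map construction

A mapping session is a set of stimulation events (xᵢ, yᵢ, zᵢ): a scalp
coordinate in vertex-referenced centimeters (x mediolateral, y
anteroposterior) and the peak-to-peak MEP amplitude zᵢ (mV) that pulse evoked.
Events closer than 0.05 cm are merged by averaging amplitude (a triangulation
needs unique vertices). The merged points are Delaunay-triangulated and
linearly interpolated (scipy's `LinearNDInterpolator`) at the centers of the
50 × 50 = 2500 partitions tiling the 5 × 7 cm grid; partition (i, j) maps to
the center of the half-open cell ((j+0.5)/50 · width, (i+0.5)/50 · height),
row 0 posterior, column 0 medial. Partition centers outside the convex hull
of the stimulated coordinates receive 0 mV (no extrapolation), and the
surface is floored at 0.

Partitions exceeding 25% of the surface peak are **active**. The peak is the
maximum of that session's interpolated surface — a per-map reference; a
per-participant-across-sessions reference is a one-line change if a study
defines it that way. Area, volume and CoG are computed over the active set
only, matching the "active partition" construction; restricting the CoG to
the suprathreshold region keeps it from being dragged by near-zero
out-of-hull mass. Consequences worth knowing:

* scaling every amplitude by c > 0 leaves the active mask, area and CoG
  unchanged and scales volume by c (relative threshold);
* translating all coordinates and the grid together translates the CoG and
  leaves area/volume unchanged;
* the active-partition count is monotone non-increasing in the threshold.

Fewer than three usable points, or a collinear set, is an error, not a
degenerate map. Percent changes are signed, 100·(post − pre)/pre, and require
a positive baseline.

## MEP extraction

Peak-to-peak amplitude is max − min of the samples in a 10–60 ms
post-stimulus window (hamstring MEP latencies sit near 20–30 ms; the window
is configurable since no standard exists). Background contraction is
summarized as the RMS of the 50 ms before the stimulus. Frames with
non-finite samples are rejected; frames whose pre-stimulus RMS deviates more
than 50% from the participant-session median are rejected as inconsistent
contraction. Rejected frames are excluded from mapping and logged.

A response is **discernible** when its amplitude strictly exceeds
max(0.1 mV, 2 × pre-stimulus RMS) — an active-contraction convention; the
rule object is replaceable. The active motor threshold (aMT) is the lowest
intensity on an ascending 1% grid whose 10-pulse train yields ≥ 5 discernible
MEPs; the baseline aMT is carried to follow-up sessions (mapping intensity is
bookkeeping only — amplitudes are never intensity-normalized). The hotspot is
the coordinate of the largest single MEP, first occurrence winning ties.

Peak-to-peak is a biased-up estimator in noise: the extremes of ~100 samples
of band-limited background add roughly 4.6 × RMS to an empty window. This
matters wherever weak true responses meet a relative threshold (see the
background-level default below).

## Responder classification

Per metric (volume, area), the control group's signed percent changes give a
reference band: mean of |Δ| plus 1 sample SD (n−1), requiring ≥ 2 controls.
An experimental participant's signed change is compared symmetrically:
strictly above +band → facilitator; at or below −band → depressor (the
depression criterion is inclusive, the facilitation one strict — an exact hit
on +band is a nonresponse); otherwise nonresponder. The signed-vs-band
reading is the only one under which facilitation and depression are both
detectable, and the boundary asymmetry mirrors the usual phrasing
("greater than 1 SD above" vs "at least 1 SD below"). Controls are
nonresponders by construction. Reported percentages use
round-half-away-from-zero (12/26 → 46%).

## Statistics

The 2 × 2 mixed ANOVA partitions sums of squares into a between-subjects
stratum (a one-way ANOVA of subject means, scaled by the number of time
levels) and a within-subjects stratum, where time and group × time effects
are estimated with sum-to-zero contrasts via model comparison — Type III, so
unbalanced groups (26 vs 10) test unweighted-mean hypotheses, as SPSS-style
GLM repeated measures would. Useful identity for two time levels: the
interaction F equals the squared pooled two-sample t on change scores.

Greenhouse–Geisser ε is computed generically from the eigenvalues of the
orthonormally-contrasted covariance (ε = tr(M)²/((k−1)tr(M²))), as is
Mauchly's W; with two repeated levels both are vacuous (ε = 1, W = 1) but the
machinery extends to longer designs. Shapiro–Wilk runs per group × time cell.
Incomplete participants are dropped listwise per outcome and counted.

Pooled two-sample t-tests accept either raw samples or published summary
statistics (mean, SD, n per group) — the latter lets printed tables be
re-verified exactly: df = n₁+n₂−2, MD = m₁−m₂, CI₉₅ = MD ± t₀.₉₇₅,df · SE.
Zero pooled variance with a nonzero MD reports an infinite t with a warning
rather than crashing. Sidak adjustment is p' = 1−(1−p)^m capped at 1.
Pearson correlations carry a magnitude band: |r| < 0.3 weak, 0.3 ≤ |r| ≤ 0.5
moderate, |r| > 0.5 strong (closed moderate interval; the band is a function
of |r| since "strong" conventionally applies to r = −0.56 as much as +0.56).

Correlations between map changes and outcome changes are computed on
baseline→Day-2 change scores by default (`correlate_on="change"`); Day-2
levels are a config switch, since published correlation tables often leave
this ambiguous.

## Synthetic cohort model

Each participant's corticomotor representation is a Gaussian bump
S(x, y) = floor + A·exp(−((x−cx)² + (y−cy)²)/(2σ²)). Day 2 applies a
multiplicative peak gain, a spread factor and a center shift. Defaults
(chosen once, as the study conditions the generator emulates):

| parameter | default | rationale |
|---|---|---|
| peak amplitude A | ~N(1.2, 0.3) mV, > 0.4 | typical hamstring MEPs at 110% aMT |
| spread σ | ~N(0.9, 0.1) cm | active region ≈ 1.67σ ≈ 1.5 cm radius |
| floor | 0.05 mV | keeps all sites responsive, above the 0.02 mV discernibility floor so the noise-free limit is exact |
| cohort | 26 experimental / 10 control | the asymmetric RCT allocation the design assumes |
| regimes | 12 facilitation / 12 depression / 2 none | facilitation gain 2.0·LogN(0, 0.35), spread ×1.25·LogN(0, 0.15); depression gain 0.5·LogN(0, 0.35), spread ×0.8·LogN(0, 0.15) |
| control Day-2 gain | N(1, 0.05) truncated > 0 | stable controls |
| Day-2 shift | experimental \|N(1.2, 0.8)\| cm, control \|N(0.4, 0.1)\| cm | representational displacement scales |
| trial noise | LogNormal(0, 0.15²), multiplicative | calibrated so control \|Δvolume\| ≈ 9% ± 3% and \|Δarea\| ≈ 12% ± 7% |
| stimuli | 90 per session, every one of the 48 sites covered, ≤ 0.2 cm jitter | hand-held pseudorandom delivery |
| EMG background | 0.02 mV RMS, 20–950 Hz band-limited | 10%-MVC contraction; see below |
| MEP waveform | derivative-of-Gaussian, onset 20 ms, duration 15 ms | typical hamstring latency; configurable |
| PPT | baseline N(600, 150) kPa; ΔPPT = slope·ΔV% + N(0, 80 kPa) | slope defaults to the value giving population r ≈ −0.56 against the cohort's ΔV spread (`slope_for_target_r`) |

Day-2 shifts are constrained to keep the suprathreshold bump inside the grid
(direction resampled, magnitude truncated at an interior margin of ~1.67σ):
a representation the grid no longer covers yields a volume collapse that is a
coverage artifact, not a corticomotor change.

The EMG background default deserves its own note. At 0.05 mV RMS the
peak-to-peak noise floor (~0.23 mV) exceeds the 25%-of-peak threshold of
depressed Day-2 maps, so extraction inflates weak sites, depression is masked
and the control band widens well past its calibration target. 0.02 mV RMS —
equally realistic for well-prepared surface EMG at low contraction levels —
keeps the noise floor below threshold. Users simulating noisier recordings
should expect exactly this bias; it is a property of peak-to-peak estimation,
not of the mapping.

Behavioural outcomes are drawn from truncated distributions at the
group-level Day-2 profiles of the emulated design (e.g. experimental NRS at
rest 1.3 ± 1.2, soreness 4.5 ± 1.8 on the integer 0–6 scale, pain area
25.9 ± 16.6; control pain outcomes exactly zero or Bernoulli(0.2);
LEFS/MVIC with experimental-group Day-2 decrements), respecting instrument
ranges (NRS 0–10, soreness 0–6, LEFS 0–80).

All randomness flows through explicitly passed `numpy.random.Generator`
objects; a cohort seed is fanned out deterministically per participant and
stage via `SeedSequence.spawn`, so a fixed seed reproduces every file
byte-for-byte.

### What the generator does *not* emulate

Real scalp geometry (the grid is a flat plane), coil orientation effects,
aMT drift between sessions, non-Gaussian or multi-peaked representations,
EMG artifacts (stimulus artifact, movement, ECG), missing data, and any
biomechanics of eccentric exercise — group membership is a label with outcome
distributions. Tests passing on synthetic cohorts therefore certify the
*pipeline arithmetic and its statistical calibration*, not the physiology.

## Numerical choices and degenerate inputs

* Interpolation queries off the convex hull → 0 (conservative; makes area
  well defined on the full 35 cm² frame).
* Zero total active amplitude → CoG is an error, not NaN.
* ANOVA F-ratios use a scale-aware tolerance so constant data reports F = 0
  rather than 0/0 noise; zero pooled variance with a nonzero effect reports
  F = ∞.
* Hotspot ties break by trial order; classification boundary ties follow the
  strict/inclusive asymmetry above.
* Problem sizes in the test suite (cohorts of 8–36 participants, 50–100
  random oracle instances, 300–500 simulation replicates) were chosen to make
  Monte-Carlo assertions statistically decisive at the stated tolerances.

## Known limitations

* The mixed ANOVA supports exactly two between-factor levels (the designs it
  serves); the within factor is general.
* Map metrics are not invariant to the grid's partition resolution below
  ~30 × 30; 50 × 50 is the assumed operating point.
* The discernibility rule's 0.1 mV floor and 2×RMS multiple are conventions,
  not estimates; studies with different contraction levels should recalibrate.
* `percent_change` is undefined for zero-baseline maps — a participant whose
  baseline map has no active partitions cannot be classified (flagged and
  excluded, never imputed).
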