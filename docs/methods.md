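# Methods

`grazetrack` re-implements, as a tested pipeline, the video-based
quantification of benthic grazer foraging used in flume grazing
experiments: colour-marker detection, identity linking, movement-state
classification, grazed-area measurement, CHEMTAX-style pigment unmixing and
the statistical layer of a two-factorial (phosphorus x grazing) design.
Because raw footage and raw assay tables from such experiments are rarely
deposited, the package ships a synthetic scene generator with full ground
truth; every estimator is validated by parameter recovery against that
truth, and the published summary statistics double as generator defaults.

## Synthetic scenes

**Geometry.** One flume is 62 x 8 cm with a centred 3 x 10 tray of
2.3 cm ceramic tiles (158.7 cm^2 of substrate). Individual tiles can be
flagged as removed (sampled before the grazing phase); removed tiles render
as tray floor and are excluded from the substrate area. Frames are rendered
top-down with pixel coordinate = pixel index (origin top-left), at
`px_per_cm` resolution.

**Movement model.** The literature describing this workflow classifies
grazer speed into resting (0 to < 0.4 cm/h), slow (0.4-4 cm/h) and fast
(> 4 cm/h) but does not specify a generative movement model, so the
generator uses the simplest model that makes those latent states
recoverable: a three-state Markov chain per frame interval with per-state
uniform speed supports and von Mises heading persistence (a state-switching
correlated random walk). The speed supports are required to lie strictly
inside the classifier bands, so the latent state is identifiable from a
noise-free speed measurement by construction; supports narrower than the
bands (e.g. resting up to 0.36 cm/h) leave a margin that absorbs sub-pixel
centroid error. Initial states are drawn from the chain's stationary
distribution.

**Walls.** Nets confine grazers, so the walk reflects: if a proposed
straight step would exit the flume, the offending heading component is
flipped before the step. Reflecting the *heading* rather than folding the
path keeps the per-interval net displacement exactly equal to
speed x interval, so ground-truth displacements always lie inside the
generating state's speed band — the property every classifier test relies
on. This requires the largest possible step to be under half the free flume
extent, which holds for every shipped profile and is checked at simulation
time.

**Rendering and grazing footprint.** Each grazer is drawn as an
anti-aliased disc of the marker colour (default pink, RGB 255/82/168) at
its continuous position; coverage-weighted blending keeps the disc-centre
pixel exactly the marker colour. Biofilm within `mouth_radius_cm` (default
0.25 cm) of any visited position becomes bare tile, accumulated monotonely
over frames and clipped to the substrate mask; the rendered bare region *is*
the returned ground-truth grazed mask, so rendering-then-measuring is exact
by construction. An optional light:dark cycle dims frames (off by default:
whether cameras record through the dark phase is an open question in the
source workflow, and the simulator records continuously).

**Profiles.** The desk profile — used by all tests — simulates 2 h at 15 s
frames (481 frames of 310 x 40 px at 5 px/cm, 8 grazers). A full
experiment-scale profile (14 days, area sampling every 12 h) exists but is
deliberately not exercised by the test suite; all quoted recovery numbers
refer to desk-scale problem sizes (a package design choice: the estimators
are scale-free, and the desk profile already exposes every failure mode the
estimators have).
The classification tests use a boundary-resolvable profile (20 px/cm,
15-min frames, speed supports with wider margins, uncorrelated headings) in
which per-interval displacements at the category boundaries span multiple
pixels; at the native 15-s/5-px-per-cm scale the 0.4 cm/h boundary is
deeply sub-pixel, which is a property of the original recording geometry,
not of the classifier.

**Assay tables.** Elemental and pigment tables are drawn per treatment from
configurable normal distributions truncated at zero (defaults: molar C:P
144 +/- 26 for P+ vs 316 +/- 68 for P-; dry mass 1.91 +/- 0.15 vs
0.72 +/- 0.29 mg cm^-2 pre-grazing, the four-cell 2 x 2 means post-grazing;
diatom share 49 +/- 18 % vs 94 +/- 2 % of chl a). C and P masses are
constructed so each row's molar C:P equals its drawn ratio exactly. Pigment
rows are group-abundance vectors times the ratio matrix with independent
multiplicative lognormal noise (default CV 5%); the generating abundances
are returned as ground truth.

## Estimators

**Detection.** Plain RGB matching (Euclidean distance, default tolerance 60
on the 0-255 cube; per-channel mode available) followed by 8-connected
component extraction with sub-pixel centroids (arithmetic mean of member
pixel indices). Blob-size gates default to 25-400% of the expected marker
disc area. 8-connectivity keeps anti-aliased disc rims in one component.

**Linking.** Per frame, tracks are matched to detections by globally
optimal bipartite assignment (Hungarian algorithm) on Euclidean distance —
the well-defined form of the "shortest distance in consecutive frames"
rule, coinciding with it for well-separated slow movers. A pair is feasible
within a gate of `max_step_px x (gap + 1)`, so tracks that miss detections
are recaptured with a linearly growing search radius; gaps are stored
explicitly (never interpolated). Ties break towards lower track id, then
lexicographically smaller detection coordinates, via epsilon cost offsets
(1e-7 px per track index, 1e-9 px per detection rank) that are far below
any physically meaningful distance difference. Identity correctness is only
guaranteed for non-crossing motion; `simulate_noncrossing` redraws a scene
until all pairwise distances exceed a separation threshold, making the
100%-identity check well-posed.

**Kinematics.** Speed = Euclidean displacement between consecutive
*observed* entries divided by the spanned time (gap-spanning intervals use
the full elapsed time). Categories follow the published bands with the 0.4
boundary assigned to "slow" (the stricter caption form `0 to < 0.4`), i.e.
resting [0, 0.4), slow [0.4, 4], fast (4, inf) — a total function on the
non-negative reals. A "detection" in the per-flume tallies is one
classified grazer x frame interval; unobserved intervals are not counted in
any category. An optional positional smoothing window exists (default 1 =
off).

**Grazed area.** Bare ceramic is much brighter than biofilm, so grazed
substrate is segmented by luminance difference against an intact-biofilm
baseline (reference frame or scalar), restricted to the substrate mask,
with Otsu's threshold as fallback when none is given (a near-zero-contrast
difference image short-circuits to all-intact / all-grazed to keep the Otsu
fallback off noise). Exactly-matched marker pixels are excluded from
thresholding and then classified like their nearest visible neighbour
(Euclidean distance transform): the substrate under a grazer is
unobservable, and its neighbourhood is the best available evidence.
Components smaller than 4 px are removed. Pixel counts convert to cm^2 via
`px_per_cm` calibrated from the known 2.3 cm tile side. On desk-scale
scenes the final-area recovery error is a few percent; the residual error
comes from anti-aliased trail rims and the occluded-pixel fill, both of
which shrink with resolution.

**Pigment unmixing.** Per sample, group abundances (chl-a-equivalent units)
solve a non-negative least-squares problem against the groups x pigments
ratio matrix; rms is the root mean squared residual over all table entries
(unweighted — a per-sample-normalised variant exists as a fit on scaled
inputs). The ratio matrix is refined iteratively: each iteration evaluates
60 candidates (the unperturbed current matrix plus 59 copies whose
non-zero, non-chl-a entries are jittered by independent uniform factors in
[1-0.35, 1+0.35]), keeps the 6 lowest-rms candidates (10%) and averages
them elementwise into the next proposal. Candidates are regenerated every
iteration. The estimate returned is the lowest-rms matrix ever evaluated
(best-so-far), not the final average: selection-averaging is a good
proposal generator but averaging always mixes perturbed matrices into the
estimate, so the average cannot reach the exact solution even on noiseless
self-consistent input, while the best-so-far does (and makes the logged rms
non-increasing by construction). "Stable" is quantified as a relative
change below 1e-4 in both the best rms and the best matrix between
consecutive iterations. The chl-a column is pinned at 1 and structural
zeros are preserved throughout, as in standard CHEMTAX practice; one ratio
matrix is fitted per treatment group of samples.

The default pigment library (two groups, ten pigments) carries a full
accessory-pigment signature per group — fucoxanthin, chl-c2,
diadinoxanthin, diatoxanthin for diatoms; chl-b, lutein, zeaxanthin,
violaxanthin, neoxanthin for chlorophytes. The breadth is deliberate:
composition identifiability under multiplicative noise improves roughly
with the root of the number of informative pigments, and with only one or
two markers per group the per-sample composition noise floor under 5%
pigment noise exceeds 5 percentage points even when fitting with the true
matrix. The shipped values are plausible field-style ratios meant to be
edited, not measurements. Recovery claims are therefore stated at the
treatment-mean level (within 5 points of the generating composition from a
+/-20%-distorted start under 5% noise); single samples at a ~50/50 split
can deviate by more than 5 points for any method, true matrix included.

**Stoichiometry and statistics.** Molar C:P = (C/12.011)/(P/30.974).
Percent reduction and per-individual grazing rate
((control - grazed) dry mass x substrate area / (grazers x hours), negative
differences clipped to 0 with a warning) take their area and duration as
explicit parameters. Two-group comparisons: Student (pooled variance),
Welch (Satterthwaite df) — both accept raw samples or printed
mean/SD/n summaries, which makes published t statistics reproducible
without raw data — and Wilcoxon-Mann-Whitney with exact enumeration for
min(n) <= 8 (ties fall back to the normal approximation without continuity
correction; both p values are always reported). The balanced 2 x 2 ANOVA
(type I = type II) and Tukey HSD are delegated to statsmodels; Shapiro-Wilk
and Levene (centre = mean) to scipy. No multiple-testing correction is
applied, matching the reporting convention of the experiments this mirrors.

## Pipeline and reproducibility

`run_pipeline` executes simulate -> render -> detect -> link -> classify ->
area -> assay -> unmix -> stats for all four treatments, writing plain CSV
intermediates so any stage can be re-run standalone or fed real footage.
Grazer-free flumes skip tracking and kinematics; their area series is still
measured (zero by construction). Flume-level seeds derive from the global
seed by fixed offsets; a fixed seed reproduces every output file bitwise. A
failing flume is recorded in the manifest and does not abort the run. The
CLI (`grazetrack simulate|detect|track|classify|area|unmix|stats|run-all|report`)
is a thin layer over these functions.

## What the synthetic scenes do not emulate

Biofilm growth and regrowth, hydrodynamics, grazer-grazer interaction,
appearance changes of the marker, lens distortion, lighting drift and
manual-selection subjectivity are all absent. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated image
formation model, not robustness to real-footage nuisances. Crossing
trajectories are explicitly outside the identity guarantee; real deployments
should check the non-crossing assumption (slow movers, sparse stocking)
before trusting per-individual statistics.
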