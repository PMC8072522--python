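# Methods

This note documents the models and procedures implemented in `strokeconn`,
the parameters that matter, what the synthetic cohorts do and do not
emulate, and the design choices made where the design was genuinely open.

## Preprocessing model

**Frame-wise displacement.** The realignment-parameter table (three
translations in mm, three rotations in radians) is summarized per frame as
the Power composite FD_t = Σ|Δd| + r·Σ|Δθ|, with sphere radius
r = 50 mm (configurable). The first frame's FD is 0. Rotations may be
supplied in degrees via a flag. Frames are censored when FD > 0.5 mm or
when the global percent BOLD change — 100·|g_t − g_{t−1}| / mean(g), with
g the within-brain-mask mean intensity — exceeds 50. Only flagged frames
are censored; neighbour padding is available (`censor_pad`) but defaults
to 0. The *mean* FD (over all frames, censored included) is the motion
nuisance covariate used downstream.

**Confound regression.** The per-run design is: intercept, the six
realignment parameters, one indicator column per censored frame (so each
censored frame's residual is exactly zero), and k = 5 principal-component
time series each from the white-matter and CSF compartments (aCompCor).
Components are computed from the temporally demeaned voxel×time matrix by
SVD, which makes them exactly zero-mean and orthonormal; the sign is fixed
by making each component's largest-magnitude spatial loading positive.
Global-signal regression is deliberately absent — the aCompCor strategy is
used precisely to avoid it. Rank-deficient designs fall back to the
pseudo-inverse with a warning.

**Band-pass.** Residuals are filtered with a hard FFT mask keeping
frequencies in [0.009, 0.08] Hz. A hard mask was chosen over a Butterworth
filter for exact band edges, exact idempotence and testable spectra.
Censored frames are linearly interpolated before the transform (so
artefact energy cannot leak into the pass band) and remain flagged:
correlations later exclude them outright. Regression-then-filter ordering
is used; filtering first (or simultaneously) is a known alternative, and
the difference is the non-commutativity of the two projections, which is
small when the confounds are slow relative to the band.

**Order of extraction and denoising.** Both confound regression and the
FFT filter are linear and identical across units, so they commute with
spatial averaging. The pipeline therefore extracts lesion-masked ROI mean
series from the raw BOLD first and denoises the 106 series, which is
mathematically identical to denoising every voxel and then averaging, at a
fraction of the cost. (The aCompCor components are computed from tissue
voxels either way.)

## Lesion handling

Lesion masks are subtracted from every ROI voxel set, making the atlas
subject-specific. An ROI left with zero voxels is *unavailable*: its
matrix rows, index memberships and model rows propagate as missing values
(pairwise exclusion), never as zeros. The unmasked variant
(`lesion_masking: false`) reproduces the robustness analysis in which
lesioned voxels are retained.

To pool patients with left- and right-sided lesions, stroke matrices are
reoriented by swapping homologous ROI pairs so the lesioned hemisphere
always occupies the canonical side. Canonical side = right, matching the
majority lesion side in the emulated design; the choice is exposed in
config. Controls are never flipped. Midline/unpaired ROIs are fixed points
of the flip and belong to no compartment. The flip is an involution and
commutes with correlation, which is tested.

## Selection and indices

Connection-wise, baseline Fisher-z values are regressed on group
(healthy = 0, stroke = 1, so negative coefficients mean stroke < healthy)
plus mean FD; the group coefficient's two-sided t p-value (df = n − 3)
feeds a Benjamini–Hochberg correction applied *within each seed's row*
(m = finite entries in that row). A connection is selected if it survives
in at least one of its two rows — the common toolbox convention for
ROI-to-ROI seed-level FDR; a stricter both-rows mode is available. A
zero-variance FD covariate is dropped, in which case the statistic reduces
exactly to the pooled two-sample t. Selected connections are classed by
coefficient sign (a coefficient of exactly 0 cannot be classed and is
dropped with a warning) and assigned to compartments by the hemispheres of
their endpoints in canonical orientation.

The six indices are plain arithmetic means of a subject's available member
z-values per (class, compartment); members with an unavailable ROI are
skipped and `n_connections_used` is reported. An index with no available
members is missing, not zero.

## Treatment-effect model

Per index and contrast (T1→T2, T1→T3), subjects complete for both
sessions enter a linear mixed model: fixed effects session, arm,
session×arm, age, and mean FD averaged over the contrast's sessions;
random per-subject intercept; REML fitting. The session×arm coefficient is
the treatment effect, sign convention (sensorimotor − motor). Covariates
enter as main effects only (not interacted with session); with two
sessions and complete data and no covariates the estimate equals the
between-arm difference of mean change scores exactly, which anchors the
test suite. The change-score least-squares model (Δ ~ arm + covariates) is
the documented fallback when the mixed fit fails and the cross-check
oracle otherwise.

P-values use a t reference with df = n − 2 − n_covariates (the
between-subject denominator df of the equivalent change-score contrast)
rather than the Wald normal reference, which is anti-conservative at
n ≈ 30: in null simulations the normal reference rejected at ~0.095
instead of 0.05, while the t reference is calibrated (~0.06). Multiplicity
is handled by Bonferroni over 6 indices × 3 assessment times:
0.05/18 ≈ 0.00278, reported rounded as 0.003.

**Brain–behaviour.** Spearman partial correlation: x, y and the covariates
(age, mean FD) are rank-transformed; ranked x and y are residualized on
the ranked covariates; ρ is the Pearson correlation of residuals with p
from t on df = n − 2 − n_covariates. This equals the partial correlation
obtained by inverting the 4×4 rank-correlation matrix (tested to 1e−10)
and is invariant to strictly monotone transforms of x and y.

## Synthetic cohorts

The volume-level generator emulates the study design: 19 controls scanned
once and 18 + 12 stroke patients (sensorimotor/motor arms) scanned at T1,
T2, T3; 106 lateralized block ROIs (92 cortical + 14 subcortical, no
cerebellum) on a ~30³ grid; 250 frames at TR = 1.7 s; expected 35%
high-motion frames in patients (5% in controls); two-thirds right-sided
lesions; planted aberrant-connection sets sized to the realized study
counts (inter 12 hypo / 2 hyper, ipsilesional 8/3, contralesional 4/12)
with ∓0.5 z shifts by default; and motor-arm pre-to-post shifts of +0.155
(contra-hypo) and +0.144 (contra-hyper) z at T2, none at T3.

BOLD series are latent ROI signals from a multivariate normal whose
correlation matrix is tanh of a base Fisher-z template (background 0.1)
plus the group/arm/session shifts, broadcast to member voxels, mixed with
voxel noise, WM/CSF confound signals (which also leak weakly into grey
matter, giving aCompCor something real to remove), and additive global
intensity deviations on motion-spike frames. Lesion voxels carry noise
only. Shifted templates are projected to the nearest valid correlation
matrix by eigenvalue clipping; with strong shifts this projection can
induce small off-target correlation differences on unplanted pairs, so
recovery experiments score planted pairs only.

Motion: realignment tables are a low-amplitude random-walk drift plus
persistent step "spikes" sized so exactly the spiked frame exceeds 0.5 mm
FD. Each subject's spike rate is drawn from a Beta distribution
(concentration 15) around the group rate: real cohorts show wide
between-subject spreads of scrubbed-frame fractions, and a degenerate
constant rate would make mean FD collinear with group, which no real data
exhibit. Spike frames also receive a global intensity deviation
(default 30 Δ%, configurable above the 50 Δ% criterion).

Behavioural scores are a generic linear-plus-noise stand-in: per-subject
change = coupling × (true index change) + noise, with the true index
change being the arm effect plus a per-subject N(0, 0.1²) response
deviation. Ages are drawn with the emulated arm imbalance (sensorimotor
older), and age has a small true effect on change; since the mixed model
enters age as a main effect only, a ~−0.011 residual confounding bias
remains in the −0.15 recovery experiment — a deliberate illustration of
the covariate-specification limitation, well inside the ±0.03 tolerance.

What the generator does **not** emulate: anatomy, haemodynamics, spatial
autocorrelation, scanner noise physics, dropout/registration error, and
any distributional claim about the study's behavioural instruments.
Passing tests therefore demonstrate the correctness and calibration of the
*analysis machinery* under the design's statistical structure, not
performance on real clinical data.

**Determinism.** Every subject gets an RNG stream derived from
(seed, subject index) and every session from (seed, subject, session), so
cohorts are byte-reproducible and stable under partial regeneration.

## Problem sizes used in tests and calibration

Simulation studies run at desk scale, chosen to keep the full suite and
the acceptance script in the tens of seconds while leaving ample power:
null selection calibration at 40 ROIs, 20+20 subjects, 160 frames, 100
replicates; planted-connection recovery (−0.6 z on 5 pairs) at 15+15, 50
replicates; treatment-effect recovery/type-I at 18+12 subjects, 200
replicates each; the end-to-end demo cohort at 20 ROIs on a 16³ grid with
6 controls and 5+5 patients at 200–250 frames. The full-size defaults
(106 ROIs, 30³ grid, 19/18/12 subjects) are generated the same way, only
larger.

## Numerical choices and degenerate inputs

- Correlations are clipped to |r| ≤ 1 − 1e−7 before atanh; diagonals are
  stored missing, never ±∞. Correlation matrices are symmetrized to the
  last ulp before the transform.
- Fewer than 3 uncensored frames, an empty tissue mask, an arm with fewer
  than 2 complete subjects, or a group with no data for a connection raise
  explicit errors; zero-variance ROIs and rank-deficient designs degrade
  gracefully with warnings.
- The FDR step uses Benjamini–Hochberg per seed row via statsmodels;
  brute-force enumeration serves as the oracle in tests.
- The pipeline writes TSV/JSON intermediates per stage; every stage can be
  re-run from the previous stage's outputs, and a run report records the
  config hash and seed.

## Known limitations

- The "50 Δ% BOLD" scrub criterion is operationalized as global
  percent-change between adjacent frames; toolchains differ here and some
  use a z-scored global-signal criterion.
- Seed-level FDR's "survives in ≥ 1 of its two rows" rule is a convention,
  not an identity; the both-rows mode is stricter.
- Whether matrices should be hemisphere-flipped before or after the
  selection contrast — and whether controls should be flipped at all — is
  not uniquely determined; selection honours the configured orientation
  (flip stroke only, by default).
- With two sessions per contrast the mixed model adds little over the
  change-score model; it is retained as the primary estimator for
  structural fidelity, with the equivalence exploited as a test oracle.
- Repository shape: the project is organised as an analysis (numbered
  drivers over a library) rather than a monolithic CLI; the pipeline
  module's stage functions are the orchestration surface.
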