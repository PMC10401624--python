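# Methods

This note documents the models implemented in `antjump`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
generators do and do not emulate.

## Muscle architecture

PCSA is defined as muscle volume over the arithmetic mean of traced fiber
lengths, so `pcsa * mean_fiber_length == volume` holds identically. The
arithmetic mean is a deliberate choice: fiber-tracing exports give a length
per fiber and no volume weighting, and in the absence of force–length data
no alternative summary (harmonic mean, volume-weighted mean) is better
justified.

Effective PCSA discounts PCSA by the pennation angle, the fraction of fiber
force transmitted along the tendon axis. Two aggregations are provided:

- `mean_angle` (default): `(V/L̄)·cos(θ̄)` — one cosine at the mean angle;
- `per_fiber`: `Σᵢ (V/n)·cos(θᵢ)/Lᵢ` — each fiber carries an equal share of
  the volume. For heterogeneous fiber lengths this is a harmonic-type mean
  that up-weights short fibers and can exceed `V/L̄`; the two modes coincide
  when all fibers share one length. `mean_angle` is the default because the
  inequality `effective_pcsa ≤ pcsa` (equality at zero pennation) only holds
  for it in general, which makes downstream summaries easier to reason about.

Fiber statistics report mean ± sample s.d. (n−1 denominator, matching the
±s.d. convention for traced fiber populations); a single-fiber muscle gets
s.d. 0 with a warning rather than an error. Pennation angles of exactly 0
are legal (parallel-fibered muscle); angles are stored in degrees and
converted to radians only where a cosine is evaluated.

## Size normalization

Metrics are normalized by the expected geometric scaling: muscle volume by
thorax volume (exponent 1), PCSA by V_muscle^0.66, fiber length by
V_muscle^0.33. The defaults are the display exponents 0.66/0.33 rather than
the dimensionally exact 2/3 and 1/3 — reproducibility of reported numbers
first — and the exact values are one config field away
(`PhysiologicalConstants(pcsa_exponent=2/3, fiber_exponent=1/3)`). With the
exact exponents all normalized metrics are invariant under isometric
scaling; with the display exponents a 10× volume change drifts them by
c^(2/3−0.66) and c^(1/3−0.33), which the tests assert analytically.

Thorax volume proxies body mass via a uniform tissue density of
1040 kg m⁻³. The supporting isometry check is an OLS regression of log10
volume on log10 volume with a t-based 95% CI on the slope; OLS is the
default because the reference-axis convention for such data is not settled,
and a reduced-major-axis estimator is provided for users who consider both
axes error-prone. The thorax surface-area proxy used in the alternative
PCSA normalization is V_thorax^(2/3), the unique power-law surface proxy
consistent with isometry.

## Comparative analysis

Fold changes are simple ratios of identically normalized metrics
(jumper/non-jumper), with strict muscle-set matching to prevent comparing
different normalizations. Leg ratios divide each leg by the shortest leg
and round half-up to 1 decimal for display (integer percent for hind-leg %
of body length), because printed ratio tables follow the ordinary half-up
convention; unrounded values are always retained alongside.

The PCA z-scores each column (sample s.d.) and eigen-decomposes the
covariance of the standardized matrix — equivalent to a correlation-matrix
PCA, which is what "centered and scaled absolute volumes" implies.
Component signs are fixed deterministically (largest-|entry| of each
loading vector positive) so results are stable across eigen-solvers.
Group separation on PC1 is an exhaustive interval-threshold check (n = 8
species), not a fitted classifier: the groups are separated iff one group's
scores all lie beyond the other's, and the margin is the gap width.

No phylogenetic comparative methods are attempted: with four independent
origins of jumping and one specimen per species, the design supports direct
paired comparison only.

## Kinematics

A trial is a digitized 2-D CoM track with two annotated events (first
movement of a propulsive leg; last loss of ground contact). Event detection
is deliberately out of scope — annotations come from frame inspection of
the video. Duration is the event difference; mean velocity is net CoM
displacement over duration; take-off velocity is the speed at last contact
from a Savitzky–Golay local-quadratic derivative computed over the stance
segment only. Post-takeoff samples are excluded from the fit because the
motion model changes discontinuously to ballistic flight at lift-off;
including them biases the end-of-contact estimate. The estimator is exact
for noise-free uniformly accelerated motion, including at the segment edge.

The default window is 5 samples (clean tracks); noisy 6000-fps tracks are
analyzed with window 21 (~3.5 ms), the span at which a ~0.5-pixel tracking
noise (σ ≈ 1e-5 m at a typical macro-lens scale of ~20 µm/pixel) leaves the
3-trial mean take-off velocity within 5% of truth. Mean acceleration is
take-off velocity over duration. Because the duration/velocity definitions
in the field are ambiguous, both the net-displacement mean velocity and the
end-of-contact instantaneous velocity are always reported; energetics uses
the end-of-contact value by default.

## Jump energetics

W = ½mv² (gravitational potential energy excluded by default — marginal at
ant scale — with an opt-in m·g·h term), P = W/t. Demands convert to muscle
volumes via conserved muscle properties: work density 70 J kg⁻¹, average
power density 350 W kg⁻¹, muscle density 1040 kg m⁻³. The work-based
volume demand is multiplied by the elastic-storage factor 3: at most one
third of muscle work density can be converted into elastic strain energy
even with an optimal spring, so this is a conservative lower bound for a
recoil-driven jump. Setting the factor to 1 recovers the unbounded direct
work demand.

Classification compares the measured actuator volume with both demands:
meeting the power demand ⇒ `direct_and_elastic_feasible`; meeting only the
×3 work demand ⇒ `elastic_only`; neither ⇒ `infeasible`; no measurement ⇒
`unknown` (deliberately not an error: a species can be representable
without kinematic data). The default "measured" volume is the summed
bilateral mid+hind trochanter-depressor volume, on the assumption that
these muscles provide the primary upward force; `total_muscle_volume`
accepts any muscle subset and side convention, since whether published
totals sum both body sides is not documented. No Hill-type force–velocity
dynamics and no spring/latch mechanics beyond the ×3 bound are modelled.

## Reference observations

`reference_data.py` carries the published *inputs* the pipeline consumes —
body masses, take-off speeds and times, measured depressor volumes for the
three species with jump recordings, and mean leg/body lengths for all eight
study species. Derived numbers (work, power, ratios, classifications) are
always recomputed.

## Synthetic generators

The generators emulate the statistical structure of the upstream exports:

- **Volume tables**: non-jumper muscle volume = baseline relative volume ×
  thorax volume × lognormal noise; jumpers additionally carry per-muscle
  fold changes. The default cast is 4 jumper/non-jumper pairs with the
  observed comparative structure: mid/hind trochanter depressors ×3–5,
  posterior coxal remotors ×0.2–0.6, the mesial mesocoxal remotor enlarged
  ×2–6 (the center of the observed 1.5–10× span), plus lineage-specific
  profiles (petiole levator ×3 in the metasoma-swinging lineage, front-leg
  depressor ×2 in two lineages). Volume noise cv defaults to 0.1,
  comfortably above the intraspecific/segmentation variation seen in
  replicate specimens (an intraspecific-replicate mode with cv 0.05 is
  provided for that error-check design). Thorax volumes scatter lognormally
  (cv 0.1) around 3×10⁻⁹ m³ (a ~3 mm³ thorax, a 10 mm ant).
- **Fiber sets**: lengths lognormal, rescaled so the sample mean equals the
  configured mean exactly — hence V/L̄ recovers the implied PCSA
  identically; angles truncated-normal on [0, 90). Lognormal lengths and
  truncated-normal angles are modelling choices (only means ± s.d. are
  reported for real muscles); both distributions respect positivity/range
  constraints by construction.
- **Take-off tracks**: uniformly accelerated 2-D motion along a fixed
  launch angle, sampled at ~6000 fps (the frame interval is adjusted to the
  nearest divisor of the duration so the last stance sample coincides with
  the annotated lift-off), continued ballistically for a few frames, with
  isotropic Gaussian tracking noise.

All generators are pure functions of (config, seed).

**What the synthetic cast does not emulate.** The cast is similar-sized by
default. The real study species span a ~4× thorax-volume range, and a PCA
of *absolute* volumes confounds body size with group membership: with that
size range and fold changes capped at 3–5×, PC1 becomes a size axis and
group separation degrades, whereas the real data separated because its
largest fold changes reached 8–14×. Passing the synthetic PCA checks
therefore demonstrates that the pipeline recovers a fold-change signal of
the configured magnitude at the configured noise — not that PCA separation
is robust to arbitrary size heterogeneity, and not the particular variance
fractions of the real dataset (which depend on the archived volumes).
Likewise the generators do not model muscle shrinkage from ethanol
preservation, segmentation bias, per-leg lift-off sequencing within a
take-off, or any 3-D image content.

## Numerical conventions

Internal units are SI throughout; CSV readers take declared units and
convert by exact powers of ten (single correctly-rounded multiply or
divide), and CSV parsing uses round-trip float precision, so
write-then-read is bit-exact. Printed-precision comparisons round half-up
to the printed significant digits while full-precision values are retained
in all outputs (CSV floats are written with 12 significant digits).
Duplicate (species, muscle) rows in a volume table are an error, not
averaged — the design is one specimen per species, so duplicates indicate a
corrupted table. Full-run outputs embed a provenance block (version, seed,
constants) and contain no timestamps, so identical configs produce
bit-identical bundles.

## Problem sizes

The seeded statistical checks use 100 synthetic casts (8 species × 10
variables) for the PCA separation rate, 100 replicates of a 231-point
log-log regression for isometry-CI coverage, 91-fiber sets for architecture
recovery, and 3 noisy ~120-frame tracks for velocity recovery — sizes
chosen to match the corresponding real designs (8-species cast, 231-genus
regression, ~90-fiber muscles, 3 recorded jumps) while keeping the full
suite fast.
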