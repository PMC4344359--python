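# Methods

## Geometry and conventions

The orientation matrix `A` (the Busing–Levy UB matrix) maps an integer
Miller index `h` (column vector) to the reciprocal-space vector
`q = A·h` in Å⁻¹; `A[i, j]` is the i-th laboratory-Cartesian component
of the j-th reciprocal basis vector. The zero-rotation basis `B` is
taken from the gemmi fractionalisation matrix (reciprocal basis vectors
as columns) so that `A = U·B` for a rotation `U`, and `A` is validated
against the cell's reciprocal metric tensor on construction.

The beam travels along a unit vector (default +z) with incident
wavevector `S0 = direction/λ`. The signed Ewald offset is
`Δr = |q + S0| − 1/λ`: positive outside the sphere, negative inside.
Only |Δr| enters the partiality; the sign is retained so that the
least-squares orientation derivatives are smooth through Δr = 0.

Orientation perturbations are `A' = R_y(θy)·R_x(θx)·A` about *fixed
laboratory axes* perpendicular to the beam (re-orthogonalisation per
frame is not performed; for the sub-0.5° corrections involved the two
conventions differ only at second order). For a non-+z beam the two
axes are built deterministically by Gram–Schmidt against the laboratory
axis least aligned with the beam.

Misorientation between two indexing solutions is computed over all
proper point-group rotations `g` (from gemmi, acting on Miller indices):
the rotation carrying `A_model` to `A_true·g` with minimal total angle
is split by the exact swing–twist decomposition about the beam axis into
`r_z` (twist, about the beam) and `r_xy` (swing, about an axis exactly
perpendicular to the beam). The swing angle is exactly invariant under
extra beam-axis rotations of either input, which is the property the
`r_xy` metric needs; this is a closed-form refinement of extracting the
beam-axis component of the rotation vector, with which it agrees to
second order in the angles.

## Partiality model

Two parameters describe crystal imperfection: the effective mosaic block
size `D_eff` (Å) and the effective full-width angular mosaic spread `η`
(rad). They give a reciprocal-lattice-point (rlp) ball radius

    r_Q(d) = 1/D_eff + (η/2)/d,        r_0 = r_Q(∞) = 1/D_eff,

a size term independent of resolution plus an angular term proportional
to 1/d. These constant-factor conventions (1/D_eff, η/2) are *the* fixed
convention of this package; program output that quotes a half-width
spread is accepted by the I/O layer via an `eta_half_deg` column /
`half_width=True` flag and doubled on input.

The Ewald-sphere/ball intersection is approximated by a flat circle of
radius `r_F = √(max(0, r_Q² − Δr²))`. Exact sphere–sphere geometry gives
a cap area `2πR·h = π r_F² · R/(R+Δr)`, so the relative error of the
circle approximation is |Δr|/R ≲ λ·r_Q — about 0.1% for r_Q ≤ 10⁻³ Å⁻¹
at λ ≈ 1.3 Å; a property test bounds it at 1%.

Partiality is the area-to-volume ratio normalised by the F000 point:

    P = (π r_F²/V_Q) / (π r_0²/V_0) = r_F² r_0 / r_Q³.

This expression is pinned by three limits: P = 1 when η = 0 and Δr = 0
(the normalisation cancels exactly); P < 1 at Δr = 0 whenever η > 0
(peak partiality decreases with resolution); and P = 0 at |Δr| = r_Q.
The output is clipped to [0, 1] against last-ulp rounding. `D_eff = ∞`
is allowed in the radius (angular term only) but rejected in the
partiality, whose F000 normaliser 1/D_eff would vanish; `D_eff = ∞`
together with η = 0 is rejected outright (zero-radius rlp).

Polychromatic partiality is the spectrum-weight-normalised mean of the
monochromatic value with the energy-dependent offset Δr(λᵢ), spectra
used as given (no re-binning); a utility aggregates dense spectra to
≤ 512 points conserving total weight. Beam divergence, dispersion-aware
prediction and non-top-hat rocking profiles are out of scope.

Full-spot correction is `I_full = I/P`, `σ_full = σ/P`, applied only to
geometrically accepted reflections (|Δr| ≤ r_Q). A configurable floor
`p_min` (default 0.1 in the pipeline, 0 = bare geometric filter)
additionally rejects near-edge reflections: dividing by partialities of
a few percent amplifies noise quadratically in 1/P and measurably
degrades merged-truth correlation in simulation, so the floor is on by
default; setting `p_min = 0` reproduces the bare |Δr| ≤ r_Q filter.

## Per-frame scaling and postrefinement

Each frame minimises, over observations matched to a reference entry
under the point group,

    Σ_h [ I_obs(h) − G · exp(−2B sin²θ_B/λ²) · P_h(θx, θy) · I_ref(h) ]².

With sin θ_B = λ/2d the Debye–Waller factor is exp(−B/2d²). The model
side carries `G·I_ref`, so scaling the reference by c divides the
fitted G by c (verified exactly in the noiseless tests). Residuals are
unweighted by default (1/σ weighting behind a flag). In `scale_only`
mode the partiality is held at its θ = 0 value (or omitted entirely when
partiality correction is disabled); in `postrefine` mode P is recomputed
from the θ-perturbed orientation inside every residual evaluation.

Optimisation is scipy's trust-region-reflective least squares with
numerical Jacobians, `ln G` parameterisation (G > 0 enforced),
B ∈ [−25, 100] Å², |θ| ≤ 1°, ftol = xtol = 10⁻⁸, ≤ 100 iterations.
G is initialised from the ratio of summed matched intensities at
B = θ = 0 (the target is nearly linear in G there), B = θ = 0. Frames
with fewer matched observations than free parameters raise; frames below
`min_obs` (default 10) or failing to converge are flagged rejected and
excluded from merging, not raised. Mosaic parameters are per-frame
inputs and are not re-estimated inside the fit. The reference can be an
external intensity table or, for self-contained runs, a mean-of-merged
bootstrap (one outer iteration).

## Filtering, merging, statistics

*Per-lattice cutoff.* Observations are binned into equal-volume shells
(uniform in 1/d³, default 10). Scanning from low to high resolution, the
frame is truncated at the first shell whose mean I/σ falls below the
threshold (default 0.5); everything beyond is dropped, even if a later
shell would pass. The cutoff runs on the raw observation list *before*
negative-measurement removal — removing negatives first would bias the
shell means upward and defeat the filter. `None` disables it
(fixed-resolution protocols).

*Merging.* Observations are corrected to
`I = I_raw/(G·exp(−B/2d²)·P)` and mapped to the reciprocal-space
asymmetric unit (gemmi); Friedel mates are kept separate by default
(anomalous workflows) and collapsed on request. Merged intensity is the
unweighted mean of duplicates; merged σ is the larger of the propagated
estimate √(Σσ²)/n and the sample-scatter estimate s/√n for n ≥ 2,
guarding against underestimated errors on discrepant duplicates.
Completeness counts against every symmetry-unique index of the cell in
range. No outlier rejection is applied beyond the stated filters.

*Statistics.* CC½ is the Pearson correlation and R-split the
2^(−1/2)·Σ|I₁−I₂| / (½Σ(I₁+I₂)) agreement of two seeded random frame
halves merged independently. The L-test draws seeded random
within-shell pairs (≤ 10 pairs per reflection, never pairing the two
Friedel branches of one index) and reports ⟨|L|⟩, ⟨L²⟩ and the exact
(KS-style, evaluated one-sidedly at the sample points) sup-deviation of
N(|L|) from the acentric-untwinned line N(|L|) = |L|; at least 100 pairs
are required. N(z) normalises intensities by shell means (shells with
< 20 reflections excluded) separately per centricity class and reports
the same exact sup-deviation against 1 − e^(−z) and erf(√(z/2)); an
empty class reports None.

## Synthetic data generator

The generator emulates, at the reflection level, the statistical
structure the pipeline assumes: Wilson-distributed truth (exponential
acentric, one-degree-χ² centric) with mean `scale·exp(−B_truth/2d²)`;
uniformly random orientations (normalised Gaussian quaternions);
log-normal per-frame G and uniform B; partiality attenuation under the
true mosaic model; additive Gaussian noise with
σ = √(gain·I + background²) (the Poisson-like first term mirrors
counting statistics); and a deliberate misorientation of the recorded
("indexed") matrix by a configured angle about a random axis
perpendicular to the beam, so orientation recovery can be scored against
the stored truth. All randomness flows from one seed through per-frame
substreams (SeedSequence spawn keys), so adding frames never changes
earlier ones.

Default conditions: λ = 1.269 Å; mosaic block size 4220 Å and full-width
spread 0.336° (a fitted thermolysin-like regime); resolution 30–2.2 Å;
an orthorhombic P2₁2₁2₁ cell of 55×60×70 Å chosen to keep per-frame
reflection counts in the hundreds (a PSI-like hexagonal cell,
a = b = 281 Å, c = 165.2 Å, can be configured for fidelity checks);
truth falloff B_truth = 25 Å² with background σ = 15 so that per-frame
shell I/σ reaches ≈ 0.5 near the resolution edge — the regime the
per-lattice cutoff exists for; G log-normal (median 1, σ_ln = 0.3),
B ∈ [0, 10] Å²; indexing error 0.03°.

What the generator does **not** emulate: pixel-level images and
integration masks, detector geometry and metrology, per-shot spectra
(beyond toy spectra for the polychromatic sum), non-isotropic mosaicity,
cell-parameter scatter between crystals, and non-Gaussian outliers.
Passing tests therefore demonstrate the *self-consistency* of the model
and estimator — correct forward/inverse algebra, parameter recovery,
correct direction of protocol effects — not performance on real detector
data with systematic errors outside the model.

## Protocol comparison

`protocol_experiment` processes identical frames under up to four
protocols: `scale_only` (G, B fit, no partiality correction, I/σ = 0.5
per-lattice cutoff), `scale_only_fixedres` (same, no cutoff),
`postrefine` (partiality + orientation refinement, cutoff) and
`postrefine_fixedres` (same, no cutoff), reporting merged-vs-truth
correlation, multiplicity, completeness and the QC block per protocol.
In simulation the postrefined protocols recover markedly higher
merged-truth correlation and half-set agreement than scale-only; fewer
unique indices survive because far-off-sphere measurements are
discarded instead of merged as noise.

## Problem sizes

The shipped defaults run a frame in milliseconds (a few hundred
reflections against ~12 000 unique truth indices); test-suite
experiments use 8–40 frames and the seeded statistical checks use 10⁵
draws, sizes at which the Monte-Carlo tolerances asserted in the tests
(±0.05 on the second moment, ±0.01 on the L moments, 0.005–0.01° on
orientation recovery) are comfortably resolved.

## Known limitations

- The partiality model is monochromatic and top-hat; real SASE spectra
  (~0.5% bandpass) violate it, which is the motivation for the
  polychromatic sum when per-shot spectra exist.
- The mean-of-merged bootstrap reference is a single outer iteration;
  it will not fully de-bias strongly partial data without an external
  reference.
- Mean multiplicity can *decrease* when weak high-resolution data are
  added at low completeness (new singly-observed indices dilute the
  mean); the "fixed resolution keeps more data" ordering is therefore
  asserted on the scale-only pair and at frame counts where the unique
  set is reasonably saturated.
- Equal-volume shells put few reflections in the lowest-resolution
  shells of small test cells; shell statistics there are noisy and the
  N(z) test excludes shells with fewer than 20 reflections.
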