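# stillmerge

Partiality correction, per-image scaling/postrefinement, merging and
intensity-distribution quality statistics for **still-shot serial
crystallography** (XFEL or synchrotron stills), together with a
reflection-level synthetic data generator so the whole pipeline can be
exercised and validated at desk scale.

## The problem

A still exposure records each Bragg spot while the crystal is *not*
rotating, so every measured intensity is only a fraction — the
*partiality* P — of the full-spot intensity that a rotation experiment
would integrate. Merging thousands of such stills without modelling P
(and without knowing each crystal's orientation to millidegree accuracy)
systematically distorts the merged structure factors.

`stillmerge` implements a geometric partiality model based on the
crystal's mosaic structure. A reciprocal lattice point at resolution *d*
is widened into a ball of radius

```
r_Q(d) = 1/D_eff + (η/2)/d            [Å⁻¹]
```

where `D_eff` is the effective mosaic block size (Å) and `η` the
effective full-width angular mosaic spread (rad). If the point sits a
distance `Δr` from the Ewald sphere (radius 1/λ), the sphere/ball
intersection is approximated by a circle of radius
`r_F = √(r_Q² − Δr²)`, and the partiality is the area-to-volume ratio of
the intersection normalised by the same ratio for the F000 point at the
reciprocal-space origin (always exactly on the sphere, radius
`r_0 = 1/D_eff`):

```
P = (π r_F² / V_Q) / (π r_0² / V_0) = r_F² · r_0 / r_Q³  ∈ [0, 1]
```

Measurements with `|Δr| > r_Q` carry no signal under the model and are
discarded; the rest are corrected to `I_full = I/P`. Because `Δr` is a
sensitive function of the two orientation angles that spot positions do
not constrain, each frame's scale `G`, temperature factor `B` and
orientation corrections `(θx, θy)` are refined by nonlinear least
squares against a reference intensity set (*postrefinement*):

```
min  Σ_h [ I_obs(h) − G · exp(−2B sin²θ_B/λ²) · P_h(θx, θy) · I_ref(h) ]²
```

Merged output is scored with the standard intensity-distribution
statistics: the Wilson second moment ⟨I²⟩/⟨I⟩² (acentric theory 2.0),
the Padilla–Yeates L-test (⟨|L|⟩ = 0.5, ⟨L²⟩ = 1/3, N(|L|) = |L|),
cumulative N(z) against 1 − e^(−z) (acentric) and erf(√(z/2)) (centric),
CC½ and R-split of random half-datasets, multiplicity, completeness and
per-shell I/σ.

## Worked example

Compare plain per-frame scaling against partiality correction with
postrefinement on identical simulated frames (each frame carries a
deliberate 0.03° indexing misorientation):

```sh
stillmerge protocol-compare --n-frames 20 --seed 3 --protocols scale_only,postrefine
```

```
                      scale_only   postrefine
n_frames_merged        20.000000    20.000000
n_unique             3109.000000  2458.000000
multiplicity            1.226118     1.185924
completeness            0.253176     0.200163
cc_truth                0.758646     0.977696
cc_half                 0.651439     0.949297
r_split                 0.415837     0.157572
moment_ratio            2.241794     2.239418
mean_abs_l              0.479644     0.456145
mean_l2                 0.308059     0.283048
nz_max_dev_acentric     0.036660     0.061237
nz_max_dev_centric      0.146643     0.181547
```

`cc_truth` is the Pearson correlation between the merged intensities and
the generator's ground truth: correcting partiality with a postrefined
orientation lifts it from 0.76 to 0.98, and the half-dataset agreement
improves in step (CC½ 0.65 → 0.95, R-split 0.42 → 0.16). The
postrefined column has fewer unique indices because reflections the
model places too far from the Ewald sphere (or with partiality below the
0.1 floor) are discarded rather than merged as noise.

Other subcommands: `simulate` (write synthetic frames + ground truth),
`correct` (append per-reflection partiality columns), `postrefine`,
`merge` (TSV and optional MTZ), `qc`, and `run` (the full pipeline; see
`stillmerge run --help`).

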