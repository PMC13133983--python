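# Methods

Model, procedures, parameters and numerical choices of the mtseam
package. Units: lengths in Å unless a name says `_px` (pixels) or
`_vox` (voxels); angles in degrees.

## Lattice model

A microtubule architecture is the pair `N-S`: N protofilaments
(8 ≤ N ≤ 18) and S helical starts (S ∈ {2, 3, 4}), with monomer axial
repeat a = 41.0 Å. One subunit step of the left-handed lattice helix has

- rise = S·a / N  (Å per subunit)
- twist = −360 / N  (degrees per subunit)

For the canonical 14-3 lattice: rise 8.785714… Å, twist −25.714285…°,
displayed as 8.79 Å and −25.7°. Values are exact internally and rounded
only for display.

Euler angles are intrinsic ZYZ: the reference-to-image rotation is
R = Rz(ψ)·Ry(θ)·Rz(φ), with φ the rotation about the helix axis in the
reference frame, θ the tilt (≈90° for a filament lying in the ice), and
ψ the in-plane angle. Limiting cases fix the convention: at θ = 90°,
ψ = 0 an axial translation projects fully into the image plane; at θ = 0
the triplets (φ, 0, ψ) with equal φ+ψ coincide. The helical operator for
step k is a rotation of k·twist about Z composed with a translation of
k·rise along Z; operators compose additively in k.

## Trace repair and extension (`trace_extend`)

Filament tracers drop picks and occasionally assign picks to the wrong
filament. The repair pass:

1. **Split** each filament at jumps in ψ larger than
   `max_psi_jump_deg` (default 10°) between arc-consecutive picks.
2. **Fit** each group's centerline: picks are parameterized by chord
   length; a straight line is fitted first, and if more than
   `quad_fallback_frac` (default 0.10) of picks deviate from it by more
   than `deviation_tol_px` the model falls back to a quadratic.
   `deviation_tol_px` = diameter/(4·pixel size); the default 360 Å
   filament diameter gives 90 px at 1 Å/px.
3. **Reassign** every pick to the nearest centerline within
   `reassign_radius_px` (default = `deviation_tol_px`), iterated to a
   fixed point (at most `n_iter` = 5 rounds plus a safety margin). Only
   groups with at least `min_members` = 3 picks propose a model:
   smaller fragments — typically created by splitting at a swapped
   pick's ψ — would otherwise fit zero-residual models of themselves
   and freeze the iteration.
4. **Merge** groups tracing the same centerline: two groups merge when
   each group's picks lie, on average, within the reassign radius of
   the other group's extended model. The merge loop also runs to a
   fixed point. Crossing filaments do not merge because the mean
   distance over a whole group stays large.
5. **Extrapolate**: a pick grid at `spacing_A` (default 82 Å, two
   dimers) anchored at the first pick is laid along each centerline
   across the full field; grid nodes near an existing pick snap to it,
   empty nodes become new picks with ψ from the model tangent. The
   tangent fixes ψ only modulo 180° — filament polarity is not decided
   at the picking stage.

Measured on the synthetic generator (15% dropout, 10% identity swaps,
1 px jitter, 4 filaments on a 4096 px field): membership purity
≥ 0.995 and dropped-position recovery 1.0 over seeds 0–7.

## Synthetic references (`replicate_protofilament`, `build_reference_set`)

A single-protofilament density centered in a cubic box is placed at the
lattice radius along +X and summed over helical operator powers k
(symmetric k range filling the box by default, or an explicit copy
count). The lattice radius scales linearly with N — circumference grows
by one protofilament width per added protofilament — so a radius
measured on the N_ref = 14 map transfers as radius·N/14. One volume per
candidate architecture (11-3, 12-3, 13-3, 14-3, 15-4, 16-4 by default)
forms the supervised classification reference set.

Numerical choices:

- **Interpolation order.** Resampling uses cubic splines
  (`order=3`). Trilinear placement leaves ~6×10⁻³ relative asymmetry in
  the completed ring even for smooth test densities, an order of
  magnitude above the 10⁻³ acceptance bound; cubic achieves ~10⁻⁴.
  `order=1` remains available for speed.
- **C_N test geometry.** A helix of discrete blobs is *not* C_N
  symmetric (rotating by 360/N maps copy k onto copy k−1's azimuth but
  not its z), and even for a z-uniform rod the per-copy z-shift
  truncates density at the box floor. Exact C_N therefore holds on the
  z band above the largest copy shift of a z-uniform rod, which is what
  the acceptance test evaluates.
- The register-reference counterpart of the 41 Å particle shift is a
  cubic-spline axial translation of the volume (`shift_volume_axial`).

## Class smoothing (`smooth_classes`, `regroup_stretches`)

Architecture is a per-filament property, so per-particle 3D-class labels
are smoothed along each filament: every particle takes the modal class
of the centered window of 7 particles (truncated at ends; ties keep the
particle's own label, otherwise the smallest tied label). Contiguous
off-modal runs are then examined: runs of at least `min_run` = 7
particles whose dominant class exceeds `stretch_frac` = 0.70 become new
filament groups; all other runs are unified to the filament's modal
class, making every output filament class-uniform.

The minimum stretch length is a deliberate extension: a single modal
pass leaves wrong clusters of ≥ 4 consecutive labels as fixed points
(measured 96.6% accuracy at 20% planted error), and such short runs are
statistically indistinguishable from classifier noise, while genuine
architecture transitions produce extended stretches. With the minimum
in place, accuracy at 20% planted error is 99.4–99.7% and long planted
stretches still split.

## Angle unification (`unify_psi`, `unify_phi`)

**ψ.** Per filament, the modal ψ is found on the circle (4° histogram
bins refined by circular mean); a quadratic ψ(t) in arc length t is
fitted through inliers within ±10° of the mode (falling back to linear
below 3 inliers, constant below 2), and *all* particles' ψ are replaced
by the fitted track. Outliers — including 180°-flipped picks — are
thereby replaced, not flipped. Recovery on planted quadratic tracks
(σ = 2°, 5% uniform outliers): < 1° RMS. Idempotent to 10⁻⁹.

**φ.** A global refinement leaves each particle's φ on one of N
symmetry-equivalent lines φ_j(t) = φ0 + s·t + j·360/N. The family is
fitted by grid search over the supertwist slope s (±0.05 °/Å, step
0.001, then a linear refinement of residuals folded modulo 360/N, with
φ0 the circular mean of folded residuals); each particle is assigned to
its nearest line and all φ are set to the modal line's value at their
t. Applied for 2 rounds; idempotent to 10⁻⁹. If all lines are equally
populated the tie goes to j = 0 with a warning.

Parameter recovery is limited by statistics, not by the fit: at the
generator's σ = 3° line noise the intercept's Cramér–Rao bound is about
6/√n degrees, so a 60-particle track cannot meet a 0.5° φ0 tolerance
(bound ≈ 0.78°) for any estimator. The acceptance test checks φ0/slope
recovery on a 1500-particle track (bound ≈ 0.15°) and the structural
properties (single-line output to 10⁻⁶, idempotence) on example-sized
tracks.

## Expansion, register and un-expansion (`mtseam.expand`)

`symmetry_expand` replicates each particle N-fold: copy k keeps the
parent's θ/ψ, adds k·twist to φ, and adds the image-plane projection of
a k·rise axial translation — the first two components of R·(0,0,k·rise)
— to its origin shifts. Copies carry `pf_index` = k and a parent link;
expanding an already-expanded table is an error.

`shift_register` translates one register class (α/β ambiguity) by a
signed axial shift, default 41 Å = one tubulin monomer, through the same
projection, and relabels it to the other class. The round trip (shift B
by +41, then the relabeled records by −41) restores origin shifts to
10⁻⁹ Å. `recenter_metadata` applies an arbitrary 3D recentering offset
to all records and is exactly inverted by the negated offset.

`unexpand_at_seam` keeps, for each parent, only the copy whose
`pf_index` equals the microtubule's consensus seam index, restores the
parent's particle id and clears the expansion columns; microtubules
without a seam entry are dropped with a warning.

## Seam finding (`mtseam.seam`)

After register classification, each expanded layer (one parent particle,
N protofilament records) carries a register vector r over pf positions.
The changepoint score of seam position p under orientation (u, v) is the
fraction of assigned labels consistent with register u before p and v
from p on. A single orientation per microtubule is fixed by majority
vote over layers (preventing sign-flip cancellation); the per-layer
score vectors under that orientation are averaged and the argmax is the
consensus seam, with the mean score at the seam as confidence. Ties
break toward the smaller index, with a warning. Recovery is exact for
noiseless vectors over N ∈ 8..18 at every seam position, and 200/200 at
flip rate 0.2 with 50 layers.

## Synthetic generators (`mtseam.simulate`)

- `make_micrograph_picks`: random straight (optionally gently parabolic)
  filaments clipped to a 4096 px field, picked every 82 Å with 1 px
  Gaussian jitter; a uniform fraction of picks is dropped (15%) and a
  uniform fraction relabeled to another filament's id (10%). Uniform
  relabeling is deliberately harder than crossing-only swaps, since the
  wrong label is arbitrary. Truth records positions, memberships and
  noise flags.
- `make_angle_tracks`: ψ follows a low-order polynomial of arc length
  (default 30° + 0.002 °/Å − 2×10⁻⁷ °/Å², i.e. a gently curved
  microtubule spanning ~5–10° over a 5 µm trace, consistent with the
  ±10° inlier window) with σ = 2° noise and 5% circular-uniform
  outliers; φ is drawn per particle from one of the N family lines with
  σ = 3° noise.
- `make_register_layers`: expanded layers with a planted seam, per-label
  flip and dropout rates.
- `make_pf_volume`: sums of isotropic Gaussian blobs with analytic
  centers as placement oracles.

Limits: generators use straight/quadratic filament geometry, iid label
noise and isotropic jitter; no CTF, no density noise, no lattice
defects within a filament (defects appear only as planted class
stretches).

## End-to-end pipeline (`run_pipeline`, `mtseam run`)

Stage order: simulate → trace-extend → smooth-classes → unify-psi →
unify-phi → expand → register-merge → seam-find → unexpand. Inputs that
production pipelines receive from external refinements (class labels,
angle scatter, register labels) are planted at the corresponding stage
boundaries with configured noise; planted truth is written as sidecar
CSVs, enabling the closure check that every retained record sits at the
planted seam. Reference generation is volume-based and independent of
the particle-table chain, so it is a separate subcommand (`make-refs`)
rather than a pipeline stage. All randomness derives from one seed;
re-runs are byte-identical. `--strict` asserts stage conservation rules
(no lost picks, exact N-fold counts, no residual class-B records, one
copy per parent after un-expansion). Seam scoring uses the pre-merge
register labels (stashed in a passthrough column), since the merge
relabels the shifted class.

Default problem sizes throughout (fields of 4096 px, 2–4 filaments,
50–60 particles per filament, 64–96 voxel boxes) are the package's own
choices, sized so the full test suite runs in under a minute on one
CPU.

## Tie-breaks and conventions (summary)

- Angle wrapping to (−180, 180]; −180 maps to +180.
- Window-mode ties: keep own label, else smallest label.
- Filament majority-class 50/50 ties: class of the longest contiguous
  run, with a warning.
- Seam score ties: smaller index, with a warning.
- Degenerate φ line population: j = 0, with a warning.
- New filament ids: per-micrograph max + 1; first split segment keeps
  the original id.
- Volumes are (z, y, x) float32 cubic grids; helix axis along Z through
  the box center; tables use RELION STAR tags plus `_mts*` extensions
  (particle id, register, protofilament index, parent link), and
  unknown STAR columns pass through verbatim.
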