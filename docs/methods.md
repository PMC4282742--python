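# Methods

## Coordinate conventions

Positions are in millimetres, angles in degrees. The laboratory frame has
X along the walking direction, Y vertical (up) and Z to the subject's
right; the ground plane is Y = 0. Left feet are mirrored (Z → −Z) on
ingest so that every downstream sign convention — inversion positive,
adduction positive, valgus offset positive — is side-independent; writers
restore the original coordinates. Missing samples carry a NaN sentinel
(C3D negative residual, blank TSV cell), never zeros.

Default pre-processing fills interior gaps of up to 10 frames with a
not-a-knot cubic spline (exact for cubic-polynomial trajectories; edge
gaps are never extrapolated) and applies a zero-phase 4th-order
Butterworth low-pass at 6 Hz (a 2nd-order filter run forward and
backward, the conventional zero-lag smoother of gait laboratories). Both
are configurable; event detection deliberately runs on unfiltered
trajectories (below).

## Segment frames

Six right-handed orthonormal frames are built per frame from marker
triads: shank (HF, TT, LM, MM), calcaneus (CA, PT, ST), midfoot (TN, C,
SMB), metatarsus (FMH, VMH, SMB), whole foot (CA, FMH, VMH) and the
hallux proximal phalanx (PM, FMH, VMH; origin FMH, X along FMH→PM, Y
normal to the three-marker plane, Z = X × Y). Plane normals are
disambiguated "up-positive": the normal is flipped to a positive lab-Y
component at construction. This assumes a near-upright subject —
constructions are performed in standing or walking postures where no
segment plane tilts past horizontal — and during a trial the sign instead
follows the previous frame's normal, so momentary extreme poses cannot
flip a frame mid-trial. Triads with triangle area below 1e−6 mm² are
rejected as degenerate (physiologic inter-marker areas are ~10³ mm²).

The calcaneus *technical* frame used to carry virtual points applies no
up-flip at all: its orientation is a deterministic function of the marker
order, which makes virtual-point tracking exact (≤ 1e−9 mm) under
arbitrary rigid motion of the cluster, with no orientation-domain caveat.

## Joint angles

For each joint the relative rotation R_rel = R_proxᵀ R_dist is decomposed
with e₁ = proximal Z (Do/Pl), e₃ = distal X (Eve/Inv) and floating
e₂ = e₃ × e₁ (Abd/Add) — the knee-style joint coordinate system adapted to
segments whose long axis is antero-posterior rather than longitudinal.
Numerically this is the intrinsic Z–Y′–X″ Euler factorisation
R_rel = R_Z(DoPl) · R_Y(AbdAdd) · R_X(EveInv); with the axis conventions
above, positive angles are dorsiflexion, adduction and inversion for
either side (left feet being mirrored). The decomposition is exact away
from |Abd/Add| = 90°; at the gimbal a warning is raised and angles are
still returned. The forward constructor `jcs_compose` exists primarily so
that tests and the synthetic generator can state rotations independently
of the decomposition path.

The hallux is reported only through F2Ps/F2Pt (sagittal/transverse
Met-Hal components): a three-marker phalanx sharing FMH and VMH with the
metatarsus leaves the axial component underdetermined, so Met-Hal
Eve/Inv is computed but not part of the clinical angle set.

## Static calibration

* **Hindfoot frontal offset**: per static frame, CA − HL is projected
  into the shank frontal plane (spanned by shank Y and Z) and the signed
  angle to shank +Y is averaged over frames; the top of the calcaneus
  tilting laterally reads positive (valgus). This value *replaces* the
  frame-derived static Sha-Cal frontal angle in all reports and in the
  classification, because the anatomical-frame construction is tipped
  into inversion by the typically higher ST marker. HL is used only in
  the static trial.
* **CAp**: the vertical ground projection of CA, (CA_x, 0, CA_z),
  averaged over static frames, stored in calcaneus technical-frame
  coordinates, and re-projected to the lab per walking frame.
* **Static reference angles**: all 15 joint components and 8 planar
  angles time-averaged over the full static trial (no trimming). The
  stored Sha-Cal Eve/Inv entry is the HL-based offset.

Classification uses an inclusive neutral band: |offset| ≤ 2° neutral,
offset > 2° valgus, offset < −2° varus. The per-foot MLA reported in
cohort summaries is the static (double-leg stance) value.

## MLA angle

CAp, ST and FMH are projected into the foot sagittal plane — the plane
through CA spanned by the foot frame's X axis and the lab vertical,
recomputed every frame so the measure follows the foot during gait. The
angle at ST is the interior angle while ST lies dorsal to the CAp–FMH
line and its reflex (360° − interior) when ST drops below it, so flat
arches read ≥ 180°. The angle is invariant to vertical-axis rotations and
horizontal translations (it references the ground plane through CAp), and
strictly decreases as ST is elevated.

## Gait events and ensembles

Foot strike and toe off are detected from marker coordinates alone. The
forward velocity of CA (strike) and SMH (toe off) is assigned a
three-valued sign with a dead band — the larger of 80 mm/s and 7.5% of
the trajectory's 95th-percentile speed, so the band scales with walking
speed; stance reads 0. A strike candidate is a +1 → ≤0 transition, a toe
off a ≤0 → +1 transition, each gated by a vertical-position local minimum
(prominence ≥ 2 mm on a 5-frame-smoothed height signal) within ±3 frames.
The reported frame refines the transition by fitting the linear part of
the swing velocity ramp (samples between 2× and 8× the dead band) and
extrapolating to zero velocity: the ramp intersection is far sharper than
the near-flat height minimum at foot-flat, and is insensitive to where
exactly the dead band is crossed. Candidates closer than 0.5 s keep the
one with the tighter velocity/height coincidence. Event detection runs on
unfiltered (only gap-filled) trajectories: the strike impact is a
velocity corner that a 6 Hz zero-phase filter smears over ±8 frames,
which would bias the detected frame by 2–3 frames at higher cadences.

Cycles (strike → next strike, toe off strictly inside) are resampled onto
101 points (0–100%) by linear interpolation with exact endpoints; cycles
with more than 20% missing samples are rejected. Ensembles report the
pointwise mean and sample SD (n−1; SD = 0 for a single curve), pooling
all cycles of all trials per foot and then across feet.

## Synthetic gait generator

The generator is the package's oracle: a rigid template foot posed by
prescribed joint curves with every inverse quantity known exactly.

* **Template**: 17 markers on a ~230 mm right foot; arch height is the ST
  marker elevation (default 18 mm, giving a static MLA of ≈ 185°; the
  achievable MLA range is ≈ 135–207°, inverted numerically by Brent's
  method when a target MLA is requested); the hindfoot frontal tilt is
  realised exactly by placing HL below CA along a direction tilted by the
  requested angle inside the shank frontal plane; an HL placement-offset
  parameter models the acknowledged uncertainty of that landmark.
* **Chain**: the kinematic chain is rooted at the calcaneus. Relative
  joint rotations are composed with `jcs_compose` as static value +
  prescribed deviation curve (sums of 1–2 harmonics per component,
  default amplitudes of a few degrees, |total| < 60°), so the measured
  decomposition equals the prescription identically regardless of global
  motion. The Lisfranc pivot is placed exactly at the shared SMB marker,
  keeping both the midfoot and metatarsus measured frames rigid; the
  hallux marker PM is placed on a sphere around FMH so that measured
  Met-Hal Do/Pl and Abd/Add equal the prescribed values, its axial
  component being derived. Ground truth for the composite Sha-Foo and
  Cal-Met joints is built from the noise-free markers.
* **Gait choreography**: stance occupies 60% of the cycle; the foot is
  flat until 40%, pitches to −26° about the toe by toe off at 60%, and
  the heel descends linearly into the next strike (an impact corner, as
  in real gait) after a 30 mm swing clearance; an 8 mm heel bob during
  stance gives the strike minimum a definite basin. Stride defaults to
  1100 mm at 0.8–1.2 cycles/s; 100 Hz sampling; optional i.i.d. isotropic
  Gaussian marker noise. Soft-tissue artefact, marker occlusion patterns
  and force data are *not* modelled, so passing tests demonstrate
  correctness of the geometry/signal pipeline, not robustness to the
  structured artefacts of real captures.
* **Cohort**: 10 participants × 2 feet by default, 7/5/8
  neutral/varus/valgus with offsets drawn uniformly inside each category
  band (±1.8°, [−6.5, −2.5]°, [2.5, 6.5]°; the gap around ±2° keeps the
  constructed category unambiguous at the classification boundary), and
  static MLA targets from a normal law (183 ± 16°) truncated to
  [153, 206]° and sampled by permuted quantile midpoints so that any seed
  yields a cohort representative of the prescribed distribution;
  i.i.d. sampling is available as an option. One static plus three
  walking trials per foot; all seeds recorded in the manifest.

## Numerical choices and test conditions

* Orthonormality/handedness of every constructed frame: ≤ 1e−9.
* Forward–inverse round trip: noise-free recovery is exact to ~1e−12°;
  with 0.5 mm noise and 6 Hz filtering, joint-angle RMS error stays below
  1° (typically 0.3–0.7°), which documents the model's noise sensitivity.
* Event detection is verified over cadences 0.8–1.2 Hz and noise up to
  1 mm SD, requiring ≥ 95% of events within ±1 frame of ground truth at
  100 Hz.
* Rigid-motion invariance of 3D joint angles is asserted for rotations
  tilting the vertical by up to 60°, the domain of the up-positive normal
  rule; ground-referenced planar angles are asserted invariant under
  vertical-axis rotations and horizontal translations, which is the
  largest group that preserves the ground plane they reference.
* Problem sizes in the test suite and acceptance script (3-cycle trials,
  20-foot cohorts, 1000-rotation oracle sweeps) are chosen so a full run
  completes in well under a minute on one CPU while every property is
  exercised at the same study conditions the defaults encode.

## Known limitations

* The HL placement rule is anatomically underspecified; the offset is
  sensitive to medio-lateral placement error (~1.9°/mm at the default
  30 mm CA–HL distance), which is exactly why the generator exposes it.
* Angles are reported for upright locomotion; captures in which segment
  planes invert (acrobatics, crawling) violate the normal-sign assumption.
* The hallux axial rotation is not measurable with this marker set.
* The original frontal-offset and two-vector MLA definitions that this
  model supersedes are not implemented (a comparison hook exists but is
  intentionally empty).
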