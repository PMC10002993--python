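# Methods

## Coordinate conventions

All geometry lives in a single signed AC-PC frame: origin at the posterior
commissure, +X lateral toward the patient's right, +Y anterior, +Z
inferior.  `build_frame` constructs it from three world-space landmarks
(AC, PC, and a superior midsagittal point); the frame is orthonormal to
1e-9 and right-handed once Z is flipped back to superior.  Degeneracy is
declared when the midsagittal point is collinear with the AC-PC line to
sin(angle) < 1e-6.

Clinical summary tables print left-hemisphere rows with all three axes
negated.  We treat that strictly as a *display* convention: data are stored
signed, the flip is applied only at reporting/pooling time, and bilateral
("all") summaries pool per-axis magnitudes.  This is the only reading under
which left-row discrepancy arithmetic (e.g. −12.11 vs −11.82 giving −0.29)
is internally consistent, and we apply it to Y and Z as well as X.

## Electrode model

The lead is modelled as a straight line through two landmarks: the
ventral-most contact centre and a cranial point on the shaft (the cranial
segment is the part least affected by bending).  Contact *i* (0-based,
ventral first) sits at `i × 2.0 mm` along the dorsal unit direction; the
published per-coordinate distance equations (`xᵢ = x₁ − √(lᵢ² − …)` etc.)
are the scalar form of this parametric line and carry a sign ambiguity,
which we resolve by always stepping toward the cranial landmark — contacts
are dorsal to the ventral-most contact by hardware definition.  The
physical tip sits 2.25 mm below the ventral contact *centre*: the 1.5 mm
tip-to-contact gap stated by both manufacturers plus half the 1.5 mm
contact length, since reconstruction coordinates are contact centres.
Electrode geometry is data-driven (`ElectrodeSpec`); Medtronic 3389 and
PINS L301 ship with identical constants.

The four contact centres of each electrode are averaged per axis before any
between-method comparison; the averaged point is the unit of analysis.

## Relative-position construction

1. **Maximum RN level.** The red nucleus z-extent is scanned at a 0.1 mm
   step (an order of magnitude below the ~1 mm effects of interest) and the
   level with the largest cross-sectional area is kept; the grid makes the
   level deterministic and its error is bounded by the step.
2. **RN centre.** The area-weighted centroid of the exact mesh–plane
   cross-section (polygons, not voxel masks, so analytic oracles apply;
   nested loops combine even-odd).
3. **Electrode point.** The intersection of the contact span (ventral-most
   to dorsal-most contact centre, not extrapolated) with the level plane;
   electrodes whose span does not reach the plane are flagged
   `above_rn_level` and excluded from distances, mirroring how such
   electrodes are excluded clinically.
4. **Ventral STN border.** A ray from the RN centre through the electrode
   point is intersected with the STN surface; among exit crossings the one
   with the largest +Z (most inferior) is the ventral-border point.  The
   ventral border is used because it is the most clearly identifiable STN
   boundary on T2 imaging; "exit, most inferior" is our geometric
   operationalization of it, since the ray travels laterally/ventrally
   toward the electrode.  If the ray misses the STN the distance is left
   undefined and only the categorical position is recorded.
5. **Relative distance and category.** Euclidean distance between electrode
   point and border point; the category is `within` when the electrode
   point lies in the STN cross-section, otherwise the dominant axis-wise
   offset from the section centroid (medial/lateral along X,
   hemisphere-aware; anterior/posterior along Y; equal offsets resolve to
   the X category, i.e. lateral beats anterior).

Ray–triangle intersection is a vectorized Möller–Trumbore over all faces
with shared-edge hits merged; point-in-mesh uses the generalized winding
number with on-surface points counting as inside (contacts touching a
border are scored as overlapping, as in manual assessments).  Axis-aligned
analytic spheres/ellipsoids implement the same interface with closed-form
sections, containment and ray roots; they serve both as an input format and
as the exact-geometry path that the mesh path is checked against (a
tessellated sphere agrees with the analytic one only to chordal error,
~1e-4 of the radius at the default tessellation).

## Statistical ladder

- **Normality.** One-sample Kolmogorov–Smirnov with the Lilliefors
  correction (statsmodels), because the normal parameters are estimated
  from the sample and plain KS would be anti-conservative.  Normal means
  p ≥ 0.05.  Samples below n = 4 cannot be assessed and default to the
  parametric branch; zero-variance difference sets carry no evidence
  against normality and also pass the gate.
- **Two methods, one axis/scope.** Paired t when the differences pass the
  gate, Wilcoxon signed-rank otherwise; gating is per comparison.
  Differences are method B − method A.  Identical methods (all differences
  zero) are reported as statistic 0, p = 1.
- **Three paired conditions.** If all pairwise difference sets pass the
  gate: repeated-measures ANOVA with Tukey HSD on the within-subject error
  term, `q = |Δmean|/√(MSE/n)` against the studentized range with
  (n−1)(k−1) df.  Otherwise: Friedman, then Dunn's pairwise z on mean
  within-subject ranks with Bonferroni adjustment over the three pairs.
  Incomplete triplets are dropped listwise with a logged count.
- **Rates.** Consistency is the fraction of index-matched equal categorical
  calls; subregion rate the fraction of contacts labelled dorsolateral;
  both reported as 1-decimal percentages.  Reported coordinate
  discrepancies are rounded to 2 decimals; all internal computation is
  full-precision.

The test suite checks the Tukey branch against a 10⁵-replicate
within-subject permutation of the studentized range (agreement to ~0.002 on
null fixtures — label permutation is exchangeable only under the global
null, so oracle fixtures are null-distributed).  Dunn's z is a
large-sample normal approximation on discrete ranks; compared against the
mid-p permutation null it agrees to a few hundredths at n = 6, which is the
tolerance the tests use.

## Synthetic cohort generator

The generator emulates the statistical structure of a bilateral STN-DBS
cohort measured by two reconstruction methods; its defaults are the study
conditions the analysis is designed for.

- **Anatomy.** Per side: an ellipsoidal STN (radii 5×3×2 mm) with its long
  axis toward the posterior-lateral-dorsal pole, centred at
  (±11, 9, 4) mm, and a spherical RN (radius 2.5 mm) medial-posterior at
  (±5, 4.5, 2.5) mm; left structures are exact x-mirrors of the right.
  The dorsolateral (sensorimotor) subregion is the STN part beyond the
  60th percentile of vertex projections onto the long axis, sliced and
  capped as a closed mesh — a qualitative stand-in for the sensorimotor
  partition of probabilistic atlases, whose exact geometry is out of
  scope.  Structure placement is chosen so that the maximum RN level falls
  within every electrode's contact span and mean contact coordinates stay
  clearly away from zero on all axes (magnitude pooling is linear there).
  Meshes are subdivided icospheres (subdivision 4; volumes within ~0.1% of
  the analytic values).
- **Implants.** The planned target sits at the dorsolateral centroid plus a
  (0, 0, +3.5) mm offset — the stereotactic convention of targeting the
  point where the *tip* lands, near the ventral STN.  The shaft direction
  is a typical double-oblique approach (≈(±0.25, 0.50, −0.83) unit vector)
  perturbed uniformly within a 5° cone; the true tip deviates from plan by
  an isotropic Gaussian (SD 0.5 mm, an assumption — no distributional data
  exist for final placement deviation); the MER depth is the true
  tip-to-target distance plus Gaussian reading noise (SD 0.5 mm), clipped
  at zero.
- **Measurements.** Each method observes the two trajectory landmarks with
  independent per-axis N(0, 1 mm²) noise; method B adds the systematic
  bias (−0.13, −1.16, +0.59) mm.  The bias is defined in the magnitude
  (display) convention, so its X component is mirrored on the left side —
  "0.13 mm less lateral" means the same thing in both hemispheres.  Noise
  perturbs the *landmarks*, not the finished contacts, so trajectory
  fitting and interpolation error propagation are exercised.  One master
  seed drives keyed substreams per (stage, patient, side), so enlarging
  the cohort never changes earlier patients' draws.

What the generator does *not* model: image formation and co-registration
(noise is applied directly in coordinate space), electrode bending, brain
shift and pneumocephalus, non-Gaussian localization error, anatomical
variability across patients (all patients share one anatomy), and clinical
outcome scores.  Passing tests therefore demonstrate that the computational
chain recovers known biases and preserves known geometry under the stated
noise model — not that any particular reconstruction method is accurate on
real images.

Two visible consequences of the noise model are worth noting.  First,
tip-to-target Euclidean distances computed from noisy coordinates are
upward-inflated relative to the physically recorded MER depth
(E‖x+ε‖ > E‖x‖), so at 1 mm noise the distance-vs-MER comparison *does*
detect a difference in synthetic cohorts; the no-difference null property
is tested at small noise where the inflation is negligible.  Second,
categorical position calls near the STN border flip easily under 1 mm
noise, so between-method consistency percentages are lower than for a
human rater judging coarse position.

## Problem sizes and numerics

Default cohorts are 26 patients (52 electrodes).  Parameter-recovery
properties use 100 measurement replicates; type-I calibration uses 1000
(test) / 400 (acceptance script) replicates of the n=52 null cohort; the
line–sphere oracle uses 1000 random configurations at 1e-6 mm; permutation
oracles use 10⁵ replicates.  Collinearity/degeneracy tolerances are 1e-6
(sin of angle, landmark separation) and 1e-9 (unit vectors, contact
spacing); surface-membership tolerance is 1e-9 mm with winding ≥ 0.45
counting as inside.  CSV output uses full `repr` float precision,
locale-independent, `\n` endings; OBJ export uses 12 significant digits so
write/read round-trips hold to 1e-9.

## Open design choices made

- "All-electrodes" comparisons pair electrodes (n = 52), not patients; the
  alternative (averaging hemispheres per patient) is exposed by filtering
  the table before testing.
- The electrode point for the ray construction is the trajectory–plane
  intersection at the RN level, not the nearest contact centre; the two
  differ by at most half the contact spacing along the shaft.
- The stand-in for the clinically programmed "optimal contact" in the
  pipeline report is the contact nearest the dorsolateral centroid (the
  sensorimotor sweet spot); real optimal contacts come from programming
  outcomes, which are not modelled.
- Whether coordinates refer to contact centres in every workflow is not
  universally documented; we assume centres throughout.
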