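# Methods

## Coordinate and label conventions

Volumes are integer-labeled 3D arrays with axes ordered (z, y, x),
0-based indices, and voxel centers at `origin + (index + 0.5) * spacing`
in physical micrometres. Label 0 is tissue/background, label 1 the
alveolar-duct lumen, labels ≥ 2 individual alveolar lumina. Respiratory
state (`expiration`/`inspiration`) and ventilation metadata (PEEP and
IPP in cm H₂O) travel with the volume. Meshes are closed,
outward-oriented triangle surfaces in the same physical frame.

## Mesh morphometry

Surfaces are extracted by marching cubes at level 0.5 on the binary
indicator of one label, padded so the surface always closes; no
smoothing is applied by default, because smoothing changes surface area
systematically. Volume is the sum of signed tetrahedra spanned by the
origin and each triangle — exact for polyhedra and independent of the
origin — and area the sum of triangle areas. On binary voxelizations,
marching-cubes *volume* converges quickly (≲0.5% for structures tens of
voxels across) while *area* carries a known staircase overestimate of
several percent. All dimensionless ratios used downstream (the shape
factor k = S/V^(2/3) compared across two similarly-sized states, i.e.
q) cancel that bias almost completely: phantom q recovery errors stay
below ~0.4% even though each state's raw area is ~7% high.

The apparent diameter is D_A = (6V/π)^(1/3); the shape factor obeys the
isoperimetric bound k ≥ 6^(2/3)π^(1/3) ≈ 4.8360 with equality only for
the sphere, which the test suite verifies on random convex meshes and
icosphere refinements.

## Entrance rings and alveolar surface area

The aperture between an alveolus and its duct is found on the voxel
grid (alveolar voxels 26-adjacent to duct voxels), then refined on the
alveolar mesh: each face is classified as *mouth* (the voxel just
outside it along the outward normal carries the duct label) or
*membrane*, the labeling is regularized by majority vote over
edge-adjacent faces, and only the largest connected mouth patch is kept
(extra patches raise a multi-aperture warning). The entrance ring is the
ordered boundary loop between the two partitions. Because that loop
zigzags at voxel scale, the reported perimeter is the convex-hull
perimeter of the loop projected into the least-squares mouth plane:
exact for convex apertures, stable to staircase jitter, and 1–3%
accurate on phantom mouths ~7 voxels in radius. The raw loop is kept on
the ring object.

The alveolar surface area S_A is the membrane submesh area — the mouth
cap is excluded, since gas exchange happens on the membrane and the
aperture is characterized separately by its ring perimeter. The closed
mesh (membrane + cap) still defines the alveolar volume. Both the
aperture-excluded and total areas are recorded. The same bookkeeping
makes unit assembly additive: the duct's external area excludes its
aperture interfaces, so V_AAD = V_duct + Σ V_alveoli and S_AAD is the
plain sum of the parts' areas, which the tests check against a directly
extracted union mesh.

## Wall thickness

T_A is measured from the Euclidean distance transform of the tissue
mask. Every tissue voxel is attributed to its nearest air region; where
the alveolus' territory meets another air region's territory, each
face-adjacent (6-connected) voxel pair spans the septum and the two
distances-to-air sum to the local thickness; T_A is the minimum of that
sum. Diagonal (26-connected) pairs are excluded from the sum because
they undercut the septum. Ridge voxels within `ring_exclusion_um`
(default 5 µm) of the mouth are excluded: at the aperture rim the
tissue wedge thins toward zero by construction and belongs to the
entrance ring, not to a septum. Accuracy is ±1 voxel on slab and
shell constructions.

## Inter-alveolar angle

θ is measured at the midpoint of the two mouth-plane centers, between
the rays to the two lumen centroids, reported in degrees in [0, 180].
This pins down an otherwise operator-dependent three-point measurement;
the angle is invariant under rigid motion and uniform scaling, so
isotropic inflation leaves it unchanged and Δθ = θ_insp − θ_exp is a
pure anisotropy signal: duct widening pushes neighboring alveoli apart
(Δθ > 0), alveolar deepening pulls their centroids radially outward and
the rays toward parallel (Δθ < 0).

## The synthetic phantom

A phantom unit is a duct — cylinder of radius R with hemispherical end
caps — carrying n alveoli, each the major spherical cap of a sphere of
radius r cut by a mouth plane of radius a = mouth_fraction·r. The mouth
plane is held `mouth_neck_um` (default 1.5 µm) above the duct surface;
the neck channel between duct surface and mouth plane belongs to the
duct lumen. The neck plays the role of the fibrous entrance-ring rim of
real alveoli, and numerically it keeps the peri-mouth septum at least a
couple of voxels thick — with the mouth plane exactly tangent to the
cylinder, the tissue wedge at the rim is sub-voxel over a ~2 µm annulus
and voxel adjacency would place the detected aperture well outside the
true rim.

All ground truth comes from the generating parameters: spherical-cap
closed forms for alveolar V, S, centroid; 1D quadratures for the neck
volume, neck wall area and the duct-surface patch each mouth opens;
2πa for ring perimeters; sphere-gap distances for septa; the vertex/ray
construction above for θ. Nothing is measured from meshes or voxels.

Mouths are placed by rejection sampling of (azimuth, axial position) on
the duct surface, requiring in *both* states a minimum tissue gap
(`septum_gap`, default 2 µm) between alveolar spheres and clearance from
the end caps, and non-overlapping mouths. Failure after `max_attempts`
(default 10 000) proposals raises a placement error naming the seed and
n_alveoli — never a silent reduction of n. Everything is deterministic
given `placement_seed`.

Deformation: the inspiration state scales the duct (R, L, mouth
positions, mouth radii, neck) by s_d and the alveolar radii by s_a.
Isotropic mode sets s_d = s_a = volume_ratio^(1/3). In the anisotropic
modes the weaker compartment is locked at
1 + deformation_split·(s_iso − 1) (split default 0.15) and the other
scale is solved (Brent) so the whole-unit volume ratio is hit exactly.
Mouth radii follow the *duct* scale in every mode: alveolus-dominant
expansion therefore deepens the cups relative to their apertures
(q > 1, Δθ < 0) and duct-dominant expansion flattens them (q < 1,
Δθ > 0). Scaling the mouths with their alveoli instead would leave each
alveolus' own shape factor unchanged and produce a weak, sign-unstable
q — the cup-deepening parameterization is what gives the three regimes
their signatures.

Default scales emulate a mouse acinus: alveolar radius 30 µm
(D_A within the 50–100 µm range), duct radius 35 µm and length 160 µm
(duct ≈ 40% of unit volume), 6 alveoli, mouth fraction 0.45, volume
ratio 1.5 (a deep tidal breath), voxel spacing 0.65 µm. The validation
phantoms are geometrically similar units scaled down (duct 10/40 µm,
alveoli 10 µm, 4 alveoli) so that a two-state study fits a ~100³ grid at
the same 0.65 µm spacing; q, strains and angles are scale-free, so the
scaled phantom probes the same estimator behavior at the same
voxels-per-structure resolution a full-size unit would need ~350³
voxels to reach.

Grayscale rendering is two-material (air 60, tissue 200) plus seeded
Gaussian noise. It emulates the *contrast* of reconstructed tomograms,
not their physics: no phase-contrast fringes, reconstruction artifacts,
beam hardening, motion blur, or capillary-scale texture. Passing tests
therefore demonstrate correctness of the measurement chain on clean
two-material volumes, not robustness to real tomographic artifacts.

## Segmentation and instance splitting

Air/tissue segmentation is Otsu's threshold (deterministic; a
contrast-failure error on effectively unimodal histograms; an
invert-contrast flag for opposite polarity). Instances are separated by
marker-controlled watershed on the interior Euclidean distance
transform: markers are h-maxima plateaus (depth `h_depth_um`, default
1 µm — deep enough to ignore voxel noise, shallower than the
inscribed-radius drop at any mouth), boundaries use the negated
distance, labels are assigned in decreasing-volume order (label 1 =
largest = duct), and objects below `min_volume_um3` (default 500 µm³,
far below any alveolus at D_A ≈ 20 µm) are removed and logged. The duct
can also be identified as the largest instance touching both axial
faces, falling back to largest volume. On noise-free phantoms the split
recovers exactly duct + n alveoli and is idempotent; under heavy noise
it can oversplit (extra small instances), which the mIoU score exposes.

mIoU matches predicted to reference instances one-to-one by maximizing
total IoU (Hungarian assignment) and averages per-class IoU over the
foreground classes of the reference; unmatched reference classes score
zero.

## Dynamics and statistics

Structures are paired across states by persistent id (phantoms) or
nearest centroid within a maximum displacement; unmatched structures
are reported, never dropped silently. ε_A is derived from the membrane
area strain through ε = (1+ΔS)^(1/2) − 1; ε_ER directly from ring
perimeters (a perimeter is already a length). Both the area-route and
perimeter-route values are kept.

All tests are two-sided. The one-sample t accepts raw values or the
printed (mean, SEM, n) triple — t = (mean − null)/SEM, df = n − 1 — and
the two routes agree to machine precision; its p-values are calibrated
(type-I error 0.05 within binomial error over 10⁴ null replicates) and
agree with exact sign-flip permutation enumeration at n = 8. Welch's
unequal-variance t with Welch–Satterthwaite df serves as the pairwise
post-hoc after one-way ANOVA across PEEP groups; no multiplicity
adjustment is applied by default (Holm by flag). SEM uses the n−1
sample SD. Five-number summaries use linear-interpolation quartiles —
the convention is fixed here because spreadsheet implementations vary.
Tests treat individual structures (units, angle pairs) as independent
observations; mouse-level aggregation can be performed upstream by
averaging per-animal tables before testing.

## Problem sizes and numerical choices

The phantom recovery study runs 20 replicates per deformation mode at
0.65 µm on ~100³ grids (the acceptance script defaults to 8 per mode);
calibration simulations use 10⁴ replicates. Analytic phantom meshes at
refinement level 4 (128 azimuthal segments) agree with the closed forms
to ≤0.1%, comfortably inside the 0.5% tolerance the tests assert.
Quadratures use adaptive Gauss–Kronrod with guarded integrands at the
domain endpoints. Degenerate inputs raise typed errors throughout
(empty masks, unimodal histograms, structures under 10 voxels, open
meshes, zero SEM with a nonzero effect, single-group ANOVA).

## Known limitations

- Marching-cubes area bias (~+7% on binary masks) cancels in q and ε_A
  but makes absolute single-state areas systematically high; absolute S
  should be compared only between like-resolution volumes.
- ε_ER through the full watershed chain is noisier than through direct
  labels: the instance-splitting cut lands at slightly different
  positions along the mouth neck in the two states. Strain validation
  therefore measures on direct voxelizations; ring strains from
  watershed labels carry a few extra percent of scatter.
- The phantom's alveoli are spherical caps on a straight duct; real
  acini have polyhedral alveoli, shared septal walls, curved ducts and
  capillary texture. Results on phantoms validate the estimators, not
  anatomical realism.
- T_A is a 3D minimum over septal ridges; studies that measured wall
  thickness on 2D rendered views will differ systematically.
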