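# Methods

## Surface model

The reconstruction treats a stack of closed planar contours as boundary
conditions for a fairing problem on a triangulated tube. Contours are
closed simple polylines, one per slice, ordered along the slicing axis;
the two extreme slices must be delineated. Each contour is canonicalised
(counter-clockwise winding viewed down the +axis; start point at maximal
first-in-plane coordinate, ties broken by the second) and resampled to a
fixed number of points at equal arc length. Canonicalisation plus a
twist-minimising cyclic offset per gap (exhaustive search over all K
offsets, minimising total squared connecting-edge length) makes the
scaffold deterministic: the underlying problem — point correspondence
between unparameterised closed curves — has no unique answer, and this is
the simplest determinate choice consistent with connecting contours by
straight lines.

The scaffold inserts a fixed number of intermediate rings per gap (linear
interpolation at equal fractions of the gap, the "parallel contours"
initialisation), triangulates each band as quads split along the fixed
diagonal (i, j) → (i+1, j+1) — giving every interior vertex valence 6 —
and closes the tube with centroid-apex fans at both ends.

On the scaffold's graph the umbrella Laplacian `L` has unit diagonal,
off-diagonal −1/deg(v) at adjacencies, zero row sums. Order 1 (membrane,
spring force balance) solves `L x = 0` per coordinate on the unknown
vertices; order 2 (thin plate) solves `L² x = 0`. The default and
recommended order is 2: the membrane solution minimises area, necks inward
between rings and tolerates creases at the known contours, while the
thin-plate solution penalises curvature across the known rings and tracks
the intended smooth shape.

**Cap handling.** The fairing graph covers ring vertices only. The two cap
fans close the surface geometrically (their apices are fixed at the
extreme-ring centroids) but contribute no edges to the operator: a flat
centroid fan meets the tube at a right angle, and letting the bi-Laplacian
penalise curvature across that artificial disc pushes the rings near the
ends far outward (on a test pair of coaxial circles of radius 5 mm, mean
intermediate radii reached 6.5–7.0 mm; with cap edges excluded the
thin-plate solution stays at 4.95–5.0 mm and the membrane solution necks to
4.76 mm, the expected qualitative contrast). End slices are therefore flat;
the reconstruction does not extrapolate beyond the extreme contours.

**Solver.** Per coordinate the known columns move to the right-hand side
and the restricted sparse system is solved by BiCG, warm-started at the
linear-interpolation scaffold positions, relative tolerance 1e-8, maxiter
10·N; on non-convergence a sparse-LU direct solve takes over (systems here
are a few hundred to a few thousand unknowns; the fallback is capped at
20k unknowns). Known vertex positions are never written, so interpolation
of the delineated contours is exact. A default-size reconstruction
(7 contours × 100 points, 3 intermediate rings per gap → ~2.5k vertices)
takes ~20 ms.

## Parameter defaults

| parameter | default | notes |
|---|---|---|
| points per contour | 100 | overlap plateaus near 100; 10 is badly under-resolved |
| intermediate rings per gap | 3 | results depend only weakly on 1–6 |
| fairing order | 2 | thin plate; order 1 kept for comparison |
| minimum contours | 4 | both extreme slices always included |
| sparse selection | round(i·(S−1)/(k−1)) | even intervals, deterministic |
| overlap grid spacing | 0.5 mm | half the smallest default voxel size |

The sweep behaviour is reproduced by `experiments.run_sweep` on phantoms:
a large Jaccard jump from 10 to 50 points per contour, a plateau (|ΔJ| <
0.01) beyond 100 points, and < 0.02 variation across 1–6 intermediate
rings.

## Geometry and metrics

All geometry lives in world millimetres; label volumes carry a NIfTI
0-based voxel-centre → mm affine. Meshes come from topology-correct
(Lewiner) marching cubes at the 0.5 level of the binary field, padded by
one zero voxel so surfaces always close; no smoothing or decimation is
applied afterwards. Volumes use the divergence theorem over faces.

Point-in-mesh containment is a vectorised +z ray-crossing parity test:
projected triangles are tested with a half-open top-left rasterisation rule
so a ray grazing a shared edge or vertex is counted exactly once, and
points within a scaled tolerance of the surface count as inside
(deterministic boundary handling for grid points on faces). The overlap
grid is anchored at the joint bounding-box minimum padded by twice the
spacing, making the counts exactly symmetric in the two meshes. One known
artefact follows from the boundary convention: when a mesh face is exactly
grid-aligned (axis-aligned cubes evaluated on their own bounding-box grid)
the closed boundary adds a whole layer of grid points and refinement is no
longer monotone; any generic orientation restores clean convergence. On
half-overlapping unit cubes in generic orientation the estimator is within
0.01% of the analytic 1/3 at 0.02 mm spacing.

PVD is signed (first argument minus second, antisymmetric, range ±200%);
PVC is volume change relative to baseline, positive for shrinkage.
Registration is consumed, not estimated: a pre-computed 4×4 world affine
(e.g. a FLIRT matrix) can be applied to one mesh before comparison.

## Synthetic phantoms

Analytic solids (sphere, ellipsoid, cylinder, box) carry closed-form
volumes. The hippocampus-like phantom is an elliptical cross-section
(minor/major ratio 0.62) swept along a planar C-shaped centerline (total
bend 40°), with a linear head→tail taper (ratio 0.6) modulated by an
elliptic longitudinal profile that rounds the structure off toward both
extreme slices — a cut-off tube would place its largest contour on an end
slice, which manual outlining never produces. Cross-sections are defined in
the slice plane and the centerline is monotone along the slicing axis, so
every slice contains exactly one contour by construction. Defaults
(max semi-axis 10.5 mm, length 23 mm, 1×1×1.2 mm voxels) give ~20 occupied
slices and ~2.3 cm³, the regime of manually outlined hippocampi; the
continuum volume (dense quadrature of the closed-form cross-section area)
is stored as metadata.

Back-to-back pairs add independent band-limited boundary jitter (angular
harmonics 1–3 × longitudinal harmonics 0–2, unit-RMS-normalised Gaussian
coefficients scaled by σ in mm, no k=0 term so the perturbation is
mean-zero over the boundary) to the same underlying shape, emulating
independent re-delineations of same-session scans; pairwise Jaccard falls
smoothly with σ (≈0.92 at 0.2 mm, ≈0.80 at 0.5 mm, ≈0.64 at 1 mm).
Atrophic follow-ups shrink the cross-section radii by √(1−f) at fixed
length, so the continuum volume loss is exactly the requested fraction and
pairs are co-registered by construction. All randomness derives from one
integer seed; identical spec + seed is bit-reproducible.

What the phantoms do **not** emulate: MRI intensities and artefacts (the
method never reads intensities), protocol-specific boundary definitions,
inter-rater disagreement structure, multi-component or cavitated
anatomy, and the irregular shapes of pathology. Passing phantom tests shows
the machinery is correct for smooth single-contour-per-slice structures; it
does not certify accuracy on clinical data.

## Experiment designs and problem sizes

- *Agreement*: reconstructions from k = 4…10 contours against the full
  marching-cubes mesh. On the 21-slice ellipsoid phantom 7 contours reach
  Jaccard ≈ 0.93, non-decreasing in k (±0.01 noise).
- *Robustness*: reconstruct from scan A's contours, compare against scan
  B's full mesh and vice versa on a jittered pair; also reported are the
  biased within-scan agreement, the A-vs-B reproducibility ceiling, and
  their difference (the bias). Jitter only degrades cross-pair overlap, so
  agreement ≥ robustness and robustness cannot exceed the ceiling by more
  than grid noise.
- *Atrophy*: cohorts default to 20 baseline/follow-up pairs with volume
  loss spread over 0–10%; PVC is computed from full meshes and from
  7-contour reconstructions. These phantoms are rasterised at 0.5 mm: at
  scan-like 1 mm voxels the *full-mesh* PVC itself is quantisation-biased
  (slope ≈ 1.10 against truth, while the reconstruction tracks truth at
  ≈ 0.96), so the finer grid isolates the quantity under study. The
  reconstructed-vs-full slope is then ≈ 1.0. Because PVC is a ratio of two
  same-pipeline volumes, the contour-count-dependent volume bias cancels
  between time points: recovery error stays below one percentage point from
  4 contours upward and does not order monotonically in k on smooth
  phantoms.
- *Sweep*: 10 input contours, intermediate rings 1–6 × points per contour
  {10, 50, 100, 400}.

Cohort and grid sizes are desk-scale choices (single phantom geometry per
cohort, 20 subjects, 0.5 mm overlap grids) that keep the full suite and the
acceptance script in the tens of seconds while leaving every trend far from
its threshold.

## Known limitations

One contour per slice, no internal cavities (both rejected with explicit
errors); flat end caps (no extrapolation past the extreme contours); smooth
structures only — the thin-plate prior is wrong for irregular shapes such
as tumours; the uniform-weight umbrella operator ignores edge lengths, so
strongly anisotropic ring spacing biases the fair surface; containment
assumes watertight, consistently wound meshes.
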