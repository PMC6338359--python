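# fastsurf

Reconstruction of a closed anatomical surface — prototypically the
hippocampus on structural MRI — from a **sparse set of planar contours**, by
discrete surface fairing, together with the mesh-based metrics used to
evaluate such segmentations (grid-approximated Jaccard/Dice overlap,
percentage volume difference, longitudinal percentage volume change) and a
synthetic-phantom simulation framework.

Fully manual hippocampus delineation takes one to two hours per pair and is
the de-facto gold standard for volumetry and atrophy-rate measurement. The
slice-to-slice change of the hippocampal cross-section is small, so the full
surface can be recovered from a handful of outlined slices: the delineator
traces only a few contours (always including the two extreme slices), and the
surface in between is completed automatically in well under a second,
without image intensities, atlases, or shape priors.

## Method

Delineated contours are resampled to a fixed number of equally spaced
points and connected into a regular triangulated tube: between each pair of
known contour rings, intermediate rings are inserted by linear
interpolation, bands are triangulated, and point correspondence across each
gap is fixed by the cyclic offset minimising total squared connecting-edge
length (twist removal). On the connectivity graph of this scaffold the
discrete (umbrella) Laplacian is

```
L[n,m] = 1                  n = m
       = -1 / deg(v_n)      v_m adjacent to v_n
       = 0                  otherwise
```

Treating edges as equal-stiffness springs and demanding zero net force at
every vertex gives the membrane system `L x = L y = L z = 0` per coordinate,
whose solution is a minimal-surface-like completion that necks inward and
puts no penalty on the crease at the known contours. Minimising curvature
instead gives the thin-plate system `L² x = L² y = L² z = 0`. Known vertex
positions are moved to the right-hand side and the restricted sparse system
is solved per coordinate with the bi-conjugate gradient method (direct
sparse factorisation as fallback). The thin-plate (bi-Laplacian) solution is
the reconstruction.

Evaluation is mesh-based throughout: label volumes are converted to
watertight meshes with topology-correct marching cubes at the 0.5 iso-level,
volumes come from the divergence theorem, and overlap is estimated on a fine
regular grid enclosing both surfaces,

```
Jacc(A,B) ≈ N_{A∩B} / N_{A∪B},          D = 2J / (1 + J)
PVD(A,B)  = 2 (V_A − V_B)/(V_A + V_B) · 100
PVC(A,B)  = (V_A − V_B)/V_A · 100       (baseline → follow-up)
```

## Worked example

```python
import fastsurf as fs

# hippocampus-like phantom: curved, tapered tube at 1 x 1 x 1.2 mm voxels
vol = fs.make_phantom(fs.PhantomSpec(seed=1))          # ~2.3 cm^3, 20 slices
full = fs.mesh_from_labels(vol)                        # marching-cubes mesh

stack = fs.resample_stack(fs.extract_contours(vol, axis=2), 100)
sparse = fs.select_sparse(stack, 7)                    # keep 7 of 20 contours
recon = fs.reconstruct(sparse, order=2)                # bi-Laplacian fairing

report = fs.compare(full, recon, spacing=0.5)
print(f"jaccard {report.jaccard:.3f}  dice {report.dice:.3f}  "
      f"pvd {report.pvd:+.2f}%")
```

prints

```
jaccard 0.926  dice 0.962  pvd +1.35%
```

i.e. the surface reconstructed from 7 of the 20 contours overlaps the full
segmentation's mesh at Jaccard 0.93 (Dice 0.96) with a volume difference of
1.4% — comfortably above the Jaccard 0.67 / Dice 0.8 level usually taken as
good accuracy for a structure this small.

The same pipeline is scriptable from the shell:

```sh
fastsurf simulate --kind hippocampus --seed 7 --out phantom.nii.gz
fastsurf reconstruct --contours stack.json --order 2 --out mesh.ply
fastsurf evaluate --ref full.ply --test mesh.ply --spacing 0.5
fastsurf experiment agreement --seed 1 --out agreement.csv
```

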