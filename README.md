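# tubegeom

Lagrangian cylindrical coordinates for tubular anatomic surfaces.

Given an ordered stack of closed 3D cross-sectional lumen contours (for
example, orthogonal segmentations of a blood vessel), `tubegeom` builds a
material coordinate frame `(sigma, theta)`:

* **sigma** — signed arc length along the piecewise-linear centerline through
  the contour centroids, zero at the origin contour;
* **theta** — angular coordinate measured from a per-contour *Greenwich
  point*, anchored at a bifurcation-derived fiducial (the most distal
  intersection of mother and daughter lumen boundaries) and propagated along
  the vessel to form the Greenwich curve (the surface's prime meridian).

On this frame it quantifies:

* pointwise **longitudinal and circumferential surface curvature** by
  windowed three-point circle fitting (reciprocal circumradius), plus
  product/mean proxies for Gaussian and mean curvature;
* generalized **cross-sectional eccentricity** `e = sqrt(1 - d^2/D^2)` from
  the orthogonal centroid-diameter pair minimizing `d/D`, its orientation
  `theta_e` relative to the Greenwich direction, and the spirality
  `d(theta_e)/d(sigma)`;
* pointwise **difference fields** between two states (e.g. systole/diastole)
  of the same vessel, matched by Lagrangian labels.

Two idealized software phantoms with full analytic references (a simple
90-degree bend with circular sections, and a complex two-bend phantom with
rotating elliptical sections) are first-class generators used for validation
and window-size studies.

All coordinates are in mm; curvature is reported in 1/cm by default
(`--units mm` for 1/mm).

## CLI

```bash
# generate a phantom as contour-set files
tubegeom phantom complex --out work/phantom

# full analysis: curvature fields, eccentricity profile, Greenwich curve, VTK
tubegeom analyze work/phantom/mother.json \
    --fiducial-branch work/phantom/branch.json --fiducial-tolerance 2.5 \
    --out work/results

# difference field between two states of the same vessel
tubegeom compare state_a.json state_b.json --fiducial-point 10,0,25 --out work/diff

# window-size study against a phantom's analytic reference
tubegeom sweep work/phantom/mother.json --kind complex --windows 20,30,40 \
    --fiducial-branch work/phantom/branch.json --fiducial-tolerance 2.5 \
    --out work/sweep
```

The fiducial can come from a daughter-branch contour set
(`--fiducial-branch`), an explicit 3D point (`--fiducial-point x,y,z`), or an
`(arc_mm, angle_rad)` seed (`--fiducial-seed`).  Contour sets are JSON
documents (`units`, `contours: [{index, points}]`) or a flat CSV with columns
`contour_id,x,y,z`.

Outputs per analysis: `nodes.csv` (per-point sigma, theta, r, curvatures,
proxies; masked values are empty cells), `contours.csv` (per-contour
eccentricity records and spirality), `greenwich.csv` (the Greenwich
polyline), and `surface.vtk` (legacy-ASCII polydata with curvature scalars).

## Python API

```python
import tubegeom as tg

mother, branch, ref = tg.generate_complex()
result = tg.analyze(mother, daughter=branch,
                    config=tg.AnalysisConfig(fiducial_tolerance=2.5))
result.longitudinal          # CurvatureField (1/cm)
result.eccentricity          # per-contour records (sigma, D, d, e, theta_e)
tg.phantoms.error_summary(result.longitudinal, ref)
```

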