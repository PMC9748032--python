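# lesionfit3d

3D measurement of prostate tumours from MRI segmentation masks by
constrained ellipsoid fitting — with the radiologist-style 2D measurements
it is compared against, PI-RADS v2.1 size-criterion rescoring, and
method-agreement statistics.

## The problem

Prostate MRI protocols acquire thick axial slices (typically 3 mm) separated
by an inter-slice gap (3 mm), while in-plane resolution is sub-millimetre.
Clinical practice measures a lesion's maximum diameter on the single axial
slice where it looks largest, and estimates volume — if at all — by
planimetry (per-slice contoured areas × slice profile).  But a tumour's true
maximum diameter (TMD) can point in **any** direction; when the major axis is
oblique to the axial plane, the in-plane measurement systematically
underestimates it.  This matters clinically: PI-RADS v2.1 separates
assessment category 4 from 5 by a TMD cut-off of 1.5 cm.

`lesionfit3d` measures lesions in 3D.  Per-slice ROIs are stacked, the
gapped slices are resampled to 1 mm by shape-based interpolation (linear
interpolation of per-slice signed distance maps), sub-voxel surface samples
are extracted, and an ellipsoid

$$\frac{x^2}{a^2} + \frac{y^2}{b^2} + \frac{z^2}{c^2} = 1$$

is fitted by least squares on the general quadric
`a x² + b y² + c z² + 2f yz + 2g xz + 2h xy + 2p x + 2q y + 2r z + d = 0`
under the ellipsoid-specific constraint

$$kJ - I^2 = 1,\qquad I = a+b+c,\quad J = ab+bc+ac-f^2-g^2-h^2,\quad k = 4,$$

solved non-iteratively via block elimination and a 6×6 generalized
eigenproblem.  The clinical outputs are

$$\mathrm{TMD} = 2a \quad\text{(major axis, any orientation)},\qquad
  V = \tfrac{4\pi}{3}\,abc .$$

## Worked example

Rasterize a known ellipsoidal lesion (semi-axes 15 × 10 × 6 mm, major axis
tilted 30° out of the axial plane) on a T2-like grid (0.49 mm in-plane,
3 mm slices + 3 mm gap) and measure it both ways:

```python
from lesionfit3d import LesionEllipsoidModel
from lesionfit3d.measure import axial_max_diameter, planimetric_volume
from lesionfit3d.synthetic import PhantomSpec, t2_grid, voxelize_ellipsoid

g = t2_grid(nx=100, ny=100, nz=12)
centre = (24.255, 24.255, 34.5)          # 1.5 mm off the slice lattice
spec = PhantomSpec(center=centre, semi_axes=(15.0, 10.0, 6.0),
                   grid=g, euler_deg=(0, 30, 0))
mask, truth = voxelize_ellipsoid(spec)   # truth: TMD 3.00 cm, TV 3.77 cc

print(LesionEllipsoidModel(mask).fit().summary())
print(f"manual-style: TMD {axial_max_diameter(mask):.2f} cm, "
      f"TV {planimetric_volume(mask):.2f} cc")
```

Output:

```
Constrained ellipsoid fit (kJ - I^2 = 1)
============================================
constraint k                    4
points fitted                5536
residual RMS            1.525e-01
centre (mm)            (23.97, 24.25, 34.64)
semi-axes a,b,c (mm)   (14.07, 8.76, 6.63)
max diameter TMD (cm)        2.81
volume TV (cc)               3.42

manual-style: TMD 1.96 cm, TV 3.83 cc
```

The ellipsoid fit recovers the tilted major axis (2.81 cm vs 3.00 cm true,
−6%), while the axial in-plane measurement sees only 1.96 cm (−35%) — the
lesion would be mis-sized against the 1.5 cm PI-RADS threshold family of
decisions whenever the truth straddles it.  Volumes agree within 10–15% of
the analytic 3.77 cc despite the 6 mm through-plane sampling.  The residual
RMS is the dimensionless unit-form misfit (0 for a perfect ellipsoid).

## Command line

Each workflow stage is a subcommand:

```bash
lesionfit3d fit      --mask lesion.nii.gz --thickness 3 --gap 3 --out fit.json
lesionfit3d measure  --mask lesion.nii.gz --thickness 3 --gap 3 --mode both
lesionfit3d rescore  --cohort cohort.csv --score3-n 10 --score4-n 18 --out rescore.json
lesionfit3d stats    --cohort cohort.csv --out report.json --plots figs/
lesionfit3d simulate --n3 10 --n4 18 --n5 15 --seed 7 --out cohort.csv
```

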