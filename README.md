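# headforge

A desk-scale, fully synthetic re-implementation of the computational chain used to
build and validate a multi-modal anatomical head model:

- **phantom** — analytic head-phantom generator (nested skin / 3-layer skull / CSF /
  GM / WM / ventricles / eyes) with rendered T1/T2-like contrasts, simulated raters
  with known sensitivity/specificity, ground-truth diffusion-tensor fields and
  synthetic DWI stacks. All ground truth is exact; no image downloads are needed.
- **segtools** — segmentation primitives: Gaussian smoothing (mm-space kernels),
  Otsu/manual thresholding, 6-connected region growing, k-means intensity
  clustering, morphological cleanup (open/close/island-removal/hole-fill) and
  distance-transform inter-slice interpolation.
- **register** — 12-DOF affine registration maximising normalised mutual
  information (Studholme dialect), with a coarse-to-fine pyramid, Parzen-windowed
  joint histograms and a derivative-free optimiser.
- **consensus** — binary STAPLE: EM estimation of a hidden consensus segmentation
  plus per-rater sensitivity/specificity, with fixed or estimated prevalence and an
  optional mean-field spatial prior.
- **validate** — Dice, modified Hausdorff distance (boundary-voxel based),
  Kruskal-Wallis (chi-square and exact-permutation), Monte-Carlo Lilliefors, and a
  rater-variability study driver producing per-structure CSV/JSON reports.
- **surfaces** — conformal multi-region surface extraction from label volumes
  (shared-vertex, tagged interfaces), Taubin smoothing, guarded edge-collapse
  simplification (normal-flip / degeneracy / tag / self-intersection guards,
  quadric vertex placement) and a mesh-quality audit.
- **dti** — log-linear diffusion-tensor fitting, FA, tissue masking, the linear
  tensor-to-conductivity map with eigenvalue capping (1.8 S/m default) and tensor
  resampling onto solver grids.
- **solver** — quasi-electrostatic forward solvers: 7-point finite-volume voxel
  solver (scalar/diagonal conductivities) and a structured-tetrahedra P1 FEM
  supporting full anisotropic tensors; electrode montages (Fpz-Cz and Cz-ring
  presets), montage comparison and scalar-vs-tensor field studies.
- **pipeline** — end-to-end seeded studies: segmentation-validation
  (raters → STAPLE → Dice/MHD → statistics) and tACS (DWI → tensors →
  conductivity → field solves), with provenance metadata.

## Command line

```bash
headforge phantom make --out run/phantom --seed 1 --shape 48 48 48 --spacing 2 2 2
headforge seg smooth --image run/phantom/t1.nii --fwhm 1 1 1 --out run/smooth.nii
headforge seg threshold --image run/smooth.nii --out run/mask.nii
headforge register run --moving t2.nii --fixed t1.nii --out T.json
headforge staple run --masks a.nii --masks b.nii --masks c.nii --out run/staple
headforge surface extract --labels run/phantom/labels.nii --out run/surf
headforge dti fit --dwi dwi.nii --bvals bvals --bvecs bvecs --out run/dti
headforge solve voxel --sigma sigma.nii --montage montage.json --out run/fields
headforge validate --out run/validation --seed 1     # full validation study
headforge tacs --out run/tacs --seed 1               # full tACS study
```

## Conventions

- Grids are (x, y, z)-indexed with voxel-centre world coordinates
  `origin + spacing * index` in mm; NIfTI affines are diagonal.
- Foreground connectivity is 6-connected everywhere.
- Affine transforms are `T·R·Sh·Sc` (translation mm, rotation rad `Rz·Ry·Rx`,
  upper-triangular unit shear, scale), serialised as JSON with the 4×4 matrix.
- Every stochastic operation takes an explicit integer seed and is a pure
  function of (inputs, seed).
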