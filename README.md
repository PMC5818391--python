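# nemaquant

Synthetic NEMA IEC body-phantom imaging plus the segmentation and
quantification procedures used in emission-tomography image-quality studies:
threshold VOIs, background-adapted threshold VOIs, CT-based ROIs, recovery
coefficients, threshold sweeps for volume recovery, line profiles and
contrast-to-noise detectability scores.

The phantom (six hot spheres of 10–37 mm inner diameter, a 51-mm cylindrical
lung insert, a torso-shaped background compartment) is modelled analytically
and rasterized onto SPECT-like (9.3-mm isotropic voxels, counts) or PET-like
(3.65 × 3.65 × 3.27-mm voxels, kBq/mL) grids. Reconstructed-image properties
are emulated in image space by a stationary Gaussian PSF plus a noise model;
projection-domain physics and tomographic reconstruction are out of scope.

## Layout

| module | contents |
| --- | --- |
| `nemaquant.geometry` | phantom model, grids, rasterization, CT reference ROIs |
| `nemaquant.simulator` | activity composition, blur, noise, modality presets |
| `nemaquant.segmentation` | threshold / background-adapted / CT VOI methods |
| `nemaquant.quantification` | calibration, recovery coefficients, threshold sweeps |
| `nemaquant.reporting` | line profiles, detectability, batch experiment driver |
| `nemaquant.io` | NIfTI image/mask I/O with JSON sidecars |
| `nemaquant.cli` | `nemaquant` command-line entry point |

## CLI

```sh
# simulate a PET-like image at sphere-to-background ratio 5:1
nemaquant simulate --preset pet-ga68 --sbr 5:1 --seed 1 -o img.nii

# segment the 37-mm sphere with a background-adapted 40% threshold
nemaquant segment img.nii --sphere sphere_37mm --method adapted --threshold 0.4 -o voi.nii

# quantify max/mean/volume over the VOI
nemaquant quantify img.nii voi.nii --true-concentration 20

# threshold sweep (10–90% in steps of 10) and best-threshold report
nemaquant sweep img.nii --method threshold --sphere-concentration 20 --best volume -o sweep.csv

# line profile through the 37- and 17-mm sphere centres
nemaquant profile img.nii -o profile.csv

# full experiment matrix (presets x SBR levels x seeds) with manifest
nemaquant run --out-dir results --seeds 1,2,3
```

All images are NIfTI with a `.json` sidecar carrying the value unit
(`counts` or `kBq/mL`) and provenance (preset, seed, noise, blur).

## Assumptions

Quantities the reference protocols leave unstated are explicit, overridable
defaults: reconstructed PSF FWHM (12 mm SPECT-like, 6.5 mm PET-like, plus a
2.5-mm positron-range surrogate for the ga-68 preset), Gaussian noise level
(10% / 2% of the sphere maximum), sphere layout (centres coplanar on a
114.4-mm circle), the stadium-shaped body outline, background-ROI placement,
and the 26-connectivity / seeded-growth rule for threshold VOIs. Gibbs
ringing from resolution-modelling reconstruction is not simulated.
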