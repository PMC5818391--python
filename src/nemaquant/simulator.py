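"""Synthetic SPECT-like / PET-like image generation.

Reconstructed-image properties are emulated directly in image space: the
partial-volume-exact activity map is convolved with a stationary Gaussian
point-spread function and noise is added on top.  Projection-domain physics
(attenuation, scatter, tomographic reconstruction) is deliberately out of
scope; see the preset docstrings for the default resolution/noise stand-ins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import AlignmentError, InvalidArgumentError
from .geometry import FractionMap, GridSpec, PhantomGeometry, voxelize

__all__ = [
    "ActivityConfig",
    "AcquisitionConfig",
    "ImageVolume",
    "NoiseModel",
    "compose_activity",
    "blur",
    "add_noise",
    "simulate",
    "preset",
    "PRESET_NAMES",
    "FWHM_TO_SIGMA",
]

log = logging.getLogger(__name__)

#: Conversion from Gaussian FWHM to standard deviation.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # = 1/2.3548


@dataclass(frozen=True)
class ActivityConfig:
    """Compartment activity concentrations in kBq/mL.

    All six spheres share one concentration (they are filled from the same
    solution); ``background_concentration == 0`` encodes the no-background
    (NB) condition.
    """

    sphere_concentration: float
    background_concentration: float = 0.0
    lung_concentration: float = 0.0

    def __post_init__(self):
        for v in (
            self.sphere_concentration,
            self.background_concentration,
            self.lung_concentration,
        ):
            if v < 0:
                raise InvalidArgumentError("concentrations must be >= 0")

    @property
    def is_nb(self) -> bool:
        return self.background_concentration == 0.0

    @property
    def sbr(self) -> float | None:
        """Sphere-to-background ratio; None in the NB condition."""
        if self.is_nb:
            return None
        return self.sphere_concentration / self.background_concentration

    @property
    def sbr_label(self) -> str:
        return "NB" if self.is_nb else f"{self.sbr:g}:1"

    @classmethod
    def from_sbr(cls, sbr: float | str | None, sphere_concentration: float = 20.0) -> "ActivityConfig":
        """Build a config from an SBR given as number, "5:1"-style string or "NB"."""
        if sbr is None or (isinstance(sbr, str) and sbr.upper() == "NB"):
            return cls(sphere_concentration, 0.0)
        if isinstance(sbr, str):
            sbr = float(sbr.split(":")[0]) / float(sbr.split(":")[1]) if ":" in sbr else float(sbr)
        if sbr <= 0:
            raise InvalidArgumentError("SBR must be positive")
        return cls(sphere_concentration, sphere_concentration / sbr)

    def concentration_of(self, compartment: str) -> float:
        if compartment.startswith("sphere"):
            return self.sphere_concentration
        if compartment == "background":
            return self.background_concentration
        if compartment == "lung":
            return self.lung_concentration
        return 0.0  # outside


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic perturbation applied after blurring.

    kind 'gaussian': additive N(0, magnitude * image maximum).
    kind 'poisson' : values v -> Poisson(v * magnitude) / magnitude, i.e.
    magnitude is the counts-per-image-unit scale.
    """

    kind: str = "none"  # none | gaussian | poisson
    magnitude: float = 0.0

    def __post_init__(self):
        if self.kind not in ("none", "gaussian", "poisson"):
            raise InvalidArgumentError(f"unknown noise kind {self.kind!r}")
        if self.magnitude < 0:
            raise InvalidArgumentError("noise magnitude must be >= 0")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Everything about the virtual camera except the activity fill."""

    modality: str  # spect-like | pet-like
    psf_fwhm: tuple[float, float, float]  # mm
    extra_blur_fwhm: float = 0.0  # mm, positron-range surrogate
    noise: NoiseModel = field(default_factory=NoiseModel)
    sensitivity_factor: float | None = None  # cps per MBq per voxel (spect-like)
    duration: float = 0.0  # s, effective per-voxel acquisition time
    value_unit: str = "kBq/mL"  # counts | kBq/mL

    def __post_init__(self):
        if self.modality not in ("spect-like", "pet-like"):
            raise InvalidArgumentError(f"unknown modality {self.modality!r}")
        if any(f < 0 for f in self.psf_fwhm) or self.extra_blur_fwhm < 0:
            raise InvalidArgumentError("FWHM values must be >= 0")
        if self.modality == "spect-like" and self.value_unit != "counts":
            raise InvalidArgumentError("spect-like images are in counts")
        if self.modality == "pet-like" and self.value_unit != "kBq/mL":
            raise InvalidArgumentError("pet-like images are in kBq/mL")
        if self.modality == "spect-like":
            if self.sensitivity_factor is None or self.sensitivity_factor <= 0:
                raise InvalidArgumentError("spect-like needs a positive sensitivity_factor")
            if self.duration <= 0:
                raise InvalidArgumentError("spect-like needs a positive duration")


@dataclass
class ImageVolume:
    """A 3-D scalar image with grid, unit tag and free-form provenance."""

    values: np.ndarray
    grid: GridSpec
    value_unit: str = "kBq/mL"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if tuple(self.values.shape) != tuple(self.grid.dims):
            raise AlignmentError(
                f"image shape {self.values.shape} != grid dims {self.grid.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("image values must be finite")

    def with_values(self, values: np.ndarray, **prov) -> "ImageVolume":
        return ImageVolume(
            values=values,
            grid=self.grid,
            value_unit=self.value_unit,
            provenance={**self.provenance, **prov},
        )


def compose_activity(fractions: FractionMap, activity: ActivityConfig) -> ImageVolume:
    """Partial-volume-exact ground-truth activity map in kBq/mL.

    Each voxel value is the fraction-weighted sum of compartment
    concentrations.
    """
    values = np.zeros(fractions.grid.dims, dtype=float)
    for name, frac in fractions.items():
        c = activity.concentration_of(name)
        if c != 0.0:
            values += c * frac
    return ImageVolume(
        values=values,
        grid=fractions.grid,
        value_unit="kBq/mL",
        provenance={"stage": "compose_activity", "sbr": activity.sbr_label},
    )


def blur(image: ImageVolume, fwhm: tuple[float, float, float] | float) -> ImageVolume:
    """Gaussian blur with per-axis FWHM in mm; FWHM 0 is the identity."""
    if np.isscalar(fwhm):
        fwhm = (float(fwhm),) * 3
    if any(f < 0 for f in fwhm):
        raise InvalidArgumentError("FWHM must be >= 0")
    if all(f == 0 for f in fwhm):
        return image
    sigma_vox = [f * FWHM_TO_SIGMA / s for f, s in zip(fwhm, image.grid.spacing)]
    values = ndimage.gaussian_filter(image.values, sigma=sigma_vox, mode="constant")
    return image.with_values(values, blur_fwhm_mm=tuple(fwhm))


def add_noise(image: ImageVolume, noise: NoiseModel, seed=None) -> ImageVolume:
    """Apply a noise model; identical seed and inputs give identical output."""
    if noise.kind == "none" or noise.magnitude == 0.0:
        return image
    rng = np.random.default_rng(seed)
    if noise.kind == "gaussian":
        sigma = noise.magnitude * float(image.values.max())
        values = image.values + rng.normal(0.0, sigma, size=image.values.shape)
    else:  # poisson
        expected = image.values * noise.magnitude
        if np.any(expected < 0):
            warnings.warn("negative expected counts clamped to 0", stacklevel=2)
            log.warning("negative expected counts clamped to 0 before Poisson draw")
            expected = np.clip(expected, 0.0, None)
        values = rng.poisson(expected).astype(float) / noise.magnitude
    return image.with_values(values, noise=(noise.kind, noise.magnitude), seed=seed)


def _concentration_to_counts(image: ImageVolume, acq: AcquisitionConfig) -> ImageVolume:
    """kBq/mL -> expected counts per voxel via the configured sensitivity."""
    mbq_per_voxel = image.values / 1000.0 * image.grid.voxel_volume_ml
    counts = mbq_per_voxel * acq.sensitivity_factor * acq.duration
    out = image.with_values(counts, calibration="sensitivity_factor")
    out.value_unit = "counts"
    return out


def simulate(
    geometry: PhantomGeometry,
    grid: GridSpec,
    activity: ActivityConfig,
    acq: AcquisitionConfig,
    seed=None,
    fractions: FractionMap | None = None,
    subsampling: int = 2,
) -> ImageVolume:
    """Full image-formation chain: compose, blur, calibrate, add noise.

    A precomputed ``fractions`` map (from :func:`~nemaquant.geometry.voxelize`)
    may be passed to amortize rasterization across seeds and activity levels;
    it must be aligned with ``grid``.
    """
    if fractions is None:
        fractions = voxelize(geometry, grid, subsampling=subsampling)
    elif fractions.grid != grid:
        raise AlignmentError("fractions were rasterized on a different grid")
    image = compose_activity(fractions, activity)
    image = blur(image, acq.psf_fwhm)
    if acq.extra_blur_fwhm > 0:
        image = blur(image, acq.extra_blur_fwhm)
    if acq.modality == "spect-like":
        image = _concentration_to_counts(image, acq)
    image = add_noise(image, acq.noise, seed=seed)
    image.provenance.update(modality=acq.modality, seed=seed)
    return image


# --- presets -----------------------------------------------------------

PRESET_NAMES = ("spect-in111", "pet-ga68", "pet-f18")

# Reconstructed-resolution and noise defaults are stand-ins chosen in the
# clinically typical range (the reference protocols do not state them); all
# are overridable via replace()/config.
_SPECT_GRID = GridSpec.centered((64, 64, 25), (9.3, 9.3, 9.3))
_PET_GRID = GridSpec.centered((192, 192, 63), (3.65, 3.65, 3.27))


def preset(name: str) -> tuple[GridSpec, AcquisitionConfig]:
    """Named (grid, acquisition) presets for the two virtual cameras.

    - ``spect-in111``: 64x64 matrix, 9.3-mm isotropic voxels, counts,
      12-mm PSF, 10% gaussian noise, sensitivity-factor calibration.
    - ``pet-ga68``: 192x192 matrix, 3.65/3.65/3.27-mm voxels, kBq/mL,
      6.5-mm PSF plus a 2.5-mm positron-range surrogate blur, 2% noise.
    - ``pet-f18``: as pet-ga68 but without the extra blur term.
    """
    if name == "spect-in111":
        return _SPECT_GRID, AcquisitionConfig(
            modality="spect-like",
            psf_fwhm=(12.0, 12.0, 12.0),
            extra_blur_fwhm=0.0,
            noise=NoiseModel("gaussian", 0.10),
            sensitivity_factor=5.0,
            duration=3584.0,  # 28 s/angle x 128 projections, as one scalar
            value_unit="counts",
        )
    if name in ("pet-ga68", "pet-f18"):
        return _PET_GRID, AcquisitionConfig(
            modality="pet-like",
            psf_fwhm=(6.5, 6.5, 6.5),
            extra_blur_fwhm=2.5 if name == "pet-ga68" else 0.0,
            noise=NoiseModel("gaussian", 0.02),
            duration=180.0,
            value_unit="kBq/mL",
        )
    raise InvalidArgumentError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")


def with_noise(acq: AcquisitionConfig, noise: NoiseModel) -> AcquisitionConfig:
    """Convenience: same acquisition with a different noise model."""
    return replace(acq, noise=noise)
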