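"""Phantom generation and projection-domain low-dose CT simulation.

The training and evaluation data for the denoiser are fully synthetic:
elliptical phantoms in Hounsfield units, forward-projected to a parallel-beam
sinogram, corrupted with Poisson noise on the transmitted photon counts, and
reconstructed with filtered back projection (FBP). This mirrors the standard
way low-dose acquisitions are emulated from normal-dose images: noise is
injected in the projection domain, where photon statistics actually live,
rather than in the image domain.

Conventions
-----------
* Hounsfield units: air = -1000 HU, water = 0 HU.
* HU -> linear attenuation: ``mu = mu_water * (1 + HU/1000)`` clipped at 0,
  with ``mu_water = 0.02 / mm`` by default.
* Sinogram values are line integrals of ``mu`` (dimensionless, since mu is
  per mm and path length is in mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import radon, iradon

__all__ = [
    "AIR_HU",
    "WATER_HU",
    "DEFAULT_MU_WATER",
    "PhantomSpec",
    "CTImage",
    "Sinogram",
    "PatchPair",
    "Ellipse",
    "generate_phantom",
    "random_phantom_spec",
    "forward_project",
    "fbp_reconstruct",
    "simulate_low_dose",
    "extract_patches",
    "hu_to_mu",
    "mu_to_hu",
]

AIR_HU = -1000.0
WATER_HU = 0.0
DEFAULT_MU_WATER = 0.02  # 1/mm, water linear attenuation at diagnostic energies

#: HU assigned to each tissue class of a phantom. Bone sits above the
#: 320 HU bone-water clustering floor by construction.
DEFAULT_HU_PER_CLASS = {
    "air": -1000.0,
    "water": 0.0,
    "soft": 40.0,
    "bone": 1000.0,
    "metal": 3000.0,
}


@dataclass(frozen=True)
class Ellipse:
    """One elliptical insert, in canvas-relative coordinates ([0, 1] square)."""

    center: tuple[float, float]        # (x, y), relative
    semi_axes: tuple[float, float]     # (a, b), relative
    rotation_deg: float
    tissue: str

    def extent(self) -> tuple[float, float]:
        """Half-width/half-height of the axis-aligned bounding box."""
        a, b = self.semi_axes
        th = math.radians(self.rotation_deg)
        ex = math.hypot(a * math.cos(th), b * math.sin(th))
        ey = math.hypot(a * math.sin(th), b * math.cos(th))
        return ex, ey


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a deterministic elliptical phantom."""

    canvas_size: int
    ellipses: tuple[Ellipse, ...] = ()
    hu_per_class: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HU_PER_CLASS))
    seed: int = 0

    def __post_init__(self):
        if self.canvas_size < 32:
            raise ValueError(f"canvas_size must be >= 32, got {self.canvas_size}")
        object.__setattr__(self, "ellipses", tuple(self.ellipses))
        for e in self.ellipses:
            if e.tissue not in self.hu_per_class:
                raise ValueError(f"unknown tissue class {e.tissue!r}")
            ex, ey = e.extent()
            cx, cy = e.center
            if not (0.0 <= cx - ex and cx + ex <= 1.0
                    and 0.0 <= cy - ey and cy + ey <= 1.0):
                raise ValueError(f"ellipse {e} extends outside the unit canvas")


@dataclass
class CTImage:
    """A 2-D slice in Hounsfield units with isotropic pixel spacing (mm)."""

    values: np.ndarray
    pixel_spacing: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("CTImage requires a non-empty 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CTImage values must be finite")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class Sinogram:
    """Parallel-beam line integrals: rows are view angles, columns detectors."""

    values: np.ndarray                 # (n_angles, n_detectors)
    angles: np.ndarray                 # degrees, in [0, 180)
    pixel_spacing: float = 1.0
    incident_photons: float | None = None  # I0; None means noise-free

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.values.shape[0] != self.angles.size:
            raise ValueError("one angle per sinogram row required")
        if self.angles.size < 16:
            raise ValueError("at least 16 projection angles required")
        if self.incident_photons is not None and self.incident_photons <= 0:
            raise ValueError("incident_photons must be positive")


@dataclass
class PatchPair:
    """Co-located noisy/clean training patches cut from a paired image set."""

    noisy: np.ndarray
    clean: np.ndarray
    source_index: int = 0
    offset: tuple[int, int] = (0, 0)

    def __post_init__(self):
        if self.noisy.shape != self.clean.shape:
            raise ValueError("noisy and clean patches must share a shape")


def hu_to_mu(hu: np.ndarray, mu_water: float = DEFAULT_MU_WATER) -> np.ndarray:
    """HU -> linear attenuation (1/mm), clipped at zero."""
    return np.clip(mu_water * (1.0 + np.asarray(hu, dtype=np.float64) / 1000.0),
                   0.0, None)


def mu_to_hu(mu: np.ndarray, mu_water: float = DEFAULT_MU_WATER) -> np.ndarray:
    return 1000.0 * (np.asarray(mu, dtype=np.float64) / mu_water - 1.0)


def generate_phantom(spec: PhantomSpec, pixel_spacing: float = 1.0) -> CTImage:
    """Rasterize a phantom spec; overlaps resolve to the last-listed ellipse."""
    n = spec.canvas_size
    # pixel centers on the unit square
    coords = (np.arange(n) + 0.5) / n
    xx, yy = np.meshgrid(coords, coords)   # xx: column coord, yy: row coord
    img = np.full((n, n), spec.hu_per_class.get("air", AIR_HU), dtype=np.float64)
    for e in spec.ellipses:
        cx, cy = e.center
        a, b = e.semi_axes
        th = math.radians(e.rotation_deg)
        xr = (xx - cx) * math.cos(th) + (yy - cy) * math.sin(th)
        yr = -(xx - cx) * math.sin(th) + (yy - cy) * math.cos(th)
        mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        img[mask] = spec.hu_per_class[e.tissue]
    return CTImage(img, pixel_spacing=pixel_spacing)


def random_phantom_spec(seed: int, canvas_size: int = 128,
                        n_inserts: int = 5) -> PhantomSpec:
    """A randomized torso-like phantom: a large water body with random
    soft/bone/water inserts. Used to build varied training sets."""
    rng = np.random.default_rng(seed)
    ellipses = [Ellipse((0.5, 0.5), (0.38, 0.30), float(rng.uniform(0, 180)),
                        "water")]
    tissues = ["soft", "bone", "water"]
    for _ in range(n_inserts):
        tissue = tissues[int(rng.integers(len(tissues)))]
        a = float(rng.uniform(0.03, 0.10))
        b = float(rng.uniform(0.03, 0.10))
        # keep inserts inside the body ellipse
        r = float(rng.uniform(0.0, 0.18))
        phi = float(rng.uniform(0.0, 2 * math.pi))
        center = (0.5 + r * math.cos(phi), 0.5 + r * math.sin(phi))
        ellipses.append(Ellipse(center, (a, b), float(rng.uniform(0, 180)), tissue))
    return PhantomSpec(canvas_size=canvas_size, ellipses=tuple(ellipses),
                       seed=seed)


def forward_project(image: CTImage, n_angles: int = 180,
                    mu_water: float = DEFAULT_MU_WATER) -> Sinogram:
    """Parallel-beam Radon transform of the attenuation map derived from HU."""
    if n_angles < 16:
        raise ValueError("n_angles must be >= 16")
    mu = hu_to_mu(image.values, mu_water)
    angles = np.linspace(0.0, 180.0, n_angles, endpoint=False)
    # radon sums pixel values along rays in pixel-length units
    sino_px = radon(mu, theta=angles, circle=False)   # (n_det, n_angles)
    return Sinogram(values=sino_px.T * image.pixel_spacing, angles=angles,
                    pixel_spacing=image.pixel_spacing)


def fbp_reconstruct(sino: Sinogram, output_size: int,
                    mu_water: float = DEFAULT_MU_WATER) -> CTImage:
    """Ramp-filtered back projection back to Hounsfield units."""
    mu = iradon(sino.values.T / sino.pixel_spacing, theta=sino.angles,
                filter_name="ramp", interpolation="linear",
                circle=False, output_size=output_size)
    return CTImage(mu_to_hu(mu, mu_water), pixel_spacing=sino.pixel_spacing)


def add_poisson_noise(sino: Sinogram, incident_photons: float, seed: int,
                      electronic_sigma: float = 0.0) -> Sinogram:
    """Replace each line integral p with -log(N / I0), N ~ Poisson(I0 e^-p).

    Counts are floored at 1 before the log so fully opaque rays stay finite.
    ``electronic_sigma`` optionally adds zero-mean Gaussian noise (in counts)
    on top of the Poisson draw; it is off by default.
    """
    if incident_photons <= 0:
        raise ValueError("incident_photons must be positive")
    rng = np.random.default_rng(seed)
    expected = incident_photons * np.exp(-sino.values)
    counts = rng.poisson(expected).astype(np.float64)
    if electronic_sigma > 0:
        counts += rng.normal(0.0, electronic_sigma, size=counts.shape)
    counts = np.maximum(counts, 1.0)
    noisy = np.log(incident_photons / counts)
    return Sinogram(values=noisy, angles=sino.angles.copy(),
                    pixel_spacing=sino.pixel_spacing,
                    incident_photons=incident_photons)


def simulate_low_dose(image: CTImage, incident_photons: float, seed: int,
                      n_angles: int = 180,
                      mu_water: float = DEFAULT_MU_WATER,
                      electronic_sigma: float = 0.0) -> CTImage:
    """Simulate a low-dose acquisition of a (noise-free) CT image.

    Pipeline: forward project -> transmission counts ``I0 exp(-p)`` ->
    Poisson draw -> log back to line integrals -> ramp-filter FBP.
    Deterministic for a fixed seed.
    """
    sino = forward_project(image, n_angles=n_angles, mu_water=mu_water)
    noisy = add_poisson_noise(sino, incident_photons, seed,
                              electronic_sigma=electronic_sigma)
    return fbp_reconstruct(noisy, output_size=image.shape[0], mu_water=mu_water)


def extract_patches(noisy: CTImage, clean: CTImage, patch_size: int = 48,
                    n_patches: int = 100, seed: int = 0,
                    source_index: int = 0) -> list[PatchPair]:
    """Cut co-located random patches from a paired noisy/clean image."""
    if noisy.shape != clean.shape:
        raise ValueError("paired images must share a shape")
    h, w = noisy.shape
    if patch_size > h or patch_size > w:
        raise ValueError(f"patch_size {patch_size} exceeds image shape {noisy.shape}")
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, h - patch_size + 1, size=n_patches)
    cols = rng.integers(0, w - patch_size + 1, size=n_patches)
    out = []
    for r, c in zip(rows, cols):
        r, c = int(r), int(c)
        out.append(PatchPair(
            noisy=noisy.values[r:r + patch_size, c:c + patch_size].copy(),
            clean=clean.values[r:r + patch_size, c:c + patch_size].copy(),
            source_index=source_index, offset=(r, c)))
    return out
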