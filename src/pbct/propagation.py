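"""Forward simulation of in-line (propagation-based) phase-contrast projections.

Model: parallel, fully coherent, monochromatic beam; projection approximation
through the complex refractive index followed by angular-spectrum free-space
propagation and an optional Poisson photon-noise detector. All projections
are flat-field normalized (background intensity 1).

Frequency convention: spatial frequencies f in cycles/µm; the free-space
transfer function is H(f) = exp(−iπλR|f|²), matched by the phase-retrieval
filter in :mod:`pbct.retrieval` so that retrieval inverts the linearized
forward model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import units
from .phantom import ComplexIndexVolume


class FresnelSamplingWarning(UserWarning):
    """First Fresnel fringe narrower than one detector pixel."""


@dataclass(frozen=True)
class BeamSpec:
    """Monochromatic beam with an optional photon budget for the noise model."""

    energy_kev: float = 22.0
    photons_per_pixel: float | None = None

    def __post_init__(self) -> None:
        if self.energy_kev <= 0:
            raise ValueError("energy must be positive")
        if self.photons_per_pixel is not None and self.photons_per_pixel <= 0:
            raise ValueError("photons_per_pixel must be positive (or None)")

    @property
    def wavelength_angstrom(self) -> float:
        return units.wavelength_angstrom(self.energy_kev)

    @property
    def wavelength_um(self) -> float:
        return units.wavelength_um(self.energy_kev)


@dataclass
class ProjectionStack:
    """Flat-field-normalized intensity projections plus geometry metadata."""

    intensities: np.ndarray  # (angle, row, column), unitless, > 0
    angles: np.ndarray  # degrees, strictly increasing, span ≤ 360
    distance_cm: float
    pixel_size_um: float
    beam: BeamSpec
    noise_applied: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (angle, row, column)")
        if len(self.angles) != self.intensities.shape[0]:
            raise ValueError("number of angles must match the first array dimension")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.angles[-1] - self.angles[0] > 360.0 + 1e-9:
            raise ValueError("angles must span at most 360 degrees")
        if self.intensities.min() <= 0:
            raise ValueError("normalized intensities must be positive")
        if self.distance_cm < 0:
            raise ValueError("distance must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def n_angles(self) -> int:
        return len(self.angles)


def complex_transmission(
    volume: ComplexIndexVolume, angle: float, beam: BeamSpec
) -> np.ndarray:
    """Complex transmission t = exp(−(2π/λ)∫β dz − i(2π/λ)∫δ dz).

    Line integrals run along the (rotated) column axis; the returned field is
    indexed (detector row = volume slice, detector column = volume row).
    """
    if not 0.0 <= angle < 360.0:
        raise ValueError("angle must lie in [0, 360)")
    grid = volume.delta + 1j * volume.beta
    if angle != 0.0:
        grid = ndimage.rotate(grid, angle, axes=(1, 2), reshape=False, order=1)
    path = grid.sum(axis=2) * volume.voxel_size  # (slice, row): ∫δ, ∫β in µm
    k = 2.0 * np.pi / beam.wavelength_um
    t = np.exp(-k * path.imag) * np.exp(-1j * k * path.real)
    if np.abs(t).max() > 1.0 + 1e-12:
        raise ValueError("|t| > 1: negative absorption path encountered")
    return t


def _padded_shape(shape: tuple[int, int], margin: int = 64) -> tuple[int, int]:
    return tuple(int(2 ** np.ceil(np.log2(n + 2 * margin))) for n in shape)


def fresnel_propagate(
    field: np.ndarray,
    distance_cm: float,
    wavelength_angstrom: float,
    pixel_size_um: float,
    pad: bool = True,
) -> np.ndarray:
    """Angular-spectrum propagation with H(f) = exp(−iπλR|f|²).

    Unitary (energy conserving); ``distance_cm = 0`` returns the input
    bit-exactly. With ``pad=True`` the field is symmetrically padded to the
    next power of two (≥ 64 px margin) and cropped after propagation to
    suppress periodic wrap-around fringes.
    """
    field = np.asarray(field)
    if not np.all(np.isfinite(field)):
        raise ValueError("field contains non-finite values")
    if distance_cm < 0:
        raise ValueError("distance must be non-negative")
    if distance_cm == 0:
        return field.copy()

    lam = wavelength_angstrom * units.UM_PER_ANGSTROM
    r_um = distance_cm * units.UM_PER_CM
    # warn only when fringes are both under-sampled and non-negligible
    if 0.25 * pixel_size_um < np.sqrt(lam * r_um) < pixel_size_um:
        warnings.warn(
            "first Fresnel fringe narrower than one pixel "
            f"(sqrt(lambda*R) = {np.sqrt(lam * r_um):.2f} um < {pixel_size_um} um); "
            "edge fringes are under-sampled",
            FresnelSamplingWarning,
            stacklevel=2,
        )

    if pad:
        ny, nx = field.shape
        py, px = _padded_shape(field.shape)
        before_y = (py - ny) // 2
        before_x = (px - nx) // 2
        work = np.pad(
            field,
            ((before_y, py - ny - before_y), (before_x, px - nx - before_x)),
            mode="symmetric",
        )
    else:
        work = field

    fy = np.fft.fftfreq(work.shape[0], d=pixel_size_um)
    fx = np.fft.fftfreq(work.shape[1], d=pixel_size_um)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    transfer = np.exp(-1j * np.pi * lam * r_um * f2)
    out = np.fft.ifft2(np.fft.fft2(work) * transfer)

    if pad:
        out = out[before_y : before_y + ny, before_x : before_x + nx]
    return out


def detect(
    field: np.ndarray,
    beam: BeamSpec,
    seed: int | np.random.Generator | None = None,
    noise: bool = False,
) -> np.ndarray:
    """Intensity I = |field|², optionally with Poisson photon noise.

    With noise on, each pixel becomes Poisson(N·I)/N for N = expected photons
    per pixel; zero-count pixels are clamped to 0.5/N so downstream −ln(I)
    stays finite.
    """
    intensity = np.abs(np.asarray(field)) ** 2
    if not noise:
        return intensity
    if beam.photons_per_pixel is None:
        raise ValueError("photons_per_pixel must be set to enable noise")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = beam.photons_per_pixel
    counts = rng.poisson(n * intensity).astype(np.float64)
    return np.maximum(counts, 0.5) / n


def simulate_scan(
    volume: ComplexIndexVolume,
    distances_cm,
    n_angles: int,
    beam: BeamSpec,
    seed: int | None = None,
    noise: bool = False,
) -> dict[float, ProjectionStack]:
    """Simulate one projection stack per sample-to-detector distance.

    Angles are evenly spaced over 360°. The complex transmission through the
    phantom is computed once per angle and propagated to every distance, so
    per-distance stacks share the phantom; per-distance noise streams are
    spawned deterministically from ``seed``.
    """
    if n_angles < 1:
        raise ValueError("n_angles must be at least 1")
    distances = [float(d) for d in distances_cm]
    angles = np.arange(n_angles) * (360.0 / n_angles)
    ns, nr, _ = volume.shape

    rngs = None
    if noise:
        seqs = np.random.SeedSequence(seed).spawn(len(distances))
        rngs = [np.random.default_rng(s) for s in seqs]

    stacks = {d: np.empty((n_angles, ns, nr)) for d in distances}
    for i, angle in enumerate(angles):
        t = complex_transmission(volume, float(angle), beam)
        for j, d in enumerate(distances):
            fld = fresnel_propagate(
                t, d, beam.wavelength_angstrom, volume.voxel_size
            )
            stacks[d][i] = detect(fld, beam, rngs[j] if noise else None, noise=noise)

    return {
        d: ProjectionStack(
            intensities=np.maximum(stacks[d], 1e-12),
            angles=angles,
            distance_cm=d,
            pixel_size_um=volume.voxel_size,
            beam=beam,
            noise_applied=noise,
            seed=seed,
        )
        for d in distances
    }


def bin_projections(stack: ProjectionStack, factor: int) -> ProjectionStack:
    """Integer-bin detector pixels (factor x factor mean), e.g. 2x2 binning.

    Rows/columns are truncated to a multiple of ``factor``; the effective
    pixel size scales by ``factor``.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("binning factor must be a positive integer")
    if factor == 1:
        return stack
    a, r, c = stack.intensities.shape
    r2, c2 = (r // factor) * factor, (c // factor) * factor
    binned = (
        stack.intensities[:, :r2, :c2]
        .reshape(a, r2 // factor, factor, c2 // factor, factor)
        .mean(axis=(2, 4))
    )
    return ProjectionStack(
        intensities=binned,
        angles=stack.angles.copy(),
        distance_cm=stack.distance_cm,
        pixel_size_um=stack.pixel_size_um * factor,
        beam=stack.beam,
        noise_applied=stack.noise_applied,
        seed=stack.seed,
    )


def add_poisson_noise(
    stack: ProjectionStack, photons_per_pixel: float, seed: int | None = None
) -> ProjectionStack:
    """Return a copy of a noise-free stack with Poisson photon noise applied.

    Equivalent to re-running the scan with noise enabled: counts are drawn as
    Poisson(N·I)/N per pixel with N = ``photons_per_pixel``.
    """
    if stack.noise_applied:
        raise ValueError("stack already carries noise")
    beam = BeamSpec(stack.beam.energy_kev, photons_per_pixel)
    rng = np.random.default_rng(seed)
    noisy = np.maximum(rng.poisson(photons_per_pixel * stack.intensities), 0.5)
    return ProjectionStack(
        intensities=noisy / photons_per_pixel,
        angles=stack.angles.copy(),
        distance_cm=stack.distance_cm,
        pixel_size_um=stack.pixel_size_um,
        beam=beam,
        noise_applied=True,
        seed=seed,
    )


def save_projection_stack(stack: ProjectionStack, path_tif: str | Path) -> None:
    """Multi-page TIFF (one page per angle) plus a JSON sidecar."""
    import json

    import tifffile

    path_tif = Path(path_tif)
    path_tif.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path_tif, stack.intensities.astype(np.float32), photometric="minisblack")
    meta = {
        "energy_keV": stack.beam.energy_kev,
        "photons_per_pixel": stack.beam.photons_per_pixel,
        "distance_cm": stack.distance_cm,
        "pixel_size_um": stack.pixel_size_um,
        "angles_deg": stack.angles.tolist(),
        "noise": stack.noise_applied,
        "seed": stack.seed,
    }
    path_tif.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_projection_stack(path_tif: str | Path) -> ProjectionStack:
    import json

    import tifffile

    path_tif = Path(path_tif)
    meta = json.loads(path_tif.with_suffix(".json").read_text())
    beam = BeamSpec(meta["energy_keV"], meta.get("photons_per_pixel"))
    return ProjectionStack(
        intensities=tifffile.imread(path_tif).astype(np.float64),
        angles=np.asarray(meta["angles_deg"]),
        distance_cm=meta["distance_cm"],
        pixel_size_um=meta["pixel_size_um"],
        beam=beam,
        noise_applied=meta.get("noise", False),
        seed=meta.get("seed"),
    )
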