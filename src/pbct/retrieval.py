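"""Single-distance TIE (Paganin-type) phase retrieval.

Under the homogeneous-object assumption δ/β = γ, the edge-enhanced intensity
projection I(x, y) at distance R is converted to a retrieved projected
attenuation A = µ·T by the Fourier filter

    A = −ln( IFFT[ FFT[I / I₀] · G(f) ] ),   G(f) = 1 / (1 + π λ R γ |f|²),

with f in cycles per unit length and I₀ = 1 (flat-field-normalized input).
The filter convention matches the simulator's transfer function
exp(−iπλR|f|²) so retrieval analytically inverts the linearized forward
model. Output is projected attenuation (so FBP yields µ); δ follows from
:func:`attenuation_to_delta`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import units
from .propagation import ProjectionStack, _padded_shape


class GeometryMismatchError(ValueError):
    """Stack metadata disagrees with the retrieval parameters."""


@dataclass(frozen=True)
class RetrievalParams:
    gamma: float
    distance_cm: float
    energy_kev: float
    pixel_size_um: float
    pad_margin_px: int = 64

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.distance_cm < 0:
            raise ValueError("distance must be non-negative")
        if self.energy_kev <= 0:
            raise ValueError("energy must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def wavelength_um(self) -> float:
        return units.wavelength_um(self.energy_kev)


@dataclass
class RetrievedStack:
    """Per-angle retrieved projected attenuation A = µ·T (µ in 1/µm, T in µm)."""

    images: np.ndarray  # (angle, row, column)
    angles: np.ndarray
    distance_cm: float
    pixel_size_um: float
    params: RetrievalParams

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        if not np.all(np.isfinite(self.images)):
            raise ValueError("retrieved images contain non-finite values")

    @property
    def n_angles(self) -> int:
        return len(self.angles)


def tie_filter_gain(f_cycles_per_um, params: RetrievalParams):
    """Low-pass gain G(f) = 1 / (1 + πλRγ|f|²); G(0) = 1, G ≡ 1 for γR = 0."""
    f = np.asarray(f_cycles_per_um, dtype=np.float64)
    lam = params.wavelength_um
    r_um = params.distance_cm * units.UM_PER_CM
    return 1.0 / (1.0 + np.pi * lam * r_um * params.gamma * f**2)


def retrieve_projection(intensity: np.ndarray, params: RetrievalParams) -> np.ndarray:
    """Apply the TIE filter to one flat-field-normalized projection.

    Returns the retrieved projected attenuation A = −ln(filtered intensity).
    The image is symmetrically padded to the next power of two before the FFT
    and cropped afterwards.
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    if intensity.ndim != 2:
        raise ValueError("intensity must be a 2-D image")
    if intensity.min() <= 0:
        raise ValueError("intensity must be positive everywhere (flat-field normalized)")

    ny, nx = intensity.shape
    py, px = _padded_shape(intensity.shape, margin=params.pad_margin_px)
    by, bx = (py - ny) // 2, (px - nx) // 2
    work = np.pad(intensity, ((by, py - ny - by), (bx, px - nx - bx)), mode="symmetric")

    fy = np.fft.fftfreq(py, d=params.pixel_size_um)
    fx = np.fft.fftfreq(px, d=params.pixel_size_um)
    gain = tie_filter_gain(np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2), params)
    filtered = np.fft.ifft2(np.fft.fft2(work) * gain).real
    filtered = filtered[by : by + ny, bx : bx + nx]
    if filtered.min() <= 0:
        raise ValueError("filtered intensity non-positive; cannot take the log")
    out = -np.log(filtered)
    if not np.all(np.isfinite(out)):
        raise ValueError("retrieved image contains non-finite values")
    return out


def retrieve_stack(
    stack: ProjectionStack, params: RetrievalParams, override_geometry: bool = False
) -> RetrievedStack:
    """Per-angle retrieval of a full projection stack.

    The stack's distance, energy and pixel size must match ``params`` unless
    ``override_geometry`` is set.
    """
    mismatches = []
    if not np.isclose(stack.distance_cm, params.distance_cm):
        mismatches.append(f"distance {stack.distance_cm} vs {params.distance_cm} cm")
    if not np.isclose(stack.beam.energy_kev, params.energy_kev):
        mismatches.append(f"energy {stack.beam.energy_kev} vs {params.energy_kev} keV")
    if not np.isclose(stack.pixel_size_um, params.pixel_size_um):
        mismatches.append(f"pixel {stack.pixel_size_um} vs {params.pixel_size_um} um")
    if mismatches and not override_geometry:
        raise GeometryMismatchError("; ".join(mismatches))

    images = np.empty_like(stack.intensities)
    for i in range(stack.n_angles):
        images[i] = retrieve_projection(stack.intensities[i], params)
    return RetrievedStack(
        images=images,
        angles=stack.angles.copy(),
        distance_cm=stack.distance_cm,
        pixel_size_um=stack.pixel_size_um,
        params=params,
    )


def attenuation_to_delta(recon_mu, gamma: float, wavelength_angstrom: float):
    """δ = γ·β = γ·µλ/(4π) voxelwise, with µ in 1/µm and λ in Å."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    lam_um = wavelength_angstrom * units.UM_PER_ANGSTROM
    return gamma * np.asarray(recon_mu) * lam_um / (4.0 * np.pi)
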