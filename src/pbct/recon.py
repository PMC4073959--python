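"""Parallel-beam sinogram formation and filtered back-projection.

The geometry matches the simulator: at angle θ a pixel at in-plane offset
(u, w) from the slice centre projects to detector coordinate
s = u·cosθ − w·sinθ. Sinogram values are dimensionless line integrals
∫µ dl with length in µm, so reconstructed slices are in µ units of 1/µm.

``radon_oracle`` is an independent rotation+sum projector used only by tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

FBP_FILTERS = ("ramp", "shepp-logan", "hann")


@dataclass
class Sinogram:
    values: np.ndarray  # (angle, detector column)
    angles: np.ndarray  # degrees
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("sinogram must be 2-D (angle, detector)")
        if len(self.angles) != self.values.shape[0]:
            raise ValueError("angle count must match the first dimension")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram contains non-finite values")


@dataclass
class ReconVolume:
    """Stack of reconstructed slices; µ-scale for PhR, µ plus edge terms for PBI."""

    slices: np.ndarray  # (slice, row, column), 1/µm
    pixel_size_um: float
    mode: str  # "pbi" or "phr"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=np.float64)
        if self.slices.ndim != 3 or self.slices.shape[1] != self.slices.shape[2]:
            raise ValueError("slices must be (slice, n, n) with square in-plane extent")
        if not np.all(np.isfinite(self.slices)):
            raise ValueError("reconstruction contains non-finite values")
        if self.mode not in ("pbi", "phr"):
            raise ValueError("mode must be 'pbi' or 'phr'")


def to_sinograms(stack, mode: str) -> list[Sinogram]:
    """One sinogram per detector row.

    ``mode='pbi'`` applies −ln to a :class:`ProjectionStack`'s intensities;
    ``mode='phr'`` passes a :class:`RetrievedStack`'s images through.
    """
    if mode == "pbi":
        intensities = stack.intensities
        if intensities.min() <= 0:
            raise ValueError("non-positive intensity; cannot take −ln")
        values = -np.log(intensities)
    elif mode == "phr":
        values = stack.images
    else:
        raise ValueError("mode must be 'pbi' or 'phr'")
    return [
        Sinogram(values[:, r, :], stack.angles, stack.pixel_size_um)
        for r in range(values.shape[1])
    ]


def _fourier_filter(size: int, name: str) -> np.ndarray:
    """Band-limited ramp filter (frequency response of the Ram-Lak kernel)."""
    n = np.concatenate(
        (np.arange(1, size // 2 + 1, 2), np.arange(size // 2 - 1, 0, -2))
    )
    kernel = np.zeros(size)
    kernel[0] = 0.25
    kernel[1::2] = -1.0 / (np.pi * n) ** 2
    filt = 2.0 * np.real(np.fft.fft(kernel))  # ≥ 0, ramp-like
    freq = np.fft.fftfreq(size)
    if name == "ramp":
        pass
    elif name == "shepp-logan":
        omega = np.pi * freq
        nz = omega != 0
        filt[nz] *= np.sin(omega[nz]) / omega[nz]
    elif name == "hann":
        filt *= 0.5 * (1.0 + np.cos(2.0 * np.pi * freq))
    else:
        raise ValueError(f"unknown filter {name!r}; choose from {FBP_FILTERS}")
    return filt


def fbp(sino: Sinogram, filter_name: str = "ramp", fold180: bool = False) -> np.ndarray:
    """Ramp-filtered back-projection with linear interpolation.

    Returns a square slice of side equal to the detector length, in units of
    1/µm (a uniform disk of linear attenuation µ reconstructs to µ). With
    ``fold180`` angles ≥ 180° are folded onto [0°, 180°) by mirroring the
    detector axis before back-projection.
    """
    angles = np.asarray(sino.angles, dtype=np.float64)
    values = sino.values
    if len(angles) < 2:
        raise ValueError("need at least 2 projection angles")
    if np.ptp(angles) == 0:
        raise ValueError("degenerate angle set (all angles equal)")

    if fold180:
        folded = angles % 180.0
        flip = (angles % 360.0) >= 180.0
        values = np.where(flip[:, None], values[:, ::-1], values)
        angles = folded

    n_det = values.shape[1]
    pad = max(64, int(2 ** np.ceil(np.log2(2 * n_det))))
    filt = _fourier_filter(pad, filter_name)
    proj = np.fft.fft(values, n=pad, axis=1) * filt[None, :]
    filtered = np.real(np.fft.ifft(proj, axis=1))[:, :n_det]

    center = (n_det - 1) / 2.0
    u = np.arange(n_det) - center  # rows
    w = np.arange(n_det) - center  # columns
    uu = u[:, None]
    ww = w[None, :]
    out = np.zeros((n_det, n_det))
    det = np.arange(n_det, dtype=np.float64)
    for k, ang in enumerate(np.deg2rad(angles)):
        s = uu * np.cos(ang) - ww * np.sin(ang) + center
        out += np.interp(s.ravel(), det, filtered[k], left=0.0, right=0.0).reshape(
            n_det, n_det
        )
    # Δθ weight: π/n for angles spanning 180°, and identically π/n over 360°
    # (each direction is then covered twice); the extra factor 1/2 absorbs the
    # filter's gain of 2|f|.
    out *= np.pi / (2.0 * len(angles))
    return out / sino.pixel_size_um


def radon_oracle(image: np.ndarray, angles) -> Sinogram:
    """Brute-force projection by grid rotation and summation (test oracle).

    Matches the simulator's geometry; values are line integrals with length
    measured in pixels times the image values (multiply by the pixel size for
    physical units).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("radon_oracle expects a square 2-D image")
    angles = np.asarray(angles, dtype=np.float64)
    sino = np.empty((len(angles), image.shape[0]))
    for i, a in enumerate(angles):
        rot = image if a == 0 else ndimage.rotate(image, a, reshape=False, order=1)
        sino[i] = rot.sum(axis=1)
    return Sinogram(sino, angles, pixel_size_um=1.0)


def reconstruct_volume(stack, mode: str, filter_name: str = "ramp") -> ReconVolume:
    """FBP every detector row of a projection/retrieved stack into a volume."""
    sinos = to_sinograms(stack, mode)
    slices = np.stack([fbp(s, filter_name=filter_name) for s in sinos])
    prov = {"distance_cm": stack.distance_cm, "filter": filter_name}
    if mode == "phr":
        prov["gamma"] = stack.params.gamma
    return ReconVolume(slices, stack.pixel_size_um, mode, prov)


def save_recon(volume: ReconVolume, path_tif) -> None:
    import json
    from pathlib import Path

    import tifffile

    path_tif = Path(path_tif)
    path_tif.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path_tif, volume.slices.astype(np.float32), photometric="minisblack")
    meta = {"pixel_size_um": volume.pixel_size_um, "mode": volume.mode}
    meta.update({k: v for k, v in volume.provenance.items()})
    path_tif.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_recon(path_tif) -> ReconVolume:
    import json
    from pathlib import Path

    import tifffile

    path_tif = Path(path_tif)
    meta = json.loads(path_tif.with_suffix(".json").read_text())
    mode = meta.pop("mode")
    pixel = meta.pop("pixel_size_um")
    return ReconVolume(
        tifffile.imread(path_tif).astype(np.float64), pixel, mode, provenance=meta
    )
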