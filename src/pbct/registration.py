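"""Slice matching and in-plane Fourier–Mellin registration.

Protocol: a reference slice is located in the moving volume by zero-normalized
2-D cross-correlation; in-plane scale/rotation/translation are then recovered
by phase correlation of log-polar magnitude spectra followed by a translation
phase correlation. A 3×3×3 mean pre-filter is available for edge-enhanced
(PBI) volumes and is used *only* to drive registration — metric noise is
always measured on the original, untransformed data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import SimilarityTransform, warp, warp_polar


class RegistrationError(RuntimeError):
    """Registration failed to reach the minimum correlation score."""


@dataclass
class RegistrationTransform:
    """Similarity transform mapping moving-image coordinates onto the fixed frame.

    A point x (row, col) in the moving image corresponds to
    R(rotation)·scale·(x − c) + c + translation in the fixed image, with c the
    image centre.
    """

    scale: float
    rotation_deg: float
    translation: tuple[float, float]  # (row, col) pixels
    score: float
    matched_slice_index: int | None = None

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not -1.0 - 1e-9 <= self.score <= 1.0 + 1e-9:
            raise ValueError("score must lie in [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "rotation_deg": self.rotation_deg,
            "translation_px": list(self.translation),
            "score": self.score,
            "matched_slice": self.matched_slice_index,
        }


def mean_filter_3d(volume: np.ndarray, size: int = 3) -> np.ndarray:
    """Cubic mean filter (reflect boundaries); registration pre-filter only."""
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3 or min(volume.shape) < size:
        raise ValueError(f"volume must be 3-D with at least {size} voxels per axis")
    return ndimage.uniform_filter(volume, size=size, mode="reflect")


def _zncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def find_matching_slice(
    reference_slice: np.ndarray, moving_volume: np.ndarray
) -> tuple[int, float]:
    """Index of the moving-volume slice maximizing zero-normalized correlation.

    Ties are broken toward the lowest index.
    """
    moving_volume = np.asarray(moving_volume)
    if moving_volume.ndim != 3 or moving_volume.shape[0] == 0:
        raise ValueError("moving volume must be a non-empty 3-D array")
    if moving_volume.shape[1:] != np.asarray(reference_slice).shape:
        raise ValueError("in-plane shapes must match (resample first)")
    scores = np.array(
        [_zncc(reference_slice, moving_volume[i]) for i in range(moving_volume.shape[0])]
    )
    idx = int(np.argmax(scores))
    return idx, float(scores[idx])


def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    return np.outer(np.hanning(shape[0]), np.hanning(shape[1]))


def _highpass(shape: tuple[int, int]) -> np.ndarray:
    """Radial high-pass emphasis for the magnitude spectra (Reddy–Chatterjee)."""
    yy = np.linspace(-0.5, 0.5, shape[0])[:, None]
    xx = np.linspace(-0.5, 0.5, shape[1])[None, :]
    x = np.cos(np.pi * yy) * np.cos(np.pi * xx)
    return (1.0 - x) * (2.0 - x)


def _log_magnitude_spectrum(image: np.ndarray) -> np.ndarray:
    f = np.fft.fftshift(np.abs(np.fft.fft2(image * _hann2d(image.shape))))
    return f * _highpass(image.shape)


def _center_transform(
    shape: tuple[int, int], scale: float, rotation_deg: float, translation=(0.0, 0.0)
) -> SimilarityTransform:
    """Similarity transform in (x, y) convention, rotating/scaling about the centre."""
    # skimage transforms act on (col, row) = (x, y) points.
    c = np.array([(shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0])
    shift_to = SimilarityTransform(translation=-c)
    core = SimilarityTransform(scale=scale, rotation=np.deg2rad(rotation_deg))
    shift_back = SimilarityTransform(
        translation=c + np.array([translation[1], translation[0]])
    )
    return shift_to + core + shift_back


def apply_transform(
    image: np.ndarray, transform: RegistrationTransform, fill: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Resample ``image`` (moving) into the fixed frame.

    Returns (resampled, valid_mask); out-of-field pixels hold ``fill`` and are
    False in the mask so metrics can exclude them.
    """
    tform = _center_transform(
        image.shape, transform.scale, transform.rotation_deg, transform.translation
    )
    out = warp(
        np.asarray(image, dtype=np.float64),
        tform.inverse,
        order=1,
        cval=np.nan,
        preserve_range=True,
    )
    mask = np.isfinite(out)
    out[~mask] = fill
    return out, mask


def fourier_mellin(
    fixed: np.ndarray,
    moving: np.ndarray,
    angular_samples: int = 360,
    radial_samples: int = 256,
    upsample_factor: int = 20,
    min_score: float = 0.2,
) -> RegistrationTransform:
    """Recover in-plane scale, rotation and translation.

    Rotation/scale come from phase correlation of log-polar magnitude spectra
    (rotation has an inherent 180° ambiguity because magnitude spectra are
    point-symmetric; both candidates are scored and the better one kept),
    translation from a second phase correlation after de-rotating/de-scaling.
    """
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving images must share a shape")

    radius = min(fixed.shape) // 2
    klog = radial_samples / np.log(radius)

    def _logpolar(img: np.ndarray) -> np.ndarray:
        pol = warp_polar(
            _log_magnitude_spectrum(img),
            radius=radius,
            output_shape=(angular_samples, radial_samples),
            scaling="log",
            order=1,
        )
        # magnitude spectra are point-symmetric: half the angular range suffices
        return pol[: angular_samples // 2]

    pol_fixed = _logpolar(fixed)

    # Phase-correlate in log-polar space; refine iteratively because the
    # polar resampling biases single-shot estimates by a fraction of a sample.
    rotation, scale = 0.0, 1.0
    adjusted = moving
    for _ in range(3):
        shifts, _, _ = phase_cross_correlation(
            pol_fixed,
            _logpolar(adjusted),
            upsample_factor=upsample_factor,
            normalization=None,
        )
        rotation += shifts[0] * (360.0 / angular_samples)
        scale *= float(np.exp(-shifts[1] / klog))
        base = _center_transform(moving.shape, scale, rotation)
        adjusted = warp(moving, base.inverse, order=1, cval=0.0, preserve_range=True)

    # candidates: the log-polar estimate, its 180°-ambiguous twin, and a
    # pure-translation fallback for noise-dominated spectra
    candidates = [(scale, rotation), (scale, rotation + 180.0)]
    if abs(scale - 1.0) > 1e-6 or abs(rotation) > 1e-6:
        candidates.append((1.0, 0.0))
    best: RegistrationTransform | None = None
    for scale, rot in candidates:
        rot = ((rot + 180.0) % 360.0) - 180.0
        base = _center_transform(moving.shape, scale, rot)
        adjusted = warp(moving, base.inverse, order=1, cval=0.0, preserve_range=True)
        tshift, _, _ = phase_cross_correlation(
            fixed, adjusted, upsample_factor=upsample_factor, normalization=None
        )
        cand = RegistrationTransform(
            scale=scale,
            rotation_deg=float(rot),
            translation=(float(tshift[0]), float(tshift[1])),
            score=0.0,
        )
        resampled, mask = apply_transform(moving, cand)
        score = _zncc(fixed[mask], resampled[mask]) if mask.any() else -1.0
        cand.score = score
        if best is None or score > best.score:
            best = cand

    if best.score < min_score:
        raise RegistrationError(
            f"registration score {best.score:.3f} below threshold {min_score}"
        )
    return best
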