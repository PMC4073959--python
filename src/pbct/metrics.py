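"""Quantification suite: ROI statistics, CNR, EEI, averaged edge profiles,
sigmoid steepness fitting, and the Gaussian steepness-matching experiment.

Noise standard deviations entering CNR/EEI must come from original,
untransformed, unfiltered data; the functions here take plain statistics and
the pipeline enforces that data flow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal

from . import units


@dataclass
class RoiStats:
    mean: float
    sd: float  # sample s.d., n−1 denominator
    area_mm2: float
    n_pixels: int
    roi_spec: tuple | None = None  # (row0, col0, height, width) or None for pooled


@dataclass
class LineProfile:
    """Averaged line profile; positions in mm at uniform pixel pitch."""

    positions: np.ndarray  # mm, strictly increasing
    values: np.ndarray
    n_averaged: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have the same length")
        steps = np.diff(self.positions)
        if len(steps) and (np.any(steps <= 0) or np.ptp(steps) > 1e-9 * steps[0]):
            raise ValueError("positions must be strictly increasing and uniform")

    @property
    def length_mm(self) -> float:
        return float(self.positions[-1] - self.positions[0])


@dataclass
class SigmoidFit:
    """f(x) = k1 + k4 / (1 + exp(−k2·(x − k3))); steepness = k2 (1/mm).

    Canonicalized so k4 > 0; k2 > 0 means the profile ascends with position
    (air → tissue), k2 < 0 a descending (mirrored) profile.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    residual_rms: float
    converged: bool

    @property
    def steepness(self) -> float:
        return abs(self.k2)

    @property
    def ascending(self) -> bool:
        return self.k2 > 0


def sigmoid(x, k1, k2, k3, k4):
    return k1 + k4 / (1.0 + np.exp(-np.clip(k2 * (x - k3), -500, 500)))


def roi_stats(
    image: np.ndarray,
    roi_rect: tuple[int, int, int, int],
    pixel_size_um: float,
    mask: np.ndarray | None = None,
) -> RoiStats:
    """Mean and sample s.d. over a rectangular ROI (row0, col0, height, width)."""
    image = np.asarray(image)
    r0, c0, h, w = roi_rect
    if r0 < 0 or c0 < 0 or r0 + h > image.shape[0] or c0 + w > image.shape[1]:
        raise ValueError("ROI extends outside the slice")
    if h < 1 or w < 1:
        raise ValueError("ROI must contain at least one pixel")
    if mask is not None and not np.all(mask[r0 : r0 + h, c0 : c0 + w]):
        raise ValueError("ROI overlaps masked pixels")
    pix = image[r0 : r0 + h, c0 : c0 + w].ravel()
    px_mm = pixel_size_um / units.UM_PER_MM
    return RoiStats(
        mean=float(pix.mean()),
        sd=float(pix.std(ddof=1)) if pix.size > 1 else 0.0,
        area_mm2=pix.size * px_mm**2,
        n_pixels=pix.size,
        roi_spec=(r0, c0, h, w),
    )


def pool_roi_stats(stats: list[RoiStats]) -> RoiStats:
    """Pool ROI statistics as if all pixels were one sample."""
    if not stats:
        raise ValueError("no ROI statistics to pool")
    n = np.array([s.n_pixels for s in stats], dtype=float)
    means = np.array([s.mean for s in stats])
    sds = np.array([s.sd for s in stats])
    ntot = n.sum()
    grand = float(np.sum(n * means) / ntot)
    ss = np.sum((n - 1) * sds**2 + n * (means - grand) ** 2)
    sd = math.sqrt(ss / (ntot - 1)) if ntot > 1 else 0.0
    return RoiStats(grand, sd, float(sum(s.area_mm2 for s in stats)), int(ntot))


def cnr(tissue: RoiStats, air: RoiStats, denominator: str = "rms") -> float:
    """Contrast-to-noise ratio |mean₁ − mean₂| / sqrt((σ₁² + σ₂²)/2).

    ``denominator='mean'`` uses (σ₁ + σ₂)/2 instead. Symmetric in its
    arguments; 0 for equal means; +inf (with a warning) when both s.d. vanish
    but the means differ.
    """
    contrast = abs(tissue.mean - air.mean)
    if denominator == "rms":
        noise = math.sqrt((tissue.sd**2 + air.sd**2) / 2.0)
    elif denominator == "mean":
        noise = (tissue.sd + air.sd) / 2.0
    else:
        raise ValueError("denominator must be 'rms' or 'mean'")
    if noise == 0:
        if contrast == 0:
            return 0.0
        warnings.warn("zero noise with non-zero contrast: CNR is infinite")
        return math.inf
    return contrast / noise


def extract_profiles(
    image: np.ndarray,
    center_px: tuple[float, float],
    direction: tuple[float, float],
    length_mm: float,
    pixel_size_um: float,
    n_profiles: int = 5,
    spacing_px: float = 2.0,
) -> LineProfile:
    """Average of ``n_profiles`` parallel line profiles.

    Segments of the given length (sampled at pixel pitch, endpoints
    inclusive) are centred on ``center_px`` along ``direction`` (row, col),
    offset perpendicular to it by multiples of ``spacing_px``. Bilinear
    sampling; raises if any segment exits the image.
    """
    image = np.asarray(image, dtype=np.float64)
    d = np.asarray(direction, dtype=np.float64)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("direction must be non-zero")
    d = d / norm
    perp = np.array([-d[1], d[0]])

    length_um = length_mm * units.UM_PER_MM
    n_samples = int(length_um // pixel_size_um) + 1
    t = (np.arange(n_samples) - (n_samples - 1) / 2.0)  # pixels along the segment
    offsets = (np.arange(n_profiles) - (n_profiles - 1) / 2.0) * spacing_px

    profiles = np.empty((n_profiles, n_samples))
    for i, off in enumerate(offsets):
        start = np.asarray(center_px) + off * perp
        rows = start[0] + t * d[0]
        cols = start[1] + t * d[1]
        if (
            rows.min() < 0
            or cols.min() < 0
            or rows.max() > image.shape[0] - 1
            or cols.max() > image.shape[1] - 1
        ):
            raise ValueError("profile segment exits the slice bounds")
        profiles[i] = ndimage.map_coordinates(
            image, np.vstack([rows, cols]), order=1, mode="nearest"
        )
    positions = np.arange(n_samples) * pixel_size_um / units.UM_PER_MM
    return LineProfile(positions, profiles.mean(axis=0), n_profiles)


def eei(profile: LineProfile, sd_air: float, sd_tissue: float) -> float:
    """Edge-enhancement index (P − L) / sqrt((σ_air² + σ_tissue²)/2).

    P and L are the highest and lowest profile values; the σ's must be
    measured on original (untransformed, unfiltered) data.
    """
    p, low = float(profile.values.max()), float(profile.values.min())
    noise = math.sqrt((sd_air**2 + sd_tissue**2) / 2.0)
    if noise == 0:
        if p == low:
            return 0.0
        warnings.warn("zero noise with non-flat profile: EEI is infinite")
        return math.inf
    return (p - low) / noise


def profile_end_sds(profile: LineProfile, fraction: float = 0.25) -> tuple[float, float]:
    """(σ_first, σ_last) from the profile's end segments (default first/last 25%)."""
    n = len(profile.values)
    k = max(int(n * fraction), 2)
    return (
        float(profile.values[:k].std(ddof=1)),
        float(profile.values[-k:].std(ddof=1)),
    )


def fit_sigmoid(profile: LineProfile) -> SigmoidFit:
    """Least-squares logistic fit; non-convergence is flagged, not raised."""
    x = profile.positions
    y = profile.values
    if len(x) < 8:
        raise ValueError("need at least 8 samples to fit a sigmoid")
    rng_y = float(np.ptp(y))
    if rng_y == 0:
        raise ValueError("profile is flat; no edge to fit")

    ascending = y[-1] >= y[0]
    k1_0 = float(y.min())
    k4_0 = rng_y
    half = k1_0 + 0.5 * k4_0
    crossings = np.nonzero(np.diff(np.sign(y - half)))[0]
    k3_0 = float(x[crossings[0]]) if len(crossings) else float(x[len(x) // 2])
    max_slope = float(np.abs(np.diff(y)).max() / (x[1] - x[0]))
    k2_0 = 4.0 * max_slope / k4_0
    if not ascending:
        k2_0 = -k2_0

    try:
        popt, _ = optimize.curve_fit(
            sigmoid, x, y, p0=[k1_0, k2_0, k3_0, k4_0], maxfev=10000
        )
        converged = bool(np.all(np.isfinite(popt))) and popt[3] != 0
    except RuntimeError:
        popt = [k1_0, k2_0, k3_0, k4_0]
        converged = False

    k1, k2, k3, k4 = (float(v) for v in popt)
    if k4 < 0:  # canonicalize: k1 + k4/(1+e^-u) == (k1+k4) + (−k4)/(1+e^u)
        k1, k2, k4 = k1 + k4, -k2, -k4
    resid = y - sigmoid(x, k1, k2, k3, k4)
    rms = float(np.sqrt(np.mean(resid**2)))
    # Fits that park the edge centre outside the window or explain the data no
    # better than a flat line are degenerate, not edges.
    if converged and (k3 < x[0] or k3 > x[-1] or rms > 0.9 * np.std(y)):
        converged = False
    return SigmoidFit(k1, k2, k3, k4, rms, converged)


def steepness_percent(
    fits: dict, reference: object
) -> dict:
    """Express each fit's |k2| as a percentage of the reference fit's |k2|.

    Unconverged fits are omitted from the result (reported as absent, not 0).
    The reference entry is exactly 100.
    """
    ref = fits[reference]
    if not ref.converged:
        raise ValueError("reference fit did not converge")
    out = {}
    for key, fit in fits.items():
        if not fit.converged:
            continue
        out[key] = 100.0 if key == reference else 100.0 * fit.steepness / ref.steepness
    return out


def match_steepness_by_gaussian(
    pbi_slice: np.ndarray,
    target_k2: float,
    profile_fn,
    cnr_fn=None,
    max_iter: int = 300,
    sigma_px: float = 0.8,
    truncate: float = 1.25,
):
    """Iteratively Gaussian-filter a PBI slice to a target edge steepness.

    A fixed small kernel (3-pixel support: σ = 0.8 px, truncated at one
    pixel radius) is applied repeatedly; after each pass the sigmoid is
    re-fitted via ``profile_fn(slice) -> LineProfile``. Stops at the first
    pass with fitted |k2| ≤ target (or at ``max_iter``, flagged as not
    reached). Returns (filtered slice, achieved_k2, achieved_cnr, n_passes,
    reached) with achieved_cnr from ``cnr_fn(slice)`` if provided.
    """
    current = np.asarray(pbi_slice, dtype=np.float64).copy()
    fit = fit_sigmoid(profile_fn(current))
    if target_k2 >= fit.steepness:
        achieved_cnr = cnr_fn(current) if cnr_fn else None
        return current, fit.steepness, achieved_cnr, 0, True

    reached = False
    n_passes = 0
    for n_passes in range(1, max_iter + 1):
        current = ndimage.gaussian_filter(
            current, sigma=sigma_px, truncate=truncate, mode="nearest"
        )
        fit = fit_sigmoid(profile_fn(current))
        if fit.converged and fit.steepness <= target_k2:
            reached = True
            break
    if not reached:
        warnings.warn(f"target steepness not reached within {max_iter} passes")
    achieved_cnr = cnr_fn(current) if cnr_fn else None
    return current, fit.steepness, achieved_cnr, n_passes, reached


def second_difference_sign_changes(
    values: np.ndarray, rel_threshold: float = 0.08
) -> int:
    """Count sign changes of the second difference across an edge profile.

    Second differences smaller than ``rel_threshold`` times the profile range
    are ignored, so smooth monotone (sigmoidal) edges count 0–1 sign change
    while overshoot–undershoot fringes count ≥ 2.
    """
    values = np.asarray(values, dtype=np.float64)
    d2 = np.diff(values, n=2)
    keep = d2[np.abs(d2) >= rel_threshold * np.ptp(values)]
    if len(keep) < 2:
        return 0
    signs = np.sign(keep)
    return int(np.sum(signs[1:] != signs[:-1]))


@dataclass
class ModeStats:
    n_modes: int
    valley_to_peak: float  # valley height / lower of the two main peaks; 1.0 if unimodal
    peak_positions: list = field(default_factory=list)


def histogram_modes(
    values: np.ndarray,
    bins: int = 96,
    smooth_sigma: float = 2.0,
    prominence_frac: float = 0.05,
) -> ModeStats:
    """Detect histogram modes for the bimodality check.

    The histogram is Gaussian-smoothed; peaks are found with a prominence of
    ``prominence_frac`` times the maximum count. With ≥ 2 peaks the
    valley-to-peak ratio is the minimum between the two most prominent peaks
    divided by the lower of those peaks.
    """
    values = np.asarray(values).ravel()
    counts, edges = np.histogram(values, bins=bins)
    smooth = ndimage.gaussian_filter1d(counts.astype(np.float64), smooth_sigma)
    peaks, props = signal.find_peaks(smooth, prominence=prominence_frac * smooth.max())
    centers = 0.5 * (edges[:-1] + edges[1:])
    if len(peaks) < 2:
        return ModeStats(len(peaks), 1.0, [float(centers[p]) for p in peaks])
    order = np.argsort(props["prominences"])[::-1][:2]
    p1, p2 = sorted(peaks[order])
    valley = smooth[p1 : p2 + 1].min()
    ratio = float(valley / min(smooth[p1], smooth[p2]))
    return ModeStats(len(peaks), ratio, [float(centers[p]) for p in (p1, p2)])
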