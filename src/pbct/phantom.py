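"""Seeded complex-refractive-index phantoms.

Volumes are (slice, row, column) arrays of the refractive-index decrement
``delta`` and absorption index ``beta`` (n = 1 − δ + iβ), together with an
integer material label grid. The beam travels along the column axis during
projection at angle 0; all phantoms are contained inside the cylinder
inscribed in the (row, column) plane so rotation never clips material.

Materials: 0 = air, 1 = soft tissue, 2 = bone, 3 = agarose.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import units

AIR = 0
SOFT_TISSUE = 1
BONE = 2
AGAROSE = 3

# Soft-tissue decrement scale at 22 keV; only the delta/beta ratio matters for
# retrieval correctness, the absolute value sets image contrast.
DEFAULT_DELTA_TISSUE = 4.06e-7
DEFAULT_DELTA_BONE = 7.3e-7
DEFAULT_GAMMA_LUNG = 1950.0
DEFAULT_GAMMA_BONE = 250.0


@dataclass
class ComplexIndexVolume:
    """Voxelized δ/β grids plus material labels.

    Attributes
    ----------
    delta, beta : (S, R, C) float arrays, unitless, ≥ 0, finite.
    labels : (S, R, C) integer material labels.
    voxel_size : isotropic voxel edge in µm.
    annotations : geometry hints (airway centre, reserved ROI zones, ...)
        recorded by the generators for downstream ROI/profile placement.
    """

    delta: np.ndarray
    beta: np.ndarray
    labels: np.ndarray
    voxel_size: float
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=np.float64)
        self.beta = np.asarray(self.beta, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if not (self.delta.shape == self.beta.shape == self.labels.shape):
            raise ValueError("delta, beta and labels must share a shape")
        if self.delta.ndim != 3:
            raise ValueError("volume grids must be 3-D (slice, row, column)")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        for name, grid in (("delta", self.delta), ("beta", self.beta)):
            if not np.all(np.isfinite(grid)):
                raise ValueError(f"{name} grid contains non-finite values")
            if grid.min() < 0:
                raise ValueError(f"{name} grid contains negative values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.delta.shape

    def gamma_of(self, label: int) -> float:
        """Mean δ/β over voxels with the given label (β > 0 required)."""
        sel = self.labels == label
        if not sel.any():
            raise ValueError(f"no voxels labelled {label}")
        beta = self.beta[sel]
        if np.any(beta <= 0):
            raise ValueError("gamma undefined where beta = 0")
        return float(np.mean(self.delta[sel] / beta))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters fully determining a lung-like phantom (with the seed)."""

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 9.0  # µm
    vesicle_count: int = 60
    vesicle_radius_range: tuple[float, float] = (27.0, 72.0)  # µm
    bone_rod: bool = True
    bone_radius: float = 90.0  # µm
    gamma_lung: float = DEFAULT_GAMMA_LUNG
    gamma_bone: float = DEFAULT_GAMMA_BONE
    delta_tissue: float = DEFAULT_DELTA_TISSUE
    delta_bone: float = DEFAULT_DELTA_BONE
    agarose_shell: bool = True
    # cosine taper width (voxels) of the shell's outer surface; a smooth rim
    # keeps the strong sample/air boundary free of high-frequency content
    shell_taper_px: float = 8.0
    # Multiplicative density texture inside soft tissue: delta and beta are
    # jointly scaled by (1 + amplitude * g) with g a smooth unit-variance
    # random field, so the per-voxel delta/beta ratio is preserved exactly.
    texture_amplitude: float = 0.0
    texture_length_um: float = 27.0
    airway_radius_frac: float = 0.18  # of min in-plane extent
    seed: int = 0

    def validate(self) -> None:
        if any(s < 16 for s in self.shape):
            raise ValueError("phantom shape must be at least 16 voxels per axis")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.gamma_lung <= 0 or self.gamma_bone <= 0:
            raise ValueError("gamma values must be positive")
        lo, hi = self.vesicle_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("vesicle_radius_range must be positive and ordered")
        if lo < 2 * self.voxel_size:
            raise ValueError("vesicle radii must span at least 2 voxels")
        half_extent = 0.5 * min(self.shape[1], self.shape[2]) * self.voxel_size
        if hi > half_extent:
            raise ValueError("vesicle radius exceeds half the volume extent")
        if self.vesicle_count < 0:
            raise ValueError("vesicle_count must be non-negative")
        if self.texture_amplitude < 0 or self.texture_amplitude >= 1:
            raise ValueError("texture_amplitude must lie in [0, 1)")


def _cylinder_mask(shape, center_rc, radius_px):
    """In-plane disk replicated along the slice axis."""
    _, nr, nc = shape
    rr, cc = np.ogrid[:nr, :nc]
    disk = (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 <= radius_px**2
    return np.broadcast_to(disk, shape)


def _texture_field(shape, length_px, rng):
    """Smooth zero-mean, unit-variance Gaussian random field."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=length_px)
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def make_lung_phantom(spec: PhantomSpec) -> ComplexIndexVolume:
    """Air vesicles in soft tissue with an airway, bone rod and agarose shell.

    Deterministic under ``spec.seed``. Geometry annotations (airway centre,
    vesicle-free tissue zone, bone centre) are recorded for ROI placement.
    """
    spec.validate()
    ns, nr, nc = spec.shape
    rng = np.random.default_rng(spec.seed)
    n_inplane = min(nr, nc)
    center = ((nr - 1) / 2.0, (nc - 1) / 2.0)

    labels = np.zeros(spec.shape, dtype=np.uint8)

    tissue_r = 0.42 * n_inplane
    shell_r = 0.47 * n_inplane if spec.agarose_shell else tissue_r
    if spec.agarose_shell:
        labels[_cylinder_mask(spec.shape, center, shell_r)] = AGAROSE
    labels[_cylinder_mask(spec.shape, center, tissue_r)] = SOFT_TISSUE

    # Guaranteed pure-air cavity (airway) and a vesicle-free tissue zone,
    # mirroring the "regions solely containing air or soft tissue" protocol.
    airway_r = spec.airway_radius_frac * n_inplane
    airway_c = (center[0], center[1] - 0.20 * n_inplane)
    tissue_zone_r = 0.14 * n_inplane
    tissue_zone_c = (center[0], center[1] + 0.25 * n_inplane)
    bone_c = (center[0] - 0.26 * n_inplane, center[1] + 0.05 * n_inplane)
    bone_r_px = spec.bone_radius / spec.voxel_size

    # corridor above the airway kept vesicle-free so the air–tissue edge
    # profiles cross a clean interface
    profile_c = (airway_c[0] - airway_r, airway_c[1])
    keepout = [
        (airway_c, airway_r + 2),
        (tissue_zone_c, tissue_zone_r + 2),
        (profile_c, 0.12 * n_inplane),
    ]
    if spec.bone_rod:
        keepout.append((bone_c, bone_r_px + 2))

    # Random air vesicles (spheres); air wins over tissue on overlap.
    air = np.zeros(spec.shape, dtype=bool)
    placed = 0
    attempts = 0
    max_attempts = 50 * max(spec.vesicle_count, 1)
    zz, rr_idx, cc_idx = np.ogrid[:ns, :nr, :nc]
    while placed < spec.vesicle_count and attempts < max_attempts:
        attempts += 1
        r_um = rng.uniform(*spec.vesicle_radius_range)
        r_px = r_um / spec.voxel_size
        cs = rng.uniform(r_px, ns - 1 - r_px)
        max_rad = tissue_r - r_px - 1
        if max_rad <= 0:
            break
        ang = rng.uniform(0, 2 * np.pi)
        rad = np.sqrt(rng.uniform(0, 1)) * max_rad
        cr = center[0] + rad * np.sin(ang)
        cc_ = center[1] + rad * np.cos(ang)
        if any(
            (cr - kc[0]) ** 2 + (cc_ - kc[1]) ** 2 <= (kr + r_px) ** 2
            for kc, kr in keepout
        ):
            continue
        air |= (zz - cs) ** 2 + (rr_idx - cr) ** 2 + (cc_idx - cc_) ** 2 <= r_px**2
        placed += 1

    if airway_r > 0:
        air |= _cylinder_mask(spec.shape, airway_c, airway_r)
    labels[air] = AIR

    if spec.bone_rod:
        bone = _cylinder_mask(spec.shape, bone_c, bone_r_px) & ~air
        labels[bone] = BONE

    delta = np.zeros(spec.shape)
    beta = np.zeros(spec.shape)
    tissue_like = (labels == SOFT_TISSUE) | (labels == AGAROSE)
    delta[tissue_like] = spec.delta_tissue
    beta[tissue_like] = spec.delta_tissue / spec.gamma_lung
    if spec.agarose_shell and spec.shell_taper_px > 0:
        rr2, cc2 = np.ogrid[:nr, :nc]
        radial = np.sqrt((rr2 - center[0]) ** 2 + (cc2 - center[1]) ** 2)
        ramp = np.clip((shell_r - radial) / spec.shell_taper_px, 0.0, 1.0)
        taper = np.broadcast_to(0.5 - 0.5 * np.cos(np.pi * ramp), spec.shape)
        sel = labels == AGAROSE
        delta[sel] *= taper[sel]
        beta[sel] *= taper[sel]
    if spec.bone_rod:
        delta[labels == BONE] = spec.delta_bone
        beta[labels == BONE] = spec.delta_bone / spec.gamma_bone

    if spec.texture_amplitude > 0:
        g = _texture_field(spec.shape, spec.texture_length_um / spec.voxel_size, rng)
        factor = np.clip(1.0 + spec.texture_amplitude * g, 0.05, None)
        sel = labels == SOFT_TISSUE
        delta[sel] *= factor[sel]
        beta[sel] *= factor[sel]

    annotations = {
        "spec": dataclasses.asdict(spec),
        "tissue_radius_px": tissue_r,
        "center_px": center,
        "airway_center_px": airway_c,
        "airway_radius_px": airway_r,
        "tissue_zone_center_px": tissue_zone_c,
        "tissue_zone_radius_px": tissue_zone_r,
        "bone_center_px": bone_c if spec.bone_rod else None,
        "bone_radius_px": bone_r_px if spec.bone_rod else None,
    }
    return ComplexIndexVolume(delta, beta, labels, spec.voxel_size, annotations)


def make_edge_phantom(
    shape: tuple[int, int, int],
    voxel_size: float,
    gamma: float = DEFAULT_GAMMA_LUNG,
    delta_tissue: float = DEFAULT_DELTA_TISSUE,
) -> ComplexIndexVolume:
    """Half-space air / half-space tissue with a planar interface.

    The interface is normal to the row axis at index ``shape[1] // 2`` with
    air on the low-index side, so a projection along the column axis shows a
    single straight edge at that detector coordinate.
    """
    if any(s < 32 for s in shape):
        raise ValueError("edge phantom needs at least 32 voxels per axis")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    interface = shape[1] // 2
    labels = np.zeros(shape, dtype=np.uint8)
    labels[:, interface:, :] = SOFT_TISSUE
    delta = np.where(labels == SOFT_TISSUE, delta_tissue, 0.0)
    beta = np.where(labels == SOFT_TISSUE, delta_tissue / gamma, 0.0)
    ann = {"interface_axis": 1, "interface_index": interface}
    return ComplexIndexVolume(delta, beta, labels, voxel_size, ann)


def make_disk_phantom(
    shape: tuple[int, int, int],
    voxel_size: float,
    mu_disk: float,
    energy_kev: float = 22.0,
    radius_frac: float = 0.3,
    center_offset_px: tuple[float, float] = (0.0, 0.0),
) -> ComplexIndexVolume:
    """Uniform-absorption cylinder (δ = 0), an analytic FBP oracle fixture.

    ``mu_disk`` is the linear attenuation coefficient in 1/µm; β is derived
    from µ = 4πβ/λ at the stated energy.
    """
    if mu_disk < 0:
        raise ValueError("mu_disk must be non-negative")
    if radius_frac > 0.4:
        raise ValueError("disk radius must be at most 0.4 of the field of view")
    _, nr, nc = shape
    center = ((nr - 1) / 2.0 + center_offset_px[0], (nc - 1) / 2.0 + center_offset_px[1])
    radius_px = radius_frac * min(nr, nc)
    mask = _cylinder_mask(shape, center, radius_px)
    lam = units.wavelength_um(energy_kev)
    beta = np.where(mask, units.beta_from_mu(mu_disk, lam), 0.0)
    delta = np.zeros(shape)
    labels = np.where(mask, SOFT_TISSUE, AIR).astype(np.uint8)
    ann = {"disk_center_px": center, "disk_radius_px": radius_px, "mu_disk": mu_disk}
    return ComplexIndexVolume(delta, beta, labels, voxel_size, ann)


def interface_band_mask(labels: np.ndarray, width: int = 3) -> np.ndarray:
    """Boolean mask of voxels within ``width`` pixels of an in-plane label change."""
    labels = np.asarray(labels)
    edges = np.zeros(labels.shape, dtype=bool)
    edges[:, :-1, :] |= labels[:, :-1, :] != labels[:, 1:, :]
    edges[:, 1:, :] |= labels[:, :-1, :] != labels[:, 1:, :]
    edges[:, :, :-1] |= labels[:, :, :-1] != labels[:, :, 1:]
    edges[:, :, 1:] |= labels[:, :, :-1] != labels[:, :, 1:]
    if width > 1:
        struct = np.zeros((1, 3, 3), dtype=bool)
        struct[0] = True
        edges = ndimage.binary_dilation(edges, structure=struct, iterations=width - 1)
    return edges


def save_phantom(volume: ComplexIndexVolume, directory: str | Path) -> None:
    """Write delta/beta/labels as multi-page TIFFs plus a JSON sidecar."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "delta.tif", volume.delta.astype(np.float32), photometric="minisblack")
    tifffile.imwrite(directory / "beta.tif", volume.beta.astype(np.float32), photometric="minisblack")
    tifffile.imwrite(directory / "labels.tif", volume.labels.astype(np.uint8), photometric="minisblack")
    meta = {"voxel_size_um": volume.voxel_size, "annotations": _jsonable(volume.annotations)}
    (directory / "phantom.json").write_text(json.dumps(meta, indent=2))


def load_phantom(directory: str | Path) -> ComplexIndexVolume:
    import tifffile

    directory = Path(directory)
    meta = json.loads((directory / "phantom.json").read_text())
    return ComplexIndexVolume(
        tifffile.imread(directory / "delta.tif").astype(np.float64),
        tifffile.imread(directory / "beta.tif").astype(np.float64),
        tifffile.imread(directory / "labels.tif"),
        meta["voxel_size_um"],
        meta.get("annotations", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
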