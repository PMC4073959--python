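"""End-to-end experiment: simulate → retrieve → reconstruct → register → measure.

The default configuration mirrors the acquisition and analysis protocol
(22 keV, 9 µm pixels, distances 7/30/100 cm, 1800 projections over 360°,
γ = 1950 retrieval, 0.4 mm² ROIs, five 0.2 mm profiles); ``desk_scale()``
provides the reduced testing profile (128³ phantom, 256 angles).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as M
from . import phantom as P
from . import recon as R
from . import registration as REG
from . import retrieval as RET
from . import units
from .propagation import BeamSpec, add_poisson_noise, simulate_scan


@dataclass
class ExperimentConfig:
    phantom: P.PhantomSpec = field(default_factory=P.PhantomSpec)
    energy_kev: float = 22.0
    distances_cm: tuple[float, ...] = (7.0, 30.0, 100.0)
    n_angles: int = 1800
    gamma_retrieval: float = 1950.0
    photons_per_pixel: float = 2.0e4
    noise: bool = True
    roi_area_mm2: float = 0.4
    n_roi_regions: int = 3
    n_roi_slices: int = 6
    n_profiles: int = 5
    profile_length_mm: float = 0.2
    profile_spacing_px: float = 2.0
    eei_sigma_source: str = "profile_ends"  # or "roi"
    cnr_denominator: str = "rms"
    fbp_filter: str = "ramp"
    seed: int = 0

    def __post_init__(self) -> None:
        self.distances_cm = tuple(float(d) for d in self.distances_cm)
        if any(d <= 0 for d in self.distances_cm):
            raise ValueError("distances must be positive")
        if tuple(sorted(self.distances_cm)) != self.distances_cm:
            raise ValueError("distances must be sorted ascending")
        if self.n_angles < 1:
            raise ValueError("n_angles must be positive")

    @classmethod
    def desk_scale(cls, seed: int = 0, noise: bool = True) -> "ExperimentConfig":
        """Reduced testing profile: 128³ phantom, 256 angles, small ROIs."""
        spec = P.PhantomSpec(
            shape=(128, 128, 128),
            vesicle_count=60,
            vesicle_radius_range=(36.0, 90.0),
            texture_amplitude=0.04,
            seed=seed,
        )
        return cls(
            phantom=spec,
            n_angles=256,
            noise=noise,
            photons_per_pixel=800.0,
            roi_area_mm2=0.012,
            seed=seed,
        )

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        try:
            phantom_raw = raw.pop("phantom", {})
            for key in ("shape", "vesicle_radius_range"):
                if key in phantom_raw:
                    phantom_raw[key] = tuple(phantom_raw[key])
            spec = P.PhantomSpec(**phantom_raw)
            if "distances_cm" in raw:
                raw["distances_cm"] = tuple(raw["distances_cm"])
            return cls(phantom=spec, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


class ConfigError(ValueError):
    pass


@dataclass
class MetricsReport:
    """CNR / EEI / steepness-of-fit per (mode, distance), Table-style."""

    entries: dict  # (mode, distance) -> {"cnr":…, "eei":…, "steepness_percent":…}
    reference_label: str
    extras: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {}
        for (mode, dist), vals in sorted(self.entries.items()):
            label = f"{mode.upper()} {dist:g} cm"
            cols[label] = {
                "CNR air-soft-tissue": vals.get("cnr"),
                "EEI": vals.get("eei"),
                "Steepness of fit (%)": vals.get("steepness_percent"),
            }
        return pd.DataFrame(cols)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(outdir / "report.csv")
        payload = {
            "reference": self.reference_label,
            "entries": {
                f"{mode}:{dist:g}": vals for (mode, dist), vals in self.entries.items()
            },
            "extras": self.extras,
        }
        (outdir / "report.json").write_text(json.dumps(payload, indent=2, default=float))


def roi_rects_from_annotations(
    annotations: dict, roi_area_mm2: float, pixel_size_um: float, n_regions: int = 3
) -> dict:
    """Rectangular ROIs solely in air (airway) and soft tissue (reserved zone).

    The requested ROI area is capped by the square inscribed in each zone;
    each zone is split into ``n_regions`` vertical strips.
    """
    px_mm = pixel_size_um / units.UM_PER_MM
    out = {}
    for name, ckey, rkey in (
        ("air", "airway_center_px", "airway_radius_px"),
        ("tissue", "tissue_zone_center_px", "tissue_zone_radius_px"),
    ):
        cr, cc = annotations[ckey]
        radius = annotations[rkey]
        side_zone = int(np.floor(radius * np.sqrt(2.0))) - 2
        side_req = int(np.floor(np.sqrt(roi_area_mm2) / px_mm))
        side = max(min(side_zone, side_req), n_regions)
        r0 = int(round(cr - side / 2))
        c0 = int(round(cc - side / 2))
        strip = side // n_regions
        out[name] = [
            (r0, c0 + i * strip, side, strip if i < n_regions - 1 else side - strip * (n_regions - 1))
            for i in range(n_regions)
        ]
    return out


def profile_spec_from_annotations(annotations: dict) -> dict:
    """Profile geometry crossing the airway's air–tissue interface radially."""
    cr, cc = annotations["airway_center_px"]
    radius = annotations["airway_radius_px"]
    return {
        "center_px": (cr - radius, cc),  # interface point, beam-side up
        "direction": (-1.0, 0.0),  # outward along −row
    }


def roi_slice_indices(n_slices: int, n_wanted: int) -> list[int]:
    mid = n_slices // 2
    half = n_wanted // 2
    return [mid - half + i for i in range(n_wanted)]


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


@dataclass
class ExperimentResult:
    report: MetricsReport
    manifest: dict
    recons: dict  # (mode, distance) -> ReconVolume
    transforms: dict
    phantom: P.ComplexIndexVolume


def measure_volume(
    volume: R.ReconVolume,
    annotations: dict,
    config: ExperimentConfig,
) -> dict:
    """CNR, EEI and sigmoid fit for one reconstructed volume.

    All statistics come from the original (untransformed, unfiltered) volume.
    """
    rois = roi_rects_from_annotations(
        annotations, config.roi_area_mm2, volume.pixel_size_um, config.n_roi_regions
    )
    slices = roi_slice_indices(volume.slices.shape[0], config.n_roi_slices)
    air_stats = M.pool_roi_stats(
        [
            M.roi_stats(volume.slices[s], rect, volume.pixel_size_um)
            for s in slices
            for rect in rois["air"]
        ]
    )
    tissue_stats = M.pool_roi_stats(
        [
            M.roi_stats(volume.slices[s], rect, volume.pixel_size_um)
            for s in slices
            for rect in rois["tissue"]
        ]
    )
    cnr_val = M.cnr(tissue_stats, air_stats, denominator=config.cnr_denominator)

    pspec = profile_spec_from_annotations(annotations)
    mid_slice = volume.slices[volume.slices.shape[0] // 2]
    profile = M.extract_profiles(
        mid_slice,
        pspec["center_px"],
        pspec["direction"],
        config.profile_length_mm,
        volume.pixel_size_um,
        n_profiles=config.n_profiles,
        spacing_px=config.profile_spacing_px,
    )
    if config.eei_sigma_source == "roi":
        sd_air, sd_tissue = air_stats.sd, tissue_stats.sd
    else:
        sd_air, sd_tissue = M.profile_end_sds(profile)
    eei_val = M.eei(profile, sd_air, sd_tissue)
    fit = M.fit_sigmoid(profile)
    return {
        "cnr": cnr_val,
        "eei": eei_val,
        "fit": fit,
        "profile": profile,
        "air_stats": air_stats,
        "tissue_stats": tissue_stats,
    }


def run_full_experiment(
    config: ExperimentConfig, outdir: str | Path | None = None
) -> ExperimentResult:
    """Simulate, retrieve, reconstruct, register and measure; emit the report."""
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}
    t_start = time.time()

    def stage(name):
        manifest["stages"][name] = {"t_start_s": round(time.time() - t_start, 2)}
        return manifest["stages"][name]

    st = stage("phantom")
    volume = P.make_lung_phantom(config.phantom)
    st["digest"] = _digest(volume.delta)

    st = stage("simulate")
    beam = BeamSpec(config.energy_kev, config.photons_per_pixel)
    clean = simulate_scan(
        volume, config.distances_cm, config.n_angles, beam, seed=config.seed
    )
    scans = clean
    if config.noise:
        seqs = np.random.SeedSequence(config.seed).spawn(len(config.distances_cm))
        scans = {
            d: add_poisson_noise(clean[d], config.photons_per_pixel, seed=seqs[i])
            for i, d in enumerate(config.distances_cm)
        }
    st["digest"] = {f"{d:g}": _digest(scans[d].intensities) for d in config.distances_cm}

    st = stage("reconstruct")
    recons: dict = {}
    for d in config.distances_cm:
        recons[("pbi", d)] = R.reconstruct_volume(scans[d], "pbi", config.fbp_filter)
        params = RET.RetrievalParams(
            gamma=config.gamma_retrieval,
            distance_cm=d,
            energy_kev=config.energy_kev,
            pixel_size_um=volume.voxel_size,
        )
        retrieved = RET.retrieve_stack(scans[d], params)
        recons[("phr", d)] = R.reconstruct_volume(retrieved, "phr", config.fbp_filter)
    st["digest"] = {f"{m}:{d:g}": _digest(v.slices) for (m, d), v in recons.items()}

    st = stage("register")
    ref_key = ("pbi", min(config.distances_cm))
    # the mean pre-filter is applied to PBI volumes only, and only here
    ref_vol = REG.mean_filter_3d(recons[ref_key].slices)
    ref_slice = ref_vol[ref_vol.shape[0] // 2]
    transforms = {}
    for key, vol in recons.items():
        moving = REG.mean_filter_3d(vol.slices) if key[0] == "pbi" else vol.slices
        idx, _score = REG.find_matching_slice(ref_slice, moving)
        tf = REG.fourier_mellin(ref_slice, moving[idx])
        tf.matched_slice_index = idx
        transforms[key] = tf
    st["transforms"] = {f"{m}:{d:g}": tf.to_dict() for (m, d), tf in transforms.items()}

    st = stage("measure")
    entries = {}
    fits = {}
    details = {}
    for key, vol in recons.items():
        res = measure_volume(vol, volume.annotations, config)
        entries[key] = {"cnr": res["cnr"], "eei": res["eei"]}
        fits[key] = res["fit"]
        details[key] = res
    ref = max(
        (k for k in fits if fits[k].converged), key=lambda k: fits[k].steepness
    )
    percents = M.steepness_percent(fits, ref)
    for key in entries:
        entries[key]["steepness_percent"] = percents.get(key)
        entries[key]["k2_per_mm"] = fits[key].steepness if fits[key].converged else None
        entries[key]["fit_converged"] = fits[key].converged

    # §3.3-style non-equivalence experiment at the middle distance
    extras = {}
    mid = config.distances_cm[len(config.distances_cm) // 2]
    if fits[("phr", mid)].converged:
        extras["steepness_match"] = gaussian_match_experiment(
            recons, volume.annotations, config, distance=mid
        )

    # histogram bimodality on the centre slice, inside the sample support
    extras["histogram"] = {}
    for key in (("pbi", mid), ("phr", mid)):
        vol = recons[key]
        sl = vol.slices[vol.slices.shape[0] // 2]
        stats = M.histogram_modes(_support_values(sl, volume.annotations))
        extras["histogram"][f"{key[0]}:{mid:g}"] = {
            "n_modes": stats.n_modes,
            "valley_to_peak": stats.valley_to_peak,
        }

    ref_label = f"{ref[0].upper()} {ref[1]:g} cm"
    report = MetricsReport(entries=entries, reference_label=ref_label, extras=extras)
    manifest["wall_clock_s"] = round(time.time() - t_start, 2)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.save(outdir)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str)
        )
        P.save_phantom(volume, outdir / "phantom")
        for (mode, d), vol in recons.items():
            R.save_recon(vol, outdir / f"recon_{mode}_{d:g}cm.tif")
    return ExperimentResult(report, manifest, recons, transforms, volume)


def _support_values(slice2d: np.ndarray, annotations: dict) -> np.ndarray:
    """Grey values of the lung region: inside the tissue cylinder (air
    cavities included), excluding the bone rod and its blur margin."""
    cr, cc = annotations["center_px"]
    radius = annotations["tissue_radius_px"] - 2
    rr, ccx = np.mgrid[: slice2d.shape[0], : slice2d.shape[1]]
    keep = (rr - cr) ** 2 + (ccx - cc) ** 2 < radius**2
    if annotations.get("bone_center_px") is not None:
        br, bc = annotations["bone_center_px"]
        bone_r = annotations["bone_radius_px"] + 12
        keep &= (rr - br) ** 2 + (ccx - bc) ** 2 > bone_r**2
    return slice2d[keep]


def gaussian_match_experiment(
    recons: dict, annotations: dict, config: ExperimentConfig, distance: float
) -> dict:
    """Filter the PBI slice to the PhR steepness and compare CNRs (§ non-equivalence)."""
    pspec = profile_spec_from_annotations(annotations)
    rois = roi_rects_from_annotations(
        annotations, config.roi_area_mm2, recons[("pbi", distance)].pixel_size_um,
        config.n_roi_regions,
    )
    pixel = recons[("pbi", distance)].pixel_size_um

    def profile_fn(slice2d):
        return M.extract_profiles(
            slice2d,
            pspec["center_px"],
            pspec["direction"],
            config.profile_length_mm,
            pixel,
            n_profiles=config.n_profiles,
            spacing_px=config.profile_spacing_px,
        )

    def cnr_fn(slice2d):
        air = M.pool_roi_stats(
            [M.roi_stats(slice2d, rect, pixel) for rect in rois["air"]]
        )
        tis = M.pool_roi_stats(
            [M.roi_stats(slice2d, rect, pixel) for rect in rois["tissue"]]
        )
        return M.cnr(tis, air, denominator=config.cnr_denominator)

    phr_vol = recons[("phr", distance)]
    pbi_vol = recons[("pbi", distance)]
    mid = pbi_vol.slices.shape[0] // 2
    target_k2 = M.fit_sigmoid(profile_fn(phr_vol.slices[mid])).steepness
    _filtered, achieved_k2, achieved_cnr, n_passes, reached = (
        M.match_steepness_by_gaussian(
            pbi_vol.slices[mid], target_k2, profile_fn, cnr_fn
        )
    )
    return {
        "distance_cm": distance,
        "target_k2_per_mm": target_k2,
        "achieved_k2_per_mm": achieved_k2,
        "achieved_cnr_filtered_pbi": achieved_cnr,
        "cnr_phr": cnr_fn(phr_vol.slices[mid]),
        "n_passes": n_passes,
        "reached": reached,
    }
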