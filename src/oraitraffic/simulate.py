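"""Synthetic two-channel confocal z-stacks with known ground truth.

No imaging data accompany the study this package reproduces, so the
quantification code is exercised on simulated stacks that emulate the
acquisition geometry: a PM-marker channel (TMEM16A-mCherry-like) whose axial
intensity peaks at the plasma-membrane focal plane, and a cargo channel
(GFP-Orai-like) whose total signal is split between the PM plane (fraction
``pm_fraction``) and deeper cytosolic vesicles (the rest). Slices are 0.5 µm
apart and frames default to 512×512 pixels, matching the acquisition the
quantification was designed for; z index 0 is the outermost ("surface")
slice, increasing inward ("deep").

Rendering is layered so tests can interrogate each stage: an ideal noise-free
scene (cargo PM mass entirely in the PM slice), anisotropic Gaussian PSF
blur, constant background, Poisson shot noise at a photon scale, Gaussian
read noise. Everything is reproducible from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

Z_ORDER_TAG = "outermost-first"


class SimulationError(ValueError):
    """Raised for invalid stack configurations or malformed stack files."""


@dataclass(frozen=True)
class StackConfig:
    """Geometry, optics and noise of one simulated stack.

    Lengths are µm. ``pm_plane`` is a z index; ``vesicle_depth_range`` is an
    inclusive (lo, hi) z-index range strictly deeper than the PM plane.
    """

    nz: int = 20
    ny: int = 512
    nx: int = 512
    z_step: float = 0.5
    pixel_size: float = 0.25
    pm_plane: int = 4
    pm_fraction: float = 0.5
    n_vesicles: int = 40
    vesicle_radius: float = 0.4
    vesicle_depth_range: tuple[int, int] | None = None  # default (pm_plane+4, nz-2)
    marker_axial_sigma: float = 0.4
    psf_sigma_lateral: float = 0.1
    psf_sigma_axial: float = 0.10
    background: float = 0.25
    photon_scale: float = 50.0
    read_noise_sd: float = 0.5
    curved_pm: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nz < 3:
            raise SimulationError("nz must be >= 3")
        if not 0 <= self.pm_plane <= self.nz - 1:
            raise SimulationError("pm_plane outside [0, nz-1]")
        if not 0.0 <= self.pm_fraction <= 1.0:
            raise SimulationError("pm_fraction must lie in [0, 1]")
        for name in ("z_step", "pixel_size", "marker_axial_sigma",
                     "psf_sigma_lateral", "psf_sigma_axial"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be > 0")
        lo, hi = self.vesicle_range
        if lo <= self.pm_plane:
            raise SimulationError(
                "vesicle depth range must lie strictly deeper than pm_plane"
            )
        if not lo <= hi <= self.nz - 1:
            raise SimulationError("invalid vesicle depth range")

    @property
    def vesicle_range(self) -> tuple[int, int]:
        if self.vesicle_depth_range is not None:
            return self.vesicle_depth_range
        lo = min(self.pm_plane + 4, self.nz - 1)
        return (lo, max(lo, self.nz - 2))


@dataclass
class TwoChannelStack:
    """Marker + cargo stack, z outermost-first, with acquisition metadata."""

    marker: np.ndarray
    cargo: np.ndarray
    z_order: str = Z_ORDER_TAG
    z_step: float = 0.5
    pixel_size: float = 0.25
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        if self.marker.shape != self.cargo.shape:
            raise SimulationError("marker and cargo shapes differ")
        if self.marker.ndim != 3:
            raise SimulationError("stacks must be 3-D (z, y, x)")
        if not self.z_order:
            raise SimulationError("z_order tag is required")

    @property
    def nz(self) -> int:
        return self.marker.shape[0]


_MARKER_AMP = 100.0
_CARGO_TOTAL_PER_PIXEL = 100.0


def _pm_profile(cfg: StackConfig) -> np.ndarray:
    """Marker axial profile: Gaussian in z centred on the PM plane."""
    z = np.arange(cfg.nz)
    return np.exp(-0.5 * (((z - cfg.pm_plane) * cfg.z_step) / cfg.marker_axial_sigma) ** 2)


def render_ideal(cfg: StackConfig) -> TwoChannelStack:
    """Noise-free, PSF-free scene with exact ground-truth cargo split.

    The cargo PM component sits entirely in the ``pm_plane`` slice, so the
    pre-PSF surface fraction equals ``pm_fraction`` exactly; vesicle puncta
    carry the remaining mass at sampled positions strictly deeper.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.nz, cfg.ny, cfg.nx)
    marker = np.zeros(shape)
    cargo = np.zeros(shape)

    if cfg.curved_pm:
        # spherical-cap PM: the membrane slice index rises toward the frame
        # edge; per-slice sums (what the statistic uses) are unaffected in
        # spirit but the peak broadens.
        yy, xx = np.mgrid[0: cfg.ny, 0: cfg.nx]
        r2 = ((yy - cfg.ny / 2) ** 2 + (xx - cfg.nx / 2) ** 2) / (
            (max(cfg.ny, cfg.nx) / 2) ** 2
        )
        plane_map = cfg.pm_plane + np.round(2.0 * r2).astype(int)
        plane_map = np.clip(plane_map, 0, cfg.nz - 1)
        prof = _pm_profile(cfg)
        for dz in range(cfg.nz):
            marker[dz] = _MARKER_AMP * prof[np.clip(
                dz - (plane_map - cfg.pm_plane), 0, cfg.nz - 1)]
        pm_sheet = np.zeros(shape)
        for iy in range(cfg.ny):
            pm_sheet[plane_map[iy, :], iy, np.arange(cfg.nx)] = 1.0
    else:
        marker += _MARKER_AMP * _pm_profile(cfg)[:, None, None]
        pm_sheet = np.zeros(shape)
        pm_sheet[cfg.pm_plane] = 1.0

    total_cargo = _CARGO_TOTAL_PER_PIXEL * cfg.ny * cfg.nx
    pm_mass = cfg.pm_fraction * total_cargo
    cargo += pm_sheet * (pm_mass / pm_sheet.sum())

    lo, hi = cfg.vesicle_range
    centers = []
    vesicle_mass = (1.0 - cfg.pm_fraction) * total_cargo
    if vesicle_mass > 0 and cfg.n_vesicles > 0:
        per_vesicle = vesicle_mass / cfg.n_vesicles
        margin_px = max(2, int(np.ceil(3 * cfg.vesicle_radius / cfg.pixel_size)))
        for _ in range(cfg.n_vesicles):
            zc = int(rng.integers(lo, hi + 1))
            yc = int(rng.integers(margin_px, cfg.ny - margin_px))
            xc = int(rng.integers(margin_px, cfg.nx - margin_px))
            centers.append((zc, yc, xc))
        puncta = np.zeros(shape)
        for zc, yc, xc in centers:
            puncta[zc, yc, xc] += per_vesicle
        sigma_vox = (
            cfg.vesicle_radius / cfg.z_step,
            cfg.vesicle_radius / cfg.pixel_size,
            cfg.vesicle_radius / cfg.pixel_size,
        )
        blobs = ndimage.gaussian_filter(puncta, sigma_vox, mode="constant")
        # vesicles live strictly in the cytoplasm: clip any axial tail that
        # crosses the PM plane, renormalize so the surface/cytoplasm split of
        # the ideal scene equals pm_fraction exactly
        blobs[: cfg.pm_plane + 1] = 0.0
        blobs *= vesicle_mass / blobs.sum()
        cargo += blobs

    gt = {
        "pm_fraction": cfg.pm_fraction,
        "pm_plane": cfg.pm_plane,
        "vesicle_centers": centers,
    }
    return TwoChannelStack(
        marker=marker,
        cargo=cargo,
        z_step=cfg.z_step,
        pixel_size=cfg.pixel_size,
        ground_truth=gt,
    )


def _apply_psf(img: np.ndarray, cfg: StackConfig) -> np.ndarray:
    sigma_vox = (
        cfg.psf_sigma_axial / cfg.z_step,
        cfg.psf_sigma_lateral / cfg.pixel_size,
        cfg.psf_sigma_lateral / cfg.pixel_size,
    )
    return ndimage.gaussian_filter(img, sigma_vox, mode="constant")


def generate_stack(cfg: StackConfig) -> TwoChannelStack:
    """Render, blur with the anisotropic PSF, add background and noise.

    Noise model: Poisson(photon_scale × intensity)/photon_scale shot noise,
    then additive Gaussian read noise, clipped at zero. ``photon_scale = 0``
    or ``read_noise_sd = 0`` switch the respective stage off.
    """
    ideal = render_ideal(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC0F0]))
    out = {}
    for name, img in (("marker", ideal.marker), ("cargo", ideal.cargo)):
        img = _apply_psf(img, cfg) + cfg.background
        if cfg.photon_scale > 0:
            img = rng.poisson(np.maximum(img, 0) * cfg.photon_scale) / cfg.photon_scale
        if cfg.read_noise_sd > 0:
            img = img + rng.normal(0.0, cfg.read_noise_sd, img.shape)
        out[name] = np.maximum(img, 0.0)
    return TwoChannelStack(
        marker=out["marker"],
        cargo=out["cargo"],
        z_step=cfg.z_step,
        pixel_size=cfg.pixel_size,
        ground_truth=ideal.ground_truth,
    )


def generate_coloc_pair(shape: tuple[int, int], target_rho: float, seed: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Two noisy images whose pixelwise Pearson correlation targets ``rho``.

    Construction: shared + independent standard-normal fields mixed as
    I1 = √|ρ|·S + √(1−|ρ|)·N1, I2 = sign(ρ)·√|ρ|·S + √(1−|ρ|)·N2, giving
    correlation exactly ρ in expectation (ρ = ±1 ⇒ deterministically equal /
    opposite images). Output is affinely shifted to a positive intensity
    scale, which leaves the coefficient unchanged.
    """
    if not -1.0 <= target_rho <= 1.0:
        raise SimulationError("target_rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    a = abs(target_rho)
    shared = rng.standard_normal(shape)
    n1 = rng.standard_normal(shape)
    n2 = rng.standard_normal(shape)
    i1 = np.sqrt(a) * shared + np.sqrt(1 - a) * n1
    i2 = np.sign(target_rho or 1.0) * np.sqrt(a) * shared + np.sqrt(1 - a) * n2
    return 100.0 + 20.0 * i1, 100.0 + 20.0 * i2


def write_stack(stack: TwoChannelStack, path: str | Path) -> Path:
    """Write a stack as multichannel TIFF (z, channel, y, x) + JSON sidecar.

    The sidecar carries the z-order tag, voxel size and ground truth; the
    round-trip is lossless (arrays bit-identical, dtype preserved).
    """
    path = Path(path)
    data = np.stack([stack.marker, stack.cargo], axis=1)  # (z, c, y, x)
    tifffile.imwrite(path, data)
    sidecar = {
        "z_order": stack.z_order,
        "z_step": stack.z_step,
        "pixel_size": stack.pixel_size,
        "channels": ["marker", "cargo"],
        "ground_truth": _jsonable(stack.ground_truth),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2) + "\n"
    )
    return path


def _jsonable(obj):
    if obj is None:
        return None
    return json.loads(json.dumps(obj, default=lambda o: (
        o.tolist() if isinstance(o, np.ndarray) else
        float(o) if isinstance(o, np.floating) else
        int(o) if isinstance(o, np.integer) else str(o))))


def read_stack(path: str | Path) -> TwoChannelStack:
    """Read a stack written by :func:`write_stack`.

    A missing sidecar or absent z-order tag is a hard error: the percent-PM
    statistic is direction-sensitive and cannot be computed on a stack whose
    acquisition direction is unknown.
    """
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise SimulationError(f"{path}: missing metadata sidecar {sidecar_path.name}")
    meta = json.loads(sidecar_path.read_text())
    if not meta.get("z_order"):
        raise SimulationError(f"{path}: metadata lacks the z_order tag")
    data = tifffile.imread(path)
    if data.ndim != 4 or data.shape[1] != 2:
        raise SimulationError(
            f"{path}: expected (z, 2, y, x) data, got shape {data.shape}"
        )
    return TwoChannelStack(
        marker=data[:, 0],
        cargo=data[:, 1],
        z_order=meta["z_order"],
        z_step=float(meta.get("z_step", 0.5)),
        pixel_size=float(meta.get("pixel_size", 0.25)),
        ground_truth=meta.get("ground_truth"),
    )
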