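"""Synthetic liver-like light-sheet phantoms with ground-truth labels.

The generator emulates the imaging situation the analysis modules are built
for: unstained murine liver autofluorescence under five excitation lines
(405/488/561/640/785 nm), acquired as separate left- and right-illuminated
stacks.  A phantom contains four ground-truth classes — image background, a
branching vessel-lumen network, and parenchyma split into spatially
alternating low- and high-autofluorescence zones (the zonation-like pattern
that is most pronounced at 785 nm excitation).  On top of the clean per-class
intensities the generator applies exponential depth attenuation along the
detection (z) axis, one-sided illumination shading along x (mirrored between
the left and right acquisitions), and signal-proportional Gaussian noise with
an optional Poisson shot-noise component.

Everything is deterministic under a fixed seed: the geometry stream is
separate from the noise streams, so class voxel counts are invariant to the
noise and illumination settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import ndtr

from .io import (
    AcquisitionMetadata,
    MultiChannelVolume,
    RegionLabelVolume,
    VALID_WAVELENGTHS,
    default_channel_metadata,
)

#: Ground-truth class coding (0 stays reserved for "unlabeled").
CLASS_NAMES = {1: "background", 2: "lumen", 3: "low_AF", 4: "high_AF"}

#: Default per-class mean intensities per excitation channel (arbitrary counts).
#: Parenchyma is brightest at 785 nm and the high-AF zone is twice the low-AF
#: zone; lumen and background sit at the detector background level.
DEFAULT_CLASS_SIGNATURE: dict[str, dict[int, float]] = {
    "background": {nm: 5.0 for nm in VALID_WAVELENGTHS},
    "lumen": {nm: 5.0 for nm in VALID_WAVELENGTHS},
    "low_AF": {405: 20.0, 488: 25.0, 561: 30.0, 640: 40.0, 785: 80.0},
    "high_AF": {405: 40.0, 488: 50.0, 561: 60.0, 640: 80.0, 785: 160.0},
}


@dataclass(frozen=True)
class NoiseModel:
    """Sensor noise: ``gaussian_sd`` is the *relative* (signal-proportional)
    standard deviation of the Gaussian component; ``poisson_scale`` > 0 adds
    shot noise with that many counts per photon-equivalent."""

    gaussian_sd: float = 0.05
    poisson_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0 or self.poisson_scale < 0:
            raise ValueError("noise parameters must be nonnegative")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic liver volume.

    All physical sizes are micrometres and are converted through
    ``voxel_size_um``; ``seed`` fully determines the output.
    """

    shape_voxels: tuple[int, int, int] = (32, 128, 128)
    voxel_size_um: tuple[float, float, float] = (20.0, 20.0, 20.0)
    class_signature: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_SIGNATURE.items()}
    )
    zonation_period_um: float = 500.0
    vessel_count: int = 12
    vessel_radius_um: tuple[float, float] = (60.0, 120.0)
    attenuation_length_um: float = 5000.0
    illumination_decay_um: float = 5000.0
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    background_level: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.shape_voxels):
            raise ValueError("shape_voxels must be positive")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel_size_um must be positive")
        required = {"background", "lumen", "low_AF", "high_AF"}
        if not required <= set(self.class_signature):
            raise ValueError(f"class_signature must include {sorted(required)}")
        for cls, row in self.class_signature.items():
            if any(v < 0 for v in row.values()):
                raise ValueError(f"class_signature[{cls!r}] has negative entries")
        if self.zonation_period_um <= 0:
            raise ValueError("zonation_period_um must be positive")
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be nonnegative")
        r0, r1 = self.vessel_radius_um
        if not (0 < r0 <= r1):
            raise ValueError("vessel_radius_um must be a positive (min, max) range")
        extent = min(n * v for n, v in zip(self.shape_voxels, self.voxel_size_um))
        if 2 * r1 > extent:
            raise ValueError("vessel radius larger than volume")
        if self.attenuation_length_um <= 0 or self.illumination_decay_um <= 0:
            raise ValueError("attenuation/illumination lengths must be positive (inf allowed)")

    @property
    def channels(self) -> list[int]:
        return sorted(next(iter(self.class_signature.values())))


def _zonation_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth periodic lobule-like field; its sign splits parenchyma into the
    high- and low-AF zones."""
    nz, ny, nx = spec.shape_voxels
    vz, vy, vx = spec.voxel_size_um
    k = 2.0 * np.pi / spec.zonation_period_um
    pz, py, px = rng.uniform(0, 2 * np.pi, size=3)
    z = (np.arange(nz) * vz)[:, None, None]
    y = (np.arange(ny) * vy)[None, :, None]
    x = (np.arange(nx) * vx)[None, None, :]
    # sum of oblique plane waves: band-limited, period ~ zonation_period_um
    f = (
        np.sin(k * z + pz) * np.sin(k * y + py)
        + np.sin(k * y + py / 2) * np.sin(k * x + px)
        + np.sin(k * (x + z) / np.sqrt(2.0) + px - pz)
    )
    return f


def _ball_offsets(radius_um: float, voxel_size_um: tuple[float, float, float]) -> np.ndarray:
    vz, vy, vx = voxel_size_um
    rz, ry, rx = (int(np.floor(radius_um / v)) for v in (vz, vy, vx))
    dz, dy, dx = np.mgrid[-rz : rz + 1, -ry : ry + 1, -rx : rx + 1]
    inside = (dz * vz) ** 2 + (dy * vy) ** 2 + (dx * vx) ** 2 <= radius_um**2
    return np.stack([dz[inside], dy[inside], dx[inside]], axis=1)


def _vessel_mask(
    spec: PhantomSpec, organ: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Random-walk tubes with per-branch radius, carved inside the organ."""
    nz, ny, nx = spec.shape_voxels
    voxel = np.asarray(spec.voxel_size_um)
    mask = np.zeros(spec.shape_voxels, dtype=bool)
    inside = np.argwhere(organ)
    if inside.size == 0 or spec.vessel_count == 0:
        return mask
    extent_um = float(np.max(np.asarray(spec.shape_voxels) * voxel))
    for _ in range(spec.vessel_count):
        radius = rng.uniform(*spec.vessel_radius_um)
        offsets = _ball_offsets(radius, spec.voxel_size_um)
        pos = inside[rng.integers(len(inside))].astype(float)  # voxel coords
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        step_um = max(radius / 2.0, float(voxel.min()))
        n_steps = max(4, int(0.6 * extent_um / step_um))
        for _ in range(n_steps):
            center = np.rint(pos).astype(int)
            pts = center[None, :] + offsets
            ok = (
                (pts[:, 0] >= 0) & (pts[:, 0] < nz)
                & (pts[:, 1] >= 0) & (pts[:, 1] < ny)
                & (pts[:, 2] >= 0) & (pts[:, 2] < nx)
            )
            pts = pts[ok]
            mask[pts[:, 0], pts[:, 1], pts[:, 2]] = True
            direction = direction + rng.normal(scale=0.35, size=3)
            direction /= np.linalg.norm(direction)
            pos = pos + direction * (step_um / voxel)
            if not ((0 <= pos) & (pos < np.asarray(spec.shape_voxels))).all():
                break
    return mask & organ


def _labels_for(spec: PhantomSpec, organ: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    zon = _zonation_field(spec, rng)
    vessels = _vessel_mask(spec, organ, rng)
    labels = np.ones(spec.shape_voxels, dtype=np.int32)  # background
    labels[organ] = np.where(zon[organ] > 0, 4, 3)  # high_AF / low_AF
    labels[vessels] = 2  # lumen
    return labels


def _attenuation(spec: PhantomSpec) -> np.ndarray:
    nz = spec.shape_voxels[0]
    z_um = np.arange(nz) * spec.voxel_size_um[0]
    return np.exp(-z_um / spec.attenuation_length_um)[:, None, None]


def illumination_profile(spec: PhantomSpec, side: str) -> np.ndarray:
    """One-sided light-sheet shading along x; ``right`` mirrors ``left``."""
    nx = spec.shape_voxels[2]
    x_um = np.arange(nx) * spec.voxel_size_um[2]
    decay = np.exp(-x_um / spec.illumination_decay_um)
    if side == "right":
        decay = decay[::-1].copy()
    elif side != "left":
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return decay[None, None, :]


def _apply_noise(clean: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    out = clean
    if noise.poisson_scale > 0:
        out = rng.poisson(out / noise.poisson_scale) * noise.poisson_scale
    if noise.gaussian_sd > 0:
        out = out + rng.normal(size=out.shape) * (noise.gaussian_sd * clean)
    return np.clip(out, 0.0, None)


def clean_channel_volume(spec: PhantomSpec, labels: np.ndarray, channel_nm: int) -> np.ndarray:
    """Noiseless, unshaded intensity: ``S[class, channel]`` looked up per voxel."""
    lut = np.zeros(max(CLASS_NAMES) + 1, dtype=np.float64)
    for lab, name in CLASS_NAMES.items():
        lut[lab] = spec.class_signature[name][channel_nm]
    return lut[labels]


def _generate(
    spec: PhantomSpec, organ: np.ndarray
) -> tuple[MultiChannelVolume, MultiChannelVolume, RegionLabelVolume]:
    ss = np.random.SeedSequence(spec.seed)
    geom_ss, left_ss, right_ss = ss.spawn(3)
    labels = _labels_for(spec, organ, np.random.default_rng(geom_ss))
    atten = _attenuation(spec)
    shade = {s: illumination_profile(spec, s) for s in ("left", "right")}
    noise_rng = {"left": np.random.default_rng(left_ss), "right": np.random.default_rng(right_ss)}
    volumes = {}
    for side in ("left", "right"):
        channels = {}
        for nm in spec.channels:
            clean = clean_channel_volume(spec, labels, nm) * atten * shade[side]
            channels[nm] = _apply_noise(clean, spec.noise_model, noise_rng[side]).astype(np.float32)
        volumes[side] = MultiChannelVolume(
            channels, default_channel_metadata(spec.voxel_size_um, side=side)
        )
    truth = RegionLabelVolume(labels, CLASS_NAMES)
    return volumes["left"], volumes["right"], truth


def _organ_ellipsoid(spec: PhantomSpec) -> np.ndarray:
    nz, ny, nx = spec.shape_voxels
    semi = [0.46 * (n - 1) for n in (nz, ny, nx)]
    z, y, x = np.ogrid[:nz, :ny, :nx]
    cz, cy, cx = ((n - 1) / 2.0 for n in (nz, ny, nx))
    return (
        ((z - cz) / semi[0]) ** 2 + ((y - cy) / semi[1]) ** 2 + ((x - cx) / semi[2]) ** 2
    ) <= 1.0


def generate_liver_phantom(
    spec: PhantomSpec,
) -> tuple[MultiChannelVolume, MultiChannelVolume, RegionLabelVolume]:
    """Whole-organ liver phantom: an ellipsoidal organ in image background.

    Returns separately shaded left and right acquisitions plus the
    ground-truth label volume.
    """
    return _generate(spec, _organ_ellipsoid(spec))


def generate_biopsy_phantom(
    spec: PhantomSpec,
    diameter_um: float = 1000.0,
    length_um: float | None = None,
) -> tuple[MultiChannelVolume, MultiChannelVolume, RegionLabelVolume]:
    """Liver-textured tissue cylinder (percutaneous biopsy core) along z.

    Everything outside the cylinder is image background.  The default 1 mm
    diameter matches the clinical extractor's maximum core size.
    """
    nz, ny, nx = spec.shape_voxels
    vz, vy, vx = spec.voxel_size_um
    if length_um is None:
        length_um = nz * vz
    radius_um = diameter_um / 2.0
    if 2 * radius_um > ny * vy or 2 * radius_um > nx * vx or length_um > nz * vz:
        raise ValueError(
            f"cylinder (diameter {diameter_um} µm, length {length_um} µm) does not fit "
            f"inside {tuple(spec.shape_voxels)} voxels of size {spec.voxel_size_um} µm"
        )
    z, y, x = np.ogrid[:nz, :ny, :nx]
    cz, cy, cx = ((n - 1) / 2.0 for n in (nz, ny, nx))
    radial = ((y - cy) * vy) ** 2 + ((x - cx) * vx) ** 2
    organ = (radial <= radius_um**2) & (np.abs((z - cz) * vz) <= length_um / 2.0)
    return _generate(spec, organ)


def generate_edge_phantom(
    sigma_blur_px: float,
    low: float,
    high: float,
    shape: tuple[int, int, int] = (4, 16, 128),
) -> np.ndarray:
    """Gaussian-blurred ideal step along x — analytic ground truth for
    edge-rise-distance measurements.

    The step sits at the x mid-plane; the profile is the continuous
    convolution of the step with an isotropic Gaussian of ``sigma_blur_px``,
    i.e. ``low + (high - low) * Phi((x - edge) / sigma)``.  With ``sigma = 0``
    the array contains only the two plateau values.
    """
    if high <= low:
        raise ValueError("high must exceed low")
    if sigma_blur_px < 0:
        raise ValueError("sigma_blur_px must be nonnegative")
    nz, ny, nx = shape
    x = np.arange(nx, dtype=np.float64)
    edge = nx / 2.0 - 0.5
    if sigma_blur_px == 0:
        profile = np.where(x < edge, float(low), float(high))
    else:
        profile = low + (high - low) * ndtr((x - edge) / sigma_blur_px)
    return np.broadcast_to(profile, (nz, ny, nx)).copy()


def sample_sparse_annotations(
    truth: RegionLabelVolume,
    slice_indices: list[int],
    n_per_class: int = 1000,
    seed: int = 0,
) -> RegionLabelVolume:
    """Sparse training annotations: up to ``n_per_class`` random voxels per
    class on each selected slice, 0 elsewhere (the manual-scribble analogue)."""
    rng = np.random.default_rng(seed)
    sparse = np.zeros_like(truth.labels)
    for zi in slice_indices:
        plane = truth.labels[zi]
        for lab in truth.class_names:
            idx = np.argwhere(plane == lab)
            if len(idx) == 0:
                continue
            take = idx[rng.choice(len(idx), size=min(n_per_class, len(idx)), replace=False)]
            sparse[zi, take[:, 0], take[:, 1]] = lab
    return RegionLabelVolume(sparse, truth.class_names)
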