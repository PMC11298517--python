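"""Acquisition-to-analysis image conditioning.

Bilateral light-sheet acquisitions are combined by digital image addition (in
32-bit float, never saturating — would-be saturation in the input dtype is
only reported), volumes are downsampled by trilinear block averaging (e.g.
isotropic 5 µm -> 20 µm with factor 4), and intensities can be normalized per
exposure time or by a percentile-clipped histogram rescale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import AcquisitionMetadata, MultiChannelVolume, RegionLabelVolume


@dataclass
class FusionResult:
    """Sum of the left- and right-illuminated stacks.

    ``clipped_fraction`` is the fraction of voxels whose float sum exceeds the
    input integer dtype's maximum — a saturation diagnostic only; the sum
    itself is never clipped.
    """

    fused: np.ndarray
    clipped_fraction: float = 0.0
    provenance: dict = field(default_factory=dict)
    metadata: AcquisitionMetadata | None = None


def fuse_bilateral(
    left: np.ndarray,
    right: np.ndarray,
    left_meta: AcquisitionMetadata | None = None,
    right_meta: AcquisitionMetadata | None = None,
) -> FusionResult:
    """Digital image addition of the two one-sided acquisitions.

    Performed in 32-bit float; commutative; raises on shape mismatch or when
    the two stacks belong to different excitation channels.
    """
    left = np.asarray(left)
    right = np.asarray(right)
    if left.shape != right.shape:
        raise ValueError(f"shape mismatch: {left.shape} vs {right.shape}")
    if left_meta is not None and right_meta is not None:
        if left_meta.excitation_nm != right_meta.excitation_nm:
            raise ValueError(
                f"cannot fuse different excitation channels "
                f"({left_meta.excitation_nm} vs {right_meta.excitation_nm})"
            )
    fused = left.astype(np.float32) + right.astype(np.float32)
    clipped = 0.0
    for arr in (left, right):
        if np.issubdtype(arr.dtype, np.integer):
            dtype_max = float(np.iinfo(arr.dtype).max)
            clipped = float(np.mean(fused > dtype_max))
            break
    meta = None
    if left_meta is not None:
        meta = left_meta.with_(side="fused")
    return FusionResult(fused=fused, clipped_fraction=clipped, metadata=meta)


def fuse_bilateral_mcv(left: MultiChannelVolume, right: MultiChannelVolume) -> MultiChannelVolume:
    """Channel-wise bilateral fusion of two multi-channel volumes."""
    channels, metadata = {}, {}
    for nm in left.wavelengths:
        res = fuse_bilateral(left[nm], right[nm], left.metadata[nm], right.metadata[nm])
        channels[nm] = res.fused
        metadata[nm] = res.metadata
    return MultiChannelVolume(channels, metadata)


def _block_mean_axis(volume: np.ndarray, factor: int, axis: int) -> np.ndarray:
    """Mean over consecutive blocks of ``factor`` along one axis; a trailing
    partial block is averaged over the voxels actually present."""
    n = volume.shape[axis]
    starts = np.arange(0, n, factor)
    sums = np.add.reduceat(volume, starts, axis=axis)
    counts = np.minimum(starts + factor, n) - starts
    shape = [1] * volume.ndim
    shape[axis] = len(starts)
    return sums / counts.reshape(shape)


def downsample_trilinear(
    volume: np.ndarray,
    factor: int | tuple[int, int, int],
    metadata: AcquisitionMetadata | None = None,
) -> np.ndarray | tuple[np.ndarray, AcquisitionMetadata]:
    """Trilinear (block-average) downsampling.

    Each output voxel is the arithmetic mean of its ``fz x fy x fx`` input
    block.  With metadata supplied, the voxel size is scaled accordingly and
    ``(array, metadata)`` is returned.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if np.isscalar(factor):
        factor = (int(factor),) * 3
    factor = tuple(int(f) for f in factor)
    if any(f <= 0 for f in factor):
        raise ValueError(f"factors must be positive integers, got {factor}")
    out = volume
    for axis, f in enumerate(factor):
        if f > 1:
            out = _block_mean_axis(out, f, axis)
    out = out.astype(np.float32)
    if metadata is not None:
        vz, vy, vx = metadata.voxel_size_um
        meta = metadata.with_(voxel_size_um=(vz * factor[0], vy * factor[1], vx * factor[2]))
        return out, meta
    return out


def downsample_labels(labels: RegionLabelVolume, factor: int | tuple[int, int, int]) -> RegionLabelVolume:
    """Majority-vote block downsampling of a label volume (ties go to the
    smaller label id).  Requires evenly dividing factors."""
    if np.isscalar(factor):
        factor = (int(factor),) * 3
    arr = labels.labels
    for axis, f in enumerate(factor):
        if arr.shape[axis] % f:
            raise ValueError(f"axis {axis} size {arr.shape[axis]} not divisible by {f}")
    fz, fy, fx = factor
    nz, ny, nx = (s // f for s, f in zip(arr.shape, factor))
    blocks = arr.reshape(nz, fz, ny, fy, nx, fx).transpose(0, 2, 4, 1, 3, 5).reshape(nz, ny, nx, -1)
    max_lab = int(arr.max())
    counts = np.stack([(blocks == lab).sum(axis=-1) for lab in range(max_lab + 1)], axis=-1)
    counts[..., 0] = 0  # never vote for "unlabeled" when real labels are present
    out = np.argmax(counts, axis=-1).astype(arr.dtype)
    out[blocks.max(axis=-1) == 0] = 0
    return RegionLabelVolume(out, labels.class_names)


def normalize_exposure(
    volume: np.ndarray, metadata: AcquisitionMetadata
) -> tuple[np.ndarray, AcquisitionMetadata]:
    """Scale intensities to counts per millisecond (divide by exposure time).

    Refuses to run twice on the same metadata.
    """
    if metadata.exposure_normalized:
        raise ValueError("volume is already exposure-normalized")
    out = np.asarray(volume, dtype=np.float32) / np.float32(metadata.exposure_ms)
    return out, metadata.with_(exposure_normalized=True)


def normalize_histogram(
    volume: np.ndarray, p_low: float = 0.1, p_high: float = 99.9
) -> np.ndarray:
    """Percentile-clipped min–max rescale to [0, 1].

    The ``p_low`` percentile maps to 0 and ``p_high`` to 1, with values
    clipped into [0, 1].  This linear interpretation (rather than histogram
    equalization) keeps downstream channel subtraction meaningful.  A
    constant volume yields all zeros with a warning.
    """
    if not (0 <= p_low < p_high <= 100):
        raise ValueError(f"need 0 <= p_low < p_high <= 100, got ({p_low}, {p_high})")
    volume = np.asarray(volume, dtype=np.float32)
    lo, hi = np.percentile(volume, [p_low, p_high])
    if hi <= lo:
        warnings.warn("zero dynamic range: histogram normalization returns all zeros")
        return np.zeros_like(volume, dtype=np.float32)
    return np.clip((volume - lo) / np.float32(hi - lo), 0.0, 1.0).astype(np.float32)
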