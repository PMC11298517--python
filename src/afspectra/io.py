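"""Reading and writing light-sheet image stacks, label volumes and channel configs.

All volumes are 3D arrays in ``(z, y, x)`` order with 0-based indices and voxel
centers at integer coordinates.  Integer pixel data are preserved on read;
arithmetic modules promote to 32-bit float.  On-disk formats are OME-TIFF /
multipage TIFF (or a directory of per-slice TIFFs ordered by filename) for
intensities and unsigned-integer TIFF for label volumes; channel metadata lives
in a YAML/JSON config keyed by excitation wavelength.
"""

from __future__ import annotations

import hashlib
import json
import logging
import uuid
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
import yaml

logger = logging.getLogger("afspectra")

#: Excitation lines of the five-laser setup (nm).
VALID_WAVELENGTHS = (405, 488, 561, 640, 785)

#: Emission filters paired with each excitation laser on the instrument.
DEFAULT_FILTERS = {405: "525/50", 488: "535/30", 561: "620/20", 640: "680/30", 785: "845/55"}

#: Camera exposure per channel (ms): 104 ms everywhere, ten-fold at 785 nm.
DEFAULT_EXPOSURES_MS = {405: 104.0, 488: 104.0, 561: 104.0, 640: 104.0, 785: 1040.0}

_OME_NS = "{http://www.openmicroscopy.org/Schemas/OME/2016-06}"


class StackReadError(RuntimeError):
    """Raised when a stack path is missing, unreadable, or inconsistent."""


class ConfigError(ValueError):
    """Raised when a channel config fails validation."""


@dataclass(frozen=True)
class AcquisitionMetadata:
    """Per-channel acquisition settings.

    Parameters
    ----------
    excitation_nm : int
        Excitation laser wavelength; one of 405, 488, 561, 640, 785.
    emission_filter : str
        Bandpass filter token, e.g. ``"845/55"``.
    exposure_ms : float
        Camera exposure time in milliseconds (> 0).
    laser_power : float
        Laser power in arbitrary units (>= 0).
    voxel_size_um : tuple of float
        Voxel edge lengths ``(z, y, x)`` in micrometres (> 0).
    side : str
        Illumination side: ``"left"``, ``"right"`` or ``"fused"``.
    exposure_normalized : bool
        True once intensities have been divided by ``exposure_ms``.
    """

    excitation_nm: int
    emission_filter: str = ""
    exposure_ms: float = 104.0
    laser_power: float = 0.0
    voxel_size_um: tuple[float, float, float] = (20.0, 20.0, 20.0)
    side: str = "fused"
    exposure_normalized: bool = False

    def __post_init__(self) -> None:
        if self.excitation_nm not in VALID_WAVELENGTHS:
            raise ConfigError(
                f"unknown excitation wavelength {self.excitation_nm}; "
                f"expected one of {VALID_WAVELENGTHS}"
            )
        if not self.exposure_ms > 0:
            raise ConfigError(f"exposure_ms must be > 0, got {self.exposure_ms}")
        if self.laser_power < 0:
            raise ConfigError("laser_power must be >= 0")
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ConfigError(f"voxel_size_um must be 3 positive reals, got {self.voxel_size_um}")
        if self.side not in ("left", "right", "fused"):
            raise ConfigError(f"side must be left/right/fused, got {self.side!r}")

    def with_(self, **kwargs) -> "AcquisitionMetadata":
        return replace(self, **kwargs)


def default_channel_metadata(
    voxel_size_um: tuple[float, float, float] = (20.0, 20.0, 20.0),
    side: str = "fused",
) -> dict[int, AcquisitionMetadata]:
    """Metadata for the instrument's five-laser configuration."""
    return {
        nm: AcquisitionMetadata(
            excitation_nm=nm,
            emission_filter=DEFAULT_FILTERS[nm],
            exposure_ms=DEFAULT_EXPOSURES_MS[nm],
            laser_power=1.0,
            voxel_size_um=tuple(voxel_size_um),
            side=side,
        )
        for nm in VALID_WAVELENGTHS
    }


class MultiChannelVolume:
    """Per-channel 3D intensity arrays sharing one voxel grid.

    ``channels`` maps excitation wavelength (nm) to a ``(z, y, x)`` array of
    finite nonnegative intensities; ``metadata`` maps the same keys to
    :class:`AcquisitionMetadata`.  All channels must share one shape and voxel
    size.
    """

    def __init__(
        self,
        channels: Mapping[int, np.ndarray],
        metadata: Mapping[int, AcquisitionMetadata],
    ) -> None:
        if not channels:
            raise ValueError("MultiChannelVolume needs at least one channel")
        self.channels: dict[int, np.ndarray] = {}
        self.metadata: dict[int, AcquisitionMetadata] = {}
        shape = None
        voxel = None
        for nm, arr in channels.items():
            arr = np.asarray(arr)
            if arr.ndim != 3:
                raise ValueError(f"channel {nm}: expected 3D (z,y,x) array, got ndim={arr.ndim}")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(f"channel {nm}: shape {arr.shape} != {shape}")
            if not np.isfinite(arr).all():
                raise ValueError(f"channel {nm}: non-finite intensities")
            if arr.min() < 0:
                raise ValueError(f"channel {nm}: negative intensities")
            if nm not in metadata:
                raise ValueError(f"channel {nm}: missing metadata")
            md = metadata[nm]
            if voxel is None:
                voxel = md.voxel_size_um
            elif md.voxel_size_um != voxel:
                raise ValueError(f"channel {nm}: voxel size {md.voxel_size_um} != {voxel}")
            self.channels[nm] = arr
            self.metadata[nm] = md
        self._shape = shape
        self._voxel = voxel

    @property
    def shape(self) -> tuple[int, int, int]:
        return self._shape

    @property
    def voxel_size_um(self) -> tuple[float, float, float]:
        return self._voxel

    @property
    def wavelengths(self) -> list[int]:
        return sorted(self.channels)

    def __getitem__(self, nm: int) -> np.ndarray:
        return self.channels[nm]

    def __contains__(self, nm: int) -> bool:
        return nm in self.channels

    def map(self, func) -> "MultiChannelVolume":
        """Apply ``func(array, metadata) -> (array, metadata)`` to every channel."""
        out_c, out_m = {}, {}
        for nm in self.wavelengths:
            a, m = func(self.channels[nm], self.metadata[nm])
            out_c[nm], out_m[nm] = a, m
        return MultiChannelVolume(out_c, out_m)


class RegionLabelVolume:
    """Integer-coded 3D segmentation with named classes.

    Label 0 is reserved for "unlabeled / ignore"; every nonzero label must have
    an entry in ``class_names``.
    """

    def __init__(self, labels: np.ndarray, class_names: Mapping[int, str]) -> None:
        labels = np.asarray(labels)
        if labels.ndim != 3:
            raise ValueError(f"labels must be 3D (z,y,x), got ndim={labels.ndim}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError(f"labels must be integer, got {labels.dtype}")
        self.class_names = {int(k): str(v) for k, v in class_names.items()}
        if 0 in self.class_names:
            raise ValueError("label 0 is reserved for unlabeled voxels")
        present = np.unique(labels)
        missing = [int(v) for v in present if v != 0 and int(v) not in self.class_names]
        if missing:
            raise ValueError(f"labels {missing} have no class_names entry")
        self.labels = labels

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def name_to_label(self) -> dict[str, int]:
        return {v: k for k, v in self.class_names.items()}

    def mask(self, class_name: str) -> np.ndarray:
        """Boolean mask of one named class."""
        return self.labels == self.name_to_label[class_name]

    def class_counts(self) -> dict[str, int]:
        return {name: int((self.labels == lab).sum()) for lab, name in self.class_names.items()}


def _deterministic_uuid(array: np.ndarray) -> str:
    digest = hashlib.md5(array.tobytes()).digest()
    return f"urn:uuid:{uuid.UUID(bytes=digest)}"


def write_stack(
    array: np.ndarray,
    metadata: AcquisitionMetadata | None,
    path: str | Path,
) -> Path:
    """Write a 3D array as OME-TIFF with voxel size and channel metadata embedded.

    Floating-point data are written as 32-bit; integer dtypes are preserved.
    The OME UUID is derived from the pixel content so identical data produce
    byte-identical files.
    """
    path = Path(path)
    array = np.asarray(array)
    if array.ndim == 2:
        array = array[None]
    if array.ndim != 3:
        raise ValueError(f"expected 3D array, got ndim={array.ndim}")
    if not np.isfinite(array).all():
        raise ValueError("array contains non-finite values")
    if np.issubdtype(array.dtype, np.floating):
        array = array.astype(np.float32)
    vz, vy, vx = metadata.voxel_size_um if metadata else (1.0, 1.0, 1.0)
    ome_md = {
        "axes": "ZYX",
        "PhysicalSizeZ": float(vz),
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeY": float(vy),
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeX": float(vx),
        "PhysicalSizeXUnit": "µm",
        "UUID": _deterministic_uuid(array),
    }
    if metadata is not None:
        ome_md["Description"] = json.dumps(
            {
                "excitation_nm": metadata.excitation_nm,
                "emission_filter": metadata.emission_filter,
                "exposure_ms": metadata.exposure_ms,
                "laser_power": metadata.laser_power,
                "side": metadata.side,
                "exposure_normalized": metadata.exposure_normalized,
            },
            sort_keys=True,
        )
    try:
        tifffile.imwrite(path, array, ome=True, metadata=ome_md, photometric="minisblack")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise StackReadError(f"cannot write {path}: {exc}") from exc
    return path


def _read_ome_voxel_size(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    if not tf.is_ome or not tf.ome_metadata:
        return None
    try:
        root = ET.fromstring(tf.ome_metadata)
    except ET.ParseError:
        return None
    pixels = root.find(f"{_OME_NS}Image/{_OME_NS}Pixels")
    if pixels is None:
        return None
    sizes = [pixels.get(f"PhysicalSize{ax}") for ax in "ZYX"]
    if any(s is None for s in sizes):
        return None
    return tuple(float(s) for s in sizes)


def _read_ome_description(tf: tifffile.TiffFile) -> dict | None:
    if not tf.is_ome or not tf.ome_metadata:
        return None
    try:
        root = ET.fromstring(tf.ome_metadata)
    except ET.ParseError:
        return None
    desc = root.find(f"{_OME_NS}Image/{_OME_NS}Description")
    if desc is None or not desc.text:
        return None
    try:
        return json.loads(desc.text)
    except json.JSONDecodeError:
        return None


def read_stack(
    path: str | Path,
    metadata: AcquisitionMetadata | None = None,
) -> tuple[np.ndarray, AcquisitionMetadata | None]:
    """Read a multipage TIFF, OME-TIFF, or directory of per-slice TIFFs.

    Returns a ``(z, y, x)`` array (a single-page TIFF becomes ``(1, H, W)``)
    and metadata.  Integer pixel types are preserved.  When the file carries
    OME voxel-size tags that disagree with the supplied metadata, the file
    wins and a notice is logged.
    """
    path = Path(path)
    if not path.exists():
        raise StackReadError(f"no such path: {path}")
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise StackReadError(f"directory {path} contains no TIFF files")
        slices = []
        for f in files:
            try:
                page = tifffile.imread(f)
            except Exception as exc:
                raise StackReadError(f"unreadable TIFF {f}: {exc}") from exc
            if page.ndim != 2:
                raise StackReadError(f"slice {f} is not 2D (shape {page.shape})")
            if slices and page.shape != slices[0].shape:
                raise StackReadError(
                    f"inconsistent slice shapes: {f} has {page.shape}, "
                    f"expected {slices[0].shape}"
                )
            slices.append(page)
        return np.stack(slices, axis=0), metadata
    try:
        with tifffile.TiffFile(path) as tf:
            array = tf.asarray()
            ome_voxel = _read_ome_voxel_size(tf)
            ome_desc = _read_ome_description(tf)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise StackReadError(f"unreadable TIFF {path}: {exc}") from exc
    if array.ndim == 2:
        array = array[None]
    if array.ndim != 3:
        raise StackReadError(f"{path}: expected a 2D/3D stack, got shape {array.shape}")
    if ome_voxel is not None:
        if metadata is not None and tuple(metadata.voxel_size_um) != ome_voxel:
            logger.info(
                "voxel size from OME tags %s overrides config %s for %s",
                ome_voxel, metadata.voxel_size_um, path,
            )
            metadata = metadata.with_(voxel_size_um=ome_voxel)
        elif metadata is None and ome_desc is not None and "excitation_nm" in ome_desc:
            metadata = AcquisitionMetadata(
                excitation_nm=int(ome_desc["excitation_nm"]),
                emission_filter=ome_desc.get("emission_filter", ""),
                exposure_ms=float(ome_desc.get("exposure_ms", 104.0)),
                laser_power=float(ome_desc.get("laser_power", 0.0)),
                voxel_size_um=ome_voxel,
                side=ome_desc.get("side", "fused"),
                exposure_normalized=bool(ome_desc.get("exposure_normalized", False)),
            )
    return array, metadata


def write_labels(labels: RegionLabelVolume, path: str | Path,
                 voxel_size_um: tuple[float, float, float] = (20.0, 20.0, 20.0)) -> Path:
    """Write a label volume as unsigned-integer OME-TIFF plus a JSON sidecar of class names."""
    path = Path(path)
    arr = labels.labels
    dtype = np.uint8 if arr.max() < 256 else np.uint16
    arr = arr.astype(dtype)
    md = {
        "axes": "ZYX",
        "PhysicalSizeZ": float(voxel_size_um[0]),
        "PhysicalSizeY": float(voxel_size_um[1]),
        "PhysicalSizeX": float(voxel_size_um[2]),
        "UUID": _deterministic_uuid(arr),
        "Description": json.dumps({"class_names": labels.class_names}, sort_keys=True),
    }
    tifffile.imwrite(path, arr, ome=True, metadata=md, photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".classes.json")
    sidecar.write_text(json.dumps(labels.class_names, sort_keys=True, indent=1) + "\n")
    return path


def read_labels(path: str | Path) -> RegionLabelVolume:
    """Read a label volume written by :func:`write_labels`."""
    path = Path(path)
    arr, _ = read_stack(path)
    sidecar = path.with_suffix(path.suffix + ".classes.json")
    if sidecar.exists():
        class_names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    else:
        with tifffile.TiffFile(path) as tf:
            desc = _read_ome_description(tf)
        if desc is None or "class_names" not in desc:
            raise StackReadError(f"no class names found for label volume {path}")
        class_names = {int(k): v for k, v in desc["class_names"].items()}
    return RegionLabelVolume(arr.astype(np.int32), class_names)


def load_channel_config(path: str | Path | None = None) -> dict[int, AcquisitionMetadata]:
    """Load per-channel acquisition metadata from a YAML/JSON config.

    The config is a mapping of excitation wavelength to a record with
    ``emission_filter``, ``exposure_ms``, ``laser_power``, ``voxel_size_um``
    and ``side`` keys; omitted keys fall back to the instrument defaults
    (five lasers, paired filters, 104 ms exposure except 1040 ms at 785 nm).
    With ``path=None`` the defaults are returned directly.
    """
    defaults = default_channel_metadata()
    if path is None:
        return defaults
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or not raw:
        raise ConfigError(f"config {path} is empty or not a mapping")
    out: dict[int, AcquisitionMetadata] = {}
    for key, record in raw.items():
        try:
            nm = int(key)
        except (TypeError, ValueError):
            raise ConfigError(f"config key {key!r} is not a wavelength") from None
        if nm not in VALID_WAVELENGTHS:
            raise ConfigError(f"unknown wavelength {nm}; expected one of {VALID_WAVELENGTHS}")
        record = dict(record or {})
        base = defaults[nm]
        voxel = record.get("voxel_size_um", base.voxel_size_um)
        out[nm] = AcquisitionMetadata(
            excitation_nm=nm,
            emission_filter=str(record.get("emission_filter", base.emission_filter)),
            exposure_ms=float(record.get("exposure_ms", base.exposure_ms)),
            laser_power=float(record.get("laser_power", base.laser_power)),
            voxel_size_um=tuple(float(v) for v in voxel),
            side=str(record.get("side", base.side)),
        )
    return out
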