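"""Trainable pixel classification of autofluorescence volumes.

A WEKA-style multiscale feature bank (Gaussian smoothing, Sobel gradient
magnitude, Hessian eigenvalues, differences of Gaussians, and membrane
projections — line filters rotated over a patch) feeds a random forest
trained from sparse slice annotations of four classes: background, lumen
(the vessel network), and the low- and high-autofluorescence parenchymal
zones.  The forest's vote fractions give per-class probability maps, which
are postprocessed by subtracting the background probability from the tissue
classes (the background map itself being replaced by its inversion, the
organ's gross-structure map).  Training follows the five-annotated-slices-
from-each-of-two-samples design, predicting an independent third volume; the
default training channel is 785 nm, where the liver zonation pattern is
strongest.

Features are computed per 2D slice (training happens on individual images and
memory stays bounded); sigma values are powers of two up to ``max_sigma``,
with sigma 0 denoting "no pre-smoothing".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.signal import fftconvolve
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.transform import rotate
from sklearn.ensemble import RandomForestClassifier

from .io import MultiChannelVolume, RegionLabelVolume
from .metrics import dice

MEMBRANE_AGGREGATIONS = ("sum", "mean", "max", "min", "median", "std")
_N_MEMBRANE_ROTATIONS = 30  # 6 degree steps over the half circle


@dataclass(frozen=True)
class FeatureBankConfig:
    """Multiscale feature-bank settings (field of view via min/max sigma)."""

    min_sigma: float = 0.0
    max_sigma: float = 16.0
    features_enabled: tuple[str, ...] = (
        "gaussian",
        "sobel",
        "hessian_eigenvalues",
        "difference_of_gaussians",
        "membrane_projections",
    )
    membrane_thickness: int = 1
    membrane_patch_size: int = 19

    _KNOWN = (
        "gaussian",
        "gradient_magnitude",
        "sobel",
        "hessian_eigenvalues",
        "difference_of_gaussians",
        "membrane_projections",
        "mean_patch",
        "variance_patch",
    )

    def __post_init__(self) -> None:
        if self.min_sigma < 0:
            raise ValueError("min_sigma must be nonnegative")
        if self.max_sigma < self.min_sigma or self.max_sigma <= 0:
            raise ValueError("max_sigma must be positive and >= min_sigma")
        unknown = set(self.features_enabled) - set(self._KNOWN)
        if unknown:
            raise ValueError(f"unknown features: {sorted(unknown)}")
        if self.membrane_patch_size % 2 == 0 or self.membrane_patch_size <= 0:
            raise ValueError("membrane_patch_size must be odd and positive")
        if self.membrane_thickness <= 0:
            raise ValueError("membrane_thickness must be positive")

    @property
    def sigma_set(self) -> tuple[float, ...]:
        """0 (iff min_sigma == 0) plus powers of two up to max_sigma."""
        sigmas: list[float] = []
        if self.min_sigma == 0:
            sigmas.append(0.0)
        s = max(self.min_sigma, 1.0)
        while s <= self.max_sigma:
            sigmas.append(float(s))
            s *= 2
        return tuple(sigmas)

    def feature_names(self) -> list[str]:
        """Deterministic names of every feature the bank produces."""
        names: list[str] = []
        sigmas = self.sigma_set
        patch_features = {"mean_patch": "mean", "variance_patch": "variance"}
        for feat in self.features_enabled:
            if feat == "gaussian":
                names += [f"gaussian_s{s:g}" for s in sigmas]
            elif feat in ("sobel", "gradient_magnitude"):
                names += [f"{feat}_s{s:g}" for s in sigmas]
            elif feat == "hessian_eigenvalues":
                for s in sigmas:
                    names += [f"hessian_eig1_s{s:g}", f"hessian_eig2_s{s:g}"]
            elif feat == "difference_of_gaussians":
                names += [
                    f"dog_s{si:g}_s{sj:g}"
                    for i, si in enumerate(sigmas)
                    for sj in sigmas[i + 1 :]
                ]
            elif feat == "membrane_projections":
                names += [f"membrane_{agg}" for agg in MEMBRANE_AGGREGATIONS]
            elif feat in patch_features:
                names += [f"{feat}_s{s:g}" for s in sigmas if s > 0]
        return names

    @property
    def feature_count(self) -> int:
        return len(self.feature_names())


def _membrane_kernels(config: FeatureBankConfig) -> list[np.ndarray]:
    size = config.membrane_patch_size
    base = np.zeros((size, size), dtype=np.float64)
    mid = size // 2
    half_t = config.membrane_thickness / 2.0
    for col in range(size):
        if abs(col - mid) <= half_t - 0.5 or (config.membrane_thickness == 1 and col == mid):
            base[:, col] = 1.0
    kernels = []
    for k in range(_N_MEMBRANE_ROTATIONS):
        angle = 180.0 * k / _N_MEMBRANE_ROTATIONS
        kernels.append(rotate(base, angle, order=1, preserve_range=True))
    return kernels


def compute_feature_bank(
    plane: np.ndarray, config: FeatureBankConfig | None = None
) -> tuple[np.ndarray, list[str]]:
    """Compute the multiscale feature stack of one 2D slice.

    Returns ``(stack, names)`` where ``stack`` has shape
    ``(n_features, H, W)`` and ``names`` matches
    :meth:`FeatureBankConfig.feature_names`.
    """
    if config is None:
        config = FeatureBankConfig()
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2:
        raise ValueError(f"expected a 2D slice, got ndim={plane.ndim}")
    if not np.isfinite(plane).all():
        raise ValueError("slice contains non-finite values")
    sigmas = config.sigma_set
    smoothed = {s: (plane if s == 0 else ndi.gaussian_filter(plane, s)) for s in sigmas}
    features: list[np.ndarray] = []
    for feat in config.features_enabled:
        if feat == "gaussian":
            features += [smoothed[s] for s in sigmas]
        elif feat in ("sobel", "gradient_magnitude"):
            for s in sigmas:
                gy = ndi.sobel(smoothed[s], axis=0)
                gx = ndi.sobel(smoothed[s], axis=1)
                features.append(np.hypot(gy, gx))
        elif feat == "hessian_eigenvalues":
            for s in sigmas:
                h = hessian_matrix(plane, sigma=max(s, 1e-9), mode="reflect",
                                   order="rc", use_gaussian_derivatives=False)
                e1, e2 = hessian_matrix_eigvals(h)
                features += [e1, e2]
        elif feat == "difference_of_gaussians":
            for i, si in enumerate(sigmas):
                for sj in sigmas[i + 1 :]:
                    features.append(smoothed[si] - smoothed[sj])
        elif feat == "membrane_projections":
            pad = config.membrane_patch_size // 2
            padded = np.pad(plane, pad, mode="reflect")
            responses = np.stack(
                [
                    fftconvolve(padded, k, mode="same")[pad:-pad, pad:-pad]
                    for k in _membrane_kernels(config)
                ]
            )
            features += [
                responses.sum(axis=0),
                responses.mean(axis=0),
                responses.max(axis=0),
                responses.min(axis=0),
                np.median(responses, axis=0),
                responses.std(axis=0),
            ]
        elif feat == "mean_patch":
            features += [ndi.uniform_filter(plane, int(2 * s + 1)) for s in sigmas if s > 0]
        elif feat == "variance_patch":
            for s in sigmas:
                if s > 0:
                    size = int(2 * s + 1)
                    m = ndi.uniform_filter(plane, size)
                    features.append(np.maximum(ndi.uniform_filter(plane**2, size) - m**2, 0.0))
    names = config.feature_names()
    stack = np.stack(features).astype(np.float32)
    assert stack.shape[0] == len(names)
    return stack, names


@dataclass
class TrainedPixelClassifier:
    """A fitted random-forest pixel classifier with its provenance."""

    model: RandomForestClassifier
    class_names: dict[int, str]
    feature_config: FeatureBankConfig
    channel_nm: int
    training_provenance: dict = field(default_factory=dict)

    @property
    def class_order(self) -> list[int]:
        return [int(c) for c in self.model.classes_]


def _get_channel(volume: MultiChannelVolume | np.ndarray, channel_nm: int) -> np.ndarray:
    if isinstance(volume, MultiChannelVolume):
        if channel_nm not in volume:
            raise ValueError(f"volume has no {channel_nm} nm channel")
        return volume[channel_nm]
    return np.asarray(volume)


def train_classifier(
    volumes: list[MultiChannelVolume | np.ndarray],
    annotations: list[RegionLabelVolume],
    config: FeatureBankConfig | None = None,
    channel_nm: int = 785,
    n_trees: int = 200,
    seed: int = 0,
) -> TrainedPixelClassifier:
    """Train the pixel classifier from sparse slice annotations.

    Every slice containing any nonzero annotation contributes its labeled
    pixels as training rows (features computed slice-wise).  All annotated
    classes must have at least one labeled pixel and at least two classes
    must be present.  The forest uses ``sqrt(n_features)`` candidate features
    per split and a recorded seed, so training is reproducible.
    """
    if config is None:
        config = FeatureBankConfig()
    if len(volumes) != len(annotations):
        raise ValueError("need one annotation volume per intensity volume")
    class_names = dict(annotations[0].class_names)
    xs, ys = [], []
    n_slices = 0
    for vol, ann in zip(volumes, annotations):
        data = _get_channel(vol, channel_nm)
        if data.shape != ann.shape:
            raise ValueError(f"annotation shape {ann.shape} != volume shape {data.shape}")
        for zi in np.unique(np.nonzero(ann.labels)[0]):
            plane_labels = ann.labels[zi]
            stack, _ = compute_feature_bank(data[zi], config)
            sel = plane_labels > 0
            xs.append(stack[:, sel].T)
            ys.append(plane_labels[sel])
            n_slices += 1
    if not xs:
        raise ValueError("no labeled pixels in any annotation")
    X = np.concatenate(xs)
    y = np.concatenate(ys)
    present = set(int(v) for v in np.unique(y))
    missing = [name for lab, name in class_names.items() if lab not in present]
    if missing:
        raise ValueError(f"classes with zero labeled pixels: {missing}")
    if len(present) < 2:
        raise ValueError("need labeled pixels from at least two classes")
    model = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    model.fit(X, y)
    per_class = {class_names[int(lab)]: int((y == lab).sum()) for lab in sorted(present)}
    provenance = {
        "n_annotated_slices": n_slices,
        "n_source_volumes": len(volumes),
        "n_labeled_pixels": per_class,
        "training_accuracy": float(model.score(X, y)),
        "n_trees": n_trees,
        "seed": seed,
        "channel_nm": channel_nm,
    }
    return TrainedPixelClassifier(
        model=model,
        class_names=class_names,
        feature_config=config,
        channel_nm=channel_nm,
        training_provenance=provenance,
    )


@dataclass
class ProbabilityMapSet:
    """Per-class 3D probability volumes; ``stage`` is ``raw`` (simplex per
    voxel) or ``background_subtracted``."""

    maps: dict[str, np.ndarray]
    stage: str = "raw"

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.maps.values())).shape

    def __getitem__(self, class_name: str) -> np.ndarray:
        return self.maps[class_name]


def predict_probabilities(
    classifier: TrainedPixelClassifier,
    volume: MultiChannelVolume | np.ndarray,
) -> ProbabilityMapSet:
    """Per-voxel class probabilities (forest vote fractions), slice-streamed."""
    data = _get_channel(volume, classifier.channel_nm)
    nz = data.shape[0]
    out = {
        name: np.zeros(data.shape, dtype=np.float32)
        for name in classifier.class_names.values()
    }
    order = classifier.class_order
    for zi in range(nz):
        stack, _ = compute_feature_bank(data[zi], classifier.feature_config)
        probs = classifier.model.predict_proba(stack.reshape(stack.shape[0], -1).T)
        for col, lab in enumerate(order):
            name = classifier.class_names[lab]
            out[name][zi] = probs[:, col].reshape(data.shape[1:]).astype(np.float32)
    return ProbabilityMapSet(maps=out, stage="raw")


def postprocess_background_subtraction(
    maps: ProbabilityMapSet, background_class: str = "background"
) -> ProbabilityMapSet:
    """Subtract the background probability from every tissue class (clipped at
    0); the background map is replaced by its inversion, the organ's
    gross-structure map."""
    if maps.stage != "raw":
        raise ValueError(f"expected raw-stage maps, got {maps.stage!r}")
    if background_class not in maps.maps:
        raise ValueError(f"no {background_class!r} class in probability maps")
    bg = maps[background_class]
    out = {}
    for name, p in maps.maps.items():
        if name == background_class:
            out[name] = np.clip(1.0 - bg, 0.0, 1.0).astype(np.float32)
        else:
            out[name] = np.clip(p - bg, 0.0, 1.0).astype(np.float32)
    return ProbabilityMapSet(maps=out, stage="background_subtracted")


def probability_to_mask(
    maps: ProbabilityMapSet,
    class_name: str | None = None,
    threshold: float = 0.5,
    class_ids: dict[str, int] | None = None,
) -> RegionLabelVolume:
    """Threshold one class map into a binary mask, or (``class_name=None``)
    argmax all maps into a full label volume."""
    if class_name is not None:
        if class_name not in maps.maps:
            raise ValueError(f"unknown class {class_name!r}")
        if not (0 < threshold < 1):
            raise ValueError("threshold must be in (0, 1)")
        mask = (maps[class_name] >= threshold).astype(np.int32)
        return RegionLabelVolume(mask, {1: class_name})
    names = sorted(maps.maps)
    if class_ids is None:
        class_ids = {name: i + 1 for i, name in enumerate(names)}
    stack = np.stack([maps[name] for name in names])
    winner = np.argmax(stack, axis=0)
    ids = np.array([class_ids[name] for name in names], dtype=np.int32)
    return RegionLabelVolume(ids[winner], {class_ids[n]: n for n in names})


def evaluate_segmentation(
    pred: RegionLabelVolume, truth: RegionLabelVolume
) -> pd.DataFrame:
    """Per-class DICE between a predicted and a reference label volume,
    matched by class name, plus the macro average."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    pred_names = set(pred.class_names.values())
    truth_names = set(truth.class_names.values())
    if pred_names != truth_names:
        raise ValueError(f"class-name mismatch: {sorted(pred_names)} vs {sorted(truth_names)}")
    rows = []
    for name in sorted(truth_names):
        a = pred.mask(name)
        b = truth.mask(name)
        both_empty = not (a.any() or b.any())
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            score = dice(a, b)
        rows.append({"class": name, "dice": score, "both_empty": both_empty})
    df = pd.DataFrame(rows).set_index("class")
    df.loc["macro_average"] = {"dice": df["dice"].mean(), "both_empty": False}
    return df
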