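"""Per-spot histology feature extraction behind a pluggable interface.

A Visium H&E image contributes one feature vector per spot: a square patch is
cropped around each spot center and passed through a :class:`FeatureExtractor`.
The package ships two extractors:

* :func:`stub_extractor` — a deterministic summary-statistic extractor
  (channel means, channel standard deviations, seeded random projection of
  the flattened patch) used throughout the test suite; it needs no weights.
* :class:`ViTExtractor` — an adapter that wraps a pretrained vision
  transformer from ``timm`` when the user has ``torch``/``timm`` installed.
  No weights are bundled.

Precomputed feature tables (CSV) bypass this module entirely via
:func:`stmmr.data.load_tabular`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PatchSet",
    "FeatureExtractor",
    "extract_patches",
    "featurize",
    "stub_extractor",
    "ViTExtractor",
]


@dataclass
class PatchSet:
    """Square RGB crops, one per spot, centered on the spot pixel coordinates."""

    patches: np.ndarray  # spots × side × side × 3, uint8
    side: int
    centers: np.ndarray  # spots × 2, (x, y) pixels

    def __post_init__(self):
        n, s1, s2, c = self.patches.shape
        if s1 != self.side or s2 != self.side or c != 3:
            raise ValueError("patches must be spots × side × side × 3")
        if self.centers.shape != (n, 2):
            raise ValueError("one center per patch required")


class FeatureExtractor:
    """Interface: maps a batch of patches to a spots × M feature matrix.

    Implementations must be deterministic given fixed weights and must return
    finite values.
    """

    output_dim: int
    name: str

    def features(self, patches: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def extract_patches(image: np.ndarray, coords: np.ndarray, side: int) -> PatchSet:
    """Crop a ``side``×``side`` patch around each spot center.

    ``coords`` are (x, y) pixel positions.  Crops overlapping the image border
    are completed by reflection padding (reflection preserves local stain
    statistics, which zero padding would bias).  Spot centers outside the
    image raise with the offending spot indices.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be H × W × 3")
    coords = np.asarray(coords)
    h, w = image.shape[:2]
    xs = np.round(coords[:, 0]).astype(int)
    ys = np.round(coords[:, 1]).astype(int)
    bad = np.flatnonzero((xs < 0) | (xs >= w) | (ys < 0) | (ys >= h))
    if bad.size:
        raise ValueError(f"spot centers outside the image: indices {bad.tolist()[:10]}")

    pad = side  # generous; any crop then lies fully inside the padded image
    padded = np.pad(image, ((pad, pad), (pad, pad), (0, 0)), mode="reflect")
    half = side // 2
    patches = np.empty((len(xs), side, side, image.shape[2]), dtype=image.dtype)
    for i, (x, y) in enumerate(zip(xs, ys)):
        r0 = y + pad - half
        c0 = x + pad - half
        patches[i] = padded[r0 : r0 + side, c0 : c0 + side]
    return PatchSet(patches=patches, side=side, centers=coords[:, :2].astype(np.float64))


def featurize(ps: PatchSet, ex: FeatureExtractor) -> np.ndarray:
    """Apply the extractor patch-by-patch; returns a spots × M matrix."""
    n = ps.patches.shape[0]
    out = np.empty((n, ex.output_dim), dtype=np.float64)
    for i in range(n):
        try:
            vec = ex.features(ps.patches[i : i + 1])[0]
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise RuntimeError(f"feature extractor '{ex.name}' failed on patch {i}") from exc
        if not np.isfinite(vec).all():
            raise RuntimeError(f"feature extractor '{ex.name}' produced non-finite values on patch {i}")
        out[i] = vec
    return out


@dataclass
class _StubExtractor(FeatureExtractor):
    """Deterministic summary-statistic extractor (see :func:`stub_extractor`)."""

    output_dim: int
    seed: int = 0
    name: str = "stub"
    _proj: dict = field(default_factory=dict, repr=False)

    def _projection(self, flat_dim: int) -> np.ndarray:
        if flat_dim not in self._proj:
            rng = np.random.default_rng(self.seed)
            n_extra = self.output_dim - 6
            self._proj[flat_dim] = rng.normal(size=(n_extra, flat_dim)) / np.sqrt(flat_dim)
        return self._proj[flat_dim]

    def features(self, patches: np.ndarray) -> np.ndarray:
        x = np.asarray(patches, dtype=np.float64) / 255.0  # n × s × s × 3
        means = x.mean(axis=(1, 2))  # n × 3
        stds = x.std(axis=(1, 2))  # n × 3
        base = np.concatenate([means, stds], axis=1)[:, : self.output_dim]
        if self.output_dim <= 6:
            return base
        flat = x.reshape(x.shape[0], -1)
        proj = flat @ self._projection(flat.shape[1]).T
        return np.concatenate([base, proj], axis=1)


def stub_extractor(output_dim: int, seed: int = 0) -> FeatureExtractor:
    """Deterministic test-double extractor.

    Features are: per-channel means (3), per-channel standard deviations (3),
    then a fixed seeded Gaussian random projection of the flattened patch up
    to ``output_dim`` dimensions.  Pixel values are scaled to [0, 1] first.
    """
    if output_dim < 3:
        raise ValueError("output_dim must be at least 3")
    return _StubExtractor(output_dim=output_dim, seed=seed)


class ViTExtractor(FeatureExtractor):
    """Adapter around a pretrained vision transformer from ``timm``.

    Requires ``torch`` and ``timm`` (optional dependencies; not used by any
    test).  Patches are resized to the model's expected input and the pooled
    token embedding is returned.
    """

    name = "vit-adapter"

    def __init__(self, model_name: str = "vit_base_patch16_224", device: str = "cpu"):
        try:
            import timm
            import torch
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "ViTExtractor requires the optional dependencies 'torch' and 'timm'; "
                "install them or use stub_extractor / precomputed features"
            ) from exc
        self._torch = torch
        self._model = timm.create_model(model_name, pretrained=True, num_classes=0)
        self._model.eval().to(device)
        self._device = device
        self.output_dim = self._model.num_features

    def features(self, patches: np.ndarray) -> np.ndarray:  # pragma: no cover
        torch = self._torch
        x = torch.from_numpy(np.asarray(patches, dtype=np.float32) / 255.0)
        x = x.permute(0, 3, 1, 2).to(self._device)
        size = self._model.default_cfg.get("input_size", (3, 224, 224))[1:]
        x = torch.nn.functional.interpolate(x, size=size, mode="bilinear", align_corners=False)
        with torch.no_grad():
            out = self._model(x)
        return out.cpu().numpy().astype(np.float64)
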