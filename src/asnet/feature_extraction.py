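"""Deep feature extraction from frozen pretrained backbones, plus a toy extractor.

Six layer taps across three ImageNet-pretrained convolutional networks give
six feature matrices per dataset:

==============  ============  ============================================
backbone        layer tap     meaning
==============  ============  ============================================
densenet201     fc1000        final affine output, pre-softmax (d=1000)
densenet201     avg_pool      global-average-pool output (d=1920)
resnet50        fc1000        final affine output, pre-softmax (d=1000)
resnet50        avg_pool      global-average-pool output (d=2048)
shufflenet      node_200      last global-pooling output (d=1024)
shufflenet      node_202      final fully-connected output (d=1000)
==============  ============  ============================================

The ShuffleNet taps are export-graph node names; the registry maps them to
the pooled and fully-connected outputs of torchvision's shufflenet_v2_x1_0
and can be overridden in config. Pretrained weights (torch + torchvision)
are an optional runtime dependency; the ``toy`` backbone is a seeded,
dependency-free extractor that projects hand-crafted image statistics to a
declared dimension and is the default for tests and fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .data_io import DatasetManifest, FeatureMatrix, ImageTensor, read_image

# ImageNet training-set channel statistics, the standard transfer-learning
# preprocessing constants for all three backbones.
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])

#: The six registered (backbone, layer) taps, in fixed pipeline order.
REGISTERED_TAPS: tuple[tuple[str, str], ...] = (
    ("densenet201", "fc1000"),
    ("densenet201", "avg_pool"),
    ("resnet50", "fc1000"),
    ("resnet50", "avg_pool"),
    ("shufflenet", "node_200"),
    ("shufflenet", "node_202"),
)

_VALID_LAYERS = {
    "densenet201": ("fc1000", "avg_pool"),
    "resnet50": ("fc1000", "avg_pool"),
    "shufflenet": ("node_200", "node_202"),
}

# Distinct output widths for the six toy stand-ins, all above the retained
# feature count so top-k selection is non-trivial in tests and fixtures.
TOY_DIMS: tuple[int, ...] = (300, 320, 340, 360, 380, 400)


class ExtractionError(RuntimeError):
    pass


@dataclass(frozen=True)
class BackboneSpec:
    """One registered feature tap of a (frozen) backbone."""

    backbone: str
    layer: str
    input_size: tuple[int, int] = (224, 224)
    toy_dim: int = 300
    toy_seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone == "toy":
            if self.toy_dim < 1:
                raise ExtractionError("toy output dimension must be >= 1")
            return
        valid = _VALID_LAYERS.get(self.backbone)
        if valid is None:
            raise ExtractionError(
                f"unknown backbone '{self.backbone}'; valid: "
                f"{sorted(_VALID_LAYERS)} or 'toy'"
            )
        if self.layer not in valid:
            raise ExtractionError(
                f"unknown layer '{self.layer}' for {self.backbone}; valid taps: {valid}"
            )
        if self.input_size[0] < 1 or self.input_size[1] < 1:
            raise ExtractionError("input_size must be positive")

    @property
    def name(self) -> str:
        return f"{self.backbone}/{self.layer}"


def default_specs(mode: str = "pretrained", seed: int = 0) -> list[BackboneSpec]:
    """The six pipeline taps; in toy mode, six seeded stand-ins of distinct width."""
    if mode == "pretrained":
        return [BackboneSpec(b, l) for b, l in REGISTERED_TAPS]
    if mode == "toy":
        return [
            BackboneSpec("toy", f"{b}.{l}", toy_dim=d, toy_seed=seed * 1009 + i)
            for i, ((b, l), d) in enumerate(zip(REGISTERED_TAPS, TOY_DIMS))
        ]
    raise ExtractionError(f"unknown extractor mode '{mode}' (use 'pretrained' or 'toy')")


def preprocess_for_backbone(img: ImageTensor, spec: BackboneSpec) -> ImageTensor:
    """Resize to the backbone's input size and normalize with its training constants.

    Grayscale inputs are replicated across three channels. Intensities are
    scaled to [0, 1] by the image's own maximum representable range (the
    observed maximum for float inputs, 255 for 8-bit-like content) and then
    z-scored per channel with the ImageNet constants. Deterministic.
    """
    px = img.pixels
    if px.shape[0] < 1 or px.shape[1] < 1:
        raise ExtractionError("zero-area image")
    if px.shape[2] == 1:
        px = np.repeat(px, 3, axis=2)
    h, w = spec.input_size
    px = _resize_bilinear(px, h, w)
    peak = px.max()
    scale = 255.0 if peak <= 255.0 else peak
    unit = px / scale if scale > 0 else px
    out = (unit - IMAGENET_MEAN) / IMAGENET_STD
    return ImageTensor(pixels=out + 0.0, channels=3, value_range="normalized")


def _resize_bilinear(px: np.ndarray, h: int, w: int) -> np.ndarray:
    """Separable bilinear resize with corner-aligned sampling; no aspect preservation."""
    sh, sw, c = px.shape
    if (sh, sw) == (h, w):
        return px.copy()
    ys = np.linspace(0, sh - 1, h)
    xs = np.linspace(0, sw - 1, w)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, sh - 1)
    x1 = np.minimum(x0 + 1, sw - 1)
    fy = (ys - y0)[:, None, None]
    fx = (xs - x0)[None, :, None]
    top = px[y0][:, x0] * (1 - fx) + px[y0][:, x1] * fx
    bot = px[y1][:, x0] * (1 - fx) + px[y1][:, x1] * fx
    return top * (1 - fy) + bot * fy


# --------------------------------------------------------------------------
# Toy extractor: seeded random projection of hand-crafted image statistics.
# --------------------------------------------------------------------------

def image_statistics(img: ImageTensor, grid: int = 4, n_hist: int = 16) -> np.ndarray:
    """Fixed-length statistics vector: global moments, histogram, block stats.

    Lipschitz in pixel intensities, so class-dependent intensity and texture
    differences survive projection.
    """
    px = img.pixels.mean(axis=2)
    peak = px.max()
    unit = px / (255.0 if peak <= 255.0 else peak) if peak > 0 else px
    mom = np.array([unit.mean(), unit.std(), np.mean(unit**3), np.mean((unit - unit.mean()) ** 2)])
    hist = np.histogram(unit, bins=n_hist, range=(0.0, 1.0))[0] / unit.size
    gy, gx = np.gradient(unit)
    h, w = unit.shape
    yb = np.linspace(0, h, grid + 1).astype(int)
    xb = np.linspace(0, w, grid + 1).astype(int)
    block_mean = np.empty(grid * grid)
    block_grad = np.empty(grid * grid)
    k = 0
    for i in range(grid):
        for j in range(grid):
            tile = unit[yb[i]:yb[i + 1], xb[j]:xb[j + 1]]
            gtile = gy[yb[i]:yb[i + 1], xb[j]:xb[j + 1]] ** 2 + gx[yb[i]:yb[i + 1], xb[j]:xb[j + 1]] ** 2
            block_mean[k] = tile.mean() if tile.size else 0.0
            block_grad[k] = gtile.mean() if gtile.size else 0.0
            k += 1
    return np.concatenate([mom, hist, block_mean, block_grad])


def toy_extract(img: ImageTensor, d: int, seed: int) -> np.ndarray:
    """Project the image-statistics vector to dimension *d* with a seeded Gaussian map."""
    if d < 1:
        raise ExtractionError(f"toy output dimension must be >= 1, got {d}")
    stats = image_statistics(img)
    rng = np.random.default_rng(seed)
    proj = rng.standard_normal((d, stats.size)) / np.sqrt(stats.size)
    return proj @ stats


# --------------------------------------------------------------------------
# Extraction over a manifest
# --------------------------------------------------------------------------

def extract_features(
    manifest: DatasetManifest, spec: BackboneSpec, batch_size: int = 8
) -> FeatureMatrix:
    """Row i is the flattened activation of ``spec.layer`` for manifest sample i.

    Output is independent of ``batch_size``; weights are frozen so repeated
    passes are identical.
    """
    if len(manifest) == 0:
        raise ExtractionError("no samples in manifest")
    if spec.backbone == "toy":
        rows = [
            toy_extract(read_image(s.path), spec.toy_dim, spec.toy_seed)
            for s in manifest.samples
        ]
        values = np.vstack(rows)
    else:
        values = _extract_pretrained(manifest, spec, batch_size)
    return FeatureMatrix(
        values=values,
        sample_ids=manifest.sample_ids(),
        labels=manifest.label_codes(),
        source=spec.name,
    )


def _extract_pretrained(
    manifest: DatasetManifest, spec: BackboneSpec, batch_size: int
) -> np.ndarray:
    try:
        import torch
        import torchvision.models as tvm
    except ImportError as exc:
        raise ExtractionError(
            "pretrained extraction needs the optional 'torch' and 'torchvision' "
            "dependencies (pip install asnet[pretrained]); for a dependency-free "
            "run use the toy extractor (mode='toy')"
        ) from exc

    torch.manual_seed(0)
    if spec.backbone == "densenet201":
        model = tvm.densenet201(weights=tvm.DenseNet201_Weights.IMAGENET1K_V1)
    elif spec.backbone == "resnet50":
        model = tvm.resnet50(weights=tvm.ResNet50_Weights.IMAGENET1K_V1)
    else:
        model = tvm.shufflenet_v2_x1_0(weights=tvm.ShuffleNet_V2_X1_0_Weights.IMAGENET1K_V1)
    model.eval()

    want_pool = spec.layer in ("avg_pool", "node_200")
    rows: list[np.ndarray] = []
    with torch.no_grad():
        batch: list[np.ndarray] = []

        def flush() -> None:
            if not batch:
                return
            x = torch.from_numpy(np.stack(batch).transpose(0, 3, 1, 2)).float()
            if spec.backbone == "densenet201":
                feats = model.features(x)
                pooled = torch.nn.functional.adaptive_avg_pool2d(
                    torch.nn.functional.relu(feats), 1
                ).flatten(1)
                out = pooled if want_pool else model.classifier(pooled)
            elif spec.backbone == "resnet50":
                x = model.conv1(x)
                x = model.bn1(x)
                x = model.relu(x)
                x = model.maxpool(x)
                x = model.layer1(x)
                x = model.layer2(x)
                x = model.layer3(x)
                x = model.layer4(x)
                pooled = model.avgpool(x).flatten(1)
                out = pooled if want_pool else model.fc(pooled)
            else:
                x = model.conv1(x)
                x = model.maxpool(x)
                x = model.stage2(x)
                x = model.stage3(x)
                x = model.stage4(x)
                x = model.conv5(x)
                pooled = x.mean([2, 3])
                out = pooled if want_pool else model.fc(pooled)
            rows.extend(out.numpy().astype(np.float64))
            batch.clear()

        for s in manifest.samples:
            batch.append(preprocess_for_backbone(read_image(s.path), spec).pixels)
            if len(batch) >= batch_size:
                flush()
        flush()
    return np.vstack(rows)


def extract_all(
    manifest: DatasetManifest,
    specs: Optional[list[BackboneSpec]] = None,
    mode: str = "pretrained",
    seed: int = 0,
    batch_size: int = 8,
) -> list[FeatureMatrix]:
    """The six feature matrices, in the fixed registered-tap order."""
    if len(manifest) == 0:
        raise ExtractionError("no samples in manifest")
    if specs is None:
        specs = default_specs(mode=mode, seed=seed)
    out = []
    for spec in specs:
        try:
            out.append(extract_features(manifest, spec, batch_size=batch_size))
        except ExtractionError as exc:
            raise ExtractionError(f"[{spec.name}] {exc}") from exc
    return out
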