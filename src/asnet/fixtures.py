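"""Seeded synthetic fixtures: feature matrices and two-class phantom images.

These generators stand in for clinical MRI data so the full pipeline can run
with zero downloads. They emulate only the statistical task the pipeline
assumes — a two-class problem where one class carries localized
hyperintensity (features: a mean shift on a fraction of columns; images:
bright blobs adjacent to a joint line) — not MRI physics.

Everything is fully determined by the seed; there is no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import DatasetManifest, FeatureMatrix, Sample


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic two-class dataset.

    delta is the class separation in units of the noise standard deviation:
    a mean shift for feature fixtures, the blob-to-background contrast for
    image fixtures. informative_fraction is the share of feature columns
    that carry the shift (ignored for images).
    """

    n_per_class: int = 100
    d: int = 600
    image_size: tuple[int, int] = (64, 64)
    delta: float = 6.0
    noise_sd: float = 1.0
    informative_fraction: float = 0.1
    seed: int = 0
    class_names: tuple[str, str] = ("control", "AS")

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise FixtureError("n_per_class must be >= 1")
        if self.delta < 0:
            raise FixtureError("delta must be >= 0")
        if not 0 <= self.informative_fraction <= 1:
            raise FixtureError("informative_fraction must be in [0, 1]")


def gen_feature_dataset(spec: FixtureSpec) -> tuple[FeatureMatrix, np.ndarray]:
    """Two-class Gaussian feature matrix with a mean shift on informative columns.

    Informative columns (the first ``round(d * informative_fraction)``, then
    shuffled into random positions) differ between classes by
    ``delta * noise_sd``; all remaining columns are pure noise. Class codes
    are 1 (first class name) and 2 (second). Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_class
    n_info = int(round(spec.d * spec.informative_fraction))
    if spec.delta > 0 and n_info < 1:
        import warnings

        warnings.warn("delta > 0 but no informative columns carry the shift", stacklevel=2)
    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.d))
    y = np.repeat([1, 2], spec.n_per_class)
    info_cols = rng.permutation(spec.d)[:n_info]
    X[np.ix_(y == 2, info_cols)] += spec.delta * spec.noise_sd
    ids = [f"s{i:04d}" for i in range(n)]
    fm = FeatureMatrix(values=X, sample_ids=ids, labels=y, source="fixture/features")
    return fm, y


def _phantom(
    rng: np.random.Generator,
    size: tuple[int, int],
    noise_sd: float,
    blob_contrast: float,
    n_blobs: int,
) -> np.ndarray:
    """Grayscale phantom: dark background, bright symmetric joint line, optional blobs.

    The joint line is a vertical band through the image center shared by both
    classes; disease-like images add Gaussian blobs adjacent to the line with
    the requested contrast.
    """
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full((h, w), 60.0)
    # symmetric joint line: vertical bright band with soft edges
    center = w / 2 + rng.uniform(-1.5, 1.5)
    img += 80.0 * np.exp(-((xx - center) ** 2) / (2 * 2.5**2))
    for _ in range(n_blobs):
        side = rng.choice([-1.0, 1.0])
        bx = center + side * rng.uniform(4.0, 10.0)
        by = rng.uniform(0.2 * h, 0.8 * h)
        r = rng.uniform(2.0, 4.0)
        img += blob_contrast * np.exp(-(((xx - bx) ** 2 + (yy - by) ** 2) / (2 * r**2)))
    img += rng.normal(0.0, noise_sd, size=(h, w))
    return np.clip(img, 0.0, 255.0)


def gen_image_dataset(spec: FixtureSpec, out_dir: str | Path) -> DatasetManifest:
    """Write a two-class phantom PNG dataset under ``out_dir`` and return its manifest.

    Both classes share the joint-line background; the second class
    ("AS-like") adds 1-3 hyperintense blobs with contrast
    ``delta * noise_sd``. delta = 0 makes the classes statistically
    identical. PNGs are byte-deterministic per seed.
    """
    from PIL import Image

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise FixtureError(f"cannot create fixture directory {out_dir}: {exc}") from exc
    rng = np.random.default_rng(spec.seed)
    # image noise lives on the 0..255 intensity scale
    pixel_noise_sd = 8.0 * spec.noise_sd
    samples: list[Sample] = []
    for ci, cls in enumerate(spec.class_names):
        cdir = out_dir / cls
        cdir.mkdir(exist_ok=True)
        for i in range(spec.n_per_class):
            n_blobs = int(rng.integers(1, 4)) if ci == 1 else 0
            img = _phantom(
                rng,
                spec.image_size,
                pixel_noise_sd,
                blob_contrast=spec.delta * pixel_noise_sd,
                n_blobs=n_blobs,
            )
            path = cdir / f"{cls}_{i:04d}.png"
            Image.fromarray(np.round(img).astype(np.uint8), mode="L").save(path)
            samples.append(Sample(f"{cls}/{path.name}", path, cls))
    return DatasetManifest(samples=samples, class_names=list(spec.class_names))
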