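"""Dataset manifests, image loading, and feature-table persistence.

The pipeline is aligned to a :class:`DatasetManifest`: an ordered list of
(sample_id, path, label) records plus a fixed class-name order. Class names
are mapped to the integer codes ``1..C`` in ``class_names`` order, and that
order fixes the confusion-matrix axes everywhere downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".dcm", ".dicom"}


class DataError(ValueError):
    """Raised for malformed datasets, manifests, or feature tables."""


@dataclass(frozen=True)
class Sample:
    sample_id: str
    path: Path
    label: str
    group_id: Optional[str] = None


@dataclass
class DatasetManifest:
    """Ordered sample records with a fixed class-name order.

    ``class_names`` order is authoritative: it defines the integer label
    encoding (1-based) and the confusion-matrix axis order.
    """

    samples: list[Sample]
    class_names: list[str]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate sample_id(s): {dupes}")
        if len(self.class_names) < 2:
            raise DataError("degenerate class structure: need >= 2 classes")
        present = {s.label for s in self.samples}
        for c in self.class_names:
            if c not in present:
                raise DataError(f"degenerate class: '{c}' has 0 samples")
        unknown = present - set(self.class_names)
        if unknown:
            raise DataError(f"labels not in class_names: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def label_codes(self) -> np.ndarray:
        """Integer labels 1..C in class_names order."""
        code = {c: i + 1 for i, c in enumerate(self.class_names)}
        return np.array([code[s.label] for s in self.samples], dtype=np.int64)

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def group_ids(self) -> Optional[list[str]]:
        gids = [s.group_id for s in self.samples]
        return None if all(g is None for g in gids) else [g or s.sample_id for g, s in zip(gids, self.samples)]


@dataclass
class ImageTensor:
    """H x W x C nonnegative intensity array with declared channel count."""

    pixels: np.ndarray  # H x W x C float64
    channels: int
    value_range: str = "raw"

    def __post_init__(self) -> None:
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3:
            raise DataError(f"expected 2D or 3D pixel array, got ndim={self.pixels.ndim}")
        h, w, c = self.pixels.shape
        if h < 1 or w < 1:
            raise DataError("zero-area image")
        if c not in (1, 3):
            raise DataError(f"channel count must be 1 or 3, got {c}")
        if not np.isfinite(self.pixels).all():
            raise DataError("non-finite pixel values")
        self.channels = c


@dataclass
class FeatureMatrix:
    """n x d real feature matrix aligned row-for-row to a manifest."""

    values: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray  # integer class codes, 1-based
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DataError("feature matrix must be 2-D")
        if self.values.shape[0] != len(self.sample_ids):
            raise DataError("row count does not match sample_ids")
        if not np.isfinite(self.values).all():
            raise DataError(f"non-finite values in feature matrix '{self.source}'")
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def load_manifest(root: str | Path, layout: str = "class-subdirs") -> DatasetManifest:
    """Discover a two-class (or multi-class) image dataset.

    ``class-subdirs``: each immediate subdirectory of *root* is one class and
    every image file inside it one sample. ``manifest-file``: *root* is (or
    contains) ``manifest.csv`` with columns sample_id, path, label and an
    optional group_id; paths are resolved relative to the manifest location.

    Sample order is lexicographic by path so repeated loads are identical.
    """
    root = Path(root)
    if layout == "class-subdirs":
        if not root.is_dir():
            raise DataError(f"not a directory: {root}")
        classes = sorted(p.name for p in root.iterdir() if p.is_dir())
        if not classes:
            raise DataError(f"no samples: {root} has no class subdirectories")
        samples: list[Sample] = []
        for cls in classes:
            files = sorted(
                p for p in (root / cls).rglob("*")
                if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
            )
            if not files:
                raise DataError(f"degenerate class: '{cls}' has 0 images")
            for f in files:
                samples.append(Sample(sample_id=str(f.relative_to(root)), path=f, label=cls))
        return DatasetManifest(samples=samples, class_names=classes)

    if layout == "manifest-file":
        mpath = root if root.is_file() else root / "manifest.csv"
        if not mpath.is_file():
            raise DataError(f"manifest file not found: {mpath}")
        df = pd.read_csv(mpath, dtype=str)
        required = {"sample_id", "path", "label"}
        if not required.issubset(df.columns):
            raise DataError(f"manifest must have columns {sorted(required)}")
        if df.empty:
            raise DataError("no samples: manifest file is empty")
        base = mpath.parent
        samples = []
        for _, row in df.iterrows():
            p = Path(row["path"])
            if not p.is_absolute():
                p = base / p
            if not p.is_file():
                raise DataError(f"missing file: {p}")
            gid = row.get("group_id") if "group_id" in df.columns else None
            gid = None if gid is None or pd.isna(gid) else str(gid)
            samples.append(Sample(str(row["sample_id"]), p, str(row["label"]), gid))
        # declared order of first appearance fixes the class order
        seen: list[str] = []
        for s in samples:
            if s.label not in seen:
                seen.append(s.label)
        return DatasetManifest(samples=samples, class_names=seen)

    raise DataError(f"unknown layout '{layout}' (use 'class-subdirs' or 'manifest-file')")


def read_image(path: str | Path) -> ImageTensor:
    """Read a PNG/JPEG/BMP or single-frame DICOM file into an ImageTensor.

    DICOM pixel data is rescaled with RescaleSlope/RescaleIntercept when
    present; no windowing is applied. Grayscale files yield C=1; color files
    keep the decoder's RGB channel order.
    """
    path = Path(path)
    if not path.is_file():
        raise DataError(f"missing file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom") or _looks_like_dicom(path):
        return _read_dicom(path)
    try:
        from PIL import Image

        with Image.open(path) as im:
            if im.mode in ("1", "L", "I", "I;16", "F"):
                arr = np.asarray(im.convert("F"), dtype=np.float64)
            else:
                arr = np.asarray(im.convert("RGB"), dtype=np.float64)
    except DataError:
        raise
    except Exception as exc:  # noqa: BLE001 - decoder errors vary by format
        raise DataError(f"unreadable image file: {path} ({exc})") from exc
    return ImageTensor(pixels=arr, channels=1 if arr.ndim == 2 else 3)


def _looks_like_dicom(path: Path) -> bool:
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def _read_dicom(path: Path) -> ImageTensor:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
    except Exception as exc:  # noqa: BLE001
        raise DataError(f"unreadable DICOM file: {path} ({exc})") from exc
    if arr.ndim == 3 and arr.shape[-1] not in (3,):
        raise DataError(f"multi-frame DICOM not supported: {path}")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    out = arr.astype(np.float64) * slope + intercept
    return ImageTensor(pixels=out, channels=3 if out.ndim == 3 else 1)


def write_feature_table(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as CSV: sample_id,label,f0001,...

    Values use repr-precision floats so a round-trip is lossless to at least
    12 significant digits. A sidecar ``<path>.meta.json`` records provenance.
    """
    path = Path(path)
    width = max(4, len(str(matrix.d)))
    cols = [f"f{i + 1:0{width}d}" for i in range(matrix.d)]
    df = pd.DataFrame(matrix.values, columns=cols)
    df.insert(0, "label", matrix.labels)
    df.insert(0, "sample_id", matrix.sample_ids)
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {"source": matrix.source, "n": matrix.n, "d": matrix.d}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_feature_table(path: str | Path) -> FeatureMatrix:
    """Read a CSV feature table written by :func:`write_feature_table`.

    Any delimited table with a ``sample_id`` column, a ``label`` column and
    numeric feature columns is accepted.
    """
    path = Path(path)
    if not path.is_file():
        raise DataError(f"missing file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataError("no samples: feature table is empty") from exc
    if df.empty:
        raise DataError("no samples: feature table has no rows")
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise DataError(f"feature table missing '{col}' column")
    feat_cols = [c for c in df.columns if c not in ("sample_id", "label", "group_id")]
    if not feat_cols:
        raise DataError("feature table has no feature columns")
    values = np.empty((len(df), len(feat_cols)), dtype=np.float64)
    for j, c in enumerate(feat_cols):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = np.nonzero(col.isna().to_numpy() & df[c].notna().to_numpy())[0]
        if bad.size:
            raise DataError(f"non-numeric feature cell at (row {bad[0]}, col '{c}')")
        if col.isna().any():
            row = int(np.nonzero(col.isna().to_numpy())[0][0])
            raise DataError(f"missing feature cell at (row {row}, col '{c}')")
        values[:, j] = col.to_numpy(dtype=np.float64)
    labels = pd.to_numeric(df["label"], errors="coerce")
    if labels.isna().any():
        raise DataError("non-numeric label value")
    meta_path = Path(str(path) + ".meta.json")
    source = "file"
    if meta_path.is_file():
        try:
            source = json.loads(meta_path.read_text()).get("source", "file")
        except (json.JSONDecodeError, OSError):
            pass
    return FeatureMatrix(
        values=values,
        sample_ids=[str(s) for s in df["sample_id"]],
        labels=labels.to_numpy(dtype=np.int64),
        source=source,
    )


def save_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "path": str(s.path),
            "label": s.label,
            **({"group_id": s.group_id} if s.group_id else {}),
        }
        for s in manifest.samples
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
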