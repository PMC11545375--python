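"""Core data containers and plain-text I/O.

Grayscale angiogram patches travel as Netpbm PGM files (both the ASCII
``P2`` and binary ``P5`` dialects), feature tables as delimited text with a
header row.  All pixel coordinates in this package are 0-based, row-major,
origin at the top-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrayImage",
    "LabeledDataset",
    "PartitionSpec",
    "PGMParseError",
    "read_pgm",
    "write_pgm",
    "load_feature_table",
    "save_feature_table",
    "split_dataset",
]


class PGMParseError(ValueError):
    """Raised for malformed PGM input; carries the byte offset of the defect."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at byte offset {offset})")
        self.offset = offset


@dataclass
class GrayImage:
    """A grayscale raster with integer intensities in ``[0, maxval]``."""

    pixels: np.ndarray
    maxval: int = 255

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.maxval not in (255, 65535):
            raise ValueError("maxval must be 255 or 65535")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValueError("pixels must have an integer dtype")
        if self.pixels.min() < 0 or self.pixels.max() > self.maxval:
            raise ValueError("pixel values must lie in [0, maxval]")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    def as_float(self) -> np.ndarray:
        """Intensities rescaled to floats in [0, 1]."""
        return self.pixels.astype(np.float64) / float(self.maxval)

    def __eq__(self, other: object) -> bool:  # pragma: no cover - trivial
        if not isinstance(other, GrayImage):
            return NotImplemented
        return self.maxval == other.maxval and np.array_equal(self.pixels, other.pixels)


# --------------------------------------------------------------------------
# PGM I/O
# --------------------------------------------------------------------------

_WS = b" \t\r\n\x0b\x0c"


def _next_token(data: bytes, pos: int) -> tuple[bytes, int]:
    """Return the next whitespace-delimited token, skipping ``#`` comments."""
    n = len(data)
    while pos < n:
        c = data[pos : pos + 1]
        if c in (b"#",):
            while pos < n and data[pos : pos + 1] != b"\n":
                pos += 1
        elif c in _WS:
            pos += 1
        else:
            break
    if pos >= n:
        raise PGMParseError("unexpected end of file in header", pos)
    start = pos
    while pos < n and data[pos : pos + 1] not in _WS and data[pos : pos + 1] != b"#":
        pos += 1
    return data[start:pos], pos


def _int_token(data: bytes, pos: int, what: str) -> tuple[int, int]:
    tok, end = _next_token(data, pos)
    try:
        value = int(tok)
    except ValueError:
        raise PGMParseError(f"malformed header: non-integer {what} {tok!r}", pos) from None
    return value, end


def read_pgm(path: str | Path) -> GrayImage:
    """Read a PGM file (ASCII ``P2`` or binary ``P5``).

    Header comments (``#`` to end of line) are tolerated anywhere in the
    header.  ``maxval`` > 255 rasters are read as 2-byte big-endian samples,
    per the Netpbm standard.
    """
    data = Path(path).read_bytes()
    if len(data) < 2:
        raise PGMParseError("file too short for a PGM magic number", 0)
    magic = data[:2]
    if magic not in (b"P2", b"P5"):
        raise PGMParseError(f"unsupported magic number {magic!r}", 0)
    pos = 2
    width, pos = _int_token(data, pos, "width")
    height, pos = _int_token(data, pos, "height")
    maxval, pos = _int_token(data, pos, "maxval")
    if width < 1 or height < 1:
        raise PGMParseError("malformed header: non-positive dimensions", pos)
    if not 0 < maxval < 65536:
        raise PGMParseError(f"malformed header: maxval {maxval} out of range", pos)
    n_px = width * height

    if magic == b"P5":
        if pos >= len(data):
            raise PGMParseError("truncated raster: no data after header", pos)
        pos += 1  # exactly one whitespace byte separates header and raster
        bytes_per = 1 if maxval < 256 else 2
        need = n_px * bytes_per
        raster = data[pos : pos + need]
        if len(raster) < need:
            raise PGMParseError(
                f"truncated raster: expected {need} bytes, found {len(raster)}", pos
            )
        dtype = np.uint8 if bytes_per == 1 else np.dtype(">u2")
        pixels = np.frombuffer(raster, dtype=dtype, count=n_px).astype(np.int64)
    else:
        pixels = np.empty(n_px, dtype=np.int64)
        for i in range(n_px):
            try:
                value, pos = _int_token(data, pos, "sample")
            except PGMParseError as exc:
                raise PGMParseError(
                    f"truncated raster: expected {n_px} samples, found {i}", exc.offset
                ) from None
            pixels[i] = value

    if pixels.max(initial=0) > maxval:
        raise PGMParseError(f"sample value exceeds maxval {maxval}", pos)
    canonical = 255 if maxval < 256 else 65535
    return GrayImage(pixels.reshape(height, width), maxval=canonical)


def write_pgm(img: GrayImage, path: str | Path, binary: bool = True) -> None:
    """Write ``img`` as ``P5`` (binary, default) or ``P2`` (ASCII)."""
    path = Path(path)
    header = f"{'P5' if binary else 'P2'}\n{img.width} {img.height}\n{img.maxval}\n"
    if binary:
        dtype = np.uint8 if img.maxval < 256 else np.dtype(">u2")
        path.write_bytes(header.encode("ascii") + img.pixels.astype(dtype).tobytes())
    else:
        body = "\n".join(" ".join(str(v) for v in row) for row in img.pixels)
        path.write_text(header + body + "\n")


# --------------------------------------------------------------------------
# Feature tables
# --------------------------------------------------------------------------


@dataclass
class LabeledDataset:
    """A samples x features real matrix with binary stenosis labels.

    ``labels[i] == 1`` marks a positive stenosis case.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("labels length must match the number of samples")
        if not np.isfinite(self.features).all():
            raise ValueError("features contain missing or non-finite values")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must contain only 0 and 1")
        self.feature_names = [str(n) for n in self.feature_names]
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length must match the number of features")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")

    @property
    def n_samples(self) -> int:
        return int(self.features.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.features.shape[1])

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        frame = pd.DataFrame(self.features, columns=self.feature_names)
        frame[label_column] = self.labels
        return frame


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def load_feature_table(
    path: str | Path, label_column: str = "label", delimiter: str | None = None
) -> LabeledDataset:
    """Load a delimited feature table with a header row into a LabeledDataset."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    with open(path, "r") as fh:
        header = fh.readline().rstrip("\r\n").split(sep)
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise ValueError(f"duplicate feature name {name!r} in {path}")
        seen.add(name)
    if label_column not in header:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    frame = pd.read_csv(path, sep=sep)
    labels_raw = frame.pop(label_column)
    labels = pd.to_numeric(labels_raw, errors="raise").to_numpy()
    if not np.isin(labels, (0, 1)).all():
        raise ValueError(f"label column {label_column!r} is not binary")
    for col in frame.columns:
        if not np.issubdtype(frame[col].dtype, np.number):
            raise ValueError(f"non-numeric cell in feature column {col!r}")
    return LabeledDataset(
        features=frame.to_numpy(dtype=np.float64),
        labels=labels.astype(np.int64),
        feature_names=list(frame.columns),
    )


def save_feature_table(
    ds: LabeledDataset,
    path: str | Path,
    label_column: str = "label",
    delimiter: str | None = None,
) -> None:
    path = Path(path)
    ds.to_frame(label_column).to_csv(path, sep=_delimiter_for(path, delimiter), index=False)


# --------------------------------------------------------------------------
# Partitioning
# --------------------------------------------------------------------------


@dataclass
class PartitionSpec:
    """Disjoint train / validation / test index sets covering all samples."""

    train_idx: np.ndarray
    validation_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=np.int64)
        self.validation_idx = np.asarray(self.validation_idx, dtype=np.int64)
        self.test_idx = np.asarray(self.test_idx, dtype=np.int64)
        parts = [self.train_idx, self.validation_idx, self.test_idx]
        if any(p.size == 0 for p in parts):
            raise ValueError("every partition split must be non-empty")
        combined = np.concatenate(parts)
        if len(np.unique(combined)) != combined.size:
            raise ValueError("partition splits must be pairwise disjoint")

    def validate_covering(self, n_samples: int) -> None:
        combined = np.sort(
            np.concatenate([self.train_idx, self.validation_idx, self.test_idx])
        )
        if combined.size != n_samples or not np.array_equal(
            combined, np.arange(n_samples)
        ):
            raise ValueError("partition does not cover all samples exactly once")

    def split(self, name: str) -> np.ndarray:
        try:
            return {"train": self.train_idx, "validation": self.validation_idx, "test": self.test_idx}[name]
        except KeyError:
            raise ValueError(f"unknown split {name!r}") from None


def _stratified_allocation(
    class_sizes: Sequence[int], counts: Sequence[int], n: int
) -> np.ndarray:
    """Allocate per-split, per-class counts by largest-remainder rounding."""
    n_splits, n_classes = len(counts), len(class_sizes)
    ideal = np.array(
        [[counts[s] * class_sizes[c] / n for c in range(n_classes)] for s in range(n_splits)]
    )
    alloc = np.floor(ideal).astype(int)
    frac = ideal - alloc
    slack = np.array(counts) - alloc.sum(axis=1)
    leftover = np.array(class_sizes) - alloc.sum(axis=0)
    # hand leftover samples of each class to the splits with spare room,
    # largest fractional part first
    order = np.argsort(-frac, axis=0)
    for c in range(n_classes):
        for s in order[:, c]:
            while leftover[c] > 0 and slack[s] > 0:
                alloc[s, c] += 1
                leftover[c] -= 1
                slack[s] -= 1
                break
    # any residue (degenerate roundings) goes wherever room remains
    for c in range(n_classes):
        s = 0
        while leftover[c] > 0:
            if slack[s] > 0:
                alloc[s, c] += 1
                leftover[c] -= 1
                slack[s] -= 1
            else:
                s += 1
    return alloc


def split_dataset(
    ds: LabeledDataset,
    counts: tuple[int, int, int],
    seed: int,
    stratified: bool = True,
) -> PartitionSpec:
    """Randomly partition ``ds`` into train/validation/test of the given sizes.

    Stratified by default: within each split, class proportions match the
    dataset's within +-1 sample.  Deterministic for a fixed ``seed``.
    """
    if len(counts) != 3:
        raise ValueError("counts must be (train, validation, test)")
    if any(c <= 0 for c in counts):
        raise ValueError("every split must receive at least one sample")
    if sum(counts) != ds.n_samples:
        raise ValueError(
            f"counts sum to {sum(counts)} but the dataset has {ds.n_samples} samples"
        )
    rng = np.random.default_rng(seed)
    if not stratified:
        perm = rng.permutation(ds.n_samples)
        a, b = counts[0], counts[0] + counts[1]
        return PartitionSpec(perm[:a], perm[a:b], perm[b:])

    classes, class_sizes = np.unique(ds.labels, return_counts=True)
    alloc = _stratified_allocation(class_sizes, counts, ds.n_samples)
    if (alloc == 0).any():
        raise ValueError(
            "stratified split would leave a split with zero samples of one class"
        )
    splits: list[list[np.ndarray]] = [[], [], []]
    for c, cls in enumerate(classes):
        idx = np.flatnonzero(ds.labels == cls)
        idx = rng.permutation(idx)
        start = 0
        for s in range(3):
            splits[s].append(idx[start : start + alloc[s, c]])
            start += alloc[s, c]
    parts = [rng.permutation(np.concatenate(group)) for group in splits]
    return PartitionSpec(*parts)
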