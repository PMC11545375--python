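"""Angiographic feature bank: intensity, GLCM texture, and vessel morphology.

From each 64x64 grayscale patch the extractor computes:

* six intensity statistics of the raw image;
* the 14 Haralick texture statistics of a symmetric, normalized gray-level
  co-occurrence matrix averaged over four unit offsets;
* for each of eight vessel-enhancement methods (Frangi, Salem-style Hessian
  vesselness, single- and multi-scale Gabor, multi-scale linear matched,
  single- and multi-scale Gaussian matched, morphological top-hat): the
  intensity statistics of the response plus morphological descriptors of its
  Otsu segmentation (per-component compactness P^2/A, circularity 4*pi*A/P^2,
  elongatedness of the minimum rotated rectangle, skeleton-branch "vessel
  segment" statistics, and gray-level / gradient coefficients of variation
  over vessel pixels).

X-ray convention throughout: vessels are darker than the background, so
ridge filters either run with dark-ridge settings or on the inverted image.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy import signal
from shapely import MultiPoint
from skimage import measure, morphology
from skimage.feature import graycomatrix
from skimage.filters import frangi as _frangi, gabor_kernel, sato as _sato, threshold_otsu

from .data import GrayImage

__all__ = [
    "ENHANCEMENT_METHODS",
    "METHOD_LABELS",
    "FilterBankSpec",
    "FeatureVector",
    "VesselSegment",
    "intensity_features",
    "glcm_haralick",
    "enhance",
    "segment_vessels",
    "skeleton_segments",
    "morphology_features",
    "extract_feature_vector",
    "catalog_size",
]

ENHANCEMENT_METHODS = (
    "frangi",
    "salem",
    "gabor_single",
    "gabor_multi",
    "linear_matched_multi",
    "gaussian_matched_single",
    "gaussian_matched_multi",
    "tophat",
)

METHOD_LABELS = {
    "frangi": "Frangi",
    "salem": "Salem",
    "gabor_single": "Single-Scale Gabor",
    "gabor_multi": "Multi-Scale Gabor",
    "linear_matched_multi": "Multi-Scale Linear Matched",
    "gaussian_matched_single": "Single-Scale Gaussian Matched",
    "gaussian_matched_multi": "Multi-Scale Gaussian Matched",
    "tophat": "Top-Hat",
}


@dataclass(frozen=True)
class FilterBankSpec:
    """Parameters of the eight-method vessel enhancement bank.

    Orientation counts (K) span 180 degrees; thickness/length parameters are
    in pixels.  The top-hat ``size`` is the structuring-disk diameter.
    """

    # Frangi / Salem-style Hessian vesselness
    hessian_sigma_range: tuple[float, float] = (1.0, 12.0)
    hessian_sigma_step: float = 0.5
    hessian_alpha: float = 0.5
    hessian_beta: float = 15.0
    # Gabor filters: K orientations, vessel thickness T, kernel elongation L
    gabor_single_orientations: int = 45
    gabor_single_thickness: float = 5.0
    gabor_elongation: float = 2.5
    gabor_multi_scales: int = 3
    gabor_multi_thickness_range: tuple[float, float] = (2.0, 20.0)
    gabor_multi_orientations: int = 45
    # Multi-scale linear matched filter: line lengths L, K orientations
    linear_matched_length_range: tuple[int, int] = (1, 15)
    linear_matched_orientations: int = 12
    # Gaussian matched filters: profile length L, window T, width sigma
    gmf_single_length: float = 13.0
    gmf_single_window: int = 15
    gmf_single_sigma: float = 2.82
    gmf_orientations: int = 12
    gmf_multi_length: float = 13.0
    gmf_multi_window: int = 15
    gmf_multi_sigma_range: tuple[float, float] = (1.5, 2.5)
    gmf_multi_sigma_step: float = 0.5
    # Morphological top-hat
    tophat_shape: str = "disk"
    tophat_size: int = 19
    # GLCM texture
    glcm_levels: int = 8
    glcm_offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))

    def __post_init__(self) -> None:
        for lo, hi in (
            self.hessian_sigma_range,
            self.gabor_multi_thickness_range,
            self.linear_matched_length_range,
            self.gmf_multi_sigma_range,
        ):
            if lo > hi:
                raise ValueError("parameter ranges must be non-empty")
        if self.tophat_size < 1 or self.glcm_levels < 2:
            raise ValueError("sizes must be positive; glcm_levels >= 2")

    @property
    def hessian_sigmas(self) -> tuple[float, ...]:
        lo, hi = self.hessian_sigma_range
        n = int(round((hi - lo) / self.hessian_sigma_step)) + 1
        return tuple(lo + k * self.hessian_sigma_step for k in range(n))

    @property
    def gmf_multi_sigmas(self) -> tuple[float, ...]:
        lo, hi = self.gmf_multi_sigma_range
        n = int(round((hi - lo) / self.gmf_multi_sigma_step)) + 1
        return tuple(lo + k * self.gmf_multi_sigma_step for k in range(n))


class FeatureVector:
    """An ordered, uniquely named map of real-valued per-patch features."""

    def __init__(self, items: Iterable[tuple[str, float]] = ()):  # noqa: D401
        self._data: dict[str, float] = {}
        for name, value in items:
            self.append(name, value)

    def append(self, name: str, value: float) -> None:
        if name in self._data:
            raise ValueError(f"duplicate feature name {name!r}")
        value = float(value)
        if not math.isfinite(value):
            raise ValueError(f"feature {name!r} is not finite")
        self._data[name] = value

    def extend(self, other: "FeatureVector", suffix: str = "") -> None:
        for name, value in other.items():
            self.append(name + suffix, value)

    @property
    def names(self) -> list[str]:
        return list(self._data)

    @property
    def values(self) -> np.ndarray:
        return np.array(list(self._data.values()), dtype=np.float64)

    def items(self):
        return self._data.items()

    def __getitem__(self, name: str) -> float:
        return self._data[name]

    def __len__(self) -> int:
        return len(self._data)

    def __contains__(self, name: str) -> bool:
        return name in self._data


# ---------------------------------------------------------------------------
# Intensity statistics
# ---------------------------------------------------------------------------

_STAT_NAMES = ("Minimum", "Maximum", "Median", "Mean", "Variance", "Standard Deviation")


def _six_stats(values: np.ndarray) -> tuple[float, ...]:
    v = np.asarray(values, dtype=np.float64).ravel()
    return (
        float(v.min()),
        float(v.max()),
        float(np.median(v)),
        float(v.mean()),
        float(v.var()),
        float(v.std()),
    )


def intensity_features(img: GrayImage | np.ndarray, label: str = "Intensity") -> FeatureVector:
    """Min, max, median, mean, variance and std of the pixel intensities."""
    pixels = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    if pixels.size == 0:
        raise ValueError("image must be non-empty")
    stats = _six_stats(pixels)
    fv = FeatureVector()
    for stat_name, value in zip(_STAT_NAMES, stats):
        fv.append(f"{stat_name} {label}", value)
    return fv


# ---------------------------------------------------------------------------
# GLCM Haralick texture
# ---------------------------------------------------------------------------

HARALICK_NAMES = (
    "Angular Second Moment",
    "Contrast",
    "Correlation",
    "Sum of Squares Variance",
    "Inverse Difference Moment",
    "Sum Average",
    "Sum Variance",
    "Sum Entropy",
    "Entropy",
    "Difference Variance",
    "Difference Entropy",
    "Information Measure of Correlation 1",
    "Information Measure of Correlation 2",
    "Maximal Correlation Coefficient",
)


def _quantize(pixels: np.ndarray, levels: int) -> np.ndarray:
    p = np.asarray(pixels, dtype=np.float64)
    lo, hi = p.min(), p.max()
    if hi == lo:
        return np.zeros(p.shape, dtype=np.uint8)
    q = np.floor((p - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _haralick_from_glcm(P: np.ndarray) -> dict[str, float]:
    """The 14 Haralick statistics of one normalized symmetric GLCM."""
    L = P.shape[0]
    i = np.arange(L, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    # p_{x+y}(k), k = 0..2L-2 and p_{x-y}(k), k = 0..L-1
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (ii + jj).astype(int), P)
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(ii - jj).astype(int), P)
    k_sum = np.arange(2 * L - 1, dtype=np.float64)
    k_diff = np.arange(L, dtype=np.float64)

    asm = float((P**2).sum())
    contrast = float(((ii - jj) ** 2 * P).sum())
    degenerate = sd_x == 0.0 or sd_y == 0.0
    if degenerate:
        warnings.warn("degenerate GLCM (single gray level); correlation-type features set to 0")
        correlation = 0.0
    else:
        correlation = float(((ii * jj * P).sum() - mu_x * mu_y) / (sd_x * sd_y))
    variance = float(((ii - mu_x) ** 2 * P).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())
    sum_avg = float((k_sum * p_sum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    sum_ent = _entropy(p_sum)
    entropy = _entropy(P.ravel())
    diff_avg = float((k_diff * p_diff).sum())
    diff_var = float(((k_diff - diff_avg) ** 2 * p_diff).sum())
    diff_ent = _entropy(p_diff)

    hx = _entropy(px)
    hy = _entropy(py)
    pxy = np.outer(px, py)
    with np.errstate(divide="ignore"):
        log_pxy = np.where(pxy > 0, np.log(pxy), 0.0)
    hxy1 = float(-(P * log_pxy).sum())
    hxy2 = float(-(pxy[pxy > 0] * np.log(pxy[pxy > 0])).sum())
    denom = max(hx, hy)
    imc1 = 0.0 if denom == 0.0 else float((entropy - hxy1) / denom)
    imc2 = float(np.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy)))))

    # maximal correlation coefficient: sqrt of the 2nd largest eigenvalue of
    # Q_ij = sum_k P_ik P_jk / (px_i py_k)
    if degenerate:
        mcc = 0.0
    else:
        A = P / np.where(px[:, None] > 0, px[:, None], 1.0)
        B = P / np.where(py[None, :] > 0, py[None, :], 1.0)
        Q = A @ B.T
        eig = np.sort(np.abs(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, eig[-2].real))) if eig.size >= 2 else 0.0

    values = (
        asm, contrast, correlation, variance, idm, sum_avg, sum_var, sum_ent,
        entropy, diff_var, diff_ent, imc1, imc2, mcc,
    )
    return dict(zip(HARALICK_NAMES, values))


def glcm_haralick(
    img: GrayImage | np.ndarray,
    levels: int = 8,
    offsets: Sequence[tuple[int, int]] = ((0, 1), (1, 0), (1, 1), (1, -1)),
    label: str = "",
) -> FeatureVector:
    """The 14 Haralick statistics of the offset-averaged symmetric GLCM."""
    pixels = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    if levels < 2:
        raise ValueError("levels must be >= 2")
    q = _quantize(pixels, levels)
    distances = [float(np.hypot(dy, dx)) for dy, dx in offsets]
    angles = [float(np.arctan2(dy, dx)) for dy, dx in offsets]
    mats = []
    for d, a in zip(distances, angles):
        glcm = graycomatrix(
            q, distances=[d], angles=[a], levels=levels, symmetric=True, normed=True
        )
        mats.append(glcm[:, :, 0, 0])
    P = np.mean(mats, axis=0)
    P = P / P.sum()
    stats = _haralick_from_glcm(P)
    suffix = f" ({label})" if label else ""
    return FeatureVector((f"{k}{suffix}", v) for k, v in stats.items())


# ---------------------------------------------------------------------------
# Vessel enhancement bank
# ---------------------------------------------------------------------------


def _orientations(k: int) -> np.ndarray:
    return np.arange(k) * np.pi / k


@lru_cache(maxsize=64)
def _gabor_bank(k: int, thicknesses: tuple[float, ...], elongation: float):
    kernels = []
    for t in thicknesses:
        sigma_x = 0.5 * t
        sigma_y = elongation * sigma_x
        for theta in _orientations(k):
            kern = gabor_kernel(
                frequency=1.0 / t, theta=theta, sigma_x=sigma_x, sigma_y=sigma_y
            )
            kernels.append(np.real(kern))
    return kernels


def _oriented_kernel(
    length: float, window: int, orientation: float, profile_sigma: float | None
) -> np.ndarray:
    """Zero-mean matched-filter kernel in a window x window support.

    ``profile_sigma`` None gives a 1-px-wide line profile (linear matched
    filter); otherwise a Gaussian cross-section of that width.
    """
    half = window // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    u = x * math.cos(orientation) + y * math.sin(orientation)  # across the vessel
    v = -x * math.sin(orientation) + y * math.cos(orientation)  # along the vessel
    along = np.abs(v) <= length / 2.0
    if profile_sigma is None:
        profile = (np.abs(u) <= 0.5).astype(np.float64)
    else:
        profile = np.exp(-(u**2) / (2.0 * profile_sigma**2))
        profile[np.abs(u) > 3.0 * profile_sigma] = 0.0
    kern = profile * along
    return kern - kern.mean()


@lru_cache(maxsize=64)
def _matched_bank(
    lengths: tuple[float, ...],
    window: int,
    k: int,
    sigmas: tuple[float, ...] | None,
) -> tuple[np.ndarray, ...]:
    kernels = []
    for length in lengths:
        w = window if window > 0 else max(5, int(2 * math.ceil(length / 2) + 3))
        for sigma in sigmas or (None,):
            for theta in _orientations(k):
                kernels.append(_oriented_kernel(length, w, theta, sigma))
    return tuple(kernels)


def _max_response(image: np.ndarray, kernels) -> np.ndarray:
    out = np.full(image.shape, -np.inf)
    for kern in kernels:
        resp = signal.fftconvolve(image, kern[::-1, ::-1], mode="same")
        np.maximum(out, resp, out=out)
    return out


def enhance(img: GrayImage, method: str, spec: FilterBankSpec = FilterBankSpec()) -> np.ndarray:
    """Apply one vessel-enhancement method; returns a same-shape float response.

    Multi-scale / multi-orientation methods take the per-pixel maximum over
    the kernel bank.
    """
    f = img.as_float()
    inverted = 1.0 - f  # vessels bright
    if method == "frangi":
        return _frangi(
            f,
            sigmas=spec.hessian_sigmas,
            alpha=spec.hessian_alpha,
            beta=spec.hessian_beta,
            black_ridges=True,
        )
    if method == "salem":
        # Salem-compatible stand-in: Sato Hessian-eigenvalue vesselness over
        # the shared sigma range.
        return _sato(f, sigmas=spec.hessian_sigmas, black_ridges=True)
    if method == "gabor_single":
        bank = _gabor_bank(
            spec.gabor_single_orientations,
            (spec.gabor_single_thickness,),
            spec.gabor_elongation,
        )
        return _max_response(inverted, bank)
    if method == "gabor_multi":
        lo, hi = spec.gabor_multi_thickness_range
        thicknesses = tuple(np.linspace(lo, hi, spec.gabor_multi_scales))
        bank = _gabor_bank(
            spec.gabor_multi_orientations, thicknesses, spec.gabor_elongation
        )
        return _max_response(inverted, bank)
    if method == "linear_matched_multi":
        lo, hi = spec.linear_matched_length_range
        bank = _matched_bank(
            tuple(float(v) for v in range(int(lo), int(hi) + 1)),
            0,
            spec.linear_matched_orientations,
            None,
        )
        return _max_response(inverted, bank)
    if method == "gaussian_matched_single":
        bank = _matched_bank(
            (spec.gmf_single_length,),
            spec.gmf_single_window,
            spec.gmf_orientations,
            (spec.gmf_single_sigma,),
        )
        return _max_response(inverted, bank)
    if method == "gaussian_matched_multi":
        bank = _matched_bank(
            (spec.gmf_multi_length,),
            spec.gmf_multi_window,
            spec.gmf_orientations,
            spec.gmf_multi_sigmas,
        )
        return _max_response(inverted, bank)
    if method == "tophat":
        footprint = morphology.disk(spec.tophat_size // 2)
        return morphology.black_tophat(f, footprint)
    raise ValueError(f"unknown enhancement method {method!r}")


# ---------------------------------------------------------------------------
# Segmentation and morphology
# ---------------------------------------------------------------------------


def segment_vessels(response: np.ndarray) -> np.ndarray:
    """Otsu-threshold a filter response into a boolean vessel mask."""
    response = np.asarray(response, dtype=np.float64)
    if not np.isfinite(response).all():
        raise ValueError("response contains non-finite values")
    if response.max() == response.min():
        warnings.warn("constant filter response; returning an empty vessel mask")
        return np.zeros(response.shape, dtype=bool)
    thr = threshold_otsu(response)
    return response > thr


@dataclass
class VesselSegment:
    """One skeleton branch: its pixel path, length (pixel count), and the
    arterial section (mask connected component) it belongs to."""

    path: list[tuple[int, int]]
    section: int

    @property
    def length(self) -> int:
        return max(len(self.path), 1)


def _neighbors8(p: tuple[int, int], present: set) -> list[tuple[int, int]]:
    """8-neighbors in the skeleton, pruning diagonal links that are redundant
    with an orthogonal two-step path (avoids spurious junctions)."""
    r, c = p
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            q = (r + dr, c + dc)
            if q not in present:
                continue
            if dr != 0 and dc != 0 and ((r, c + dc) in present or (r + dr, c) in present):
                continue
            out.append(q)
    return out


def skeleton_segments(mask: np.ndarray) -> list[VesselSegment]:
    """Decompose the skeleton of ``mask`` into branches between branch/end
    points.  Branch length is its pixel count (endpoints included)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    skel = morphology.skeletonize(mask)
    sections = measure.label(mask, connectivity=2)
    present = set(map(tuple, np.argwhere(skel)))
    degree = {p: len(_neighbors8(p, present)) for p in present}
    nodes = {p for p, d in degree.items() if d != 2}
    visited_edges: set[frozenset] = set()
    covered: set = set()
    segments: list[VesselSegment] = []

    def walk(start, first):
        path = [start, first]
        visited_edges.add(frozenset((start, first)))
        while path[-1] not in nodes:
            nxt = [q for q in _neighbors8(path[-1], present) if q != path[-2]]
            step = None
            for q in nxt:
                if frozenset((path[-1], q)) not in visited_edges:
                    step = q
                    break
            if step is None:
                break
            visited_edges.add(frozenset((path[-1], step)))
            path.append(step)
        return path

    for node in sorted(nodes):
        if degree[node] == 0:
            segments.append(VesselSegment([node], int(sections[node])))
            covered.add(node)
            continue
        for nb in _neighbors8(node, present):
            if frozenset((node, nb)) in visited_edges:
                continue
            path = walk(node, nb)
            segments.append(VesselSegment(path, int(sections[path[0]])))
            covered.update(path)
    # pure cycles: degree-2 pixels never reached from a node
    remaining = sorted(present - covered - nodes)
    while remaining:
        start = remaining[0]
        nb = _neighbors8(start, present)[0]
        path = walk(start, nb)
        segments.append(VesselSegment(path, int(sections[start])))
        covered.update(path)
        remaining = [p for p in remaining if p not in covered]
    return segments


def _component_shape(coords: np.ndarray, perimeter: float, area: float) -> tuple[float, float, float]:
    """(compactness, circularity, elongatedness) of one component."""
    compactness = perimeter**2 / area
    circularity = 4.0 * math.pi * area / perimeter**2
    corners = np.concatenate(
        [coords + off for off in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))]
    )
    rect = MultiPoint(corners).minimum_rotated_rectangle
    xy = np.asarray(rect.exterior.coords)[:4] if rect.geom_type == "Polygon" else None
    if xy is None:
        elong = 1.0
    else:
        side_a = float(np.linalg.norm(xy[1] - xy[0]))
        side_b = float(np.linalg.norm(xy[2] - xy[1]))
        long_side, short_side = max(side_a, side_b), min(side_a, side_b)
        elong = long_side / short_side if short_side > 0 else 1.0
    return compactness, circularity, elong


_MIN_COMPONENT_AREA = 5  # px; smaller specks make the estimators degenerate


def morphology_features(
    mask: np.ndarray,
    response: np.ndarray,
    gradient: np.ndarray | None = None,
    label: str = "",
) -> FeatureVector:
    """Shape, skeleton-segment, and coefficient-of-variation descriptors.

    An empty mask yields 0.0 sentinel values and a logged warning.
    """
    mask = np.asarray(mask, dtype=bool)
    response = np.asarray(response, dtype=np.float64)
    suffix = f" ({label})" if label else ""
    fv = FeatureVector()

    labeled = measure.label(mask, connectivity=2)
    props = [p for p in measure.regionprops(labeled) if p.area >= _MIN_COMPONENT_AREA]
    clean = np.isin(labeled, [p.label for p in props])

    def add_stats(base: str, values: Sequence[float], std_name: str | None = None) -> None:
        arr = np.asarray(values, dtype=np.float64)
        if arr.size == 0:
            arr = np.zeros(1)
        fv.append(f"Minimum {base}{suffix}", arr.min())
        fv.append(f"Maximum {base}{suffix}", arr.max())
        fv.append(f"Median {base}{suffix}", np.median(arr))
        fv.append(f"Mean {base}{suffix}", arr.mean())
        fv.append(std_name or f"Standard Deviation of {base}{suffix}", arr.std())

    if not props:
        warnings.warn(f"empty vessel mask{suffix}; morphology features set to 0 sentinels")

    fv.append(f"Number Of Arterial Sections{suffix}", float(len(props)))
    shapes = [
        _component_shape(p.coords.astype(np.float64), p.perimeter, float(p.area))
        for p in props
        if p.perimeter > 0
    ]
    add_stats("Compactness", [s[0] for s in shapes])
    add_stats("Circularity Ratio", [s[1] for s in shapes])
    add_stats("Elongatedness", [s[2] for s in shapes])

    segments = skeleton_segments(clean)
    fv.append(f"Number Of Vessel Segments{suffix}", float(len(segments)))
    add_stats("Vessel Length", [s.length for s in segments])
    per_section: dict[int, list[int]] = {}
    for s in segments:
        per_section.setdefault(s.section, []).append(s.length)
    section_stds = [float(np.std(v)) for v in per_section.values()]
    add_stats(
        "Standard Deviation of Segments Length in all Arterial Sections",
        section_stds,
        std_name=(
            "Standard Deviation of the Standard Deviations of Segments Length "
            f"in all Arterial Sections{suffix}"
        ),
    )

    def coeff_var(values: np.ndarray) -> float:
        if values.size == 0 or values.mean() == 0.0:
            return 0.0
        return float(values.std() / abs(values.mean()))

    vessel_values = response[clean]
    fv.append(f"Gray Level Coefficient of Variation{suffix}", coeff_var(vessel_values))
    if gradient is None:
        gy, gx = np.gradient(response)
        gradient = np.hypot(gy, gx)
    fv.append(
        f"Gradient Coefficient of Variation{suffix}",
        coeff_var(np.asarray(gradient, dtype=np.float64)[clean]),
    )
    return fv


# ---------------------------------------------------------------------------
# Full catalog
# ---------------------------------------------------------------------------


def extract_feature_vector(
    img: GrayImage, spec: FilterBankSpec = FilterBankSpec()
) -> FeatureVector:
    """The full per-patch feature catalog.

    Raw-image intensity statistics, Haralick texture, then per enhancement
    method the response's intensity statistics and morphology descriptors.
    Naming and ordering are stable for a given spec.
    """
    fv = FeatureVector()
    fv.extend(intensity_features(img))
    fv.extend(glcm_haralick(img, levels=spec.glcm_levels, offsets=spec.glcm_offsets))
    for method in ENHANCEMENT_METHODS:
        response = enhance(img, method, spec)
        mlabel = METHOD_LABELS[method]
        fv.extend(intensity_features(response, label=f"Intensity ({mlabel})"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mask = segment_vessels(response)
            fv.extend(morphology_features(mask, response, label=mlabel))
    return fv


def catalog_size(spec: FilterBankSpec = FilterBankSpec()) -> int:
    """Number of features in the default catalog: 6 + 14 + 8 * (6 + 29)."""
    return 6 + 14 + len(ENHANCEMENT_METHODS) * (6 + 29)
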