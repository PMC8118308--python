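"""Needle-crystal morphometry of SHG images.

Pipeline: Otsu binarization -> watershed splitting of touching objects on
the negated Euclidean distance transform -> straight-needle decomposition of
labels that a single line cannot explain (crossing needles merge into one
watershed basin because the junction dominates the distance-transform
ridge) -> overlap rejection by oriented-bounding-rectangle intersection ->
per-object maximum-Feret length and orientation, count and per-area
density.

Length convention: an object's length is the maximum caliper (Feret)
diameter over the *boundary* of its pixel squares (pixel centers +-0.5), so
a single pixel has length ``pixel_size_um`` and a straight 1xN run has
length ~ N pixels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull
from shapely.geometry import Polygon
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import h_maxima
from skimage.segmentation import watershed
from skimage.transform import hough_line, hough_line_peaks

from .io import IntensityImage

__all__ = [
    "ObjectStatus",
    "NeedleObject",
    "SegmentationResult",
    "MorphometryConfig",
    "MorphometryResult",
    "otsu_threshold",
    "watershed_split",
    "reject_overlaps",
    "measure_length",
    "run_morphometry",
]

N_OTSU_BINS = 256


class ObjectStatus(str, Enum):
    PASSED = "PASSED"
    FAILED_OVERLAP = "FAILED_OVERLAP"
    FAILED_SIZE = "FAILED_SIZE"


@dataclass
class NeedleObject:
    """One segmented crystal candidate."""

    label: int
    pixels: np.ndarray  # (n, 2) int (row, col)
    pixel_count: int
    length_um: float
    orientation_deg: float
    centroid: tuple[float, float]
    status: ObjectStatus
    overlap_fraction: float = 0.0


@dataclass
class SegmentationResult:
    binary_mask: np.ndarray
    labeled_mask: np.ndarray
    threshold_value: float


@dataclass
class MorphometryConfig:
    """Tunables of the morphometry pipeline.

    overlap_fraction_max
        An object fails when the fraction of its oriented bounding
        rectangle covered by other objects' rectangles exceeds this.
    min_object_px
        Objects below this pixel count are FAILED_SIZE (noise specks).
    h_maxima
        Depth parameter of the distance-transform h-maxima used as
        watershed markers.
    smooth_sigma_px
        Gaussian pre-smoothing applied before thresholding (0 disables);
        suppresses noise-induced breaks in dim needle edges.
    split_crossings / needle_halfband_px / axis_residual_p90_max /
    rect_fill_single_min
        Straight-needle decomposition: a connected component whose
        total-least-squares axis leaves a 90th-percentile perpendicular
        residual above ``axis_residual_p90_max`` pixels, and whose oriented
        bounding rectangle is mostly empty (fill below
        ``rect_fill_single_min``), is re-split into straight needles by
        Hough-line extraction with an inlier band of half-width
        ``needle_halfband_px``.
    length_metric
        "feret" (max caliper diameter, default) or "skeleton" (geodesic
        length along the morphological skeleton).
    """

    overlap_fraction_max: float = 0.2
    min_object_px: int = 8
    h_maxima: float = 1.0
    smooth_sigma_px: float = 1.0
    split_crossings: bool = True
    needle_halfband_px: float = 2.0
    axis_residual_p90_max: float = 2.4
    rect_fill_single_min: float = 0.72
    length_metric: str = "feret"


@dataclass
class MorphometryResult:
    objects: list[NeedleObject]
    n_passed: int
    n_total: int
    density_per_mm2: float
    length_mean_um: float
    length_median_um: float
    length_sd_um: float
    analysis_area_mm2: float
    threshold_value: float

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_passed": self.n_passed,
            "n_failed_overlap": sum(
                1 for o in self.objects if o.status is ObjectStatus.FAILED_OVERLAP
            ),
            "n_failed_size": sum(1 for o in self.objects if o.status is ObjectStatus.FAILED_SIZE),
            "density_per_mm2": self.density_per_mm2,
            "length_mean_um": self.length_mean_um,
            "length_median_um": self.length_median_um,
            "length_sd_um": self.length_sd_um,
            "analysis_area_mm2": self.analysis_area_mm2,
            "threshold_value": self.threshold_value,
            "objects": [
                {
                    "label": o.label,
                    "pixel_count": o.pixel_count,
                    "length_um": o.length_um,
                    "orientation_deg": o.orientation_deg,
                    "centroid": list(o.centroid),
                    "status": o.status.value,
                    "overlap_fraction": o.overlap_fraction,
                }
                for o in self.objects
            ],
        }


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------

def otsu_threshold(image: IntensityImage | np.ndarray) -> tuple[float, np.ndarray]:
    """Otsu threshold on a 256-bin histogram spanning [min, max].

    Returns the bin-center threshold maximizing the between-class variance
    and the mask of pixels strictly above it.

    Raises
    ------
    ValueError
        "degenerate histogram" for a constant image.
    """
    arr = image.pixels if isinstance(image, IntensityImage) else np.asarray(image, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        raise ValueError("degenerate histogram: image has a single intensity value")
    counts, edges = np.histogram(arr, bins=N_OTSU_BINS, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    thr = float(threshold_otsu(hist=(counts, centers)))
    return thr, arr > thr


# ---------------------------------------------------------------------------
# Watershed splitting
# ---------------------------------------------------------------------------

def watershed_split(binary_mask: np.ndarray, h: float = 1.0) -> np.ndarray:
    """Partition a binary mask into labels by marker-based watershed.

    The landscape is the negated Euclidean distance transform; markers are
    the h-maxima of the distance transform, i.e. peaks of topographic
    prominence >= h: a neck between two blobs splits them while the ridge
    of a single straight needle stays one object. Because the rasterized
    ridge of a rotated needle carries sub-pixel dips, the raw h-maxima set
    fragments along it; the prominence rule is therefore enforced exactly by
    a post-pass that merges adjacent basins whose separating saddle on the
    distance transform rises to within h of the lower of the two basin
    peaks. Every foreground pixel receives exactly one label (1..n,
    contiguous).
    """
    mask = np.asarray(binary_mask, dtype=bool)
    if not mask.any():
        warnings.warn("watershed_split: empty mask, returning empty labeling")
        return np.zeros(mask.shape, dtype=np.int32)
    edt = ndi.distance_transform_edt(mask)
    peaks = h_maxima(edt, h, footprint=np.ones((3, 3), dtype=bool))
    markers = cc_label(peaks, connectivity=2)
    if markers.max() == 0:
        markers = cc_label(mask, connectivity=2)
    labels = watershed(-edt, markers=markers, mask=mask, connectivity=2)
    labels = _merge_shallow_basins(labels, edt, h)
    out, _, _ = _relabel(labels)
    return out


def _adjacent_saddles(labels: np.ndarray, edt: np.ndarray) -> dict[tuple[int, int], float]:
    """Max over boundary pixel pairs of min(edt_a, edt_b) for each pair of
    8-adjacent labels."""
    saddles: dict[tuple[int, int], float] = {}
    shifts = [(0, 1), (1, 0), (1, 1), (1, -1)]
    for dr, dc in shifts:
        a = labels[max(0, -dr) : labels.shape[0] - max(0, dr), max(0, -dc) : labels.shape[1] - max(0, dc)]
        b = labels[max(0, dr) :, max(0, dc) :] if dc >= 0 else labels[max(0, dr) :, : labels.shape[1] - 1]
        if dc == -1:
            a = labels[: labels.shape[0] - 1, 1:]
            b = labels[1:, : labels.shape[1] - 1]
        ea = edt[max(0, -dr) : edt.shape[0] - max(0, dr), max(0, -dc) : edt.shape[1] - max(0, dc)]
        eb = edt[max(0, dr) :, max(0, dc) :] if dc >= 0 else edt[max(0, dr) :, : edt.shape[1] - 1]
        if dc == -1:
            ea = edt[: edt.shape[0] - 1, 1:]
            eb = edt[1:, : edt.shape[1] - 1]
        touching = (a > 0) & (b > 0) & (a != b)
        if not touching.any():
            continue
        la, lb = a[touching], b[touching]
        val = np.minimum(ea[touching], eb[touching])
        lo = np.minimum(la, lb)
        hi = np.maximum(la, lb)
        for key_lo, key_hi, v in zip(lo, hi, val):
            key = (int(key_lo), int(key_hi))
            if v > saddles.get(key, -np.inf):
                saddles[key] = float(v)
    return saddles


def _merge_shallow_basins(labels: np.ndarray, edt: np.ndarray, h: float) -> np.ndarray:
    """Union adjacent watershed basins whose saddle prominence is < h."""
    n = int(labels.max())
    if n <= 1:
        return labels
    peak = ndi.maximum(edt, labels=labels, index=np.arange(1, n + 1))
    peak = np.concatenate([[0.0], np.atleast_1d(peak)])
    parent = list(range(n + 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    saddles = _adjacent_saddles(labels, edt)
    # process highest saddles first (dendrogram order)
    for (i, j), s in sorted(saddles.items(), key=lambda kv: -kv[1]):
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        if min(peak[ri], peak[rj]) - s < h:
            parent[rj] = ri
            peak[ri] = max(peak[ri], peak[rj])
    roots = np.array([find(i) for i in range(n + 1)])
    return roots[labels]


def _relabel(labels: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    vals = np.unique(labels)
    vals = vals[vals > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(vals, start=1):
        out[labels == old] = new
    return out, len(vals), vals


# ---------------------------------------------------------------------------
# Straight-needle decomposition of merged crossings
# ---------------------------------------------------------------------------

_HOUGH_THETA = np.linspace(-np.pi / 2, np.pi / 2, 360, endpoint=False)


def _line_band(coords: np.ndarray, theta: float, rho: float, halfband: float) -> np.ndarray:
    dist = np.abs(coords[:, 1] * math.cos(theta) + coords[:, 0] * math.sin(theta) - rho)
    return dist <= halfband


def decompose_needles(
    pixels: np.ndarray,
    shape: tuple[int, int],
    config: MorphometryConfig,
) -> list[np.ndarray] | None:
    """Split one label's pixel set into straight needles by iterative
    Hough-line extraction.

    Returns None when the label is already explained by a single line (or
    decomposition fails to find >= 2 needles), i.e. the caller should keep
    the label intact. Extracted needles partition the pixel set: leftover
    fragments below ``min_object_px`` are attached to the nearest needle.
    """
    coords = np.asarray(pixels)

    # Single straight needle: the total-least-squares axis explains the
    # pixels (90th-percentile perpendicular residual within a needle's
    # half-width plus anti-aliasing), or the object fills its oriented
    # bounding rectangle like a bar. Either way there is nothing to split.
    center = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - center, full_matrices=False)
    axis_normal = np.array([-vt[0][1], vt[0][0]])
    resid_p90 = float(np.percentile(np.abs((coords - center) @ axis_normal), 90))
    rect = _oriented_rect(coords)
    fill = len(coords) / rect.area if rect.area > 0 else 1.0
    if resid_p90 <= config.axis_residual_p90_max or fill >= config.rect_fill_single_min:
        return None

    patch = _rasterize(coords, shape)

    # Candidate lines: strong, mutually distinct Hough peaks. Vote counts
    # are quantization-noisy for thin needles, so candidates are re-ranked
    # by how many pixels their inlier band actually explains.
    hspace, thetas, rhos = hough_line(patch, theta=_HOUGH_THETA)
    accum_max = hspace.max()
    _, peak_thetas, peak_rhos = hough_line_peaks(
        hspace,
        thetas,
        rhos,
        num_peaks=12,
        min_distance=10,
        min_angle=8,  # bins of 0.5 deg -> 4 deg angular separation
        threshold=max(config.min_object_px, 0.3 * accum_max),
    )
    if len(peak_thetas) == 0:
        return None
    cands = []
    for th, rh in zip(peak_thetas, peak_rhos):
        band = _line_band(coords, float(th), float(rh), config.needle_halfband_px)
        cands.append((int(band.sum()), float(th), float(rh), band))
    cands.sort(key=lambda c: -c[0])

    # Greedy set cover over the coverage-ordered candidates: a line is a new
    # needle only if its band explains enough pixels no accepted line
    # already claims — this drops tilted near-duplicate chords.
    min_new = max(config.min_object_px, 0.15 * len(coords))
    claimed = np.zeros(len(coords), dtype=bool)
    lines: list[tuple[float, float]] = []
    for _, th, rh, band in cands:
        if (band & ~claimed).sum() >= min_new:
            lines.append((th, rh))
            claimed |= band
    if len(lines) < 2:
        return None

    dists = np.stack(
        [
            np.abs(coords[:, 1] * math.cos(th) + coords[:, 0] * math.sin(th) - rh)
            for th, rh in lines
        ],
        axis=1,
    )
    assignment = np.argmin(dists, axis=1)
    # k-lines refinement: Hough lines are quantized to 0.5 deg / 1 px, so
    # re-fit each part's axis by total least squares and reassign pixels to
    # the nearest fitted axis; two rounds are enough to converge here
    for _ in range(2):
        fitted = []
        for k in range(len(lines)):
            sel = coords[assignment == k]
            if len(sel) < 2:
                continue
            center = sel.mean(axis=0)
            _, _, vt = np.linalg.svd(sel - center, full_matrices=False)
            fitted.append((center, vt[0]))
        if len(fitted) < 2:
            break
        dists = np.stack(
            [
                np.abs((coords - ctr) @ np.array([-ax[1], ax[0]]))
                for ctr, ax in fitted
            ],
            axis=1,
        )
        assignment = np.argmin(dists, axis=1)
    parts = [coords[assignment == k] for k in range(int(assignment.max()) + 1)]
    parts = [p for p in parts if len(p) >= config.min_object_px]
    if len(parts) < 2:
        return None
    return parts


def _rasterize(coords: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[coords[:, 0], coords[:, 1]] = True
    return m


# ---------------------------------------------------------------------------
# Length and orientation
# ---------------------------------------------------------------------------

def _boundary_points(pixels: np.ndarray) -> np.ndarray:
    """Corner points of the pixel squares (centers +-0.5)."""
    offs = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    pts = (pixels[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    return np.unique(pts, axis=0)


def measure_length(
    object_pixels: np.ndarray,
    pixel_size_um: float,
    metric: str = "feret",
    hull: np.ndarray | None = None,
) -> tuple[float, float]:
    """Length and orientation of one object.

    Feret metric: maximum pairwise distance between pixel-boundary corner
    points (exact, via the convex hull), times the pixel size. Orientation
    is the angle of the maximizing chord in degrees, measured from the
    +column axis and folded to [0, 180). A single pixel has length equal to
    one pixel's extent and orientation 0 by convention.

    Skeleton metric: geodesic length along the morphological skeleton
    (longest shortest-path between skeleton pixels, 8-connected steps).
    """
    pixels = np.asarray(object_pixels)
    if pixels.ndim != 2 or len(pixels) == 0:
        raise ValueError("object_pixels must be a non-empty (n, 2) array")
    if metric == "skeleton":
        return _skeleton_length(pixels, pixel_size_um)
    if len(pixels) == 1:
        return float(pixel_size_um), 0.0
    pts = _corner_hull(pixels) if hull is None else hull
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = (diff**2).sum(axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    length_px = math.sqrt(d2[i, j])
    vec = pts[j] - pts[i]  # (drow, dcol)
    ang = math.degrees(math.atan2(vec[0], vec[1])) % 180.0
    # corner-to-corner Feret counts both half-pixel borders but also the
    # width's contribution to the diagonal; report the chord length as is
    return length_px * pixel_size_um, ang


def _skeleton_length(pixels: np.ndarray, pixel_size_um: float) -> tuple[float, float]:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import shortest_path
    from skimage.morphology import skeletonize

    rmin, cmin = pixels.min(axis=0)
    local = pixels - [rmin, cmin]
    m = np.zeros(tuple(local.max(axis=0) + 1), dtype=bool)
    m[local[:, 0], local[:, 1]] = True
    skel = skeletonize(m)
    pts = np.argwhere(skel)
    if len(pts) == 0:
        pts = local
    if len(pts) == 1:
        return float(pixel_size_um), 0.0
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    adj = np.where(d <= math.sqrt(2) + 1e-9, d, 0.0)
    graph = coo_matrix(adj)
    dist = shortest_path(graph, directed=False)
    dist[~np.isfinite(dist)] = 0.0
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    vec = pts[j] - pts[i]
    ang = math.degrees(math.atan2(vec[0], vec[1])) % 180.0
    # add one pixel for the two half-pixel end caps
    return (dist[i, j] + 1.0) * pixel_size_um, ang


# ---------------------------------------------------------------------------
# Overlap rejection
# ---------------------------------------------------------------------------

def _corner_hull(pixels: np.ndarray) -> np.ndarray:
    """Convex hull vertices of the pixel-square corners.

    The hull of the corner cloud equals the hull of the corners of the
    center-hull pixels, so the expensive hull runs on few points.
    """
    pixels = np.asarray(pixels, dtype=float)
    if len(pixels) > 4:
        try:
            hull = ConvexHull(pixels)
            pixels = pixels[hull.vertices]
        except Exception:  # collinear center sets
            pass
    pts = _boundary_points(pixels)
    if len(pts) > 4:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:
            pass
    return pts


def _oriented_rect(pixels: np.ndarray, hull: np.ndarray | None = None) -> Polygon:
    """Minimum-area oriented bounding rectangle of the pixel squares
    (rotating calipers over the corner hull)."""
    pts = _corner_hull(pixels) if hull is None else hull
    edges = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    keep = lengths > 1e-12
    if not keep.any():
        return Polygon()  # single point, degenerate
    dirs = edges[keep] / lengths[keep, None]
    normals = np.stack([-dirs[:, 1], dirs[:, 0]], axis=1)
    proj_u = pts @ dirs.T  # (n_pts, n_edges)
    proj_v = pts @ normals.T
    du = proj_u.max(axis=0) - proj_u.min(axis=0)
    dv = proj_v.max(axis=0) - proj_v.min(axis=0)
    areas = du * dv
    k = int(np.argmin(areas))
    d, nvec = dirs[k], normals[k]
    u0, u1 = proj_u[:, k].min(), proj_u[:, k].max()
    v0, v1 = proj_v[:, k].min(), proj_v[:, k].max()
    corners = [
        u0 * d + v0 * nvec,
        u1 * d + v0 * nvec,
        u1 * d + v1 * nvec,
        u0 * d + v1 * nvec,
    ]
    return Polygon([tuple(c) for c in corners])


def reject_overlaps(
    labeled_mask_or_objects: np.ndarray | list[np.ndarray],
    overlap_fraction_max: float = 0.2,
    min_object_px: int = 8,
    pixel_size_um: float = 1.0,
    length_metric: str = "feret",
) -> list[NeedleObject]:
    """Classify objects as PASSED / FAILED_OVERLAP / FAILED_SIZE.

    For each object the minimum-area oriented bounding rectangle of its
    pixels is intersected with every other object's rectangle; the overlap
    fraction is (area of its rectangle covered by the union of the others')
    / (its rectangle area). Objects whose fraction exceeds
    ``overlap_fraction_max`` fail as overlapping; objects smaller than
    ``min_object_px`` fail on size (and do not count toward anyone's
    overlap).
    """
    if isinstance(labeled_mask_or_objects, np.ndarray):
        labels = labeled_mask_or_objects
        pixel_sets = [
            np.argwhere(labels == lab) for lab in range(1, int(labels.max()) + 1)
        ]
        pixel_sets = [p for p in pixel_sets if len(p)]
    else:
        pixel_sets = [np.asarray(p) for p in labeled_mask_or_objects]

    hulls = [_corner_hull(p) if len(p) else None for p in pixel_sets]
    rects = [
        _oriented_rect(p, hull=h) if len(p) else None for p, h in zip(pixel_sets, hulls)
    ]
    sizes = [len(p) for p in pixel_sets]
    big = [i for i, s in enumerate(sizes) if s >= min_object_px]

    objects: list[NeedleObject] = []
    for i, pix in enumerate(pixel_sets):
        length_um, orient = measure_length(
            pix, pixel_size_um, metric=length_metric, hull=hulls[i]
        )
        centroid = tuple(pix.mean(axis=0))
        if sizes[i] < min_object_px:
            status, frac = ObjectStatus.FAILED_SIZE, 0.0
        else:
            mine = rects[i]
            inter = None
            for j in big:
                if j == i:
                    continue
                other = rects[j]
                if not mine.intersects(other):
                    continue
                piece = mine.intersection(other)
                inter = piece if inter is None else inter.union(piece)
            frac = (inter.area / mine.area) if inter is not None and mine.area > 0 else 0.0
            status = (
                ObjectStatus.FAILED_OVERLAP if frac > overlap_fraction_max else ObjectStatus.PASSED
            )
        objects.append(
            NeedleObject(
                label=i + 1,
                pixels=pix,
                pixel_count=sizes[i],
                length_um=length_um,
                orientation_deg=orient,
                centroid=(float(centroid[0]), float(centroid[1])),
                status=status,
                overlap_fraction=float(frac),
            )
        )
    return objects


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_morphometry(
    image: IntensityImage,
    config: MorphometryConfig | None = None,
    plaque_mask: np.ndarray | None = None,
) -> MorphometryResult:
    """Binarize, split, reject overlaps and measure an SHG needle field.

    Density is n_passed over the analysis area: the full frame by default,
    or the plaque mask area when one is supplied.
    """
    config = config or MorphometryConfig()
    pixels = image.pixels
    if config.smooth_sigma_px > 0:
        # light denoising before thresholding; the half-maximum contour of a
        # needle is preserved under symmetric smoothing
        pixels = ndi.gaussian_filter(pixels, config.smooth_sigma_px)
    try:
        thr, mask = otsu_threshold(pixels)
    except ValueError:
        # constant frame (background only): nothing to segment
        area = (
            float(np.asarray(plaque_mask, dtype=bool).sum()) * (image.pixel_size_um * 1e-3) ** 2
            if plaque_mask is not None
            else image.area_mm2()
        )
        return MorphometryResult(
            objects=[], n_passed=0, n_total=0, density_per_mm2=0.0,
            length_mean_um=0.0, length_median_um=0.0, length_sd_um=0.0,
            analysis_area_mm2=area, threshold_value=float("nan"),
        )
    if plaque_mask is not None:
        mask = mask & np.asarray(plaque_mask, dtype=bool)
    labels = watershed_split(mask, h=config.h_maxima)

    # Object formation: crossing needles merge into one connected component
    # whose junction watershed cuts transversally, so multi-line components
    # are decomposed into straight needles as whole components; everything
    # else keeps its watershed labels.
    pixel_sets: list[np.ndarray] = []
    components = cc_label(mask, connectivity=2)
    for comp in range(1, int(components.max()) + 1):
        comp_mask = components == comp
        pix = np.argwhere(comp_mask)
        if config.split_crossings and len(pix) >= 2 * config.min_object_px:
            parts = decompose_needles(pix, mask.shape, config)
            if parts is not None:
                pixel_sets.extend(parts)
                continue
        comp_labels = np.unique(labels[comp_mask])
        comp_labels = comp_labels[comp_labels > 0]
        for lab in comp_labels:
            pixel_sets.append(np.argwhere((labels == lab) & comp_mask))

    objects = reject_overlaps(
        pixel_sets,
        overlap_fraction_max=config.overlap_fraction_max,
        min_object_px=config.min_object_px,
        pixel_size_um=image.pixel_size_um,
        length_metric=config.length_metric,
    )

    if plaque_mask is not None:
        area_mm2 = float(np.asarray(plaque_mask, dtype=bool).sum()) * (
            image.pixel_size_um * 1e-3
        ) ** 2
    else:
        area_mm2 = image.area_mm2()
    passed = [o for o in objects if o.status is ObjectStatus.PASSED]
    lengths = np.array([o.length_um for o in passed])
    return MorphometryResult(
        objects=objects,
        n_passed=len(passed),
        n_total=len(objects),
        density_per_mm2=len(passed) / area_mm2,
        length_mean_um=float(lengths.mean()) if len(lengths) else 0.0,
        length_median_um=float(np.median(lengths)) if len(lengths) else 0.0,
        length_sd_um=float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0,
        analysis_area_mm2=area_mm2,
        threshold_value=thr,
    )
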