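"""Candidate nucleus boundary extraction.

Four-step flow: Sobel gradient magnitude -> hysteresis edge filter with
thinning -> size and closed-contour filtering -> bifurcation removal and
restriction to the cell-cluster support.  Nucleus walls separate dark
nuclei from brighter cytoplasm and therefore sit on ridges of the
gradient magnitude; the edge filter extracts those ridge centrelines as
1-px-wide closed curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import apply_hysteresis_threshold
from skimage.morphology import skeletonize

from papnuclei.preprocessing import ClusterMask

__all__ = [
    "NucleusRegion",
    "gradient_magnitude",
    "edge_filter",
    "hysteresis_select",
    "size_filter",
    "closed_contour_filter",
    "remove_bifurcations",
    "contours_to_regions",
    "regions_to_label_mask",
]

log = logging.getLogger(__name__)

_S8 = np.ones((3, 3), bool)          # 8-connectivity structure
_K8 = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], np.uint8)  # neighbour kernel


@dataclass
class NucleusRegion:
    """One candidate nucleus: a closed boundary and its filled support.

    ``boundary_pixels`` is an (K, 2) array of (row, col) boundary
    coordinates; ``filled_mask`` is a full-frame boolean raster of the
    enclosed area; ``bounding_box`` is (row0, col0, row1, col1),
    half-open.
    """

    label: int
    boundary_pixels: np.ndarray
    filled_mask: np.ndarray
    bounding_box: tuple[int, int, int, int]

    @property
    def area(self) -> int:
        return int(self.filled_mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        rows, cols = np.nonzero(self.filled_mask)
        return float(rows.mean()), float(cols.mean())


def gradient_magnitude(gray: np.ndarray) -> np.ndarray:
    """Euclidean combination of Sobel x/y responses, border replicated."""
    gray = np.asarray(gray, np.float64)
    if gray.ndim != 2:
        raise ValueError("expected a 2-D grayscale array")
    gx = ndi.sobel(gray, axis=1, mode="nearest")
    gy = ndi.sobel(gray, axis=0, mode="nearest")
    return np.hypot(gx, gy)


def hysteresis_select(norm: np.ndarray, low: float, high: float) -> np.ndarray:
    """Hysteresis thresholding of a [0, 1]-normalised magnitude raster.

    Keeps pixels >= low that are 8-connected to a pixel >= high; monotone
    non-increasing in both thresholds.
    """
    return apply_hysteresis_threshold(norm, low, high)


def edge_filter(
    gradient: np.ndarray,
    high_threshold: float = 0.4,
    low_ratio: float = 0.4,
    smooth_sigma: float = 0.0,
) -> np.ndarray:
    """Extract 1-px-wide boundary curves from a gradient-magnitude raster.

    The raster is normalised to [0, 1] by its maximum, selected by
    hysteresis (low threshold = ``low_ratio * high_threshold``) and
    thinned to the ridge centreline.  Nucleus walls, being the strongest
    gradient ridges, survive as closed curves; weak cytoplasm/background
    transitions fall below the low threshold.

    ``smooth_sigma`` optionally Gaussian-smooths the magnitude first; the
    default is no smoothing, because smoothing blends the wall ridge with
    the interior intensity ramp and drags the extracted contour inward.
    """
    if not (0.0 < high_threshold < 1.0):
        raise ValueError("high_threshold must lie in (0, 1)")
    if not (0.0 < low_ratio <= 1.0):
        raise ValueError("low_ratio must lie in (0, 1]")
    mag = np.asarray(gradient, np.float64)
    if smooth_sigma > 0:
        mag = ndi.gaussian_filter(mag, smooth_sigma)
    peak = mag.max()
    if peak <= 0:
        return np.zeros(mag.shape, bool)
    norm = mag / peak
    selected = hysteresis_select(norm, low_ratio * high_threshold,
                                 high_threshold)
    return skeletonize(selected)


def size_filter(edges: np.ndarray, min_pixels: int,
                max_pixels: int) -> np.ndarray:
    """Drop 8-connected edge components outside [min_pixels, max_pixels]."""
    if min_pixels > max_pixels:
        raise ValueError("min_pixels must be <= max_pixels")
    edges = np.asarray(edges, bool)
    lab, n = ndi.label(edges, structure=_S8)
    if n == 0:
        return edges.copy()
    counts = np.bincount(lab.ravel())
    keep = (counts >= min_pixels) & (counts <= max_pixels)
    keep[0] = False
    return keep[lab]


def _component_views(edges: np.ndarray):
    """Yield (slice, padded component) for each 8-connected component."""
    lab, n = ndi.label(edges, structure=_S8)
    slices = ndi.find_objects(lab)
    for i in range(1, n + 1):
        sl = slices[i - 1]
        comp = np.pad(lab[sl] == i, 1)
        yield sl, comp


def _encloses_interior(comp: np.ndarray) -> bool:
    return bool(ndi.binary_fill_holes(comp).sum() > comp.sum())


def closed_contour_filter(edges: np.ndarray) -> np.ndarray:
    """Keep only edge components that enclose at least one interior pixel."""
    edges = np.asarray(edges, bool)
    out = np.zeros_like(edges)
    for sl, comp in _component_views(edges):
        if _encloses_interior(comp):
            out[sl] |= comp[1:-1, 1:-1]
    return out


def _neighbor_count(comp: np.ndarray) -> np.ndarray:
    return ndi.convolve(comp.astype(np.uint8), _K8, mode="constant")


def _prune_spurs(comp: np.ndarray) -> np.ndarray:
    while True:
        nb = _neighbor_count(comp)
        spurs = comp & (nb <= 1)
        if not spurs.any():
            return comp
        comp = comp & ~spurs


def _one_component(comp: np.ndarray) -> bool:
    return comp.any() and ndi.label(comp, structure=_S8)[1] == 1


def _prune_junctions(comp: np.ndarray) -> np.ndarray:
    """Delete junction whiskers: pixels whose removal (followed by spur
    pruning) leaves the contour one component that still encloses every
    previously enclosed interior pixel.  Preserving the interior (not
    merely *some* closure) stops the curve from re-routing through chord
    shortcuts and collapsing."""
    while True:
        fill = ndi.binary_fill_holes(comp)
        interior = fill & ~comp
        # wall pixels touch both the exterior and the enclosed interior;
        # whisker stubs and chord shortcuts touch at most one side and are
        # the pixels this pass is meant to delete
        wall = comp & ndi.binary_dilation(~fill, _S8) \
            & ndi.binary_dilation(interior, _S8)
        nb = _neighbor_count(comp)
        candidates = np.argwhere(comp & (nb > 2))
        candidates = sorted(map(tuple, candidates),
                            key=lambda rc: (bool(wall[rc]), rc))
        removed = False
        for r, c in candidates:
            trial = comp.copy()
            trial[r, c] = False
            trial = _prune_spurs(trial)
            if not _one_component(trial):
                continue
            trial_interior = ndi.binary_fill_holes(trial) & ~trial
            if (interior & ~trial_interior).any():
                continue
            comp = trial
            removed = True
            break
        if not removed:
            return comp


def remove_bifurcations(edges: np.ndarray, min_component: int = 8) -> np.ndarray:
    """Reduce each closed contour to a simple curve.

    Spur pixels (one 8-neighbour) are pruned to fixpoint, then junction
    whiskers — pixels whose removal keeps the contour closed and
    8-connected — are deleted.  Components degenerating below
    ``min_component`` pixels are dropped with a log entry.
    """
    edges = np.asarray(edges, bool)
    out = np.zeros_like(edges)
    for sl, comp in _component_views(edges):
        comp = _prune_spurs(comp)
        comp = _prune_junctions(comp)
        if comp.sum() < min_component or not _encloses_interior(comp):
            log.info("dropping degenerate contour (%d px) at %s",
                     int(comp.sum()), sl)
            continue
        out[sl] |= comp[1:-1, 1:-1]
    return out


def contours_to_regions(
    edges: np.ndarray,
    cluster_mask: ClusterMask | np.ndarray,
    min_nucleus_area: int = 50,
) -> list[NucleusRegion]:
    """Fill simple closed contours into candidate nucleus regions.

    Regions whose centroid falls outside the cell-cluster support and
    regions smaller than ``min_nucleus_area`` are discarded.  Labels are
    assigned in raster-scan order of the region centroids, and region
    masks are kept pairwise disjoint (earlier regions claim contested
    pixels).
    """
    edges = np.asarray(edges, bool)
    support = cluster_mask.pixels if isinstance(cluster_mask, ClusterMask) \
        else np.asarray(cluster_mask, bool)
    if support.shape != edges.shape:
        raise ValueError("cluster mask shape must match edge map shape")

    candidates = []
    for sl, comp in _component_views(edges):
        inner = comp[1:-1, 1:-1]
        filled = ndi.binary_fill_holes(inner)
        rows, cols = np.nonzero(filled)
        if rows.size == 0:
            continue
        cy, cx = rows.mean() + sl[0].start, cols.mean() + sl[1].start
        ir = min(max(int(round(cy)), 0), support.shape[0] - 1)
        ic = min(max(int(round(cx)), 0), support.shape[1] - 1)
        if not support[ir, ic]:
            continue
        candidates.append((cy, cx, sl, inner, filled))

    candidates.sort(key=lambda t: (t[0], t[1]))
    regions: list[NucleusRegion] = []
    claimed = np.zeros_like(edges)
    for cy, cx, sl, inner, filled in candidates:
        full = np.zeros_like(edges)
        full[sl] = filled
        full &= ~claimed
        if full.sum() < min_nucleus_area:
            continue
        claimed |= full
        boundary_local = np.argwhere(inner)
        boundary = boundary_local + [sl[0].start, sl[1].start]
        rows, cols = np.nonzero(full)
        bbox = (int(rows.min()), int(cols.min()),
                int(rows.max()) + 1, int(cols.max()) + 1)
        regions.append(NucleusRegion(
            label=len(regions) + 1,
            boundary_pixels=boundary,
            filled_mask=full,
            bounding_box=bbox,
        ))
    return regions


def regions_to_label_mask(regions: list[NucleusRegion],
                          shape: tuple[int, int]) -> np.ndarray:
    """Labelled uint16 raster with each region's filled support."""
    out = np.zeros(shape, np.uint16)
    for reg in regions:
        out[reg.filled_mask] = reg.label
    return out
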