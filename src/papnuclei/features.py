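"""Five-feature descriptor of candidate nucleus regions.

Three shape features measure departure from an ideal circle —
eccentricity of the moment-matched ellipse, major/minor axis ratio, and
the ratio of the equivalent diameter (circle with the region's area) to
the "actual" diameter implied by the boundary pixel count.  Two texture
features respond to the multiple intensity valleys that overlapping
produces: the number of 8-connected grayscale local minima inside the
region and the maximum Euclidean distance between them.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial.distance import pdist
from skimage.measure import regionprops

from papnuclei.segmentation import NucleusRegion

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "shape_features",
    "local_minima",
    "max_minima_distance",
    "extract_features",
    "feature_matrix",
    "features_to_frame",
    "frame_to_features",
    "write_features_csv",
    "read_features_csv",
]

log = logging.getLogger(__name__)

#: column order of the descriptor; indices are relied on by the
#: overlap-calling rule (n_minima is feature index 3)
FEATURE_NAMES = ("eccentricity", "axis_ratio", "diameter_ratio",
                 "n_minima", "max_minima_dist")

_S4 = ndi.generate_binary_structure(2, 1)
_S8 = np.ones((3, 3), bool)
_FOOT8 = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], bool)


@dataclass
class FeatureVector:
    region_label: int
    eccentricity: float
    axis_ratio: float
    diameter_ratio: float
    n_minima: int
    max_minima_dist: float
    valid: bool = True

    def as_array(self) -> np.ndarray:
        return np.array([self.eccentricity, self.axis_ratio,
                         self.diameter_ratio, float(self.n_minima),
                         self.max_minima_dist])


def shape_features(region: NucleusRegion) -> tuple[float, float, float]:
    """(eccentricity, axis_ratio, diameter_ratio) of a filled region.

    Axis lengths come from the mask's second central moments (best-fit
    ellipse); eccentricity = sqrt(1 - b^2/a^2).  The equivalent diameter
    is sqrt(4*Area/pi); the actual diameter is P_n/pi, where P_n counts
    region pixels with at least one 4-neighbour outside the region.  A
    degenerate mask (zero minor axis) clamps eccentricity to 1 - 1e-9
    with a warning.
    """
    mask = region.filled_mask
    if not mask.any():
        raise ValueError("region mask is empty")
    r0, c0, r1, c1 = region.bounding_box
    crop = mask[r0:r1, c0:c1]
    props = regionprops(crop.astype(np.uint8))[0]
    major = props.axis_major_length
    minor = props.axis_minor_length
    if minor <= 1e-9:
        warnings.warn("degenerate region (zero minor axis); "
                      "eccentricity clamped", stacklevel=2)
        ecc = 1.0 - 1e-9
        ratio = major / max(minor, 1e-9)
    else:
        ecc = math.sqrt(max(0.0, 1.0 - (minor / major) ** 2))
        ratio = major / minor
    area = crop.sum()
    perim_n = int((crop & ~ndi.binary_erosion(crop, _S4)).sum())
    eq_diam = math.sqrt(4.0 * area / math.pi)
    actual_diam = perim_n / math.pi
    return ecc, ratio, eq_diam / actual_diam


def local_minima(
    gray: np.ndarray,
    region: NucleusRegion,
    smoothing_sigma: float = 0.0,
) -> np.ndarray:
    """Grayscale local minima inside a region, as an (M, 2) array.

    A pixel is a minimum when its intensity is strictly lower than all
    8-neighbours; a connected constant-intensity plateau counts as one
    minimum (represented by the plateau pixel nearest its centroid) when
    every in-region neighbour of the plateau is strictly brighter.  Only
    pixels whose full 8-neighbourhood lies inside the region are
    eligible to represent a minimum.  Regions of area < 9 return an
    empty set with a warning.  ``smoothing_sigma`` optionally smooths
    the intensities first (default: raw 8-bit values).
    """
    mask = region.filled_mask
    if mask.sum() < 9:
        warnings.warn(f"region {region.label} too small for minima "
                      "detection", stacklevel=2)
        return np.empty((0, 2), int)
    gray = np.asarray(gray)
    if gray.shape != mask.shape:
        raise ValueError("gray image and region mask shapes differ")

    r0, c0, r1, c1 = region.bounding_box
    m = np.pad(mask[r0:r1, c0:c1], 1)
    vals = np.pad(gray[r0:r1, c0:c1].astype(np.float64), 1, mode="edge")
    if smoothing_sigma > 0:
        vals = ndi.gaussian_filter(vals, smoothing_sigma)
    vals = np.where(m, vals, np.inf)

    eligible = ndi.binary_erosion(m, _S8)
    nbmin = ndi.minimum_filter(vals, footprint=_FOOT8, mode="constant",
                               cval=np.inf)
    seeds = eligible & (vals <= nbmin)
    if not seeds.any():
        return np.empty((0, 2), int)

    minima = []
    for v in np.unique(vals[seeds]):
        level = m & (vals == v)
        lab, n = ndi.label(level, structure=_S8)
        for i in range(1, n + 1):
            plateau = lab == i
            if not (plateau & seeds).any():
                continue
            ring = ndi.binary_dilation(plateau, _S8) & m & ~plateau
            if ring.any() and vals[ring].min() <= v:
                continue
            pts = np.argwhere(plateau & eligible)
            cen = np.argwhere(plateau).mean(axis=0)
            rep = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
            d2 = ((rep - cen) ** 2).sum(axis=1)
            best = rep[int(np.argmin(d2))]
            minima.append(best)
    if not minima:
        return np.empty((0, 2), int)
    out = np.array(minima) - 1 + [r0, c0]  # undo padding, back to frame
    return out[np.lexsort((out[:, 1], out[:, 0]))]


def max_minima_distance(minima: np.ndarray) -> float:
    """Maximum pairwise Euclidean distance; 0 for sets of size <= 1."""
    pts = np.asarray(minima, float).reshape(-1, 2)
    if len(pts) <= 1:
        return 0.0
    return float(pdist(pts).max())


def extract_features(
    gray: np.ndarray,
    regions: list[NucleusRegion],
    smoothing_sigma: float = 0.0,
) -> list[FeatureVector]:
    """One FeatureVector per region, in region-label order.

    A region that fails feature computation yields a flagged record
    (``valid=False``, NaN features) rather than aborting the batch.
    """
    out: list[FeatureVector] = []
    for reg in sorted(regions, key=lambda r: r.label):
        try:
            ecc, ratio, dratio = shape_features(reg)
            pts = local_minima(gray, reg, smoothing_sigma)
            out.append(FeatureVector(
                region_label=reg.label,
                eccentricity=ecc,
                axis_ratio=ratio,
                diameter_ratio=dratio,
                n_minima=len(pts),
                max_minima_dist=max_minima_distance(pts),
            ))
        except Exception:                                  # noqa: BLE001
            log.exception("feature extraction failed for region %d",
                          reg.label)
            out.append(FeatureVector(reg.label, math.nan, math.nan,
                                     math.nan, 0, math.nan, valid=False))
    return out


def feature_matrix(features: list[FeatureVector]) -> np.ndarray:
    """(N, 5) matrix in FEATURE_NAMES order (valid records only)."""
    return np.array([f.as_array() for f in features if f.valid]).reshape(-1, 5)


def features_to_frame(features: list[FeatureVector]) -> pd.DataFrame:
    cols = [f.name for f in fields(FeatureVector)]
    return pd.DataFrame([[getattr(fv, c) for c in cols] for fv in features],
                        columns=["label" if c == "region_label" else c
                                 for c in cols])


def frame_to_features(frame: pd.DataFrame) -> list[FeatureVector]:
    return [FeatureVector(
        region_label=int(row["label"]),
        eccentricity=float(row["eccentricity"]),
        axis_ratio=float(row["axis_ratio"]),
        diameter_ratio=float(row["diameter_ratio"]),
        n_minima=int(row["n_minima"]),
        max_minima_dist=float(row["max_minima_dist"]),
        valid=bool(row.get("valid", True)),
    ) for _, row in frame.iterrows()]


def write_features_csv(path, features: list[FeatureVector]) -> None:
    # %.17g preserves doubles exactly across the write/read cycle
    features_to_frame(features).to_csv(path, index=False,
                                       float_format="%.17g")


def read_features_csv(path) -> list[FeatureVector]:
    return frame_to_features(pd.read_csv(path, float_precision="round_trip"))
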