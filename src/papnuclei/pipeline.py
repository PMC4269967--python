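"""End-to-end pipeline: preprocess -> segment -> describe -> classify.

:class:`RunConfig` gathers every tunable with its default; size-related
thresholds are specified at the 1280x960 reference scale and scaled by
the actual image area.  The semi-automated path accepts a pre-segmented
labelled nucleus mask and skips boundary extraction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi

from papnuclei import clustering, features, preprocessing, segmentation
from papnuclei.clustering import ClusterModel, OverlapCall
from papnuclei.features import FeatureVector
from papnuclei.preprocessing import ClusterMask
from papnuclei.segmentation import NucleusRegion

__all__ = ["RunConfig", "PipelineResult", "run_pipeline",
           "regions_from_mask", "REFERENCE_AREA"]

log = logging.getLogger(__name__)

REFERENCE_AREA = 1280 * 960


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with defaults.

    ``size_min``/``size_max`` (edge-component pixel counts) and
    ``min_nucleus_area`` are given at the 1280x960 reference scale and
    multiplied by (image area / reference area) at run time.
    """

    hue_lo: float = 0.2
    hue_hi: float = 0.7
    closing_radius: int = 5
    canny_high: float = 0.4
    canny_low_ratio: float = 0.4
    canny_sigma: float = 0.0
    size_min: int = 20
    size_max: int = 5000
    min_nucleus_area: int = 50
    minima_sigma: float = 1.0
    standardize: bool = True
    method: str = "fcm"
    fuzzifier_m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 300
    n_restarts: int = 10
    rng_seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.hue_lo < self.hue_hi <= 1.0):
            raise ValueError("invalid hue limits")
        if not (0.0 < self.canny_high < 1.0):
            raise ValueError("canny_high must lie in (0, 1)")
        if self.method not in ("fcm", "kmeans"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.fuzzifier_m <= 1.0:
            raise ValueError("fuzzifier_m must be > 1")
        if self.size_min > self.size_max:
            raise ValueError("size_min must be <= size_max")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Flat ``key = value`` text file (also accepts JSON objects)."""
        text = Path(path).read_text()
        stripped = text.lstrip()
        if stripped.startswith("{"):
            raw = json.loads(text)
        else:
            raw = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                raw[key.strip()] = value.strip()
        defaults = cls()
        coerced = {}
        for key, value in raw.items():
            if isinstance(value, str):
                current = getattr(defaults, key, None)
                if isinstance(current, bool):
                    value = value.lower() in ("1", "true", "yes")
                elif isinstance(current, int):
                    value = int(value)
                elif isinstance(current, float):
                    value = float(value)
            coerced[key] = value
        return cls.from_dict(coerced)


@dataclass
class PipelineResult:
    gray: np.ndarray
    cluster_mask: ClusterMask
    edges: np.ndarray | None
    regions: list[NucleusRegion]
    features: list[FeatureVector]
    model: ClusterModel | None
    calls: list[OverlapCall]
    config: RunConfig = field(default_factory=RunConfig)


def regions_from_mask(mask: np.ndarray,
                      min_nucleus_area: int = 1) -> list[NucleusRegion]:
    """Build regions from a pre-segmented nucleus mask (semi-automated
    mode).  A labelled mask keeps its labels; a binary mask is labelled
    by 8-connected components."""
    mask = np.asarray(mask)
    if mask.dtype == bool or len(np.unique(mask)) <= 2:
        lab, _ = ndi.label(mask > 0, structure=np.ones((3, 3)))
    else:
        lab = mask.astype(np.int64)
    regions = []
    s4 = ndi.generate_binary_structure(2, 1)
    for value in sorted(int(v) for v in np.unique(lab) if v != 0):
        filled = ndi.binary_fill_holes(lab == value)
        if filled.sum() < min_nucleus_area:
            continue
        boundary = filled & ~ndi.binary_erosion(filled, s4)
        rows, cols = np.nonzero(filled)
        regions.append(NucleusRegion(
            label=value,
            boundary_pixels=np.argwhere(boundary),
            filled_mask=filled,
            bounding_box=(int(rows.min()), int(cols.min()),
                          int(rows.max()) + 1, int(cols.max()) + 1),
        ))
    return regions


def run_pipeline(
    rgb: np.ndarray,
    config: RunConfig | None = None,
    mask: np.ndarray | None = None,
) -> PipelineResult:
    """Run the full detection pipeline on an RGB image.

    When ``mask`` is given (semi-automated mode), segmentation is
    skipped and regions are built from the mask directly.  With fewer
    than two regions no clustering is possible; every region is then
    reported as single with a warning.
    """
    config = config or RunConfig()
    config.validate()
    gray = preprocessing.to_grayscale(rgb)
    cmask = preprocessing.hue_gate(rgb, config.hue_lo, config.hue_hi,
                                   closing_radius=config.closing_radius)
    scale = (rgb.shape[0] * rgb.shape[1]) / REFERENCE_AREA
    min_area = max(1, int(round(config.min_nucleus_area * scale)))

    edges = None
    if mask is None:
        mag = segmentation.gradient_magnitude(gray)
        edges = segmentation.edge_filter(
            mag, config.canny_high, config.canny_low_ratio,
            config.canny_sigma)
        edges = segmentation.size_filter(
            edges,
            max(1, int(round(config.size_min * scale))),
            max(1, int(round(config.size_max * scale))))
        edges = segmentation.closed_contour_filter(edges)
        edges = segmentation.remove_bifurcations(edges)
        regions = segmentation.contours_to_regions(edges, cmask, min_area)
    else:
        regions = regions_from_mask(mask, min_nucleus_area=min_area)

    fvs = features.extract_features(gray, regions, config.minima_sigma)
    valid = [f for f in fvs if f.valid]
    if len(valid) < 2:
        if valid:
            warnings.warn("fewer than two regions; reporting all as single",
                          stacklevel=2)
        calls = [OverlapCall(f.region_label, "single", 1.0) for f in valid]
        model = None
    else:
        model, calls = clustering.classify_features(
            fvs,
            method=config.method,
            standardize_first=config.standardize,
            fuzzifier_m=config.fuzzifier_m,
            tol=config.tol,
            max_iter=config.max_iter,
            n_restarts=config.n_restarts,
            rng_seed=config.rng_seed,
        )
    log.info("pipeline: %d regions, %d calls (%s)", len(regions),
             len(calls), config.method)
    return PipelineResult(gray=gray, cluster_mask=cmask, edges=edges,
                          regions=regions, features=fvs, model=model,
                          calls=calls, config=config)
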