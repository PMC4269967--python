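"""Ground-truthed synthetic cervical cytology scenes.

The generator emulates the appearance that drives the detection pipeline:
a light background whose hue falls outside the cytoplasmic hue band,
mid-intensity cytoplasmic clusters with hue inside [0.2, 0.7], and dark
elliptical nuclei whose intensity rises quadratically from a single dark
valley at the centre.  An overlapped pair is rendered as the pixelwise
minimum of two such radial profiles, so the merged region keeps both
valley bottoms and acquires the flattened, irregular outline that the
shape features respond to.

Colour is synthesised so that the 8-bit luma of the rendered RGB image is
*exactly* the intended grayscale raster: each pixel's three channels are
the target gray level plus a fixed small-chroma offset whose luma
contribution rounds away.  Cytoplasmic pixels (including nuclei) use the
offset ``(g-5, g+3, g+1)`` (hue 0.458), background pixels ``(g+4, g-2,
g-1)`` (hue 0.972).  This keeps the hue gate and the grayscale pipeline
bit-reproducible without modelling stain chemistry.

All stochastic choices are drawn from one seeded generator in a fixed
order (object geometry in placement order, then pixel noise), so a scene
is a pure function of its :class:`SceneSpec`.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "SceneCapacityError",
    "generate_scene",
    "generate_feature_points",
    "write_scene",
    "read_truth",
]

#: semantic class names used in ground-truth label maps
SINGLE = "single"
OVERLAPPED = "overlapped"


class SceneCapacityError(RuntimeError):
    """Raised when the requested objects cannot be placed in the frame."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    ``n_overlap`` counts overlapped *pairs*; each pair is one ground-truth
    object.  ``overlap_offset_fraction`` is the centre distance of a pair
    as a fraction of the two ellipse radii summed along the centre line,
    so values in (0, 1) guarantee genuine intersection.  Intensities are
    8-bit gray levels and must satisfy nucleus < cytoplasm < background
    (nuclei are among the darkest structures in a cervical sample).
    """

    width: int = 1280
    height: int = 960
    n_single: int = 17
    n_overlap: int = 3
    nucleus_radius_range: tuple[float, float] = (14.0, 24.0)
    overlap_offset_fraction: float = 0.6
    nucleus_intensity: int = 30
    cytoplasm_intensity: int = 150
    background_intensity: int = 230
    noise_sigma: float = 1.0
    rng_seed: int = 0
    # rendering details: cytoplasm halo width around nuclei and the width
    # of the intensity ramp from cytoplasm level to background level
    cytoplasm_pad: float = 18.0
    rim_ramp: float = 10.0

    def validate(self) -> None:
        if self.n_single < 0 or self.n_overlap < 0:
            raise ValueError("object counts must be non-negative")
        if self.n_single + self.n_overlap < 1:
            raise ValueError("scene must contain at least one object")
        if not (0.0 < self.overlap_offset_fraction < 1.0):
            raise ValueError("overlap_offset_fraction must lie in (0, 1)")
        if not (self.nucleus_intensity < self.cytoplasm_intensity
                < self.background_intensity):
            raise ValueError(
                "intensities must satisfy nucleus < cytoplasm < background")
        lo, hi = self.nucleus_radius_range
        if not (0 < lo <= hi):
            raise ValueError("invalid nucleus_radius_range")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if min(self.width, self.height) < 3:
            raise ValueError("frame must be at least 3x3")


@dataclass
class GroundTruth:
    """Instance-level truth for a rendered scene.

    ``instance_mask`` holds 0 for background and k for the k-th object
    (an overlapped pair is a single object).  ``region_labels`` maps each
    instance label to ``"single"`` or ``"overlapped"``.  ``cluster_mask``
    is the cytoplasmic cell-cluster support; every instance pixel lies
    inside it.  ``objects`` records the analytic geometry of each object
    (list of ellipse parameter tuples) for tests that need the exact
    outline.
    """

    instance_mask: np.ndarray
    region_labels: dict[int, str]
    cluster_mask: np.ndarray
    objects: list[dict] = field(default_factory=list)


# ----------------------------------------------------------------------
# geometry helpers

def _ellipse_radius(a: float, b: float, theta: float, phi: float) -> float:
    """Support radius of an ellipse (semi-axes a, b, rotated by theta)
    along the direction phi."""
    c = math.cos(phi - theta)
    s = math.sin(phi - theta)
    return a * b / math.hypot(b * c, a * s)


def _ellipse_r2(shape, cy, cx, a, b, theta):
    """Normalised squared elliptic radius over a bounding window.

    Returns (window slice, r2 array) with r2 <= 1 inside the ellipse.
    """
    h, w = shape
    rad = max(a, b) + 2
    r0 = max(int(cy - rad), 0)
    r1 = min(int(cy + rad) + 2, h)
    c0 = max(int(cx - rad), 0)
    c1 = min(int(cx + rad) + 2, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - cy
    dx = xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = (dy * ct + dx * st) / a
    v = (-dy * st + dx * ct) / b
    return (slice(r0, r1), slice(c0, c1)), u * u + v * v


def _draw_ellipse_params(rng: np.random.Generator,
                         radius_range: tuple[float, float]):
    a = rng.uniform(*radius_range)
    ratio = rng.uniform(1.0, 1.3)
    b = a / ratio
    theta = rng.uniform(0.0, math.pi)
    return a, b, theta


# ----------------------------------------------------------------------
# scene generation

_MAX_TRIES = 500
#: minimum clearance (px) between bounding circles of distinct objects,
#: so their gradient ridges never touch
_CLEARANCE = 10.0


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene and its ground truth.

    Returns an ``(H, W, 3)`` uint8 RGB image and a :class:`GroundTruth`.
    Deterministic given ``spec.rng_seed``.  Raises
    :class:`SceneCapacityError` when the requested object count cannot be
    placed without contact after bounded retries.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.height, spec.width

    kinds = [SINGLE] * spec.n_single + [OVERLAPPED] * spec.n_overlap
    placed: list[tuple[float, float, float]] = []  # (cy, cx, bound radius)
    objects: list[dict] = []

    for kind in kinds:
        for _ in range(_MAX_TRIES):
            if kind == SINGLE:
                a, b, th = _draw_ellipse_params(rng, spec.nucleus_radius_range)
                rb = a
                cy = rng.uniform(0, h)
                cx = rng.uniform(0, w)
                ellipses = [(cy, cx, a, b, th)]
            else:
                a1, b1, t1 = _draw_ellipse_params(rng, spec.nucleus_radius_range)
                a2, b2, t2 = _draw_ellipse_params(rng, spec.nucleus_radius_range)
                phi = rng.uniform(0.0, 2 * math.pi)
                r1 = _ellipse_radius(a1, b1, t1, phi)
                r2 = _ellipse_radius(a2, b2, t2, phi + math.pi)
                d = spec.overlap_offset_fraction * (r1 + r2)
                cy = rng.uniform(0, h)
                cx = rng.uniform(0, w)
                cy2 = cy + d * math.sin(phi)
                cx2 = cx + d * math.cos(phi)
                ellipses = [(cy, cx, a1, b1, t1), (cy2, cx2, a2, b2, t2)]
                # bounding circle around the pair midpoint
                cy = (cy + cy2) / 2.0
                cx = (cx + cx2) / 2.0
                rb = d / 2.0 + max(a1, a2)
            margin = rb + spec.cytoplasm_pad + spec.rim_ramp + 2
            if not (margin <= cy <= h - margin and margin <= cx <= w - margin):
                continue
            if all(math.hypot(cy - py, cx - px) >= rb + prb + _CLEARANCE
                   for py, px, prb in placed):
                placed.append((cy, cx, rb))
                objects.append({"kind": kind, "ellipses": ellipses})
                break
        else:
            raise SceneCapacityError(
                f"could not place object {len(objects) + 1} of "
                f"{len(kinds)} after {_MAX_TRIES} attempts")

    # rasterise: nucleus support + radial profiles, composed by minimum
    rim = (spec.nucleus_intensity + spec.cytoplasm_intensity) / 2.0
    depth = rim - spec.nucleus_intensity
    profile = np.full((h, w), np.inf)
    instance = np.zeros((h, w), np.uint16)
    for idx, obj in enumerate(objects, start=1):
        for (ecy, ecx, a, b, th) in obj["ellipses"]:
            win, r2 = _ellipse_r2((h, w), ecy, ecx, a, b, th)
            inside = r2 <= 1.0
            vals = np.where(inside, spec.nucleus_intensity + depth * r2, np.inf)
            profile[win] = np.minimum(profile[win], vals)
            instance[win][inside] = idx

    nucleus_support = np.isfinite(profile)
    cluster = ndi.distance_transform_edt(~nucleus_support) <= spec.cytoplasm_pad
    dist_out = ndi.distance_transform_edt(~cluster)
    span = spec.background_intensity - spec.cytoplasm_intensity
    gray = np.where(
        cluster,
        float(spec.cytoplasm_intensity),
        np.minimum(float(spec.background_intensity),
                   spec.cytoplasm_intensity + span * dist_out / spec.rim_ramp),
    )
    gray = np.where(nucleus_support, profile, gray)

    if spec.noise_sigma > 0:
        gray = gray + rng.normal(0.0, spec.noise_sigma, gray.shape)
    # keep headroom for the fixed-chroma channel offsets below
    gray = np.clip(np.round(gray), 6, 250).astype(np.int16)

    rgb_cyto = np.stack([gray - 5, gray + 3, gray + 1], axis=-1)
    rgb_bg = np.stack([gray + 4, gray - 2, gray - 1], axis=-1)
    rgb = np.where(cluster[..., None], rgb_cyto, rgb_bg)
    rgb = np.clip(rgb, 0, 255).astype(np.uint8)

    labels = {i: obj["kind"] for i, obj in enumerate(objects, start=1)}
    truth = GroundTruth(instance_mask=instance, region_labels=labels,
                        cluster_mask=cluster, objects=objects)
    return rgb, truth


# ----------------------------------------------------------------------
# feature-space point clouds (clustering fixtures)

def generate_feature_points(
    n_per_class: int,
    centroid_a,
    centroid_b,
    spread,
    rng_seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Two isotropic Gaussian clouds in 5-D feature space.

    Returns ``(points, labels)`` with labels 0 (class a) and 1 (class b),
    class a first.  ``spread`` may be a scalar or a per-dimension scale.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ca = np.asarray(centroid_a, float)
    cb = np.asarray(centroid_b, float)
    if ca.shape != (5,) or cb.shape != (5,):
        raise ValueError("centroids must be 5-vectors")
    if not (np.isfinite(ca).all() and np.isfinite(cb).all()):
        raise ValueError("centroid entries must be finite")
    s = np.broadcast_to(np.asarray(spread, float), (5,))
    if (s < 0).any():
        raise ValueError("spread must be non-negative elementwise")
    rng = np.random.default_rng(rng_seed)
    pa = ca + rng.normal(size=(n_per_class, 5)) * s
    pb = cb + rng.normal(size=(n_per_class, 5)) * s
    points = np.vstack([pa, pb])
    labels = np.repeat([0, 1], n_per_class)
    return points, labels


# ----------------------------------------------------------------------
# on-disk representation

def write_scene(outdir, rgb: np.ndarray, truth: GroundTruth,
                spec: SceneSpec) -> dict[str, Path]:
    """Write scene.png (8-bit RGB), instance_mask.png (16-bit),
    cluster_mask.png (8-bit binary) and truth.json sidecar."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "scene": outdir / "scene.png",
        "instance_mask": outdir / "instance_mask.png",
        "cluster_mask": outdir / "cluster_mask.png",
        "truth": outdir / "truth.json",
    }
    iio.imwrite(paths["scene"], rgb)
    iio.imwrite(paths["instance_mask"], truth.instance_mask.astype(np.uint16))
    iio.imwrite(paths["cluster_mask"],
                (truth.cluster_mask * 255).astype(np.uint8))
    sidecar = {
        "region_labels": {str(k): v for k, v in truth.region_labels.items()},
        "spec": asdict(spec),
    }
    paths["truth"].write_text(json.dumps(sidecar, indent=2))
    return paths


def read_truth(path) -> dict[int, str]:
    """Read the region-label map from a truth.json sidecar."""
    data = json.loads(Path(path).read_text())
    return {int(k): v for k, v in data["region_labels"].items()}
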