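"""Fiducial detection and registration into the canonical plate frame.

The device carries four near-black square fiducials around the plate.
Detection thresholds the channel-maximum image (fiducials are dark in
every channel, dye only in the absorbed ones), keeps solid connected
components of plausible area, and demands exactly one per image quadrant.
Four point correspondences determine the pixel->mm projective homography
exactly (8 constraints, 8 degrees of freedom); images are then rectified
into the canonical millimetre frame by bilinear resampling.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.transform import ProjectiveTransform, warp

from .errors import FiducialError
from .geometry import DEFAULT_GEOMETRY, FIDUCIAL_LABELS, PlateGeometry
from .image import PlateImage

#: Area window (relative to the expected fiducial area) for candidate blobs.
AREA_WINDOW = (0.25, 4.0)
MIN_SOLIDITY = 0.8


@dataclass
class FiducialSet:
    """Four sub-pixel fiducial centroids labelled by image quadrant."""

    centroids: dict[str, tuple[float, float]]  # label -> (x, y) pixels
    areas: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.centroids) != set(FIDUCIAL_LABELS):
            raise FiducialError(
                f"fiducial set must carry labels {FIDUCIAL_LABELS}"
            )
        areas = np.array([self.areas[k] for k in FIDUCIAL_LABELS])
        if areas.max() > 3.0 * areas.min():
            raise FiducialError("fiducial areas differ by more than 3x")
        pts = self.as_array()
        # cyclic order tl -> tr -> br -> bl must not self-intersect
        poly = pts[[0, 1, 3, 2]]
        area2 = 0.0
        for i in range(4):
            xa, ya = poly[i]
            xb, yb = poly[(i + 1) % 4]
            area2 += xa * yb - xb * ya
        if abs(area2) < 1e-9:
            raise FiducialError("degenerate fiducial geometry")

    def as_array(self, order: tuple[str, ...] = FIDUCIAL_LABELS) -> np.ndarray:
        return np.array([self.centroids[k] for k in order], dtype=np.float64)


def _refined_centroid(
    gray: np.ndarray, bbox: tuple[int, int, int, int], thr: float
) -> tuple[float, float]:
    """Darkness-weighted sub-pixel centroid of one dark component.

    The weight normalises each pixel's darkness against the local
    background level, so interior pixels count fully and anti-aliased
    edge pixels fractionally, regardless of the illumination gradient
    across the mark.
    """
    pad = 3
    r0 = max(bbox[0] - pad, 0)
    c0 = max(bbox[1] - pad, 0)
    r1 = min(bbox[2] + pad, gray.shape[0])
    c1 = min(bbox[3] + pad, gray.shape[1])
    sub = gray[r0:r1, c0:c1]
    background = sub[sub >= thr]
    bg = float(np.median(background)) if background.size else 255.0
    dmin = float(sub.min())
    if bg - dmin < 1.0:
        bg = dmin + 1.0
    weight = np.clip((bg - sub) / (bg - dmin), 0.0, 1.0)
    weight[weight < 0.05] = 0.0
    rows, cols = np.mgrid[r0:r1, c0:c1]
    total = weight.sum()
    return float((cols * weight).sum() / total), float((rows * weight).sum() / total)


def detect_fiducials(
    image: PlateImage,
    expected_area_px: float | None = None,
    min_solidity: float = MIN_SOLIDITY,
) -> FiducialSet:
    """Locate the four dark fiducial squares with sub-pixel precision.

    The fiducials are near-black in *every* channel, unlike dye (dark
    only in the absorbed channels), so candidates are components of the
    channel-maximum image below half the image's median brightness.
    Each surviving component gets a darkness-weighted sub-pixel
    centroid.  When ``expected_area_px`` is not given, the median
    candidate area stands in for it.
    """
    arr = image.to_float()
    gray = arr.max(axis=2)
    thr = 0.5 * float(np.median(gray))
    binary = gray < thr
    if not binary.any():
        raise FiducialError("expected 4 fiducials, found 0")
    labels = sk_label(binary)
    props = [p for p in regionprops(labels) if p.solidity > min_solidity]
    if not props:
        raise FiducialError("expected 4 fiducials, found 0")
    if expected_area_px is None:
        expected_area_px = float(np.median([p.area for p in props]))
    lo, hi = AREA_WINDOW
    props = [
        p
        for p in props
        if lo * expected_area_px <= p.area <= hi * expected_area_px
    ]
    if len(props) != 4:
        raise FiducialError(f"expected 4 fiducials, found {len(props)}")

    cy0, cx0 = (gray.shape[0] - 1) / 2.0, (gray.shape[1] - 1) / 2.0
    centroids: dict[str, tuple[float, float]] = {}
    areas: dict[str, float] = {}
    for p in props:
        col, row = _refined_centroid(gray, p.bbox, thr)
        label_ = ("t" if row < cy0 else "b") + ("l" if col < cx0 else "r")
        if label_ in centroids:
            raise FiducialError(f"two fiducial candidates in quadrant {label_!r}")
        centroids[label_] = (col, row)
        areas[label_] = float(p.area)
    if set(centroids) != set(FIDUCIAL_LABELS):
        missing = sorted(set(FIDUCIAL_LABELS) - set(centroids))
        raise FiducialError(f"no fiducial found in quadrant(s) {missing}")
    return FiducialSet(centroids=centroids, areas=areas)


@dataclass
class PlateTransform:
    """Projective homography pixel -> plate-mm with fit diagnostics."""

    matrix: np.ndarray  # 3x3, maps (x_px, y_px) to (x_mm, y_mm)
    residual_mm: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3) or abs(np.linalg.det(m)) < 1e-15:
            raise FiducialError("plate transform must be an invertible 3x3 matrix")
        self.matrix = m / m[2, 2]
        if self.residual_mm < 0:
            raise FiducialError("residual must be non-negative")

    @property
    def inverse_matrix(self) -> np.ndarray:
        inv = np.linalg.inv(self.matrix)
        return inv / inv[2, 2]

    def _apply(self, matrix: np.ndarray, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        hom = (matrix @ np.hstack([pts, np.ones((pts.shape[0], 1))]).T).T
        return hom[:, :2] / hom[:, 2:3]

    def px_to_mm(self, points_px: np.ndarray) -> np.ndarray:
        return self._apply(self.matrix, points_px)

    def mm_to_px(self, points_mm: np.ndarray) -> np.ndarray:
        return self._apply(self.inverse_matrix, points_mm)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "matrix_px_to_mm": self.matrix.tolist(),
                    "residual_mm": self.residual_mm,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PlateTransform":
        cfg = json.loads(Path(path).read_text())
        return cls(
            matrix=np.asarray(cfg["matrix_px_to_mm"]),
            residual_mm=float(cfg["residual_mm"]),
        )


def _any_collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    for i in range(4):
        tri = np.delete(points, i, axis=0)
        v1, v2 = tri[1] - tri[0], tri[2] - tri[0]
        span = max(np.abs(tri).max(), 1.0)
        if abs(v1[0] * v2[1] - v1[1] * v2[0]) < tol * span**2:
            return True
    return False


def fit_transform(
    fiducials: FiducialSet,
    canonical_mm: dict[str, tuple[float, float]] | None = None,
) -> PlateTransform:
    """Exact homography through the four labelled correspondences."""
    if canonical_mm is None:
        canonical_mm = DEFAULT_GEOMETRY.fiducial_points()
    if set(canonical_mm) != set(FIDUCIAL_LABELS):
        raise FiducialError(
            f"canonical positions must be keyed by {FIDUCIAL_LABELS}"
        )
    src = fiducials.as_array()
    dst = np.array([canonical_mm[k] for k in FIDUCIAL_LABELS], dtype=np.float64)
    if _any_collinear(src) or _any_collinear(dst):
        raise FiducialError("degenerate fiducial geometry")
    tform = ProjectiveTransform.from_estimate(src, dst)
    if not tform:
        raise FiducialError("homography estimation failed")
    transform = PlateTransform(matrix=tform.params)
    residual = float(
        np.linalg.norm(transform.px_to_mm(src) - dst, axis=1).max()
    )
    transform.residual_mm = residual
    return transform


def align(
    image: PlateImage,
    transform: PlateTransform,
    output_scale: float,
    geometry: PlateGeometry = DEFAULT_GEOMETRY,
) -> PlateImage:
    """Rectify an image into the canonical plate frame.

    The output covers the plate footprint at ``output_scale`` px/mm with
    bilinear resampling; output pixels that sample outside the source
    frame are masked out and excluded from all downstream histograms.
    """
    if output_scale <= 0:
        raise FiducialError("output scale must be strictly positive")
    out_w = int(round(geometry.plate_width_mm * output_scale))
    out_h = int(round(geometry.plate_height_mm * output_scale))
    # output px -> mm -> source px
    to_mm = np.diag([1.0 / output_scale, 1.0 / output_scale, 1.0])
    mapping = ProjectiveTransform(matrix=transform.inverse_matrix @ to_mm)

    arr = image.to_float()
    channels = [
        warp(
            arr[..., ch],
            mapping,
            output_shape=(out_h, out_w),
            order=1,
            cval=-1.0,
            preserve_range=True,
        )
        for ch in range(3)
    ]
    data = np.stack(channels, axis=-1)
    coverage = warp(
        image.valid_mask.astype(np.float64),
        mapping,
        output_shape=(out_h, out_w),
        order=1,
        cval=0.0,
        preserve_range=True,
    )
    mask = (coverage > 0.9999) & np.all(data >= 0.0, axis=-1)
    data[~mask] = 0.0
    return PlateImage(
        data=data,
        mask=mask,
        provenance=f"{image.provenance}/aligned",
        scale_px_per_mm=float(output_scale),
    )
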