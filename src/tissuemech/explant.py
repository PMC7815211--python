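"""Tissue-spreading assay metrics for explant time-lapses.

An explant laid on a fibronectin substrate spreads (or not) over ~3 hours.
Three complementary statistics quantify its behaviour:

- **spreading**: total area normalised to the first frame, read out at fixed
  times (60 and 170 min by default);
- **dispersion**: mean Delaunay-triangle area between nuclei, compared
  between the onset of spreading (30 min, when the explant has adhered) and
  the end of the movie (170 min).  A ratio near 1 means cohesive spreading,
  above 1 dispersal, below 1 compaction;
- **intercalation**: number of nuclei in the basal (substrate-apposed) layer
  at 170 min over the count at 30 min — radial intercalation adds cells to
  that layer.

Retraction events (the abrupt large-scale contractions that punctuate
mesoderm spreading) are detected as sustained decreasing runs of the area
curve exceeding a fractional-drop threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .synthetic import NucleiFrames

__all__ = [
    "ExplantTimecourse",
    "RetractionEvent",
    "normalize_area",
    "detect_retractions",
    "mean_triangle_area",
    "delaunay_dispersion",
    "intercalation_ratio",
    "area_from_stack",
]


@dataclass
class ExplantTimecourse:
    """Explant area per frame (um^2) on a uniform time grid (min)."""

    t_min: np.ndarray
    area_um2: np.ndarray
    explant_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.area_um2 = np.asarray(self.area_um2, dtype=float)
        if self.t_min.shape != self.area_um2.shape:
            raise ValueError("t_min and area_um2 must have the same length")
        if np.any(self.area_um2 <= 0):
            raise ValueError("areas must be positive")
        if len(self.t_min) >= 3:
            dt = np.diff(self.t_min)
            if not np.allclose(dt, dt[0]):
                raise ValueError("frame interval must be constant")

    @property
    def frame_interval_min(self) -> float:
        return float(self.t_min[1] - self.t_min[0]) if len(self.t_min) > 1 else float("nan")


@dataclass(frozen=True)
class RetractionEvent:
    t_start: float
    t_end: float
    drop_frac: float


def normalize_area(
    tc: ExplantTimecourse, at_min: tuple[float, ...] = (60.0, 170.0)
) -> tuple[np.ndarray, dict[float, float]]:
    """Area curve divided by the first frame's area, plus values at set times.

    The values at ``at_min`` are nearest-frame lookups with a tolerance of
    one frame interval; a requested time outside that tolerance raises.
    Normalising an already-normalised curve is the identity.
    """
    rel = tc.area_um2 / tc.area_um2[0]
    tol = tc.frame_interval_min if len(tc.t_min) > 1 else 0.0
    at: dict[float, float] = {}
    for t_req in at_min:
        i = int(np.argmin(np.abs(tc.t_min - t_req)))
        if abs(tc.t_min[i] - t_req) > tol:
            raise ValueError(
                f"requested time {t_req} min outside trace (nearest frame {tc.t_min[i]} min)"
            )
        at[t_req] = float(rel[i])
    return rel, at


def detect_retractions(
    tc: ExplantTimecourse, min_drop_frac: float = 0.05, min_frames: int = 2
) -> list[RetractionEvent]:
    """Maximal decreasing runs whose cumulative fractional drop is large enough.

    A retraction event is a run of at least ``min_frames`` consecutive
    frame-to-frame area decreases whose total drop, relative to the area at
    the run's start, is at least ``min_drop_frac``.
    """
    if len(tc.t_min) < 5:
        raise ValueError("need at least 5 frames to detect retractions")
    a, t = tc.area_um2, tc.t_min
    events: list[RetractionEvent] = []
    i = 0
    while i < len(a) - 1:
        if a[i + 1] < a[i]:
            j = i
            while j < len(a) - 1 and a[j + 1] < a[j]:
                j += 1
            drop = (a[i] - a[j]) / a[i]
            if j - i >= min_frames and drop >= min_drop_frac:
                events.append(RetractionEvent(float(t[i]), float(t[j]), float(drop)))
            i = j
        else:
            i += 1
    return events


def _points_at(
    frames: NucleiFrames, t_min: float, tol_min: float | None, layer: str | None
) -> np.ndarray:
    df = frames.frame_at(t_min, tol_min)
    if layer is not None:
        df = df[df["layer"] == layer]
    pts = df[["x_um", "y_um"]].to_numpy(dtype=float)
    uniq, idx = np.unique(pts, axis=0, return_index=True)
    if len(uniq) < len(pts):
        warnings.warn(
            f"{len(pts) - len(uniq)} duplicate nucleus coordinates deduplicated", stacklevel=3
        )
        pts = pts[np.sort(idx)]
    return pts


def mean_triangle_area(points: np.ndarray) -> float:
    """Mean area (um^2) of the Delaunay triangles of a 2-D point set.

    Raises ``ValueError`` for fewer than 3 points or collinear input.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 nuclei")
    try:
        tri = Delaunay(pts)
    except QhullError as err:
        raise ValueError("collinear nuclei: Delaunay triangulation undefined") from err
    simplices = pts[tri.simplices]
    e1 = simplices[:, 1] - simplices[:, 0]
    e2 = simplices[:, 2] - simplices[:, 0]
    areas = 0.5 * np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    return float(areas.mean())


@dataclass(frozen=True)
class DispersionResult:
    mean_area_start: float
    mean_area_end: float
    ratio: float
    t_start_min: float
    t_end_min: float


def delaunay_dispersion(
    frames: NucleiFrames,
    t_start: float = 30.0,
    t_end: float = 170.0,
    tol_min: float | None = None,
    layer: str | None = None,
) -> DispersionResult:
    """Dispersion ratio: mean Delaunay-triangle area at ``t_end`` / ``t_start``.

    The start default of 30 min corresponds to the stage when the explant has
    adhered to the substrate and begun to spread.  ``layer`` optionally
    restricts the triangulated nuclei (e.g. ``"basal"``); by default all
    nuclei in the frame are used.
    """
    p0 = _points_at(frames, t_start, tol_min, layer)
    p1 = _points_at(frames, t_end, tol_min, layer)
    a0 = mean_triangle_area(p0)
    a1 = mean_triangle_area(p1)
    return DispersionResult(
        mean_area_start=a0,
        mean_area_end=a1,
        ratio=a1 / a0,
        t_start_min=t_start,
        t_end_min=t_end,
    )


def intercalation_ratio(
    frames: NucleiFrames,
    t_start: float = 30.0,
    t_end: float = 170.0,
    tol_min: float | None = None,
) -> float:
    """Basal-layer nucleus count at ``t_end`` divided by the count at ``t_start``."""
    n0 = len(frames.frame_at(t_start, tol_min).query("layer == 'basal'"))
    n1 = len(frames.frame_at(t_end, tol_min).query("layer == 'basal'"))
    if n0 == 0:
        raise ValueError(
            f"no basal nuclei at t = {t_start} min; intercalation ratio undefined"
        )
    return n1 / n0


def area_from_stack(stack: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Otsu-threshold area extractor for synthetic image stacks (um^2/frame).

    A convenience for end-to-end tests; real explant segmentation is out of
    scope (areas are normally inputs).
    """
    from skimage.filters import threshold_otsu

    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a (frames, rows, cols) stack")
    areas = np.empty(len(stack))
    for i, img in enumerate(stack):
        mask = img > threshold_otsu(img)
        areas[i] = mask.sum() * pixel_size_um**2
    return areas
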