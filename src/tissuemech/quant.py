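"""Single-cell fluorescence and motility quantification operators.

Re-implementations of the confocal-image measurements used throughout the
study: the fraction of ventral vinculin concentrated in adhesion clusters,
cortical and cell-contact enrichment ratios from line scans, the
skeleton-based membrane-mask pipeline for cryosection markers, Pearson and
Manders colocalization, ventral-surface morphometry, cell-axis orientation,
track speeds and adhesion-assay fractions.

All ratio operators subtract background first and are therefore invariant to
a positive rescaling of every intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from skimage.draw import line as _line
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import perimeter_crofton
from skimage.morphology import dilation, footprint_rectangle, skeletonize
from skimage.restoration import rolling_ball

from .synthetic import QuantImage

__all__ = [
    "LineScan",
    "CellTrack",
    "cluster_fraction",
    "scan_mean",
    "cortical_ratio",
    "contact_enrichment",
    "membrane_mask_quant",
    "colocalization",
    "morphometry",
    "orientation_angle",
    "track_speed",
    "adhesion_fraction",
    "adhesion_statistics",
    "morphology_distribution",
]

MORPHOLOGY_CATEGORIES = ("b", "r", "p", "s", "pb")
"""Cell morphology labels: round-and-blebbing, round, polarized, spread,
polarized-with-bleb."""


# ---------------------------------------------------------------------------
# line scans


@dataclass(frozen=True)
class LineScan:
    """Polyline (um coordinates) along which mean intensity is measured."""

    points: tuple[tuple[float, float], ...]
    kind: str = "free_edge"  # free_edge | contact | cytoplasm

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("line scan needs at least 2 points")
        if self.kind not in ("free_edge", "contact", "cytoplasm"):
            raise ValueError(f"unknown scan kind: {self.kind!r}")


def _scan_mask(img_shape: tuple[int, int], scan: LineScan, pixel_size_um: float, width_px: int) -> np.ndarray:
    mask = np.zeros(img_shape, dtype=bool)
    px = np.asarray(scan.points, dtype=float) / pixel_size_um
    for (r0, c0), (r1, c1) in zip(px[:-1], px[1:]):
        rr, cc = _line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
        if np.any((rr < 0) | (rr >= img_shape[0]) | (cc < 0) | (cc >= img_shape[1])):
            raise ValueError("line scan extends outside the image")
        mask[rr, cc] = True
    if width_px > 1:
        mask = dilation(mask, footprint_rectangle((width_px, width_px)))
    return mask


def scan_mean(
    img: QuantImage, scan: LineScan, channel: str = "signal", width_px: int = 3
) -> float:
    """Mean intensity along a polyline scan averaged over ``width_px``."""
    data = img.channels[channel]
    mask = _scan_mask(data.shape, scan, img.pixel_size_um, width_px)
    return float(data[mask].mean())


# ---------------------------------------------------------------------------
# intensity-ratio operators


def cluster_fraction(
    img: QuantImage,
    ventral_mask: np.ndarray | None = None,
    cluster_mask: np.ndarray | None = None,
    channel: str = "signal",
    k_mad: float = 3.0,
    background: float | None = None,
) -> float:
    """Fraction of ventral-surface fluorescence concentrated in clusters.

    Background-subtracted summed intensity inside the cluster mask divided by
    the background-subtracted summed intensity over the whole ventral mask.
    When no cluster mask is supplied, clusters are segmented as the pixels
    brighter than ``median + k_mad * MAD`` within the ventral mask (a robust
    threshold; the scaled MAD estimates sigma).  Background defaults to the
    median intensity outside the ventral mask.

    Being a ratio of two linear functionals of the same background-subtracted
    image, the fraction is invariant to scaling all intensities, so it is
    comparable across expression levels.
    """
    data = np.asarray(img.channels[channel], dtype=float)
    if ventral_mask is None:
        ventral_mask = img.masks.get("ventral")
    if ventral_mask is None or not np.any(ventral_mask):
        raise ValueError("empty or missing ventral mask")
    ventral_mask = np.asarray(ventral_mask, dtype=bool)
    if background is None:
        outside = ~ventral_mask
        background = float(np.median(data[outside])) if np.any(outside) else 0.0

    sub = data - background
    if cluster_mask is None:
        inside = sub[ventral_mask]
        med = np.median(inside)
        mad = np.median(np.abs(inside - med)) * 1.4826
        cluster_mask = ventral_mask & (sub > med + k_mad * mad)
    else:
        cluster_mask = np.asarray(cluster_mask, dtype=bool) & ventral_mask

    total = float(sub[ventral_mask].sum())
    if not np.any(cluster_mask):
        warnings.warn("empty cluster mask: fraction set to 0", stacklevel=2)
        return 0.0
    if total <= 0:
        raise ValueError("non-positive total ventral intensity after background subtraction")
    return float(sub[cluster_mask].sum() / total)


def cortical_ratio(
    img: QuantImage,
    edge_scan: LineScan,
    cyto_scan: LineScan,
    channel: str = "signal",
    background: float = 0.0,
    width_px: int = 3,
) -> float:
    """Cortical enrichment: mean edge (or contact) over adjacent cytoplasm.

    Both line-scan means are background-subtracted first; a non-positive
    cytoplasm mean leaves the ratio undefined (NaN, with a warning).
    """
    edge = scan_mean(img, edge_scan, channel, width_px) - background
    cyto = scan_mean(img, cyto_scan, channel, width_px) - background
    if cyto <= 0:
        warnings.warn("cytoplasm mean <= 0 after background subtraction", stacklevel=2)
        return float("nan")
    return edge / cyto


class EnrichmentResult(NamedTuple):
    ratio: float  # contact / (2 * free edge)
    raw_ratio: float  # contact / free edge


def contact_enrichment(
    img: QuantImage,
    contact_scan: LineScan,
    edge_scan: LineScan,
    channel: str = "signal",
    background: float = 0.0,
    width_px: int = 3,
) -> EnrichmentResult:
    """Contact enrichment: contact intensity over twice the free-edge intensity.

    A cell-cell contact contains two apposed membranes, so an unpolarized
    membrane marker gives a ratio of 1; values above 1 indicate genuine
    enrichment at contacts.  The raw (undivided) contact/edge ratio is also
    returned.
    """
    contact = scan_mean(img, contact_scan, channel, width_px) - background
    edge = scan_mean(img, edge_scan, channel, width_px) - background
    if edge <= 0:
        warnings.warn("free-edge mean <= 0 after background subtraction", stacklevel=2)
        return EnrichmentResult(float("nan"), float("nan"))
    return EnrichmentResult(contact / (2.0 * edge), contact / edge)


# ---------------------------------------------------------------------------
# membrane-mask pipeline


@dataclass
class MembraneMaskResult:
    mask: np.ndarray
    peripheral_means: dict[str, float]  # cytoplasm-subtracted mean per channel
    stages: dict[str, int] = field(default_factory=dict)  # pixel counts per stage


def membrane_mask_quant(
    marker: np.ndarray,
    measure: Mapping[str, np.ndarray],
    sigma: float = 1.0,
    global_pct: float = 1.0,
    rolling_radius: int = 25,
    mask_thickness_px: int = 3,
) -> MembraneMaskResult:
    """Skeleton-based membrane mask and peripheral intensity measurement.

    The marker channel (a junctional marker such as beta-catenin) is
    Gaussian-filtered, background-subtracted twice (global: a low percentile
    of the whole image; local: rolling ball), Otsu-thresholded, skeletonized
    and dilated back to a ``mask_thickness_px``-pixel-thick band.  Each
    measured channel's mean inside the band is reported minus the cytoplasmic
    mean obtained through the complementary mask.

    Raises ``ValueError`` with per-stage pixel counts if the mask comes out
    empty.
    """
    m = np.asarray(marker, dtype=float)
    smoothed = gaussian(m, sigma=sigma, preserve_range=True)
    sub_global = smoothed - np.percentile(smoothed, global_pct)
    sub_global = np.maximum(sub_global, 0.0)
    background = rolling_ball(sub_global, radius=rolling_radius)
    sub_local = sub_global - background

    binary = sub_local > threshold_otsu(sub_local)
    skeleton = skeletonize(binary)
    n_dilations = max(0, (mask_thickness_px - 1) // 2)
    mask = skeleton
    for _ in range(n_dilations):
        mask = dilation(mask, footprint_rectangle((3, 3)))

    stages = {
        "binary_px": int(binary.sum()),
        "skeleton_px": int(skeleton.sum()),
        "mask_px": int(mask.sum()),
    }
    if not np.any(mask):
        raise ValueError(f"empty membrane mask; pipeline stages: {stages}")

    out: dict[str, float] = {}
    complement = ~mask
    for name, chan in measure.items():
        chan = np.asarray(chan, dtype=float)
        cyto = float(chan[complement].mean()) if np.any(complement) else 0.0
        out[name] = float(chan[mask].mean()) - cyto
    return MembraneMaskResult(mask=mask, peripheral_means=out, stages=stages)


# ---------------------------------------------------------------------------
# colocalization


class ColocalizationResult(NamedTuple):
    pearson: float
    m1: float
    m2: float


def colocalization(
    img_a: np.ndarray,
    img_b: np.ndarray,
    roi_mask: np.ndarray | None = None,
    thresholds: tuple[float, float] | None = None,
) -> ColocalizationResult:
    """Pearson and Manders coefficients of two channels within an ROI.

    ``M1`` is the fraction of channel-A intensity falling on pixels where
    channel B exceeds its threshold; ``M2`` is the converse.  Thresholds
    default to per-channel Otsu within the ROI.  A channel with zero variance
    leaves Pearson undefined (NaN, with a warning).
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must share dimensions")
    if roi_mask is None:
        roi_mask = np.ones(a.shape, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not np.any(roi_mask):
        raise ValueError("empty ROI")
    av, bv = a[roi_mask], b[roi_mask]

    da, db = av - av.mean(), bv - bv.mean()
    denom = np.sqrt((da**2).sum() * (db**2).sum())
    if denom == 0:
        warnings.warn("zero variance in a channel: Pearson undefined", stacklevel=2)
        pearson = float("nan")
    else:
        pearson = float((da * db).sum() / denom)

    if thresholds is None:
        ta = threshold_otsu(av) if av.min() < av.max() else av.max()
        tb = threshold_otsu(bv) if bv.min() < bv.max() else bv.max()
    else:
        ta, tb = thresholds
    sum_a, sum_b = av.sum(), bv.sum()
    m1 = float(av[bv > tb].sum() / sum_a) if sum_a > 0 else float("nan")
    m2 = float(bv[av > ta].sum() / sum_b) if sum_b > 0 else float("nan")
    return ColocalizationResult(pearson, m1, m2)


# ---------------------------------------------------------------------------
# morphometry and orientation


class MorphometryResult(NamedTuple):
    area_um2: float
    circularity: float
    ventral_to_max_ratio: float


def morphometry(
    ventral_mask: np.ndarray, maxproj_mask: np.ndarray, pixel_size_um: float
) -> MorphometryResult:
    """Ventral-surface area, circularity and ventral/maximal area ratio.

    Circularity is ``4 pi A / P^2`` (1 for a disc), computed with the Crofton
    perimeter estimate and clipped to (0, 1].  Blebs are expected to have
    been excluded from the masks upstream.
    """
    ventral = np.asarray(ventral_mask, dtype=bool)
    maxproj = np.asarray(maxproj_mask, dtype=bool)
    if not np.any(ventral) or not np.any(maxproj):
        raise ValueError("masks must be non-empty")
    area_px = float(ventral.sum())
    perim = float(perimeter_crofton(ventral, directions=4))
    circ = min(4.0 * np.pi * area_px / perim**2, 1.0) if perim > 0 else 1.0
    return MorphometryResult(
        area_um2=area_px * pixel_size_um**2,
        circularity=circ,
        ventral_to_max_ratio=area_px / float(maxproj.sum()),
    )


def orientation_angle(
    cell_axis_endpoints: Sequence[tuple[float, float]],
    interface_polyline: Sequence[tuple[float, float]],
) -> float:
    """Acute angle (degrees) between a cell's axis and the tissue interface.

    The interface tangent is taken from the polyline segment nearest to the
    axis midpoint; the result is folded into [0, 90].
    """
    (x0, y0), (x1, y1) = cell_axis_endpoints
    axis = np.array([x1 - x0, y1 - y0], dtype=float)
    if np.linalg.norm(axis) == 0:
        raise ValueError("axis endpoints must be distinct")
    poly = np.asarray(interface_polyline, dtype=float)
    if len(poly) < 2:
        raise ValueError("interface needs at least 2 points")
    segs = np.diff(poly, axis=0)
    lengths = np.linalg.norm(segs, axis=1)
    if np.all(lengths == 0):
        raise ValueError("degenerate interface segment")
    mid = 0.5 * (np.array([x0, y0]) + np.array([x1, y1]))
    centers = 0.5 * (poly[:-1] + poly[1:])
    valid = lengths > 0
    nearest = np.where(valid)[0][np.argmin(np.linalg.norm(centers[valid] - mid, axis=1))]
    tangent = segs[nearest] / lengths[nearest]
    cosang = abs(float(np.dot(axis / np.linalg.norm(axis), tangent)))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


# ---------------------------------------------------------------------------
# tracks, adhesion, morphology


@dataclass
class CellTrack:
    """Time-stamped cell positions with optional per-frame morphology labels."""

    cell_id: str
    frames: np.ndarray  # frame indices
    t_min: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    morphology: Sequence[str] | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        n = len(self.frames)
        if not (len(self.t_min) == len(self.x_um) == len(self.y_um) == n):
            raise ValueError("all per-frame arrays must have equal length")
        if self.morphology is not None and len(self.morphology) != n:
            raise ValueError("morphology labels must match the number of frames")


class TrackSpeedResult(NamedTuple):
    mean_speed: float  # um/min
    per_morphology: dict[str, float]


def track_speed(
    track: CellTrack, window_frames: tuple[int, int] = (10, 40)
) -> TrackSpeedResult:
    """Mean instantaneous speed (um/min) within a frame window.

    Speeds are computed between consecutive time points and averaged over the
    steps whose both endpoints lie within ``window_frames`` (inclusive) —
    frames 10 to 40 correspond to 25 to 100 min at 2.5 min/frame.  When
    morphology labels are present, steps within segments sharing a label are
    additionally averaged per category.  A track not fully covering the
    window is used on the available overlap, with a warning.
    """
    lo, hi = window_frames
    if track.frames[0] > lo or track.frames[-1] < hi:
        warnings.warn(
            f"track {track.cell_id} does not cover frames {lo}..{hi}; "
            "using the available overlap",
            stacklevel=2,
        )
    sel = (track.frames >= lo) & (track.frames <= hi)
    if sel.sum() < 2:
        raise ValueError("fewer than 2 frames in the analysis window")
    t = track.t_min[sel]
    x, y = track.x_um[sel], track.y_um[sel]
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("non-increasing time stamps")
    speeds = np.hypot(np.diff(x), np.diff(y)) / dt

    per_morph: dict[str, float] = {}
    if track.morphology is not None:
        labels = np.asarray(track.morphology)[sel]
        step_labels = labels[:-1]  # label at the step's start frame
        same = labels[:-1] == labels[1:]  # steps within one morphology segment
        for cat in np.unique(step_labels[same]):
            per_morph[str(cat)] = float(speeds[same & (step_labels == cat)].mean())
    return TrackSpeedResult(float(speeds.mean()), per_morph)


def adhesion_fraction(count_before: int, count_after: int) -> float:
    """Percentage of cells remaining adherent after the rotation assay."""
    if count_before <= 0:
        raise ValueError("count_before must be positive")
    if count_after > count_before:
        raise ValueError(f"miscount: {count_after} adherent after > {count_before} before")
    if count_after < 0:
        raise ValueError("count_after must be >= 0")
    return 100.0 * count_after / count_before


def adhesion_statistics(
    counts: Sequence[tuple[int, int]]
) -> tuple[np.ndarray, float, float]:
    """Per-experiment adhesion percentages with their mean and SD.

    Statistics are computed on the percentage per experiment (each experiment
    is the unit of replication, as in rotation-assay reporting).
    """
    pct = np.array([adhesion_fraction(b, a) for b, a in counts])
    return pct, float(pct.mean()), float(pct.std(ddof=1)) if len(pct) > 1 else float("nan")


def morphology_distribution(labels: Sequence[str]) -> dict[str, float]:
    """Percentage of cells per morphology category at a reference frame.

    Categories: ``b`` round-and-blebbing, ``r`` round, ``p`` polarized,
    ``s`` spread, ``pb`` polarized-with-bleb.  Percentages sum to 100.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("no labels given")
    unknown = sorted(set(labels) - set(MORPHOLOGY_CATEGORIES))
    if unknown:
        raise ValueError(f"unknown morphology labels: {unknown}")
    n = len(labels)
    return {cat: 100.0 * labels.count(cat) / n for cat in MORPHOLOGY_CATEGORIES}
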