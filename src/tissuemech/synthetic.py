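"""Synthetic-data generators with known ground truth.

Every input class consumed by the analysis modules can be generated here:
doublet outlines from prescribed tensions (Young-Laplace circular-arc
geometry), micropipette-aspiration creep traces from the viscous-flow model,
nuclei point clouds undergoing scaling/dispersion/intercalation, and
single/dual-channel intensity images with membrane, cytoplasm and
adhesion-cluster compartments.  All generators are deterministic given
``(params, seed)`` and store their ground truth next to the generated data,
so downstream estimators can be validated by round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay
from skimage.draw import disk as _disk, polygon as _polygon
from skimage.morphology import dilation, footprint_rectangle

from .doublet import check_neumann_domain, neumann_angles

__all__ = [
    "DoubletParams",
    "DoubletGeometry",
    "simulate_doublet",
    "AspirationParams",
    "AspirationTrace",
    "simulate_aspiration",
    "NucleiSimParams",
    "NucleiFrames",
    "simulate_nuclei_timecourse",
    "CellImageSpec",
    "QuantImage",
    "render_cell_image",
]


# ---------------------------------------------------------------------------
# cell doublets


@dataclass(frozen=True)
class DoubletParams:
    """Ground-truth mechanical parameters of a two-cell doublet.

    Tensions are in arbitrary (relative) units; only ratios matter.  The
    triple must satisfy the Neumann validity domain
    ``|ct_a - ct_b| < t_ab < ct_a + ct_b``.
    """

    ct_a: float
    ct_b: float
    t_ab: float
    radius_a: float = 50.0  # free-surface radius of curvature, um
    n_points: int = 200  # samples per arc
    jitter_sd: float = 0.0  # positional noise, um
    seed: int = 0

    def __post_init__(self) -> None:
        check_neumann_domain(self.ct_a, self.ct_b, self.t_ab)
        if self.n_points < 30:
            raise ValueError("n_points must be >= 30")
        if self.radius_a <= 0:
            raise ValueError("radius_a must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


@dataclass
class DoubletGeometry:
    """Sampled 2-D doublet outline: three arcs meeting at two vertices.

    ``arcs`` maps ``"freeA"``, ``"freeB"``, ``"contact"`` to ``(n, 2)`` micron
    coordinate arrays, each ordered from vertex 0 (top) to vertex 1 (bottom).
    ``ground_truth`` records the generating tensions, the closed-form angles
    and the arc curvature radii.
    """

    arcs: dict[str, np.ndarray]
    vertices: np.ndarray
    ground_truth: dict = field(default_factory=dict)


def _arc_points(
    center: np.ndarray, radius: float, ang0: float, ang1: float, n: int
) -> np.ndarray:
    ang = np.linspace(ang0, ang1, n)
    return center + radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)


def simulate_doublet(params: DoubletParams) -> DoubletGeometry:
    """Generate a doublet outline whose vertex angles satisfy the Neumann laws.

    Construction
    ------------
    The contact chord is placed on the y-axis with vertices at ``(0, +-h)``.
    Both free surfaces are given the same radius of curvature ``radius_a``,
    which fixes the internal pressures through Young-Laplace
    (``P_X = Ct_X / radius_a``); the contact interface then carries the
    signed curvature ``(P_A - P_B)/T_AB``, bulging into the lower-tension
    cell.  With the Neumann angles ``theta_A, theta_B`` this closure is
    exactly self-consistent and closed-form:

    - mean angle ``phi = (theta_A + theta_B)/2``; half-chord ``h = radius_a sin(phi)``
    - contact tangent tilt at a vertex ``beta = (theta_B - theta_A)/2``
    - contact radius ``R_c = h / |sin(beta)|`` (straight when ``beta == 0``)

    Cell A occupies ``x < 0``, cell B ``x > 0``.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    theta_a, theta_b = neumann_angles(p.ct_a, p.ct_b, p.t_ab)
    phi = np.radians(0.5 * (theta_a + theta_b))
    beta = np.radians(0.5 * (theta_b - theta_a))
    r = p.radius_a
    h = r * np.sin(phi)
    v_top = np.array([0.0, h])
    v_bot = np.array([0.0, -h])

    # free arc A: circle centered on the x-axis at -r*cos(phi), the arc left
    # of the chord, sampled from the top vertex around to the bottom vertex
    c_a = np.array([-r * np.cos(phi), 0.0])
    ang_top = np.arctan2(h - c_a[1], 0.0 - c_a[0])  # position angle of v_top
    free_a = _arc_points(c_a, r, ang_top, 2.0 * np.pi - ang_top, p.n_points)
    # free arc B: mirror image (x -> -x), same ordering top -> bottom
    c_b = np.array([r * np.cos(phi), 0.0])
    free_b = free_a.copy() * np.array([-1.0, 1.0])

    if abs(np.sin(beta)) < 1e-12:
        contact = np.stack(
            [np.zeros(p.n_points), np.linspace(h, -h, p.n_points)], axis=1
        )
        r_c = np.inf
    else:
        r_c = h / abs(np.sin(beta))
        d = np.sqrt(r_c**2 - h**2)
        if beta > 0:
            # interface bulges toward B (+x): center on A's side, minor arc
            # sampled clockwise through the rightmost point
            c_c = np.array([-d, 0.0])
            a0 = np.arctan2(h, d)
            contact = _arc_points(c_c, r_c, a0, -a0, p.n_points)
        else:
            # bulges toward A (-x): mirrored, counterclockwise through the left
            c_c = np.array([d, 0.0])
            a0 = np.arctan2(h, -d)
            contact = _arc_points(c_c, r_c, a0, 2.0 * np.pi - a0, p.n_points)

    if p.jitter_sd > 0:
        for arr in (free_a, free_b, contact):
            arr += rng.normal(0.0, p.jitter_sd, size=arr.shape)

    gt = {
        "ct_a": p.ct_a,
        "ct_b": p.ct_b,
        "t_ab": p.t_ab,
        "theta_a_deg": theta_a,
        "theta_b_deg": theta_b,
        "radius_free_um": r,
        "radius_contact_um": float(r_c),
        "half_chord_um": float(h),
        "seed": p.seed,
    }
    return DoubletGeometry(
        arcs={"freeA": free_a, "freeB": free_b, "contact": contact},
        vertices=np.stack([v_top, v_bot]),
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# micropipette aspiration


@dataclass(frozen=True)
class AspirationParams:
    """Ground truth for a simulated aspiration/release experiment.

    The slow phases follow the viscous-flow model used for tissue aggregates:
    aspiration advances at ``v_asp = R_p (dP - P_c) / (3 pi eta)`` and, after
    pressure release, the tongue retracts at ``v_ret = R_p P_c / (3 pi eta)``
    where ``P_c = 2 gamma (1/R_p - 1/R_0)`` is the critical pressure.  The
    fast elastic response is modelled as a single-exponential jump of
    amplitude ``l_fast`` and time constant ``tau_fast``; the analysis modules
    must not depend on that particular form.
    """

    eta: float = 1.3e4  # tissue viscosity, Pa s
    gamma: float = 5.0  # tissue surface tension, mN/m
    r_p: float = 50.0  # pipette radius, um
    r_0: float = 150.0  # explant radius, um
    delta_p: float = 250.0  # applied pressure, Pa
    l_fast: float = 20.0  # elastic jump amplitude, um
    tau_fast: float = 4.0  # elastic time constant, s
    t_release: float = 240.0  # pressure reset time, s
    t_end: float = 480.0  # end of trace, s
    dt: float = 1.0  # sampling interval, s
    noise_sd: float = 0.0  # additive noise, um
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not self.r_0 > self.r_p > 0:
            raise ValueError("need r_0 > r_p > 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.t_release < self.t_end:
            raise ValueError("t_release must precede t_end")
        if self.l_fast < 0 or self.tau_fast < 0:
            raise ValueError("l_fast and tau_fast must be >= 0")
        if self.critical_pressure >= self.delta_p:
            raise ValueError(
                f"no aspiration at this pressure: P_c={self.critical_pressure:.1f} Pa "
                f">= delta_p={self.delta_p} Pa"
            )

    @property
    def critical_pressure(self) -> float:
        """``P_c = 2 gamma (1/R_p - 1/R_0)`` in Pa (gamma mN/m, radii um)."""
        return 2.0 * self.gamma * 1e-3 * (1.0 / self.r_p - 1.0 / self.r_0) * 1e6

    @property
    def v_asp(self) -> float:
        """Slow aspiration rate, um/s."""
        return self.r_p * (self.delta_p - self.critical_pressure) / (3.0 * np.pi * self.eta)

    @property
    def v_ret(self) -> float:
        """Slow retraction rate, um/s."""
        return self.r_p * self.critical_pressure / (3.0 * np.pi * self.eta)


@dataclass
class AspirationTrace:
    """Tongue-length trace ``L(t)`` with its pressure protocol."""

    t_s: np.ndarray
    l_um: np.ndarray
    delta_p: float
    t_release: float
    r_p: float
    r_0: float
    clipped: bool = False  # retraction reached L = 0 and was floored
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.l_um = np.asarray(self.l_um, dtype=float)
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("t_s must be strictly increasing")
        if not self.r_0 > self.r_p > 0:
            raise ValueError("need r_0 > r_p > 0")
        if not (self.t_s[0] <= self.t_release <= self.t_s[-1]):
            raise ValueError("t_release must lie within the trace")

    @property
    def pressure_pa(self) -> np.ndarray:
        return np.where(self.t_s < self.t_release, self.delta_p, 0.0)


def simulate_aspiration(params: AspirationParams) -> AspirationTrace:
    """Simulate a creep/release trace from the viscous-flow model.

    ``L(t) = l_fast (1 - exp(-t/tau)) + v_asp t`` during aspiration; after
    release the tongue recoils elastically by ``l_fast`` (same time constant)
    and then retracts linearly at ``v_ret``, floored at zero deformation
    (``clipped`` is set when the floor is reached).
    """
    p = params
    rng = np.random.default_rng(p.seed)
    t = np.arange(0.0, p.t_end + 0.5 * p.dt, p.dt)
    asp = t < p.t_release

    def jump(tau: float, tt: np.ndarray) -> np.ndarray:
        if tau <= 0:
            return np.ones_like(tt)
        return 1.0 - np.exp(-tt / tau)

    l = np.empty_like(t)
    l[asp] = p.l_fast * jump(p.tau_fast, t[asp]) + p.v_asp * t[asp]
    l_rel = p.l_fast * jump(p.tau_fast, p.t_release) + p.v_asp * p.t_release
    dt_rel = t[~asp] - p.t_release
    l[~asp] = l_rel - p.l_fast * jump(p.tau_fast, dt_rel) - p.v_ret * dt_rel
    clipped = bool(np.any(l < 0.0))
    l = np.maximum(l, 0.0)
    if p.noise_sd > 0:
        l = l + rng.normal(0.0, p.noise_sd, size=l.shape)

    gt = {
        "eta_pa_s": p.eta,
        "gamma_mn_m": p.gamma,
        "p_c_pa": p.critical_pressure,
        "v_asp_um_s": p.v_asp,
        "v_ret_um_s": p.v_ret,
        "l_fast_um": p.l_fast,
        "tau_fast_s": p.tau_fast,
        "seed": p.seed,
    }
    return AspirationTrace(
        t_s=t,
        l_um=l,
        delta_p=p.delta_p,
        t_release=p.t_release,
        r_p=p.r_p,
        r_0=p.r_0,
        clipped=clipped,
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# nuclei time courses


@dataclass(frozen=True)
class NucleiSimParams:
    """Parameters of a scaling/intercalating nuclei point-cloud time course."""

    n0: int = 40  # initial basal nuclei
    frames: int = 57  # 2.5-min frames cover 0..140 min; 69 cover 0..170
    frame_interval_min: float = 2.5
    scale_per_frame: float = 1.0  # isotropic expansion factor per frame
    intercalation_per_frame: float = 0.0  # Poisson rate of new basal nuclei
    jitter_sd: float = 0.0  # Brownian jitter, um
    n_upper: int = 0  # static upper-layer nuclei
    extent_um: float = 150.0  # half-width of the initial uniform cloud
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n0 < 3:
            raise ValueError("n0 must be >= 3")
        if self.scale_per_frame <= 0:
            raise ValueError("scale_per_frame must be positive")
        if self.frames < 1:
            raise ValueError("frames must be >= 1")
        if self.intercalation_per_frame < 0 or self.jitter_sd < 0:
            raise ValueError("rates and noise must be >= 0")


@dataclass
class NucleiFrames:
    """Per-frame nuclei coordinates in tidy form.

    ``table`` columns: ``frame``, ``t_min``, ``nucleus_id``, ``x_um``,
    ``y_um``, ``layer`` (``basal`` or ``upper``).
    """

    table: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)

    def frame_at(self, t_min: float, tol_min: float | None = None) -> pd.DataFrame:
        """Rows of the frame nearest to ``t_min`` (within ``tol_min`` if given)."""
        times = np.sort(self.table["t_min"].unique())
        i = int(np.argmin(np.abs(times - t_min)))
        if tol_min is not None and abs(times[i] - t_min) > tol_min:
            raise ValueError(
                f"no frame within {tol_min} min of t={t_min} min (nearest: {times[i]})"
            )
        return self.table[self.table["t_min"] == times[i]]


def simulate_nuclei_timecourse(params: NucleiSimParams) -> NucleiFrames:
    """Simulate nuclei positions under expansion, jitter and intercalation.

    Frame ``k`` positions are frame-0 positions scaled by
    ``scale_per_frame**k`` about the cloud centroid, plus Gaussian jitter.
    Each frame, ``Poisson(intercalation_per_frame)`` new nuclei join the
    basal layer, placed uniformly inside the current convex hull.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    base = rng.uniform(-p.extent_um, p.extent_um, size=(p.n0, 2))
    centroid = base.mean(axis=0)
    upper = rng.uniform(-p.extent_um, p.extent_um, size=(p.n_upper, 2))

    rows: list[dict] = []
    n_added_per_frame: list[int] = []
    new_pts: list[np.ndarray] = []  # frame-0-equivalent coordinates of intercalated nuclei
    next_id = p.n0 + p.n_upper
    for k in range(p.frames):
        s = p.scale_per_frame**k
        t_min = k * p.frame_interval_min
        pts0 = np.vstack([base] + new_pts) if new_pts else base
        pts = centroid + (pts0 - centroid) * s
        if p.jitter_sd > 0:
            pts = pts + rng.normal(0.0, p.jitter_sd, size=pts.shape)
        for j, (x, y) in enumerate(pts):
            rows.append(
                {
                    "frame": k,
                    "t_min": t_min,
                    "nucleus_id": j if j < p.n0 else p.n0 + p.n_upper + (j - p.n0),
                    "x_um": x,
                    "y_um": y,
                    "layer": "basal",
                }
            )
        up = centroid + (upper - centroid) * s
        for j, (x, y) in enumerate(up):
            rows.append(
                {
                    "frame": k,
                    "t_min": t_min,
                    "nucleus_id": p.n0 + j,
                    "x_um": x,
                    "y_um": y,
                    "layer": "upper",
                }
            )
        # intercalation happening during this frame appears from the next one
        n_new = int(rng.poisson(p.intercalation_per_frame))
        n_added_per_frame.append(n_new)
        if n_new > 0:
            hull = ConvexHull(pts)
            tri = Delaunay(pts[hull.vertices])
            added = _uniform_in_hull(rng, tri, n_new)
            # store de-scaled so future scaling applies about the centroid
            new_pts.append(centroid + (added - centroid) / s)
            next_id += n_new

    gt = {
        "n0": p.n0,
        "n_upper": p.n_upper,
        "scale_per_frame": p.scale_per_frame,
        "n_added_per_frame": n_added_per_frame,
        "seed": p.seed,
    }
    return NucleiFrames(table=pd.DataFrame(rows), ground_truth=gt)


def _uniform_in_hull(rng: np.random.Generator, tri: Delaunay, n: int) -> np.ndarray:
    """Draw ``n`` points uniformly inside a Delaunay-triangulated hull."""
    simplices = tri.points[tri.simplices]
    a = simplices[:, 0]
    edges = simplices[:, 1:] - simplices[:, [0]]
    e0, e1 = edges[:, 0], edges[:, 1]
    areas = 0.5 * np.abs(e0[:, 0] * e1[:, 1] - e0[:, 1] * e1[:, 0])
    which = rng.choice(len(areas), size=n, p=areas / areas.sum())
    u, v = rng.uniform(size=(2, n))
    flip = u + v > 1
    u[flip], v[flip] = 1 - u[flip], 1 - v[flip]
    return a[which] + u[:, None] * edges[which, 0] + v[:, None] * edges[which, 1]


# ---------------------------------------------------------------------------
# quantification images


@dataclass(frozen=True)
class CellImageSpec:
    """Blueprint of a synthetic fluorescence image of one cell.

    The cell body is a polygon filled at ``cytoplasm_value`` on a
    ``background_value`` field; membrane/cortex polylines are rasterized at
    ``membrane_value`` with the given thickness, and adhesion clusters are
    filled discs at ``cluster_value``.  Where compartments overlap, the pixel
    takes the maximum of the competing values.
    """

    shape_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.5
    membrane_value: float = 100.0
    cytoplasm_value: float = 20.0
    background_value: float = 0.0
    cluster_value: float = 200.0
    cell_polygon: Sequence[tuple[float, float]] | None = None  # (row, col) px
    cluster_centers: Sequence[tuple[float, float]] = ()  # (row, col) px
    cluster_radius_px: float = 6.0
    contact_segments: Sequence[Sequence[tuple[float, float]]] = ()
    free_edge_segments: Sequence[Sequence[tuple[float, float]]] = ()
    membrane_thickness_px: int = 3
    noise_model: Literal["none", "gaussian", "poisson"] = "none"
    noise_sd: float = 2.0  # gaussian noise level, intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("membrane_value", "cytoplasm_value", "background_value", "cluster_value"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class QuantImage:
    """Pixel-size-calibrated intensity image with named channels and masks."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share dimensions")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


def _polyline_mask(
    shape: tuple[int, int],
    polyline: Sequence[tuple[float, float]],
    thickness_px: int,
) -> np.ndarray:
    from skimage.draw import line as _line

    mask = np.zeros(shape, dtype=bool)
    pts = np.asarray(polyline, dtype=float)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = _line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[ok], cc[ok]] = True
    if thickness_px > 1:
        mask = dilation(mask, footprint_rectangle((thickness_px, thickness_px)))
    return mask


def render_cell_image(spec: CellImageSpec) -> QuantImage:
    """Rasterize a :class:`CellImageSpec` into a single-channel image.

    Returns a :class:`QuantImage` with channel ``"signal"`` and ground-truth
    masks ``"ventral"`` (cell body), ``"membrane"`` and ``"clusters"``.
    Overlapping compartments take the maximum of their values.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape_px)
    img = np.full(shape, float(spec.background_value))

    ventral = np.zeros(shape, dtype=bool)
    if spec.cell_polygon is not None:
        poly = np.asarray(spec.cell_polygon, dtype=float)
        rr, cc = _polygon(poly[:, 0], poly[:, 1], shape=shape)
        ventral[rr, cc] = True
        img[ventral] = np.maximum(img[ventral], spec.cytoplasm_value)

    membrane = np.zeros(shape, dtype=bool)
    for seg in list(spec.contact_segments) + list(spec.free_edge_segments):
        membrane |= _polyline_mask(shape, seg, spec.membrane_thickness_px)
    img[membrane] = np.maximum(img[membrane], spec.membrane_value)

    clusters = np.zeros(shape, dtype=bool)
    for center in spec.cluster_centers:
        rr, cc = _disk(center, spec.cluster_radius_px, shape=shape)
        clusters[rr, cc] = True
    img[clusters] = np.maximum(img[clusters], spec.cluster_value)

    if spec.noise_model == "gaussian":
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    elif spec.noise_model == "poisson":
        img = rng.poisson(np.maximum(img, 0.0)).astype(float)
    elif spec.noise_model != "none":
        raise ValueError(f"unknown noise model: {spec.noise_model!r}")

    return QuantImage(
        channels={"signal": img},
        pixel_size_um=spec.pixel_size_um,
        masks={"ventral": ventral | membrane | clusters, "membrane": membrane, "clusters": clusters},
    )
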