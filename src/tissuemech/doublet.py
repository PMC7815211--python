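"""Tension inference from cell-doublet vertex geometry.

A doublet of two adherent cells is governed, at each of its two contact
vertices, by the balance of three interfacial tensions: the cortical tensions
``Ct_A`` and ``Ct_B`` acting along the free surfaces and the contact tension
``T_AB`` acting along the cell-cell interface.  In mechanical equilibrium the
three tension vectors close a triangle (the Neumann triangle), which ties the
interfacial angles to the tension magnitudes:

.. math::

    \\cos\\theta_A = \\frac{T_{AB}^2 + Ct_A^2 - Ct_B^2}{2\\,T_{AB}\\,Ct_A}

and symmetrically for :math:`\\theta_B`, where :math:`\\theta_X` is the angle
between cell X's free-surface tangent and the continuation of the contact
interface beyond the vertex.  Resolving the balance normal and tangential to
the contact gives the two inverse relations implemented here:

- ``Ct_A / Ct_B = sin(theta_B) / sin(theta_A)``   (normal balance)
- ``T_AB = Ct_A cos(theta_A) + Ct_B cos(theta_B)``  (tangential balance)

For homotypic doublets (``Ct_A == Ct_B``) the contact tension can be written
``T = 2 Ct cos(theta)`` with the symmetric contact angle
``theta = (theta_A + theta_B)/2``, and the reduction of interfacial tension by
adhesion is summarised by the adhesiveness index ``alpha = 1 - cos(theta)``,
which runs from 0 (no adhesion, vanishing contact) to 1 (maximal adhesion,
90-degree contact angle).

Angles are measured on sampled outlines by total-least-squares circle fits to
a fractional window of each arc next to the vertex; tangents are taken from
the fitted circles, so curved contact interfaces (heterotypic doublets) are
handled without a chord approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "VertexAngles",
    "neumann_angles",
    "check_neumann_domain",
    "NeumannDomainError",
    "measure_vertex_angles",
    "tension_ratio",
    "contact_tension",
    "adhesiveness",
    "condition_statistics",
    "fit_circle",
]

#: sin(theta) below which the normal force balance is numerically undefined
SIN_TOL = 1e-3


class NeumannDomainError(ValueError):
    """Tension triple outside the domain where a stable contact exists."""


def check_neumann_domain(ct_a: float, ct_b: float, t_ab: float) -> None:
    """Validate ``|Ct_A - Ct_B| < T_AB < Ct_A + Ct_B`` (triangle inequality).

    ``T_AB >= Ct_A + Ct_B`` means the contact shrinks to a point (no stable
    contact); ``T_AB <= |Ct_A - Ct_B|`` is the engulfment limit where one cell
    spreads over the other completely.
    """
    if ct_a <= 0 or ct_b <= 0 or t_ab <= 0:
        raise NeumannDomainError("tensions must be positive")
    if t_ab >= ct_a + ct_b:
        raise NeumannDomainError(
            f"no stable contact: T_AB={t_ab} >= Ct_A+Ct_B={ct_a + ct_b} (point contact)"
        )
    if t_ab <= abs(ct_a - ct_b):
        raise NeumannDomainError(
            f"no stable contact: T_AB={t_ab} <= |Ct_A-Ct_B|={abs(ct_a - ct_b)} (engulfment limit)"
        )


def neumann_angles(ct_a: float, ct_b: float, t_ab: float) -> tuple[float, float]:
    """Forward Neumann relations: interfacial angles (degrees) from tensions.

    Returns ``(theta_a, theta_b)``, each the angle between the corresponding
    free-surface tangent and the contact continuation at a vertex.
    """
    check_neumann_domain(ct_a, ct_b, t_ab)
    cos_a = (t_ab**2 + ct_a**2 - ct_b**2) / (2.0 * t_ab * ct_a)
    cos_b = (t_ab**2 + ct_b**2 - ct_a**2) / (2.0 * t_ab * ct_b)
    return (
        float(np.degrees(np.arccos(np.clip(cos_a, -1.0, 1.0)))),
        float(np.degrees(np.arccos(np.clip(cos_b, -1.0, 1.0)))),
    )


@dataclass
class VertexAngles:
    """Interfacial angles measured at one doublet vertex (degrees)."""

    theta_a: float
    theta_b: float
    bleb_adjacent: bool = False
    vertex_id: str = ""
    doublet_id: str = ""

    def __post_init__(self) -> None:
        for name, th in (("theta_a", self.theta_a), ("theta_b", self.theta_b)):
            if not (0.0 < th < 180.0):
                raise ValueError(f"{name}={th} outside (0, 180) degrees")


# ---------------------------------------------------------------------------
# circle fitting


def fit_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Total-least-squares (geometric) circle fit.

    Parameters
    ----------
    points : (n, 2) array
        Sampled arc points, ``n >= 3``.

    Returns
    -------
    center : (2,) array
    radius : float

    Raises
    ------
    ValueError
        If fewer than 3 points are given or the points are collinear (the
        caller is expected to fall back to a line fit).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("circle fit needs an (n>=3, 2) point array")

    # Kasa linear fit for the initial center
    x, y = pts[:, 0], pts[:, 1]
    mx, my = x.mean(), y.mean()
    u, v = x - mx, y - my
    Suu, Svv, Suv = (u * u).sum(), (v * v).sum(), (u * v).sum()
    Suuu, Svvv = (u**3).sum(), (v**3).sum()
    Suvv, Svuu = (u * v * v).sum(), (v * u * u).sum()
    A = np.array([[Suu, Suv], [Suv, Svv]])
    b = 0.5 * np.array([Suuu + Suvv, Svvv + Svuu])
    det = np.linalg.det(A)
    scale = max(Suu, Svv)
    if scale <= 0 or abs(det) < 1e-12 * scale**2:
        raise ValueError("collinear points: circle fit degenerate")
    c0 = np.linalg.solve(A, b)

    def resid(c: np.ndarray) -> np.ndarray:
        d = np.hypot(x - c[0] - mx, y - c[1] - my)
        return d - d.mean()

    sol = least_squares(resid, c0, method="lm")
    center = sol.x + np.array([mx, my])
    radius = float(np.hypot(x - center[0], y - center[1]).mean())
    return center, radius


def _tangent_at_vertex(arc: np.ndarray, vertex: np.ndarray, window_frac: float) -> np.ndarray:
    """Unit tangent of an arc at ``vertex``, pointing into the arc.

    The arc must be ordered so that one of its ends coincides with the vertex.
    A circle is fitted to the points within ``window_frac`` of the arc length
    from the vertex; degenerate (collinear) windows fall back to a straight
    line fit.
    """
    arc = np.asarray(arc, dtype=float)
    if len(arc) < 3:
        raise ValueError("arc has fewer than 3 points")
    # orient arc so it starts at the vertex
    if np.linalg.norm(arc[-1] - vertex) < np.linalg.norm(arc[0] - vertex):
        arc = arc[::-1]
    seg = np.linalg.norm(np.diff(arc, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    window = arc[s <= max(window_frac * s[-1], s[2] if len(s) > 2 else s[-1])]
    if len(window) < 3:
        window = arc[:3]

    chord = window.mean(axis=0) - vertex
    try:
        center, _ = fit_circle(window)
        radial = vertex - center
        tangent = np.array([-radial[1], radial[0]])
    except ValueError:
        # straight interface: principal direction of the window
        d = window - window.mean(axis=0)
        _, _, vt = np.linalg.svd(d, full_matrices=False)
        tangent = vt[0]
    tangent = tangent / np.linalg.norm(tangent)
    if np.dot(tangent, chord) < 0:
        tangent = -tangent
    return tangent


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    cosang = np.clip(np.dot(u, v), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def measure_vertex_angles(
    geometry,
    fit_window_frac: float = 0.2,
    doublet_id: str = "",
    bleb_adjacent: tuple[bool, bool] = (False, False),
) -> list[VertexAngles]:
    """Measure ``theta_A`` and ``theta_B`` at both vertices of a doublet outline.

    Parameters
    ----------
    geometry
        Object with attributes ``arcs`` (mapping with keys ``"freeA"``,
        ``"freeB"``, ``"contact"``, each an ``(n, 2)`` micron coordinate
        array ordered from vertex 1 to vertex 2) and ``vertices``
        (``(2, 2)`` array), e.g. a
        :class:`tissuemech.synthetic.DoubletGeometry`.
    fit_window_frac : float
        Fraction of each arc's length, adjacent to the vertex, used for the
        tangent-defining circle fit.
    bleb_adjacent : pair of bool
        Flags marking vertices flanked by a bleb; such vertices are excluded
        from all downstream tension statistics.

    Returns
    -------
    list of :class:`VertexAngles`, one per vertex.

    Notes
    -----
    ``theta_X`` is the unsigned angle between cell X's free-surface tangent
    (pointing away from the vertex along the arc) and the continuation of the
    contact interface beyond the vertex, both obtained from circle fits.
    """
    arcs = geometry.arcs
    vertices = np.asarray(geometry.vertices, dtype=float)
    out: list[VertexAngles] = []
    for i, vertex in enumerate(vertices):
        t_a = _tangent_at_vertex(np.asarray(arcs["freeA"]), vertex, fit_window_frac)
        t_b = _tangent_at_vertex(np.asarray(arcs["freeB"]), vertex, fit_window_frac)
        t_c = _tangent_at_vertex(np.asarray(arcs["contact"]), vertex, fit_window_frac)
        # contact continuation beyond the vertex = -t_c
        theta_a = _angle_between(t_a, -t_c)
        theta_b = _angle_between(t_b, -t_c)
        out.append(
            VertexAngles(
                theta_a=theta_a,
                theta_b=theta_b,
                bleb_adjacent=bool(bleb_adjacent[i]),
                vertex_id=f"v{i}",
                doublet_id=doublet_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# inverse force balance


def tension_ratio(angles: VertexAngles) -> float:
    """``Ct_A / Ct_B`` from the force balance normal to the contact.

    Returns NaN (with a warning) when either angle is so close to 0 or 180
    degrees that its sine falls below ``SIN_TOL``.
    """
    if angles.bleb_adjacent:
        raise ValueError("bleb-adjacent vertex: excluded from tension statistics")
    sin_a = np.sin(np.radians(angles.theta_a))
    sin_b = np.sin(np.radians(angles.theta_b))
    if sin_a < SIN_TOL or sin_b < SIN_TOL:
        warnings.warn(
            f"vertex {angles.vertex_id}: angle too close to 0/180 deg, ratio undefined",
            stacklevel=2,
        )
        return float("nan")
    return float(sin_b / sin_a)


def contact_tension(angles: VertexAngles, ct_a: float, ct_b: float) -> float:
    """``T_AB = Ct_A cos(theta_A) + Ct_B cos(theta_B)`` (tangential balance).

    ``ct_a`` and ``ct_b`` must be expressed in a common (relative) unit; the
    returned contact tension is in that same unit.
    """
    return float(
        ct_a * np.cos(np.radians(angles.theta_a)) + ct_b * np.cos(np.radians(angles.theta_b))
    )


def adhesiveness(angles: VertexAngles, asym_tol_deg: float = 15.0) -> float:
    """Adhesiveness ``alpha = 1 - cos(theta)`` for a homotypic vertex.

    ``theta`` is the mean of the two measured angles.  Homotypic doublets are
    assumed symmetric (``Ct_A == Ct_B``); a measured asymmetry larger than
    ``asym_tol_deg`` triggers a warning since it violates that assumption.
    The result is clamped to [0, 1].
    """
    if angles.bleb_adjacent:
        raise ValueError("bleb-adjacent vertex: excluded from tension statistics")
    if abs(angles.theta_a - angles.theta_b) > asym_tol_deg:
        warnings.warn(
            f"vertex {angles.vertex_id}: |theta_A - theta_B| = "
            f"{abs(angles.theta_a - angles.theta_b):.1f} deg exceeds the homotypic "
            f"symmetry tolerance ({asym_tol_deg} deg)",
            stacklevel=2,
        )
    theta = 0.5 * (angles.theta_a + angles.theta_b)
    return float(np.clip(1.0 - np.cos(np.radians(theta)), 0.0, 1.0))


# ---------------------------------------------------------------------------
# cohort aggregation


@dataclass
class ConditionSummary:
    """Per-condition tension statistics (medians of per-doublet values)."""

    table: pd.DataFrame
    reference_condition: str
    excluded_vertices: list[str] = field(default_factory=list)


def condition_statistics(
    estimates: pd.DataFrame,
    reference_condition: str,
    ct_scale: Mapping[str, float] | None = None,
) -> ConditionSummary:
    """Aggregate per-vertex estimates to per-doublet and per-condition values.

    Parameters
    ----------
    estimates : DataFrame
        Per-vertex rows with columns ``condition``, ``doublet_id``,
        ``vertex_id``, ``bleb_adjacent`` and any of ``ct_ratio``, ``t_ab``,
        ``alpha``.
    reference_condition : str
        Condition whose median contact tension defines ``rel_t = 1``.
    ct_scale : mapping, optional
        Relative cortical tension per condition (e.g. chained from
        heterotypic ``ct_ratio`` measurements against the reference cell
        type).  ``t_ab`` values are multiplied by it before aggregation, so
        contact tensions measured in per-condition cortical units are brought
        to the reference unit.

    Returns
    -------
    :class:`ConditionSummary` whose ``table`` is indexed by condition with
    columns ``n_doublets``, ``n_vertices`` and the medians ``ct_ratio``,
    ``t_ab``, ``rel_t``, ``alpha`` (where the inputs carried them).

    Notes
    -----
    Per-doublet values are the mean of the doublet's valid (non-bleb)
    vertices; per-condition values are the median over doublets, matching how
    doublet cohorts are commonly reported.
    """
    df = estimates.copy()
    required = {"condition", "doublet_id", "bleb_adjacent"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"estimates missing columns: {sorted(missing)}")

    excluded = df[df["bleb_adjacent"].astype(bool)]
    excluded_ids = [
        f"{r.doublet_id}/{getattr(r, 'vertex_id', '?')}" for r in excluded.itertuples()
    ]
    valid = df[~df["bleb_adjacent"].astype(bool)]
    if valid.empty:
        raise ValueError(
            "no valid vertices remain after bleb exclusion; excluded: "
            + ", ".join(excluded_ids)
        )

    metrics = [c for c in ("ct_ratio", "t_ab", "alpha") if c in valid.columns]
    if ct_scale is not None and "t_ab" in metrics:
        valid = valid.assign(
            t_ab=valid["t_ab"] * valid["condition"].map(lambda c: ct_scale.get(c, 1.0))
        )

    per_doublet = (
        valid.groupby(["condition", "doublet_id"])[metrics].mean().reset_index()
    )
    grouped = per_doublet.groupby("condition")
    table = grouped[metrics].median()
    table["n_doublets"] = grouped.size()
    table["n_vertices"] = valid.groupby("condition").size()

    if reference_condition not in table.index:
        raise ValueError(f"reference condition {reference_condition!r} not present")
    if int(table.loc[reference_condition, "n_vertices"]) < 3:
        raise ValueError(
            f"reference condition {reference_condition!r} has fewer than 3 valid vertices"
        )
    if "t_ab" in metrics:
        ref_t = table.loc[reference_condition, "t_ab"]
        if ref_t <= 0:
            raise ValueError("reference condition median contact tension is not positive")
        table["rel_t"] = table["t_ab"] / ref_t
    return ConditionSummary(
        table=table, reference_condition=reference_condition, excluded_vertices=excluded_ids
    )


def angles_table(
    angle_sets: Sequence[VertexAngles], condition: str = ""
) -> pd.DataFrame:
    """Tidy per-vertex DataFrame (ct_ratio, t_ab in Ct units, alpha) from angles."""
    rows = []
    for a in angle_sets:
        row = {
            "condition": condition,
            "doublet_id": a.doublet_id,
            "vertex_id": a.vertex_id,
            "theta_a_deg": a.theta_a,
            "theta_b_deg": a.theta_b,
            "bleb_adjacent": a.bleb_adjacent,
        }
        if not a.bleb_adjacent:
            row["ct_ratio"] = tension_ratio(a)
            # homotypic convention: tensions in units of the condition's Ct
            row["t_ab"] = contact_tension(a, 1.0, 1.0)
            row["alpha"] = adhesiveness(a)
        rows.append(row)
    return pd.DataFrame(rows)
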