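"""Parametric synthetic femora, plates, and cohorts.

The study protocol (plate positioning, distance measurement, bow radius,
cohort statistics) needs bone and plate surface models with controllable
geometry.  This module generates:

* **Femora** — an idealized long bone: outer and inner cortex surfaces of
  revolution around a canal centreline that is a circular arc of radius
  ``r_bow`` in the sagittal plane (the anterior bow), with a distal
  condylar block carrying a lateral flare, posterior condyle masses, an
  intercondylar notch, and a lateral facet inclined medially by a
  configurable angulation.  All anatomical landmarks are computed
  analytically from the construction, so every downstream measurement has
  an exact ground truth.
* **Plates** — a pre-contoured lateral distal femur plate undersurface,
  modelled as a strip conforming to a template femur: the head wraps the
  condylar template, the shaft follows an arc of the configured plate bow
  radius (default 940 mm, the radius of a reverse-engineered commercial
  plate) with a slight transverse clearance so that only the apex line
  seats on the bone.  Hole counts of 9/11/13 set the shaft length.
* **Cohorts** — subject strata (ethnicity x age group x sex) with heights
  drawn from stratum distributions and bow radii coupled linearly to
  height plus noise, calibrated so the stratum medians and the
  height–bow-radius rank correlation resemble published descriptive
  statistics for Caucasian and Vietnamese femora.

The anatomy is deliberately stylized: the protocol's mathematics needs a
controllable bow, landmarks, and a condylar contact geometry — not a
statistically realistic femur shape.

Coordinate frame (canonical left femur): ``+z`` runs proximal -> distal,
``+x`` is anterior, ``+y`` is lateral.  Units are millimetres.
"""

from __future__ import annotations

import json
import dataclasses
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .errors import MeshValidationError, PlatefitError
from .mesh_core import TriangleMesh, save_mesh

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class FemurParams:
    """Generator parameters for one synthetic femur (mm / degrees)."""

    r_bow: float = 900.0             # canal centreline arc radius (sagittal)
    diaphysis_length: float = 340.0  # proximal end -> condyle start
    canal_radius: float = 6.0
    cortex_thickness: float = 6.5
    condyle_height: float = 60.0     # axial extent of the condylar block
    condyle_width_amp: float = 17.0  # medial/lateral condyle flare amplitude
    condyle_flare: float = 8.0       # posterior condyle mass amplitude
    notch_depth: float = 10.0        # intercondylar notch carve depth
    medial_angulation_deg: float = 10.0  # lateral facet inclination
    lt_base_z: float = 50.0          # axial position of lesser trochanter base
    apex_from_distal: float = 230.0  # bow apex distance from the distal end
    side: str = "left"
    resolution: float = 1.0          # target mesh edge length
    surface_noise: float = 0.0       # radial jitter SD (0 = analytic surface)
    seed: int = 0

    @property
    def total_length(self) -> float:
        return self.diaphysis_length + self.condyle_height

    @property
    def outer_radius(self) -> float:
        return self.canal_radius + self.cortex_thickness

    def validate(self) -> None:
        if self.r_bow <= 0:
            raise MeshValidationError("r_bow must be positive")
        if self.diaphysis_length <= 0 or self.condyle_height <= 0:
            raise MeshValidationError("lengths must be positive")
        if self.resolution > 1.0:
            raise MeshValidationError(
                "mesh resolution must be <= 1.0 mm so that vertex spacing is "
                "far below the 0.2-3 mm distance thresholds")
        if self.resolution <= 0:
            raise MeshValidationError("resolution must be positive")
        reach = max(self.apex_from_distal,
                    self.total_length - self.apex_from_distal)
        if self.r_bow < reach + 1.0:
            raise MeshValidationError(
                f"r_bow={self.r_bow} too small for a bone of length "
                f"{self.total_length}")
        if self.side not in ("left", "right"):
            raise MeshValidationError("side must be 'left' or 'right'")
        if not (0 < self.lt_base_z < self.diaphysis_length):
            raise MeshValidationError("lt_base_z must lie within the diaphysis")


@dataclass
class PlateParams:
    """Generator parameters for a synthetic plate undersurface."""

    holes: int = 13
    shaft_hole_pitch: float = 20.0
    head_length: float = 51.0        # condylar coverage from the distal end
    bow_radius: float = 940.0        # shaft midline arc radius (plate ROC)
    width: float = 12.0              # shaft strip width (arc length)
    head_wrap_deg: float = 110.0     # angular wrap of the head around condyle
    standoff: float = 0.1            # nominal undersurface-bone standoff
    edge_clearance: float = 12.0     # transverse flattening amplitude (shaft)
    tip_relief: float = 1.0          # tapered-tip relief depth at the tip
    relief_span: float = 60.0        # axial extent of the tip taper
    sample_spacing: float = 1.5      # undersurface grid spacing
    row_pitch: float = 40.0          # shaft measurement-row spacing (~4 cm)
    seed: int = 0

    @property
    def shaft_rows(self) -> int:
        # 9/11/13 holes -> 5/6/7 rows of shaft measurement points
        return (self.holes + 1) // 2

    @property
    def shaft_length(self) -> float:
        return self.row_pitch * self.shaft_rows + 20.0

    @property
    def length(self) -> float:
        return self.head_length + self.shaft_length

    def validate(self) -> None:
        if self.holes not in (9, 11, 13):
            raise PlatefitError(f"unsupported hole count: {self.holes}")
        if self.bow_radius <= 0 or self.width <= 0:
            raise PlatefitError("bow_radius and width must be positive")


@dataclass
class Screw:
    origin: np.ndarray      # on the plate undersurface
    direction: np.ndarray   # unit vector
    length: float


@dataclass
class FemurModel:
    outer: TriangleMesh
    inner: TriangleMesh
    landmarks: dict              # name -> (3,) point or (k, 3) point set
    metadata: dict
    true_r_bow: float
    params: FemurParams


@dataclass
class PlateModel:
    undersurface_points: np.ndarray   # (n, 3) structured sample grid
    undersurface_mesh: TriangleMesh   # triangulated strip (export/visual)
    centre_curve: np.ndarray          # shaft midline polyline, distal->proximal
    anchors: dict                     # named measurement/contact points
    screws: list                      # list[Screw]
    proximal_screw_index: int
    holes: int
    params: PlateParams
    shaft_mask: np.ndarray = field(default=None)  # bool per undersurface sample


# ---------------------------------------------------------------------------
# Shared analytic geometry
# ---------------------------------------------------------------------------

def _smoothstep(t):
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def arc_x(params: FemurParams, z):
    """Anterior (x) offset of the canal centreline at axial position z.

    The centreline is a circular arc of radius ``r_bow`` in the sagittal
    plane.  The arc is anchored at the distal end (x = 0 there) with its
    anterior apex a fixed ``apex_from_distal`` proximal of the distal
    end, so the geometry of the distal femur relative to the shaft
    depends only on the bow radius, not on bone length — bones of equal
    bow radius present identical distal anatomy to a plate.
    """
    z = np.asarray(z, dtype=float)
    R = params.r_bow
    z_apex = params.total_length - params.apex_from_distal
    anchor = np.sqrt(R * R - params.apex_from_distal ** 2)
    return np.sqrt(R * R - (z - z_apex) ** 2) - anchor


def centreline(params: FemurParams, z):
    z = np.asarray(z, dtype=float)
    x = arc_x(params, z)
    return np.stack([x, np.zeros_like(x), z], axis=-1)


def _wrapped_gauss(theta, centre_deg, sigma_deg):
    d = np.angle(np.exp(1j * (theta - np.deg2rad(centre_deg))))
    s = np.deg2rad(sigma_deg)
    return np.exp(-0.5 * (d / s) ** 2)


def outer_radius(params: FemurParams, z, theta):
    """Outer cortex ring radius at axial position z and angle theta.

    theta = 0 anterior, pi/2 lateral, pi posterior (canonical left side).
    The condylar block blends in over ``condyle_height`` with lateral and
    medial flares, posterior condyle masses, an intercondylar notch, and
    a medially inclined lateral facet.
    """
    z = np.asarray(z, dtype=float)
    theta = np.asarray(theta, dtype=float)
    t = np.clip((z - params.diaphysis_length) / params.condyle_height, 0.0, 1.0)
    s = _smoothstep(t)
    # lateral facet amplitude shrinks distally -> medial angulation
    tilt = np.tan(np.deg2rad(params.medial_angulation_deg)) * params.condyle_height
    a_lat = np.maximum(params.condyle_width_amp - tilt * np.maximum(t - 0.5, 0.0), 2.0)
    notch = params.notch_depth * _smoothstep((t - 0.55) / 0.4)
    bump = (a_lat * _wrapped_gauss(theta, 90.0, 25.0)
            + params.condyle_width_amp * _wrapped_gauss(theta, -90.0, 25.0)
            + params.condyle_flare * (_wrapped_gauss(theta, 150.0, 20.0)
                                      + _wrapped_gauss(theta, -150.0, 20.0))
            - notch * _wrapped_gauss(theta, 180.0, 15.0))
    return params.outer_radius + s * bump


def surface_point(params: FemurParams, z, theta, offset: float = 0.0):
    """Point on (or radially offset from) the outer cortex surface."""
    z = np.asarray(z, dtype=float)
    theta = np.asarray(theta, dtype=float)
    rho = outer_radius(params, z, theta) + offset
    c = centreline(params, z)
    u = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=-1)
    return c + rho[..., None] * u


# ---------------------------------------------------------------------------
# Mesh assembly helpers
# ---------------------------------------------------------------------------

def _tube_mesh(ring_centres: np.ndarray, ring_radii: np.ndarray,
               name: str) -> TriangleMesh:
    """Closed tube: rings of vertices around given centres, capped ends.

    ``ring_centres`` is (nz, 3); ``ring_radii`` is (nz, nt) of radii at
    angles 2*pi*j/nt.  Ring vertices share indices between neighbouring
    strips, so the result is watertight by construction.
    """
    nz, nt = ring_radii.shape
    theta = np.arange(nt) * TWO_PI / nt
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    verts = np.empty((nz * nt + 2, 3))
    for i in range(nz):
        verts[i * nt:(i + 1) * nt, 0] = ring_centres[i, 0] + ring_radii[i] * cos_t
        verts[i * nt:(i + 1) * nt, 1] = ring_centres[i, 1] + ring_radii[i] * sin_t
        verts[i * nt:(i + 1) * nt, 2] = ring_centres[i, 2]
    i_cap0 = nz * nt       # proximal cap centre
    i_cap1 = nz * nt + 1   # distal cap centre
    verts[i_cap0] = ring_centres[0]
    verts[i_cap1] = ring_centres[-1]

    j = np.arange(nt)
    j1 = (j + 1) % nt
    strips = []
    for i in range(nz - 1):
        a = i * nt + j
        b = i * nt + j1
        c = (i + 1) * nt + j1
        d = (i + 1) * nt + j
        strips.append(np.stack([a, b, c], axis=1))
        strips.append(np.stack([a, c, d], axis=1))
    cap0 = np.stack([np.full(nt, i_cap0), j1, j], axis=1)
    cap1 = np.stack([np.full(nt, i_cap1), (nz - 1) * nt + j,
                     (nz - 1) * nt + j1], axis=1)
    faces = np.concatenate(strips + [cap0, cap1])
    mesh = TriangleMesh.from_arrays(verts, faces, name=name)
    if mesh.as_trimesh().volume < 0:  # enforce outward orientation
        mesh = TriangleMesh.from_arrays(verts, faces[:, ::-1], name=name)
    return mesh


def _mirror_to_right(points: np.ndarray) -> np.ndarray:
    out = np.array(points, dtype=float, copy=True)
    out[..., 1] *= -1.0
    return out


# ---------------------------------------------------------------------------
# Femur generation
# ---------------------------------------------------------------------------

def make_femur(params: FemurParams, metadata: dict | None = None) -> FemurModel:
    """Generate a synthetic femur (outer + inner cortex, landmarks).

    Deterministic for a given parameter set (including ``seed``, which
    only matters when ``surface_noise > 0``).
    """
    params.validate()
    res = params.resolution
    L = params.total_length
    z_cs = params.diaphysis_length

    # --- outer cortex ---
    nz = int(np.ceil(L / res)) + 1
    zs = np.linspace(0.0, L, nz)
    rho_max = params.outer_radius + params.condyle_width_amp + params.condyle_flare
    nt = max(32, int(np.ceil(TWO_PI * rho_max / res)))
    theta = np.arange(nt) * TWO_PI / nt
    radii = outer_radius(params, zs[:, None], theta[None, :])
    if params.surface_noise > 0:
        rng = np.random.default_rng(params.seed)
        radii = radii + rng.normal(0.0, params.surface_noise, radii.shape)
    centres = centreline(params, zs)
    outer = _tube_mesh(centres, radii, name="outer_cortex")

    # --- inner cortex (canal) ---
    z0_in = max(params.lt_base_z - 10.0, 1.0)
    z1_in = z_cs
    nz_in = int(np.ceil((z1_in - z0_in) / res)) + 1
    zs_in = np.linspace(z0_in, z1_in, nz_in)
    nt_in = max(24, int(np.ceil(TWO_PI * params.canal_radius / res)))
    radii_in = np.full((nz_in, nt_in), params.canal_radius)
    inner = _tube_mesh(centreline(params, zs_in), radii_in, name="inner_cortex")

    # --- landmarks (analytic, on the outer surface) ---
    deg = np.deg2rad
    z_contact = z_cs + 0.6 * params.condyle_height
    fossa_t = np.linspace(deg(165.0), deg(195.0), 3)
    fossa_z = z_cs + params.condyle_height * np.linspace(0.75, 0.95, 4)
    fz, ft = np.meshgrid(fossa_z, fossa_t)
    landmarks = {
        "lesser_trochanter_base": surface_point(params, params.lt_base_z, deg(90.0)),
        "lateral_condyle_start": surface_point(params, z_cs, deg(90.0)),
        "distal_anterior_contact": surface_point(params, z_contact, deg(50.0)),
        "distal_posterior_contact": surface_point(params, z_contact, deg(130.0)),
        "intercondylar_fossa_region": surface_point(
            params, fz.ravel(), ft.ravel()),
    }

    if params.side == "right":
        outer = TriangleMesh.from_arrays(_mirror_to_right(outer.vertices),
                                         outer.faces[:, ::-1], name=outer.name)
        inner = TriangleMesh.from_arrays(_mirror_to_right(inner.vertices),
                                         inner.faces[:, ::-1], name=inner.name)
        landmarks = {k: _mirror_to_right(v) for k, v in landmarks.items()}

    return FemurModel(outer=outer, inner=inner, landmarks=landmarks,
                      metadata=dict(metadata or {}), true_r_bow=params.r_bow,
                      params=params)


def canonicalize_side(model: FemurModel) -> FemurModel:
    """Mirror a right-side femur to the canonical left frame (no-op for left)."""
    if model.params.side != "right":
        return model
    outer = TriangleMesh.from_arrays(_mirror_to_right(model.outer.vertices),
                                     model.outer.faces[:, ::-1],
                                     name=model.outer.name)
    inner = TriangleMesh.from_arrays(_mirror_to_right(model.inner.vertices),
                                     model.inner.faces[:, ::-1],
                                     name=model.inner.name)
    landmarks = {k: _mirror_to_right(v) for k, v in model.landmarks.items()}
    params = dataclasses.replace(model.params, side="left")
    return FemurModel(outer=outer, inner=inner, landmarks=landmarks,
                      metadata=model.metadata, true_r_bow=model.true_r_bow,
                      params=params)


# ---------------------------------------------------------------------------
# Plate generation
# ---------------------------------------------------------------------------

def template_femur_params(plate: PlateParams) -> FemurParams:
    """The template femur whose lateral surface the plate conforms to.

    Condylar geometry uses the femur defaults; the shaft follows the
    plate's own bow radius.  Only the analytic surface functions of this
    template are used — no template mesh is built.
    """
    return FemurParams(r_bow=plate.bow_radius, diaphysis_length=400.0)


def make_plate(params: PlateParams) -> PlateModel:
    """Generate a synthetic plate undersurface with anchors and screws.

    The plate is expressed in the frame of its template femur: the head
    conforms to the condylar template (offset by ``standoff``); the shaft
    strip follows the plate bow arc with a transverse ``edge_clearance``
    flattening so only the apex line seats on a matching bone.
    """
    params.validate()
    tmpl = template_femur_params(params)
    deg = np.deg2rad
    z_cs = tmpl.diaphysis_length
    z_pd = z_cs + params.head_length          # distal plate end
    z_tip = z_cs - params.shaft_length        # proximal plate tip
    half_wrap_shaft = params.width / (2.0 * tmpl.outer_radius)  # radians
    half_wrap_head = deg(params.head_wrap_deg) / 2.0

    def under_points(z, theta):
        """Undersurface sample: template surface + standoff + transverse
        edge clearance + tapered-tip relief."""
        z = np.asarray(z, float)
        theta = np.asarray(theta, float)
        ramp = _smoothstep((z_cs - z) / 20.0)
        clear = params.edge_clearance * (1.0 - np.cos(theta - deg(90.0))) * ramp
        relief = params.tip_relief * _smoothstep(
            (z_tip + params.relief_span - z) / params.relief_span)
        offset = params.standoff + clear + relief
        return surface_point(tmpl, z, theta, offset=0.0) + \
            offset[..., None] * np.stack(
                [np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=-1)

    # --- structured sample grid (shaft strip + head patch) ---
    dz = params.sample_spacing
    dth = deg(2.5)
    z_shaft = np.arange(z_tip, z_cs - 1e-9, dz)
    th_shaft = deg(90.0) + np.arange(-half_wrap_shaft, half_wrap_shaft + 1e-9, dth)
    z_head = np.arange(z_cs, z_pd + 1e-9, dz)
    th_head = deg(90.0) + np.arange(-half_wrap_head, half_wrap_head + 1e-9, dth)

    zs_g, th_s = np.meshgrid(z_shaft, th_shaft, indexing="ij")
    zh_g, th_h = np.meshgrid(z_head, th_head, indexing="ij")
    pts_shaft = under_points(zs_g.ravel(), th_s.ravel())
    pts_head = under_points(zh_g.ravel(), th_h.ravel())
    points = np.vstack([pts_shaft, pts_head])
    shaft_mask = np.zeros(len(points), dtype=bool)
    shaft_mask[: len(pts_shaft)] = True

    mesh = _strip_mesh([(pts_shaft, zs_g.shape), (pts_head, zh_g.shape)],
                       name=f"plate_{params.holes}h_undersurface")

    # --- shaft centre curve (<= 2 mm spacing, endpoints included) ---
    # axial step 1.8 mm keeps the 3D chord length under 2 mm despite the
    # sagittal slope of the bow arc; the centre curve traces the plate
    # body's shaft midline (standoff only, without the tip taper, which
    # is an undersurface relief feature rather than body curvature)
    n_cc = int(np.ceil(params.shaft_length / 1.8)) + 1
    z_cc = np.linspace(z_tip, z_cs, n_cc)
    centre_curve = surface_point(tmpl, z_cc, np.full_like(z_cc, deg(90.0)),
                                 offset=params.standoff)

    # --- measurement anchors ---
    rows = params.shaft_rows
    anchors: dict = {}
    anchors["c1"] = under_points(z_cs + 0.8 * params.head_length,
                                 deg(90.0) - half_wrap_head)
    c2_rows_z = [z_pd, z_pd - 17.0, z_pd - 34.0]
    c2 = []
    c2_ids = []
    for r, zr in enumerate(c2_rows_z, start=1):
        for label, off in (("ant", -deg(30.0)), ("ctr", 0.0), ("post", deg(30.0))):
            c2.append(under_points(zr, deg(90.0) + off))
            c2_ids.append(f"c2_r{r}_{label}")
    anchors["c2"] = np.array(c2)
    anchors["c2_ids"] = c2_ids
    c3 = []
    c3_ids = []
    for k in range(1, rows + 1):
        zk = z_cs - 30.0 - params.row_pitch * (k - 1)
        for label, off in (("ant", -deg(20.0)), ("ctr", 0.0), ("post", deg(20.0))):
            c3.append(under_points(zk, deg(90.0) + off))
            c3_ids.append(f"c3_r{k}_{label}")
    c3.append(under_points(z_tip, deg(90.0)))
    c3_ids.append("c3_tip")
    anchors["c3"] = np.array(c3)
    anchors["c3_ids"] = c3_ids
    anchors["distal_tip"] = under_points(z_pd, deg(90.0))
    anchors["proximal_tip"] = under_points(z_tip, deg(90.0))
    anchors["contact_anterior"] = under_points(z_cs + 0.6 * tmpl.condyle_height,
                                               deg(50.0))
    anchors["contact_posterior"] = under_points(z_cs + 0.6 * tmpl.condyle_height,
                                                deg(130.0))
    # shaft contact target at 60% of the shaft length from the transition
    z_sc = z_cs - 0.6 * params.shaft_length
    anchors["contact_shaft"] = under_points(z_sc, deg(90.0))
    anchors["contact_shaft_fraction"] = 0.6
    # zero-standoff twins on the template surface: the landmark-alignment
    # correspondences (bone landmarks lie on the bone surface)
    anchors["align_anterior"] = surface_point(
        tmpl, z_cs + 0.6 * tmpl.condyle_height, deg(50.0))
    anchors["align_posterior"] = surface_point(
        tmpl, z_cs + 0.6 * tmpl.condyle_height, deg(130.0))
    anchors["align_shaft"] = surface_point(tmpl, z_sc, deg(90.0))

    # --- screws ---
    screws = []
    head_dir = np.array([np.sin(deg(15.0)), -np.cos(deg(15.0)), 0.0])
    for frac in (0.2, 0.45, 0.7, 0.9):
        zsc = z_cs + frac * params.head_length
        origin = under_points(zsc, deg(90.0))
        screws.append(Screw(origin=origin, direction=head_dir.copy(),
                            length=2.0 * (tmpl.outer_radius
                                          + tmpl.condyle_width_amp)))
    z_ps = z_tip + 10.0
    origin_ps = under_points(z_ps, deg(90.0))
    target = centreline(tmpl, z_ps)
    d = target - origin_ps
    length_ps = float(np.linalg.norm(d))
    screws.append(Screw(origin=origin_ps, direction=d / length_ps,
                        length=length_ps))
    proximal_screw_index = len(screws) - 1

    return PlateModel(undersurface_points=points, undersurface_mesh=mesh,
                      centre_curve=centre_curve, anchors=anchors,
                      screws=screws, proximal_screw_index=proximal_screw_index,
                      holes=params.holes, params=params, shaft_mask=shaft_mask)


def _strip_mesh(blocks, name: str) -> TriangleMesh:
    """Triangulate structured (nz, nt) point grids into an open strip mesh."""
    verts = []
    faces = []
    base = 0
    for pts, shape in blocks:
        nz, nt = shape
        verts.append(pts)
        i, j = np.meshgrid(np.arange(nz - 1), np.arange(nt - 1), indexing="ij")
        a = base + (i * nt + j).ravel()
        b = base + (i * nt + j + 1).ravel()
        c = base + ((i + 1) * nt + j + 1).ravel()
        d = base + ((i + 1) * nt + j).ravel()
        faces.append(np.stack([a, b, c], axis=1))
        faces.append(np.stack([a, c, d], axis=1))
        base += nz * nt
    return TriangleMesh.from_arrays(np.vstack(verts), np.concatenate(faces),
                                    name=name)


def make_plate_set(params: PlateParams | None = None) -> dict:
    """The 9/11/13-hole plate family sharing all other parameters."""
    base = params or PlateParams()
    out = {}
    for holes in (9, 11, 13):
        out[holes] = make_plate(PlateParams(**{**asdict(base), "holes": holes}))
    return out


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class StratumSpec:
    ethnicity: str
    age_group: str        # 'young' (< 65) or 'old' (>= 65)
    sex: str              # 'male' / 'female'
    n: int
    height_median: float  # cm
    height_sd: float
    height_range: tuple
    age_median: float
    age_sd: float
    age_range: tuple
    roc_intercept: float  # mm
    roc_slope: float      # mm per cm of height
    roc_noise_sd: float   # mm

    def validate(self):
        if self.n < 0:
            raise PlatefitError("stratum n must be >= 0")
        if self.height_sd <= 0 or self.age_sd <= 0 or self.roc_noise_sd <= 0:
            raise PlatefitError("stratum SDs must be positive")


@dataclass
class CohortSpec:
    strata: list
    roc_clip: tuple = (400.0, 1800.0)
    height_to_length: float = 2.5   # bone model length = factor * height_cm

    def validate(self):
        if not self.strata:
            raise PlatefitError("cohort spec has no strata")
        for s in self.strata:
            s.validate()

    @property
    def n_total(self):
        return sum(s.n for s in self.strata)

    def scaled(self, fraction: float) -> "CohortSpec":
        """Proportionally smaller cohort (>=1 subject per non-empty stratum)."""
        strata = []
        for s in self.strata:
            ns = max(1, int(round(s.n * fraction))) if s.n > 0 else 0
            strata.append(StratumSpec(**{**asdict(s), "n": ns}))
        return CohortSpec(strata=strata, roc_clip=self.roc_clip,
                          height_to_length=self.height_to_length)


# Stratum descriptive statistics emulating the published two-ethnicity
# cohort (n = 159).  ROC is coupled to height with a common slope; the
# per-stratum intercept reproduces the stratum median ROC at the median
# height, and the noise SD tops up the residual ROC variance.
_ROC_SLOPE = 10.0  # mm per cm

_TABLE1 = [
    # ethnicity, group, sex, n, h_med, h_sd, h_range, a_med, a_sd, a_range, roc_med, roc_sd
    ("caucasian", "young", "male", 20, 171, 10.8, (150, 193), 31, 6.9, (25, 48), 919, 206),
    ("caucasian", "young", "female", 20, 160, 7.1, (152, 180), 29, 7.6, (21, 47), 986, 218),
    ("caucasian", "old", "male", 20, 170, 7.8, (158, 186), 81, 8.9, (65, 96), 1086, 274),
    ("caucasian", "old", "female", 20, 158, 6.3, (150, 173), 81, 8.1, (68, 96), 966, 184),
    ("vietnamese", "young", "male", 19, 167, 6.3, (154, 176), 53, 10.4, (31, 63), 956, 180),
    ("vietnamese", "young", "female", 17, 158, 4.4, (149, 165), 44, 7.9, (33, 60), 862, 142),
    ("vietnamese", "old", "male", 15, 165, 4.0, (156, 171), 70, 5.2, (65, 82), 907, 161),
    ("vietnamese", "old", "female", 28, 153, 4.5, (144, 165), 68, 5.0, (65, 84), 781, 146),
]


def default_cohort_spec() -> CohortSpec:
    strata = []
    for (eth, grp, sex, n, h_med, h_sd, h_rng, a_med, a_sd, a_rng,
         roc_med, roc_sd) in _TABLE1:
        noise = np.sqrt(max(roc_sd ** 2 - (_ROC_SLOPE * h_sd) ** 2, 80.0 ** 2))
        strata.append(StratumSpec(
            ethnicity=eth, age_group=grp, sex=sex, n=n,
            height_median=h_med, height_sd=h_sd, height_range=h_rng,
            age_median=a_med, age_sd=a_sd, age_range=a_rng,
            roc_intercept=roc_med - _ROC_SLOPE * h_med,
            roc_slope=_ROC_SLOPE, roc_noise_sd=float(noise)))
    return CohortSpec(strata=strata)


def _trunc_normal(rng, med, sd, lo, hi, size):
    a, b = (lo - med) / sd, (hi - med) / sd
    return truncnorm.rvs(a, b, loc=med, scale=sd, size=size, random_state=rng)


def sample_cohort_table(spec: CohortSpec, seed: int = 0) -> pd.DataFrame:
    """Draw subject metadata and femur generator parameters (no meshes)."""
    spec.validate()
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for s in spec.strata:
        if s.n == 0:
            continue
        h = _trunc_normal(rng, s.height_median, s.height_sd,
                          *s.height_range, size=s.n)
        age = _trunc_normal(rng, s.age_median, s.age_sd, *s.age_range, size=s.n)
        roc = s.roc_intercept + s.roc_slope * h + rng.normal(0, s.roc_noise_sd, s.n)
        roc = np.clip(roc, *spec.roc_clip)
        sides = np.where(rng.random(s.n) < 0.5, "left", "right")
        for k in range(s.n):
            rows.append({
                "id": f"{s.ethnicity[:4]}_{s.age_group[0]}_{s.sex[0]}_{idx:03d}",
                "ethnicity": s.ethnicity,
                "age": float(age[k]),
                "age_group": s.age_group,
                "sex": s.sex,
                "height_cm": float(h[k]),
                "true_R_bow_mm": float(roc[k]),
                "side": str(sides[k]),
                "total_length_mm": float(spec.height_to_length * h[k]),
            })
            idx += 1
    return pd.DataFrame(rows)


def femur_params_from_row(row, resolution: float = 1.0) -> FemurParams:
    """Femur generator parameters for one cohort-table row."""
    condyle_height = 60.0
    return FemurParams(
        r_bow=float(row["true_R_bow_mm"]),
        diaphysis_length=float(row["total_length_mm"]) - condyle_height,
        condyle_height=condyle_height,
        side=str(row["side"]),
        resolution=resolution,
    )


def make_femur_from_row(row, resolution: float = 1.0) -> FemurModel:
    meta = {k: row[k] for k in ("id", "ethnicity", "age", "age_group",
                                "sex", "height_cm")}
    return make_femur(femur_params_from_row(row, resolution), metadata=meta)


def sample_cohort(spec: CohortSpec, seed: int = 0,
                  resolution: float = 1.0) -> tuple:
    """Generate the full cohort: femur models plus a metadata table.

    For large cohorts prefer :func:`sample_cohort_table` plus
    :func:`make_femur_from_row` to build meshes one at a time.
    """
    table = sample_cohort_table(spec, seed=seed)
    models = [make_femur_from_row(row, resolution=resolution)
              for _, row in table.iterrows()]
    return models, table


# ---------------------------------------------------------------------------
# Disk I/O
# ---------------------------------------------------------------------------

def write_femur(model: FemurModel, directory, stem: str | None = None) -> None:
    """Write outer/inner STL plus a JSON landmark + metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or model.metadata.get("id", "femur")
    save_mesh(model.outer, directory / f"{stem}_outer.stl")
    save_mesh(model.inner, directory / f"{stem}_inner.stl")
    sidecar = {
        "landmarks": {k: np.asarray(v).tolist()
                      for k, v in model.landmarks.items()},
        "metadata": model.metadata,
        "true_r_bow_mm": model.true_r_bow,
    }
    (directory / f"{stem}_landmarks.json").write_text(
        json.dumps(sidecar, indent=1))


def load_landmarks(path) -> dict:
    data = json.loads(Path(path).read_text())
    return {k: np.asarray(v, dtype=float)
            for k, v in data["landmarks"].items()}
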