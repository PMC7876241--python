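"""Planar crossed four-bar knee kinematics.

The knee is modelled in a sagittal, tibia-fixed frame: origin at the tibial
plateau reference point (taken as the knee centre), x anterior, y proximal,
angles in degrees with 0 = full extension and flexion positive.  The two
cruciate ligaments are treated as rigid isometric fibres; together with the
tibial plateau (a straight, flat facet) and the femoral link joining the two
cruciate femoral attachments they form a crossed four-bar linkage with a
single degree of freedom, the knee flexion angle.  As the linkage moves, the
femoral condyle rolls and slides on the plateau: the tibiofemoral contact
point is the foot of the perpendicular dropped from the instant centre (the
crossing point of the two cruciate lines) onto the plateau.

The extensor mechanism follows the same classical planar construction: the
trochlea is a circular arc fixed in the femur, the patella is a point body
riding on that arc, linked to the tibial tuberosity by an inextensible
patellar tendon, and pulled proximally along the femoral shaft by the
quadriceps tendon.  The hamstrings insert on the posterior plateau and pull
parallel to the femoral shaft.

Geometry is defined by exactly 14 scalar parameters (12 linear, 2 angular in
the default registry layout below — see ``PARAM_REGISTRY``), scaled linearly
to each subject's tibia length.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "KneeGeometry",
    "LinkageState",
    "StructureLoAs",
    "PARAM_REGISTRY",
    "STRUCTURES",
    "scale_geometry",
    "solve_four_bar",
    "structure_loas",
    "load_geometry",
    "default_geometry",
    "ClosureError",
]

#: structure identifiers, in the conventional order used throughout the package
STRUCTURES = ("AC", "PC", "TF", "PT", "HT", "QT", "PF")

#: the (name, tag) registry of the M = 14 geometric parameters
PARAM_REGISTRY = (
    ("ac_tibia_anterior", "linear"),
    ("pc_tibia_posterior", "linear"),
    ("ac_length", "linear"),
    ("pc_length", "linear"),
    ("femoral_link_length", "linear"),
    ("patellar_tendon_length", "linear"),
    ("patella_thickness", "linear"),
    ("trochlea_radius", "linear"),
    ("trochlea_offset", "linear"),
    ("tuberosity_distance", "linear"),
    ("hamstring_posterior", "linear"),
    ("femoral_link_angle", "angular"),
    ("trochlea_angle", "angular"),
    ("quadriceps_angle_offset", "angular"),
)

LINEAR_PARAMS = tuple(n for n, t in PARAM_REGISTRY if t == "linear")
ANGULAR_PARAMS = tuple(n for n, t in PARAM_REGISTRY if t == "angular")

#: the tibial tuberosity sits on an anterior-distal ray from the plateau
#: reference point; this ray angle is a frame convention, not a parameter.
_TUBEROSITY_RAY_DEG = -45.0

FLEXION_MIN = 0.0
FLEXION_MAX = 135.0


class ClosureError(RuntimeError):
    """Raised when the four-bar (or patella) loop cannot be closed."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.hypot(v[0], v[1]))
    if n == 0.0:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def _rot(deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s], [s, c]])


def _udir(deg: float) -> np.ndarray:
    a = math.radians(deg)
    return np.array([math.cos(a), math.sin(a)])


def _circle_intersection(c0, r0, c1, r1, pick_max_y=True):
    """Intersect two circles; return the intersection with larger (or smaller) y.

    Raises ClosureError when the circles do not meet.
    """
    c0 = np.asarray(c0, float)
    c1 = np.asarray(c1, float)
    d = c1 - c0
    dist = float(np.hypot(d[0], d[1]))
    if dist == 0.0:
        raise ClosureError("concentric circles")
    if dist > r0 + r1 or dist < abs(r0 - r1):
        raise ClosureError(
            f"circles do not intersect (separation {dist:.6g}, radii {r0:.6g}, {r1:.6g})"
        )
    a = (r0**2 - r1**2 + dist**2) / (2.0 * dist)
    h2 = r0**2 - a**2
    h = math.sqrt(max(h2, 0.0))
    mid = c0 + a * d / dist
    perp = np.array([-d[1], d[0]]) / dist
    p1, p2 = mid + h * perp, mid - h * perp
    if pick_max_y:
        return p1 if p1[1] >= p2[1] else p2
    return p1 if p1[1] < p2[1] else p2


def _line_intersection(p0, d0, p1, d1):
    """Intersection of two lines given as point + direction. Raises on parallel."""
    A = np.column_stack([d0, -np.asarray(d1, float)])
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    if abs(det) < 1e-14:
        raise ClosureError("cruciate lines are parallel; no instant centre")
    t = np.linalg.solve(A, np.asarray(p1, float) - np.asarray(p0, float))
    return np.asarray(p0, float) + t[0] * np.asarray(d0, float)


@dataclass(frozen=True)
class KneeGeometry:
    """The 14-parameter planar knee geometry, scaled to one tibia length.

    All linear parameters are positive distances in metres; sign conventions
    (anterior vs posterior) are applied by the model, so e.g.
    ``pc_tibia_posterior = 0.03`` places the PCL tibial attachment at
    x = -0.03 m.  Angular parameters are degrees.
    """

    name: str
    reference_tibia_length: float
    tibia_length: float
    # linear (m)
    ac_tibia_anterior: float
    pc_tibia_posterior: float
    ac_length: float
    pc_length: float
    femoral_link_length: float
    patellar_tendon_length: float
    patella_thickness: float
    trochlea_radius: float
    trochlea_offset: float
    tuberosity_distance: float
    hamstring_posterior: float
    # angular (deg)
    femoral_link_angle: float
    trochlea_angle: float
    quadriceps_angle_offset: float

    def __post_init__(self):
        for pname in LINEAR_PARAMS:
            if getattr(self, pname) <= 0:
                raise ValueError(f"linear parameter {pname!r} must be positive")
        if self.reference_tibia_length <= 0 or self.tibia_length <= 0:
            raise ValueError("tibia lengths must be positive")
        # cruciates must be able to span their tibia->femur gap at extension
        st = solve_four_bar(self, 0.0)
        del st

    # -- parameter registry ------------------------------------------------
    @property
    def n_params(self) -> int:
        return len(PARAM_REGISTRY)

    def param(self, name: str) -> float:
        if name not in dict(PARAM_REGISTRY):
            raise KeyError(f"unknown geometric parameter {name!r}")
        return getattr(self, name)

    def param_tag(self, name: str) -> str:
        try:
            return dict(PARAM_REGISTRY)[name]
        except KeyError:
            raise KeyError(f"unknown geometric parameter {name!r}") from None

    def with_param(self, name: str, value: float) -> "KneeGeometry":
        """Return a copy with one registered parameter replaced."""
        self.param_tag(name)
        return replace(self, **{name: value})

    # -- fixed tibia-frame landmarks ----------------------------------------
    @property
    def ac_tibia(self) -> np.ndarray:
        return np.array([self.ac_tibia_anterior, 0.0])

    @property
    def pc_tibia(self) -> np.ndarray:
        return np.array([-self.pc_tibia_posterior, 0.0])

    @property
    def tuberosity(self) -> np.ndarray:
        return self.tuberosity_distance * _udir(_TUBEROSITY_RAY_DEG)

    @property
    def hamstring_tibia(self) -> np.ndarray:
        return np.array([-self.hamstring_posterior, 0.0])

    def reference_state(self) -> "LinkageState":
        """Full-extension (0 degrees) configuration."""
        return solve_four_bar(self, 0.0)


@dataclass(frozen=True)
class LinkageState:
    """Pose of the four-bar linkage at one flexion angle (tibia frame)."""

    flexion_angle: float
    ac_femur: np.ndarray        # femoral attachment of the AC
    pc_femur: np.ndarray        # femoral attachment of the PC
    instant_centre: np.ndarray  # crossing of the two cruciate lines
    contact_point: np.ndarray   # TF contact on the plateau (y = 0)
    femur_rotation_deg: float   # femur rotation relative to full extension
    geometry: KneeGeometry = field(repr=False, compare=False)

    @property
    def femur_rotation(self) -> np.ndarray:
        return _rot(self.femur_rotation_deg)


@dataclass(frozen=True)
class StructureLoAs:
    """Origins and unit directions of the seven load-bearing structures.

    Directions are oriented so that a positive force magnitude means tension
    for ligaments/tendons (force pulls the attachment toward the other end)
    and compression for the two contacts.  QT and PF act on the patella; the
    other five act on the tibia/shank.
    """

    flexion_angle: float
    origins: dict
    directions: dict
    patella_point: np.ndarray
    trochlea_centre: np.ndarray

    def origin(self, s: str) -> np.ndarray:
        return self.origins[s]

    def direction(self, s: str) -> np.ndarray:
        return self.directions[s]


def scale_geometry(base: KneeGeometry, tibia_length: float) -> KneeGeometry:
    """Scale all linear parameters by ``tibia_length / reference length``.

    Angular parameters are left untouched.
    """
    if tibia_length <= 0:
        raise ValueError("tibia_length must be positive")
    f = tibia_length / base.reference_tibia_length
    scaled = {n: getattr(base, n) * f for n in LINEAR_PARAMS}
    return replace(base, tibia_length=tibia_length, **scaled)


def solve_four_bar(geom: KneeGeometry, flexion_angle: float) -> LinkageState:
    """Close the crossed four-bar loop at one flexion angle.

    The femoral link (between the two cruciate femoral attachments) is rigid
    with the femur and therefore rotated by exactly the flexion angle from
    its full-extension orientation.  Closure places the AC femoral
    attachment at the intersection of the circle of radius ``ac_length``
    about the AC tibial attachment with the circle of radius ``pc_length``
    about the PC tibial attachment translated by the (known) femoral link
    vector; the proximal (y > 0) branch is taken.
    """
    if not (FLEXION_MIN <= flexion_angle <= FLEXION_MAX):
        raise ValueError(
            f"flexion angle {flexion_angle:g} deg outside model range "
            f"[{FLEXION_MIN:g}, {FLEXION_MAX:g}]"
        )
    link_dir = _udir(geom.femoral_link_angle + flexion_angle)
    d = geom.femoral_link_length * link_dir  # vector AC_femur -> PC_femur
    try:
        ac_f = _circle_intersection(
            geom.ac_tibia, geom.ac_length, geom.pc_tibia - d, geom.pc_length
        )
    except ClosureError as e:
        raise ClosureError(
            f"four-bar closure failed at {flexion_angle:g} deg: {e}"
        ) from None
    pc_f = ac_f + d
    ic = _line_intersection(
        geom.ac_tibia, ac_f - geom.ac_tibia, geom.pc_tibia, pc_f - geom.pc_tibia
    )
    contact = np.array([ic[0], 0.0])
    return LinkageState(
        flexion_angle=float(flexion_angle),
        ac_femur=ac_f,
        pc_femur=pc_f,
        instant_centre=ic,
        contact_point=contact,
        femur_rotation_deg=float(flexion_angle),
        geometry=geom,
    )


def _patella_point(geom: KneeGeometry, state: LinkageState) -> tuple[np.ndarray, np.ndarray]:
    """Locate the trochlea arc centre and the patella reference point.

    The trochlea centre is fixed in the femur at polar offset
    (``trochlea_offset``, ``trochlea_angle``) from the AC femoral attachment.
    The patella centre rides at ``trochlea_radius + patella_thickness`` from
    the arc centre and at ``patellar_tendon_length`` from the tuberosity;
    the anterior intersection branch is the physiologic one.
    """
    centre = state.ac_femur + geom.trochlea_offset * _udir(
        geom.trochlea_angle + state.femur_rotation_deg
    )
    r_pat = geom.trochlea_radius + geom.patella_thickness
    tub = geom.tuberosity
    d = centre - tub
    dist = float(np.hypot(d[0], d[1]))
    if dist > r_pat + geom.patellar_tendon_length or dist < abs(
        r_pat - geom.patellar_tendon_length
    ):
        raise ClosureError(
            f"patella loop cannot close at {state.flexion_angle:g} deg "
            f"(centre-tuberosity distance {dist:.4g} m)"
        )
    a = (r_pat**2 - geom.patellar_tendon_length**2 + dist**2) / (2 * dist)
    h = math.sqrt(max(r_pat**2 - a**2, 0.0))
    u = (tub - centre) / dist
    mid = centre + a * u
    perp = np.array([-u[1], u[0]])
    p1, p2 = mid + h * perp, mid - h * perp
    patella = p1 if p1[0] >= p2[0] else p2  # anterior branch
    return centre, patella


def structure_loas(geom: KneeGeometry, state: LinkageState) -> StructureLoAs:
    """Origins and unit directions of all seven structures at one pose."""
    if state.geometry is not geom and state.geometry != geom:
        raise ValueError("LinkageState was produced with a different geometry")

    centre, patella = _patella_point(geom, state)
    shaft = _rot(state.femur_rotation_deg) @ np.array([0.0, 1.0])
    quad_dir = _rot(state.femur_rotation_deg + geom.quadriceps_angle_offset) @ np.array(
        [0.0, 1.0]
    )
    # quadriceps wrap: in deeper flexion the straight tendon line from the
    # patella along the femoral shaft would cut the trochlea arc; the tendon
    # then wraps on the cartilage and its effective pull at the patella is
    # the tangent from the patella to the arc (continuous at engagement).
    v = centre - patella
    vn = float(np.hypot(v[0], v[1]))
    perp = abs(quad_dir[0] * v[1] - quad_dir[1] * v[0])
    if float(np.dot(quad_dir, v)) > 0.0 and perp < geom.trochlea_radius and vn > geom.trochlea_radius:
        gamma = math.asin(min(geom.trochlea_radius / vn, 1.0))
        side = 1.0 if (v[0] * quad_dir[1] - v[1] * quad_dir[0]) >= 0.0 else -1.0
        quad_dir = _rot(side * math.degrees(gamma)) @ (v / vn)

    origins = {
        "AC": geom.ac_tibia,
        "PC": geom.pc_tibia,
        "TF": state.contact_point,
        "PT": geom.tuberosity,
        "HT": geom.hamstring_tibia,
        "QT": patella,
        "PF": patella,
    }
    directions = {
        "AC": _unit(state.ac_femur - geom.ac_tibia),
        "PC": _unit(state.pc_femur - geom.pc_tibia),
        # femur pushes the tibia distally along the plateau normal
        "TF": np.array([0.0, -1.0]),
        "PT": _unit(patella - geom.tuberosity),
        "HT": shaft.copy(),
        "QT": quad_dir,
        "PF": _unit(patella - centre),
    }
    return StructureLoAs(
        flexion_angle=state.flexion_angle,
        origins=origins,
        directions=directions,
        patella_point=patella,
        trochlea_centre=centre,
    )


# ---------------------------------------------------------------------------
# configuration I/O


def load_geometry(path) -> KneeGeometry:
    """Load a geometry config JSON (see data/default_geometry.json)."""
    with open(path) as fh:
        doc = json.load(fh)
    params = {p["name"]: p for p in doc["parameters"]}
    expected = dict(PARAM_REGISTRY)
    if set(params) != set(expected):
        missing = set(expected) - set(params)
        extra = set(params) - set(expected)
        raise ValueError(
            f"geometry config must register exactly the {len(expected)} known "
            f"parameters (missing: {sorted(missing)}, unknown: {sorted(extra)})"
        )
    for name, p in params.items():
        tag = expected[name]
        if p.get("tag") != tag:
            raise ValueError(f"parameter {name!r} must carry tag {tag!r}")
        unit = "m" if tag == "linear" else "deg"
        if p.get("unit") != unit:
            raise ValueError(f"parameter {name!r} must be in {unit}")
    ref = float(doc["reference_tibia_length_m"])
    return KneeGeometry(
        name=doc.get("name", "unnamed"),
        reference_tibia_length=ref,
        tibia_length=ref,
        **{name: float(p["value"]) for name, p in params.items()},
    )


def default_geometry() -> KneeGeometry:
    """The packaged synthetic reference geometry (see its JSON for caveats)."""
    return load_geometry(Path(__file__).parent / "data" / "default_geometry.json")
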