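"""Tricompartment-unloader (TCU) brace moment curves and load injection.

The brace stores energy during gravity-assisted flexion and returns it as an
extension-assist moment, modelled as a force F_B = M(theta)/r_B applied
perpendicular to the tibia (anteriorly) at a distance r_B distal to the knee
centre.  Three stock moment/angle curves are shipped (squat: linear;
general: quadratic; plateau: quadratic clamped above its plateau angle); all
are configurable stand-ins flagged ``approximate`` in their JSON configs —
manufacturer bench calibrations are not public.  Curves are functions of
flexion angle alone (no hysteresis), so any descent/ascent asymmetry in the
braced results comes from the dynamics of the movement, not from the brace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .dynamics import NetKneeLoad
from .geometry import FLEXION_MAX, FLEXION_MIN

__all__ = [
    "BraceModel",
    "brace_moment",
    "apply_brace",
    "load_brace",
    "default_brace",
    "NO_BRACE",
    "BRACE_NAMES",
]

BRACE_NAMES = ("none", "squat", "general", "plateau")
CURVE_FORMS = ("zero", "linear", "quadratic")


@dataclass(frozen=True)
class BraceModel:
    """A brace moment/angle curve plus its point of application.

    ``coefficients`` are (c0, c1, c2) of M(theta) = c0 + c1*theta + c2*theta^2
    in N*m with theta in degrees; the curve must vanish at full extension and
    be non-negative over the whole flexion range.  ``pure_couple`` switches
    the load injection to a couple with no force component (comparison mode).
    """

    name: str
    curve_form: str
    coefficients: tuple = (0.0, 0.0, 0.0)
    r_b: float = 0.20  # m, moment arm below knee centre
    plateau_angle: float | None = None  # deg; clamp M above this angle
    approximate: bool = True
    pure_couple: bool = False

    def __post_init__(self):
        if self.curve_form not in CURVE_FORMS:
            raise ValueError(f"unknown curve form {self.curve_form!r}")
        if self.r_b <= 0:
            raise ValueError("brace moment arm r_b must be positive")
        c0, c1, c2 = self.coefficients
        if abs(c0) > 1e-12:
            raise ValueError("brace moment must vanish at full extension (c0 = 0)")
        if self.curve_form == "zero" and any(abs(c) > 0 for c in self.coefficients):
            raise ValueError("zero curve must have zero coefficients")
        if self.curve_form == "linear" and abs(c2) > 0:
            raise ValueError("linear curve must have c2 = 0")
        grid = np.linspace(FLEXION_MIN, FLEXION_MAX, 272)
        if np.any(self._eval(grid) < -1e-9):
            raise ValueError(
                f"brace {self.name!r}: moment/angle curve goes negative in "
                f"[{FLEXION_MIN:g}, {FLEXION_MAX:g}] deg"
            )

    def _eval(self, theta):
        c0, c1, c2 = self.coefficients
        th = np.asarray(theta, float)
        if self.plateau_angle is not None:
            th = np.minimum(th, self.plateau_angle)
        return c0 + c1 * th + c2 * th**2

    def moment(self, flexion_angle):
        return brace_moment(self, flexion_angle)


NO_BRACE = BraceModel(name="none", curve_form="zero")


def brace_moment(model: BraceModel, flexion_angle):
    """Extension-assist moment (N*m) at one or many flexion angles."""
    th = np.asarray(flexion_angle, float)
    if np.any(th < FLEXION_MIN - 1e-9) or np.any(th > FLEXION_MAX + 1e-9):
        raise ValueError("flexion angle outside [0, 135] deg")
    out = model._eval(th)
    return float(out) if np.isscalar(flexion_angle) else out


def apply_brace(load: NetKneeLoad, model: BraceModel, flexion_angle) -> NetKneeLoad:
    """Add the brace load to a net knee load (whole series or one sample).

    The brace force F_B = M/r_B acts anteriorly on the tibia at r_B distal
    to the knee, so the applied anterior force grows by F_B while the
    internal extensor moment demand falls by M.  With ``pure_couple`` only
    the moment is injected.
    """
    m = brace_moment(model, flexion_angle)
    m = np.broadcast_to(np.asarray(m, float), load.fx.shape)
    f_b = np.zeros_like(load.fx) if model.pure_couple else m / model.r_b
    return NetKneeLoad(fx=load.fx + f_b, fy=load.fy.copy(), mz=load.mz - m)


# ---------------------------------------------------------------------------
# configuration I/O

def load_brace(path) -> BraceModel:
    with open(path) as fh:
        doc = json.load(fh)
    return BraceModel(
        name=doc["name"],
        curve_form=doc["curve_form"],
        coefficients=tuple(doc.get("coefficients", (0.0, 0.0, 0.0))),
        r_b=float(doc.get("r_B_m", 0.20)),
        plateau_angle=doc.get("plateau_angle_deg"),
        approximate=bool(doc.get("approximate", True)),
    )


def default_brace(name: str) -> BraceModel:
    """One of the packaged stand-in brace models by name."""
    if name == "none":
        return NO_BRACE
    if name not in BRACE_NAMES:
        raise KeyError(f"unknown brace model {name!r}; choose from {BRACE_NAMES}")
    return load_brace(Path(__file__).parent / "data" / f"brace_{name}.json")
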