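"""Planar inverse dynamics of the shank and foot.

Computes the net (intersegmental) sagittal load transmitted across the knee
from trial kinematics, ground reactions, gravity and segment inertia, by a
Newton-Euler recursion over the foot and shank in the lab sagittal plane,
then expresses the result in the tibia frame.

Conventions
-----------
* Lab frame: x forward, y up, gravity -y.
* The shank origin in the trial file is the knee joint centre; the foot
  origin is the ankle joint centre.  Segment angles are the rotation of the
  segment frame relative to the lab (0 = tibia vertical / foot flat).
* ``NetKneeLoad`` stores the *applied* external load reduced to the knee
  point in the tibia frame (anterior/proximal force components), together
  with the internal sagittal knee moment demand, extensor positive: the
  moment the knee structures must generate to balance the externals.

Segment inertial parameters default to the classic anthropometric
coefficient table of Winter (mass, centre-of-mass and radius-of-gyration
fractions), configurable per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GRAVITY",
    "AnthroParams",
    "TrialData",
    "NetKneeLoad",
    "net_knee_load",
    "split_phases",
    "read_trial_csv",
    "write_trial_csv",
    "TRIAL_COLUMNS",
]

GRAVITY = 9.81  # m/s^2

#: Winter's anthropometric coefficients (fractions of body mass / segment
#: length): (mass_fraction, com_from_proximal, radius_of_gyration)
WINTER_SHANK = (0.0465, 0.433, 0.302)
WINTER_FOOT = (0.0145, 0.50, 0.475)

TRIAL_COLUMNS = [
    "time_s",
    "knee_flexion_deg",
    "shank_angle_rad",
    "shank_origin_x_m",
    "shank_origin_y_m",
    "foot_angle_rad",
    "foot_origin_x_m",
    "foot_origin_y_m",
    "grf_x_N",
    "grf_y_N",
    "cop_x_m",
]


@dataclass(frozen=True)
class AnthroParams:
    """Subject anthropometrics plus segment inertial coefficients."""

    body_mass: float  # kg
    height: float  # m
    tibia_length: float  # m
    foot_length: float = 0.0  # m; 0 -> 0.152 * height (Winter)
    shank_coeffs: tuple = WINTER_SHANK
    foot_coeffs: tuple = WINTER_FOOT
    subject_id: str = "S0"

    def __post_init__(self):
        if self.body_mass <= 0 or self.height <= 0 or self.tibia_length <= 0:
            raise ValueError("mass, height and tibia length must be positive")
        for c in (*self.shank_coeffs, *self.foot_coeffs):
            if not (0.0 < c < 1.0):
                raise ValueError("segment coefficient fractions must lie in (0, 1)")

    @property
    def body_weight(self) -> float:
        return self.body_mass * GRAVITY

    @property
    def effective_foot_length(self) -> float:
        return self.foot_length if self.foot_length > 0 else 0.152 * self.height

    def segment(self, name: str):
        """(mass, com_offset_from_proximal, moment_of_inertia) for a segment."""
        if name == "shank":
            mf, cf, rf = self.shank_coeffs
            length = self.tibia_length
        elif name == "foot":
            mf, cf, rf = self.foot_coeffs
            length = self.effective_foot_length
        else:
            raise KeyError(name)
        m = mf * self.body_mass
        return m, cf * length, m * (rf * length) ** 2


@dataclass
class TrialData:
    """One DKB repetition for one leg (uniformly sampled time series)."""

    time: np.ndarray
    knee_flexion: np.ndarray  # deg
    shank_angle: np.ndarray  # rad, lab frame
    shank_origin: np.ndarray  # (n, 2) m, knee centre in lab
    foot_angle: np.ndarray  # rad
    foot_origin: np.ndarray  # (n, 2) m, ankle in lab
    grf: np.ndarray  # (n, 2) N
    cop_x: np.ndarray  # m, lab frame
    leg_id: str = "R"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.time)
        for name in ("knee_flexion", "shank_angle", "foot_angle", "cop_x"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"series {name!r} length mismatch")
        for name in ("shank_origin", "foot_origin", "grf"):
            if getattr(self, name).shape != (n, 2):
                raise ValueError(f"series {name!r} must have shape (n, 2)")
        if n >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.knee_flexion < -1e-9) or np.any(self.knee_flexion > 135 + 1e-9):
            raise ValueError("knee flexion outside the model range [0, 135] deg")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.time)
        return bool(np.allclose(d, d[0], rtol=rtol))


@dataclass
class NetKneeLoad:
    """External load reduced at the knee, tibia frame, per time sample.

    ``fx``/``fy`` are the anterior/proximal components of the resultant
    external force applied to the shank-foot system (N); ``mz`` is the
    internal sagittal knee moment demand (N*m), extensor positive.  The knee
    structures must jointly produce ``-(fx, fy)`` and an extensor moment
    ``mz`` about the knee centre.
    """

    fx: np.ndarray
    fy: np.ndarray
    mz: np.ndarray

    def __post_init__(self):
        if not (len(self.fx) == len(self.fy) == len(self.mz)):
            raise ValueError("component length mismatch")
        if not (np.all(np.isfinite(self.fx)) and np.all(np.isfinite(self.fy))
                and np.all(np.isfinite(self.mz))):
            raise ValueError("net knee load must be finite")

    def __len__(self) -> int:
        return len(self.fx)

    def sample(self, i: int) -> tuple[float, float, float]:
        return float(self.fx[i]), float(self.fy[i]), float(self.mz[i])


def _central_diff2(x: np.ndarray, dt: float) -> np.ndarray:
    """Second derivative by central differences, one-sided at the ends."""
    a = np.empty_like(x)
    a[1:-1] = (x[2:] - 2 * x[1:-1] + x[:-2]) / dt**2
    a[0] = a[1]
    a[-1] = a[-2]
    return a


def net_knee_load(
    trial: TrialData, anthro: AnthroParams, quasi_static: bool = True
) -> NetKneeLoad:
    """Net sagittal knee load from a Newton-Euler foot->shank recursion.

    With ``quasi_static`` all acceleration terms are zeroed, so the knee
    load balances ground reaction and segment weights only.  Otherwise
    segment linear/angular accelerations are obtained by central finite
    differences of the pose series.
    """
    if len(trial) >= 3 and not trial.is_uniform():
        raise ValueError("trial requires uniform sampling; resample first")

    n = len(trial)
    g = np.array([0.0, -GRAVITY])

    m_sh, c_sh, i_sh = anthro.segment("shank")
    m_ft, c_ft, i_ft = anthro.segment("foot")

    # segment COM positions in the lab frame.  The shank COM lies c_sh below
    # the knee along the tibia axis; the foot COM lies c_ft along the foot
    # axis from the ankle.
    sh_axis = np.column_stack([np.sin(trial.shank_angle), np.cos(trial.shank_angle)])
    ft_axis = np.column_stack([np.cos(trial.foot_angle), np.sin(trial.foot_angle)])
    com_sh = trial.shank_origin - c_sh * sh_axis
    com_ft = trial.foot_origin + c_ft * ft_axis

    if quasi_static or n < 3:
        acc_sh = np.zeros((n, 2))
        acc_ft = np.zeros((n, 2))
        alpha_sh = np.zeros(n)
        alpha_ft = np.zeros(n)
    else:
        dt = trial.dt
        acc_sh = np.column_stack(
            [_central_diff2(com_sh[:, 0], dt), _central_diff2(com_sh[:, 1], dt)]
        )
        acc_ft = np.column_stack(
            [_central_diff2(com_ft[:, 0], dt), _central_diff2(com_ft[:, 1], dt)]
        )
        alpha_sh = _central_diff2(np.unwrap(trial.shank_angle), dt)
        alpha_ft = _central_diff2(np.unwrap(trial.foot_angle), dt)

    knee = trial.shank_origin
    cop = np.column_stack([trial.cop_x, np.zeros(n)])

    def crossz(r, f):
        return r[:, 0] * f[:, 1] - r[:, 1] * f[:, 0]

    # resultant external (non-knee) force on the foot+shank system
    w_sh = m_sh * g
    w_ft = m_ft * g
    f_ext_lab = trial.grf + w_sh + w_ft
    # inertial correction: required net force = m*a, so the joint force is
    # m*a - externals; equivalently external applied load minus inertia
    f_applied_lab = f_ext_lab - (m_sh * acc_sh + m_ft * acc_ft)

    m_ext_lab = (
        crossz(cop - knee, trial.grf)
        + crossz(com_sh - knee, np.broadcast_to(w_sh, (n, 2)))
        + crossz(com_ft - knee, np.broadcast_to(w_ft, (n, 2)))
    )
    m_inertial = (
        crossz(com_sh - knee, m_sh * acc_sh)
        + i_sh * alpha_sh
        + crossz(com_ft - knee, m_ft * acc_ft)
        + i_ft * alpha_ft
    )
    m_applied_lab = m_ext_lab - m_inertial

    # rotate force into the tibia frame: tibia y-axis = -sh_axis... the shank
    # axis above points knee->ankle opposite of proximal; tibia proximal axis
    # is the unit vector from ankle to knee.
    prox = sh_axis  # knee = ankle + L*prox holds when sh_axis is ankle->knee
    ant = np.column_stack([prox[:, 1], -prox[:, 0]])
    fx = np.einsum("ij,ij->i", f_applied_lab, ant)
    fy = np.einsum("ij,ij->i", f_applied_lab, prox)
    mz = -m_applied_lab  # extensor-internal positive (z out of plane is +)

    return NetKneeLoad(fx=fx, fy=fy, mz=mz)


def split_phases(trial: TrialData) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the descent (before peak flexion) and ascent phases.

    The peak is the global flexion maximum; ties break to the earliest
    sample.  Descent is [0, peak), ascent [peak, n); both must be non-empty.
    """
    flex = np.asarray(trial.knee_flexion)
    peak = int(np.argmax(flex))
    if peak == 0:
        raise ValueError("flexion waveform has no descent phase before its peak")
    descent = np.arange(0, peak)
    ascent = np.arange(peak, len(flex))
    return descent, ascent


# ---------------------------------------------------------------------------
# trial CSV dialect


def write_trial_csv(trial: TrialData, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": trial.time,
            "knee_flexion_deg": trial.knee_flexion,
            "shank_angle_rad": trial.shank_angle,
            "shank_origin_x_m": trial.shank_origin[:, 0],
            "shank_origin_y_m": trial.shank_origin[:, 1],
            "foot_angle_rad": trial.foot_angle,
            "foot_origin_x_m": trial.foot_origin[:, 0],
            "foot_origin_y_m": trial.foot_origin[:, 1],
            "grf_x_N": trial.grf[:, 0],
            "grf_y_N": trial.grf[:, 1],
            "cop_x_m": trial.cop_x,
        }
    )
    df.to_csv(path, index=False)


def read_trial_csv(path, leg_id: str = "R") -> TrialData:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV missing columns {missing}")
    return TrialData(
        time=df["time_s"].to_numpy(float),
        knee_flexion=df["knee_flexion_deg"].to_numpy(float),
        shank_angle=df["shank_angle_rad"].to_numpy(float),
        shank_origin=df[["shank_origin_x_m", "shank_origin_y_m"]].to_numpy(float),
        foot_angle=df["foot_angle_rad"].to_numpy(float),
        foot_origin=df[["foot_origin_x_m", "foot_origin_y_m"]].to_numpy(float),
        grf=df[["grf_x_N", "grf_y_N"]].to_numpy(float),
        cop_x=df["cop_x_m"].to_numpy(float),
        leg_id=leg_id,
    )
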