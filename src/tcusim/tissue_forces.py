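"""Resolution of knee tissue forces from the net intersegmental load.

The sagittal force system at the proximal tibia is underdetermined: five
structures (patellar tendon PT, hamstring tendon HT, anterior cruciate AC,
posterior cruciate PC, tibiofemoral contact TF) against three planar
equilibrium equations.  Following the classical planar-knee treatment, the
system is reduced to four fully determined candidate solutions, one per
(tendon, ligament) pair, each solved exactly from the two force and one
moment equations.  The admissible candidate (tensile tendon and ligament,
compressive contact) with the lowest TF contact force is retained: the knee
cannot push with a ligament nor pull with its articular surface, and among
feasible solutions the one loading the joint least is selected.  When the
patellar tendon carries load, the quadriceps tendon (QT) and patellofemoral
contact (PF) forces follow from the patella treated as a three-force body.

Sign conventions: tendon/ligament magnitudes are tensions (>= 0); contact
magnitudes are compressions stored positive.  Forces are reported normalised
to body weight (BW = body mass * g).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .brace import BraceModel, apply_brace
from .dynamics import AnthroParams, NetKneeLoad, TrialData, net_knee_load, split_phases
from .geometry import KneeGeometry, StructureLoAs, solve_four_bar, structure_loas

__all__ = [
    "CandidateSolution",
    "TissueForceSeries",
    "CANDIDATE_PAIRS",
    "VALID_FLEXION_MAX",
    "candidate_solutions",
    "select_solution",
    "patella_equilibrium",
    "solve_trial",
]

#: candidate enumeration order (also the documented tie-break order)
CANDIDATE_PAIRS = (("PT", "AC"), ("PT", "PC"), ("HT", "AC"), ("HT", "PC"))

#: force outputs beyond this flexion angle are flagged invalid (the model's
#: trustworthy range established by sensitivity + implant validation)
VALID_FLEXION_MAX = 100.0

ADMISSIBILITY_TOL = 1e-9

FORCE_CHANNELS = ("F_PT", "F_QT", "F_HT", "F_AC", "F_PC", "F_TF", "F_PF")


def _crossz(r, d):
    return r[0] * d[1] - r[1] * d[0]


@dataclass(frozen=True)
class CandidateSolution:
    """One fully determined (tendon, ligament, contact) solution."""

    tendon_id: str
    ligament_id: str
    f_tendon: float
    f_ligament: float
    f_tf: float
    admissible: bool
    condition_number: float
    singular: bool = False
    fallback: bool = False

    @property
    def violation(self) -> float:
        """Total unilateral-constraint violation (N); 0 when admissible."""
        if self.singular:
            return float("inf")
        return sum(max(0.0, -v) for v in (self.f_tendon, self.f_ligament, self.f_tf))


def candidate_solutions(
    loas: StructureLoAs, load_sample: tuple[float, float, float]
) -> list[CandidateSolution]:
    """Solve all four (tendon, ligament) candidates for one load sample.

    ``load_sample`` is ``(fx, fy, mz)`` per ``NetKneeLoad`` conventions:
    applied anterior/proximal force and internal extensor moment demand.
    The three structure magnitudes satisfy planar equilibrium exactly.
    """
    fx, fy, mz = load_sample
    b = np.array([-fx, -fy, mz])
    scale = max(1.0, float(np.linalg.norm(b)))
    tol = ADMISSIBILITY_TOL * scale
    out = []
    for tendon, lig in CANDIDATE_PAIRS:
        A = np.zeros((3, 3))
        for j, s in enumerate((tendon, lig, "TF")):
            d = loas.direction(s)
            r = loas.origin(s)
            A[0, j] = d[0]
            A[1, j] = d[1]
            A[2, j] = _crossz(r, d)
        cond = float(np.linalg.cond(A))
        if not np.isfinite(cond) or cond > 1e12:
            out.append(
                CandidateSolution(tendon, lig, np.nan, np.nan, np.nan,
                                  admissible=False, condition_number=cond,
                                  singular=True)
            )
            continue
        x = np.linalg.solve(A, b)
        adm = bool(np.all(x >= -tol))
        out.append(
            CandidateSolution(tendon, lig, float(x[0]), float(x[1]), float(x[2]),
                              admissible=adm, condition_number=cond)
        )
    return out


def select_solution(
    candidates: list[CandidateSolution], tol: float = ADMISSIBILITY_TOL
) -> CandidateSolution:
    """Retain the admissible candidate with the lowest TF contact force.

    Ties break by candidate enumeration order.  If no candidate is
    admissible, the candidate with the smallest total constraint violation
    is returned with ``fallback=True`` — never silently.
    """
    if len(candidates) != 4:
        raise ValueError("expected the four candidate solutions")
    admissible = [c for c in candidates if c.admissible]
    if admissible:
        return min(admissible, key=lambda c: c.f_tf)
    best = min(candidates, key=lambda c: c.violation)
    if not np.isfinite(best.violation):
        # every candidate singular: return a zeroed fallback
        best = CandidateSolution(best.tendon_id, best.ligament_id, 0.0, 0.0, 0.0,
                                 admissible=False,
                                 condition_number=best.condition_number,
                                 singular=True)
    return CandidateSolution(
        best.tendon_id, best.ligament_id, best.f_tendon, best.f_ligament,
        best.f_tf, admissible=False, condition_number=best.condition_number,
        singular=best.singular, fallback=True,
    )


def patella_equilibrium(f_pt: float, loas: StructureLoAs) -> tuple[float, float]:
    """QT and PF magnitudes from the patella three-force balance.

    The patellar tendon pulls the patella toward the tuberosity, the
    quadriceps tendon pulls it proximally along the femoral shaft, and the
    trochlea pushes along the contact normal; the three lines are concurrent
    at the patella point by construction.
    """
    if f_pt < 0:
        raise ValueError("patellar tendon force must be non-negative")
    if f_pt == 0.0:
        return 0.0, 0.0
    A = np.column_stack([loas.direction("QT"), loas.direction("PF")])
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    if abs(det) < 1e-9:
        raise ArithmeticError(
            f"QT and PF lines of action are parallel at "
            f"{loas.flexion_angle:g} deg of flexion"
        )
    f_qt, f_pf = np.linalg.solve(A, f_pt * loas.direction("PT"))
    return float(f_qt), float(f_pf)


@dataclass
class TissueForceSeries:
    """BW-normalised tissue force waveforms for one trial, with provenance."""

    time: np.ndarray
    flexion: np.ndarray  # deg
    forces: dict  # channel -> ndarray (BW)
    selected_candidate: list  # "PT-PC" etc. per sample
    fallback: np.ndarray  # bool per sample
    valid: np.ndarray  # bool per sample (flexion <= 100 deg)
    phase: np.ndarray  # "descent"/"ascent" per sample
    body_weight: float  # N
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.time)

    def channel(self, name: str) -> np.ndarray:
        return self.forces[name]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.time, "knee_flexion_deg": self.flexion,
                           "phase": self.phase})
        for ch in FORCE_CHANNELS:
            df[f"{ch}_BW"] = self.forces[ch]
        df["selected_candidate"] = self.selected_candidate
        df["fallback_flag"] = self.fallback
        df["valid_flag"] = self.valid
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def at_flexion(self, angle: float, phase: str = "descent") -> dict:
        """Channel forces linearly interpolated at the first crossing of
        ``angle`` within a phase; NaN when the phase never reaches it."""
        mask = self.phase == phase
        flex = self.flexion[mask]
        if phase == "ascent":
            flex = flex[::-1]  # make flexion increasing along the search
        crossing = None
        for i in range(len(flex) - 1):
            lo, hi = flex[i], flex[i + 1]
            if (lo - angle) * (hi - angle) <= 0 and lo != hi:
                w = (angle - lo) / (hi - lo)
                crossing = (i, w)
                break
        out = {}
        if crossing is None:
            return {ch: float("nan") for ch in FORCE_CHANNELS}
        i, w = crossing
        for ch in FORCE_CHANNELS:
            f = self.forces[ch][mask]
            if phase == "ascent":
                f = f[::-1]
            out[ch] = float((1 - w) * f[i] + w * f[i + 1])
        return out


def solve_trial(
    trial: TrialData,
    geom: KneeGeometry,
    anthro: AnthroParams,
    brace: BraceModel | None = None,
    quasi_static: bool = True,
    on_error: str = "raise",
) -> TissueForceSeries:
    """Full per-sample pipeline for one trial.

    four-bar solve -> lines of action -> (brace-modified) net knee load ->
    candidate solutions -> selection -> patella three-force body.  Forces
    are BW-normalised; samples beyond 100 deg of flexion are computed but
    flagged invalid.  With ``on_error="nan"`` a failed sample yields NaN
    forces (flagged as fallback) instead of aborting the trial — used by the
    sensitivity analysis, where a perturbed geometry may be unsolvable at
    some angles.
    """
    if on_error not in ("raise", "nan"):
        raise ValueError("on_error must be 'raise' or 'nan'")
    if abs(geom.tibia_length - anthro.tibia_length) > 1e-9:
        raise ValueError("geometry and anthropometrics disagree on tibia length")
    load = net_knee_load(trial, anthro, quasi_static=quasi_static)
    if brace is not None:
        load = apply_brace(load, brace, trial.knee_flexion)

    n = len(trial)
    bw = anthro.body_weight
    forces = {ch: np.zeros(n) for ch in FORCE_CHANNELS}
    selected, fallback = [], np.zeros(n, bool)
    descent, _ = split_phases(trial)
    phase = np.where(np.arange(n) < (descent[-1] + 1), "descent", "ascent")

    for i in range(n):
        theta = float(trial.knee_flexion[i])
        try:
            state = solve_four_bar(geom, theta)
            loas = structure_loas(geom, state)
            cands = candidate_solutions(loas, load.sample(i))
            sel = select_solution(cands)
            f_qt = f_pf = 0.0
            if sel.tendon_id == "PT" and sel.f_tendon > 0:
                f_qt, f_pf = patella_equilibrium(max(sel.f_tendon, 0.0), loas)
        except Exception as e:
            if on_error == "raise":
                raise RuntimeError(f"tissue force solve failed at sample {i} "
                                   f"({theta:g} deg): {e}") from e
            for ch in FORCE_CHANNELS:
                forces[ch][i] = np.nan
            selected.append("failed")
            fallback[i] = True
            continue
        forces["F_TF"][i] = sel.f_tf / bw
        forces[f"F_{sel.tendon_id}"][i] = sel.f_tendon / bw
        forces[f"F_{sel.ligament_id}"][i] = sel.f_ligament / bw
        forces["F_QT"][i] = f_qt / bw
        forces["F_PF"][i] = f_pf / bw
        selected.append(f"{sel.tendon_id}-{sel.ligament_id}")
        fallback[i] = sel.fallback

    return TissueForceSeries(
        time=trial.time.copy(),
        flexion=trial.knee_flexion.copy(),
        forces=forces,
        selected_candidate=selected,
        fallback=fallback,
        valid=trial.knee_flexion <= VALID_FLEXION_MAX,
        phase=phase,
        body_weight=bw,
        meta={"leg_id": trial.leg_id,
              "brace": brace.name if brace is not None else "none",
              **trial.meta},
    )
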