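"""Seeded synthetic deep-knee-bend (DKB) cohort generator.

The motion data the analysis needs (healthy adults performing two-legged
deep knee bends on side-by-side force plates) are not publicly deposited, so
this module generates a statistically matched stand-in cohort: n = 8
subjects, mass 66 +/- 12 kg, height 164 +/- 8 cm, mostly female, three
repetitions per leg, peak knee flexion <= 135 degrees.

Trials are *forward-constructed*: the generator prescribes the knee flexion
trajectory (smooth, single peak at 50% of the cycle) and the internal knee
extensor moment demand (smooth, peaking later in the cycle — the load-skew
seen in squatting, default 60%), then solves for the centre of pressure that
produces exactly that moment under quasi-static equilibrium.  Running the
inverse-dynamics stage on a generated trial therefore recovers the
prescribed loads to machine precision, which makes every downstream stage
testable against known ground truth.  Realism knobs (per-repetition
amplitude jitter, smooth waveform noise, leg load share) perturb the
*prescription*, never the construction.

All randomness flows from one master seed through
``numpy.random.default_rng`` with deterministic per-subject/rep/leg streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import GRAVITY, AnthroParams, TrialData

__all__ = ["SyntheticCohortSpec", "generate_cohort", "generate_dkb_trial",
           "generate_trials"]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study conditions the generator emulates."""

    n_subjects: int = 8
    mass_mean: float = 66.0  # kg
    mass_sd: float = 12.0
    height_mean: float = 1.64  # m
    height_sd: float = 0.08
    female_fraction: float = 6.0 / 8.0
    tibia_height_ratio: float = 0.246  # shank length / stature (Winter)
    peak_flexion_mean: float = 122.0  # deg
    peak_flexion_sd: float = 8.0
    peak_flexion_range: tuple = (105.0, 135.0)
    cycle_duration: float = 4.0  # s
    n_samples: int = 111
    load_skew: float = 0.60  # fraction of cycle where knee loads peak
    knee_moment_peak_per_mass: float = 1.0  # N*m/kg, per leg (deep two-leg squat)
    knee_moment_sd_frac: float = 0.10  # between-subject moment scale SD
    shank_lean_max: float = 25.0  # deg forward shank lean at peak flexion
    # standing flexion offsets: the start posture is standardized (small
    # spread); the end posture drifts more across subjects, as seen in
    # repeated squat testing.  Both in degrees.
    start_flexion_mean: float = 4.0
    start_flexion_sd: float = 2.5
    end_flexion_mean: float = 8.0
    end_flexion_sd: float = 4.0
    rep_jitter: float = 0.02  # per-repetition amplitude jitter (fraction)
    waveform_noise: float = 0.02  # smooth within-trial moment noise (fraction)
    leg_share_sd: float = 0.02  # between-leg vertical load share SD
    n_reps: int = 3

    def __post_init__(self):
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        for name in ("mass_sd", "height_sd", "rep_jitter", "waveform_noise",
                     "leg_share_sd", "knee_moment_sd_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        lo, hi = self.peak_flexion_range
        if not (0 < lo < hi <= 135.0):
            raise ValueError("peak flexion range must lie within (0, 135]")
        if not (0.0 < self.load_skew < 1.0):
            raise ValueError("load_skew must be a cycle fraction in (0, 1)")


def _truncated_normal(rng, mean, sd, lo, hi, max_tries=1000):
    if sd == 0:
        if not (lo <= mean <= hi):
            raise ValueError("degenerate draw outside bounds")
        return mean
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    raise ValueError("rejection sampling failed; impossible constraints")


@dataclass
class SyntheticSubject:
    anthro: AnthroParams
    sex: str
    age: float
    peak_flexion: float
    moment_scale: float  # N*m/kg
    subject_index: int

    @property
    def subject_id(self) -> str:
        return self.anthro.subject_id


def generate_cohort(spec: SyntheticCohortSpec, seed: int) -> list[SyntheticSubject]:
    """Draw the subjects. Deterministic under ``seed``."""
    rng = np.random.default_rng([int(seed), 101])
    subjects = []
    n_female = int(round(spec.female_fraction * spec.n_subjects))
    for i in range(spec.n_subjects):
        mass = _truncated_normal(rng, spec.mass_mean, spec.mass_sd, 40.0, 110.0)
        height = _truncated_normal(rng, spec.height_mean, spec.height_sd, 1.40, 1.95)
        peak = _truncated_normal(rng, spec.peak_flexion_mean, spec.peak_flexion_sd,
                                 *spec.peak_flexion_range)
        mscale = spec.knee_moment_peak_per_mass * (
            1.0 + spec.knee_moment_sd_frac * float(rng.standard_normal())
        )
        age = _truncated_normal(rng, 25.0, 5.0, 18.0, 45.0)
        anthro = AnthroParams(
            body_mass=mass, height=height,
            tibia_length=spec.tibia_height_ratio * height,
            subject_id=f"S{i+1:02d}",
        )
        subjects.append(SyntheticSubject(
            anthro=anthro, sex="F" if i < n_female else "M", age=age,
            peak_flexion=peak, moment_scale=max(mscale, 0.1), subject_index=i,
        ))
    return subjects


def _smooth_bump_noise(rng, tau, amplitude, n_modes=3):
    """Smooth zero-at-endpoints noise from a few random Fourier sine modes."""
    out = np.zeros_like(tau)
    for k in range(1, n_modes + 1):
        out += rng.normal(0.0, 1.0) * np.sin(math.pi * k * tau) / k
    return amplitude * out


def generate_dkb_trial(
    subject: SyntheticSubject,
    spec: SyntheticCohortSpec,
    seed: int,
    rep: int = 0,
    leg: str = "R",
) -> TrialData:
    """Forward-construct one DKB repetition for one leg.

    The prescribed knee extensor moment series is stored in
    ``trial.meta["prescribed_mz"]`` so downstream consistency can be audited.
    """
    leg_idx = {"R": 0, "L": 1}[leg]
    rng = np.random.default_rng([int(seed), 997, subject.subject_index, rep, leg_idx])
    anthro = subject.anthro
    n = spec.n_samples
    tau = np.linspace(0.0, 1.0, n)
    time = tau * spec.cycle_duration

    # flexion: single peak near 50% cycle, subject peak amplitude with small
    # per-repetition jitter, never exceeding the 135 deg inclusion cap.
    # Standing offsets blend in at the cycle ends: start posture is
    # standardized, end posture drifts more.
    amp = subject.peak_flexion * (1.0 + spec.rep_jitter * float(rng.standard_normal()))
    amp = float(np.clip(amp, 20.0, 135.0))
    o_start = float(np.clip(rng.normal(spec.start_flexion_mean,
                                       spec.start_flexion_sd), 0.5, 12.0))
    o_end = float(np.clip(rng.normal(spec.end_flexion_mean,
                                     spec.end_flexion_sd), 0.5, 14.0))
    offset = o_start + (o_end - o_start) * tau**2 * (3.0 - 2.0 * tau)
    bump = np.sin(math.pi * tau) ** 2
    flexion = offset + (amp - offset) * bump

    # shank lean follows flexion; ankle fixed; foot flat
    lean = np.radians(spec.shank_lean_max) * flexion / max(amp, 1e-9)
    ankle = np.array([0.0, 0.039 * anthro.height])
    knee = ankle + anthro.tibia_length * np.column_stack([np.sin(lean), np.cos(lean)])
    foot_origin = np.tile(ankle, (n, 1))
    foot_angle = np.zeros(n)

    # per-leg vertical ground reaction: half body weight with a mirrored leg
    # share (the two legs' shares sum to one) and a smooth modulation that
    # vanishes at the quasi-static start
    share_rng = np.random.default_rng([int(seed), 555, subject.subject_index, rep])
    eps = spec.leg_share_sd * float(share_rng.standard_normal())
    share = 1.0 + eps * (1.0 if leg == "R" else -1.0)
    bw = anthro.body_weight
    grf_y = 0.5 * bw * share * (1.0 + 0.05 * np.sin(2.0 * math.pi * tau)
                                * float(rng.uniform(0.3, 1.0)))
    grf = np.column_stack([np.zeros(n), grf_y])

    # prescribed internal extensor moment demand: smooth, zero at the ends,
    # peaking at the load-skew fraction of the cycle, plus smooth noise.
    # A plain (not squared) sine of the warped phase keeps the descent/ascent
    # load asymmetry moderate, as seen in squatting.
    c = math.log(0.5) / math.log(spec.load_skew)
    shape = np.sin(math.pi * tau**c)
    m_peak = subject.moment_scale * anthro.body_mass
    mz = m_peak * shape
    mz = mz * (1.0 + _smooth_bump_noise(rng, tau, spec.waveform_noise))
    mz = np.maximum(mz, 0.0)

    # solve the centre of pressure that realises the prescribed moment under
    # quasi-static equilibrium (gravity of shank and foot included)
    m_sh, c_sh, _ = anthro.segment("shank")
    m_ft, c_ft, _ = anthro.segment("foot")
    prox = np.column_stack([np.sin(lean), np.cos(lean)])
    com_sh = knee - c_sh * prox
    com_ft = foot_origin + c_ft * np.column_stack(
        [np.cos(foot_angle), np.sin(foot_angle)]
    )
    cop_x = knee[:, 0] + (
        -mz
        + (com_sh[:, 0] - knee[:, 0]) * m_sh * GRAVITY
        + (com_ft[:, 0] - knee[:, 0]) * m_ft * GRAVITY
    ) / grf_y

    return TrialData(
        time=time,
        knee_flexion=flexion,
        shank_angle=lean,
        shank_origin=knee,
        foot_angle=foot_angle,
        foot_origin=foot_origin,
        grf=grf,
        cop_x=cop_x,
        leg_id=leg,
        meta={
            "subject_id": subject.subject_id,
            "rep": rep,
            "prescribed_mz": mz,
            "peak_flexion": amp,
        },
    )


def generate_trials(
    subject: SyntheticSubject, spec: SyntheticCohortSpec, seed: int,
    legs: tuple = ("R", "L"),
) -> list[TrialData]:
    """All repetitions for all requested legs of one subject."""
    return [
        generate_dkb_trial(subject, spec, seed, rep=r, leg=leg)
        for leg in legs
        for r in range(spec.n_reps)
    ]
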