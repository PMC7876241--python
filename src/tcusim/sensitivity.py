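"""Geometric-uncertainty propagation and the variability ratio.

Knee geometry is scaled from a generic template, not measured per subject,
so each of the M = 14 geometric parameters carries an assumed measurement
uncertainty: +/- 5 mm for linear dimensions, +/- 5 degrees for angular ones
(MRI attachment-identification precision).  Each parameter's effect on an
output force channel is the central half-difference of the pipeline re-run
at +delta and -delta; the per-parameter deviations combine through the
maximum-likelihood (mean-square) estimator

    dF^2 = (sum_i dF_i^2) / M

with per-parameter contributions eps_i = dF_i^2 / (dF^2 M) summing to one.
Model trustworthiness is judged by the variability ratio v = dF^2 / sigma_F^2
against between-subject variance sigma_F^2, with v < 0.2 the acceptability
threshold.  Everything is evaluated on a 1-degree flexion grid over the
descent phase, deviations averaged across subjects before combining.

A Monte-Carlo cross-check draws all parameters jointly (each with SD
delta_i / sqrt(M), so that for a locally linear response the output SD
estimates the same mean-square quantity as the Taylor combination) and
reports the output SD across draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .brace import BraceModel
from .dynamics import AnthroParams, TrialData, split_phases
from .geometry import KneeGeometry, PARAM_REGISTRY
from .tissue_forces import FORCE_CHANNELS, solve_trial

__all__ = [
    "DELTA_LINEAR",
    "DELTA_ANGULAR",
    "UPSILON_THRESHOLD",
    "UncertaintyReport",
    "force_vs_angle",
    "parameter_deviation",
    "combine_uncertainty",
    "contributions",
    "variability_ratio",
    "monte_carlo_uncertainty",
    "uncertainty_report",
    "default_delta",
]

DELTA_LINEAR = 0.005  # m
DELTA_ANGULAR = 5.0  # deg
#: acceptability threshold for the variability ratio
UPSILON_THRESHOLD = 0.2

M_PARAMS = len(PARAM_REGISTRY)


def default_delta(param_name: str) -> float:
    tag = dict(PARAM_REGISTRY)[param_name]
    return DELTA_LINEAR if tag == "linear" else DELTA_ANGULAR


def force_vs_angle(
    trial: TrialData,
    geom: KneeGeometry,
    anthro: AnthroParams,
    angle_grid: np.ndarray,
    brace: BraceModel | None = None,
    phase: str = "descent",
    channels=FORCE_CHANNELS,
) -> dict:
    """Channel forces (BW) interpolated onto a flexion-angle grid.

    Solves the tissue-force pipeline for the trial and linearly interpolates
    the requested phase's samples against flexion angle.  Grid points
    outside the achieved flexion range, or where the pipeline failed, are
    NaN.  Fallback-flagged samples (no admissible candidate — the model's
    deep-flexion degeneracy) are masked too: they are not valid equilibria.
    """
    series = solve_trial(trial, geom, anthro, brace=brace, on_error="nan")
    descent, ascent = split_phases(trial)
    idx = descent if phase == "descent" else ascent
    theta = series.flexion[idx]
    order = np.argsort(theta)
    theta = theta[order]
    fb = series.fallback[idx][order]
    grid = np.asarray(angle_grid, float)
    out = {}
    for ch in channels:
        f = np.where(fb, np.nan, series.forces[ch][idx][order])
        good = np.isfinite(f)
        if good.sum() < 2:
            out[ch] = np.full_like(grid, np.nan)
            continue
        vals = np.interp(grid, theta[good], f[good],
                         left=np.nan, right=np.nan)
        # propagate in-range failures: mask grid points nearest a NaN sample
        if not good.all():
            width = float(np.diff(grid).max()) if len(grid) > 1 else 1.0
            for ba in theta[~good]:
                vals[np.abs(grid - ba) <= width] = np.nan
        out[ch] = vals
    return out


def parameter_deviation(
    geom: KneeGeometry,
    trial: TrialData,
    anthro: AnthroParams,
    param_name: str,
    delta: float | None = None,
    angle_grid: np.ndarray | None = None,
    channels=FORCE_CHANNELS,
) -> dict:
    """Central half-difference force deviation for one parameter.

    Re-solves the full pipeline at param +/- delta and returns
    |F(+d) - F(-d)| / 2 per channel on the angle grid (NaN where either
    perturbed pipeline is unsolvable).
    """
    if delta is None:
        delta = default_delta(param_name)
    if angle_grid is None:
        angle_grid = np.arange(0.0, 135.5, 1.0)
    if delta == 0.0:
        zero = np.zeros_like(np.asarray(angle_grid, float))
        return {ch: zero.copy() for ch in channels}
    value = geom.param(param_name)
    out = {}
    sides = []
    for sgn in (+1.0, -1.0):
        try:
            g = geom.with_param(param_name, value + sgn * delta)
            sides.append(force_vs_angle(trial, g, anthro, angle_grid,
                                        channels=channels))
        except Exception:
            sides.append({ch: np.full(len(angle_grid), np.nan) for ch in channels})
    for ch in channels:
        out[ch] = np.abs(sides[0][ch] - sides[1][ch]) / 2.0
    return out


def combine_uncertainty(deviations) -> np.ndarray:
    """Total uncertainty dF = sqrt( (sum_i dF_i^2) / M ) per grid point.

    ``deviations`` is a mapping param -> series or an (M, n) array; exactly
    M = 14 parameter series are required.
    """
    if isinstance(deviations, dict):
        missing = [n for n, _ in PARAM_REGISTRY if n not in deviations]
        if missing:
            raise ValueError(f"missing parameter deviation series: {missing}")
        arr = np.vstack([np.asarray(deviations[n], float)
                         for n, _ in PARAM_REGISTRY])
    else:
        arr = np.atleast_2d(np.asarray(deviations, float))
    if arr.shape[0] != M_PARAMS:
        raise ValueError(f"expected {M_PARAMS} parameter series, got {arr.shape[0]}")
    return np.sqrt(np.sum(arr**2, axis=0) / M_PARAMS)


def contributions(deviations, delta_f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-parameter contributions eps_i = dF_i^2 / (dF^2 M).

    Returns ``(eps, degenerate)`` where ``eps`` is (M, n) summing to 1 along
    axis 0 wherever dF > 0; points with dF = 0 get the uniform 1/M and are
    flagged in the boolean ``degenerate`` mask.
    """
    if isinstance(deviations, dict):
        arr = np.vstack([np.asarray(deviations[n], float)
                         for n, _ in PARAM_REGISTRY])
    else:
        arr = np.atleast_2d(np.asarray(deviations, float))
    if arr.shape[0] != M_PARAMS:
        raise ValueError(f"expected {M_PARAMS} parameter series")
    df = np.asarray(delta_f, float)
    degenerate = ~(df > 0)
    denom = np.where(degenerate, 1.0, df**2 * M_PARAMS)
    eps = arr**2 / denom
    eps[:, degenerate] = 1.0 / M_PARAMS
    return eps, degenerate


def variability_ratio(delta_f: np.ndarray, sigma_f: np.ndarray) -> np.ndarray:
    """v = dF^2 / sigma_F^2; +inf (not an error) where sigma_F = 0."""
    df = np.asarray(delta_f, float)
    sf = np.asarray(sigma_f, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = df**2 / sf**2
    v = np.where((sf == 0) & (df > 0), np.inf, v)
    v = np.where((sf == 0) & (df == 0), 0.0, v)
    return v


def monte_carlo_uncertainty(
    geom: KneeGeometry,
    trial: TrialData,
    anthro: AnthroParams,
    n_draws: int = 200,
    seed: int = 0,
    angle_grid: np.ndarray | None = None,
    channels=FORCE_CHANNELS,
    scale: float = 1.0,
) -> tuple[dict, int]:
    """Output-force SD across joint random draws of all 14 parameters.

    Each parameter is drawn normally with SD ``scale * delta_i / sqrt(M)``
    so the result estimates the same mean-square combination as the Taylor
    formula for a locally linear response.  Returns ``(sd_per_channel,
    n_discarded)``; draws with unsolvable geometry are discarded and
    counted.
    """
    if n_draws < 2:
        raise ValueError("need at least 2 draws")
    if angle_grid is None:
        angle_grid = np.arange(0.0, 135.5, 1.0)
    rng = np.random.default_rng(seed)
    samples = {ch: [] for ch in channels}
    discarded = 0
    for _ in range(n_draws):
        g = geom
        try:
            for name, _tag in PARAM_REGISTRY:
                sd = scale * default_delta(name) / math.sqrt(M_PARAMS)
                g = g.with_param(name, g.param(name) + rng.normal(0.0, sd))
        except Exception:
            discarded += 1
            continue
        fv = force_vs_angle(trial, g, anthro, angle_grid, channels=channels)
        if any(np.all(np.isnan(fv[ch])) for ch in channels):
            discarded += 1
            continue
        for ch in channels:
            samples[ch].append(fv[ch])
    out = {}
    for ch in channels:
        if len(samples[ch]) < 2:
            out[ch] = np.full(len(angle_grid), np.nan)
        else:
            out[ch] = np.nanstd(np.vstack(samples[ch]), axis=0, ddof=1)
    return out, discarded


@dataclass
class UncertaintyReport:
    """Combined geometric-uncertainty report over an angle grid."""

    angle_grid: np.ndarray
    channels: tuple
    deviations: dict  # channel -> (M, n) per-parameter deviations (BW)
    delta_f: dict  # channel -> (n,) combined uncertainty (BW)
    epsilon: dict  # channel -> (M, n) contributions
    degenerate: dict  # channel -> (n,) bool mask where eps is uniform
    sigma_f: dict  # channel -> (n,) between-subject SD (BW)
    upsilon: dict  # channel -> (n,) variability ratio
    m_params: int = M_PARAMS
    delta_linear: float = DELTA_LINEAR
    delta_angular: float = DELTA_ANGULAR
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        names = [n for n, _ in PARAM_REGISTRY]
        rows = []
        for ch in self.channels:
            eps = self.epsilon[ch]
            top = np.argmax(eps, axis=0)
            for j, ang in enumerate(self.angle_grid):
                rows.append({
                    "channel": ch,
                    "flexion_deg": float(ang),
                    "delta_F_BW": float(self.delta_f[ch][j]),
                    "sigma_F_BW": float(self.sigma_f[ch][j]),
                    "upsilon": float(self.upsilon[ch][j]),
                    "top_contributor": names[int(top[j])],
                    "top_epsilon": float(eps[int(top[j]), j]),
                })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def uncertainty_report(
    subject_geoms: list,
    subject_trials: list,
    subject_anthros: list,
    angle_grid: np.ndarray | None = None,
    channels=("F_QT", "F_PF", "F_TF", "F_PC"),
) -> UncertaintyReport:
    """Cohort-level uncertainty propagation (descent phase).

    Per-subject parameter deviations are averaged across subjects before the
    mean-square combination; sigma_F is the between-subject SD of the
    unperturbed force waveforms on the same grid.
    """
    if not (len(subject_geoms) == len(subject_trials) == len(subject_anthros)):
        raise ValueError("per-subject inputs must align")
    if angle_grid is None:
        angle_grid = np.arange(0.0, 121.0, 1.0)
    n = len(angle_grid)
    names = [p for p, _ in PARAM_REGISTRY]

    per_subj_dev = []  # subject -> channel -> (M, n)
    per_subj_force = []  # subject -> channel -> (n,)
    for geom, trial, anthro in zip(subject_geoms, subject_trials, subject_anthros):
        devs = {ch: np.empty((M_PARAMS, n)) for ch in channels}
        for i, pname in enumerate(names):
            d = parameter_deviation(geom, trial, anthro, pname,
                                    angle_grid=angle_grid, channels=channels)
            for ch in channels:
                devs[ch][i] = d[ch]
        per_subj_dev.append(devs)
        per_subj_force.append(
            force_vs_angle(trial, geom, anthro, angle_grid, channels=channels)
        )

    deviations, delta_f, epsilon, degenerate, sigma_f, upsilon = (
        {}, {}, {}, {}, {}, {}
    )
    import warnings
    for ch in channels:
        with warnings.catch_warnings():
            # grid points beyond every subject's range are all-NaN slices
            warnings.simplefilter("ignore", RuntimeWarning)
            dev = np.nanmean(np.stack([s[ch] for s in per_subj_dev]), axis=0)
            forces = np.vstack([s[ch] for s in per_subj_force])
            sigma_f[ch] = np.nanstd(forces, axis=0, ddof=1)
        deviations[ch] = dev
        delta_f[ch] = combine_uncertainty(dev)
        epsilon[ch], degenerate[ch] = contributions(dev, delta_f[ch])
        upsilon[ch] = variability_ratio(delta_f[ch], sigma_f[ch])

    return UncertaintyReport(
        angle_grid=np.asarray(angle_grid, float),
        channels=tuple(channels),
        deviations=deviations,
        delta_f=delta_f,
        epsilon=epsilon,
        degenerate=degenerate,
        sigma_f=sigma_f,
        upsilon=upsilon,
    )
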