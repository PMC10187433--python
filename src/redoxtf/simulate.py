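"""Generative simulator of single-cell FOXO1/p53 trajectories and snapshots.

The PRDX/SRXN1 switch (:mod:`redoxtf.switch`) is deterministic for a given
dose; cell-to-cell variability enters through (i) per-cell jitter on the
hyperoxidation thresholds, which creates the dose-dependent responder
fraction, (ii) per-cell p53 amplitude variability, (iii) the stochastic
p53 waveform mode (oscillatory vs sustained, with the sustained probability
increasing with dose), (iv) a stochastic death time drawn from a hazard that
grows with time spent in the FOXO1 phase and with the p53 level, and (v)
multiplicative lognormal measurement noise.

Ground truth (phase window, p53 onset, waveform mode, dose) is carried on
every simulated cell so the downstream detection stages can be scored
against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, InputError, ParameterError
from .params import (DEFAULT_PARAMS, FRAME_MIN, T_END_MIN, DosePreset,
                     SwitchParams)
from .switch import integrate_switch

__all__ = [
    "NoiseModel", "DEFAULT_NOISE", "NOISE_FREE",
    "TrajectoryTruth", "CellTrajectory", "SnapshotCell",
    "foxo_waveform", "p53_waveform",
    "generate_trajectory", "generate_population", "generate_snapshot",
    "calibrate_death",
    "population_to_frame", "frame_to_population",
    "snapshot_to_frame", "frame_to_snapshot",
]

# --- waveform constants (a.u. and minutes) --------------------------------
FOXO_BASELINE_NF = 0.25   # cytoplasmic-resting nuclear fraction
FOXO_ACTIVE_NF = 0.85     # nuclear fraction target during the FOXO1 phase
P53_BASELINE = 100.0      # nuclear p53 baseline, a.u.
OSC_AMP = 1.5             # relative amplitude of the oscillatory p53 mode
OSC_FLOOR = 0.35          # elevated-baseline share of the active p53 response
OSC_PERIOD = 330.0        # p53 pulse period, min (free default)
SUS_AMP_MULT = 2.0        # sustained amplitude as multiple of oscillatory
SUS_RAMP_TAU = 150.0      # saturating-ramp time constant of sustained mode
LOWDOSE_DELAY = 20.0      # p53 onset delay when no FOXO1 phase occurs (1 frame)
K_ACT_UM = 15.0           # half-dose of the low-dose p53 activation route
GH2AX_BASE = 100.0        # gamma-H2AX baseline, a.u.
GH2AX_MAX_FOLD = 4.0      # saturating fold increase of gamma-H2AX
GH2AX_KD_UM = 150.0       # half-saturation dose of gamma-H2AX induction
HAZARD_A_PHASE = 3e-7     # death hazard per min of elapsed phase time, /min^2
HAZARD_B_P53 = 3e-6       # death hazard per unit excess p53, /(a.u. min)
P53_DEATH_THRESH = 250.0  # p53 level above which the apoptotic hazard acts


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic-variability settings for the simulator.

    ``sigma_meas``/``sigma_snap``/``sigma_gh`` are lognormal sigmas of the
    multiplicative measurement noise (trajectory frames, snapshot readout,
    gamma-H2AX); ``theta_cv`` is the per-cell CV of the hyperoxidation
    thresholds; ``onset_sd`` the SD (min) of the p53-onset jitter (clipped
    at 3 SD so onset always follows exit); ``amp_cv`` the lognormal sigma
    of the per-cell p53 amplitude; ``duration_cv`` the lognormal sigma of
    the per-cell phase-duration scale, standing for cell-to-cell variation
    in repair (SRXN1) capacity -- this is what spreads FOXO1 nuclear
    residence times across a population at one dose.
    """

    sigma_meas: float = 0.1
    sigma_snap: float = 0.1
    sigma_gh: float = 0.2
    theta_cv: float = 0.1
    onset_sd: float = 10.0
    amp_cv: float = 0.25
    duration_cv: float = 0.4

    def scaled(self, factor: float) -> "NoiseModel":
        return NoiseModel(*(factor * v for v in
                            (self.sigma_meas, self.sigma_snap, self.sigma_gh,
                             self.theta_cv, self.onset_sd, self.amp_cv,
                             self.duration_cv)))


DEFAULT_NOISE = NoiseModel()
NOISE_FREE = NoiseModel(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class TrajectoryTruth:
    """Ground-truth schedule of one simulated cell."""

    t_entry: float | None
    t_exit: float | None
    t_onset: float | None
    mode: str                 # "oscillatory", "sustained", or "none"
    dose: float


@dataclass
class CellTrajectory:
    """Per-cell time series of FOXO1 nuclear fraction and nuclear p53."""

    cell_id: str
    t: np.ndarray
    foxo1_nf: np.ndarray
    p53: np.ndarray
    died: bool
    t_death: float | None
    truth: TrajectoryTruth

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.foxo1_nf) == len(self.p53)):
            raise InputError("series lengths must equal the time grid length")


@dataclass(frozen=True)
class SnapshotCell:
    """One cell of an immunofluorescence-like snapshot population."""

    cell_id: str
    dose: float
    p53_nuc: float
    foxo1_nf: float
    gh2ax: float
    truth_foxo_active: bool
    truth_p53_active: bool


# ---------------------------------------------------------------------------
# Waveforms
# ---------------------------------------------------------------------------

def foxo_waveform(t: np.ndarray, t_entry: float | None, t_exit: float | None,
                  params: SwitchParams = DEFAULT_PARAMS) -> np.ndarray:
    """Noise-free FOXO1 nuclear-fraction series on the frame grid ``t``.

    Discrete first-order relaxation toward the active target while the frame
    time lies in ``[t_entry, t_exit)`` and toward baseline otherwise, with
    relaxation time ``params.tau_f`` applied over each frame interval.
    """
    t = np.asarray(t, dtype=float)
    if len(t) == 0:
        raise InputError("time grid must be non-empty")
    in_phase = np.zeros(len(t), dtype=bool)
    if t_entry is not None:
        hi_end = t_exit if t_exit is not None else np.inf
        in_phase = (t >= t_entry) & (t < hi_end)
    target = np.where(in_phase, FOXO_ACTIVE_NF, FOXO_BASELINE_NF)
    nf = np.empty(len(t))
    nf[0] = target[0]
    if len(t) > 1:
        decay = math.exp(-float(t[1] - t[0]) / params.tau_f)
        for k in range(1, len(t)):
            nf[k] = target[k] + (nf[k - 1] - target[k]) * decay
    return nf


def p53_waveform(t: np.ndarray, t_onset: float | None, mode: str,
                 amp: float = OSC_AMP) -> np.ndarray:
    """Noise-free nuclear p53 series on the frame grid ``t``.

    At onset the level steps to an elevated floor -- p53 stabilization is
    abrupt relative to the 20-min frame spacing, which keeps onset
    detection within one frame of the truth.  Oscillatory mode then adds a
    raised-cosine pulse train of period :data:`OSC_PERIOD`; sustained mode
    adds a saturating ramp whose maximum is :data:`SUS_AMP_MULT` times the
    oscillatory amplitude (p53 reaches higher levels in the sustained
    mode).  Before onset (or when ``t_onset`` is None) the series sits at
    :data:`P53_BASELINE`.
    """
    t = np.asarray(t, dtype=float)
    p = np.full(len(t), P53_BASELINE)
    if t_onset is None:
        return p
    if mode not in ("oscillatory", "sustained"):
        raise InputError(f"mode must be oscillatory or sustained, got {mode!r}")
    tau = t - t_onset
    on = tau >= 0
    tau = np.where(on, tau, 0.0)
    if mode == "oscillatory":
        act = amp * (OSC_FLOOR
                     + (1.0 - OSC_FLOOR) * 0.5 * (1.0 - np.cos(2.0 * np.pi * tau / OSC_PERIOD)))
    else:
        act = amp * SUS_AMP_MULT * (OSC_FLOOR + (1.0 - OSC_FLOOR)
                                    * (1.0 - np.exp(-tau / SUS_RAMP_TAU)))
    p[on] = P53_BASELINE * (1.0 + act[on])
    return p


# ---------------------------------------------------------------------------
# Batch machinery
# ---------------------------------------------------------------------------

def _frame_grid() -> np.ndarray:
    return np.arange(0.0, T_END_MIN + 0.5 * FRAME_MIN, FRAME_MIN)


def _phase_times_for_thresholds(states, th_on: np.ndarray, th_off: np.ndarray
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized hysteresis schedule for per-cell thresholds (NaN = never)."""
    h, t = states.h, states.t
    n = len(th_on)
    above = h[None, :] >= th_on[:, None]              # (n, T)
    has_entry = above.any(axis=1)
    i_entry = np.argmax(above, axis=1)
    t_entry = np.where(has_entry, t[np.minimum(i_entry, len(t) - 1)], np.nan)
    below = (h[None, :] <= th_off[:, None]) & (t[None, :] > t_entry[:, None])
    has_exit = has_entry & below.any(axis=1)
    i_exit = np.argmax(below, axis=1)
    t_exit = np.where(has_exit, t[np.minimum(i_exit, len(t) - 1)], np.nan)
    return t_entry, t_exit


@dataclass
class _Batch:
    """Vectorized latent state of ``n`` simulated cells (NaN = undefined)."""

    t: np.ndarray            # frame grid (F,)
    t_entry: np.ndarray      # (n,)
    t_exit: np.ndarray
    t_onset: np.ndarray
    mode: np.ndarray         # object array of "oscillatory"/"sustained"/"none"
    foxo_clean: np.ndarray   # (n, F)
    p53_clean: np.ndarray    # (n, F)
    cum_hazard1: np.ndarray  # (n, F) cumulative hazard at death_mult = 1
    dose: float


def _simulate_batch(params: SwitchParams, preset: DosePreset, n: int,
                    rng: np.random.Generator, noise: NoiseModel) -> _Batch:
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    states = integrate_switch(params, preset.H0, t_end=T_END_MIN, dt=1.0)
    t = _frame_grid()
    nf_lo, nf_hi = FOXO_BASELINE_NF, FOXO_ACTIVE_NF

    # (i) per-cell hyperoxidation thresholds (hysteresis ratio preserved)
    z_th = rng.standard_normal(n)
    th_on = np.clip(params.theta_on * (1.0 + noise.theta_cv * z_th), 0.02, 0.99)
    th_off = th_on * (params.theta_off / params.theta_on)
    t_entry, t_exit = _phase_times_for_thresholds(states, th_on, th_off)
    # per-cell repair capacity: lognormal scale on the phase duration
    z_dur = rng.standard_normal(n)
    dur_scale = np.exp(noise.duration_cv * z_dur - 0.5 * noise.duration_cv ** 2)
    scaled_exit = t_entry + (t_exit - t_entry) * dur_scale
    t_exit = np.where(scaled_exit > T_END_MIN, np.nan, scaled_exit)

    # (ii) p53 onset: after the phase (exit + tau_p53 + clipped jitter), or
    # via the low-dose route when no phase occurs at a positive dose.
    z_onset = np.clip(rng.standard_normal(n), -3.0, 3.0) * noise.onset_sd
    u_act = rng.random(n)
    has_phase = ~np.isnan(t_entry)
    has_exit = ~np.isnan(t_exit)
    t_onset = np.full(n, np.nan)
    t_onset[has_exit] = t_exit[has_exit] + params.tau_p53 + z_onset[has_exit]
    if preset.H0 > 0:
        p_act = preset.H0 / (preset.H0 + K_ACT_UM)
        lowdose = (~has_phase) & (u_act < p_act)
        t_onset[lowdose] = LOWDOSE_DELAY
    t_onset[t_onset > T_END_MIN] = np.nan

    # (iii) waveform mode and per-cell amplitude.  The sustained-mode
    # probability is the preset's logistic in dose evaluated at the cell's
    # effective dose (dose x repair-capacity scale): weak-repair cells both
    # hold FOXO1 longer and mount a sustained rather than pulsatile p53
    # response, coupling long phases, high p53, and death.
    u_mode = rng.random(n)
    if preset.H0 > 0:
        eff = preset.H0 * dur_scale
        p_sus = 1.0 / (1.0 + np.exp(-(eff - preset.mode_mid) / preset.mode_scale))
    else:
        p_sus = np.zeros(n)
    sustained = u_mode < p_sus
    mode = np.where(np.isnan(t_onset), "none",
                    np.where(sustained, "sustained", "oscillatory")).astype(object)
    amp = OSC_AMP * np.exp(noise.amp_cv * rng.standard_normal(n))

    # clean series (vectorized across cells, frame loop for FOXO relaxation)
    hi_end = np.where(has_exit, t_exit, np.inf)
    in_phase = (t[None, :] >= t_entry[:, None]) & (t[None, :] < hi_end[:, None])
    in_phase &= has_phase[:, None]
    target = np.where(in_phase, nf_hi, nf_lo)
    foxo = np.empty((n, len(t)))
    foxo[:, 0] = target[:, 0]
    decay = math.exp(-FRAME_MIN / params.tau_f)
    for k in range(1, len(t)):
        foxo[:, k] = target[:, k] + (foxo[:, k - 1] - target[:, k]) * decay

    tau = t[None, :] - t_onset[:, None]
    on = ~np.isnan(t_onset[:, None]) & (tau >= 0)
    tau = np.where(on, tau, 0.0)
    osc = (OSC_FLOOR
           + (1.0 - OSC_FLOOR) * 0.5 * (1.0 - np.cos(2.0 * np.pi * tau / OSC_PERIOD)))
    sus = SUS_AMP_MULT * (OSC_FLOOR + (1.0 - OSC_FLOOR)
                          * (1.0 - np.exp(-tau / SUS_RAMP_TAU)))
    act = amp[:, None] * np.where(sustained[:, None], sus, osc)
    p53 = P53_BASELINE * (1.0 + np.where(on, act, 0.0))

    # (iv) death hazard at unit multiplier, integrated on the frame grid.
    # The p53 arm acts on the excess above a high threshold so that death
    # strikes cells whose p53 has climbed to sustained, near-plateau levels
    # (dying cells reach higher p53 than survivors) rather than accruing
    # uniformly over any p53 exposure.
    elapsed = np.where(in_phase, t[None, :] - t_entry[:, None], 0.0)
    lam1 = (HAZARD_A_PHASE * elapsed
            + HAZARD_B_P53 * np.maximum(p53 - P53_DEATH_THRESH, 0.0))
    cum1 = np.concatenate(
        [np.zeros((n, 1)),
         np.cumsum(0.5 * (lam1[:, 1:] + lam1[:, :-1]) * FRAME_MIN, axis=1)],
        axis=1)

    return _Batch(t=t, t_entry=t_entry, t_exit=t_exit, t_onset=t_onset,
                  mode=mode, foxo_clean=foxo, p53_clean=p53,
                  cum_hazard1=cum1, dose=preset.H0)


def _sample_death(batch: _Batch, death_mult: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Death times (NaN = survives) by inverting the cumulative hazard."""
    n, F = batch.cum_hazard1.shape
    target = rng.exponential(1.0, size=n)
    t_death = np.full(n, np.nan)
    if death_mult <= 0:
        return t_death
    cum = death_mult * batch.cum_hazard1
    reached = cum[:, -1] >= target
    idx = np.argmax(cum >= target[:, None], axis=1)  # first frame at/after
    for i in np.nonzero(reached)[0]:
        k = idx[i]
        c0, c1 = cum[i, k - 1], cum[i, k]
        frac = (target[i] - c0) / (c1 - c0) if c1 > c0 else 1.0
        t_death[i] = batch.t[k - 1] + frac * FRAME_MIN
    return t_death


def _observe(batch: _Batch, t_death: np.ndarray, rng: np.random.Generator,
             noise: NoiseModel) -> tuple[np.ndarray, np.ndarray]:
    """Apply measurement noise and censor frames after death with NaN."""
    n, F = batch.foxo_clean.shape
    if noise.sigma_meas > 0:
        foxo = np.clip(batch.foxo_clean
                       * np.exp(noise.sigma_meas * rng.standard_normal((n, F))),
                       0.0, 1.0)
        p53 = batch.p53_clean * np.exp(noise.sigma_meas * rng.standard_normal((n, F)))
    else:
        foxo = batch.foxo_clean.copy()
        p53 = batch.p53_clean.copy()
    dead = ~np.isnan(t_death)
    after = dead[:, None] & (batch.t[None, :] > np.where(dead, t_death, np.inf)[:, None])
    foxo[after] = np.nan
    p53[after] = np.nan
    return foxo, p53


def _batch_to_cells(batch: _Batch, foxo: np.ndarray, p53: np.ndarray,
                    t_death: np.ndarray, id_offset: int = 0
                    ) -> list[CellTrajectory]:
    cells = []
    for i in range(len(t_death)):
        truth = TrajectoryTruth(
            t_entry=None if np.isnan(batch.t_entry[i]) else float(batch.t_entry[i]),
            t_exit=None if np.isnan(batch.t_exit[i]) else float(batch.t_exit[i]),
            t_onset=None if np.isnan(batch.t_onset[i]) else float(batch.t_onset[i]),
            mode=str(batch.mode[i]), dose=batch.dose)
        died = not np.isnan(t_death[i])
        cells.append(CellTrajectory(
            cell_id=f"c{id_offset + i:05d}", t=batch.t.copy(),
            foxo1_nf=foxo[i], p53=p53[i], died=died,
            t_death=float(t_death[i]) if died else None, truth=truth))
    return cells


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------

def generate_trajectory(params: SwitchParams, preset: DosePreset,
                        rng: np.random.Generator,
                        noise: NoiseModel = DEFAULT_NOISE) -> CellTrajectory:
    """Simulate one cell: FOXO1 nuclear fraction and nuclear p53 over 24 h."""
    batch = _simulate_batch(params, preset, 1, rng, noise)
    t_death = _sample_death(batch, preset.death_mult, rng)
    foxo, p53 = _observe(batch, t_death, rng, noise)
    return _batch_to_cells(batch, foxo, p53, t_death)[0]


def generate_population(n: int, preset: DosePreset,
                        params: SwitchParams = DEFAULT_PARAMS,
                        seed: int | np.random.SeedSequence = 0,
                        noise: NoiseModel = DEFAULT_NOISE
                        ) -> list[CellTrajectory]:
    """Simulate ``n`` cells reproducibly (identical seed, identical output)."""
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    batch = _simulate_batch(params, preset, n, rng, noise)
    t_death = _sample_death(batch, preset.death_mult, rng)
    foxo, p53 = _observe(batch, t_death, rng, noise)
    return _batch_to_cells(batch, foxo, p53, t_death)


def generate_snapshot(n: int, preset: DosePreset, t_fix: float = 300.0,
                      params: SwitchParams = DEFAULT_PARAMS,
                      seed: int | np.random.SeedSequence = 0,
                      noise: NoiseModel = DEFAULT_NOISE) -> list[SnapshotCell]:
    """Simulate an immunofluorescence-like population fixed at ``t_fix``.

    Each cell is a latent trajectory sampled at ``t_fix`` with snapshot
    measurement noise; gamma-H2AX is drawn from a saturating monotone
    function of dose with lognormal noise.  Death is not modelled here:
    the snapshot measures cells fixed at 5 h, before most death events.
    """
    t = _frame_grid()
    if t_fix not in t:
        raise InputError(
            f"t_fix={t_fix} is outside the frame grid 0..{T_END_MIN} step {FRAME_MIN}")
    k_fix = int(np.argmax(t == t_fix))
    rng = np.random.default_rng(seed)
    batch = _simulate_batch(params, preset, n, rng, noise)

    foxo = batch.foxo_clean[:, k_fix]
    p53 = batch.p53_clean[:, k_fix]
    if noise.sigma_snap > 0:
        foxo = np.clip(foxo * np.exp(noise.sigma_snap * rng.standard_normal(n)), 0, 1)
        p53 = p53 * np.exp(noise.sigma_snap * rng.standard_normal(n))
    gh = GH2AX_BASE * (1.0 + GH2AX_MAX_FOLD * batch.dose / (batch.dose + GH2AX_KD_UM))
    gh = gh * np.exp(noise.sigma_gh * rng.standard_normal(n))

    hi_end = np.where(np.isnan(batch.t_exit), np.inf, batch.t_exit)
    foxo_active = (~np.isnan(batch.t_entry)) & (batch.t_entry <= t_fix) & (t_fix < hi_end)
    p53_active = (~np.isnan(batch.t_onset)) & (batch.t_onset <= t_fix)

    return [SnapshotCell(cell_id=f"c{i:05d}", dose=batch.dose,
                         p53_nuc=float(p53[i]), foxo1_nf=float(foxo[i]),
                         gh2ax=float(gh[i]),
                         truth_foxo_active=bool(foxo_active[i]),
                         truth_p53_active=bool(p53_active[i]))
            for i in range(n)]


# ---------------------------------------------------------------------------
# Death calibration
# ---------------------------------------------------------------------------

def calibrate_death(params: SwitchParams, preset: DosePreset,
                    target_fraction: float, n_mc: int = 20000,
                    tol: float = 0.005, seed: int = 12345,
                    mult_max: float = 50.0,
                    noise: NoiseModel = DEFAULT_NOISE) -> float:
    """Hazard multiplier whose Monte-Carlo death fraction matches the target.

    Bisection on the multiplier with common random numbers: the per-cell
    unit-multiplier cumulative hazards and exponential thresholds are drawn
    once, making the simulated death fraction monotone (and piecewise
    constant) in the multiplier so bisection converges cleanly.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise InputError(f"target_fraction must be in [0,1], got {target_fraction}")
    if target_fraction == 0.0:
        return 0.0
    rng = np.random.default_rng(seed)
    batch = _simulate_batch(params, preset, n_mc, rng, noise)
    total1 = batch.cum_hazard1[:, -1]
    thresholds = rng.exponential(1.0, size=n_mc)

    def frac(mult: float) -> float:
        return float(np.mean(mult * total1 >= thresholds))

    if frac(mult_max) < target_fraction - tol:
        raise CalibrationError(
            f"target fraction {target_fraction} unreachable with multiplier "
            f"<= {mult_max} (max achievable {frac(mult_max):.3f})")
    lo, hi = 0.0, mult_max
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        f = frac(mid)
        if abs(f - target_fraction) <= tol:
            return mid
        if f < target_fraction:
            lo = mid
        else:
            hi = mid
    f = frac(0.5 * (lo + hi))
    if abs(f - target_fraction) <= tol:
        return 0.5 * (lo + hi)
    raise CalibrationError(
        f"bisection did not reach target {target_fraction} within tol {tol} "
        f"(achieved {f:.4f}); the Monte-Carlo death fraction is too granular "
        f"at n_mc={n_mc}")


# ---------------------------------------------------------------------------
# Table conversion
# ---------------------------------------------------------------------------

def population_to_frame(cells: Sequence[CellTrajectory]) -> pd.DataFrame:
    """Long-format trajectory table (one row per cell and frame)."""
    frames = []
    for c in cells:
        tr = c.truth
        frames.append(pd.DataFrame({
            "cell_id": c.cell_id, "t_min": c.t,
            "foxo1_nf": c.foxo1_nf, "p53": c.p53,
            "died": c.died,
            "t_death": np.nan if c.t_death is None else c.t_death,
            "truth_t_entry": np.nan if tr.t_entry is None else tr.t_entry,
            "truth_t_exit": np.nan if tr.t_exit is None else tr.t_exit,
            "truth_t_onset": np.nan if tr.t_onset is None else tr.t_onset,
            "truth_mode": tr.mode, "truth_dose_uM": tr.dose,
        }))
    return pd.concat(frames, ignore_index=True)


def frame_to_population(df: pd.DataFrame) -> list[CellTrajectory]:
    """Inverse of :func:`population_to_frame`."""
    cells = []
    for cell_id, g in df.groupby("cell_id", sort=False):
        g = g.sort_values("t_min")
        first = g.iloc[0]

        def _opt(v: float) -> float | None:
            return None if pd.isna(v) else float(v)

        truth = TrajectoryTruth(
            t_entry=_opt(first["truth_t_entry"]),
            t_exit=_opt(first["truth_t_exit"]),
            t_onset=_opt(first["truth_t_onset"]),
            mode=str(first["truth_mode"]), dose=float(first["truth_dose_uM"]))
        cells.append(CellTrajectory(
            cell_id=str(cell_id), t=g["t_min"].to_numpy(float),
            foxo1_nf=g["foxo1_nf"].to_numpy(float),
            p53=g["p53"].to_numpy(float), died=bool(first["died"]),
            t_death=_opt(first["t_death"]), truth=truth))
    return cells


def snapshot_to_frame(cells: Sequence[SnapshotCell]) -> pd.DataFrame:
    return pd.DataFrame({
        "cell_id": [c.cell_id for c in cells],
        "dose_uM": [c.dose for c in cells],
        "p53_nuc": [c.p53_nuc for c in cells],
        "foxo1_nf": [c.foxo1_nf for c in cells],
        "gh2ax": [c.gh2ax for c in cells],
        "truth_foxo_active": [c.truth_foxo_active for c in cells],
        "truth_p53_active": [c.truth_p53_active for c in cells],
    })


def frame_to_snapshot(df: pd.DataFrame) -> list[SnapshotCell]:
    return [SnapshotCell(cell_id=str(r.cell_id), dose=float(r.dose_uM),
                         p53_nuc=float(r.p53_nuc), foxo1_nf=float(r.foxo1_nf),
                         gh2ax=float(r.gh2ax),
                         truth_foxo_active=bool(r.truth_foxo_active),
                         truth_p53_active=bool(r.truth_p53_active))
            for r in df.itertuples()]
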