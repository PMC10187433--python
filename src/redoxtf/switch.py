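"""Deterministic core of the PRDX/SRXN1 hyperoxidation switch.

Mass-action kinetics on the PRDX thiol-state fractions, with H2O2 cleared
at a rate proportional to the non-hyperoxidized PRDX pool (plus a small
PRDX-independent term), so that higher doses both hyperoxidize more PRDX
and persist longer -- the feedback that makes the FOXO1-on window (phase 1)
lengthen with dose::

    dr/dt = k_red*d - k_ox*H*r
    ds/dt = k_ox*H*r - k_ss*s - k_hyp*H*s + k_srx*h
    dd/dt = k_ss*s - k_red*d
    dh/dt = k_hyp*H*s - k_srx*h
    dH/dt = -(k_clear_base + k_clear_cell*prdx_scale*(1-h)) * H

``r`` reduced thiol, ``s`` sulfenic acid (SOH), ``d`` disulfide, ``h``
hyperoxidized (SO2H) fractions (summing to 1), ``H`` H2O2 in uM.

Integration is a fixed-step classical Runge-Kutta scheme (RK4) at
``dt = 1`` min by default: the system is non-stiff at these rates, and a
fixed-step explicit method keeps the output bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .params import SwitchParams

__all__ = ["RedoxState", "RedoxStates", "integrate_switch", "phase_schedule",
           "time_above", "states_to_frame"]


class RedoxState(NamedTuple):
    """One time point of the redox cycle: thiol-state fractions and H2O2."""

    t: float
    r: float
    s: float
    d: float
    h: float
    H: float


@dataclass(frozen=True)
class RedoxStates:
    """Trajectory of the redox cycle on a uniform time grid (minutes)."""

    t: np.ndarray
    r: np.ndarray
    s: np.ndarray
    d: np.ndarray
    h: np.ndarray
    H: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    def __getitem__(self, i: int) -> RedoxState:
        return RedoxState(self.t[i], self.r[i], self.s[i], self.d[i],
                          self.h[i], self.H[i])

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def to_frame(self) -> pd.DataFrame:
        return states_to_frame(self)


def _rhs(y: np.ndarray, p: SwitchParams) -> np.ndarray:
    r, s, d, h, H = y
    ox = p.k_ox * H * r
    hyp = p.k_hyp * H * s
    rep = p.k_srx * h
    return np.array([
        p.k_red * d - ox,
        ox - p.k_ss * s - hyp + rep,
        p.k_ss * s - p.k_red * d,
        hyp - rep,
        -(p.k_clear_base + p.k_clear_cell * p.prdx_scale * (1.0 - h)) * H,
    ])


def integrate_switch(params: SwitchParams, dose: float,
                     t_end: float = 1440.0, dt: float = 1.0,
                     substeps: int = 10) -> RedoxStates:
    """Integrate the redox cycle from a fully reduced pool at H2O2 = ``dose``.

    Parameters
    ----------
    params : SwitchParams
        Rate constants and thresholds.
    dose : float
        Initial H2O2 concentration, uM (bolus at t = 0).
    t_end, dt : float
        Final time and output grid spacing, minutes.
    substeps : int
        Fixed RK4 substeps per output step.  The initial oxidation burst at
        high dose is fast relative to a 1-min grid, so each output step is
        integrated with ``substeps`` equal RK4 steps; output is reported on
        the ``dt`` grid.

    Returns
    -------
    RedoxStates on the grid ``0, dt, ..., t_end``; the thiol-state
    fractions conserve mass (r+s+d+h = 1) to integrator accuracy.
    """
    if not isinstance(params, SwitchParams):
        raise ParameterError("params must be a SwitchParams instance")
    if dose < 0:
        raise ParameterError(f"dose must be >= 0, got {dose}")
    if dt <= 0:
        raise ParameterError(f"dt must be > 0, got {dt}")
    if t_end < dt:
        raise ParameterError(f"t_end must be >= dt, got t_end={t_end}, dt={dt}")
    if substeps < 1:
        raise ParameterError(f"substeps must be >= 1, got {substeps}")

    n = int(round(t_end / dt))
    t = np.arange(n + 1) * dt
    out = np.empty((n + 1, 5))
    y = np.array([1.0, 0.0, 0.0, 0.0, float(dose)])
    out[0] = y
    hstep = dt / substeps
    for i in range(n):
        for _ in range(substeps):
            k1 = _rhs(y, params)
            k2 = _rhs(y + 0.5 * hstep * k1, params)
            k3 = _rhs(y + 0.5 * hstep * k2, params)
            k4 = _rhs(y + hstep * k3, params)
            y = y + (hstep / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[i + 1] = y
    return RedoxStates(t=t, r=out[:, 0], s=out[:, 1], d=out[:, 2],
                       h=out[:, 3], H=out[:, 4])


def phase_schedule(states: RedoxStates | Sequence[RedoxState],
                   params: SwitchParams) -> tuple[float | None, float | None]:
    """FOXO1-on window induced by hysteresis thresholds on ``h``.

    Entry is the first time ``h >= theta_on``; exit is the first later time
    ``h <= theta_off``.  Returns ``(None, None)`` if ``h`` never reaches
    ``theta_on``, and ``(t_entry, None)`` if repair never brings ``h`` back
    below ``theta_off`` within the window.
    """
    if isinstance(states, RedoxStates):
        t, h = states.t, states.h
    else:
        if len(states) == 0:
            raise InputError("states must be non-empty")
        t = np.array([st.t for st in states], dtype=float)
        h = np.array([st.h for st in states], dtype=float)
    if len(t) == 0:
        raise InputError("states must be non-empty")
    if np.any(np.diff(t) <= 0):
        raise InputError("states must be strictly time-ordered")

    on = h >= params.theta_on
    if not on.any():
        return None, None
    i_entry = int(np.argmax(on))
    off = (h <= params.theta_off) & (t > t[i_entry])
    if not off.any():
        return float(t[i_entry]), None
    i_exit = int(np.argmax(off))
    return float(t[i_entry]), float(t[i_exit])


def time_above(states: RedoxStates, threshold: float) -> float:
    """Total time (min) the hyperoxidized fraction spends at/above ``threshold``."""
    if len(states) < 2:
        return 0.0
    dt = float(states.t[1] - states.t[0])
    return float(np.sum(states.h >= threshold)) * dt


def states_to_frame(states: RedoxStates) -> pd.DataFrame:
    """Tabulate a redox trajectory with the canonical CSV column names."""
    return pd.DataFrame({
        "t_min": states.t, "r": states.r, "s": states.s,
        "d": states.d, "h": states.h, "H_uM": states.H,
    })
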