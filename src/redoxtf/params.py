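"""Versioned default parameters for the PRDX/SRXN1 switch and dose presets.

The 2-Cys peroxiredoxin (PRDX) redox cycle is the mechanism that times the
FOXO1/p53 response: H2O2 oxidizes the peroxidatic cysteine to sulfenic acid
(SOH), which either resolves to an inter-monomer disulfide (recycled by the
thioredoxin system) or is hyperoxidized to sulfinic acid (SO2H) at high
H2O2.  Hyperoxidized PRDX is slowly repaired by sulfiredoxin (SRXN1).  While
the hyperoxidized fraction ``h`` is above a threshold, FOXO1 is nuclear and
p53 is suppressed (phase 1); once SRXN1 repair brings ``h`` back down, FOXO1
exits and p53 rises after a fixed delay (phase 2).

All rate constants below are the package's calibrated defaults: they were
chosen once so the dose presets reproduce the qualitative single-cell
phenomenology (FOXO1 nuclear entry within an hour at high dose,
dose-increasing nuclear residence, p53 onset ~1 h after FOXO1 exit,
oscillatory p53 at low dose vs sustained at high dose, dose-dependent
death) and are not meant to be per-experiment fit parameters.  Time unit is
minutes, concentration unit is uM.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .errors import InputError, ParameterError

#: Frame spacing of the synthetic movies, min ("every 20 minutes").
FRAME_MIN = 20.0
#: Movie length, min ("for 24 hours").
T_END_MIN = 1440.0
#: H2O2 doses used across the study presets, uM.
DOSES_UM = (0.0, 20.0, 40.0, 50.0, 60.0, 80.0, 100.0, 150.0, 200.0, 300.0)

#: Perturbation presets as pure parameter maps (field -> multiplier).
PERTURBATIONS: dict[str, dict[str, float]] = {
    "default": {},
    # PRDX1 knockout: smaller effective PRDX pool -> slower H2O2 clearance,
    # so hyperoxidation (and FOXO1 activation) occurs at lower doses.
    "prdx1ko": {"prdx_scale": 0.25},
    # J14 / SRXN1 knockdown: sulfiredoxin repair nearly abolished -> prolonged
    # FOXO1 phases and delayed p53 onset.
    "j14": {"k_srx": 0.05},
    # SRXN1 overexpression: faster repair -> higher dose needed for a phase.
    "srxn1oe": {"k_srx": 4.0},
    # Conoidin A: covalent inhibitor of the PRDX peroxidatic cysteine ->
    # reduced SOH formation and disulfide resolution.
    "conoidina": {"k_ox": 0.2, "k_ss": 0.2},
}


@dataclass(frozen=True)
class SwitchParams:
    """Rate constants and thresholds of the PRDX redox cycle and TF coupling.

    Rates are first order (per-min) or second order (per-uM per-min);
    ``theta_on``/``theta_off`` are thresholds on the hyperoxidized fraction
    with hysteresis (``theta_off < theta_on``) so phase entry/exit does not
    chatter near the threshold.
    """

    k_ox: float = 0.005        # SH + H2O2 -> SOH, per-uM per-min
    k_ss: float = 0.6          # SOH -> disulfide (resolving Cys), per-min
    k_red: float = 0.3         # disulfide -> SH via thioredoxin, per-min
    k_hyp: float = 0.004      # SOH + H2O2 -> SO2H, per-uM per-min
    k_srx: float = 0.0022      # SO2H -> SOH via SRXN1, per-min
    k_clear_cell: float = 0.06  # H2O2 clearance per unit active PRDX, per-min
    k_clear_base: float = 0.002  # PRDX-independent clearance, per-min
    prdx_scale: float = 1.0    # relative PRDX pool size, (0, 1]
    theta_on: float = 0.55     # hyperoxidized fraction for FOXO1 phase entry
    theta_off: float = 0.40    # fraction for phase exit (hysteresis)
    tau_f: float = 5.0         # FOXO1 nuclear shuttling relaxation time, min
    tau_p53: float = 60.0      # delay from FOXO1 exit to p53 onset, min

    def __post_init__(self) -> None:
        for name in ("k_ox", "k_ss", "k_red", "k_hyp", "k_srx",
                     "k_clear_cell", "k_clear_base"):
            if getattr(self, name) < 0:
                raise ParameterError(f"rate {name} must be >= 0, got {getattr(self, name)}")
        if not 0 < self.prdx_scale <= 1:
            raise ParameterError(f"prdx_scale must be in (0, 1], got {self.prdx_scale}")
        if not 0 <= self.theta_off < self.theta_on <= 1:
            raise ParameterError(
                "thresholds must satisfy 0 <= theta_off < theta_on <= 1, "
                f"got theta_on={self.theta_on}, theta_off={self.theta_off}")
        if self.tau_f <= 0:
            raise ParameterError(f"tau_f must be > 0, got {self.tau_f}")
        if self.tau_p53 < 0:
            raise ParameterError(f"tau_p53 must be >= 0, got {self.tau_p53}")

    def replace(self, **changes: float) -> "SwitchParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def perturbed(self, name: str) -> "SwitchParams":
        """Apply a named perturbation preset (multiplicative parameter map)."""
        key = name.lower()
        if key not in PERTURBATIONS:
            raise ParameterError(
                f"unknown perturbation {name!r}; choose from {sorted(PERTURBATIONS)}")
        changes = {field: getattr(self, field) * mult
                   for field, mult in PERTURBATIONS[key].items()}
        return self.replace(**changes)


#: The frozen default parameter set used by every preset.
DEFAULT_PARAMS = SwitchParams()


# ---------------------------------------------------------------------------
# Dose presets
# ---------------------------------------------------------------------------

#: Per-dose death-fraction calibration anchors
#: (50 uM: 1%, 80 uM: 11%, 100 uM: 34%, 300 uM: 98%); other doses are
#: linearly interpolated in dose between anchors.
DEATH_ANCHORS: tuple[tuple[float, float], ...] = (
    (0.0, 0.0), (50.0, 0.01), (80.0, 0.11), (100.0, 0.34), (300.0, 0.98),
)

#: Calibrated death-hazard multipliers per dose, produced once by
#: ``calibrate_death`` (bisection, 50,000 Monte-Carlo cells per dose against
#: the interpolated anchors above) and frozen here as the versioned defaults.
DEFAULT_DEATH_MULT: dict[float, float] = {
    0.0: 0.0,
    20.0: 0.195312,
    40.0: 0.146484,
    50.0: 0.146484,
    60.0: 0.585938,
    80.0: 1.220703,
    100.0: 4.589844,
    150.0: 4.882812,
    200.0: 6.152344,
    300.0: 31.25,
}


def death_target_for_dose(dose: float) -> float:
    """Piecewise-linear interpolation of the per-dose death-fraction target."""
    if dose < 0:
        raise InputError(f"dose must be >= 0, got {dose}")
    xs, ys = zip(*DEATH_ANCHORS)
    if dose >= xs[-1]:
        return ys[-1]
    for (x0, y0), (x1, y1) in zip(DEATH_ANCHORS, DEATH_ANCHORS[1:]):
        if x0 <= dose <= x1:
            return y0 + (y1 - y0) * (dose - x0) / (x1 - x0)
    return ys[0]


@dataclass(frozen=True)
class DosePreset:
    """A treatment condition: initial H2O2 dose plus death/p53-mode rules.

    ``death_mult`` scales the per-cell death hazard (calibrated against the
    anchor death percentages); the p53 mode rule is a logistic in dose
    giving the probability that an activated cell shows a sustained rather
    than oscillatory p53 waveform (the oscillating proportion decreases
    with dose).
    """

    name: str
    H0: float
    death_mult: float
    mode_mid: float = 140.0    # dose of 50% sustained probability, uM
    mode_scale: float = 45.0   # logistic width, uM

    def __post_init__(self) -> None:
        if self.H0 < 0:
            raise ParameterError(f"H0 must be >= 0, got {self.H0}")
        if self.death_mult < 0:
            raise ParameterError(f"death_mult must be >= 0, got {self.death_mult}")

    @property
    def p_sustained(self) -> float:
        """Probability that an activated cell's p53 waveform is sustained."""
        import math
        if self.H0 <= 0:
            return 0.0
        return 1.0 / (1.0 + math.exp(-(self.H0 - self.mode_mid) / self.mode_scale))

    @classmethod
    def for_dose(cls, dose: float, death_mult: float | None = None) -> "DosePreset":
        """Standard preset for a dose, using the frozen calibrated hazard scale."""
        if death_mult is None:
            if dose in DEFAULT_DEATH_MULT:
                death_mult = DEFAULT_DEATH_MULT[dose]
            else:
                raise ParameterError(
                    f"no calibrated death_mult for dose {dose}; pass death_mult "
                    "explicitly or run calibrate_death")
        return cls(name=f"{dose:g}uM", H0=float(dose), death_mult=float(death_mult))
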