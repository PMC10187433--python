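"""Two-phase trajectory analysis: phase detection, p53 onset, exit
alignment, lag summary, and heatmap ordering.

Event detection uses run-length rules (default 2 consecutive frames) so a
single noisy frame cannot create or destroy an event.  A FOXO1 phase is a
first run of frames above the activation cutoff followed by a first run
below it; the p53 onset is the first sustained excursion above the early
baseline (mean + k*SD over the first frames).  Phases interrupted by the
end of the movie or by cell death are flagged censored rather than

assigned an exit, matching how interrupted trajectories are displayed in
single-cell heat maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError, InsufficientDataError
from .gating import Thresholds
from .simulate import CellTrajectory

__all__ = ["PhaseFeatures", "detect_phase", "detect_p53_onset",
           "extract_features", "exit_align", "lag_summary", "heatmap_order",
           "features_to_frame"]


@dataclass
class PhaseFeatures:
    """Per-cell event times of the two-phase response (min; None = no event)."""

    cell_id: str
    t_entry: float | None = None
    t_exit: float | None = None
    duration: float | None = None
    t_onset: float | None = None
    lag: float | None = None
    entry_censored: bool = False
    exit_censored: bool = False
    onset_censored: bool = False
    onset_rule: str = "baseline_sd"   # or "relative" when baseline SD = 0


def _first_run_start(mask: np.ndarray, m: int, start: int = 0) -> int | None:
    """Index of the first run of >= m consecutive True values at/after start."""
    run = 0
    for i in range(start, len(mask)):
        run = run + 1 if mask[i] else 0
        if run >= m:
            return i - m + 1
    return None


def _check_grid(t: np.ndarray) -> float:
    dt = np.diff(t)
    if len(dt) == 0 or not np.allclose(dt, dt[0]):
        raise InputError("trajectory must be on a uniform time grid")
    return float(dt[0])


def detect_phase(traj: CellTrajectory, th: Thresholds, m: int = 2
                 ) -> PhaseFeatures:
    """Detect the first FOXO1 nuclear phase (entry, exit, duration).

    Entry is the start of the first run of >= ``m`` frames with nuclear
    fraction above the cutoff; exit is the start of the first subsequent
    run of >= ``m`` frames below it.  A phase still open when observation
    stops (movie end or death) has ``exit_censored`` set.
    """
    if m < 1:
        raise InputError(f"m must be >= 1, got {m}")
    _check_grid(traj.t)
    nf = traj.foxo1_nf
    valid = ~np.isnan(nf)
    n_obs = int(valid.sum())
    feats = PhaseFeatures(cell_id=traj.cell_id)
    if n_obs == 0:
        return feats
    # observation stops at death; trailing NaNs are not part of any run
    last = int(np.nonzero(valid)[0][-1])
    above = np.zeros(len(nf), dtype=bool)
    above[valid] = nf[valid] > th.foxo_nf_cut

    i_entry = _first_run_start(above[:last + 1], m)
    if i_entry is None:
        # a partial (< m frame) above-run at the very end of observation is
        # an entry we could not confirm: flag only if the last frames are above
        if traj.died and above[last]:
            feats.entry_censored = True
        return feats
    feats.t_entry = float(traj.t[i_entry])
    below = ~above[:last + 1]
    i_exit = _first_run_start(below, m, start=i_entry + m)
    if i_exit is None:
        feats.exit_censored = True
        return feats
    feats.t_exit = float(traj.t[i_exit])
    feats.duration = feats.t_exit - feats.t_entry
    return feats


def detect_p53_onset(traj: CellTrajectory, k: float = 3.0,
                     baseline_frames: int = 3, m: int = 2,
                     relative_rule: float = 0.2) -> tuple[float | None, str]:
    """First sustained p53 rise above the early baseline.

    Baseline mean/SD come from the first ``baseline_frames`` frames; onset
    is the start of the first run of >= ``m`` frames above mean + k*SD.
    A degenerate baseline (SD = 0) falls back to a relative rule
    (> ``relative_rule`` above the baseline mean); the rule used is
    returned alongside the onset time.
    """
    if baseline_frames < 2:
        raise InputError(f"baseline_frames must be >= 2, got {baseline_frames}")
    _check_grid(traj.t)
    p = traj.p53
    base = p[:baseline_frames]
    if np.isnan(base).any():
        return None, "baseline_sd"
    mu, sd = float(np.mean(base)), float(np.std(base))
    if sd > 0:
        cut, rule = mu + k * sd, "baseline_sd"
    else:
        cut, rule = mu * (1.0 + relative_rule), "relative"
    valid = ~np.isnan(p)
    if not valid.any():
        return None, rule
    last = int(np.nonzero(valid)[0][-1])
    above = np.zeros(len(p), dtype=bool)
    above[valid] = p[valid] > cut
    i = _first_run_start(above[:last + 1], m)
    return (None if i is None else float(traj.t[i])), rule


def extract_features(traj: CellTrajectory, th: Thresholds, m: int = 2,
                     k: float = 3.0, baseline_frames: int = 3
                     ) -> PhaseFeatures:
    """Full per-cell feature set: phase, onset, and the exit-to-onset lag."""
    feats = detect_phase(traj, th, m=m)
    t_onset, rule = detect_p53_onset(traj, k=k, baseline_frames=baseline_frames,
                                     m=m)
    feats.onset_rule = rule
    if t_onset is None:
        # a cell whose observation ends before any rise may still be pre-onset
        feats.onset_censored = traj.died
    else:
        feats.t_onset = t_onset
    if feats.t_exit is not None and feats.t_onset is not None:
        feats.lag = feats.t_onset - feats.t_exit
    return feats


def exit_align(cells: Sequence[CellTrajectory],
               features: Sequence[PhaseFeatures],
               window: float = 480.0) -> pd.DataFrame:
    """Median FOXO1/p53 traces re-indexed to each cell's FOXO1 exit time.

    Only cells with a defined (uncensored) exit contribute; each offset
    reports the median over the cells observed at that offset and the
    contributing cell count.  Offsets are frame-quantized in
    ``[-window, window]``.
    """
    feat_by_id = {f.cell_id: f for f in features}
    usable = [(c, feat_by_id[c.cell_id]) for c in cells
              if c.cell_id in feat_by_id
              and feat_by_id[c.cell_id].t_exit is not None]
    if len(usable) < 10:
        raise InsufficientDataError(
            f"exit alignment needs >= 10 cells with a defined exit, "
            f"got {len(usable)}")
    dt = _check_grid(usable[0][0].t)
    offsets = np.arange(-window, window + 0.5 * dt, dt)
    foxo_cols, p53_cols = [], []
    for c, f in usable:
        rel = c.t - f.t_exit
        foxo_cols.append(np.interp(offsets, rel, c.foxo1_nf,
                                   left=np.nan, right=np.nan))
        p53_cols.append(np.interp(offsets, rel, c.p53,
                                  left=np.nan, right=np.nan))
    foxo = np.vstack(foxo_cols)
    p53 = np.vstack(p53_cols)
    with np.errstate(all="ignore"):
        return pd.DataFrame({
            "rel_t_min": offsets,
            "foxo1_nf_median": np.nanmedian(foxo, axis=0),
            "p53_median": np.nanmedian(p53, axis=0),
            "n_cells": np.sum(~np.isnan(p53), axis=0).astype(int),
        })


def lag_summary(features: Sequence[PhaseFeatures]
                ) -> tuple[float, tuple[float, float], int]:
    """Median and IQR of the FOXO1-exit-to-p53-onset lag over defined lags."""
    lags = np.array([f.lag for f in features if f.lag is not None])
    if len(lags) == 0:
        raise InsufficientDataError("no cells with a defined exit-onset lag")
    return (float(np.median(lags)),
            (float(np.percentile(lags, 25)), float(np.percentile(lags, 75))),
            int(len(lags)))


def heatmap_order(features: Sequence[PhaseFeatures],
                  t_death_by_id: dict[str, float] | None = None) -> list[str]:
    """Row order for single-cell heat maps, sorted by FOXO1 phase duration.

    Phase-less cells come first (duration 0), then completed phases in
    ascending duration, then cells whose phase was cut short (censored),
    ordered among themselves by death time when ``t_death_by_id`` is
    given; ties break by cell_id.  The result is a permutation of all
    cell ids.
    """
    deaths = t_death_by_id or {}
    censored = sorted((f for f in features
                       if f.t_entry is not None and f.duration is None),
                      key=lambda f: (deaths.get(f.cell_id, np.inf), f.cell_id))
    completed = sorted((f for f in features
                        if not (f.t_entry is not None and f.duration is None)),
                       key=lambda f: (f.duration if f.duration is not None
                                      else 0.0, f.cell_id))
    return [f.cell_id for f in completed] + [f.cell_id for f in censored]


def features_to_frame(features: Sequence[PhaseFeatures]) -> pd.DataFrame:
    def col(name):
        return [getattr(f, name) if getattr(f, name) is not None else np.nan
                for f in features]
    return pd.DataFrame({
        "cell_id": [f.cell_id for f in features],
        "t_entry": col("t_entry"), "t_exit": col("t_exit"),
        "duration": col("duration"), "t_onset": col("t_onset"),
        "lag": col("lag"),
        "entry_censored": [f.entry_censored for f in features],
        "exit_censored": [f.exit_censored for f in features],
        "onset_censored": [f.onset_censored for f in features],
    })
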