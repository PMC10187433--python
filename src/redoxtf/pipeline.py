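"""End-to-end pipeline: simulate -> (render -> quantify) -> gate ->
features -> ACF -> summary.

Every random stage draws from a named substream derived from one master
seed, so re-running a single stage (or reordering stages) cannot change
another stage's stream.  Each run writes a resolved copy of its
configuration (with the seed and package version) next to its outputs,
and a machine-readable ``summary.json`` with the headline quantities:
max dual-activation fraction over doses, median FOXO1 entry time, median
exit-to-onset lag, per-dose death fractions, and oscillation scores by
fate.  A stage failure halts the run with the failing stage named;
outputs of completed stages are retained.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import InsufficientDataError, RedoxTFError
from .gating import classify_cells, fit_thresholds, quadrant_table, \
    quadrants_to_frame
from .dynamics import exit_align, extract_features, features_to_frame, \
    lag_summary
from .io import write_image, write_labels, write_table
from .oscillation import compare_fates
from .params import (DEFAULT_PARAMS, DOSES_UM, DosePreset, SwitchParams)
from .quantify import measure_cells, measures_to_frame
from .render import CHANNEL_NAMES, FieldGeometry, render_field
from .simulate import (DEFAULT_NOISE, generate_population, generate_snapshot,
                       population_to_frame, snapshot_to_frame)

__all__ = ["RunConfig", "run_pipeline", "substream", "PipelineError"]


class PipelineError(RedoxTFError):
    """A pipeline stage failed; the message names the stage."""


def substream(seed: int, label: str) -> np.random.SeedSequence:
    """Independent named random substream of one master seed."""
    return np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "redoxtf_run"
    doses: tuple[float, ...] = tuple(d for d in DOSES_UM if d > 0)
    n_traj: int = 200
    n_snapshot: int = 1000
    n_control: int = 1000
    t_fix: float = 300.0
    perturbation: str = "default"
    threshold_q: float = 0.99
    render: bool = True
    n_render: int = 36
    params_overrides: dict = field(default_factory=dict)

    def resolved_params(self) -> SwitchParams:
        return DEFAULT_PARAMS.perturbed(self.perturbation).replace(
            **self.params_overrides)

    def preset_for(self, dose: float) -> DosePreset:
        return DosePreset.for_dose(dose)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.pop("package_version", None)   # provenance note, not a field
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise RedoxTFError(f"unknown config keys: {sorted(unknown)}")
        if "doses" in raw:
            raw["doses"] = tuple(float(d) for d in raw["doses"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["doses"] = list(self.doses)
        data["package_version"] = __version__
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


@_stage("simulate")
def _simulate(cfg: RunConfig, out: Path):
    params = cfg.resolved_params()
    pops, snaps = {}, {}
    for dose in cfg.doses:
        preset = cfg.preset_for(dose)
        pops[dose] = generate_population(
            cfg.n_traj, preset, params,
            seed=substream(cfg.seed, f"traj:{dose:g}"))
        snaps[dose] = generate_snapshot(
            cfg.n_snapshot, preset, t_fix=cfg.t_fix, params=params,
            seed=substream(cfg.seed, f"snap:{dose:g}"))
    control = generate_snapshot(
        cfg.n_control, cfg.preset_for(0.0), t_fix=cfg.t_fix, params=params,
        seed=substream(cfg.seed, "snap:control"))
    for dose, pop in pops.items():
        write_table(population_to_frame(pop), out / f"trajectories_{dose:g}uM.csv",
                    "trajectory", {"seed": cfg.seed, "dose_uM": dose})
    allsnaps = {0.0: control, **snaps}
    for dose, snap in allsnaps.items():
        write_table(snapshot_to_frame(snap), out / f"snapshot_{dose:g}uM.csv",
                    "snapshot", {"seed": cfg.seed, "dose_uM": dose})
    return pops, snaps, control


@_stage("render")
def _render_quantify(cfg: RunConfig, out: Path, snaps: dict):
    dose = cfg.doses[0]
    cells = snaps[dose][:cfg.n_render]
    rng = np.random.default_rng(substream(cfg.seed, "render"))
    image, labels = render_field(cells, FieldGeometry(), rng=rng,
                                 poisson_noise=True)
    write_image(image, out / f"field_{dose:g}uM.tiff")
    write_labels(labels, out / f"labels_{dose:g}uM.tiff")
    measures = measure_cells(image, labels)
    write_table(measures_to_frame(measures, CHANNEL_NAMES),
                out / f"measures_{dose:g}uM.csv", "measures")
    programmed = np.array([c.foxo1_nf for c in cells])
    recovered = np.array([m.nuclear_fraction for m in measures])
    return float(np.mean(np.abs(recovered - programmed)))


@_stage("gate")
def _gate(cfg: RunConfig, out: Path, snaps: dict, control):
    th = fit_thresholds(control, q=cfg.threshold_q)
    labels_by_dose = {dose: classify_cells(cells, th)
                      for dose, cells in snaps.items()}
    tables, max_both = quadrant_table(labels_by_dose)
    write_table(quadrants_to_frame(tables), out / "quadrants.csv", "quadrants",
                {"foxo_nf_cut": th.foxo_nf_cut, "p53_log_cut": th.p53_log_cut,
                 "method": th.method})
    return th, tables, max_both


@_stage("features")
def _features(cfg: RunConfig, out: Path, pops: dict, th):
    feats = {dose: [extract_features(c, th) for c in pop]
             for dose, pop in pops.items()}
    for dose, fs in feats.items():
        write_table(features_to_frame(fs), out / f"features_{dose:g}uM.csv",
                    "features")
    high = [d for d in cfg.doses if 80.0 <= d <= 100.0] or list(cfg.doses)
    pool_cells = [c for d in high for c in pops[d]]
    pool_feats = [f for d in high for f in feats[d]]
    aligned = None
    try:
        aligned = exit_align(pool_cells, pool_feats)
        write_table(aligned, out / "exit_aligned.csv", "aligned")
    except InsufficientDataError:
        pass
    try:
        lag_med, lag_iqr, lag_n = lag_summary(pool_feats)
    except InsufficientDataError:
        lag_med, lag_iqr, lag_n = None, (None, None), 0
    return feats, aligned, (lag_med, lag_iqr, lag_n)


@_stage("acf")
def _acf_stage(cfg: RunConfig, out: Path, pops: dict, feats: dict):
    import pandas as pd

    from .errors import (DegenerateSeriesError, InputError)
    from .oscillation import acf, oscillation_score

    rows, scores = [], {}
    for dose, pop in pops.items():
        for c in pop:
            try:
                res = acf(c.p53, dt=float(c.t[1] - c.t[0]), max_lag=480.0)
            except (InsufficientDataError, InputError, DegenerateSeriesError):
                continue
            scores[c.cell_id] = oscillation_score(res)
            rows.append(pd.DataFrame({"cell_id": c.cell_id,
                                      "lag_min": res.lags, "acf": res.acf}))
    if rows:
        write_table(pd.concat(rows, ignore_index=True), out / "acf.csv", "acf")
    pool_cells = [c for pop in pops.values() for c in pop]
    pool_feats = [f for fs in feats.values() for f in fs]
    fates = None
    if any(c.died for c in pool_cells) and any(not c.died for c in pool_cells):
        fates = compare_fates(pool_cells, pool_feats)
        comp_rows = []
        for metric in ("oscillation_score", "max_p53", "duration"):
            for grp in ("dying", "surviving"):
                m = fates[metric]
                comp_rows.append({
                    "group": grp, "metric": metric,
                    "median": m[f"median_{grp}"], "n": m[f"n_{grp}"],
                    "statistic": m["statistic"], "p_value": m["p_value"]})
        write_table(pd.DataFrame(comp_rows), out / "fate_comparison.csv",
                    "comparison")
    return scores, fates


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; return (and write) the machine-readable summary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")

    pops, snaps, control = _simulate(config, out)
    render_mae = _render_quantify(config, out, snaps) if config.render else None
    th, tables, max_both = _gate(config, out, snaps, control)
    feats, aligned, (lag_med, lag_iqr, lag_n) = _features(config, out, pops, th)
    scores, fates = _acf_stage(config, out, pops, feats)

    entries = [f.t_entry for fs in feats.values() for f in fs
               if f.t_entry is not None]
    death_frac = {f"{dose:g}": float(np.mean([c.died for c in pop]))
                  for dose, pop in pops.items()}
    n_phase = sum(1 for fs in feats.values() for f in fs
                  if f.t_entry is not None)
    osc_by_fate = None
    if fates is not None:
        osc_by_fate = {
            "dying": fates["oscillation_score"]["median_dying"],
            "surviving": fates["oscillation_score"]["median_surviving"]}

    summary = {
        "package_version": __version__,
        "seed": config.seed,
        "perturbation": config.perturbation,
        "doses_uM": list(config.doses),
        "n_traj_per_dose": config.n_traj,
        "n_snapshot_per_dose": config.n_snapshot,
        "max_frac_both": max_both,
        "thresholds": {"foxo_nf_cut": th.foxo_nf_cut,
                       "p53_log_cut": th.p53_log_cut},
        "n_phase_cells": n_phase,
        "median_entry_min": float(np.median(entries)) if entries else None,
        "median_lag_min": lag_med,
        "lag_iqr_min": list(lag_iqr) if lag_iqr[0] is not None else None,
        "n_lag_cells": lag_n,
        "death_fraction_by_dose": death_frac,
        "oscillation_score_by_fate": osc_by_fate,
        "render_nuclear_fraction_mae": render_mae,
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
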