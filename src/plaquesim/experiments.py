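"""The four standard in-silico experiments.

* ``single_pulse`` - Stephan curves for one sugar pulse at several clearance
  half-times, starting from a symbiotic (95 % NA) film;
* ``threshold_sweep`` - time below pH thresholds 5.5-6.2 versus t1/2 for a
  film midway between symbiosis and dysbiosis (50 % A / 50 % NA);
* ``dysbiosis_map`` - final composition and lowest pulse pH after a 50-day
  protocol, swept over intake frequency and t1/2;
* ``ia_trajectory`` - per-pulse integrated acid challenge IA^6.2 and IA^5.5
  as the composition evolves (4 intakes/day).

Long ecological protocols use the accelerated-growth rescaling (see
``ModelParams.accelerated``): the growth yield and death prefactor are
multiplied by ``accel`` and the simulated span divided by it, which preserves
the per-represented-day selection pressure and all rate ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diet import PulseSchedule, pulse_windows
from .driver import RunResult, child_seed, run_simulation
from .metrics import (
    crossover_frequency,
    integrated_acid,
    min_ph,
    time_below_threshold,
)
from .params import ModelParams

__all__ = [
    "ExperimentSpec",
    "single_pulse",
    "threshold_sweep",
    "dysbiosis_map",
    "ia_trajectory",
    "run_experiment",
]

EXPERIMENT_NAMES = ("single_pulse", "threshold_sweep", "dysbiosis_map", "ia_trajectory")


@dataclass
class ExperimentSpec:
    """Sweep definition for :func:`run_experiment`."""

    name: str
    t_half_list: tuple = (2.0, 4.0, 6.0)
    freq_list: tuple = (2, 3, 4, 5, 6, 7, 8)
    days: int = 50
    replicates: int = 1
    accel: float = 12.5
    frac_A: float = 0.05
    n_particles: int = 130
    thresholds: tuple = (5.5, 5.8, 6.0, 6.2)
    seed: int = 0

    def __post_init__(self):
        if self.name not in EXPERIMENT_NAMES:
            raise ValueError(f"unknown experiment {self.name!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.name in ("dysbiosis_map", "ia_trajectory") and self.days < 1:
            raise ValueError("ecological experiments need days >= 1")


def single_pulse(
    params: ModelParams,
    t_half: float,
    seed: int,
    freq_per_day: int = 4,
    total_dose: float | None = None,
    frac_A: float = 0.05,
    n_particles: int = 130,
) -> RunResult:
    """One pulse window (a full inter-pulse interval) from a fresh film."""
    base = PulseSchedule()
    schedule = PulseSchedule(
        freq_per_day=freq_per_day,
        t_half=t_half,
        total_dose=base.total_dose if total_dose is None else total_dose,
    )
    return run_simulation(
        params,
        schedule,
        duration=schedule.interval,
        seed=seed,
        n_particles=n_particles,
        frac_A=frac_A,
    )


def threshold_sweep(
    params: ModelParams,
    t_half_list=(2.0, 3.0, 4.0, 5.0, 6.0),
    thresholds=(5.5, 5.8, 6.0, 6.2),
    frac_A: float = 0.5,
    seed: int = 0,
    replicates: int = 1,
    n_particles: int = 130,
) -> pd.DataFrame:
    """Time below each pH threshold during one pulse, per clearance half-time."""
    rows = []
    for it, th in enumerate(t_half_list):
        for rep in range(replicates):
            res = single_pulse(
                params, th, child_seed(seed, it, rep),
                frac_A=frac_A, n_particles=n_particles,
            )
            row = {"t_half": th, "rep": rep, "min_ph": min_ph(res.series)}
            for theta in thresholds:
                row[f"time_below_{theta}"] = time_below_threshold(res.series, theta)
            rows.append(row)
    return pd.DataFrame(rows)


def _ecology_run(
    params: ModelParams,
    schedule: PulseSchedule,
    days: float,
    accel: float,
    seed: int,
    n_particles: int,
    frac_A: float,
    coarse: bool = True,
) -> RunResult:
    p = params.accelerated(accel) if accel != 1.0 else params
    if coarse:
        # the scaled long protocol trades pulse-shape resolution it does not
        # need for a 1.5x coarser biology step
        p = p.replace(dt_bio=1.5 * p.dt_bio, dt_bio_idle=1.5 * p.dt_bio_idle)
    duration = days * 86_400.0 / accel
    return run_simulation(
        p, schedule, duration, seed=seed, n_particles=n_particles, frac_A=frac_A
    )


def dysbiosis_map(
    params: ModelParams,
    t_half_list=(2.0, 6.0),
    freq_list=(2, 3, 4, 5, 6, 7, 8),
    days: int = 50,
    replicates: int = 3,
    accel: float = 12.5,
    seed: int = 0,
    n_particles: int = 130,
    frac_A: float = 0.05,
    cut: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Composition after the long protocol, over (t1/2, frequency).

    Returns ``(cells, crossover)``: one row per sweep cell with the final
    aciduric fraction and the lowest pulse pH over the last simulated day, and
    the per-t1/2 crossover frequency interpolated at ``frac_A = cut`` from the
    replicate-mean compositions.
    """
    rows = []
    for i, th in enumerate(t_half_list):
        for j, freq in enumerate(freq_list):
            for rep in range(replicates):
                schedule = PulseSchedule(freq_per_day=int(freq), t_half=th)
                res = _ecology_run(
                    params, schedule, days, accel,
                    child_seed(seed, i, j, rep), n_particles, frac_A,
                )
                # one simulated day holds `freq` pulses regardless of accel
                last_day = res.series.window(res.state.t - 86_400.0, res.state.t)
                frac = res.composition["frac_A"].iloc[-1]
                rows.append(
                    {
                        "t_half": th,
                        "freq": int(freq),
                        "rep": rep,
                        "final_frac_A": float(frac),
                        "min_ph_last_day": min_ph(last_day),
                        "n_final": res.state.n,
                    }
                )
    cells = pd.DataFrame(rows)
    xo = []
    for th in t_half_list:
        sub = cells[cells.t_half == th]
        mean_frac = sub.groupby("freq")["final_frac_A"].mean().to_dict()
        xo.append({"t_half": th, "crossover_freq": crossover_frequency(mean_frac, cut)})
    return cells, pd.DataFrame(xo)


def ia_trajectory(
    params: ModelParams,
    t_half_list=(2.0, 4.0, 6.0),
    days: int = 50,
    freq_per_day: int = 4,
    accel: float = 12.5,
    seed: int = 0,
    n_particles: int = 130,
    frac_A: float = 0.05,
    thresholds=(5.5, 6.2),
) -> pd.DataFrame:
    """Per-pulse IA^theta through the long protocol, one row per pulse."""
    rows = []
    for i, th in enumerate(t_half_list):
        schedule = PulseSchedule(freq_per_day=freq_per_day, t_half=th)
        res = _ecology_run(
            params, schedule, days, accel, child_seed(seed, i), n_particles, frac_A
        )
        comp = res.composition
        for start, end in pulse_windows(schedule, 0.0, res.state.t):
            win = res.series.window(start, end)
            if win.t.size < 2:
                continue
            k = int(np.searchsorted(comp["t"].to_numpy(), end) - 1)
            row = {
                "t_half": th,
                "t_start_days": start * accel / 86_400.0,
                "min_ph": min_ph(win),
                "frac_A": float(comp["frac_A"].iloc[k]),
            }
            for theta in thresholds:
                row[f"ia_{theta}"] = integrated_acid(win, theta)
            rows.append(row)
    return pd.DataFrame(rows)


def run_experiment(spec: ExperimentSpec, params: ModelParams):
    """Dispatch one of the named experiments; returns tidy result tables."""
    if spec.name == "single_pulse":
        rows = []
        for i, th in enumerate(spec.t_half_list):
            for rep in range(spec.replicates):
                res = single_pulse(
                    params, th, child_seed(spec.seed, i, rep),
                    frac_A=spec.frac_A, n_particles=spec.n_particles,
                )
                row = {"t_half": th, "rep": rep, "min_ph": min_ph(res.series)}
                for theta in spec.thresholds:
                    row[f"time_below_{theta}"] = time_below_threshold(res.series, theta)
                for theta in (5.5, 6.2):
                    row[f"ia_{theta}"] = integrated_acid(res.series, theta)
                rows.append(row)
        return pd.DataFrame(rows)
    if spec.name == "threshold_sweep":
        return threshold_sweep(
            params, spec.t_half_list, spec.thresholds,
            frac_A=0.5, seed=spec.seed, replicates=spec.replicates,
            n_particles=spec.n_particles,
        )
    if spec.name == "dysbiosis_map":
        return dysbiosis_map(
            params, spec.t_half_list, spec.freq_list, spec.days,
            spec.replicates, spec.accel, spec.seed,
            spec.n_particles, spec.frac_A,
        )
    return ia_trajectory(
        params, spec.t_half_list, spec.days, accel=spec.accel,
        seed=spec.seed, n_particles=spec.n_particles, frac_A=spec.frac_A,
    )
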