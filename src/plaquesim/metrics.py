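"""Cariogenicity and ecology metrics from simulated pH time series.

The quantities mirror what is measured on clinical Stephan curves: the
minimum pH at the tooth surface during a sugar pulse, the duration for which
the pH stays below a critical threshold (nominally 6.2 for root dentin and
5.5 for enamel), and the integrated acid challenge

    IA^theta = integral of max([H+] - 10^-theta, 0) dt   (mol L^-1 min)

i.e. the area between the tooth-surface [H+] curve and the threshold level.
Composition metrics track the aciduric fraction and locate the intake
frequency at which a biofilm crosses from symbiosis to dysbiosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SurfaceSeries",
    "StephanMetrics",
    "time_below_threshold",
    "integrated_acid",
    "min_ph",
    "stephan_metrics",
    "composition_fraction",
    "crossover_frequency",
]


@dataclass
class SurfaceSeries:
    """Sampled tooth-surface acidity series.

    ``ph_surface`` is the mean pH of the lattice layer adjacent to z = 0;
    ``h_surface`` the corresponding [H+] (mol L^-1); ``acid_max`` the highest
    undissociated-acid concentration anywhere in the biofilm (mol m^-3).
    Sample times need not be uniform (the driver samples densely only while a
    pulse is active).
    """

    t: np.ndarray
    ph_surface: np.ndarray
    h_surface: np.ndarray
    acid_max: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.ph_surface = np.asarray(self.ph_surface, dtype=float)
        self.h_surface = np.asarray(self.h_surface, dtype=float)
        self.acid_max = np.asarray(self.acid_max, dtype=float)
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")

    def window(self, t0: float, t1: float) -> "SurfaceSeries":
        m = (self.t >= t0 - 1e-9) & (self.t <= t1 + 1e-9)
        return SurfaceSeries(
            self.t[m], self.ph_surface[m], self.h_surface[m], self.acid_max[m]
        )


@dataclass
class StephanMetrics:
    """Per-pulse acidity summary."""

    min_ph: float
    time_below: dict = field(default_factory=dict)  # theta -> minutes
    ia: dict = field(default_factory=dict)          # theta -> mol L^-1 min


def _check(series: SurfaceSeries, min_samples: int = 2) -> None:
    if series.t.size < min_samples:
        raise ValueError(f"need at least {min_samples} samples")


def time_below_threshold(series: SurfaceSeries, theta: float) -> float:
    """Total time (min) with tooth-surface pH strictly below ``theta``.

    Threshold crossings are located by linear interpolation of the pH between
    samples, so the result does not jump with the sampling grid.
    """
    _check(series)
    t = series.t
    ph = series.ph_surface
    below = ph < theta
    total = 0.0
    for k in range(t.size - 1):
        dt = t[k + 1] - t[k]
        a, b = ph[k], ph[k + 1]
        if below[k] and below[k + 1]:
            total += dt
        elif below[k] != below[k + 1]:
            # crossing located at fraction (theta - a)/(b - a) of the segment;
            # the sub-threshold side is after it when entering, before it when
            # leaving
            frac = (theta - a) / (b - a)
            total += dt * ((1.0 - frac) if below[k + 1] else frac)
    return total / 60.0


def integrated_acid(series: SurfaceSeries, theta: float) -> float:
    """Integrated acid challenge IA^theta (mol L^-1 min).

    Trapezoidal integral of ``max(h_surface - 10^-theta, 0)`` over the
    window, integrating the excess in [H+] so sub-threshold stretches
    contribute nothing.
    """
    _check(series)
    excess = np.maximum(series.h_surface - 10.0 ** (-theta), 0.0)
    return float(np.trapezoid(excess, series.t)) / 60.0


def min_ph(series: SurfaceSeries) -> float:
    """Lowest sampled tooth-surface pH in the window."""
    _check(series, min_samples=1)
    return float(np.min(series.ph_surface))


def stephan_metrics(series: SurfaceSeries, thresholds=(5.5, 6.2)) -> StephanMetrics:
    """Bundle the per-pulse metrics for a set of pH thresholds."""
    return StephanMetrics(
        min_ph=min_ph(series),
        time_below={th: time_below_threshold(series, th) for th in thresholds},
        ia={th: integrated_acid(series, th) for th in thresholds},
    )


def composition_fraction(state, by_mass: bool = False) -> float:
    """Aciduric fraction of the biofilm.

    Number fraction by default (matching how composition is reported for the
    two-type community); ``by_mass=True`` weights by particle mass instead,
    for sensitivity analyses.
    """
    from .params import PTYPE_A

    if state.n == 0:
        raise ValueError("empty biofilm has no composition")
    is_a = state.ptype == PTYPE_A
    if by_mass:
        return float(state.mass[is_a].sum() / state.mass.sum())
    return float(is_a.sum() / state.n)


def crossover_frequency(final_frac_by_freq: dict, cut: float = 0.5):
    """Intake frequency at which the aciduric fraction crosses ``cut``.

    Given final compositions keyed by intakes/day, returns the smallest
    frequency at which ``frac_A >= cut``, linearly interpolated between the
    adjacent tested frequencies.  Returns ``None`` when the composition never
    crosses; returns the lowest tested frequency when all compositions are
    already dysbiotic.
    """
    if len(final_frac_by_freq) < 2:
        raise ValueError("need at least two tested frequencies")
    freqs = sorted(final_frac_by_freq)
    fracs = [final_frac_by_freq[f] for f in freqs]
    if any(not 0.0 <= x <= 1.0 for x in fracs):
        raise ValueError("fractions must lie in [0, 1]")
    if fracs[0] >= cut:
        return float(freqs[0])
    for (f0, x0), (f1, x1) in zip(zip(freqs, fracs), zip(freqs[1:], fracs[1:])):
        if x1 >= cut:
            if x1 == x0:
                return float(f1)
            return float(f0 + (f1 - f0) * (cut - x0) / (x1 - x0))
    return None
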