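"""Dietary sugar driving: periodic interface pulses with exponential clearance.

Each intake fixes the sugar concentration at the saliva-air interface to a
profile that ramps up rapidly and then decays exponentially, halving every
clearance half-time t1/2.  The integrated interface concentration per pulse
(the dose) is held constant across t1/2 values, so a short t1/2 gives a tall
narrow pulse and a long t1/2 (hyposalivation) a low broad one; this isolates
the clearance effect from the amount of sugar consumed.

The pulse peak follows from the instantaneous-rise idealisation:

    integral of peak * 2^(-t / t_half) dt = dose  =>  peak = dose ln2 / t_half
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["PulseSchedule", "pulse_peak", "interface_sugar", "pulse_windows"]

DAY = 86_400.0  # s


def pulse_peak(total_dose: float, t_half: float) -> float:
    """Peak interface concentration (mol m^-3).

    Parameters are the integrated dose (mol m^-3 min) and the clearance
    half-time (min).
    """
    if not (total_dose > 0 and t_half > 0):
        raise ValueError("total_dose and t_half must be positive")
    return total_dose * math.log(2.0) / t_half


@dataclass(frozen=True)
class PulseSchedule:
    """Periodic dietary sugar driving.

    Attributes
    ----------
    freq_per_day : intakes per day (integer >= 0); pulses are equally spaced,
        the first starting at t = 0.
    t_half : clearance half-time t1/2 (min).
    total_dose : integrated interface concentration per pulse (mol m^-3 min).
    rise_time : duration of the initial linear ramp (s); kept well below
        t1/2 so the pure-exponential peak relation stays accurate.
    day_length : s (86 400).
    """

    freq_per_day: int = 4
    t_half: float = 2.0
    total_dose: float = 112.0
    rise_time: float = 30.0
    day_length: float = DAY

    def __post_init__(self) -> None:
        if self.freq_per_day < 0 or self.freq_per_day != int(self.freq_per_day):
            raise ValueError("freq_per_day must be a nonnegative integer")
        if not (self.t_half > 0 and self.total_dose > 0 and self.rise_time > 0):
            raise ValueError("t_half, total_dose and rise_time must be positive")
        if self.rise_time > self.t_half * 60.0 / 2.0:
            raise ValueError("rise_time must be small compared with t_half")

    @property
    def peak(self) -> float:
        return pulse_peak(self.total_dose, self.t_half)

    @property
    def t_half_s(self) -> float:
        return self.t_half * 60.0

    @property
    def interval(self) -> float:
        """Spacing between pulse starts (s)."""
        if self.freq_per_day == 0:
            return math.inf
        return self.day_length / self.freq_per_day


def interface_sugar(t, schedule: PulseSchedule):
    """Interface sugar concentration (mol m^-3) at time(s) ``t`` (s, >= 0).

    Within each pulse: a linear ramp over ``rise_time``, then exponential
    decay halving every t1/2.  The decay clock starts at mid-ramp, which makes
    the realised integral match the nominal dose to second order in
    ``rise_time / t_half`` (well under 1 % at the default settings) while
    keeping the ideal ``peak = dose ln2 / t_half`` relation and the exact
    halving from the ramp end.  When a new pulse starts before the previous
    one has fully decayed, the new profile replaces the residual (pointwise
    maximum of ramp and residual); profiles are never summed, so high
    frequencies cannot accumulate without bound.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    if schedule.freq_per_day == 0:
        out = np.zeros_like(t)
        return out if out.ndim else float(out)
    peak = schedule.peak
    th = schedule.t_half_s
    rise = schedule.rise_time
    tau = np.mod(t, schedule.interval)  # time since current pulse start
    decay = peak * np.exp2(-(tau - rise / 2.0) / th)
    top = peak * np.exp2(-rise / (2.0 * th))  # ramp end = decay start value
    ramp = top * tau / rise
    # residual of the previous pulse, still decaying through the ramp window
    residual = peak * np.exp2(-(tau + schedule.interval - rise / 2.0) / th)
    out = np.where(tau < rise, np.maximum(ramp, residual), decay)
    return out if out.ndim else float(out)


def pulse_windows(schedule: PulseSchedule, t0: float, t1: float):
    """Per-pulse analysis windows.

    One ``(start, end)`` pair per pulse start in ``[t0, t1)``; each window
    extends to the next pulse start, or to ``t1`` for the last pulse.
    """
    if not t0 < t1:
        raise ValueError("need t0 < t1")
    if schedule.freq_per_day == 0:
        return []
    iv = schedule.interval
    first = math.ceil(t0 / iv - 1e-12)
    starts = []
    k = first
    while k * iv < t1 - 1e-9:
        if k * iv >= t0 - 1e-9:
            starts.append(k * iv)
        k += 1
    return [
        (s, min(s + iv, t1))
        for s in starts
    ]
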