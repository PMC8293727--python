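"""Empirical buffering chemistry: undissociated acid -> [H+] -> pH.

The plaque fluid is treated as being at chemical equilibrium at all times, so
the hydrogen-ion concentration is a memoryless function of the local
undissociated-acid concentration.  The default mapping is a saturating
three-parameter curve

    pH(acid) = pH_rest - (pH_rest - pH_floor) * acid / (acid + K_buf)

which starts at the resting pH for zero acid, drops half of the maximal pH
excursion at ``acid = K_buf`` and approaches ``pH_floor`` asymptotically.  A
tabulated (acid, pH) curve with monotone interpolation can be substituted when
a measured buffering curve is available.

Units: acid in mol m^-3, [H+] in mol L^-1 (the only place the mol L^-1 scale
appears), pH dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "BufferParams",
    "TabulatedBuffer",
    "ph_from_acid",
    "hydrogen_from_acid",
    "ph_from_hydrogen",
    "hydrogen_from_ph",
]


@dataclass(frozen=True)
class BufferParams:
    """Parameters of the saturating buffering curve.

    Attributes
    ----------
    ph_rest : resting pH of plaque fluid at zero acid (default 7.0).
    ph_floor : asymptotic minimum pH at saturating acid.
    K_buf : acid concentration (mol m^-3) at half of the maximal pH drop.
    """

    ph_rest: float = 7.0
    ph_floor: float = 4.0
    K_buf: float = 50.0

    def __post_init__(self) -> None:
        if not self.ph_floor < self.ph_rest:
            raise ValueError("ph_floor must be below ph_rest")
        if not self.K_buf > 0:
            raise ValueError("K_buf must be positive")


class TabulatedBuffer:
    """Buffering curve interpolated from measured (acid, pH) pairs.

    The acid column must be strictly increasing and the pH column strictly
    decreasing; a shape-preserving monotone (PCHIP) interpolant is used so the
    mapping stays monotone between the tabulated points.  Outside the table the
    end values are held constant.
    """

    def __init__(self, acid: np.ndarray, ph: np.ndarray):
        acid = np.asarray(acid, dtype=float)
        ph = np.asarray(ph, dtype=float)
        if acid.ndim != 1 or acid.size < 2 or acid.shape != ph.shape:
            raise ValueError("need two 1-D columns of equal length >= 2")
        if not np.all(np.diff(acid) > 0):
            raise ValueError("acid column must be strictly increasing")
        if not np.all(np.diff(ph) < 0):
            raise ValueError("pH column must be strictly decreasing")
        if acid[0] != 0.0:
            raise ValueError("table must start at acid = 0 (resting point)")
        self._acid = acid
        self._ph = ph
        self._interp = PchipInterpolator(acid, ph, extrapolate=False)

    @classmethod
    def from_csv(cls, path) -> "TabulatedBuffer":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(data[:, 0], data[:, 1])

    def ph(self, acid):
        acid = np.asarray(acid, dtype=float)
        if np.any(acid < 0):
            raise ValueError("acid concentration must be nonnegative")
        out = self._interp(np.clip(acid, self._acid[0], self._acid[-1]))
        return np.where(acid >= self._acid[-1], self._ph[-1], out)


def ph_from_acid(acid, bp: BufferParams):
    """pH of the plaque fluid at undissociated acid concentration ``acid``.

    Accepts scalars or arrays; negative acid is rejected.
    """
    if isinstance(bp, TabulatedBuffer):
        return bp.ph(acid)
    acid = np.asarray(acid, dtype=float)
    if np.any(acid < 0):
        raise ValueError("acid concentration must be nonnegative")
    drop = (bp.ph_rest - bp.ph_floor) * acid / (acid + bp.K_buf)
    out = bp.ph_rest - drop
    return out if out.ndim else float(out)


def hydrogen_from_acid(acid, bp: BufferParams):
    """[H+] (mol L^-1) at acid concentration ``acid`` (mol m^-3)."""
    return hydrogen_from_ph(ph_from_acid(acid, bp))


def ph_from_hydrogen(h):
    """pH = -log10 [H+]; rejects nonpositive [H+]."""
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise ValueError("[H+] must be positive")
    out = -np.log10(h)
    return out if out.ndim else float(out)


def hydrogen_from_ph(ph):
    ph = np.asarray(ph, dtype=float)
    out = np.power(10.0, -ph)
    return out if out.ndim else float(out)
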