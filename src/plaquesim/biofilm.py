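"""Biofilm state: spherical particles above a tooth surface, plus solutes.

Particles are spherical bacterial aggregates of one of two physiologies
(aciduric ``A`` or nonaciduric ``NA``).  Mass and radius are linked through a
fixed density rho, ``radius = (3 m / (4 pi rho))^(1/3)``.  Particle data are
stored as flat arrays for speed; :class:`Particle` offers a per-particle view
for inspection and I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fields import SoluteFields
from .params import PTYPE_A, PTYPE_NA, TYPE_CODES, TYPE_LABELS, ModelParams

__all__ = [
    "Particle",
    "BiofilmState",
    "RngStreams",
    "mass_to_radius",
    "radius_to_mass",
    "init_biofilm",
]


def mass_to_radius(mass, rho: float):
    """Radius (um) of a sphere of the given mass (pg) and density (pg um^-3)."""
    mass = np.asarray(mass, dtype=float)
    if np.any(mass <= 0) or rho <= 0:
        raise ValueError("mass and rho must be strictly positive")
    out = np.cbrt(3.0 * mass / (4.0 * math.pi * rho))
    return out if out.ndim else float(out)


def radius_to_mass(radius, rho: float):
    radius = np.asarray(radius, dtype=float)
    out = (4.0 * math.pi / 3.0) * rho * radius**3
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Particle:
    """One bacterial aggregate (read-only view)."""

    id: int
    ptype: str  # "A" | "NA"
    mass: float  # pg
    pos: tuple[float, float, float]  # um
    radius: float  # um


class RngStreams:
    """Independent child RNG streams, all derived from one root seed.

    Separate streams for initial placement, division directions, death draws
    and shove tie-breaks mean that toggling one stochastic element does not
    perturb the draws of the others.
    """

    NAMES = ("init", "divide", "death", "shove")

    def __init__(self, seed: int):
        self.seed = int(seed)
        children = np.random.SeedSequence(self.seed).spawn(len(self.NAMES))
        self.streams = {
            name: np.random.Generator(np.random.PCG64(ss))
            for name, ss in zip(self.NAMES, children)
        }

    def __getattr__(self, name):
        if name in ("streams", "seed"):
            raise AttributeError(name)
        try:
            return self.streams[name]
        except KeyError:
            raise AttributeError(name) from None

    def state_dict(self) -> dict:
        return {
            "seed": self.seed,
            "states": {n: g.bit_generator.state for n, g in self.streams.items()},
        }

    @classmethod
    def from_state_dict(cls, d: dict) -> "RngStreams":
        rng = cls(d["seed"])
        for n, st in d["states"].items():
            rng.streams[n].bit_generator.state = st
        return rng


@dataclass
class BiofilmState:
    """Full simulation state: particles, solute fields, clock, RNG."""

    ids: np.ndarray       # (n,) int64, unique
    ptype: np.ndarray     # (n,) int8: 1 = A, 0 = NA
    mass: np.ndarray      # (n,) pg
    pos: np.ndarray       # (n, 3) um
    fields: SoluteFields
    t: float
    rng: RngStreams
    next_id: int = 0

    @property
    def n(self) -> int:
        return self.ids.size

    def radius(self, params: ModelParams) -> np.ndarray:
        return mass_to_radius(self.mass, params.rho)

    def particles(self, params: ModelParams) -> list[Particle]:
        r = self.radius(params)
        return [
            Particle(int(i), TYPE_LABELS[int(p)], float(m), tuple(x), float(rr))
            for i, p, m, x, rr in zip(self.ids, self.ptype, self.mass, self.pos, r)
        ]

    # -- snapshot I/O ---------------------------------------------------------

    def to_frame(self, params: ModelParams) -> pd.DataFrame:
        r = self.radius(params)
        return pd.DataFrame(
            {
                "id": self.ids,
                "type": [TYPE_LABELS[int(p)] for p in self.ptype],
                "mass": self.mass,
                "x": self.pos[:, 0],
                "y": self.pos[:, 1],
                "z": self.pos[:, 2],
                "radius": r,
            }
        )

    def write_particles_csv(self, path, params: ModelParams) -> None:
        self.to_frame(params).to_csv(path, index=False)

    @staticmethod
    def particles_from_csv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        df = pd.read_csv(path, keep_default_na=False)
        ids = df["id"].to_numpy(dtype=np.int64)
        ptype = np.array([TYPE_CODES[t] for t in df["type"]], dtype=np.int8)
        mass = df["mass"].to_numpy(dtype=float)
        pos = df[["x", "y", "z"]].to_numpy(dtype=float)
        return ids, ptype, mass, pos


def init_biofilm(
    params: ModelParams,
    n_particles: int,
    frac_A: float,
    seed: int | None = None,
    exact_counts: bool = True,
    mass_jitter: float = 0.3,
) -> BiofilmState:
    """Construct a mechanically stable starting biofilm.

    ``n_particles`` spheres are placed by sequential random insertion with
    rejection on overlap in the slab ``radius <= z < B`` and then given one
    stabilisation pass.  In the default exact-count mode, ``floor(frac_A * n)``
    particles are aciduric and assignment order is shuffled; with
    ``exact_counts=False`` each particle is independently A with probability
    ``frac_A``.  Initial masses are jittered uniformly within
    ``+- mass_jitter`` of the half-critical mass so divisions desynchronise.
    """
    from .population import relax_overlaps  # local import to avoid a cycle

    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    if not 0.0 <= frac_A <= 1.0:
        raise ValueError("frac_A must lie in [0, 1]")
    rng = RngStreams(params.seed if seed is None else seed)
    g = rng.init

    m0 = params.m_crit / 2.0
    mass = m0 * (1.0 + mass_jitter * (2.0 * g.random(n_particles) - 1.0))
    radius = mass_to_radius(mass, params.rho)
    # packing feasibility at the configured insertion limit (~40 % fill)
    slab = params.L**2 * params.B
    if (4.0 * math.pi / 3.0) * float(np.sum(radius**3)) > 0.35 * slab:
        raise ValueError(
            f"{n_particles} particles cannot fit in L x L x B at the packing limit"
        )

    if exact_counts:
        n_a = int(math.floor(frac_A * n_particles))
        ptype = np.zeros(n_particles, dtype=np.int8)
        ptype[:n_a] = PTYPE_A
        g.shuffle(ptype)
    else:
        ptype = (g.random(n_particles) < frac_A).astype(np.int8)

    pos = np.empty((n_particles, 3))
    for i in range(n_particles):
        ri = radius[i]
        if ri >= params.B:
            raise ValueError("particle radius exceeds the thickness ceiling B")
        placed = False
        for _ in range(2000):
            x = g.random() * params.L
            y = g.random() * params.L
            z = ri + g.random() * (params.B - ri) * (1.0 - 1e-12)
            cand = np.array([x, y, z])
            if i:
                d = pos[:i] - cand
                d[:, 0] -= params.L * np.rint(d[:, 0] / params.L)
                d[:, 1] -= params.L * np.rint(d[:, 1] / params.L)
                if np.any(np.sum(d * d, axis=1) < (radius[:i] + ri) ** 2):
                    continue
            pos[i] = cand
            placed = True
            break
        if not placed:
            raise ValueError("random insertion failed; reduce n_particles")

    state = BiofilmState(
        ids=np.arange(n_particles, dtype=np.int64),
        ptype=ptype,
        mass=mass,
        pos=pos,
        fields=SoluteFields.resting(params),
        t=0.0,
        rng=rng,
        next_id=n_particles,
    )
    relax_overlaps(state, params)
    return state
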