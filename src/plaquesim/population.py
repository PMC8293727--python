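"""Per-particle biology: metabolism, growth, division, death, mechanics.

The sugar-to-acid conversion rate of a particle of mass m follows a Monod
factor in the effective local sugar concentration and a bell-shaped pH factor
centred on the physiology's preferred acidity K_acid:

    r = m * mu_max * gl_eff / (gl_eff + K_Gl) * 4 h K_acid / (h + K_acid)^2

Both factors are at most 1, so r <= m * mu_max.  Growth adds a fixed yield
fraction Y of the converted mass; particles divide in two equal halves above a
critical diameter; acid kills at a rate ``1e7 * K_death * [H+]`` (twice as
fast for NA as for A); overlapping spheres are relaxed by symmetric shoving
and the film is trimmed back to thickness B.
"""

from __future__ import annotations

import warnings

import numpy as np

from .biofilm import BiofilmState, mass_to_radius
from .params import PTYPE_A, TYPE_LABELS, ModelParams, TypeParams

try:  # compiled shove kernel; the numpy path below is the fallback
    import numba

    @numba.njit(fastmath=False)
    def _shove_kernel(pos, radius, L, tol, max_iter):  # pragma: no cover
        n = pos.shape[0]
        disp = np.zeros((n, 3))
        for it in range(1, max_iter + 1):
            for i in range(n):
                if pos[i, 2] < radius[i]:
                    pos[i, 2] = radius[i]
            max_rel = 0.0
            disp[:] = 0.0
            for i in range(n):
                for j in range(i + 1, n):
                    dx = pos[j, 0] - pos[i, 0]
                    dx -= L * np.rint(dx / L)
                    dy = pos[j, 1] - pos[i, 1]
                    dy -= L * np.rint(dy / L)
                    dz = pos[j, 2] - pos[i, 2]
                    rsum = radius[i] + radius[j]
                    d2 = dx * dx + dy * dy + dz * dz
                    if d2 >= rsum * rsum:
                        continue
                    dist = np.sqrt(d2)
                    if dist < 1e-12:
                        return -1  # coincident centres: defer to the caller
                    rel = (rsum - dist) / rsum
                    if rel > max_rel:
                        max_rel = rel
                    f = (rsum - dist) / (2.0 * dist)
                    disp[j, 0] += f * dx
                    disp[j, 1] += f * dy
                    disp[j, 2] += f * dz
                    disp[i, 0] -= f * dx
                    disp[i, 1] -= f * dy
                    disp[i, 2] -= f * dz
            if max_rel <= tol:
                return it
            for i in range(n):
                pos[i, 0] = (pos[i, 0] + disp[i, 0]) % L
                pos[i, 1] = (pos[i, 1] + disp[i, 1]) % L
                pos[i, 2] += disp[i, 2]
        return -(max_iter + 1)
except ImportError:  # pragma: no cover
    _shove_kernel = None

__all__ = [
    "metabolic_rate",
    "metabolic_rates",
    "grow_particles",
    "death_rate",
    "apply_deaths",
    "divide_particles",
    "relax_overlaps",
    "trim_thickness",
    "max_relative_overlap",
]


def metabolic_rate(mass, gl_eff, h, tp: TypeParams):
    """Sugar-to-acid conversion rate r (pg s^-1) for one physiology.

    Vectorised over any mix of scalar/array inputs.  ``gl_eff`` is the local
    sugar concentration including the constant [polyGl] background; ``h`` is
    the local hydrogen-ion concentration (mol L^-1).
    """
    mass = np.asarray(mass, dtype=float)
    gl_eff = np.asarray(gl_eff, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(mass < 0) or np.any(gl_eff < 0) or np.any(h <= 0):
        raise ValueError("need mass >= 0, gl_eff >= 0 and h > 0")
    monod = gl_eff / (gl_eff + tp.K_Gl)
    ph_factor = 4.0 * h * tp.K_acid / (h + tp.K_acid) ** 2
    out = mass * tp.mu_max * monod * ph_factor
    return out if out.ndim else float(out)


def metabolic_rates(
    state: BiofilmState, gl_local: np.ndarray, h_local: np.ndarray, params: ModelParams
) -> np.ndarray:
    """Conversion rates for every particle given sampled local conditions."""
    gl_eff = np.asarray(gl_local, dtype=float) + params.poly_gl
    r = np.empty(state.n)
    for code, tp in ((PTYPE_A, params.type_A), (0, params.type_NA)):
        m = state.ptype == code
        if m.any():
            r[m] = metabolic_rate(state.mass[m], gl_eff[m], h_local[m], tp)
    return r


def grow_particles(state: BiofilmState, r: np.ndarray, params: ModelParams, dt_bio: float) -> None:
    """Add the yield fraction of converted sugar to particle masses (in place)."""
    state.mass += params.Y * np.asarray(r, dtype=float) * dt_bio


def death_rate(tp: TypeParams, h, prefactor: float = 1.0e7):
    """Acid-driven death rate (s^-1): ``prefactor * K_death * [H+]``."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("h must be nonnegative")
    out = prefactor * tp.K_death * h
    return out if out.ndim else float(out)


def apply_deaths(
    state: BiofilmState,
    h_local: np.ndarray,
    params: ModelParams,
    dt_bio: float,
    log: list | None = None,
) -> int:
    """Remove each particle independently with probability 1 - exp(-rate dt).

    The exponential (Poisson) form is exact for any step length.  Removed
    biomass vanishes (no lysis products).  Returns the number of deaths.
    """
    rates = np.where(
        state.ptype == PTYPE_A,
        death_rate(params.type_A, h_local, params.death_prefactor),
        death_rate(params.type_NA, h_local, params.death_prefactor),
    )
    if rates.size and float(np.max(rates)) * dt_bio > 0.5:
        warnings.warn("death probability per step is large; consider a smaller dt_bio")
    p = -np.expm1(-rates * dt_bio)
    u = state.rng.death.random(state.n)
    dead = u < p
    n_dead = int(dead.sum())
    if n_dead:
        if log is not None:
            for i in np.flatnonzero(dead):
                log.append(
                    (state.t, "death", int(state.ids[i]),
                     TYPE_LABELS[int(state.ptype[i])], float(state.pos[i, 2]))
                )
        keep = ~dead
        state.ids = state.ids[keep]
        state.ptype = state.ptype[keep]
        state.mass = state.mass[keep]
        state.pos = state.pos[keep]
    return n_dead


def divide_particles(
    state: BiofilmState, params: ModelParams, log: list | None = None
) -> int:
    """Split every particle above the critical diameter into two equal halves.

    Daughters keep the parent type, carry half the mass each (total mass is
    conserved exactly) and are displaced by +- r_daughter along a uniformly
    random direction, with z clipped so neither sphere penetrates the tooth.
    Daughters are below the critical diameter by construction, so no cascade
    occurs within one call.  Returns the number of divisions.
    """
    dividing = np.flatnonzero(state.mass > params.m_crit)
    if dividing.size == 0:
        return 0
    g = state.rng.divide
    half = state.mass[dividing] / 2.0
    r_d = mass_to_radius(half, params.rho)
    vec = g.normal(size=(dividing.size, 3))
    norm = np.linalg.norm(vec, axis=1)
    norm[norm == 0] = 1.0
    u = vec / norm[:, None]
    p1 = state.pos[dividing] + u * r_d[:, None]
    p2 = state.pos[dividing] - u * r_d[:, None]
    for p in (p1, p2):
        p[:, 0] %= params.L
        p[:, 1] %= params.L
        np.clip(p[:, 2], r_d, params.H, out=p[:, 2])
    new_ids = np.arange(state.next_id, state.next_id + dividing.size, dtype=np.int64)
    state.next_id += dividing.size
    if log is not None:
        for j, i in enumerate(dividing):
            log.append(
                (state.t, "division", int(state.ids[i]),
                 TYPE_LABELS[int(state.ptype[i])], float(state.pos[i, 2]))
            )
    state.mass[dividing] = half
    state.pos[dividing] = p1
    state.ids = np.concatenate([state.ids, new_ids])
    state.ptype = np.concatenate([state.ptype, state.ptype[dividing]])
    state.mass = np.concatenate([state.mass, half])
    state.pos = np.vstack([state.pos, p2])
    return int(dividing.size)


_TRIU_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _triu_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _TRIU_CACHE:
        if len(_TRIU_CACHE) > 64:
            _TRIU_CACHE.clear()
        _TRIU_CACHE[n] = np.triu_indices(n, 1)
    return _TRIU_CACHE[n]


def _pair_overlaps(pos: np.ndarray, radius: np.ndarray, L: float, i=None, j=None):
    """Pairwise overlaps under lateral periodic wrapping.

    Returns (i, j, displacement i->j, dist, gap) with gap = dist - (ri + rj);
    gap < 0 marks an overlap.  Brute-force O(n^2) over all pairs unless a
    candidate pair subset (i, j) is supplied; adequate at desk scale.
    """
    if i is None:
        i, j = _triu_pairs(pos.shape[0])
    d = pos[j] - pos[i]
    d[:, 0] -= L * np.rint(d[:, 0] / L)
    d[:, 1] -= L * np.rint(d[:, 1] / L)
    dist = np.sqrt(np.einsum("ij,ij->i", d, d))
    return i, j, d, dist, dist - (radius[i] + radius[j])


def max_relative_overlap(state: BiofilmState, params: ModelParams) -> float:
    """Largest pairwise overlap relative to the sum of radii (O(n^2) audit)."""
    if state.n < 2:
        return 0.0
    radius = state.radius(params)
    i, j, _, dist, gap = _pair_overlaps(state.pos, radius, params.L)
    rel = -gap / (radius[i] + radius[j])
    return float(np.max(rel)) if rel.size else 0.0


def relax_overlaps(state: BiofilmState, params: ModelParams) -> int:
    """Shove overlapping spheres apart until the film is mechanically stable.

    Each iteration displaces every overlapping pair symmetrically along its
    centre line by half the overlap each (all pairs simultaneously, so the
    result does not depend on particle order), wraps x/y periodically and
    reflects spheres off the tooth plane (z >= radius).  Stops when the
    largest relative overlap is at most ``shove_tol``.  Returns the number of
    iterations used; warns if the iteration cap is hit.
    """
    radius = state.radius(params)
    L = params.L
    n = state.n
    if n == 0:
        return 0
    if _shove_kernel is not None and n >= 2:
        out = _shove_kernel(state.pos, radius, L, params.shove_tol,
                            params.shove_max_iter)
        if out > 0:
            return int(out)
        if out == -(params.shove_max_iter + 1):  # iteration cap hit
            warnings.warn("relax_overlaps hit the iteration cap; returning best state")
            return params.shove_max_iter
        # out == -1: coincident centres somewhere; fall through to the numpy
        # path, which separates them along a random direction
    # near-contact candidate pairs (20 % cushion), refreshed periodically:
    # per-iteration displacements are fractions of a radius, so the cushion
    # stays valid across a few iterations and the O(n^2) scan is amortised
    ci = cj = None
    for it in range(1, params.shove_max_iter + 1):
        np.clip(state.pos[:, 2], radius, None, out=state.pos[:, 2])
        if n < 2:
            return it
        if ci is None or (it - 1) % 4 == 0:
            i, j, d, dist, gap = _pair_overlaps(state.pos, radius, L)
            rsum_all = radius[i] + radius[j]
            near = gap < 0.2 * rsum_all
            ci, cj = i[near], j[near]
            d, dist, gap = d[near], dist[near], gap[near]
        else:
            _, _, d, dist, gap = _pair_overlaps(state.pos, radius, L, ci, cj)
        i, j = ci, cj
        rsum = radius[i] + radius[j]
        rel = -gap / rsum
        if not rel.size or float(rel.max()) <= params.shove_tol:
            # candidates may be stale: confirm with a full O(n^2) audit
            if max_relative_overlap(state, params) <= params.shove_tol:
                return it
            ci = cj = None
            continue
        # push every overlapping pair to tangency, not only those beyond the
        # tolerance: leaves slack so later steps converge in ~1 iteration
        overlapping = gap < 0.0
        ii = i[overlapping]
        jj = j[overlapping]
        dd = d[overlapping]
        dn = dist[overlapping]
        # coincident centres: push apart along a random direction
        degenerate = dn < 1e-12
        if degenerate.any():
            rnd = state.rng.shove.normal(size=(int(degenerate.sum()), 3))
            rnd /= np.linalg.norm(rnd, axis=1)[:, None]
            dd[degenerate] = rnd
            dn[degenerate] = 1.0
        u = dd / dn[:, None]
        half = (-gap[overlapping] / 2.0)[:, None] * u
        disp = np.zeros_like(state.pos)
        np.add.at(disp, jj, half)
        np.add.at(disp, ii, -half)
        state.pos += disp
        state.pos[:, 0] %= L
        state.pos[:, 1] %= L
    np.clip(state.pos[:, 2], radius, None, out=state.pos[:, 2])
    warnings.warn("relax_overlaps hit the iteration cap; returning best state")
    return params.shove_max_iter


def trim_thickness(
    state: BiofilmState, params: ModelParams, log: list | None = None
) -> int:
    """Remove particles whose centres exceed the thickness ceiling B."""
    above = state.pos[:, 2] > params.B
    n_removed = int(above.sum())
    if n_removed:
        if log is not None:
            for i in np.flatnonzero(above):
                log.append(
                    (state.t, "trim", int(state.ids[i]),
                     TYPE_LABELS[int(state.ptype[i])], float(state.pos[i, 2]))
                )
        keep = ~above
        state.ids = state.ids[keep]
        state.ptype = state.ptype[keep]
        state.mass = state.mass[keep]
        state.pos = state.pos[keep]
    return n_removed
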