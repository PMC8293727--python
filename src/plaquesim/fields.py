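"""Reaction-diffusion solute fields for sugar [Gl] and undissociated acid.

Both solutes live on a node-centred lattice spanning the box: periodic in x
and y, tooth surface at z = 0 (zero-flux for both fields) and saliva-air
interface at z = H, where the acid concentration is pinned at zero and the
sugar concentration is pinned at the dietary interface value (Dirichlet).

Three integration routes are provided:

* :func:`step_fields` - explicit (FTCS) transient step, with sink throttling
  so no voxel is driven negative;
* :class:`SteadySolver` - a prefactorised sparse direct solver for the steady
  diffusion problem (the fixed point of :func:`step_fields`) and for
  backward-Euler transient steps; this is what the driver uses;
* :func:`relax_to_steady` - steady solution with frozen reaction densities,
  including a repair loop that throttles sinks wherever the frozen-rate
  steady state would be negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

__all__ = [
    "SoluteFields",
    "ReactionDensity",
    "deposit_rates",
    "step_fields",
    "relax_to_steady",
    "sample_field",
    "SteadySolver",
    "fields_to_csv",
    "z_profile",
]


@dataclass
class SoluteFields:
    """Gridded concentrations (mol m^-3), shape (Nx, Ny, Nz), node-centred.

    ``gl[..., -1]`` is the saliva-air interface layer; ``gl[..., 0]`` touches
    the tooth.
    """

    gl: np.ndarray
    acid: np.ndarray
    spacing: float

    @classmethod
    def resting(cls, params) -> "SoluteFields":
        shape = params.grid_shape
        return cls(np.zeros(shape), np.zeros(shape), params.grid_spacing)

    def copy(self) -> "SoluteFields":
        return SoluteFields(self.gl.copy(), self.acid.copy(), self.spacing)


@dataclass
class ReactionDensity:
    """Voxelwise reaction rate densities (mol m^-3 s^-1), nonzero only where
    particles sit."""

    gl_sink: np.ndarray
    acid_source: np.ndarray


def deposit_rates(positions: np.ndarray, rates: np.ndarray, params) -> ReactionDensity:
    """Spread per-particle sugar-conversion rates (pg s^-1) onto the lattice.

    Nearest-node deposition: each particle's whole rate lands in the voxel
    containing its centre, so the total deposited sink equals the summed
    particle rates exactly (conservation by construction).  The acid source is
    the stoichiometric fraction of the sugar sink, converted through the acid
    molar mass.
    """
    nx, ny, nz = params.grid_shape
    s = params.grid_spacing
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    r = np.atleast_1d(np.asarray(rates, dtype=float))
    if pos.shape[0] != r.shape[0]:
        raise ValueError("positions and rates must have matching length")
    gl_sink = np.zeros((nx, ny, nz))
    acid_source = np.zeros((nx, ny, nz))
    if pos.shape[0]:
        if (
            np.any(pos[:, 0] < 0) or np.any(pos[:, 0] >= params.L)
            or np.any(pos[:, 1] < 0) or np.any(pos[:, 1] >= params.L)
            or np.any(pos[:, 2] < 0) or np.any(pos[:, 2] > params.H)
        ):
            raise ValueError("particle outside the simulation box")
        i = np.rint(pos[:, 0] / s).astype(int) % nx
        j = np.rint(pos[:, 1] / s).astype(int) % ny
        k = np.clip(np.rint(pos[:, 2] / s).astype(int), 0, nz - 2)
        vol = params.voxel_volume
        np.add.at(gl_sink, (i, j, k), r / (params.conv_gl * vol))
        np.add.at(
            acid_source,
            (i, j, k),
            params.acid_mass_fraction * r / (params.conv_acid * vol),
        )
    return ReactionDensity(gl_sink, acid_source)


def fields_to_csv(fields: SoluteFields, path) -> None:
    """Write both lattices as flat CSV: x_index,y_index,z_index,gl,acid."""
    nx, ny, nz = fields.gl.shape
    i, j, k = np.meshgrid(range(nx), range(ny), range(nz), indexing="ij")
    out = np.column_stack(
        [i.ravel(), j.ravel(), k.ravel(), fields.gl.ravel(), fields.acid.ravel()]
    )
    np.savetxt(
        path, out, delimiter=",", header="x_index,y_index,z_index,gl,acid",
        comments="", fmt=["%d", "%d", "%d", "%.10g", "%.10g"],
    )


def z_profile(fields: SoluteFields):
    """Laterally averaged concentration profiles versus height.

    Returns ``(z, gl_mean, acid_mean)`` arrays, one entry per lattice layer —
    the natural quantity for plotting solute penetration into the film.
    """
    nz = fields.gl.shape[2]
    z = np.arange(nz) * fields.spacing
    return z, fields.gl.mean(axis=(0, 1)), fields.acid.mean(axis=(0, 1))


def _laplacian(c: np.ndarray, spacing: float) -> np.ndarray:
    """Discrete Laplacian on interior + bottom nodes (top layer left as BC).

    Periodic in x and y; mirror (zero-flux) ghost below z = 0.
    """
    lap = np.empty_like(c)
    lap[:] = (
        np.roll(c, 1, axis=0) + np.roll(c, -1, axis=0)
        + np.roll(c, 1, axis=1) + np.roll(c, -1, axis=1)
        - 4.0 * c
    )
    lap[:, :, 1:-1] += c[:, :, :-2] + c[:, :, 2:] - 2.0 * c[:, :, 1:-1]
    lap[:, :, 0] += 2.0 * (c[:, :, 1] - c[:, :, 0])
    lap[:, :, -1] = 0.0  # Dirichlet layer: never updated through the stencil
    return lap / spacing**2


def step_fields(
    fields: SoluteFields,
    reactions: ReactionDensity,
    bc_gl_top: float,
    dt_chem: float,
    D_Gl: float,
    D_acid: float,
) -> SoluteFields:
    """One explicit transient step of both solutes.

    The sugar sink in each voxel is throttled to the concentration available
    during the step, so concentrations cannot go negative.  Raises if the
    timestep violates the FTCS stability bound or the fields diverge.
    """
    s = fields.spacing
    dt_max = s**2 / (6.0 * max(D_Gl, D_acid))
    if dt_chem > dt_max * (1.0 + 1e-9):
        raise ValueError(
            f"dt_chem={dt_chem:g}s exceeds the stability bound {dt_max:g}s"
        )
    gl = fields.gl.copy()
    acid = fields.acid.copy()
    sink = np.minimum(reactions.gl_sink, gl / dt_chem)
    gl += dt_chem * (D_Gl * _laplacian(gl, s) - sink)
    acid += dt_chem * (D_acid * _laplacian(acid, s) + reactions.acid_source)
    np.maximum(gl, 0.0, out=gl)
    np.maximum(acid, 0.0, out=acid)
    gl[:, :, -1] = bc_gl_top
    acid[:, :, -1] = 0.0
    if not (np.isfinite(gl).all() and np.isfinite(acid).all()):
        raise FloatingPointError("field solver diverged (non-finite values)")
    return SoluteFields(gl, acid, s)


class SteadySolver:
    """Prefactorised direct solver for the lattice diffusion operator.

    Solves ``-lap(c) = f / D`` on all nodes below the Dirichlet top layer
    (periodic x/y, zero-flux bottom), and backward-Euler steps
    ``(I - dt D lap) c_new = c_old + dt * source``.  The negated Laplacian is
    assembled and LU-factorised once per grid; D only rescales the right-hand
    side, so one factorisation serves both solutes.
    """

    def __init__(self, shape: tuple[int, int, int], spacing: float):
        self.shape = shape
        self.spacing = spacing
        nx, ny, nz = shape
        self.nzu = nz - 1  # unknown z-layers (top layer is Dirichlet)

        def periodic_1d(n: int) -> sp.csr_matrix:
            m = sp.lil_matrix((n, n))
            for i in range(n):
                m[i, i] += 2.0
                m[i, (i - 1) % n] -= 1.0
                m[i, (i + 1) % n] -= 1.0
            return m.tocsr()

        def z_1d(n: int) -> sp.csr_matrix:
            m = sp.lil_matrix((n, n))
            for k in range(n):
                m[k, k] = 2.0
                if k > 0:
                    m[k, k - 1] = -1.0
                if k < n - 1:
                    m[k, k + 1] = -1.0
            m[0, 1] = -2.0  # zero-flux mirror at the tooth surface
            # k == n-1 couples to the Dirichlet layer through the RHS
            return m.tocsr()

        ix, iy, iz = sp.identity(nx), sp.identity(ny), sp.identity(self.nzu)
        lap_neg = (
            sp.kron(sp.kron(periodic_1d(nx), iy), iz)
            + sp.kron(sp.kron(ix, periodic_1d(ny)), iz)
            + sp.kron(sp.kron(ix, iy), z_1d(self.nzu))
        ) / spacing**2
        self._a0 = lap_neg.tocsc()
        self._lu_a0 = splu(self._a0)
        self._lu_be: dict[tuple[float, float], object] = {}

    # -- steady ---------------------------------------------------------------

    def solve_steady(self, f: np.ndarray, D: float, bc_top: float) -> np.ndarray:
        """Steady field with volumetric source density ``f`` (negative = sink)."""
        nx, ny, _ = self.shape
        rhs = (f[:, :, : self.nzu] / D).copy()
        rhs[:, :, -1] += bc_top / self.spacing**2
        sol = self._lu_a0.solve(rhs.reshape(-1))
        out = np.empty(self.shape)
        out[:, :, : self.nzu] = sol.reshape(nx, ny, self.nzu)
        out[:, :, -1] = bc_top
        return out

    # -- backward Euler -------------------------------------------------------

    def step_implicit(
        self, c: np.ndarray, source: np.ndarray, D: float, dt: float, bc_top: float
    ) -> np.ndarray:
        """One backward-Euler step of ``dc/dt = D lap c + source``."""
        key = (float(dt), float(D))
        if key not in self._lu_be:
            n = self._a0.shape[0]
            m = (sp.identity(n, format="csc") + dt * D * self._a0).tocsc()
            self._lu_be[key] = splu(m)
        nx, ny, _ = self.shape
        rhs = c[:, :, : self.nzu] + dt * source[:, :, : self.nzu]
        rhs = rhs.copy()
        rhs[:, :, -1] += dt * D * bc_top / self.spacing**2
        sol = self._lu_be[key].solve(rhs.reshape(-1))
        out = np.empty(self.shape)
        out[:, :, : self.nzu] = sol.reshape(nx, ny, self.nzu)
        out[:, :, -1] = bc_top
        return np.maximum(out, 0.0)


def relax_to_steady(
    fields: SoluteFields,
    reactions: ReactionDensity,
    bc_gl_top: float,
    D_Gl: float,
    D_acid: float,
    tol: float = 1e-10,
    max_iter: int = 50,
    solver: SteadySolver | None = None,
) -> SoluteFields:
    """Steady-state fields for frozen reaction densities and boundary values.

    Where the frozen sugar sink exceeds what diffusion can supply, the steady
    linear solution would be negative; the repair loop scales the sink down in
    those voxels until the solution is nonnegative everywhere (within ``tol``
    of the field scale).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if solver is None:
        solver = SteadySolver(fields.gl.shape, fields.spacing)
    sink = reactions.gl_sink.copy()
    scale = max(bc_gl_top, fields.gl.max(), 1e-30)
    gl = None
    for _ in range(max_iter):
        gl = solver.solve_steady(-sink, D_Gl, bc_gl_top)
        neg = gl < -tol * scale
        if not neg.any():
            break
        sink[neg] *= 0.5
    else:
        raise RuntimeError("sink repair loop failed to converge")
    acid = solver.solve_steady(reactions.acid_source, D_acid, 0.0)
    return SoluteFields(np.maximum(gl, 0.0), np.maximum(acid, 0.0), fields.spacing)


def sample_field(fields: SoluteFields, pos: np.ndarray):
    """Trilinear interpolation of both solutes at positions ``pos`` (n, 3).

    Periodic wrapping in x and y; z must lie inside [0, H].  Returns
    ``(gl_local, acid_local)`` arrays.
    """
    nx, ny, nz = fields.gl.shape
    s = fields.spacing
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    zmax = (nz - 1) * s
    if np.any(pos[:, 2] < 0) or np.any(pos[:, 2] > zmax * (1 + 1e-12)):
        raise ValueError("position outside the box in z")
    u = pos[:, 0] / s
    v = pos[:, 1] / s
    w = np.clip(pos[:, 2] / s, 0.0, nz - 1 - 1e-12)
    i0 = np.floor(u).astype(int)
    j0 = np.floor(v).astype(int)
    k0 = np.floor(w).astype(int)
    fu = u - i0
    fv = v - j0
    fw = w - k0
    i0 %= nx
    j0 %= ny
    i1 = (i0 + 1) % nx
    j1 = (j0 + 1) % ny
    k1 = np.minimum(k0 + 1, nz - 1)

    def tri(c):
        c000 = c[i0, j0, k0]; c100 = c[i1, j0, k0]
        c010 = c[i0, j1, k0]; c110 = c[i1, j1, k0]
        c001 = c[i0, j0, k1]; c101 = c[i1, j0, k1]
        c011 = c[i0, j1, k1]; c111 = c[i1, j1, k1]
        c00 = c000 * (1 - fu) + c100 * fu
        c10 = c010 * (1 - fu) + c110 * fu
        c01 = c001 * (1 - fu) + c101 * fu
        c11 = c011 * (1 - fu) + c111 * fu
        c0 = c00 * (1 - fv) + c10 * fv
        c1 = c01 * (1 - fv) + c11 * fv
        return c0 * (1 - fw) + c1 * fw

    return tri(fields.gl), tri(fields.acid)
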