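"""Parameter containers and configuration I/O.

Unit conventions (used everywhere in the package):

* lengths in micrometres, time in seconds, particle mass in picograms;
* solute concentrations in mol m^-3;
* hydrogen-ion concentration in mol L^-1, converted from the acid field only
  inside :mod:`plaquesim.chemistry` (one conversion point);
* diffusivities in um^2 s^-1.

Two bacterial physiologies are represented: ``A`` (aciduric, acid tolerant,
low preferred pH) and ``NA`` (nonaciduric, metabolism sharply reduced at low
pH and killed twice as fast by acid).  The default parameter set ships in the
versioned config ``plaquesim/configs/default.yaml``; it is a calibration
ledger, not a measurement.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .chemistry import BufferParams

__all__ = ["TypeParams", "ModelParams", "default_params", "load_config", "dump_config"]

#: integer codes used in particle arrays
PTYPE_NA = 0
PTYPE_A = 1
TYPE_LABELS = {PTYPE_NA: "NA", PTYPE_A: "A"}
TYPE_CODES = {"NA": PTYPE_NA, "A": PTYPE_A}


@dataclass(frozen=True)
class TypeParams:
    """Physiology of one particle type.

    Attributes
    ----------
    label : ``"A"`` or ``"NA"``.
    mu_max : maximum specific sugar-conversion rate (per unit particle mass,
        s^-1): a saturated particle of mass m converts sugar at ``m * mu_max``.
    K_Gl : sugar half-saturation concentration (mol m^-3).
    K_acid : preferred hydrogen-ion concentration (mol L^-1); the pH factor of
        the rate law is maximal at [H+] = K_acid, i.e. at
        ``preferred_ph = -log10(K_acid)``.
    K_death : death-rate constant (L mol^-1 s^-1 scale, before the fixed 1e7
        prefactor).
    """

    label: str
    mu_max: float
    K_Gl: float
    K_acid: float
    K_death: float

    def __post_init__(self) -> None:
        if self.label not in ("A", "NA"):
            raise ValueError("label must be 'A' or 'NA'")
        for name in ("mu_max", "K_Gl", "K_acid", "K_death"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def preferred_ph(self) -> float:
        return -math.log10(self.K_acid)

    @classmethod
    def from_preferred_ph(cls, label, mu_max, K_Gl, preferred_ph, K_death):
        return cls(label, mu_max, K_Gl, 10.0 ** (-preferred_ph), K_death)


@dataclass(frozen=True)
class ModelParams:
    """Every constant of the model: geometry, physiology, chemistry, numerics.

    Geometry: the box is L x L x H with the tooth surface at z = 0 and the
    saliva-air interface at z = H.  Biofilm thickness is capped at B < H by
    removing particles whose centres exceed B after mechanical stabilisation.
    """

    # geometry (um)
    L: float = 36.0
    H: float = 60.0
    B: float = 24.0
    grid_spacing: float = 6.0

    # particle physiology
    type_A: TypeParams = field(
        default_factory=lambda: TypeParams.from_preferred_ph(
            "A", mu_max=1.5e-3, K_Gl=0.25, preferred_ph=5.0, K_death=1.0e-7
        )
    )
    type_NA: TypeParams = field(
        default_factory=lambda: TypeParams.from_preferred_ph(
            "NA", mu_max=1.5e-3, K_Gl=0.25, preferred_ph=7.0, K_death=2.0e-7
        )
    )
    Y: float = 0.025               # growth yield (fraction of converted sugar mass)
    death_prefactor: float = 1.0e7  # fixed dimensionless multiplier of K_death*[H+]

    # solutes
    poly_gl: float = 0.008         # background carbohydrate [polyGl], mol m^-3
    D_Gl: float = 600.0            # um^2 s^-1
    D_acid: float = 4.0            # um^2 s^-1 (effective, buffer-retarded)
    gl_molar_mass: float = 180.0   # g mol^-1 (glucose equivalent)
    acid_molar_mass: float = 90.0  # g mol^-1 (lactic acid equivalent)
    acid_stoichiometry: str = "one_minus_y"  # or "unity"

    # particle geometry / mechanics
    d_crit: float = 6.0            # critical diameter for division (um)
    rho: float = 0.1               # particle mass density, pg um^-3 (dry mass)
    shove_tol: float = 0.05        # max allowed relative sphere overlap
    shove_max_iter: int = 150

    # chemistry
    buffering: BufferParams = field(default_factory=BufferParams)

    # numerics
    dt_bio: float = 30.0           # biology step during pulse activity (s)
    dt_bio_idle: float = 600.0     # biology step between pulses (s)
    dt_chem: float | None = None   # explicit field step; None -> stability bound
    field_mode: str = "semi_implicit"  # semi_implicit | quasi_steady | transient
    picard_tol: float = 1.0e-3
    picard_max_iter: int = 8

    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.Y < 1:
            raise ValueError("Y must lie strictly between 0 and 1")
        if not 0 < self.B < self.H:
            raise ValueError("need 0 < B < H")
        for name in ("L", "H", "grid_spacing", "d_crit", "rho", "D_Gl", "D_acid"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for extent, axis in ((self.L, "L"), (self.H, "H")):
            n = extent / self.grid_spacing
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"grid_spacing must divide {axis} evenly")
        if self.dt_chem is not None and self.dt_chem > self.dt_bio:
            raise ValueError("dt_chem must not exceed dt_bio")
        if self.field_mode not in ("semi_implicit", "quasi_steady", "transient"):
            raise ValueError("unknown field_mode")
        if self.acid_stoichiometry not in ("one_minus_y", "unity"):
            raise ValueError("acid_stoichiometry must be 'one_minus_y' or 'unity'")
        if abs(self.type_NA.K_death - 2.0 * self.type_A.K_death) > 1e-12 * self.type_A.K_death:
            raise ValueError("K_death of NA must equal exactly 2x K_death of A")
        if not self.type_A.preferred_ph < self.type_NA.preferred_ph:
            raise ValueError("preferred pH of A must be below that of NA")
        # a freshly divided daughter of a just-critical parent has diameter
        # d_crit / 2^(1/3) < d_crit, so the division invariant holds by
        # construction; still guard against pathological configs
        if not self.daughter_diameter < self.d_crit:
            raise ValueError("d_crit must exceed the daughter diameter")

    # ---- derived quantities -------------------------------------------------

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """Node-centred lattice: periodic x/y, z nodes at 0, h, ..., H."""
        n = round(self.L / self.grid_spacing)
        nz = round(self.H / self.grid_spacing) + 1
        return (n, n, nz)

    @property
    def voxel_volume(self) -> float:
        return self.grid_spacing ** 3

    @property
    def m_crit(self) -> float:
        """Mass of a particle at the critical diameter (pg)."""
        return self.rho * (math.pi / 6.0) * self.d_crit ** 3

    @property
    def daughter_diameter(self) -> float:
        return self.d_crit / 2.0 ** (1.0 / 3.0)

    @property
    def conv_gl(self) -> float:
        """pg of sugar per um^3 per (mol m^-3)."""
        return self.gl_molar_mass * 1.0e-6

    @property
    def conv_acid(self) -> float:
        return self.acid_molar_mass * 1.0e-6

    @property
    def acid_mass_fraction(self) -> float:
        """Fraction of converted sugar mass appearing as acid."""
        return 1.0 if self.acid_stoichiometry == "unity" else 1.0 - self.Y

    def type_params(self, code: int) -> TypeParams:
        return self.type_A if code == PTYPE_A else self.type_NA

    def stable_dt_chem(self) -> float:
        """Explicit (FTCS) diffusive stability bound for the faster solute."""
        return self.grid_spacing ** 2 / (6.0 * max(self.D_Gl, self.D_acid))

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)

    def accelerated(self, accel: float) -> "ModelParams":
        """Rescale for compressed ecological runs.

        Growth yield and the death prefactor are both multiplied by ``accel``,
        preserving the growth:death and NA:A ratios; one simulated day then
        carries the ecological weight of ``accel`` days.
        """
        if accel <= 0:
            raise ValueError("accel must be positive")
        y = self.Y * accel
        if not y < 1:
            raise ValueError("accelerated Y would reach 1; lower accel or Y")
        return self.replace(Y=y, death_prefactor=self.death_prefactor * accel)


# ---- configuration files ----------------------------------------------------


def _params_to_dict(p: ModelParams) -> dict:
    def tp(t: TypeParams) -> dict:
        return {
            "mu_max": t.mu_max,
            "K_Gl": t.K_Gl,
            "preferred_ph": t.preferred_ph,
            "K_death": t.K_death,
        }

    return {
        "schema_version": 1,
        "geometry": {"L": p.L, "H": p.H, "B": p.B, "grid_spacing": p.grid_spacing},
        "types": {"A": tp(p.type_A), "NA": tp(p.type_NA)},
        "growth": {"Y": p.Y, "death_prefactor": p.death_prefactor},
        "solutes": {
            "poly_gl": p.poly_gl,
            "D_Gl": p.D_Gl,
            "D_acid": p.D_acid,
            "gl_molar_mass": p.gl_molar_mass,
            "acid_molar_mass": p.acid_molar_mass,
            "acid_stoichiometry": p.acid_stoichiometry,
        },
        "particles": {
            "d_crit": p.d_crit,
            "rho": p.rho,
            "shove_tol": p.shove_tol,
            "shove_max_iter": p.shove_max_iter,
        },
        "buffering": {
            "ph_rest": p.buffering.ph_rest,
            "ph_floor": p.buffering.ph_floor,
            "K_buf": p.buffering.K_buf,
        },
        "numerics": {
            "dt_bio": p.dt_bio,
            "dt_bio_idle": p.dt_bio_idle,
            "dt_chem": p.dt_chem,
            "field_mode": p.field_mode,
            "picard_tol": p.picard_tol,
            "picard_max_iter": p.picard_max_iter,
        },
        "seed": p.seed,
    }


def _coerce_floats(obj):
    """YAML 1.1 parses exponents without a sign (e.g. ``1.0e7``) as strings;
    coerce any such scalar back to float."""
    if isinstance(obj, dict):
        return {k: _coerce_floats(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_coerce_floats(v) for v in obj]
    if isinstance(obj, str):
        try:
            return float(obj)
        except ValueError:
            return obj
    return obj


def _params_from_dict(d: dict) -> ModelParams:
    d = {
        k: (_coerce_floats(v) if k not in ("numerics", "solutes") else v)
        for k, v in d.items()
    }
    for blk in ("numerics", "solutes"):
        if blk in d:
            d[blk] = {
                k: (_coerce_floats(v) if k not in ("field_mode", "acid_stoichiometry") else v)
                for k, v in d[blk].items()
            }
    geo = d.get("geometry", {})
    types = d.get("types", {})

    def tp(label: str) -> TypeParams:
        t = types[label]
        return TypeParams.from_preferred_ph(
            label, t["mu_max"], t["K_Gl"], t["preferred_ph"], t["K_death"]
        )

    buf = d.get("buffering", {})
    sol = d.get("solutes", {})
    par = d.get("particles", {})
    gro = d.get("growth", {})
    num = d.get("numerics", {})
    return ModelParams(
        L=geo["L"],
        H=geo["H"],
        B=geo["B"],
        grid_spacing=geo["grid_spacing"],
        type_A=tp("A"),
        type_NA=tp("NA"),
        Y=gro["Y"],
        death_prefactor=gro.get("death_prefactor", 1.0e7),
        poly_gl=sol["poly_gl"],
        D_Gl=sol["D_Gl"],
        D_acid=sol["D_acid"],
        gl_molar_mass=sol.get("gl_molar_mass", 180.0),
        acid_molar_mass=sol.get("acid_molar_mass", 90.0),
        acid_stoichiometry=sol.get("acid_stoichiometry", "one_minus_y"),
        d_crit=par["d_crit"],
        rho=par["rho"],
        shove_tol=par.get("shove_tol", 0.05),
        shove_max_iter=par.get("shove_max_iter", 60),
        buffering=BufferParams(
            ph_rest=buf.get("ph_rest", 7.0),
            ph_floor=buf.get("ph_floor", 4.0),
            K_buf=buf["K_buf"],
        ),
        dt_bio=num.get("dt_bio", 30.0),
        dt_bio_idle=num.get("dt_bio_idle", 600.0),
        dt_chem=num.get("dt_chem"),
        field_mode=num.get("field_mode", "semi_implicit"),
        picard_tol=num.get("picard_tol", 1.0e-3),
        picard_max_iter=num.get("picard_max_iter", 8),
        seed=d.get("seed", 0),
    )


def load_config(path) -> dict:
    """Read a YAML config file.

    Returns a dict with keys ``params`` (:class:`ModelParams`), ``schedule``
    (:class:`plaquesim.diet.PulseSchedule`) if a ``schedule`` block is present,
    and ``init`` (dict of ``n_particles``/``frac_A``) if present.
    """
    from .diet import PulseSchedule

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {"params": _params_from_dict(raw)}
    if "schedule" in raw:
        s = raw["schedule"]
        out["schedule"] = PulseSchedule(
            freq_per_day=s["freq_per_day"],
            t_half=s["t_half_min"],
            total_dose=s["total_dose"],
            rise_time=s.get("rise_time_s", 30.0),
        )
    if "init" in raw:
        out["init"] = dict(raw["init"])
    return out


def dump_config(params: ModelParams, path, schedule=None, init=None) -> None:
    raw = _params_to_dict(params)
    if schedule is not None:
        raw["schedule"] = {
            "freq_per_day": schedule.freq_per_day,
            "t_half_min": schedule.t_half,
            "total_dose": schedule.total_dose,
            "rise_time_s": schedule.rise_time,
        }
    if init is not None:
        raw["init"] = dict(init)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def default_params() -> ModelParams:
    """The shipped, calibrated default parameter set."""
    ref = resources.files("plaquesim") / "configs" / "default.yaml"
    with resources.as_file(ref) as path:
        return load_config(path)["params"]


def default_config() -> dict:
    """Full shipped config: params, schedule and initial composition."""
    ref = resources.files("plaquesim") / "configs" / "default.yaml"
    with resources.as_file(ref) as path:
        return load_config(path)
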