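"""Model constants, derived molecular scales and configuration validation.

The model couples quasi-static vesicle capillarity, micro-mechanics of
the adhesion patch and reaction–diffusion of bonds (concentration c1 on
the patch) and free binders (c2 on the whole half-vesicle) with a moving
patch edge.  This module houses every physical, kinetic and geometric
constant, the closed-form molecular scales derived from them, and the
structured-config loader.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

from . import units


class ParameterError(ValueError):
    """A configuration value violates a model precondition."""


@dataclass
class ParameterSet:
    """All physical/kinetic/geometric constants and mode switches.

    Units follow the conventions of the vesicle-adhesion literature:
    energies in J, stiffnesses/tensions in N/m, forces in N, lengths in
    μm, diffusivities in μm²/s, rates in 1/s, concentrations in
    molecules/μm² (mapped to line densities by the ribbon depth
    ``l_lat``).

    Parameters
    ----------
    kBT : thermal energy [J].
    kappa : membrane bending stiffness κ [J] (per unit depth after the
        ``l_lat`` mapping).
    gamma : membrane tension [N/m × l_lat]; ``None`` means "derive at
        equilibrium preparation" from the Young–Dupré balance.
    k : extensional stiffness of one bond [N/m].
    f_beta : slip-bond force sensitivity fβ [N]; ``inf`` gives ideal
        (force-insensitive) bonds.
    D1, D2 : diffusivities of bonds / free binders [μm²/s].  A bond
        connects one binder of each membrane, so its mobility is half
        that of a free binder: ``D2 = 2 D1`` by default.
    koff_bar : unstressed off-rate [1/s].
    Kbar : non-dimensional 2D equilibrium constant K̄ = c0·k̄on/k̄off.
        The on-rate is always derived from it, never set independently.
    c0 : reference concentration [molecules/μm² × l_lat].
    cmax : crowding saturation concentration, same units; ``inf``
        selects the dilute model.
    R0, s_hat0, L0 : initial vesicle radius, initial patch half-size,
        half-vesicle membrane length [μm].
    F_over_gamma : applied peeling force as the ratio F/γ.
    l_lat : ribbon depth [μm] mapping 2D densities to line densities.
    alpha : micro-mechanical domain factor (> 1); the separation profile
        is solved on [0, α·ŝ].
    compliant / crowding / reactions_on : mode switches.
    """

    kBT: float = 4.11e-21
    kappa: float = 1e-19
    gamma: float | None = None
    k: float = 2.5e-4
    f_beta: float = math.inf
    D1: float = 0.25
    D2: float | None = None
    koff_bar: float = 10.0
    Kbar: float = 2.0
    c0: float = 2.5e3
    cmax: float = math.inf
    R0: float = 10.0
    s_hat0: float = 2.5
    L0: float = 35.0
    F_over_gamma: float = 0.0
    l_lat: float = 1.0
    alpha: float = 1.3
    compliant: bool = False
    crowding: bool = False
    reactions_on: bool = True
    #: carry a single-site vacancy term in μ2 (crowding mode).  With it,
    #: the vacancy contributions cancel in the reaction affinity μ1−2μ2
    #: and crowding no longer promotes unbinding; the default (False)
    #: keeps μ2 ideal and puts the matching v⁻² Boltzmann factor on the
    #: off-rate, so a crowded patch unbinds faster — the weakening
    #: mechanism the crowded model exists to capture.
    mu2_vacancy: bool = False

    def __post_init__(self) -> None:
        if self.D2 is None:
            self.D2 = 2.0 * self.D1
        self.validate()

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        positive = ["kBT", "kappa", "k", "f_beta", "D1", "D2", "koff_bar",
                    "c0", "cmax", "R0", "s_hat0", "L0", "l_lat"]
        if not self.reactions_on:
            positive.remove("koff_bar")
            if self.koff_bar < 0:
                raise ParameterError("koff_bar must be >= 0")
        for name in positive:
            v = getattr(self, name)
            if not v > 0:
                raise ParameterError(f"{name} must be strictly positive, got {v!r}")
        if self.gamma is not None and not self.gamma > 0:
            raise ParameterError(f"gamma must be strictly positive, got {self.gamma!r}")
        if self.Kbar < 0:
            raise ParameterError(f"Kbar must be >= 0, got {self.Kbar!r}")
        if not self.alpha > 1:
            raise ParameterError(f"alpha must be > 1, got {self.alpha!r}")
        if not self.s_hat0 < self.R0:
            raise ParameterError("s_hat0 must be < R0 (sin(theta0) = s_hat0/R0)")
        if not self.s_hat0 < self.L0:
            raise ParameterError("s_hat0 must be < L0")
        if self.F_over_gamma < 0:
            raise ParameterError("F_over_gamma must be >= 0")
        if self.crowding and not math.isfinite(self.cmax):
            raise ParameterError("crowding mode requires a finite cmax")
        if self.gamma is not None:
            l1 = math.sqrt(self.kappa * self.l_lat * units.J_TO_PNUM
                           / (self.gamma * self.l_lat * units.NPM_TO_PNPUM))
            if (self.alpha - 1.0) * self.s_hat0 <= l1:
                raise ParameterError(
                    "alpha too small: (alpha-1)*s_hat0 must exceed l1 = sqrt(kappa/gamma)")

    # -- internal (μm, s, pN) values ----------------------------------

    @property
    def kBT_i(self) -> float:
        """Thermal energy [pN·μm]."""
        return self.kBT * units.J_TO_PNUM

    @property
    def kappa_i(self) -> float:
        """Bending stiffness of the ribbon [pN·μm²]."""
        return self.kappa * self.l_lat * units.J_TO_PNUM

    @property
    def gamma_i(self) -> float | None:
        """Membrane tension of the ribbon [pN], None if underived."""
        if self.gamma is None:
            return None
        return self.gamma * self.l_lat * units.NPM_TO_PNPUM

    @property
    def k_i(self) -> float:
        """Bond stiffness [pN/μm]."""
        return self.k * units.NPM_TO_PNPUM

    @property
    def f_beta_i(self) -> float:
        """Force sensitivity [pN]."""
        return self.f_beta * units.N_TO_PN

    @property
    def c0_i(self) -> float:
        """Reference line density [molecules/μm]."""
        return self.c0 * self.l_lat

    @property
    def cmax_i(self) -> float:
        return self.cmax * self.l_lat

    @property
    def F_i(self) -> float:
        """Applied force [pN]; requires gamma to be set."""
        if self.gamma is None:
            raise ParameterError("gamma is not set; prepare the equilibrium first")
        return self.F_over_gamma * self.gamma_i

    @property
    def x_gamma_i(self) -> float:
        """Thermal fluctuation scale of a bond, sqrt(kBT/k) [μm]."""
        return math.sqrt(self.kBT_i / self.k_i)

    @property
    def x_beta_i(self) -> float:
        """Separation sensitivity f_beta/k [μm] (inf for ideal bonds)."""
        return self.f_beta_i / self.k_i

    @property
    def kon_bar_i(self) -> float:
        """Unstressed on-rate K̄·k̄off/c0 [μm / (molecule·s)]."""
        return self.Kbar * self.koff_bar / self.c0_i

    def with_gamma_i(self, gamma_i: float) -> "ParameterSet":
        """Copy with tension set from an internal-unit value [pN]."""
        return replace(self, gamma=gamma_i / (self.l_lat * units.NPM_TO_PNPUM))


@dataclass(frozen=True)
class DerivedScales:
    """Closed-form molecular scales and non-dimensional groups (SI).

    Every field is a definition, not a fit: l1 = sqrt(κ/γ),
    l2 = [4κ/(k·c1)]^(1/4), l3 = sqrt(D1/k̄off), v0 = sqrt(D1·k̄off),
    fγ = sqrt(k·kBT), xγ = sqrt(kBT/k), xβ = fβ/k, τdiff,i and
    τreac = 1/k̄off, k̄on = K̄·k̄off/c0, Damköhler numbers
    Da_i = τdiff,i/τreac, and the interface bond concentration
    C0 = 2γ(1−cosθ0)/kBT.
    """

    l1: float        # capillary/bending length [m]
    l2: float        # elastic-foundation boundary layer [m]
    l3: float        # reaction-diffusion process zone [m]
    v0: float        # front speed scale [m/s]
    f_gamma: float   # entropic force scale [N]
    x_gamma: float   # thermal fluctuation scale [m]
    x_beta: float    # separation sensitivity [m]
    tau_diff1: float  # s_hat0^2/D1 [s]
    tau_diff2: float  # L0^2/D2 [s]
    tau_reac: float  # 1/koff [s]
    kon_bar: float   # Kbar*koff/c0 [μm^2/(molecule·s) / l_lat]
    Da1: float
    Da2: float
    C0: float        # 2γ(1−cosθ0)/kBT [molecules/μm^2 × l_lat]
    C0_over_c0: float


def derive_scales(params: ParameterSet, c1ref: float | None = None) -> DerivedScales:
    """Populate :class:`DerivedScales` from closed forms.

    Parameters
    ----------
    c1ref : reference bond concentration [molecules/μm² × l_lat] used in
        l2 and, when ``params.gamma`` is unset, in the Young–Dupré
        tension estimate γ = kBT·c1ref/[2(1−cosθ0)].
    """
    if c1ref is None:
        from .equilibrium import equilibrium_concentrations
        c1ref = equilibrium_concentrations(params)[0] * params.c0
    if not c1ref > 0:
        raise ParameterError(f"c1ref must be strictly positive, got {c1ref!r}")

    kBT, kappa, k = params.kBT_i, params.kappa_i, params.k_i
    c1ref_i = c1ref * params.l_lat
    theta0 = math.asin(params.s_hat0 / params.R0)
    if params.gamma is not None:
        gamma_i = params.gamma_i
    else:
        gamma_i = kBT * c1ref_i / (2.0 * (1.0 - math.cos(theta0)))

    koff = params.koff_bar
    l1 = math.sqrt(kappa / gamma_i) / units.M_TO_UM
    l2 = (4.0 * kappa / (k * c1ref_i)) ** 0.25 / units.M_TO_UM
    l3 = math.sqrt(params.D1 / koff) / units.M_TO_UM if koff > 0 else math.inf
    v0 = math.sqrt(params.D1 * koff) / units.M_TO_UM
    tau_diff1 = params.s_hat0 ** 2 / params.D1
    tau_diff2 = params.L0 ** 2 / params.D2
    tau_reac = 1.0 / koff if koff > 0 else math.inf
    C0_i = 2.0 * gamma_i * (1.0 - math.cos(theta0)) / kBT
    return DerivedScales(
        l1=l1,
        l2=l2,
        l3=l3,
        v0=v0,
        f_gamma=math.sqrt(k * kBT) / units.N_TO_PN,
        x_gamma=params.x_gamma_i / units.M_TO_UM,
        x_beta=params.x_beta_i / units.M_TO_UM,
        tau_diff1=tau_diff1,
        tau_diff2=tau_diff2,
        tau_reac=tau_reac,
        kon_bar=params.kon_bar_i,
        Da1=tau_diff1 / tau_reac if koff > 0 else 0.0,
        Da2=tau_diff2 / tau_reac if koff > 0 else 0.0,
        C0=C0_i / params.l_lat,
        C0_over_c0=C0_i / params.c0_i,
    )


def derive_rate_coefficients(params: ParameterSet) -> tuple[float, float, float]:
    """Return (k̄on, xγ, xβ): the on-rate K̄·k̄off/c0 [μm²/(molec·s) per
    l_lat] and the separation scales sqrt(kBT/k) and fβ/k [m]."""
    kon_bar = params.Kbar * params.koff_bar / params.c0
    return (kon_bar,
            params.x_gamma_i / units.M_TO_UM,
            params.x_beta_i / units.M_TO_UM)


# -- configuration files ---------------------------------------------

class ConfigError(ValueError):
    """Malformed configuration file (unknown key, bad table, bad type)."""


_PARAM_KEYS = {f.name for f in fields(ParameterSet)}
_SOLVER_KEYS = {
    "d_min", "d_max", "d_min_outer", "grid_ratio", "dt_init", "dt_max",
    "rtol", "cfl", "reaction_dt_factor", "constant_theta_deg", "s_min",
    "snapshot_every", "check_every", "max_rejections", "store_profiles",
    "relax_tol", "relax_max_time", "steady_v_tol",
}
_EXPERIMENT_KEYS = {
    "regime", "forces", "t_end", "seed", "cache_dir", "cmax_list",
    "theta_deg_list", "f_beta_over_f_gamma_list",
}
_SCHEMA = {"parameters": _PARAM_KEYS, "solver": _SOLVER_KEYS,
           "experiments": _EXPERIMENT_KEYS}


def load_config(path: str) -> dict:
    """Load a TOML or YAML config with one table per module.

    Returns ``{"parameters": ParameterSet, "solver": dict,
    "experiments": dict}``.  Unknown tables or keys are hard errors.
    """
    text = open(path, "rb").read()
    if str(path).endswith((".yaml", ".yml")):
        import yaml
        raw = yaml.safe_load(text)
    else:
        import tomllib
        raw = tomllib.loads(text.decode())
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a table, got {type(raw).__name__}")
    for table, content in raw.items():
        if table not in _SCHEMA:
            raise ConfigError(f"unknown config table {table!r}")
        if not isinstance(content, dict):
            raise ConfigError(f"config table {table!r} must be a mapping")
        unknown = set(content) - _SCHEMA[table]
        if unknown:
            raise ConfigError(
                f"unknown key(s) in [{table}]: {', '.join(sorted(unknown))}")
    pdict = dict(raw.get("parameters", {}))
    for key in ("gamma", "f_beta", "cmax"):
        if isinstance(pdict.get(key), str):
            if pdict[key] in ("inf", "Infinity", ".inf"):
                pdict[key] = math.inf
            else:
                raise ConfigError(f"cannot parse [parameters].{key} = {pdict[key]!r}")
    try:
        params = ParameterSet(**pdict)
    except TypeError as exc:  # pragma: no cover - guarded by schema
        raise ConfigError(str(exc)) from exc
    return {"parameters": params,
            "solver": dict(raw.get("solver", {})),
            "experiments": dict(raw.get("experiments", {}))}
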