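"""Species and energetics parameter containers.

``SpeciesParams`` collects every scalar constant of the leatherback
calibration: the von Bertalanffy growth curve, the mass-length power law,
the metabolic-scaling speed law, the thermal-gradient budget and the food
consumption scaling.  Defaults are the published leatherback values; every
field can be overridden from the run configuration to describe another
sea-turtle species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


class ConfigError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass(frozen=True)
class SpeciesParams:
    """Allometric, thermal and feeding constants for one species.

    Attributes
    ----------
    L_inf : float
        Asymptotic straight carapace length (m).
    growth_rate : float
        von Bertalanffy growth coefficient (1/yr).
    age_shift : float
        Age offset of the growth curve (yr).
    mass_coeff, mass_exp : float
        Mass-length power law ``M = mass_coeff * L**mass_exp`` (kg, m).
    rmr_mass_exp : float
        Exponent b of the resting metabolic rate scaling ``RMR ~ M**b``.
    v0 : float
        Speed scale of the maximum sustainable speed law (m/s).
    alpha : float
        Habitat-gradient-to-concentration scale (m): kappa = alpha*|grad h|.
    body_temp_min : float
        Minimum suitable body temperature (degC).
    d0 : float
        Resting thermal-gradient coefficient (degC * kg^-0.5).
    activity_ratio_max : float
        Maximum sustainable MR/RMR ratio (dimensionless).
    f0 : float
        Normalizer of the food-consumption rate; with the default value
        the normalized rate tends to 1 at large age.
    food_age_rate : float
        Age rate constant of the food-consumption curve (1/yr).
    food_shape_exp, food_rate_exp : float
        Fixed shape constants of the food-consumption curve (the
        age-infinity limit of the normalized rate is ``f0/food_rate_exp``).
    P0 : float
        NPP threshold above which the adult feeding habitat saturates
        (mmol C m^-2 day^-1).
    T3, T4 : float or None
        Optional upper pivotal temperatures (degC); unset for leatherbacks,
        which never meet unsuitably warm water.
    """

    L_inf: float = 1.43
    growth_rate: float = 0.226
    age_shift: float = 0.17
    mass_coeff: float = 112.31
    mass_exp: float = 2.86
    rmr_mass_exp: float = 0.831
    v0: float = 1.2
    alpha: float = 3.0e6
    body_temp_min: float = 24.0
    d0: float = 0.21
    activity_ratio_max: float = 5.0
    f0: float = 0.094
    food_age_rate: float = 0.299
    food_shape_exp: float = 1.86
    food_rate_exp: float = 0.094
    P0: float = 55.0
    T3: float | None = None
    T4: float | None = None

    def __post_init__(self) -> None:
        if self.L_inf <= 0:
            raise ConfigError("L_inf must be positive")
        if self.rmr_mass_exp * self.mass_exp <= 0:
            raise ConfigError("rmr_mass_exp * mass_exp must be positive")
        if not 0 < self.f0 <= 1:
            raise ConfigError("f0 must lie in (0, 1]")
        if self.alpha <= 0:
            raise ConfigError("alpha must be positive")
        if (self.T3 is None) != (self.T4 is None):
            raise ConfigError("T3 and T4 must be set together")
        if self.T3 is not None and self.T4 is not None and not self.T3 < self.T4:
            raise ConfigError("T3 < T4 required")

    def replace(self, **kwargs) -> "SpeciesParams":
        d = asdict(self)
        d.update(kwargs)
        return SpeciesParams(**d)


@dataclass(frozen=True)
class EnergeticsParams:
    """Raw energetics constants of the work-per-meter model.

    These constants cancel into ``v0`` in the operational speed law; they
    exist to verify the cost-of-transport minimization structurally.

    Attributes
    ----------
    rmr : float
        Resting metabolic rate (W).
    rho : float
        Sea-water density (kg/m^3).
    cd : float
        Drag coefficient (dimensionless).
    s : float
        Body reference surface (m^2).
    eta : float
        Overall propulsion efficiency in (0, 1].
    """

    rmr: float
    rho: float = 1025.0
    cd: float = 0.05
    s: float = 1.0
    eta: float = 0.25

    def __post_init__(self) -> None:
        for name in ("rmr", "rho", "cd", "s", "eta"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.eta > 1:
            raise ConfigError("eta must not exceed 1")
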