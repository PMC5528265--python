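"""Age- and size-dependent scalar relations.

Growth, mass, the metabolic-scaling maximum sustainable speed, the
work-per-meter (cost of transport) minimization, the lower pivotal water
temperatures and the age-dependent food consumption.  All functions accept
scalars or numpy arrays for the age/length argument.
"""

from __future__ import annotations

import numpy as np

from .params import EnergeticsParams, SpeciesParams

__all__ = [
    "length_at_age",
    "mass_at_length",
    "mass_at_age",
    "vm_exponent",
    "max_sustainable_speed",
    "speed_at_age",
    "wpm",
    "wpm_optimal_speed",
    "pivotal_temperatures",
    "food_consumption_norm",
    "food_threshold",
]

DAYS_PER_YEAR = 365.25


def _check_nonnegative_age(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be non-negative")
    return a


def length_at_age(a, params: SpeciesParams = SpeciesParams()):
    """von Bertalanffy straight carapace length (m) at age ``a`` (years).

    Strictly increasing and bounded above by ``params.L_inf``.
    """
    a = _check_nonnegative_age(a)
    L = params.L_inf * (1.0 - np.exp(-params.growth_rate * (a + params.age_shift)))
    return L if L.ndim else float(L)


def mass_at_length(L, params: SpeciesParams = SpeciesParams()):
    """Power-law body mass (kg) at straight carapace length ``L`` (m)."""
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("length must be strictly positive")
    M = params.mass_coeff * L**params.mass_exp
    return M if M.ndim else float(M)


def mass_at_age(a, params: SpeciesParams = SpeciesParams()):
    """Body mass (kg) at age ``a`` (years): growth and mass laws composed."""
    return mass_at_length(length_at_age(a, params), params)


def vm_exponent(b: float, c: float) -> float:
    """Exponent of the size dependence of the maximum sustainable speed.

    With RMR ~ M**b, M ~ L**c and wetted surface ~ L**2, minimizing the
    work per meter gives a speed proportional to L**((b*c - 2)/3).
    """
    return (b * c - 2.0) / 3.0


def max_sustainable_speed(L, params: SpeciesParams = SpeciesParams()):
    """Maximum sustainable speed (m/s) at length ``L`` (m): v0 * L**((bc-2)/3)."""
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("length must be strictly positive")
    V = params.v0 * L ** vm_exponent(params.rmr_mass_exp, params.mass_exp)
    return V if V.ndim else float(V)


def speed_at_age(a, params: SpeciesParams = SpeciesParams()):
    """Maximum sustainable speed (m/s) at age ``a`` (years)."""
    return max_sustainable_speed(length_at_age(a, params), params)


def wpm(vs, e: EnergeticsParams):
    """Work per meter (J/m) at swimming speed ``vs`` (m/s).

    The sum of the resting cost spread over the distance covered and the
    hydrodynamic drag work: RMR/vs + rho*cd*s*vs**2/(2*eta).
    """
    vs = np.asarray(vs, dtype=float)
    w = e.rmr / vs + e.rho * e.cd * e.s * vs**2 / (2.0 * e.eta)
    return w if w.ndim else float(w)


def wpm_optimal_speed(e: EnergeticsParams) -> float:
    """Speed (m/s) minimizing the work per meter: (eta*RMR/(rho*cd*s))**(1/3)."""
    return float((e.eta * e.rmr / (e.rho * e.cd * e.s)) ** (1.0 / 3.0))


def pivotal_temperatures(a, params: SpeciesParams = SpeciesParams()):
    """Lower pivotal water temperatures (T1, T2) in degC at age ``a`` (years).

    A turtle of mass M maintains a body-water temperature gradient
    d0*(MR/RMR)*sqrt(M).  T2 is the water temperature at which a *resting*
    individual holds the minimum suitable body temperature; T1 the colder
    temperature at which a maximally active one (MR/RMR at its ceiling)
    still does.  T1 < T2 < body_temp_min for any positive mass, and both
    decrease with age as mass grows.
    """
    sqrt_m = np.sqrt(mass_at_age(a, params))
    t2 = params.body_temp_min - params.d0 * sqrt_m
    t1 = params.body_temp_min - params.d0 * params.activity_ratio_max * sqrt_m
    return t1, t2


def food_consumption_norm(a, params: SpeciesParams = SpeciesParams()):
    """Normalized food-consumption rate F0(a), dimensionless in (0, 1].

    F0(a) = f0 * x * (1-x)**1.86 / (1 - (1-x)**0.094) with
    x = exp(-food_age_rate*(a + age_shift)).  Monotone increasing in age;
    the large-age limit is f0/0.094, i.e. exactly 1 for the default f0.
    Evaluated with expm1/log1p so the x -> 0 limit is numerically exact.
    """
    a = _check_nonnegative_age(a)
    x = np.exp(-params.food_age_rate * (a + params.age_shift))
    log1mx = np.log1p(-x)
    num = params.f0 * x * np.exp(params.food_shape_exp * log1mx)
    den = -np.expm1(params.food_rate_exp * log1mx)  # 1 - (1-x)**0.094
    with np.errstate(invalid="ignore"):
        f = np.where(den > 0, num / np.where(den > 0, den, 1.0),
                     params.f0 / params.food_rate_exp)
    return f if f.ndim else float(f)


def food_threshold(a, params: SpeciesParams = SpeciesParams()):
    """Age-dependent food requirement F(a) = P0 * F0(a) (mmol C m^-2 day^-1)."""
    f = params.P0 * np.asarray(food_consumption_norm(a, params))
    return f if f.ndim else float(f)
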