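"""Closed-form kinetic model family for region-of-interest (ROI) time courses.

A single well-mixed compartment exchanges nanoparticles with its arterial
supply through two opposing first-order processes,

    dC/dt = k_in * C_b(t) - k_out * C,        C(0) = 0,

where the arterial concentration itself decays first-order,
``C_b(t) = C_0 * exp(-k_in * t)``.  The solution is a double exponential

    C(t) = A * (exp(-k_out t) - exp(-k_in t)),   A = k_in C_0 / (k_in - k_out),

with two empirically important limits: ``k_out -> 0`` gives a saturating
uptake curve (sink-like organs that never show elimination within the study
window) and ``k_in >> k_out`` gives a mono-exponential washout (source-like
organs coupled to blood).  Cumulative excreted activity follows the same
saturating form, ``U(t) = U_t * (1 - exp(-k_u t))``.

All times are in hours, rates in 1/h, concentrations in %ID/g (percentage of
injected dose per gram) and activities in %ID.  The module is a pure
computational kernel: no I/O, everything vectorised over ``t``.

Numerical oracles (adaptive ODE integration, quadrature) used to verify the
closed forms live here too so that tests exercise two independent routes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate

__all__ = [
    "ModelVariant",
    "KineticParams",
    "ArterialInput",
    "DomainError",
    "DegenerateParameterizationError",
    "ContractError",
    "IntegrationError",
    "RATE_GAP_TOL",
    "eval_mono_decay",
    "eval_double_exp",
    "eval_uptake_only",
    "eval_excretion",
    "eval_variant",
    "arterial_forcing",
    "ip_initial_concentration",
    "integrate_compartment_ode",
    "auc_closed_form",
    "auc_quadrature",
    "half_life",
    "time_of_peak",
    "macro_constant",
    "initial_concentration_from_macro",
]

#: Minimum separation between k_in and k_out (1/h) before the double
#: exponential is declared degenerate.  At equal rates the macro-constant A
#: is undefined (the curve family collapses to A*k*t*exp(-k*t)).
RATE_GAP_TOL = 1e-8


class DomainError(ValueError):
    """A parameter is outside the physical domain of the model."""


class DegenerateParameterizationError(DomainError):
    """k_in and k_out too close: the double-exponential curve is ill-defined."""


class ContractError(ValueError):
    """Arguments violate an interface contract (wrong variant/params pairing etc.)."""


class IntegrationError(RuntimeError):
    """The numerical ODE oracle failed to meet its tolerance."""


class ModelVariant(str, enum.Enum):
    """Which member of the kinetic model family describes a series."""

    DOUBLE_EXP = "double_exp"    # uptake then elimination: A(e^-k_out t - e^-k_in t)
    UPTAKE_ONLY = "uptake_only"  # k_out ~ 0 limit: A(1 - e^-k_in t)
    MONO_DECAY = "mono_decay"    # k_in >> k_out limit: A e^-k_out t
    EXCRETION = "excretion"      # cumulative excreted activity: U_t(1 - e^-k_u t)

    @property
    def param_names(self) -> tuple[str, ...]:
        return _VARIANT_PARAMS[self]

    @property
    def n_params(self) -> int:
        return len(_VARIANT_PARAMS[self])


_VARIANT_PARAMS: dict[ModelVariant, tuple[str, ...]] = {
    ModelVariant.DOUBLE_EXP: ("A", "k_in", "k_out"),
    ModelVariant.UPTAKE_ONLY: ("A", "k_in"),
    ModelVariant.MONO_DECAY: ("A", "k_out"),
    ModelVariant.EXCRETION: ("U_t", "k_u"),
}


@dataclass
class KineticParams:
    """Parameter bundle for one model variant.

    Only the fields required by the variant are set; the rest stay ``None``.

    A : concentration-scale macro-constant (%ID/g, or %ID for activity data).
        For the double exponential it is the intercept of the
        back-extrapolated elimination phase, ``A = k_in C_0 / (k_in - k_out)``.
    k_in : first-order uptake/supply rate (1/h).
    k_out : first-order elimination rate (1/h).
    U_t : total excreted fraction at infinite time (%ID), in (0, 100].
    k_u : first-order excretion rate (1/h).
    """

    A: Optional[float] = None
    k_in: Optional[float] = None
    k_out: Optional[float] = None
    U_t: Optional[float] = None
    k_u: Optional[float] = None

    def get(self, name: str) -> float:
        value = getattr(self, name)
        if value is None:
            raise ContractError(f"parameter {name!r} is not set")
        return float(value)

    def as_dict(self, variant: ModelVariant) -> dict[str, float]:
        return {name: self.get(name) for name in variant.param_names}

    def validate(self, variant: ModelVariant) -> "KineticParams":
        """Check positivity/ordering constraints for ``variant``; return self."""
        for name in variant.param_names:
            value = self.get(name)
            if not math.isfinite(value) or value <= 0:
                raise DomainError(f"{name} must be finite and > 0, got {value}")
        if variant is ModelVariant.EXCRETION and self.get("U_t") > 100.0:
            raise DomainError(
                f"U_t = {self.U_t} %ID exceeds the injected dose (100 %ID)"
            )
        if variant is ModelVariant.DOUBLE_EXP:
            _check_rate_gap(self.get("k_in"), self.get("k_out"))
        return self


def _check_rate_gap(k_in: float, k_out: float) -> None:
    if k_in - k_out < RATE_GAP_TOL:
        raise DegenerateParameterizationError(
            f"double-exponential requires k_in > k_out "
            f"(separated by >= {RATE_GAP_TOL} 1/h); got k_in={k_in}, k_out={k_out}. "
            "The curve family is sign-ambiguous under label swap, and the "
            "macro-constant A is undefined at k_in = k_out."
        )


@dataclass
class ArterialInput:
    """First-order arterial forcing ``C_b(t) = C_0 exp(-k_in t)``.

    For intraperitoneal dosing the bolus assumption fails; the effective
    initial concentration is taken as the time-average of the absorption
    profile, ``C_avg = C_b_max / 2`` (zeroth-order Taylor approximation of a
    constant-rate absorption ramp).
    """

    C_0: float
    k_in: float
    C_b_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.C_0 <= 0 or self.k_in <= 0:
            raise DomainError(
                f"C_0 and k_in must be > 0; got C_0={self.C_0}, k_in={self.k_in}"
            )

    @property
    def C_avg(self) -> Optional[float]:
        """Average absorbed concentration for i.p. construction (C_b_max / 2)."""
        if self.C_b_max is None:
            return None
        return self.C_b_max / 2.0

    @classmethod
    def from_ip(cls, C_b_max: float, k_in: float) -> "ArterialInput":
        """Build i.p. forcing with ``C_0 = C_avg = C_b_max / 2``."""
        return cls(C_0=ip_initial_concentration(C_b_max), k_in=k_in,
                   C_b_max=C_b_max)


# ---------------------------------------------------------------------------
# closed-form curves
# ---------------------------------------------------------------------------

def _check_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be >= 0 h")
    return t


def eval_mono_decay(A: float, k_out: float, t) -> np.ndarray | float:
    """Mono-exponential washout ``A * exp(-k_out t)`` (source-like ROIs, i.v.)."""
    if A <= 0 or k_out <= 0:
        raise DomainError(f"A and k_out must be > 0; got A={A}, k_out={k_out}")
    t = _check_times(t)
    return A * np.exp(-k_out * t)


def eval_double_exp(A: float, k_in: float, k_out: float, t) -> np.ndarray | float:
    """Uptake-then-elimination curve ``A * (exp(-k_out t) - exp(-k_in t))``.

    Requires the labelling convention ``k_in > k_out`` (the late phase is
    elimination); rates closer than :data:`RATE_GAP_TOL` are rejected.
    """
    if A <= 0 or k_in <= 0 or k_out <= 0:
        raise DomainError(
            f"A, k_in, k_out must be > 0; got A={A}, k_in={k_in}, k_out={k_out}"
        )
    _check_rate_gap(k_in, k_out)
    t = _check_times(t)
    return A * (np.exp(-k_out * t) - np.exp(-k_in * t))


def eval_uptake_only(A: float, k_in: float, t) -> np.ndarray | float:
    """Saturating uptake ``A * (1 - exp(-k_in t))`` (sink-like ROIs, no washout)."""
    if A <= 0 or k_in <= 0:
        raise DomainError(f"A and k_in must be > 0; got A={A}, k_in={k_in}")
    t = _check_times(t)
    return A * (1.0 - np.exp(-k_in * t))


def eval_excretion(U_t: float, k_u: float, t) -> np.ndarray | float:
    """Cumulative excreted activity ``U_t * (1 - exp(-k_u t))`` in %ID."""
    if U_t <= 0 or k_u <= 0:
        raise DomainError(f"U_t and k_u must be > 0; got U_t={U_t}, k_u={k_u}")
    if U_t > 100.0:
        raise DomainError(f"U_t = {U_t} %ID exceeds the injected dose (100 %ID)")
    t = _check_times(t)
    return U_t * (1.0 - np.exp(-k_u * t))


def eval_variant(variant: ModelVariant, params: KineticParams, t):
    """Dispatch to the closed form for ``variant``."""
    if variant is ModelVariant.MONO_DECAY:
        return eval_mono_decay(params.get("A"), params.get("k_out"), t)
    if variant is ModelVariant.DOUBLE_EXP:
        return eval_double_exp(params.get("A"), params.get("k_in"),
                               params.get("k_out"), t)
    if variant is ModelVariant.UPTAKE_ONLY:
        return eval_uptake_only(params.get("A"), params.get("k_in"), t)
    if variant is ModelVariant.EXCRETION:
        return eval_excretion(params.get("U_t"), params.get("k_u"), t)
    raise ContractError(f"unknown variant {variant!r}")


def arterial_forcing(inp: ArterialInput, t) -> np.ndarray | float:
    """Arterial supply concentration ``C_0 * exp(-k_in t)``."""
    return eval_mono_decay(inp.C_0, inp.k_in, t)


def ip_initial_concentration(C_b_max: float) -> float:
    """Effective initial concentration after i.p. absorption: ``C_b_max / 2``.

    Constant-rate absorption reaches ``C_b_max`` linearly, so its time
    average over the absorption window is half the peak.
    """
    if C_b_max < 0:
        raise DomainError(f"C_b_max must be >= 0, got {C_b_max}")
    return C_b_max / 2.0


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def macro_constant(C_0: float, k_in: float, k_out: float) -> float:
    """Macro-constant ``A = k_in C_0 / (k_in - k_out)`` of the double exponential."""
    if C_0 <= 0 or k_in <= 0 or k_out <= 0:
        raise DomainError("C_0, k_in, k_out must all be > 0")
    _check_rate_gap(k_in, k_out)
    return k_in * C_0 / (k_in - k_out)


def initial_concentration_from_macro(A: float, k_in: float, k_out: float) -> float:
    """Invert the macro-constant: ``C_0 = A (k_in - k_out) / k_in``."""
    if A <= 0 or k_in <= 0 or k_out <= 0:
        raise DomainError("A, k_in, k_out must all be > 0")
    _check_rate_gap(k_in, k_out)
    return A * (k_in - k_out) / k_in


def half_life(k_out: float) -> float:
    """Elimination half-life ``ln(2) / k_out`` in hours."""
    if k_out <= 0:
        raise DomainError(f"k_out must be > 0, got {k_out}")
    return math.log(2.0) / k_out


def time_of_peak(k_in: float, k_out: float) -> float:
    """Time of the double-exponential maximum, ``ln(k_in/k_out)/(k_in-k_out)``."""
    if k_out <= 0 or k_in <= 0:
        raise DomainError("rates must be > 0")
    _check_rate_gap(k_in, k_out)
    return math.log(k_in / k_out) / (k_in - k_out)


def auc_closed_form(variant: ModelVariant, params: KineticParams,
                    T: float = 24.0, t0: float = 0.0) -> float:
    """Analytic area under the curve on ``[t0, T]`` (default 0-24 h).

    The antiderivatives are elementary; e.g. for the double exponential
    ``AUC = A [ (e^{-k_out t0} - e^{-k_out T})/k_out - (e^{-k_in t0} - e^{-k_in T})/k_in ]``.
    """
    if T <= t0 or t0 < 0:
        raise DomainError(f"need 0 <= t0 < T, got t0={t0}, T={T}")
    params.validate(variant)

    def _decay_area(k: float) -> float:
        return (math.exp(-k * t0) - math.exp(-k * T)) / k

    if variant is ModelVariant.MONO_DECAY:
        return params.get("A") * _decay_area(params.get("k_out"))
    if variant is ModelVariant.DOUBLE_EXP:
        return params.get("A") * (
            _decay_area(params.get("k_out")) - _decay_area(params.get("k_in"))
        )
    if variant is ModelVariant.UPTAKE_ONLY:
        k = params.get("k_in")
        return params.get("A") * ((T - t0) - _decay_area(k))
    if variant is ModelVariant.EXCRETION:
        k = params.get("k_u")
        return params.get("U_t") * ((T - t0) - _decay_area(k))
    raise ContractError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# independent numerical oracles
# ---------------------------------------------------------------------------

def integrate_compartment_ode(inp: ArterialInput, k_out: float, t_grid,
                              rtol: float = 1e-10, atol: float = 1e-13) -> np.ndarray:
    """Numerically integrate ``dC/dt = k_in C_b(t) - k_out C`` on ``t_grid``.

    Serves as the independent verification oracle for the closed forms
    (``k_out = 0`` reproduces the uptake-only limit exactly).  ``k_out`` may
    be zero here, unlike in the closed forms, because the ODE itself is
    regular there.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0) or np.any(t_grid < 0):
        raise DomainError("t_grid must be sorted, strictly increasing, >= 0")
    if k_out < 0:
        raise DomainError(f"k_out must be >= 0, got {k_out}")

    def rhs(t, y):
        return [inp.k_in * inp.C_0 * math.exp(-inp.k_in * t) - k_out * y[0]]

    t0 = 0.0
    t_end = float(t_grid[-1]) if t_grid[-1] > 0 else 1e-12
    sol = integrate.solve_ivp(rhs, (t0, t_end), [0.0], t_eval=t_grid,
                              rtol=rtol, atol=atol, method="DOP853")
    if not sol.success:
        raise IntegrationError(f"ODE oracle failed: {sol.message}")
    return sol.y[0]


def auc_quadrature(variant: ModelVariant, params: KineticParams,
                   T: float = 24.0, t0: float = 0.0) -> float:
    """Adaptive-quadrature AUC oracle for cross-checking :func:`auc_closed_form`."""
    params.validate(variant)
    value, _ = integrate.quad(lambda t: float(eval_variant(variant, params, t)),
                              t0, T, epsabs=1e-12, epsrel=1e-12, limit=200)
    return value
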