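"""Closed-form period, amplitude, sensitivities and MPS in the saturating
limit.

When the loop is long enough that every species saturates — peak at
``beta_i/alpha_i``, trough at zero — the cycle-closure constants are known
a priori and everything becomes explicit in the threshold ratios
``rho_i = K_i alpha_i / beta_i``:

    period      tau      = -sum_i ln[rho_i (1 - rho_i)] / alpha_i
    amplitude   eps_i    = beta_i / alpha_i
    period MPS  Phi_tau  = sum_i [(L_i - g_i)^2 + 2 g_i^2] / alpha_i^2
                           / (sum_i L_i / alpha_i)^2
    amplitude MPS        = 2          (for every species, any parameters)

with ``L_i = ln[rho_i (1 - rho_i)]`` and ``g_i = (1 - 2 rho_i)/(1 - rho_i)``.
With equal decay rates and a common rho the period MPS reduces to
``f(rho)/n``, whose minimum sets the most robust threshold ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .model import OscillatorParams
from .sensitivity import SensitivityTable

__all__ = [
    "ClosedFormResult",
    "RhoMinima",
    "period_full",
    "amplitude_full",
    "f_rho",
    "period_mps_full",
    "amplitude_mps_full",
    "period_sensitivities_analytic",
    "amplitude_sensitivities_analytic",
    "evaluate",
    "find_rho_minima",
]

_RHO_CUTOFF = 1.0 - 1e-12  # guard against log overflow as rho -> 1


def _check_rho(rho: np.ndarray | float) -> np.ndarray:
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    if np.any(rho <= 0.0) or np.any(rho > _RHO_CUTOFF):
        raise ValueError(
            "threshold ratio rho must lie in (0, 1): got "
            + np.array2string(rho, precision=6)
        )
    return rho


def _L(rho: np.ndarray) -> np.ndarray:
    return np.log(rho * (1.0 - rho))


def _g(rho: np.ndarray) -> np.ndarray:
    return (1.0 - 2.0 * rho) / (1.0 - rho)


def period_full(params: OscillatorParams) -> float:
    """Saturating-limit period ``-sum ln[rho_i(1-rho_i)]/alpha_i``."""
    rho = _check_rho(params.rho())
    return float(-np.sum(_L(rho) / params.alpha))


def amplitude_full(params: OscillatorParams) -> np.ndarray:
    """Saturating-limit amplitudes ``beta_i/alpha_i`` (threshold-free)."""
    return params.ceiling


def f_rho(rho: float) -> float:
    """Per-species shape factor of the period MPS at a common threshold ratio.

    ``f(rho) = [(L - g)^2 + 2 g^2] / L^2``; the period MPS of a uniform loop
    is ``f(rho)/n``.  Diverges as ``rho -> 1``.
    """
    r = float(_check_rho(rho)[0])
    L = float(_L(np.array([r]))[0])
    g = float(_g(np.array([r]))[0])
    return ((L - g) ** 2 + 2.0 * g * g) / (L * L)


def period_mps_full(params: OscillatorParams) -> float:
    """Closed-form period MPS: squared-sum of the analytic sensitivities."""
    rho = _check_rho(params.rho())
    L = _L(rho) / params.alpha
    g = _g(rho) / params.alpha
    return float(np.sum((L - g) ** 2 + 2.0 * g**2) / np.sum(L) ** 2)


def amplitude_mps_full() -> float:
    """Amplitude MPS in the saturating limit: exactly 2, for every species
    and every parameter set (only the species' own alpha and beta enter,
    each with unit log-sensitivity)."""
    return 2.0


def period_sensitivities_analytic(params: OscillatorParams) -> SensitivityTable:
    """Analytic log-sensitivities of the closed-form period.

    For each species, ``S_alpha = (L - g)/(tau alpha)``,
    ``S_beta = g/(tau alpha)`` and ``S_K = -S_beta``.
    """
    rho = _check_rho(params.rho())
    tau = period_full(params)
    L = _L(rho)
    g = _g(rho)
    s_alpha = (L - g) / (tau * params.alpha)
    s_beta = g / (tau * params.alpha)
    entries = np.concatenate([s_alpha, s_beta, -s_beta])
    return SensitivityTable(output_name="period", entries=entries,
                            method="analytic")


def amplitude_sensitivities_analytic(
    params: OscillatorParams, i: int
) -> SensitivityTable:
    """Analytic log-sensitivities of the amplitude of species ``i`` (1-based):
    -1 for its own alpha, +1 for its own beta, zero elsewhere."""
    n = params.n
    if not 1 <= i <= n:
        raise IndexError(f"species index {i} out of range 1..{n}")
    entries = np.zeros(3 * n)
    entries[i - 1] = -1.0
    entries[n + i - 1] = 1.0
    return SensitivityTable(output_name=f"amplitude-{i}", entries=entries,
                            method="analytic")


@dataclass(frozen=True)
class ClosedFormResult:
    period: float
    amplitude: np.ndarray
    period_mps: float
    amplitude_mps: float
    rho: np.ndarray


def evaluate(params: OscillatorParams) -> ClosedFormResult:
    """All closed-form quantities for one parameter set."""
    return ClosedFormResult(
        period=period_full(params),
        amplitude=amplitude_full(params),
        period_mps=period_mps_full(params),
        amplitude_mps=amplitude_mps_full(),
        rho=_check_rho(params.rho()),
    )


@dataclass(frozen=True)
class RhoMinima:
    """Optimal threshold ratios of the uniform closed-form loop."""

    rho_min_mps: float       # argmin of f(rho)
    f_min: float             # f at that argmin
    mps_min_n3: float        # min period MPS for a uniform 3-loop, f_min/3
    rho_min_period_vs_alpha: float  # rho minimising tau(alpha) with beta=K=1


def find_rho_minima(xatol: float = 1e-6) -> RhoMinima:
    """Locate the robustness optima of the uniform loop numerically.

    (a) minimises ``f(rho)`` over ``rho in (0,1)`` — the common threshold
    ratio giving the most parameter-robust period; the minimal 3-loop period
    MPS is ``f*/3``.  (b) minimises the 3-loop period as a function of the
    decay rate with ``beta = K = 1`` (so ``rho = alpha``), reporting rho at
    the minimiser; equivalently the zero of the alpha-sensitivity, i.e. the
    root of ``ln[rho(1-rho)] = (1-2rho)/(1-rho)``.
    """
    res_f = minimize_scalar(
        f_rho, bounds=(1e-6, 1.0 - 1e-9), method="bounded",
        options={"xatol": xatol},
    )

    def tau_of_alpha(a: float) -> float:
        return -3.0 * np.log(a * (1.0 - a)) / a

    res_tau = minimize_scalar(
        tau_of_alpha, bounds=(1e-6, 1.0 - 1e-9), method="bounded",
        options={"xatol": xatol},
    )
    return RhoMinima(
        rho_min_mps=float(res_f.x),
        f_min=float(res_f.fun),
        mps_min_n3=float(res_f.fun) / 3.0,
        rho_min_period_vs_alpha=float(res_tau.x),
    )


def rho_where_alpha_sensitivity_vanishes() -> float:
    """Independent cross-check for the period-vs-alpha minimum: solve
    ``L(rho) = g(rho)`` by bracketed root finding."""
    def h(r: float) -> float:
        return float(_L(np.array([r]))[0] - _g(np.array([r]))[0])

    return float(brentq(h, 0.5, 1.0 - 1e-9, xtol=1e-12))
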