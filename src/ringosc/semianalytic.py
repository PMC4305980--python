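"""Semi-analytical limit cycle: exact period/amplitude via integral constants.

On the limit cycle each species traces one rising and one falling exponential
arc per cycle.  Writing the rising arc as ``beta_i/alpha_i + C_i1 e^{-alpha_i t}``
and the falling arc as ``C_i2 e^{-alpha_i t}``, continuity around the cycle
fixes the ``2n`` integral constants as the root of a closed nonlinear system.
With the shorthand

    gamma_i = (K_i - beta_i/alpha_i) / C_i1,      delta_i = K_i / C_i2,

the per-species rise/fall times are ``-ln(gamma_i)/alpha_i`` and
``-ln(delta_i)/alpha_i``, the period is their total, ``C_i2`` is the peak of
species ``i`` and ``beta_i/alpha_i + C_i1`` its trough.  The root is found by
a damped Newton iteration started from the saturating-cycle limit
``C_i1 = -beta_i/alpha_i``, ``C_i2 = beta_i/alpha_i``, with a fallback start
derived from the event-driven simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import OscillatorParams, validate_params
from .simulate import LimitCycle, simulate

__all__ = [
    "IntegralConstants",
    "CycleTimes",
    "SemiAnalyticalSolution",
    "DomainError",
    "SolverError",
    "constants_residual",
    "solve_constants",
    "constants_from_cycle",
    "period",
    "amplitude",
    "cycle_times",
    "peaks",
    "troughs",
    "solve",
]


class DomainError(ValueError):
    """An iterate left the feasible region (gamma or delta not positive)."""


class SolverError(RuntimeError):
    """Newton failed to converge from every available starting point."""


@dataclass(frozen=True)
class IntegralConstants:
    """The 2n cycle-closure constants and their derived ratios."""

    C1: np.ndarray
    C2: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    residual_norm: float
    iterations: int = 0


@dataclass(frozen=True)
class CycleTimes:
    """Per-species rise times (trough -> K_i) and fall times (peak -> K_i)."""

    tau_rise: np.ndarray
    tau_fall: np.ndarray

    @property
    def total(self) -> float:
        return float(self.tau_rise.sum() + self.tau_fall.sum())


def _gamma_delta(params: OscillatorParams, C1, C2):
    gamma = (params.K - params.ceiling) / C1
    delta = params.K / C2
    if np.any(gamma <= 0.0) or np.any(delta <= 0.0):
        raise DomainError("gamma or delta non-positive: constants left the "
                          "oscillatory branch (need C1 < 0 < C2)")
    return gamma, delta


def _power_matrices(params: OscillatorParams, gamma, delta):
    # M[i, j] = value_j ** (alpha_i / alpha_j); underflow to 0 is benign
    expo = params.alpha[:, None] / params.alpha[None, :]
    with np.errstate(under="ignore"):
        return gamma[None, :] ** expo, delta[None, :] ** expo


def _closure_rhs(params: OscillatorParams, gamma, delta):
    """Right-hand sides of the closure equations for C1 and C2, plus the
    peak-to-trough product P_i (so C2_rhs = C1 * P + ceiling)."""
    n = params.n
    G, D = _power_matrices(params, gamma, delta)
    c1_rhs = np.empty(n)
    P = np.empty(n)
    for i in range(n):
        c1_rhs[i] = params.K[i] * np.prod(G[i, :i]) * np.prod(D[i, i + 1:]) \
            - params.ceiling[i]
        P[i] = np.prod(G[i, i:]) * np.prod(D[i, :i])
    return c1_rhs, P


def constants_residual(
    params: OscillatorParams, C1: np.ndarray, C2: np.ndarray
) -> np.ndarray:
    """Defect of the 2n cycle-closure equations at the given constants.

    Zero exactly at the true limit-cycle constants.  Entries 0..n-1 are the
    ``C_i1`` closure defects, entries n..2n-1 the ``C_i2`` defects.
    """
    C1 = np.asarray(C1, dtype=float)
    C2 = np.asarray(C2, dtype=float)
    gamma, delta = _gamma_delta(params, C1, C2)
    c1_rhs, P = _closure_rhs(params, gamma, delta)
    return np.concatenate([C1 - c1_rhs, C2 - (C1 * P + params.ceiling)])


def _scaled_residual(params: OscillatorParams, z: np.ndarray) -> np.ndarray:
    n = params.n
    r = constants_residual(params, z[:n], z[n:])
    scale = np.concatenate([params.ceiling, params.ceiling])
    return r / scale


def constants_from_cycle(
    params: OscillatorParams, cycle: LimitCycle
) -> IntegralConstants:
    """Constants implied by observed peaks/troughs of a converged simulation."""
    C1 = cycle.troughs - params.ceiling
    C2 = cycle.peaks.copy()
    gamma, delta = _gamma_delta(params, C1, C2)
    rn = float(np.max(np.abs(_scaled_residual(params, np.concatenate([C1, C2])))))
    return IntegralConstants(C1=C1, C2=C2, gamma=gamma, delta=delta,
                             residual_norm=rn)


def _newton(params: OscillatorParams, z0: np.ndarray, tol: float,
            max_iter: int = 100):
    """Damped Newton with finite-difference Jacobian on the scaled residual.

    Steps are halved until the iterate stays feasible (gamma, delta > 0) and
    the residual norm does not increase.
    """
    z = z0.copy()
    r = _scaled_residual(params, z)
    norm = np.max(np.abs(r))
    for it in range(1, max_iter + 1):
        if norm <= tol:
            return z, norm, it - 1
        m = z.size
        J = np.empty((m, m))
        for j in range(m):
            h = 1e-7 * max(abs(z[j]), 1e-10)
            zp = z.copy()
            zp[j] += h
            try:
                rp = _scaled_residual(params, zp)
            except DomainError:
                zp[j] = z[j] - h
                h = -h
                rp = _scaled_residual(params, zp)
            J[:, j] = (rp - r) / h
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -r, rcond=None)[0]
        lam = 1.0
        for _ in range(60):
            try:
                z_new = z + lam * step
                r_new = _scaled_residual(params, z_new)
            except DomainError:
                lam *= 0.5
                continue
            norm_new = np.max(np.abs(r_new))
            if norm_new < norm or norm_new <= tol:
                z, r, norm = z_new, r_new, norm_new
                break
            lam *= 0.5
        else:
            return z, norm, it  # stalled
    return z, norm, max_iter


def solve_constants(
    params: OscillatorParams, tol: float = 1e-12
) -> IntegralConstants:
    """Solve the cycle-closure system for the integral constants.

    ``tol`` bounds the max-norm of the residual scaled per species by
    ``beta_i/alpha_i`` (so it is dimensionless).  The first start is the
    saturating-cycle limit; if Newton stalls, a second start is derived from
    the event-driven simulator's converged peaks and troughs.
    """
    report = validate_params(params)
    if not report.oscillatory:
        raise ValueError(
            "parameters do not oscillate: " + "; ".join(report.violations)
        )
    ceiling = params.ceiling
    z0 = np.concatenate([-ceiling, ceiling])
    z, norm, iters = _newton(params, z0, tol)
    if norm > tol:
        sim = simulate(params)
        if not sim.converged:
            raise SolverError(
                f"Newton stalled (residual {norm:.3g}) and simulator fallback "
                f"did not converge: {sim.cycle.diagnostic if sim.cycle else ''}"
            )
        z0 = np.concatenate(
            [sim.cycle.troughs - ceiling, sim.cycle.peaks]
        )
        z, norm, iters2 = _newton(params, z0, tol)
        iters += iters2
        if norm > tol:
            raise SolverError(
                f"Newton failed from both starting points; best residual {norm:.3g}"
            )
    C1, C2 = z[: params.n], z[params.n:]
    gamma, delta = _gamma_delta(params, C1, C2)
    return IntegralConstants(C1=C1, C2=C2, gamma=gamma, delta=delta,
                             residual_norm=float(norm), iterations=iters)


def cycle_times(params: OscillatorParams, C: IntegralConstants) -> CycleTimes:
    """Per-species rise/fall interval times from the solved constants."""
    return CycleTimes(
        tau_rise=-np.log(C.gamma) / params.alpha,
        tau_fall=-np.log(C.delta) / params.alpha,
    )


def period(params: OscillatorParams, C: IntegralConstants) -> float:
    """Limit-cycle period: total of all per-species rise and fall times."""
    return float(-np.sum(np.log(C.gamma * C.delta) / params.alpha))


def amplitude(params: OscillatorParams, C: IntegralConstants) -> np.ndarray:
    """Peak-minus-trough amplitude of every species."""
    _, P = _closure_rhs(params, C.gamma, C.delta)
    return C.C1 * (P - 1.0)


def peaks(params: OscillatorParams, C: IntegralConstants) -> np.ndarray:
    """Per-species peak concentration (equals ``C_i2``)."""
    return C.C2.copy()


def troughs(params: OscillatorParams, C: IntegralConstants) -> np.ndarray:
    """Per-species trough concentration (equals ``beta_i/alpha_i + C_i1``)."""
    return params.ceiling + C.C1


@dataclass(frozen=True)
class SemiAnalyticalSolution:
    constants: IntegralConstants
    period: float
    amplitude: np.ndarray
    peaks: np.ndarray
    troughs: np.ndarray
    times: CycleTimes


def solve(params: OscillatorParams, tol: float = 1e-12) -> SemiAnalyticalSolution:
    """Convenience wrapper: solve the constants and evaluate everything."""
    C = solve_constants(params, tol=tol)
    return SemiAnalyticalSolution(
        constants=C,
        period=period(params, C),
        amplitude=amplitude(params, C),
        peaks=peaks(params, C),
        troughs=troughs(params, C),
        times=cycle_times(params, C),
    )
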