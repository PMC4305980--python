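"""Seeded validation experiments: tier-agreement sweeps and robustness laws.

Three solution tiers compute the same limit-cycle quantities:

* ``sim`` — exact event-driven simulation,
* ``semi`` — integral-constant root solve (exact up to solver tolerance),
* ``full`` — closed forms under the saturating peak/trough assumption.

``run_sweep`` draws random oscillatory parameter sets (alpha, beta uniform on
(0,1), K uniform on (0, beta/alpha), which makes every threshold ratio
uniform on (0,1)), evaluates period, amplitudes and their MPSs under every
tier, and summarises pairwise agreement.  ``loop_length_study`` and
``minima_report`` tabulate how robustness scales with loop length and with
the threshold ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import closedform, semianalytic
from .model import OscillatorParams
from .sensitivity import DEFAULT_DELTA
from .simulate import NonConvergenceError, simulate

__all__ = [
    "random_params",
    "fd_mps_joint",
    "run_sweep",
    "agreement_stats",
    "loop_length_study",
    "minima_report",
    "sweep_to_tsv",
]


def random_params(n: int, seed) -> OscillatorParams:
    """Draw one random oscillatory parameter set.

    ``alpha_i`` and ``beta_i`` are uniform on the open interval (0, 1);
    ``K_i`` is uniform on (0, beta_i/alpha_i), so the set is oscillatory by
    construction (for ``n >= 3``) and each threshold ratio rho_i is uniform
    on (0, 1).  ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n < 3:
        raise ValueError("need n >= 3 for an oscillatory draw")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)

    def open_unit(size: int) -> np.ndarray:
        u = rng.uniform(0.0, 1.0, size)
        while np.any(u == 0.0):  # pragma: no cover - measure-zero
            u[u == 0.0] = rng.uniform(0.0, 1.0, np.count_nonzero(u == 0.0))
        return u

    alpha = open_unit(n)
    beta = open_unit(n)
    K = open_unit(n) * beta / alpha
    return OscillatorParams(alpha=alpha, beta=beta, K=K)


def fd_mps_joint(
    solver: Callable[[OscillatorParams], tuple[float, np.ndarray]],
    params: OscillatorParams,
    delta_fraction: float = DEFAULT_DELTA,
) -> tuple[float, np.ndarray]:
    """Finite-difference MPS of the period and of every amplitude at once.

    ``solver`` maps a parameter set to ``(period, amplitudes)``; one call per
    perturbed parameter suffices for all outputs, so the full table costs
    ``3n + 1`` solves.  Returns ``(phi_period, phi_amplitude_vector)``.
    """
    n = params.n
    tau0, eps0 = solver(params)
    log_tau0 = math.log(tau0)
    log_eps0 = np.log(eps0)
    vec = params.to_vector()
    dlog = math.log(1.0 + delta_fraction)
    s_tau = np.empty(3 * n)
    s_eps = np.empty((3 * n, n))
    for j in range(3 * n):
        v = vec.copy()
        v[j] *= 1.0 + delta_fraction
        tau, eps = solver(OscillatorParams.from_vector(v))
        s_tau[j] = (math.log(tau) - log_tau0) / dlog
        s_eps[j] = (np.log(eps) - log_eps0) / dlog
    return float(np.sum(s_tau**2)), np.sum(s_eps**2, axis=0)


def _sim_solver(tol: float, max_events: int):
    def solver(p: OscillatorParams) -> tuple[float, np.ndarray]:
        res = simulate(p, tol=tol, max_events=max_events)
        if not res.converged:
            raise NonConvergenceError(
                "simulation did not reach a limit cycle: "
                + (res.cycle.diagnostic if res.cycle else ""),
                partial=res,
            )
        return res.cycle.period, res.cycle.amplitude

    return solver


def _semi_solver(tol: float):
    def solver(p: OscillatorParams) -> tuple[float, np.ndarray]:
        sol = semianalytic.solve(p, tol=tol)
        return sol.period, sol.amplitude

    return solver


@dataclass(frozen=True)
class SweepConfig:
    sim_tol: float = 1e-10
    semi_tol: float = 1e-12
    delta_fraction: float = DEFAULT_DELTA
    max_events: int = 20_000
    include_mps: bool = True
    include_sim: bool = True


def run_sweep(
    n_values: Sequence[int],
    sets_per_n: int = 200,
    seed: int = 0,
    config: SweepConfig = SweepConfig(),
) -> pd.DataFrame:
    """Evaluate all tiers over random parameter draws.

    Returns one row per draw with the period, amplitude vector and (if
    ``config.include_mps``) period/amplitude MPSs of each tier, plus a
    ``status`` column; per-record failures are recorded, never raised.
    Deterministic per ``seed``.
    """
    base = np.random.SeedSequence(seed)
    children = base.spawn(len(n_values) * sets_per_n)
    sim_solver = _sim_solver(config.sim_tol, config.max_events)
    semi_solver = _semi_solver(config.semi_tol)
    rows = []
    idx = 0
    for n in n_values:
        for k in range(sets_per_n):
            child = children[idx]
            idx += 1
            p = random_params(n, np.random.default_rng(child))
            row: dict = {
                "seed": int(child.generate_state(1)[0]),
                "n": n,
                "draw": k,
                "alpha": p.alpha.tolist(),
                "beta": p.beta.tolist(),
                "K": p.K.tolist(),
                "status": "ok",
            }
            try:
                row["tau_full"] = closedform.period_full(p)
                row["eps_full"] = closedform.amplitude_full(p).tolist()
                if config.include_mps:
                    row["mps_tau_full"] = closedform.period_mps_full(p)
                    row["mps_eps_full"] = [closedform.amplitude_mps_full()] * n

                tau_semi, eps_semi = semi_solver(p)
                row["tau_semi"] = tau_semi
                row["eps_semi"] = eps_semi.tolist()
                if config.include_mps:
                    phi_t, phi_e = fd_mps_joint(semi_solver, p,
                                                config.delta_fraction)
                    row["mps_tau_semi"] = phi_t
                    row["mps_eps_semi"] = phi_e.tolist()

                if config.include_sim:
                    tau_sim, eps_sim = sim_solver(p)
                    row["tau_sim"] = tau_sim
                    row["eps_sim"] = eps_sim.tolist()
                    if config.include_mps:
                        phi_t, phi_e = fd_mps_joint(sim_solver, p,
                                                    config.delta_fraction)
                        row["mps_tau_sim"] = phi_t
                        row["mps_eps_sim"] = phi_e.tolist()
            except (semianalytic.SolverError, NonConvergenceError) as exc:
                row["status"] = "solver_fail"
                row["error"] = str(exc)
            except ValueError as exc:
                # e.g. an MPS perturbation pushed a threshold ratio past 1
                row["status"] = "no_oscillation"
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def _rel_dev(a, b) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return np.abs(a - b) / np.abs(b)


def agreement_stats(df: pd.DataFrame) -> pd.DataFrame:
    """Median / 95th-percentile relative deviation between tiers, per n.

    Compares semi vs sim (both exact, deviations at solver tolerance) and
    full vs semi (saturation error, shrinking with loop length).  Amplitude
    deviations are pooled over species.  Failed records are excluded and
    counted.
    """
    out = []
    for n, grp in df.groupby("n"):
        ok = grp[grp["status"] == "ok"]
        rec: dict = {"n": n, "n_ok": len(ok), "n_fail": len(grp) - len(ok)}
        pairs = [("semi", "sim"), ("full", "semi")]
        for a, b in pairs:
            ta, tb = f"tau_{a}", f"tau_{b}"
            if ta not in ok or tb not in ok or ok.empty:
                continue
            dev_tau = _rel_dev(ok[ta], ok[tb])
            dev_eps = np.concatenate([
                _rel_dev(ea, eb)
                for ea, eb in zip(ok[f"eps_{a}"], ok[f"eps_{b}"])
            ]) if len(ok) else np.array([])
            rec[f"tau_{a}_vs_{b}_median"] = float(np.median(dev_tau))
            rec[f"tau_{a}_vs_{b}_p95"] = float(np.quantile(dev_tau, 0.95))
            rec[f"eps_{a}_vs_{b}_median"] = float(np.median(dev_eps))
            rec[f"eps_{a}_vs_{b}_p95"] = float(np.quantile(dev_eps, 0.95))
        out.append(rec)
    return pd.DataFrame(out)


def loop_length_study(
    n_values: Iterable[int] = range(3, 11),
    alpha: float = 1.0,
    include_sim: bool = True,
) -> pd.DataFrame:
    """Uniform symmetric loops (beta = alpha, K at half ceiling, rho = 0.5):
    closed-form period ``n ln4 / alpha`` and period MPS ``1/n``, optionally
    cross-checked against the simulator."""
    rows = []
    for n in n_values:
        p = OscillatorParams(
            alpha=np.full(n, alpha),
            beta=np.full(n, alpha),  # ceiling 1
            K=np.full(n, 0.5),
        )
        row = {
            "n": n,
            "tau_full": closedform.period_full(p),
            "phi_tau_full": closedform.period_mps_full(p),
        }
        sol = semianalytic.solve(p)
        row["tau_semi"] = sol.period
        if include_sim:
            res = simulate(p)
            row["tau_sim"] = res.cycle.period if res.converged else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def minima_report() -> dict:
    """Robustness optima of the uniform closed-form loop, as a plain dict."""
    m = closedform.find_rho_minima()
    return {
        "rho_min_mps": m.rho_min_mps,
        "f_min": m.f_min,
        "mps_min_n3": m.mps_min_n3,
        "rho_min_period_vs_alpha": m.rho_min_period_vs_alpha,
        "rho_alpha_sensitivity_root":
            closedform.rho_where_alpha_sensitivity_vanishes(),
    }


def sweep_to_tsv(df: pd.DataFrame, path) -> None:
    """Deterministic TSV export (vectors as comma-joined fields)."""
    flat = df.copy()
    for col in flat.columns:
        if flat[col].map(lambda v: isinstance(v, list)).any():
            flat[col] = flat[col].map(
                lambda v: ",".join(f"{x:.12g}" for x in v)
                if isinstance(v, list) else ""
            )
    flat.to_csv(path, sep="\t", index=False, float_format="%.12g")
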