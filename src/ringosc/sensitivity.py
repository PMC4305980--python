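"""Logarithmic parameter sensitivities and multiparameter sensitivity (MPS).

The single-parameter sensitivity of a positive scalar output ``q`` with
respect to parameter ``p_i`` is ``d ln q / d ln p_i``; MPS is the sum of the
squared sensitivities over the full 3n-parameter vector
``(alpha_1..n, beta_1..n, K_1..n)``.  For small simultaneous random
log-perturbations of all parameters, MPS equals the variance of ``ln q``
normalised by the per-parameter input variance, which :func:`mc_variance`
estimates by Monte Carlo.

Finite differencing is one-sided on the log scale:

    S ~= [ln q(p') - ln q(p)] / [ln(p_i + dp_i) - ln p_i],   dp_i = delta * p_i

with ``delta = 1e-3`` by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import math

import numpy as np

from .model import OscillatorParams, param_labels

__all__ = [
    "SensitivityTable",
    "MPSResult",
    "MCVarianceResult",
    "EvaluationError",
    "sensitivity_fd",
    "sensitivity_table_fd",
    "mps",
    "mc_variance",
]

Evaluator = Callable[[OscillatorParams], float]

DEFAULT_DELTA = 1e-3


class EvaluationError(RuntimeError):
    """The output evaluator failed on a (possibly perturbed) parameter set."""


@dataclass(frozen=True)
class SensitivityTable:
    """All 3n single-parameter sensitivities of one scalar output.

    ``entries`` follows the canonical parameter ordering
    ``(alpha_1..n, beta_1..n, K_1..n)``; ``labels`` carries the matching
    1-based names.
    """

    output_name: str
    entries: np.ndarray
    method: str  # "analytic" | "finite-difference"
    delta_fraction: float = 0.0

    @property
    def labels(self) -> list[str]:
        return param_labels(self.entries.size // 3)

    def squared_sum(self) -> float:
        return float(np.sum(self.entries**2))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("parameter\toutput\tS\tmethod\n")
            for label, s in zip(self.labels, self.entries):
                fh.write(f"{label}\t{self.output_name}\t{s:.12g}\t{self.method}\n")


@dataclass(frozen=True)
class MPSResult:
    phi: float
    table: SensitivityTable


@dataclass(frozen=True)
class MCVarianceResult:
    """Monte-Carlo estimate of the normalised output variance."""

    phi: float
    stderr: float
    n_samples: int
    n_failures: int


def _eval_positive(evaluator: Evaluator, params: OscillatorParams,
                   context: str) -> float:
    try:
        q = float(evaluator(params))
    except Exception as exc:  # noqa: BLE001 - re-raise with parameter context
        raise EvaluationError(f"evaluator failed {context}: {exc}") from exc
    if not (q > 0.0 and math.isfinite(q)):
        raise EvaluationError(f"evaluator returned non-positive value {q} {context}")
    return q


def sensitivity_fd(
    evaluator: Evaluator,
    params: OscillatorParams,
    param_index: int,
    delta_fraction: float = DEFAULT_DELTA,
    q0: float | None = None,
    central: bool = False,
) -> float:
    """One log-scale sensitivity by finite differences.

    ``param_index`` is 0-based into the canonical 3n vector (labels in error
    messages are 1-based).  ``q0`` may pass a precomputed baseline value.
    """
    if not 0.0 < delta_fraction <= 0.1:
        raise ValueError("delta_fraction must lie in (0, 0.1]")
    vec = params.to_vector()
    if not 0 <= param_index < vec.size:
        raise IndexError(
            f"param_index {param_index} out of range for {vec.size} parameters"
        )
    label = param_labels(params.n)[param_index]
    if q0 is None:
        q0 = _eval_positive(evaluator, params, "at the nominal parameters")
    pi = vec[param_index]

    def perturbed(factor: float) -> float:
        v = vec.copy()
        v[param_index] = pi * factor
        q = _eval_positive(
            evaluator,
            OscillatorParams.from_vector(v),
            f"after perturbing {label} by factor {factor:g}",
        )
        return q

    up = math.log(perturbed(1.0 + delta_fraction))
    if central:
        down = math.log(perturbed(1.0 - delta_fraction))
        return (up - down) / (
            math.log(1.0 + delta_fraction) - math.log(1.0 - delta_fraction)
        )
    return (up - math.log(q0)) / math.log(1.0 + delta_fraction)


def sensitivity_table_fd(
    evaluator: Evaluator,
    params: OscillatorParams,
    delta_fraction: float = DEFAULT_DELTA,
    output_name: str = "output",
    central: bool = False,
) -> SensitivityTable:
    """Finite-difference sensitivities for the complete 3n-parameter vector."""
    q0 = _eval_positive(evaluator, params, "at the nominal parameters")
    entries = np.array(
        [
            sensitivity_fd(evaluator, params, j, delta_fraction, q0=q0,
                           central=central)
            for j in range(3 * params.n)
        ]
    )
    return SensitivityTable(
        output_name=output_name,
        entries=entries,
        method="finite-difference",
        delta_fraction=delta_fraction,
    )


def mps(
    evaluator: Evaluator,
    params: OscillatorParams,
    delta_fraction: float = DEFAULT_DELTA,
    output_name: str = "output",
    central: bool = False,
) -> MPSResult:
    """Multiparameter sensitivity: sum of squared sensitivities over all 3n
    parameters."""
    table = sensitivity_table_fd(
        evaluator, params, delta_fraction, output_name, central=central
    )
    return MPSResult(phi=table.squared_sum(), table=table)


def mc_variance(
    evaluator: Evaluator,
    params: OscillatorParams,
    sigma: float = 0.01,
    n_samples: int = 10_000,
    seed: int | None = None,
    max_failure_fraction: float = 0.01,
) -> MCVarianceResult:
    """Normalised output variance under simultaneous random log-perturbations.

    Each of the 3n parameters is perturbed independently on the log scale by
    zero-mean uniform noise with standard deviation ``sigma``; the return is
    ``Var(ln q)`` divided by the realised per-parameter input variance, which
    converges to the MPS as ``sigma -> 0``.  ``stderr`` is the asymptotic
    standard error of the variance estimate (from the fourth sample moment).
    """
    if sigma <= 0 or sigma > 0.05:
        raise ValueError("sigma must be a small positive log-scale width")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    vec = params.to_vector()
    half_width = sigma * math.sqrt(3.0)  # uniform(-w, w) has sd w/sqrt(3)
    noise = rng.uniform(-half_width, half_width, size=(n_samples, vec.size))
    max_failures = int(max_failure_fraction * n_samples)
    logs = np.empty(n_samples)
    used = np.zeros(n_samples, dtype=bool)
    n_ok = 0
    n_fail = 0
    for k, row in enumerate(noise):
        try:
            q = _eval_positive(
                evaluator,
                OscillatorParams.from_vector(vec * np.exp(row)),
                "on a Monte-Carlo sample",
            )
        except EvaluationError:
            n_fail += 1
            if n_fail > max_failures:
                raise
            continue
        logs[n_ok] = math.log(q)
        used[k] = True
        n_ok += 1
    logs = logs[:n_ok]
    var_out = float(np.var(logs, ddof=1))
    var_in = float(np.var(noise[used].ravel(), ddof=1))
    phi = var_out / var_in
    # SE of a sample variance: sqrt((m4 - (n-3)/(n-1) * s^4) / n)
    centered = logs - logs.mean()
    m4 = float(np.mean(centered**4))
    se_var = math.sqrt(
        max(m4 - (n_ok - 3) / (n_ok - 1) * var_out**2, 0.0) / n_ok
    )
    return MCVarianceResult(
        phi=phi, stderr=se_var / var_in, n_samples=n_ok, n_failures=n_fail
    )
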