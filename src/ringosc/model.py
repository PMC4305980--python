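"""Core model definitions for the unit-step negative-feedback ring oscillator.

The model is a cyclic cascade of ``n`` species: species ``i`` is produced at
rate ``beta_i`` whenever its regulator is past threshold and decays linearly
at rate ``alpha_i``.  Species ``i-1`` activates species ``i``; the last
species represses the first, closing a negative feedback loop.  Regulation is
an all-or-none unit step, so between switching events every species relaxes
exponentially toward ``0`` or ``beta_i/alpha_i``.

Sustained oscillation requires ``n >= 3`` and every threshold to be
attainable, i.e. ``K_i < beta_i/alpha_i``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "OscillatorParams",
    "RegulationState",
    "ValidationReport",
    "theta",
    "regulation_state",
    "validate_params",
    "load_params",
    "dump_params",
    "PARAM_KINDS",
    "param_labels",
]

#: canonical ordering of the 3n-parameter vector: (alpha_1..n, beta_1..n, K_1..n)
PARAM_KINDS = ("alpha", "beta", "K")


class ParameterError(ValueError):
    """Raised for structurally invalid parameter sets (lengths, signs)."""


def _as_positive_vector(values, name: str, n: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size != n:
        raise ParameterError(
            f"{name} must be a length-{n} vector, got shape {arr.shape}"
        )
    bad = np.where(~(arr > 0.0) | ~np.isfinite(arr))[0]
    if bad.size:
        i = int(bad[0])
        raise ParameterError(
            f"{name}_{i + 1} = {arr[i]!r} is not strictly positive"
        )
    return arr


@dataclass(frozen=True)
class OscillatorParams:
    """Kinetic parameters of an ``n``-species ring oscillator.

    Parameters
    ----------
    alpha
        Decay rate constants, one per species (1/time), all ``> 0``.
    beta
        Production rate constants (concentration/time), all ``> 0``.
    K
        Regulation thresholds (concentration), all ``> 0``.

    Species indices are reported 1-based in messages and file formats.
    """

    alpha: np.ndarray
    beta: np.ndarray
    K: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.alpha, dtype=float).size
        if n < 1:
            raise ParameterError("need at least one species")
        object.__setattr__(self, "alpha", _as_positive_vector(self.alpha, "alpha", n))
        object.__setattr__(self, "beta", _as_positive_vector(self.beta, "beta", n))
        object.__setattr__(self, "K", _as_positive_vector(self.K, "K", n))

    @property
    def n(self) -> int:
        """Loop length (number of species)."""
        return self.alpha.size

    @property
    def ceiling(self) -> np.ndarray:
        """Per-species maximal attainable concentration ``beta_i / alpha_i``."""
        return self.beta / self.alpha

    def rho(self, i: int | None = None):
        """Threshold ratio ``rho_i = K_i * alpha_i / beta_i``.

        With 1-based ``i`` returns a scalar; without, the full vector.
        ``rho_i`` is the threshold divided by the maximal attainable
        concentration and must lie in ``(0, 1)`` for oscillation.
        """
        r = self.K * self.alpha / self.beta
        if i is None:
            return r
        if not 1 <= i <= self.n:
            raise IndexError(f"species index {i} out of range 1..{self.n}")
        return float(r[i - 1])

    @property
    def oscillatory(self) -> bool:
        """True iff ``n >= 3`` and every ``K_i < beta_i/alpha_i``."""
        return self.n >= 3 and bool(np.all(self.K < self.ceiling))

    # --- 3n-vector view used by the sensitivity machinery -------------------

    def to_vector(self) -> np.ndarray:
        """Flatten to ``(alpha_1..n, beta_1..n, K_1..n)``."""
        return np.concatenate([self.alpha, self.beta, self.K])

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "OscillatorParams":
        vec = np.asarray(vec, dtype=float)
        if vec.size % 3:
            raise ParameterError("parameter vector length must be a multiple of 3")
        n = vec.size // 3
        return cls(alpha=vec[:n], beta=vec[n : 2 * n], K=vec[2 * n :])

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "K": self.K.tolist(),
        }


def param_labels(n: int) -> list[str]:
    """1-based labels for the 3n-parameter vector, e.g. ``alpha_1 .. K_n``."""
    return [f"{kind}_{i + 1}" for kind in PARAM_KINDS for i in range(n)]


@dataclass(frozen=True)
class RegulationState:
    """Binary production switches ``s`` of all species at some instant."""

    s: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=np.int8)
        if not np.isin(s, (0, 1)).all():
            raise ValueError("switch entries must be exactly 0 or 1")
        object.__setattr__(self, "s", s)


def theta(a: float, b: float) -> int:
    """Unit step: ``0`` if ``a < b``, else ``1`` (ties count as on)."""
    return 1 if a >= b else 0


def regulation_state(params: OscillatorParams, x: np.ndarray) -> RegulationState:
    """Production switches implied by the concentration vector ``x``.

    Species 1 is produced while the last species sits at or below its
    threshold (repression); species ``i > 1`` is produced while species
    ``i-1`` is at or above threshold ``K_{i-1}`` (activation).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (params.n,):
        raise ValueError(f"x must have length {params.n}, got shape {x.shape}")
    s = np.empty(params.n, dtype=np.int8)
    s[0] = theta(params.K[-1], x[-1])
    for i in range(1, params.n):
        s[i] = theta(x[i - 1], params.K[i - 1])
    return RegulationState(s=s)


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of :func:`validate_params`."""

    oscillatory: bool
    violations: tuple[str, ...] = field(default_factory=tuple)


def validate_params(params: OscillatorParams) -> ValidationReport:
    """Check the two oscillation conditions, naming every violation.

    A parameter set supports sustained oscillation iff ``n >= 3`` and
    ``K_i < beta_i/alpha_i`` for every species.  Non-positive entries are
    rejected earlier, at construction time.
    """
    violations: list[str] = []
    if params.n < 3:
        violations.append(
            f"loop length n={params.n} < 3: no sustained oscillation possible"
        )
    ceiling = params.ceiling
    for i in range(params.n):
        if not params.K[i] < ceiling[i]:
            violations.append(
                f"K_{i + 1}={params.K[i]:g} >= beta_{i + 1}/alpha_{i + 1}"
                f"={ceiling[i]:g}: threshold unattainable"
            )
    return ValidationReport(oscillatory=not violations, violations=tuple(violations))


# --- parameter files ---------------------------------------------------------


def load_params(source: Union[str, Path]) -> OscillatorParams:
    """Read a JSON parameter file with fields ``n``, ``alpha``, ``beta``, ``K``.

    ``n`` is optional but, if present, must match the vector lengths.
    """
    with open(source) as fh:
        doc = json.load(fh)
    missing = [k for k in ("alpha", "beta", "K") if k not in doc]
    if missing:
        raise ParameterError(f"parameter file missing fields: {', '.join(missing)}")
    p = OscillatorParams(alpha=doc["alpha"], beta=doc["beta"], K=doc["K"])
    if "n" in doc and int(doc["n"]) != p.n:
        raise ParameterError(
            f"declared n={doc['n']} does not match vector length {p.n}"
        )
    return p


def dump_params(params: OscillatorParams, target: Union[str, Path]) -> None:
    """Write a parameter set as a JSON document."""
    with open(target, "w") as fh:
        json.dump(params.to_dict(), fh, indent=2)
        fh.write("\n")
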