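"""Closed-form models of long-term protein sequence divergence.

Three nested descriptions of how global percent identity ``y`` between a
pair of orthologs decays with divergence time ``t`` (in Gy, 10**9 years):

* Model 1 (``M1``): equal, independent substitution rates at every site and
  no back substitutions, ``y = 100 * exp(-R0 * t)``.  Identity decays to 0.
* Model 2 (``M2``): same, plus a fraction ``Y0`` of sites that remain
  identical at arbitrarily long times, ``y = Y0 + (100 - Y0) * exp(-R0*t)``.
* Model 3 (``M3``): gamma-distributed rates across sites with shape
  ``alpha``, ``y = 100 * (1 + R0 * t / alpha) ** (-alpha)`` (the survival
  function of a Poisson process whose rate is gamma-mixed across sites;
  M1 is the ``alpha -> inf`` limit).

Model 2 is algebraically identical to a finite-alphabet substitution
process with back substitutions: if each site accepts ``a`` amino-acid
types and substitutes at per-site rate ``lam``, the expected identity
between two lineages separated for time ``t`` is

    y = 1/a + (1 - 1/a) * exp(-2 * lam * a / (a - 1) * t)

i.e. Model 2 with ``Y0 = 100/a`` and ``R0 = 2*lam*a/(a-1)``.  ``Y0`` can
therefore be read as the inverse of the effective number of amino acids
accepted per site.  :func:`alphabet_to_limit` / :func:`limit_to_alphabet`
convert between the two parameterizations, and
:func:`expected_substitutions` is the corresponding finite-alphabet
distance correction (the a-state Jukes-Cantor formula).

Identity is expressed in percent (0-100] in every public interface; the
"protein distance" D = 1 - y/100 used by :func:`expansion_rate` is the one
place a fractional scale appears, and the conversion is internal to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .exceptions import (
    DegenerateAlphabetError,
    InvalidParameterError,
    SaturationError,
)

__all__ = [
    "ModelParams",
    "AlphabetParams",
    "evaluate_model",
    "divergence_rate",
    "expansion_rate",
    "alphabet_to_limit",
    "limit_to_alphabet",
    "expected_substitutions",
]

ArrayLike = Union[float, np.ndarray]

MODEL_IDS = ("M1", "M2", "M3")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of one divergence model.

    Parameters
    ----------
    model_id:
        One of ``"M1"``, ``"M2"``, ``"M3"``.
    r0:
        Substitution-rate parameter, per Gy. Must be positive.
    y0:
        Long-term identity floor in percent; only meaningful for M2
        (M1 is the ``y0 -> 0`` limit of M2).
    alpha:
        Shape of the gamma rate distribution across sites; only M3.
    """

    model_id: str
    r0: float
    y0: float | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise InvalidParameterError(f"unknown model_id {self.model_id!r}")
        if not np.isfinite(self.r0) or self.r0 <= 0:
            raise InvalidParameterError(f"R0 must be > 0, got {self.r0}")
        if self.model_id == "M2":
            # least-squares floor estimates can come out slightly negative
            # under noise (the estimator is unconstrained); interpretation
            # as 100/a requires y0 > 0 (see limit_to_alphabet)
            if self.y0 is None or not -100.0 <= self.y0 <= 100.0:
                raise InvalidParameterError(f"Y0 must be in [-100, 100], got {self.y0}")
        if self.model_id == "M3":
            if self.alpha is None or not np.isfinite(self.alpha) or self.alpha <= 0:
                raise InvalidParameterError(f"alpha must be > 0, got {self.alpha}")

    @property
    def free_names(self) -> tuple[str, ...]:
        return {
            "M1": ("r0",),
            "M2": ("y0", "r0"),
            "M3": ("r0", "alpha"),
        }[self.model_id]

    @property
    def free_values(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in self.free_names)

    def to_dict(self) -> dict:
        d = {"model_id": self.model_id, "r0": float(self.r0)}
        if self.y0 is not None:
            d["y0"] = float(self.y0)
        if self.alpha is not None:
            d["alpha"] = float(self.alpha)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            model_id=d["model_id"],
            r0=float(d["r0"]),
            y0=float(d["y0"]) if "y0" in d and d["y0"] is not None else None,
            alpha=float(d["alpha"]) if "alpha" in d and d["alpha"] is not None else None,
        )


@dataclass(frozen=True)
class AlphabetParams:
    """Finite-alphabet parameterization: ``a`` accepted residue types per
    site (real-valued, > 1; an *effective* number) and per-site substitution
    rate ``lam`` (per Gy)."""

    a: float
    lam: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.a) or self.a <= 1.0:
            raise DegenerateAlphabetError(f"alphabet size a must be > 1, got {self.a}")
        if not np.isfinite(self.lam) or self.lam <= 0:
            raise InvalidParameterError(f"lam must be > 0, got {self.lam}")

    def to_dict(self) -> dict:
        return {"a": float(self.a), "lam": float(self.lam)}

    @classmethod
    def from_dict(cls, d: dict) -> "AlphabetParams":
        return cls(a=float(d["a"]), lam=float(d["lam"]))


def _check_time(t: ArrayLike) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(~np.isfinite(t) & (t != np.inf)):
        raise InvalidParameterError("divergence time t must be >= 0")
    return t


def evaluate_model(params: ModelParams, t: ArrayLike) -> ArrayLike:
    """Percent identity predicted at divergence time ``t`` (Gy).

    Accepts scalars or arrays; returns the same shape.
    """
    t = _check_time(t)
    if params.model_id == "M1":
        out = 100.0 * np.exp(-params.r0 * t)
    elif params.model_id == "M2":
        out = params.y0 + (100.0 - params.y0) * np.exp(-params.r0 * t)
    else:  # M3
        out = 100.0 * np.power(1.0 + params.r0 * t / params.alpha, -params.alpha)
    return out if out.ndim else float(out)


def divergence_rate(params: ModelParams, t: ArrayLike) -> ArrayLike:
    """Rate of identity decrease, -dy/dt in percent per Gy, under M3.

    Always non-negative; at t=0 it equals ``100 * R0``.
    """
    if params.model_id != "M3":
        raise InvalidParameterError("divergence_rate is defined for model M3")
    t = _check_time(t)
    out = 100.0 * params.r0 * np.power(
        1.0 + params.r0 * t / params.alpha, -params.alpha - 1.0
    )
    return out if out.ndim else float(out)


def expansion_rate(params: ModelParams, D: ArrayLike) -> ArrayLike:
    """Divergence speed dD/dt (per Gy) as a function of fractional protein
    distance ``D = 1 - y/100``, under M3.

    Equivalent to ``divergence_rate(t(D)) / 100`` where ``t(D)`` inverts the
    M3 identity curve.
    """
    if params.model_id != "M3":
        raise InvalidParameterError("expansion_rate is defined for model M3")
    D = np.asarray(D, dtype=float)
    if np.any((D < 0) | (D >= 1)):
        raise InvalidParameterError("fractional distance D must be in [0, 1)")
    out = params.r0 * np.power(1.0 - D, (params.alpha + 1.0) / params.alpha)
    return out if out.ndim else float(out)


def alphabet_to_limit(ap: AlphabetParams) -> ModelParams:
    """Map finite-alphabet parameters (a, lam) to the equivalent Model 2:
    ``Y0 = 100/a``, ``R0 = 2*lam*a/(a-1)``."""
    return ModelParams(
        model_id="M2",
        r0=2.0 * ap.lam * ap.a / (ap.a - 1.0),
        y0=100.0 / ap.a,
    )


def limit_to_alphabet(params: ModelParams) -> AlphabetParams:
    """Inverse of :func:`alphabet_to_limit`: ``a = 100/Y0``,
    ``lam = R0*(a-1)/(2a)``.  Requires an M2 fit with Y0 > 0."""
    if params.model_id != "M2":
        raise InvalidParameterError("alphabet interpretation requires model M2")
    if params.y0 is None or params.y0 <= 0:
        raise DegenerateAlphabetError("Y0 must be > 0 to interpret as 1/a")
    a = 100.0 / params.y0
    if a <= 1.0:
        raise DegenerateAlphabetError(f"Y0={params.y0} implies a={a} <= 1")
    return AlphabetParams(a=a, lam=params.r0 * (a - 1.0) / (2.0 * a))


def expected_substitutions(y: ArrayLike, a: float) -> ArrayLike:
    """Substitutions per site, delta, from fractional identity ``y`` under
    the a-state finite-alphabet model with back substitutions:

        delta = -((a-1)/a) * ln(1 - (a/(a-1)) * (1-y))

    ``y`` is a fraction in (1/a, 1]; delta diverges as y -> 1/a (saturation).
    """
    if a <= 1.0:
        raise DegenerateAlphabetError(f"alphabet size a must be > 1, got {a}")
    y = np.asarray(y, dtype=float)
    if np.any(y > 1.0):
        raise InvalidParameterError("identity fraction y must be <= 1")
    if np.any(y <= 1.0 / a):
        raise SaturationError(
            f"identity {y} at or below the 1/a = {1.0 / a:.4f} floor: "
            "substitution distance undefined"
        )
    frac = (a - 1.0) / a
    out = -frac * np.log(1.0 - (1.0 - y) / frac)
    return out if out.ndim else float(out)
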