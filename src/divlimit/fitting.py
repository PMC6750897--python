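"""Least-squares fitting and comparison of the divergence models.

Observations are (identity %, divergence time) points for ortholog pairs,
optionally grouped into families (one family per enzymatic activity or
orthologous group).  Fitting is ordinary, unweighted nonlinear least
squares over all pairwise points — phylogenetic non-independence of pairs
is deliberately ignored, matching how such identity-vs-time scatters are
normally fit.  Standard errors come from the asymptotic covariance at the
optimum, ``s^2 (J'J)^{-1}``.

Model comparison: M1 (no identity floor) is nested in M2 (floor ``Y0``),
so the floor's significance is an F-test on the residual sums of squares
with (1, n-2) degrees of freedom.  Whether the fitted floor exceeds the
identity expected between unrelated sequences (~13.5% for optimal global
alignments of random proteins) is a one-sided Wald test on ``Y0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import (
    ConfigurationError,
    DegenerateFitError,
    InsufficientDataError,
    TooFewTimepointsError,
)
from .models import ModelParams, divergence_rate, evaluate_model

__all__ = [
    "DivergenceObservation",
    "ModelFit",
    "RANDOM_IDENTITY_BASELINE",
    "DEFAULT_HORIZON_GY",
    "fit_divergence_model",
    "f_test_nested",
    "wald_test_floor",
    "project_identity",
    "rate_decline_factor",
    "resample_divergence_times",
    "fit_family_table",
    "load_observations",
]

#: Mean percent identity of optimal global alignments of unrelated protein
#: sequences; default Wald-test baseline (see alignment.random_identity_baseline).
RANDOM_IDENTITY_BASELINE = 13.5

#: Default projection horizon: ~7.8 Gy, twice the age of the deepest splits
#: plus the remaining lifetime of habitable Earth environments.
DEFAULT_HORIZON_GY = 7.8


@dataclass(frozen=True)
class DivergenceObservation:
    """One ortholog pair: percent identity at a known divergence time."""

    pair_id: str
    identity: float
    time: float
    family_id: str = ""
    time_min: float | None = None
    time_max: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity must be in [0, 100], got {self.identity}")
        if self.time < 0:
            raise ValueError(f"time must be >= 0, got {self.time}")
        if self.time_min is not None and self.time_max is not None:
            if not self.time_min <= self.time_max:
                raise ValueError("time_min must be <= time_max")


@dataclass
class ModelFit:
    """A fitted divergence model with its uncertainty."""

    params: ModelParams
    covariance: np.ndarray
    rss: float
    n: int
    converged: bool = True
    n_starts: int = 0

    @property
    def se(self) -> dict[str, float]:
        """Asymptotic standard error per free parameter."""
        d = np.sqrt(np.clip(np.diag(self.covariance), 0.0, np.inf))
        return dict(zip(self.params.free_names, d))


def _model_predict(model_id: str, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    if model_id == "M1":
        return 100.0 * np.exp(-theta[0] * t)
    if model_id == "M2":
        y0, r0 = theta
        return y0 + (100.0 - y0) * np.exp(-r0 * t)
    r0, alpha = theta
    return 100.0 * np.power(1.0 + r0 * t / alpha, -alpha)


_BOUNDS = {
    # (lower, upper) per free parameter; R0 in (0, 50], alpha in (0, 100].
    # The floor Y0 is fit unconstrained below 0 (classical least squares):
    # pinning it at 0 would put the M1 truth on the parameter boundary and
    # destroy the nominal calibration of the nested F-test.
    "M1": ([1e-9], [50.0]),
    "M2": ([-100.0, 1e-9], [100.0, 50.0]),
    "M3": ([1e-9, 1e-6], [50.0, 100.0]),
}

_R0_STARTS = np.geomspace(0.05, 20.0, 5)
_ALPHA_STARTS = np.geomspace(0.05, 20.0, 5)
_Y0_STARTS = (0.0, 20.0, 40.0)


def _start_grid(model_id: str, n_starts: int) -> list[np.ndarray]:
    if model_id == "M1":
        starts = [np.array([r]) for r in np.geomspace(0.02, 30.0, max(n_starts, 2))]
        return starts[: max(n_starts, 1)]
    if model_id == "M2":
        # round-robin over Y0 values so truncated grids still span them
        starts = [
            np.array([_Y0_STARTS[i % 3], r])
            for i, r in enumerate(np.tile(_R0_STARTS, 3))
        ]
    else:
        starts = [
            np.array([r, _ALPHA_STARTS[(i + i // 5) % 5]])
            for i, r in enumerate(np.tile(_R0_STARTS, 5))
        ]
    return starts[: max(n_starts, 1)]


def fit_divergence_model(
    obs: Sequence[DivergenceObservation],
    model_id: str,
    *,
    min_times: int = 5,
    n_starts: int = 10,
) -> ModelFit:
    """Fit one divergence model to identity-vs-time observations.

    Ordinary least squares over all points, multi-start trust-region
    optimization with box bounds.  ``min_times`` enforces the inclusion
    rule that a family must span at least five distinct divergence times
    (pass ``min_times=4`` for reanalysis of validated-annotation subsets).

    Non-convergence is flagged on the returned :class:`ModelFit`, not
    raised.
    """
    if model_id not in ("M1", "M2", "M3"):
        raise ValueError(f"unknown model_id {model_id!r}")
    t = np.array([o.time for o in obs], dtype=float)
    y = np.array([o.identity for o in obs], dtype=float)
    if len(np.unique(t)) < min_times:
        raise TooFewTimepointsError(
            f"need >= {min_times} distinct divergence times, got {len(np.unique(t))}"
        )
    lo, hi = _BOUNDS[model_id]
    n_free = len(lo)
    if len(obs) < n_free + 1:
        raise InsufficientDataError("need more observations than free parameters")

    def resid(theta: np.ndarray) -> np.ndarray:
        return _model_predict(model_id, theta, t) - y

    best = None
    starts = _start_grid(model_id, n_starts)
    for x0 in starts:
        x0c = np.clip(x0, lo, hi)
        try:
            res = optimize.least_squares(resid, x0c, bounds=(lo, hi), method="trf")
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:  # pragma: no cover
        raise InsufficientDataError("all optimization starts failed")

    rss = float(2.0 * best.cost)
    dof = max(len(obs) - n_free, 1)
    s2 = rss / dof
    JTJ = best.jac.T @ best.jac
    cov = s2 * np.linalg.pinv(JTJ)

    theta = best.x
    if model_id == "M1":
        params = ModelParams("M1", r0=float(theta[0]))
    elif model_id == "M2":
        params = ModelParams("M2", r0=float(theta[1]), y0=float(theta[0]))
    else:
        params = ModelParams("M3", r0=float(theta[0]), alpha=float(theta[1]))
    return ModelFit(
        params=params,
        covariance=cov,
        rss=rss,
        n=len(obs),
        converged=bool(best.success),
        n_starts=len(starts),
    )


def f_test_nested(fit1: ModelFit, fit2: ModelFit) -> tuple[float, float]:
    """F-test of the identity floor: M1 (1 parameter) against M2 (2).

    ``F = ((rss1 - rss2) / 1) / (rss2 / (n - 2))`` with (1, n-2) degrees of
    freedom.  If the optimizer left ``rss2 > rss1`` (the nested model can
    never truly fit worse), F clamps to 0.
    """
    if fit1.n != fit2.n:
        raise ValueError("F-test requires fits to the same observations")
    n = fit1.n
    if n <= 2:
        raise InsufficientDataError("F-test needs n > 2 observations")
    num = max(fit1.rss - fit2.rss, 0.0)
    denom = fit2.rss / (n - 2)
    if denom == 0.0:
        # perfect M2 fit: any improvement is infinitely significant
        return (math.inf, 0.0) if num > 0 else (0.0, 1.0)
    F = num / denom
    p = float(stats.f.sf(F, 1, n - 2))
    return float(F), p


def wald_test_floor(
    fit2: ModelFit, baseline: float = RANDOM_IDENTITY_BASELINE
) -> tuple[float, float]:
    """One-sided Wald test that the fitted floor Y0 exceeds ``baseline``
    (the random-alignment identity).  Returns (z, p) with
    ``z = (Y0 - baseline) / SE(Y0)`` and p the upper normal tail.
    """
    if fit2.params.model_id != "M2":
        raise ValueError("Wald floor test requires an M2 fit")
    se = fit2.se.get("y0", 0.0)
    if not np.isfinite(se) or se <= 0:
        raise DegenerateFitError("SE(Y0) is zero or undefined")
    z = (fit2.params.y0 - baseline) / se
    return float(z), float(stats.norm.sf(z))


def project_identity(fit: ModelFit, horizon: float = DEFAULT_HORIZON_GY) -> float:
    """Identity (%) the fitted model predicts at ``horizon`` Gy."""
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    return float(evaluate_model(fit.params, horizon))


def rate_decline_factor(fit: ModelFit, t: float) -> float:
    """Fold-decrease of the M3 divergence rate between time 0 and ``t``:
    ``(1 + R0*t/alpha) ** (alpha + 1)``."""
    if fit.params.model_id != "M3":
        raise ValueError("rate_decline_factor requires an M3 fit")
    return float(divergence_rate(fit.params, 0.0) / divergence_rate(fit.params, t))


def _flip_key(o: DivergenceObservation) -> tuple[float, float, float]:
    return (o.time, o.time_min, o.time_max)


def resample_divergence_times(
    obs: Sequence[DivergenceObservation],
    n_runs: int,
    seed: int = 0,
    *,
    threshold: float = 25.0,
    horizon: float = DEFAULT_HORIZON_GY,
    min_times: int = 5,
    n_starts: int = 4,
) -> dict:
    """Propagate divergence-time uncertainty through the model fits.

    Per run, every distinct lineage-pair time (observations sharing the
    same (time, time_min, time_max) triple flip together) is independently
    set to its reported minimum or maximum (fair coin); Models 2 and 3 are
    refit per family.  Reports, across runs, the fraction of families
    whose fitted Y0 exceeds ``threshold`` and whose M3-projected identity
    at ``horizon`` exceeds ``threshold``.
    """
    if any(o.time_min is None or o.time_max is None for o in obs):
        raise ConfigurationError("resampling requires time_min/time_max on every observation")
    if n_runs == 0:
        return {
            "n_runs": 0,
            "fraction_y0_gt_threshold": np.array([]),
            "fraction_projected_gt_threshold": np.array([]),
        }
    rng = np.random.default_rng(seed)
    families = sorted({o.family_id for o in obs})
    keys = sorted({_flip_key(o) for o in obs})
    key_index = {k: i for i, k in enumerate(keys)}

    frac_y0 = np.empty(n_runs)
    frac_proj = np.empty(n_runs)
    for run in range(n_runs):
        coin = rng.integers(0, 2, size=len(keys))  # 1 -> max, 0 -> min
        flipped: list[DivergenceObservation] = []
        for o in obs:
            c = coin[key_index[_flip_key(o)]]
            t_new = o.time_max if c else o.time_min
            flipped.append(
                DivergenceObservation(
                    pair_id=o.pair_id,
                    identity=o.identity,
                    time=t_new,
                    family_id=o.family_id,
                    time_min=o.time_min,
                    time_max=o.time_max,
                )
            )
        y0_hits = proj_hits = n_ok = 0
        for fam in families:
            fam_obs = [o for o in flipped if o.family_id == fam]
            try:
                f2 = fit_divergence_model(fam_obs, "M2", min_times=min_times, n_starts=n_starts)
                f3 = fit_divergence_model(fam_obs, "M3", min_times=min_times, n_starts=n_starts)
            except (TooFewTimepointsError, InsufficientDataError):
                continue
            n_ok += 1
            y0_hits += f2.params.y0 > threshold
            proj_hits += project_identity(f3, horizon) > threshold
        frac_y0[run] = y0_hits / n_ok if n_ok else np.nan
        frac_proj[run] = proj_hits / n_ok if n_ok else np.nan
    return {
        "n_runs": n_runs,
        "fraction_y0_gt_threshold": frac_y0,
        "fraction_projected_gt_threshold": frac_proj,
        "mean_fraction_y0_gt_threshold": float(np.nanmean(frac_y0)),
        "mean_fraction_projected_gt_threshold": float(np.nanmean(frac_proj)),
    }


def fit_family_table(
    obs: Iterable[DivergenceObservation],
    *,
    baseline: float = RANDOM_IDENTITY_BASELINE,
    min_times: int = 5,
    horizon: float = DEFAULT_HORIZON_GY,
    n_starts: int = 10,
) -> pd.DataFrame:
    """Per-family fits of Models 1-3 with the floor tests.

    One row per family: fitted parameters, RSS, F-test of M2 vs M1, Wald
    test of Y0 against ``baseline``, and the M3 projection at ``horizon``.
    Families spanning fewer than ``min_times`` distinct times are skipped.
    """
    rows = []
    by_family: dict[str, list[DivergenceObservation]] = {}
    for o in obs:
        by_family.setdefault(o.family_id, []).append(o)
    for fam in sorted(by_family):
        fam_obs = by_family[fam]
        try:
            f1 = fit_divergence_model(fam_obs, "M1", min_times=min_times, n_starts=n_starts)
            f2 = fit_divergence_model(fam_obs, "M2", min_times=min_times, n_starts=n_starts)
            f3 = fit_divergence_model(fam_obs, "M3", min_times=min_times, n_starts=n_starts)
        except (TooFewTimepointsError, InsufficientDataError):
            continue
        F, p_f = f_test_nested(f1, f2)
        try:
            z, p_w = wald_test_floor(f2, baseline)
        except DegenerateFitError:
            z, p_w = np.nan, np.nan
        rows.append(
            {
                "family_id": fam,
                "n": f2.n,
                "m1_r0": f1.params.r0,
                "m1_rss": f1.rss,
                "m2_y0": f2.params.y0,
                "m2_r0": f2.params.r0,
                "m2_y0_se": f2.se["y0"],
                "m2_rss": f2.rss,
                "m3_r0": f3.params.r0,
                "m3_alpha": f3.params.alpha,
                "m3_rss": f3.rss,
                "f_stat": F,
                "f_pvalue": p_f,
                "wald_z": z,
                "wald_pvalue": p_w,
                "m3_projection": project_identity(f3, horizon),
            }
        )
    return pd.DataFrame(rows)


def load_observations(path) -> list[DivergenceObservation]:
    """Read observations from TSV with columns family_id, pair_id,
    identity_pct, time_gy and optional time_min_gy / time_max_gy."""
    df = pd.read_csv(path, sep="\t")
    required = {"family_id", "pair_id", "identity_pct", "time_gy"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"observation table missing columns: {sorted(missing)}")
    has_bounds = {"time_min_gy", "time_max_gy"} <= set(df.columns)
    return [
        DivergenceObservation(
            pair_id=str(r.pair_id),
            family_id=str(r.family_id),
            identity=float(r.identity_pct),
            time=float(r.time_gy),
            time_min=float(r.time_min_gy) if has_bounds else None,
            time_max=float(r.time_max_gy) if has_bounds else None,
        )
        for r in df.itertuples()
    ]
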