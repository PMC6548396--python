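"""Resampling inference for indirect and total effects.

Two interval methods are provided:

* :func:`bootstrap_effects` -- nonparametric bootstrap resampling whole dyads
  with replacement, refitting the saturated APIMeM and recomputing the effect
  decomposition per replicate.  Default intervals are bias-corrected (BC):
  with z0 the normal quantile of the fraction of replicate estimates below
  the full-sample estimate, the bounds are the bootstrap quantiles at
  Phi(2 z0 -/+ z_{alpha/2}).  No acceleration constant (BC, not BCa).
* :func:`monte_carlo_effects` -- parametric draws of the twelve path
  coefficients from a normal centred at the estimates with the fit's
  coefficient covariance, propagated through the decomposition; percentile
  bounds.

The resampling unit is always the dyad, never the individual, preserving
within-dyad dependence.  Both methods are deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dyads import DyadDataset
from .effects import EFFECT_LABELS, effect_values
from .errors import EstimationError
from .estimate import PATH_NAMES, ApimemFit, _as_wide, fit_saturated, solve_paths

DEFAULT_REPS = 5000


@dataclass(frozen=True)
class CIResult:
    label: str
    estimate: float
    lower: float
    upper: float
    method: str       # "bc" | "percentile" | "monte-carlo"
    replicates: int   # successful replicates actually used
    seed: int


def results_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [{"effect": r.label, "estimate": r.estimate, "lo95": r.lower,
          "hi95": r.upper, "method": r.method, "reps": r.replicates,
          "seed": r.seed} for r in results]
    )


def _effect_vector(paths) -> tuple[list, np.ndarray]:
    d = paths if isinstance(paths, dict) else paths.as_dict()
    return list(EFFECT_LABELS), effect_values(d)


def _bc_bounds(replicates: np.ndarray, estimate: float, alpha: float) -> tuple[float, float]:
    B = replicates.size
    frac = np.mean(replicates < estimate)
    frac = np.clip(frac, 1.0 / (B + 1), B / (B + 1.0))   # guard z0 = +/-inf
    z0 = stats.norm.ppf(frac)
    zc = stats.norm.ppf(1 - alpha / 2)
    lo_p = stats.norm.cdf(2 * z0 - zc)
    hi_p = stats.norm.cdf(2 * z0 + zc)
    return (float(np.quantile(replicates, lo_p)),
            float(np.quantile(replicates, hi_p)))


def bootstrap_effects(
    data: DyadDataset | np.ndarray,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    method: str = "bc",
    alpha: float = 0.05,
) -> list:
    """Bootstrap confidence intervals for all twenty decomposition effects.

    Resamples dyads with replacement ``reps`` times; replicates whose refit
    fails (degenerate resample) are logged and skipped -- more than 1% failed
    warns, more than 10% raises.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if method not in ("bc", "percentile"):
        raise ValueError(f"unknown method {method!r}")
    wide = _as_wide(data)
    n = wide.shape[0]

    full_fit = fit_saturated(wide)           # validates the data up front
    labels, point = _effect_vector(full_fit.paths)

    rng = np.random.default_rng(seed)
    draws = np.empty((reps, len(labels)))
    failed = 0
    for b in range(reps):
        idx = rng.integers(0, n, size=n)
        try:
            paths_b = solve_paths(wide[idx])
        except np.linalg.LinAlgError:
            draws[b] = np.nan
            failed += 1
            continue
        _, draws[b] = _effect_vector(paths_b)

    if failed > 0.10 * reps:
        raise EstimationError(f"bootstrap: {failed}/{reps} replicates failed to refit")
    if failed > 0.01 * reps:
        warnings.warn(f"bootstrap: {failed}/{reps} replicates failed and were skipped",
                      stacklevel=2)
    ok = draws[~np.isnan(draws[:, 0])]

    out = []
    for j, label in enumerate(labels):
        col = ok[:, j]
        if method == "bc":
            lo, hi = _bc_bounds(col, point[j], alpha)
        else:
            lo = float(np.quantile(col, alpha / 2))
            hi = float(np.quantile(col, 1 - alpha / 2))
        out.append(CIResult(label=label, estimate=float(point[j]), lower=lo,
                            upper=hi, method=method, replicates=ok.shape[0],
                            seed=seed))
    return out


def monte_carlo_effects(
    fit: ApimemFit,
    draws: int = DEFAULT_REPS,
    seed: int = 0,
    alpha: float = 0.05,
) -> list:
    """Monte-Carlo (parametric) intervals: sample the path vector from
    N(estimates, coefficient covariance) and propagate through the
    decomposition; percentile bounds."""
    if fit.coef_cov is None:
        raise EstimationError("fit carries no coefficient covariance; refit with fit_saturated")
    labels, point = _effect_vector(fit.paths)
    mean = np.array([fit.paths.as_dict()[p] for p in PATH_NAMES])
    rng = np.random.default_rng(seed)
    samples = rng.multivariate_normal(mean, fit.coef_cov, size=draws, method="svd")

    vals = np.empty((draws, len(labels)))
    for i in range(draws):
        d = dict(zip(PATH_NAMES, samples[i]))
        _, vals[i] = _effect_vector(d)

    out = []
    for j, label in enumerate(labels):
        out.append(CIResult(
            label=label, estimate=float(point[j]),
            lower=float(np.quantile(vals[:, j], alpha / 2)),
            upper=float(np.quantile(vals[:, j], 1 - alpha / 2)),
            method="monte-carlo", replicates=draws, seed=seed,
        ))
    return out
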