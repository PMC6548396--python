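"""Synthetic dyadic data from the APIMeM structural equations.

The generator draws the exogenous pair (x1, x2) from a bivariate normal,
propagates it through the twelve structural paths with correlated mediator
errors and correlated outcome errors, and returns a dyad dataset.  It exists
so that every downstream stage -- scoring, pairing, estimation, effect
decomposition, resampling inference -- can be exercised and validated without
access to the original study data, which were never deposited.

Defaults (:func:`default_config`) place the generator at the study's regime:
the twelve paths at the published estimates, exogenous means/SDs at the
printed descriptives (83.1 +/- 22 and 78.7 +/- 22.2), endogenous means
matched to the printed scale means, and the unprinted quantities set to
plausible dyadic values -- corr(x1, x2) = 0.3, residual correlations 0.3,
and residual variances solved so that every structural equation has
R^2 = 0.17, the study's overall equation-level fit.

Scores are continuous by default (best for estimator testing); pass
``discretize=True`` to round and clip them to the questionnaire sum ranges,
and use :func:`simulate_items` for an individual-level 62-item table.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import reference, scoring
from .dyads import DyadDataset, from_wide
from .errors import ConfigError
from .estimate import PathCoefficients

SCALE_FOR_VARIABLE = {
    "x": "social_support", "m": "family_health", "y": "family_functioning",
}


@dataclass
class ResidualBlock:
    """Variances and covariance of a correlated error pair."""

    var1: float
    var2: float
    cov: float

    def matrix(self) -> np.ndarray:
        return np.array([[self.var1, self.cov], [self.cov, self.var2]])

    def validate(self, name: str) -> None:
        m = self.matrix()
        if np.any(np.linalg.eigvalsh(m) <= 0):
            raise ConfigError(f"{name} covariance matrix is not positive definite: {m.tolist()}")


@dataclass
class SimulationConfig:
    n_dyads: int
    paths: PathCoefficients
    exog_mean: tuple = (0.0, 0.0)
    exog_sd: tuple = (1.0, 1.0)
    exog_corr: float = 0.0
    mediator_resid: ResidualBlock = field(default_factory=lambda: ResidualBlock(1.0, 1.0, 0.0))
    outcome_resid: ResidualBlock = field(default_factory=lambda: ResidualBlock(1.0, 1.0, 0.0))
    seed: int = 0
    mode: str = "score"          # "score" | "item"
    discretize: bool = False     # round + clip scores to questionnaire ranges

    def validate(self) -> None:
        if self.n_dyads <= 0:
            raise ConfigError("n_dyads must be positive")
        if not all(s > 0 for s in self.exog_sd):
            raise ConfigError("exogenous SDs must be positive")
        if not -1 < self.exog_corr < 1:
            raise ConfigError("exogenous correlation must lie in (-1, 1)")
        self.mediator_resid.validate("mediator residual")
        self.outcome_resid.validate("outcome residual")
        if self.mode not in ("score", "item"):
            raise ConfigError(f"unknown mode {self.mode!r}")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["paths"] = PathCoefficients(**d["paths"])
        d["mediator_resid"] = ResidualBlock(**d["mediator_resid"])
        d["outcome_resid"] = ResidualBlock(**d["outcome_resid"])
        d["exog_mean"] = tuple(d["exog_mean"])
        d["exog_sd"] = tuple(d["exog_sd"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def exog_covariance(config: SimulationConfig) -> np.ndarray:
    s1, s2 = config.exog_sd
    c = config.exog_corr * s1 * s2
    return np.array([[s1 * s1, c], [c, s2 * s2]])


def error_covariance(config: SimulationConfig) -> np.ndarray:
    """Block-diagonal covariance of (x-deviation, e_m, e_y): 6x6."""
    psi = np.zeros((6, 6))
    psi[:2, :2] = exog_covariance(config)
    psi[2:4, 2:4] = config.mediator_resid.matrix()
    psi[4:6, 4:6] = config.outcome_resid.matrix()
    return psi


def implied_covariance(config: SimulationConfig) -> np.ndarray:
    """Model-implied covariance of (x1, x2, m1, m2, y1, y2)."""
    T = np.eye(6) - config.paths.structural_matrix()
    Tinv = np.linalg.inv(T)
    return Tinv @ error_covariance(config) @ Tinv.T


def implied_means(config: SimulationConfig) -> np.ndarray:
    T = np.eye(6) - config.paths.structural_matrix()
    alpha = np.array([
        config.exog_mean[0], config.exog_mean[1],
        config.paths.alpha_m1, config.paths.alpha_m2,
        config.paths.alpha_y1, config.paths.alpha_y2,
    ])
    return np.linalg.solve(T, alpha)


def implied_overall_r2(config: SimulationConfig) -> float:
    """Determinant-based R^2 of the endogenous block implied by the config."""
    sigma = implied_covariance(config)
    psi = error_covariance(config)
    return 1.0 - np.linalg.det(psi[2:, 2:]) / np.linalg.det(sigma[2:, 2:])


def default_config(
    n_dyads: int = reference.N_DYADS,
    seed: int = 0,
    r2_per_equation: float = reference.STUDY_R2,
    exog_corr: float = 0.3,
    resid_corr: float = 0.3,
    **overrides,
) -> SimulationConfig:
    """The study-regime generator configuration.

    Residual variances are solved so each structural equation explains
    ``r2_per_equation`` of its variance given the published paths and the
    printed exogenous SDs; intercepts are set so that the implied means of
    (m1, m2, y1, y2) match the printed scale means.
    """
    paths = dataclasses.replace(reference.STUDY_PATHS)
    exog_mean, exog_sd = reference.study_exog_moments()
    d = paths.as_dict()

    sx = np.array([[exog_sd[0] ** 2, exog_corr * exog_sd[0] * exog_sd[1]],
                   [exog_corr * exog_sd[0] * exog_sd[1], exog_sd[1] ** 2]])
    # mediator equations: explained variance = beta' Sx beta
    bm1 = np.array([d["a_A1"], d["a_P1"]])
    bm2 = np.array([d["a_P2"], d["a_A2"]])
    expl_m = np.array([bm1 @ sx @ bm1, bm2 @ sx @ bm2])
    var_em = expl_m * (1 - r2_per_equation) / r2_per_equation
    med = ResidualBlock(var_em[0], var_em[1], resid_corr * np.sqrt(var_em[0] * var_em[1]))

    # outcome equations: regressors (x1, x2, m1, m2) -- implied 4x4 covariance
    probe = SimulationConfig(n_dyads=1, paths=paths, exog_mean=tuple(exog_mean),
                             exog_sd=tuple(exog_sd), exog_corr=exog_corr,
                             mediator_resid=med)
    s4 = implied_covariance(probe)[:4, :4]
    by1 = np.array([d["cp_A1"], d["cp_P1"], d["b_A1"], d["b_P1"]])
    by2 = np.array([d["cp_P2"], d["cp_A2"], d["b_P2"], d["b_A2"]])
    expl_y = np.array([by1 @ s4 @ by1, by2 @ s4 @ by2])
    var_ey = expl_y * (1 - r2_per_equation) / r2_per_equation
    out = ResidualBlock(var_ey[0], var_ey[1], resid_corr * np.sqrt(var_ey[0] * var_ey[1]))

    # intercepts so implied endogenous means hit the printed scale means
    mu_target = np.concatenate([exog_mean, reference.study_endogenous_means()])
    T = np.eye(6) - paths.structural_matrix()
    alpha = T @ mu_target
    paths.alpha_m1, paths.alpha_m2 = alpha[2], alpha[3]
    paths.alpha_y1, paths.alpha_y2 = alpha[4], alpha[5]

    cfg = SimulationConfig(
        n_dyads=n_dyads, paths=paths,
        exog_mean=tuple(exog_mean), exog_sd=tuple(exog_sd), exog_corr=exog_corr,
        mediator_resid=med, outcome_resid=out, seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def _discretize(wide: np.ndarray) -> np.ndarray:
    wide = np.rint(wide)
    for j, scale in enumerate(("social_support", "social_support",
                               "family_health", "family_health",
                               "family_functioning", "family_functioning")):
        lo, hi = scoring.SCALE_RANGES[scale]
        wide[:, j] = np.clip(wide[:, j], lo, hi)
    return wide


def simulate_scores(config: SimulationConfig, seed: int | None = None) -> DyadDataset:
    """Draw a dyad dataset from the structural equations; deterministic given
    the seed (``seed`` argument overrides ``config.seed``)."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_dyads
    d = config.paths.as_dict()

    x = rng.multivariate_normal(config.exog_mean, exog_covariance(config), size=n)
    em = rng.multivariate_normal(np.zeros(2), config.mediator_resid.matrix(), size=n)
    ey = rng.multivariate_normal(np.zeros(2), config.outcome_resid.matrix(), size=n)

    m1 = d["alpha_m1"] + d["a_A1"] * x[:, 0] + d["a_P1"] * x[:, 1] + em[:, 0]
    m2 = d["alpha_m2"] + d["a_A2"] * x[:, 1] + d["a_P2"] * x[:, 0] + em[:, 1]
    y1 = (d["alpha_y1"] + d["cp_A1"] * x[:, 0] + d["cp_P1"] * x[:, 1]
          + d["b_A1"] * m1 + d["b_P1"] * m2 + ey[:, 0])
    y2 = (d["alpha_y2"] + d["cp_A2"] * x[:, 1] + d["cp_P2"] * x[:, 0]
          + d["b_A2"] * m2 + d["b_P2"] * m1 + ey[:, 1])

    wide = np.column_stack([x[:, 0], x[:, 1], m1, m2, y1, y2])
    if config.discretize:
        wide = _discretize(wide)
    return from_wide(wide)


def symmetrized(config: SimulationConfig) -> SimulationConfig:
    """Config with the six patient/relative path pairs forced equal and fully
    symmetric exogenous and residual structure -- the distinguishability null."""
    d = config.paths.as_dict()
    pairs = (("a_A1", "a_A2"), ("a_P1", "a_P2"), ("b_A1", "b_A2"),
             ("b_P1", "b_P2"), ("cp_A1", "cp_A2"), ("cp_P1", "cp_P2"),
             ("alpha_m1", "alpha_m2"), ("alpha_y1", "alpha_y2"))
    for p1, p2 in pairs:
        mean = 0.5 * (d[p1] + d[p2])
        d[p1] = d[p2] = mean
    mean_sd = float(np.mean(config.exog_sd))
    med = config.mediator_resid
    vm = 0.5 * (med.var1 + med.var2)
    out = config.outcome_resid
    vy = 0.5 * (out.var1 + out.var2)
    return dataclasses.replace(
        config,
        paths=PathCoefficients(**d),
        exog_mean=(float(np.mean(config.exog_mean)),) * 2,
        exog_sd=(mean_sd, mean_sd),
        mediator_resid=ResidualBlock(vm, vm, med.cov * vm / np.sqrt(med.var1 * med.var2)),
        outcome_resid=ResidualBlock(vy, vy, out.cov * vy / np.sqrt(out.var1 * out.var2)),
    )


def simulate_null_roles(config: SimulationConfig, seed: int | None = None) -> DyadDataset:
    """Simulate under the role-exchangeable null of the distinguishability
    test (all six path pairs equal, symmetric covariance structure)."""
    return simulate_scores(symmetrized(config), seed=seed)


# ---------------------------------------------------------------------------
# item-level simulation

def _spread_items(total: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Distribute an integer scale sum in [k, 6k] over k items, each in 1..6."""
    q, r = divmod(int(total) - k, k)
    vals = np.full(k, 1 + q, dtype=int)
    if r:
        vals[rng.choice(k, size=r, replace=False)] += 1
    return vals


def simulate_items(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Individual-level 62-item table whose scale sums reproduce the
    (discretized) score-level simulation.

    Scores are rounded and clipped to the questionnaire ranges, then each
    scale sum is spread over its items (ill-being items are emitted
    reverse-coded, so default scoring recovers the targeted sums exactly).
    Returns one row per person: respondent_id, dyad_id, role, item_01..62.
    """
    config.validate()
    base_seed = config.seed if seed is None else seed
    scores = simulate_scores(config, seed=base_seed)
    rng = np.random.default_rng([base_seed, 62])

    rows = []
    for rec in scores.records:
        for role, (xs, ms, ys) in (("patient", (rec.x1, rec.m1, rec.y1)),
                                   ("nearest_relative", (rec.x2, rec.m2, rec.y2))):
            targets = {}
            for scale, raw in (("social_support", xs), ("family_health", ms),
                               ("family_functioning", ys)):
                lo, hi = scoring.SCALE_RANGES[scale]
                targets[scale] = int(np.clip(np.rint(raw), lo, hi))
            items = np.empty(scoring.N_ITEMS, dtype=int)
            start = 0
            for scale in scoring.SCALE_ORDER:
                k = sum(n for _, n in scoring.SUBSCALE_LAYOUT[scale])
                items[start:start + k] = _spread_items(targets[scale], k, rng)
                start += k
            for i in scoring.ILL_BEING_INDICES:   # emit negatively keyed
                items[i] = 7 - items[i]
            rows.append({
                "respondent_id": f"{rec.dyad_id}_{'p' if role == 'patient' else 'r'}",
                "dyad_id": rec.dyad_id,
                "role": role,
                **{f"item_{i + 1:02d}": int(v) for i, v in enumerate(items)},
            })
    return pd.DataFrame(rows)


def write_provenance(config: SimulationConfig, path) -> None:
    """Sidecar JSON recording the exact generator config and seed."""
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
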