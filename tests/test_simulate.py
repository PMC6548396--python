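"""Synthetic dyad generator: determinism, moment targets, item round trips."""

import numpy as np
import pandas as pd
import pytest

import dyadmed as dm
from dyadmed import reference, scoring
from dyadmed.dyads import build_dyads, to_wide
from dyadmed.errors import ConfigError
from dyadmed.simulate import (
    ResidualBlock,
    SimulationConfig,
    implied_covariance,
    implied_means,
    symmetrized,
)


def test_same_seed_bit_identical(study_config):
    a, _ = to_wide(dm.simulate_scores(study_config, seed=4))
    b, _ = to_wide(dm.simulate_scores(study_config, seed=4))
    assert np.array_equal(a, b)
    c, _ = to_wide(dm.simulate_scores(study_config, seed=5))
    assert not np.array_equal(a, c)


def test_degenerate_noise_yields_intercepts():
    """Zero paths and (near-)zero noise: every endogenous value is its intercept."""
    paths = dm.PathCoefficients(
        **{p: 0.0 for p in ("a_A1", "a_P1", "a_A2", "a_P2", "b_A1", "b_P1",
                            "b_A2", "b_P2", "cp_A1", "cp_P1", "cp_A2", "cp_P2")},
        alpha_m1=108.7, alpha_m2=106.9, alpha_y1=90.6, alpha_y2=89.6)
    tiny = ResidualBlock(1e-12, 1e-12, 0.0)
    cfg = SimulationConfig(n_dyads=50, paths=paths, exog_mean=(83.1, 78.7),
                           exog_sd=(22.0, 22.2), mediator_resid=tiny,
                           outcome_resid=tiny, seed=1)
    wide, _ = to_wide(dm.simulate_scores(cfg))
    np.testing.assert_allclose(wide[:, 2], 108.7, atol=1e-6)
    np.testing.assert_allclose(wide[:, 3], 106.9, atol=1e-6)
    np.testing.assert_allclose(wide[:, 4], 90.6, atol=1e-6)
    np.testing.assert_allclose(wide[:, 5], 89.6, atol=1e-6)


def test_exogenous_moments_match_published_descriptives(study_config):
    """At n = 312, sample means/SDs of support within 3 SE of 83.1+/-22, 78.7+/-22.2."""
    wide, _ = to_wide(dm.simulate_scores(study_config, seed=8))
    n = study_config.n_dyads
    for j, (mu, sd) in enumerate([(83.1, 22.0), (78.7, 22.2)]):
        assert abs(wide[:, j].mean() - mu) < 3 * sd / np.sqrt(n)
        assert abs(wide[:, j].std(ddof=1) - sd) < 3 * sd / np.sqrt(2 * (n - 1))


def test_large_sample_regression_recovers_mediator_paths(study_config):
    """Empirical regression of m1 on (x1, x2) recovers (a_A1, a_P1)."""
    cfg = dm.default_config(n_dyads=100_000, seed=13)
    wide, _ = to_wide(dm.simulate_scores(cfg))
    X = np.column_stack([np.ones(cfg.n_dyads), wide[:, 0], wide[:, 1]])
    beta = np.linalg.lstsq(X, wide[:, 2], rcond=None)[0]
    assert abs(beta[1] - cfg.paths.a_A1) < 0.01
    assert abs(beta[2] - cfg.paths.a_P1) < 0.01


def test_implied_covariance_matches_empirical(study_config):
    cfg = dm.default_config(n_dyads=200_000, seed=21)
    wide, _ = to_wide(dm.simulate_scores(cfg))
    S = np.cov(wide, rowvar=False, ddof=1)
    sigma = implied_covariance(cfg)
    assert np.max(np.abs(S - sigma) / np.abs(sigma).max()) < 0.02
    np.testing.assert_allclose(wide.mean(axis=0), implied_means(cfg), rtol=0.01)


def test_non_positive_definite_residual_rejected(study_config):
    import dataclasses

    bad = dataclasses.replace(study_config,
                              mediator_resid=ResidualBlock(1.0, 1.0, 2.0))
    with pytest.raises(ConfigError, match="positive definite"):
        dm.simulate_scores(bad)


def test_null_roles_swap_symmetry(study_config):
    """Under the symmetrized config the two roles are exchangeable: swapping
    roles leaves the implied moments identical."""
    cfg = symmetrized(study_config)
    sigma = implied_covariance(cfg)
    swap = np.array([1, 0, 3, 2, 5, 4])
    np.testing.assert_allclose(sigma, sigma[np.ix_(swap, swap)], atol=1e-12)
    mu = implied_means(cfg)
    np.testing.assert_allclose(mu, mu[swap], atol=1e-12)


def test_null_roles_constrained_fit_near_perfect(study_config):
    """On one large role-exchangeable dataset the role-equality model fits:
    chi2/df near 1 and RMSEA near 0."""
    ds = dm.simulate_null_roles(dm.default_config(n_dyads=10_000), seed=17)
    _, fs = dm.fit_constrained(ds)
    assert fs.df == 6
    assert fs.chi2 / fs.df < 3.0
    assert fs.rmsea < 0.02


def test_item_table_shape_and_range(study_config):
    cfg = dm.default_config(n_dyads=30, seed=2)
    df = dm.simulate_items(cfg)
    assert len(df) == 60                       # two members per dyad
    items = df[[f"item_{i:02d}" for i in range(1, 63)]].to_numpy()
    assert items.min() >= 1 and items.max() <= 6


def test_item_scores_roundtrip_through_scoring(study_config):
    """score_fafhes over simulate_items reproduces the discretized score-level
    simulation exactly (the clipping tolerance is absorbed by discretization)."""
    import dataclasses

    cfg = dm.default_config(n_dyads=40, seed=6)
    df = dm.simulate_items(cfg)
    responses = [
        scoring.FafhesResponse(
            respondent_id=r["respondent_id"], dyad_id=r["dyad_id"], role=r["role"],
            items=tuple(int(r[f"item_{i:02d}"]) for i in range(1, 63)))
        for _, r in df.iterrows()
    ]
    scored = scoring.scores_frame([scoring.score_fafhes(r) for r in responses])
    rebuilt = build_dyads(scored)
    wide_items, _ = to_wide(rebuilt)

    disc = dataclasses.replace(cfg, discretize=True)
    wide_scores, _ = to_wide(dm.simulate_scores(disc, seed=6))
    np.testing.assert_array_equal(wide_items, wide_scores)


def test_minimum_score_target_gives_all_ones():
    """A score at the scale minimum can only be produced by all-1 items."""
    from dyadmed.simulate import _spread_items

    rng = np.random.default_rng(0)
    assert (_spread_items(20, 20, rng) == 1).all()
    assert (_spread_items(120, 20, rng) == 6).all()


def test_injected_incomplete_dyads_are_excluded(study_config):
    """Blanking one item for 8 patients drops exactly those 8 dyads."""
    cfg = dm.default_config(n_dyads=320, seed=3)
    df = dm.simulate_items(cfg)
    rng = np.random.default_rng(99)
    broken = rng.choice(df["dyad_id"].unique(), size=8, replace=False)
    df = df.copy()
    mask = df["dyad_id"].isin(broken) & (df["role"] == "patient")
    df.loc[mask, "item_10"] = np.nan

    report = dm.validate_batch([
        scoring.FafhesResponse(
            respondent_id=r["respondent_id"], dyad_id=r["dyad_id"], role=r["role"],
            items=tuple(r[f"item_{i:02d}"] for i in range(1, 63)))
        for _, r in df.iterrows()
    ])
    scored = scoring.scores_frame([scoring.score_fafhes(r) for r in report.valid])
    ds = build_dyads(scored)
    assert ds.n == 312
    assert len(ds.exclusions) == 8


def test_config_yaml_roundtrip(tmp_path, study_config):
    path = tmp_path / "cfg.yaml"
    study_config.save(path)
    back = SimulationConfig.load(path)
    assert back.to_dict() == study_config.to_dict()
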