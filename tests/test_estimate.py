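"""APIMeM estimation: closed-form saturated fit, constrained ML, fit indices."""

import dataclasses

import numpy as np
import pytest

import dyadmed as dm
from dyadmed.dyads import to_wide
from dyadmed.errors import EstimationError, UndefinedStatisticError
from dyadmed.estimate import PATH_NAMES, ROLE_EQUALITY_CONSTRAINTS
from dyadmed.simulate import ResidualBlock


def _paths_vec(paths):
    d = paths.as_dict()
    return np.array([d[p] for p in PATH_NAMES])


def test_vanishing_noise_recovers_truth():
    """As residual noise vanishes the fit recovers the generating paths to
    numerical precision.  The mediator noise must dominate the outcome noise:
    with mediators exactly collinear with the predictors the b and c' paths
    would be unidentified."""
    cfg = dataclasses.replace(dm.default_config(n_dyads=60),
                              mediator_resid=ResidualBlock(1e-6, 1e-6, 0.0),
                              outcome_resid=ResidualBlock(1e-14, 1e-14, 0.0))
    fit = dm.fit_saturated(dm.simulate_scores(cfg, seed=2))
    np.testing.assert_allclose(_paths_vec(fit.paths), _paths_vec(cfg.paths), atol=1e-4)
    assert fit.r2_overall > 1 - 1e-6
    assert all(v > 1 - 1e-6 for v in fit.r2_per_equation.values())


def test_saturated_fit_matches_normal_equations_oracle(study_config):
    """Independently coded normal equations per structural equation."""
    wide, _ = to_wide(dm.simulate_scores(study_config, seed=14))
    fit = dm.fit_saturated(wide)
    n = wide.shape[0]
    Xm = np.column_stack([np.ones(n), wide[:, 0], wide[:, 1]])
    Xo = np.column_stack([np.ones(n), wide[:, :2], wide[:, 2:4]])
    bm1 = np.linalg.solve(Xm.T @ Xm, Xm.T @ wide[:, 2])
    bm2 = np.linalg.solve(Xm.T @ Xm, Xm.T @ wide[:, 3])
    by1 = np.linalg.solve(Xo.T @ Xo, Xo.T @ wide[:, 4])
    by2 = np.linalg.solve(Xo.T @ Xo, Xo.T @ wide[:, 5])
    d = fit.paths.as_dict()
    assert abs(d["a_A1"] - bm1[1]) < 1e-10
    assert abs(d["a_P1"] - bm1[2]) < 1e-10
    assert abs(d["a_P2"] - bm2[1]) < 1e-10
    assert abs(d["a_A2"] - bm2[2]) < 1e-10
    assert abs(d["cp_A1"] - by1[1]) < 1e-10
    assert abs(d["b_A1"] - by1[3]) < 1e-10
    assert abs(d["b_P1"] - by1[4]) < 1e-10
    assert abs(d["cp_A2"] - by2[2]) < 1e-10
    assert abs(d["b_A2"] - by2[4]) < 1e-10
    assert abs(d["b_P2"] - by2[3]) < 1e-10


def test_rank_deficient_design_names_column(study_config):
    wide, _ = to_wide(dm.simulate_scores(study_config, seed=3))
    wide[:, 1] = 5.0  # constant x2
    with pytest.raises(EstimationError, match="x2"):
        dm.fit_saturated(wide)


def test_too_few_dyads_raises(study_config):
    wide, _ = to_wide(dm.simulate_scores(study_config, seed=3))
    with pytest.raises(EstimationError):
        dm.fit_saturated(wide[:5])


def test_estimates_invariant_to_row_order(study_config):
    wide, _ = to_wide(dm.simulate_scores(study_config, seed=4))
    fit1 = dm.fit_saturated(wide)
    rng = np.random.default_rng(0)
    fit2 = dm.fit_saturated(wide[rng.permutation(len(wide))])
    np.testing.assert_allclose(_paths_vec(fit1.paths), _paths_vec(fit2.paths), atol=1e-10)


def test_role_relabel_symmetry(study_config):
    """Swapping roles in the data swaps the role-1/role-2 path names."""
    wide, _ = to_wide(dm.simulate_scores(study_config, seed=5))
    swapped = wide[:, [1, 0, 3, 2, 5, 4]]
    d1 = dm.fit_saturated(wide).paths.as_dict()
    d2 = dm.fit_saturated(swapped).paths.as_dict()
    for a, b in ROLE_EQUALITY_CONSTRAINTS:
        assert abs(d1[a] - d2[b]) < 1e-10
        assert abs(d1[b] - d2[a]) < 1e-10


def test_se_shrink_like_root_n():
    """Average SE scales ~ 1/sqrt(n) across n = 100, 400, 1600."""
    means = []
    for n in (100, 400, 1600):
        ses = []
        for rep in range(10):
            cfg = dm.default_config(n_dyads=n)
            fit = dm.fit_saturated(dm.simulate_scores(cfg, seed=1000 * n + rep))
            ses.append(np.mean([fit.se[p] for p in PATH_NAMES]))
        means.append(np.mean(ses))
    r1 = means[0] / means[1]
    r2 = means[1] / means[2]
    assert 1.7 < r1 < 2.3 and 1.7 < r2 < 2.3


def test_empty_constraints_is_saturated(study_config):
    ds = dm.simulate_scores(study_config, seed=6)
    sat = dm.fit_saturated(ds)
    con, fs = dm.fit_constrained(ds, constraints=())
    assert fs.df == 0
    assert fs.chi2 < 1e-6
    assert fs.p == 1.0
    np.testing.assert_allclose(_paths_vec(con.paths), _paths_vec(sat.paths), atol=1e-5)


def test_role_equality_constraints_give_df_6(study_config):
    ds = dm.simulate_scores(study_config, seed=7)
    _, fs = dm.fit_constrained(ds)
    assert fs.df == 6
    assert fs.chi2 > 0


def test_chi2_monotone_in_nested_constraints(study_config):
    ds = dm.simulate_scores(study_config, seed=8)
    subsets = [ROLE_EQUALITY_CONSTRAINTS[:k] for k in (0, 2, 4, 6)]
    chis = [dm.fit_constrained(ds, constraints=c)[1].chi2 for c in subsets]
    assert all(b >= a - 1e-8 for a, b in zip(chis, chis[1:]))


def test_constrained_null_distribution(study_config):
    """Under the role-exchangeable null, chi2(6) p-values look uniform:
    mean near 0.5 and rejection near alpha over 100 replicates."""
    ps = []
    for i in range(100):
        ds = dm.simulate_null_roles(study_config, seed=5000 + i)
        _, fs = dm.fit_constrained(ds)
        ps.append(fs.p)
    ps = np.array(ps)
    assert abs(ps.mean() - 0.5) < 0.1
    assert 0.0 <= np.mean(ps < 0.05) <= 0.12


def test_unknown_constraint_name_raises(study_config):
    ds = dm.simulate_scores(study_config, seed=9)
    with pytest.raises(EstimationError, match="zz"):
        dm.fit_constrained(ds, constraints=[("a_A1", "zz")])


@pytest.mark.parametrize(
    "chi2, df, n, expected",
    [(14.23, 6, 312, 0.066), (6.0, 6, 312, 0.0), (0.0, 3, 100, 0.0)],
)
def test_rmsea_values(chi2, df, n, expected):
    assert dm.rmsea(chi2, df, n) == pytest.approx(expected, abs=5e-4)


def test_rmsea_formula_oracle(rng):
    for _ in range(50):
        chi2 = float(rng.uniform(0, 50))
        df = int(rng.integers(1, 20))
        n = int(rng.integers(10, 2000))
        expected = np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))
        assert dm.rmsea(chi2, df, n) == pytest.approx(expected, rel=1e-12)


def test_rmsea_undefined_at_zero_df():
    with pytest.raises(UndefinedStatisticError):
        dm.rmsea(3.0, 0, 100)


def test_overall_r2_null_paths_near_zero():
    zero = dm.PathCoefficients(**{p: 0.0 for p in PATH_NAMES})
    from dyadmed.simulate import SimulationConfig

    cfg = SimulationConfig(n_dyads=50_000, paths=zero, exog_mean=(0, 0),
                           exog_sd=(1, 1), exog_corr=0.3,
                           mediator_resid=ResidualBlock(1, 1, 0.3),
                           outcome_resid=ResidualBlock(1, 1, 0.3), seed=5)
    fit = dm.fit_saturated(dm.simulate_scores(cfg))
    assert abs(dm.overall_r2(fit)) < 0.01


def test_overall_r2_consistent_with_generator(study_config):
    """Estimated determinant-based R^2 tracks the config-implied value."""
    from dyadmed.simulate import implied_overall_r2

    cfg = dm.default_config(n_dyads=50_000, seed=31)
    fit = dm.fit_saturated(dm.simulate_scores(cfg))
    assert dm.overall_r2(fit) == pytest.approx(implied_overall_r2(cfg), abs=0.02)
    # per-equation R^2 at the generator's calibration target
    for v in fit.r2_per_equation.values():
        assert v == pytest.approx(0.17, abs=0.02)
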