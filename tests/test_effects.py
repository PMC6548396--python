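"""Effect decomposition: published worked example, DAG-enumeration oracle,
additivity identities and proportion mediated."""

import numpy as np
import pytest

import dyadmed as dm
from dyadmed.effects import EFFECT_LABELS, decompose, effect_values, enumerate_paths
from dyadmed.errors import UndefinedStatisticError
from dyadmed.estimate import PATH_NAMES

from conftest import random_paths


def test_published_worked_example(study_paths):
    """The decomposition of the published path estimates reproduces the
    printed totals and total indirect effects."""
    t = decompose(study_paths)
    assert t.get("relative", "actor").total_ie == pytest.approx(0.139, abs=5e-4)
    assert t.get("relative", "partner").total_ie == pytest.approx(-0.024, abs=5e-4)
    assert t.get("patient", "actor").total == pytest.approx(0.153, abs=1e-3)
    assert t.get("relative", "actor").total == pytest.approx(0.137, abs=1e-3)
    assert t.get("patient", "actor").total_ie == pytest.approx(0.048, abs=1e-3)
    assert t.get("patient", "partner").total_ie == pytest.approx(0.063, abs=1e-3)
    assert t.get("relative", "partner").total == pytest.approx(-0.026, abs=1e-3)


def test_all_partner_paths_zero_degenerates_to_two_mediations():
    d = {p: 0.0 for p in PATH_NAMES}
    d.update(a_A1=0.2, a_A2=0.3, b_A1=0.5, b_A2=0.4, cp_A1=0.1, cp_A2=0.2)
    t = decompose(dm.PathCoefficients(**d))
    assert t.get("patient", "partner").total == 0.0
    assert t.get("relative", "partner").total == 0.0
    assert t.get("patient", "actor").total == pytest.approx(0.2 * 0.5 + 0.1)
    assert t.get("relative", "actor").total == pytest.approx(0.3 * 0.4 + 0.2)


def test_additivity_identities_exact(rng):
    """total - direct - sum(simple IEs) == 0 exactly, all four pathways."""
    for _ in range(100):
        t = decompose(random_paths(rng))
        for role in ("patient", "relative"):
            for pathway in ("actor", "partner"):
                c = t.get(role, pathway)
                assert abs(c.total - c.direct - sum(c.simple_ies.values())) <= 1e-12
                assert c.total_ie == sum(c.simple_ies.values())


def test_enumeration_route_inventory(study_paths):
    """x2 -> y1 has exactly the three published routes with their products."""
    routes = dict(enumerate_paths(study_paths, "x2", "y1"))
    assert set(routes) == {("x2", "m2", "y1"), ("x2", "m1", "y1"), ("x2", "y1")}
    assert routes[("x2", "m2", "y1")] == pytest.approx(0.180 * 0.236)
    assert routes[("x2", "m1", "y1")] == pytest.approx(0.038 * 0.556)
    assert routes[("x2", "y1")] == pytest.approx(-0.020)
    # totals match the patient-partner decomposition cell
    cell = decompose(study_paths).get("patient", "partner")
    indirect = sum(v for r, v in routes.items() if len(r) == 3)
    assert indirect == pytest.approx(cell.total_ie, abs=1e-12)


def test_enumeration_all_zero():
    zero = dm.PathCoefficients(**{p: 0.0 for p in PATH_NAMES})
    assert all(v == 0.0 for _, v in enumerate_paths(zero, "x1", "y1"))


SOURCE_SINK = {
    ("patient", "actor"): ("x1", "y1"),
    ("relative", "actor"): ("x2", "y2"),
    ("patient", "partner"): ("x2", "y1"),
    ("relative", "partner"): ("x1", "y2"),
}


def test_decompose_agrees_with_enumeration_oracle(rng):
    """1000 random coefficient draws: graph enumeration equals decompose."""
    for _ in range(1000):
        paths = random_paths(rng)
        t = decompose(paths)
        for (role, pathway), (src, snk) in SOURCE_SINK.items():
            routes = enumerate_paths(paths, src, snk)
            direct = sum(v for r, v in routes if len(r) == 2)
            indirect = sum(v for r, v in routes if len(r) > 2)
            cell = t.get(role, pathway)
            assert abs(direct - cell.direct) < 1e-12
            assert abs(indirect - cell.total_ie) < 1e-12
            assert abs(direct + indirect - cell.total) < 1e-12


def test_fast_effect_vector_matches_table(rng):
    paths = random_paths(rng)
    flat = decompose(paths).flat()
    vec = effect_values(paths.as_dict())
    for label, value in zip(EFFECT_LABELS, vec):
        assert flat[label] == value


def test_decompose_on_zero_noise_fit_reproduces_generator(study_config):
    """decompose(fit_saturated) on noiseless data equals decompose(truth)."""
    import dataclasses

    from dyadmed.simulate import ResidualBlock

    cfg = dataclasses.replace(study_config, n_dyads=80,
                              mediator_resid=ResidualBlock(1e-6, 1e-6, 0.0),
                              outcome_resid=ResidualBlock(1e-14, 1e-14, 0.0))
    fit = dm.fit_saturated(dm.simulate_scores(cfg, seed=12))
    got = effect_values(fit.paths.as_dict())
    want = effect_values(cfg.paths.as_dict())
    np.testing.assert_allclose(got, want, atol=1e-4)


def test_missing_path_named_in_error():
    with pytest.raises(KeyError, match="b_P2"):
        decompose({p: 0.1 for p in PATH_NAMES if p != "b_P2"})


def test_proportion_mediated_complete_mediation():
    d = {p: 0.0 for p in PATH_NAMES}
    d.update(a_A1=0.4, b_A1=0.5)   # single active route, zero direct effect
    t = decompose(dm.PathCoefficients(**d))
    assert dm.proportion_mediated(t, "patient", "actor") == pytest.approx(100.0)


def test_proportion_mediated_known_ratio():
    d = {p: 0.0 for p in PATH_NAMES}
    d.update(a_A1=0.5, b_A1=0.4, cp_A1=0.2)  # IE = 0.2, total = 0.4
    t = decompose(dm.PathCoefficients(**d))
    assert dm.proportion_mediated(t, "patient", "actor") == pytest.approx(50.0)


def test_proportion_mediated_published_narrative(study_paths):
    """Near-complete mediation for the relative actor pathway (high 90s%)."""
    t = decompose(study_paths)
    pct = dm.proportion_mediated(t, "relative", "actor")
    assert 90 < pct < 105  # printed inputs are rounded; ~98.7 from these


def test_proportion_mediated_zero_total_errors():
    zero = dm.PathCoefficients(**{p: 0.0 for p in PATH_NAMES})
    with pytest.raises(UndefinedStatisticError):
        dm.proportion_mediated(decompose(zero), "patient", "actor")


def test_proportion_mediated_flags_inconsistent_mediation():
    d = {p: 0.0 for p in PATH_NAMES}
    d.update(a_A1=0.5, b_A1=0.4, cp_A1=-0.1)  # IE 0.2, total 0.1 -> 200%
    t = decompose(dm.PathCoefficients(**d))
    with pytest.warns(UserWarning, match="outside"):
        pct = dm.proportion_mediated(t, "patient", "actor")
    assert pct == pytest.approx(200.0)
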