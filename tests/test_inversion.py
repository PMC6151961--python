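import numpy as np
import pytest

from iqspr.data_model import DescriptorTable, ReferenceProperties, ValidationError
from iqspr.diagnostics import diagnostics_report
from iqspr.inversion import (
    InverterConfig,
    InversionProblem,
    build_problem,
    invert,
    objective,
)
from iqspr.pls_core import NipalsPLS
from iqspr.preprocess import kennard_stone_split
from iqspr.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="module")
def fitted_setting():
    """Low-noise rank-2 dataset, fitted model, and an in-domain test compound."""
    spec = SyntheticSpec(n_compounds=45, n_descriptors=7, latent_dim=2,
                         n_informative=7, n_binary=1, noise_sd_x=0.05,
                         noise_sd_y=0.05, seed=3)
    desc, props, truth = generate(spec)
    split = kennard_stone_split(desc, 33)
    tr = desc.reorder(split.train_ids)
    te = desc.reorder(split.test_ids)
    ptr = props.select(split.train_ids)
    pte = props.select(split.test_ids)
    model = NipalsPLS(n_components=2).fit(tr.values, ptr.Y)
    rep = diagnostics_report(model, tr.values, ptr.Y, te.values, pte.Y,
                             ids=te.compound_ids)
    in_domain = rep.table[rep.table.in_domain].index[0]
    idx = te.compound_ids.index(in_domain)
    return model, tr, te, idx


def test_critical_limits_enter_the_problem(fitted_setting):
    model, tr, te, idx = fitted_setting
    ref = ReferenceProperties(1.0, 1.0)
    prob = build_problem(model, ref, tr, alpha=0.05)
    # c1 is the F-based Hotelling limit for (A, n_train)
    from iqspr.diagnostics import t2_critical
    assert prob.c1 == pytest.approx(t2_critical(2, 33, 0.05))
    assert prob.c2 > 0
    # tightening alpha toward 1 collapses the score ellipsoid
    tight = build_problem(model, ref, tr, alpha=0.999)
    assert tight.c1 < 0.05 * prob.c1


def test_c2_matches_rows_sitting_on_the_dmodx_limit(fitted_setting):
    model, tr, te, idx = fitted_setting
    prob = build_problem(model, ReferenceProperties(0, 0), tr)
    from iqspr.diagnostics import dmodx, dmodx_critical
    # rows scaled to lie exactly on the DModX limit have squared residual c2
    E = model.x_residuals(tr.values)
    row = np.nonzero((E ** 2).sum(axis=1) > 1e-12)[0][0]
    d = dmodx(model, tr.values[row][None, :])[0]
    scale = dmodx_critical(model, 0.05) / d
    resid_at_limit = (E[row] ** 2).sum() * scale ** 2
    assert resid_at_limit == pytest.approx(prob.c2, rel=1e-10)


def test_objective_arithmetic(fitted_setting):
    model, tr, te, idx = fitted_setting
    x = tr.values[0]
    pred = model.predict(x[None, :])[0]
    prob = build_problem(model, ReferenceProperties(float(pred[0]),
                                                    float(pred[1])), tr)
    assert objective(x, prob) == pytest.approx(0.0, abs=1e-18)
    prob2 = build_problem(model, ReferenceProperties(float(pred[0]) + 1.0,
                                                     float(pred[1])), tr)
    assert objective(x, prob2) == pytest.approx(1.0, abs=1e-10)


def test_objective_gradient_matches_linear_model(fitted_setting):
    # the scaled-space objective is quadratic: finite differences along a
    # coordinate must match the analytic gradient of the linear predictor
    model, tr, te, idx = fitted_setting
    pred0 = model.predict(tr.values[:1])[0]
    ref = ReferenceProperties(float(pred0[0]) + 0.5, float(pred0[1]) - 0.5)
    prob = build_problem(model, ref, tr)
    # interior point: training mean with lattice kinds snapped to validity
    x = tr.values.mean(axis=0)
    for j, kind in enumerate(prob.kinds):
        if kind in ("binary", "integer"):
            x[j] = np.round(x[j])
    j = prob.kinds.index("continuous")
    h = 1e-5
    xp, xm = x.copy(), x.copy()
    xp[j] += h
    xm[j] -= h
    fd = (objective(xp, prob) - objective(xm, prob)) / (2 * h)
    # analytic: d/dx_j of sum_k (y_k(x) - ref_k)^2 with linear y(x)
    refv = np.array([ref.logkw_ref, ref.logKi_ref])
    y = model.predict(x[None, :])[0]
    slope = (model.coef_[j] / model._x_scaler.scale_[j]
             * model._y_scaler.scale_)
    grad = float(2 * (y - refv) @ slope)
    assert fd == pytest.approx(grad, rel=1e-4)


def test_kind_violations_rejected(fitted_setting):
    model, tr, te, idx = fitted_setting
    prob = build_problem(model, ReferenceProperties(0, 0), tr)
    x = tr.values[0].copy()
    b = prob.kinds.index("binary")
    x[b] = 0.5
    with pytest.raises(ValidationError, match="binary"):
        objective(x, prob)


def test_inverting_toward_reachable_reference_finds_it(fitted_setting):
    """Reference = prediction of an in-domain compound -> near-zero optimum."""
    model, tr, te, idx = fitted_setting
    pred = model.predict(te.values[idx][None, :])[0]
    ref = ReferenceProperties(float(pred[0]), float(pred[1]))
    for seed in (0, 1):
        prob = build_problem(model, ref, tr,
                             config=InverterConfig(population_size=60,
                                                   generations=80, seed=seed))
        sol = invert(prob)
        assert sol.feasible
        assert sol.objective <= 1e-4


def test_solution_internal_consistency(fitted_setting):
    model, tr, te, idx = fitted_setting
    pred = model.predict(te.values[idx][None, :])[0]
    prob = build_problem(model, ReferenceProperties(*map(float, pred)), tr,
                         config=InverterConfig(population_size=40,
                                               generations=40, seed=5))
    sol = invert(prob)
    repred = model.predict(sol.x_star[None, :])[0]
    assert sol.predicted == pytest.approx(tuple(repred), abs=1e-12)
    if sol.feasible:
        assert sol.t2_value <= prob.c1 + 1e-12
        assert sol.recon_residual <= prob.c2 + 1e-12
    # bounds and lattices respected
    assert np.all(sol.x_star >= prob.bounds[:, 0] - 1e-12)
    assert np.all(sol.x_star <= prob.bounds[:, 1] + 1e-12)
    for j, kind in enumerate(prob.kinds):
        if kind == "binary":
            assert sol.x_star[j] in (0.0, 1.0)


def test_inversion_is_seed_deterministic(fitted_setting):
    model, tr, te, idx = fitted_setting
    pred = model.predict(te.values[idx][None, :])[0]
    cfg = InverterConfig(population_size=30, generations=25, seed=9)
    prob = build_problem(model, ReferenceProperties(*map(float, pred)), tr,
                         config=cfg)
    s1, s2 = invert(prob), invert(prob)
    np.testing.assert_array_equal(s1.x_star, s2.x_star)
    assert s1.objective == s2.objective


def test_unreachable_reference_reported_infeasible_or_nonzero(fitted_setting):
    # a reference far outside the achievable property range cannot reach 0
    model, tr, te, idx = fitted_setting
    ref = ReferenceProperties(1e3, -1e3)
    prob = build_problem(model, ref, tr,
                         config=InverterConfig(population_size=30,
                                               generations=25, seed=2))
    sol = invert(prob)
    assert sol.objective > 1.0
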