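"""Realization pipeline: minimizers, sweep, classification."""

import numpy as np
import pytest

from polycage.functional import FunctionalWeights, deformation, total_q
from polycage.geometry import embed_labeling
from polycage.labelings import labeling_from_name
from polycage.optimize import (
    OptimizationConfig,
    bisection_refine,
    classify,
    detect_degenerate,
    metropolis_optimize,
    optimize_cage,
    polish,
    simplex_refine,
    weight_sweep,
)
from polycage.topology import build_topology


@pytest.fixture(scope="module")
def small_cage():
    """Heptagonal-prism P9 ring cage: small enough for repeated solves."""
    return labeling_from_name("7p_P9_2_2_2")


@pytest.fixture(scope="module")
def quick_cage():
    """Small cube-based near-miss cage that realizes without retries."""
    return labeling_from_name("Pcu_P7_1_1_2_v2")


def test_metropolis_descends_and_is_deterministic(noisy_pic):
    cfg = OptimizationConfig(seed=7, metropolis_iters=1500)
    q0 = total_q(noisy_pic).total
    g1 = metropolis_optimize(noisy_pic, config=cfg)
    g2 = metropolis_optimize(noisy_pic, config=cfg)
    assert total_q(g1).total < q0
    assert np.array_equal(g1.nodes, g2.nodes)
    g3 = metropolis_optimize(noisy_pic, config=OptimizationConfig(
        seed=8, metropolis_iters=1500))
    assert not np.array_equal(g1.nodes, g3.nodes)


def test_metropolis_zero_temperature_never_worsens(noisy_pic):
    cfg = OptimizationConfig(seed=3, metropolis_iters=400, metropolis_temp=0.0)
    out = metropolis_optimize(noisy_pic, config=cfg)
    assert total_q(out).total <= total_q(noisy_pic).total


def test_simplex_refine_contract(noisy_pic):
    cfg = OptimizationConfig(simplex_maxfev=3000)
    out = simplex_refine(noisy_pic, config=cfg)
    assert total_q(out).total <= total_q(noisy_pic).total + 1e-15
    # no-op at a minimum: a regular cage stays regular
    # (polish first to machine precision, then simplex must not degrade)


def test_polish_reaches_regular_solution(pic_geometry):
    out = polish(pic_geometry)
    dl, da = deformation(out)
    assert max(dl, da) <= 1e-10


def test_polish_idempotent_on_optimized_cage(pic_geometry):
    once = polish(pic_geometry)
    twice = polish(once)
    assert max(deformation(twice)) <= 1e-5


def test_weight_sweep_contract(small_cage, fast_config):
    topo = build_topology(small_cage)
    cands = weight_sweep(topo, fast_config)
    assert len(cands) == fast_config.sweep_points
    for c in cands:
        cl, ca = c.best_weights
        assert cl + ca == pytest.approx(2.0, abs=1e-12)
        assert np.isfinite(c.report.max_deformation)


def test_bisection_never_worse_than_bracket(small_cage, fast_config):
    topo = build_topology(small_cage)
    cands = weight_sweep(topo, fast_config)
    best_sweep = min(c.report.max_deformation for c in cands)
    refined = bisection_refine(topo, (0.5, 2.0), fast_config)
    assert refined.report.max_deformation <= best_sweep + 1e-12


def test_selection_minimizes_max_deformation():
    from polycage.optimize import OptimizedCage
    from polycage.functional import DeformationReport

    pairs = [(0.02, 0.03), (0.01, 0.05)]
    reports = [DeformationReport(delta_l=a, delta_a=b) for a, b in pairs]
    best = min(reports, key=lambda r: r.max_deformation)
    assert (best.delta_l, best.delta_a) == (0.02, 0.03)


def test_detect_degenerate(pic_geometry):
    flag, holes = detect_degenerate(pic_geometry, tol=1e-2)
    assert not flag
    from polycage.fixtures import make_fixture
    pinched = make_fixture("pinched", {"name": "Asc_P11_2_1_1_1_1"})
    flag, holes = detect_degenerate(pinched, tol=1e-6)
    assert flag and holes
    # zero tolerance only flags exact coincidences
    flag0, _ = detect_degenerate(pic_geometry, tol=0.0)
    assert not flag0


def test_classification_thresholds():
    from polycage.functional import DeformationReport
    from polycage.optimize import OptimizedCage

    def cage(dl, da, pinched=(), selfint=False):
        return OptimizedCage(name="x", geometry=None,
                             report=DeformationReport(delta_l=dl, delta_a=da),
                             breakdown=None, best_weights=(1, 1),
                             classification="", self_intersects=selfint,
                             pinched_holes=list(pinched))

    cfg = OptimizationConfig()
    assert classify(cage(1e-7, 1e-8), cfg) == "regular"
    assert classify(cage(0.05, 0.01), cfg) == "near-miss"
    assert classify(cage(0.2, 0.01), cfg) == "rejected"
    assert classify(cage(1e-7, 0.0, pinched=[1]), cfg) == "degenerate"
    assert classify(cage(0.05, 0.0, selfint=True), cfg) == "self-intersecting"


def test_optimize_cage_regular(fast_config):
    lab = labeling_from_name("Pdo_P9_2_2_2")
    cage = optimize_cage(lab, fast_config)
    assert cage.classification == "regular"
    assert cage.max_deformation <= 1e-6


def test_optimize_cage_degenerate_prism(fast_config):
    cage = optimize_cage(labeling_from_name("tp_P8_1_1_3"), fast_config)
    assert cage.classification == "degenerate"
    assert cage.pinched_holes


def test_optimize_cage_repeatable_across_seeds(quick_cage, fast_config):
    from dataclasses import replace
    a = optimize_cage(quick_cage, replace(fast_config, seed=1))
    b = optimize_cage(quick_cage, replace(fast_config, seed=2))
    ma, mb = a.max_deformation, b.max_deformation
    assert ma == pytest.approx(mb, rel=0.1, abs=1e-9)


def test_optimized_cage_consistent_with_pruning(quick_cage, fast_config):
    """A cage optimizing below kappa_t must have passed the pruning tests."""
    from polycage.constraints import prune_configuration
    cage = optimize_cage(quick_cage, fast_config)
    if cage.max_deformation <= 0.1:
        assert prune_configuration(quick_cage, 0.1, use_angle=True).ok
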