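"""Geometric realization of cage candidates by deformation minimization.

The pipeline realizes each candidate topology as the most regular convex
cage it supports: assemble an initial embedding from rigid regular faces,
minimize the quality functional over all node positions, sweep the
length/angle weight ratio (c_l + c_a = 2) across log-spaced values, refine
the best ratio by bisection, and classify the result by its maximum
deformation max(delta_l, delta_a):

* regular    -- below ``regular_threshold`` (1e-5);
* near-miss  -- below ``near_miss_threshold`` (0.1, the 10% band);
* rejected   -- above the near-miss band;
* degenerate / self-intersecting -- overriding flags from the pinched-hole
  and face-interpenetration tests.

Three minimizers are provided.  ``metropolis_optimize`` is a seeded
single-node random-walk annealer on the full functional (the only one that
sees the integer convexity penalties).  ``simplex_refine`` runs
derivative-free Nelder-Mead on the flattened coordinate vector.
``polish`` exploits that the smooth part of the functional is a least
squares problem in the node coordinates (edge-length, corner-angle and
facelet-planarity residuals) and drives it to machine-level stationarity
with a trust-region least-squares solver; convexity counters are verified
afterwards and a Metropolis rescue pass handles the rare violations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.sparse import lil_matrix

from .functional import (
    DeformationReport,
    FunctionalWeights,
    QualityBreakdown,
    deformation,
    deformation_report,
    total_q,
)
from .geometry import PCageGeometry, initial_embedding
from .intersect import cage_self_intersects
from .topology import build_topology


@dataclass(frozen=True)
class OptimizationConfig:
    seed: int = 0
    # metropolis
    metropolis_iters: int = 4000
    metropolis_step: float = 0.02
    metropolis_temp: float = 1e-4
    metropolis_cooling: float = 0.999
    target_acceptance: float = 0.3
    # simplex
    simplex_maxfev: int = 20000
    simplex_tol: float = 1e-10
    # least-squares polish
    polish_tol: float = 1e-14
    polish_max_nfev: int = 200
    # weight sweep (c_l + c_a = 2, ratio log-spaced)
    sweep_points: int = 100
    ratio_range: tuple = (1e-2, 1e2)
    bisection_iters: int = 12
    # classification
    near_miss_threshold: float = 0.1
    regular_threshold: float = 1e-5
    degenerate_tol: float = 1e-2
    # hole-opening repulsion used when retrying a pinched realization
    pinch_guard_margin: float = 0.1
    pinch_guard_weight: float = 10.0
    weights: FunctionalWeights = field(default_factory=FunctionalWeights)
    use_metropolis: bool = False          # pre-polish annealing pass
    check_intersections: bool = True
    compute_similarity: bool = True


@dataclass
class OptimizedCage:
    name: str
    geometry: PCageGeometry
    report: DeformationReport
    breakdown: QualityBreakdown
    best_weights: tuple                 # (c_l, c_a)
    classification: str
    self_intersects: bool = False
    pinched_holes: list = field(default_factory=list)
    seed: int = 0

    @property
    def max_deformation(self):
        return self.report.max_deformation


# ---------------------------------------------------------------------------
# minimizers
# ---------------------------------------------------------------------------

def metropolis_optimize(geometry, weights=None, config=None):
    """Seeded annealing with single-node Gaussian proposals.

    The proposal step adapts towards the target acceptance rate and the
    temperature follows a geometric schedule; the best-seen geometry is
    returned, so the outcome never degrades the starting point.
    """
    cfg = config or OptimizationConfig()
    w = weights or cfg.weights
    rng = np.random.default_rng(cfg.seed)
    nodes = geometry.nodes.copy()
    geo = PCageGeometry(geometry.topology, nodes)
    q = total_q(geo, w).total
    best_nodes, best_q = nodes.copy(), q
    step = cfg.metropolis_step
    temp = cfg.metropolis_temp
    accepted = 0
    window = max(50, cfg.metropolis_iters // 40)
    for it in range(cfg.metropolis_iters):
        k = rng.integers(len(nodes))
        old = nodes[k].copy()
        nodes[k] = old + rng.normal(scale=step, size=3)
        q_new = total_q(geo, w).total
        dq = q_new - q
        if dq <= 0.0 or (temp > 0.0 and rng.random() < np.exp(-dq / temp)):
            q = q_new
            accepted += 1
            if q < best_q:
                best_q = q
                best_nodes = nodes.copy()
        else:
            nodes[k] = old
        temp *= cfg.metropolis_cooling
        if (it + 1) % window == 0:
            rate = accepted / window
            step *= 1.2 if rate > cfg.target_acceptance else 0.8
            accepted = 0
    return PCageGeometry(geometry.topology, best_nodes)


def simplex_refine(geometry, weights=None, config=None):
    """Downhill-simplex polish of the full coordinate vector."""
    cfg = config or OptimizationConfig()
    w = weights or cfg.weights
    topo = geometry.topology
    x0 = geometry.nodes.ravel()

    def fun(x):
        return total_q(PCageGeometry(topo, x.reshape(-1, 3)), w).total

    res = minimize(fun, x0, method="Nelder-Mead",
                   options=dict(maxfev=cfg.simplex_maxfev,
                                fatol=cfg.simplex_tol, xatol=cfg.simplex_tol))
    if res.fun <= fun(x0):
        return PCageGeometry(topo, res.x.reshape(-1, 3))
    return geometry.copy()


_SPARSITY_CACHE = {}


def _hole_pairs(topology):
    """Non-adjacent node pairs on each hole boundary (pinching candidates)."""
    pairs = []
    for hole in topology.holes:
        n = len(hole)
        for i in range(n):
            for j in range(i + 2, n):
                if i == 0 and j == n - 1:
                    continue
                pairs.append((hole[i], hole[j]))
    return np.array(pairs, dtype=int).reshape(-1, 2)


def _residual_builder(topology, weights, guard=None):
    """Residual vector of the smooth functional part (+ optional guard).

    ``guard`` = (margin, weight) adds one-sided repulsion residuals
    ``w * max(0, margin - |x_a - x_b|)`` over non-adjacent hole boundary
    node pairs, used to keep holes open when a realization pinches shut.
    """
    P = topology.P
    a0 = np.pi * (1.0 - 2.0 / P)
    sl = np.sqrt(weights.c_l)
    sa = np.sqrt(weights.c_a)
    sp = np.sqrt(weights.c_p)
    pairs = _hole_pairs(topology) if guard else None

    def residuals(x):
        geo = PCageGeometry(topology, x.reshape(-1, 3))
        l = geo.edge_lengths()
        ang = geo.face_angles()
        w = geo.facelet_normals()
        What = geo.face_unit_normals()
        perp = w - (w * What[:, None, :]).sum(axis=2, keepdims=True) * What[:, None, :]
        parts = [
            sl * (l - weights.L_f).ravel() / weights.L_f,
            sa * (ang - a0).ravel(),
            sp * perp.ravel(),
        ]
        if guard:
            margin, gw = guard
            pos = x.reshape(-1, 3)
            gaps = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
            parts.append(gw * np.maximum(0.0, margin - gaps))
        return np.concatenate(parts)

    # sparsity: each face's residual block depends on its own nodes only
    key = (P, topology.faces.tobytes(), bool(guard))
    if key not in _SPARSITY_CACHE:
        N = topology.N
        nn = int(topology.faces.max()) + 1
        m = N * P * 5 + (len(pairs) if guard else 0)
        S = lil_matrix((m, nn * 3), dtype=bool)
        for f in range(N):
            cols = []
            for node in topology.faces[f]:
                cols.extend((3 * node, 3 * node + 1, 3 * node + 2))
            for i in range(P):
                S[f * P + i, cols] = True                       # lengths
                S[N * P + f * P + i, cols] = True               # angles
                for k in range(3):
                    S[2 * N * P + (f * P + i) * 3 + k, cols] = True
        if guard:
            for r, (na, nb) in enumerate(pairs):
                cols = [3 * na, 3 * na + 1, 3 * na + 2,
                        3 * nb, 3 * nb + 1, 3 * nb + 2]
                S[N * P * 5 + r, cols] = True
        _SPARSITY_CACHE[key] = S.tocsr()
    return residuals, _SPARSITY_CACHE[key]


def polish(geometry, weights=None, config=None, guard=None):
    """Trust-region least-squares minimization of the smooth functional part.

    Returns the refined geometry; the convexity counters are re-checked by
    the caller (they are almost always zero already, because the embedding
    starts from an outward-oriented convex arrangement).
    """
    cfg = config or OptimizationConfig()
    w = weights or cfg.weights
    residuals, sparsity = _residual_builder(geometry.topology, w, guard)
    res = least_squares(residuals, geometry.nodes.ravel(), jac_sparsity=sparsity,
                        method="trf", tr_solver="lsmr",
                        ftol=cfg.polish_tol, xtol=cfg.polish_tol, gtol=cfg.polish_tol,
                        max_nfev=cfg.polish_max_nfev)
    return PCageGeometry(geometry.topology, res.x.reshape(-1, 3))


def _optimize_at(geometry, weights, config, guard=None):
    """Polish at given weights, with a Metropolis rescue if the polished
    geometry violates a convexity counter."""
    geo = polish(geometry, weights, config, guard)
    qb = total_q(geo, weights)
    if qb.q_conv_face > 0 or qb.q_conv_cage > 0:
        rescued = metropolis_optimize(geo, weights, config)
        rescued = polish(rescued, weights, config, guard)
        if total_q(rescued, weights).total < qb.total:
            geo = rescued
    return geo


# ---------------------------------------------------------------------------
# weight sweep and bisection
# ---------------------------------------------------------------------------

def _weights_for_ratio(base, ratio):
    c_l = 2.0 * ratio / (1.0 + ratio)
    return replace(base, c_l=c_l, c_a=2.0 - c_l)


def _candidate(topology, geometry, weights, config, similarity=False):
    rep = deformation_report(geometry, weights.L_f, similarity=similarity)
    return OptimizedCage(
        name=topology.labeling.name, geometry=geometry, report=rep,
        breakdown=total_q(geometry, weights),
        best_weights=(weights.c_l, weights.c_a),
        classification="unclassified", seed=config.seed)


def weight_sweep(topology, config=None, start=None, guard=None):
    """Optimize across log-spaced c_l/c_a ratios (keeping c_l + c_a = 2).

    Returns one candidate per sweep point.  ``start`` (a PCageGeometry)
    seeds every optimization; by default the spring-assembled embedding,
    pre-relaxed at c_l = c_a = 1, is used.
    """
    cfg = config or OptimizationConfig()
    if start is None:
        start = _optimize_at(initial_embedding(topology),
                             _weights_for_ratio(cfg.weights, 1.0), cfg, guard)
    ratios = np.logspace(np.log10(cfg.ratio_range[0]),
                         np.log10(cfg.ratio_range[1]), cfg.sweep_points)
    out = []
    for r in ratios:
        w = _weights_for_ratio(cfg.weights, r)
        geo = _optimize_at(start, w, cfg, guard)
        out.append(_candidate(topology, geo, w, cfg))
    return out


def bisection_refine(topology, bracket, config=None, start=None, guard=None):
    """Golden-section refinement of the weight ratio within ``bracket``.

    ``bracket`` is (ratio_lo, ratio_hi); the cage minimizing
    max(delta_l, delta_a) over all evaluations is returned, so the result
    is never worse than the bracket endpoints.
    """
    cfg = config or OptimizationConfig()
    if start is None:
        start = _optimize_at(initial_embedding(topology),
                             _weights_for_ratio(cfg.weights, 1.0), cfg, guard)
    lo, hi = np.log10(bracket[0]), np.log10(bracket[1])

    evaluated = {}

    def eval_at(logr):
        key = round(logr, 12)
        if key not in evaluated:
            w = _weights_for_ratio(cfg.weights, 10.0 ** logr)
            geo = _optimize_at(start, w, cfg, guard)
            evaluated[key] = _candidate(topology, geo, w, cfg)
        return evaluated[key].report.max_deformation

    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - phi * (b - a)
    d = a + phi * (b - a)
    fc, fd = eval_at(c), eval_at(d)
    for _ in range(cfg.bisection_iters):
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = eval_at(c)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = eval_at(d)
    eval_at(lo)
    eval_at(hi)
    return min(evaluated.values(), key=lambda c: c.report.max_deformation)


# ---------------------------------------------------------------------------
# degeneracy and classification
# ---------------------------------------------------------------------------

def detect_degenerate(geometry, tol=1e-2):
    """Pinched holes: non-adjacent boundary nodes closer than ``tol``."""
    pinched = []
    for hi, hole in enumerate(geometry.topology.holes):
        n = len(hole)
        if n < 4:
            continue
        pts = geometry.nodes[hole]
        for i in range(n):
            for j in range(i + 2, n):
                if i == 0 and j == n - 1:
                    continue
                if np.linalg.norm(pts[i] - pts[j]) <= tol:
                    pinched.append(hi)
                    break
            else:
                continue
            break
    return bool(pinched), pinched


def classify(cage, config=None):
    cfg = config or OptimizationConfig()
    if cage.pinched_holes:
        return "degenerate"
    if cage.self_intersects:
        return "self-intersecting"
    m = cage.report.max_deformation
    if m <= cfg.regular_threshold:
        return "regular"
    if m <= cfg.near_miss_threshold:
        return "near-miss"
    return "rejected"


def _realize(topo, cfg, guard=None):
    geo = initial_embedding(topo)
    if cfg.use_metropolis:
        geo = metropolis_optimize(geo, _weights_for_ratio(cfg.weights, 1.0), cfg)
    base = _optimize_at(geo, _weights_for_ratio(cfg.weights, 1.0), cfg, guard)

    if cfg.sweep_points > 0:
        candidates = weight_sweep(topo, cfg, start=base, guard=guard)
        best_i = int(np.argmin([c.report.max_deformation for c in candidates]))
        ratios = np.logspace(np.log10(cfg.ratio_range[0]),
                             np.log10(cfg.ratio_range[1]), cfg.sweep_points)
        lo = ratios[max(0, best_i - 1)]
        hi = ratios[min(len(ratios) - 1, best_i + 1)]
        best = bisection_refine(topo, (lo, hi), cfg, start=base, guard=guard)
        if candidates[best_i].report.max_deformation < best.report.max_deformation:
            best = candidates[best_i]
    else:          # iso-weight realization only
        best = _candidate(topo, base, _weights_for_ratio(cfg.weights, 1.0), cfg)

    is_pinched, pinched = detect_degenerate(best.geometry, cfg.degenerate_tol)
    best.pinched_holes = pinched
    if cfg.check_intersections:
        flag, _pairs = cage_self_intersects(best.geometry)
        best.self_intersects = flag
    best.report = deformation_report(best.geometry, cfg.weights.L_f,
                                     similarity=cfg.compute_similarity)
    best.classification = classify(best, cfg)
    return best


def optimize_cage(labeling, config=None):
    """Full realization pipeline for one labeling.

    Embed, optionally anneal, relax at iso weights, sweep the c_l/c_a
    ratio, refine the best bracket by bisection, then classify with the
    pinched-hole and self-intersection tests applied to the winner.

    Some topologies admit a zero-deformation solution in which holes pinch
    shut (opposite boundary edges merge) -- the minimizer then lands on the
    degenerate collapse rather than the open cage.  Two cases are told
    apart by the edge contributions around the pinched holes:

    * all contributions equal (a ring-like cage folding flat): the collapse
      is a minimizer artifact; the realization is retried with a
      hole-opening repulsion on nearly touching boundary node pairs and the
      retried cage is kept if it lands in the regular/near-miss band;
    * unequal contributions (a long edge run merging onto shorter ones):
      the pinch reduces the cage to a different, smaller-hole cage -- the
      degenerate-equivalence case, reported as degenerate.
    """
    cfg = config or OptimizationConfig()
    topo = build_topology(labeling)
    best = _realize(topo, cfg)
    if best.classification == "degenerate":
        symmetric = all(
            len(set(labeling.hole_q(topo.hole_faces[hi]))) == 1
            for hi in best.pinched_holes)
        if symmetric:
            guarded = _realize(
                topo, cfg,
                guard=(cfg.pinch_guard_margin, cfg.pinch_guard_weight))
            if guarded.classification in ("regular", "near-miss"):
                return guarded
    return best
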