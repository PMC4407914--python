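"""Diversity-tree likelihoods and stepwise rate-shift detection."""

import numpy as np
import pytest

import earlyburst as eb
from earlyburst.shiftscan import (
    DiversityTree,
    RateShiftModel,
    _fit_piece,
    backbone_loglik,
    fit_rate_shifts,
    unresolved_clade_loglik,
)
from earlyburst.synthdata import make_planted_shift_tree


def test_unresolved_single_species_is_geometric_head():
    r, eps, t = 0.3, 0.2, 8.0
    ert = np.exp(r * t)
    beta = (ert - 1) / (ert - eps)
    assert unresolved_clade_loglik(1, t, r, eps) == pytest.approx(np.log(1 - beta))


def test_unresolved_hand_value_yule():
    # eps = 0, r = 0.3, t = 10: P(N=5) = (1-beta) beta^4, beta = 1-e^-3
    beta = 1 - np.exp(-3.0)
    expect = np.log((1 - beta) * beta**4)
    assert unresolved_clade_loglik(5, 10.0, 0.3, 0.0) == pytest.approx(expect)


def test_unresolved_invalid_inputs():
    with pytest.raises(ValueError):
        unresolved_clade_loglik(0, 10.0, 0.3, 0.0)
    with pytest.raises(ValueError):
        unresolved_clade_loglik(3, 0.0, 0.3, 0.0)
    with pytest.raises(ValueError):
        # epsilon >= e^{rt}
        unresolved_clade_loglik(3, 1.0, 0.1, 1.2)


def test_unresolved_probabilities_sum_to_one():
    """Geometric richness pmf sums to 1 (truncation + tail oracle)."""
    for r, eps, t in [(0.3, 0.0, 10.0), (0.15, 0.6, 7.0), (0.05, 0.9, 20.0)]:
        n = np.arange(1, 1_000_001)
        ert = np.exp(r * t)
        beta = (ert - 1) / (ert - eps)
        lp = np.log1p(-beta) + (n - 1) * np.log(beta)
        total = np.exp(lp).sum() + beta ** n[-1]  # analytic geometric tail
        assert total == pytest.approx(1.0, abs=1e-10)
        # and the function agrees with the direct formula
        assert unresolved_clade_loglik(7, t, r, eps) == pytest.approx(lp[6])


def test_richness_critical_limit():
    # r -> 0: beta -> lam t / (1 + lam t)
    t, eps = 5.0, 0.5
    r = 1e-12
    lam = r / (1 - eps)
    beta = lam * t / (1 + lam * t)
    assert unresolved_clade_loglik(2, t, r, eps) == pytest.approx(
        np.log((1 - beta) * beta), rel=1e-6
    )


def test_two_tip_regime_hand_value():
    """All-richness-1 cherry: loglik reduces to pure-birth survival terms."""
    t = eb.TimeTree.from_newick("(A:4,B:4);")
    m = RateShiftModel(DiversityTree(t, [1, 1]))
    piece = m._piece(m._assignment([]), 0)
    lam = 0.3
    assert backbone_loglik(piece, lam, 0.0) == pytest.approx(-2 * lam * 4)


def test_yule_mle_recovered_exactly(yule30):
    """Base-model net rate equals the closed-form pure-birth estimate
    (branching events over total branch length) when eps sits at 0."""
    m = RateShiftModel(DiversityTree(yule30, np.ones(yule30.n_tips, dtype=int)))
    piece = m._piece(m._assignment([]), 0)
    _, r_hat, eps_hat, _ = _fit_piece(piece)
    b = len(yule30.internal_ids) - 1
    assert eps_hat == pytest.approx(0.0, abs=1e-4)
    assert r_hat == pytest.approx(b / yule30.total_branch_length, rel=1e-4)


def test_likelihood_decomposes_over_regimes(yule30):
    """Branch and node counts partition exactly across regimes."""
    m = RateShiftModel(DiversityTree(yule30, np.ones(yule30.n_tips, dtype=int)))
    v = int(yule30.internal_ids[3])
    reg = m._assignment([v])
    p0, p1 = m._piece(reg, 0), m._piece(reg, 1)
    n_births = len(p0.node_ages) + len(p1.node_ages)
    assert n_births == len(yule30.internal_ids) - 1
    total_len = (
        np.sum(p0.int_t1 - p0.int_t2) + np.sum(p1.int_t1 - p1.int_t2)
        + np.sum(p0.tip_stem) + np.sum(p1.tip_stem)
    )
    assert total_len == pytest.approx(yule30.total_branch_length, rel=1e-9)
    # total loglik is the sum of the regime terms by construction
    ll = backbone_loglik(p0, 0.2, 0.1) + backbone_loglik(p1, 0.5, 0.0)
    assert np.isfinite(ll)


def test_bd_parameter_recovery():
    """Median (r, eps) over simulated birth-death trees lands within 25%
    of the generating (0.1, 0.5)."""
    rng = np.random.default_rng(3)
    rs, es = [], []
    for _ in range(30):
        tr = None
        while tr is None or tr.n_tips < 50:
            tr = eb.simulate_bd_forward(eb.BDParams(0.2, 0.1), 40.0, rng)
        m = RateShiftModel(DiversityTree(tr, np.ones(tr.n_tips, dtype=int)))
        _, r, e, _ = _fit_piece(m._piece(m._assignment([]), 0))
        rs.append(r)
        es.append(e)
    assert abs(np.median(rs) - 0.1) < 0.025
    assert abs(np.median(es) - 0.5) < 0.125


def test_richness_validation(yule30):
    with pytest.raises(Exception):
        DiversityTree(yule30, np.zeros(yule30.n_tips, dtype=int))
    with pytest.raises(Exception):
        DiversityTree(yule30, np.ones(5, dtype=int))


def test_scan_is_deterministic(yule30):
    d = DiversityTree(yule30, np.ones(yule30.n_tips, dtype=int))
    a = fit_rate_shifts(d, max_shifts=3)
    b = fit_rate_shifts(d, max_shifts=3)
    assert a.retained.shift_nodes == b.retained.shift_nodes
    assert a.retained.aicc == pytest.approx(b.retained.aicc, rel=1e-12)


def test_aicc_strictly_decreases_along_path():
    tree, node, _ = make_planted_shift_tree(seed=2)
    res = fit_rate_shifts(
        DiversityTree(tree, np.ones(tree.n_tips, dtype=int)), max_shifts=5
    )
    path = [m.aicc for m in res.path]
    assert all(b < a for a, b in zip(path, path[1:]))
    assert res.delta_aicc >= 0


def test_planted_shift_detected_small():
    rng = np.random.default_rng(9)
    hits = 0
    for _ in range(10):
        tree, node, _ = make_planted_shift_tree(rng)
        res = fit_rate_shifts(
            DiversityTree(tree, np.ones(tree.n_tips, dtype=int)), max_shifts=5
        )
        found = set(res.retained.shift_nodes)
        hits += node in found or int(tree.parent[node]) in found
    assert hits >= 8


def test_homogeneous_tree_rarely_multi_shift():
    rng = np.random.default_rng(10)
    few = 0
    for _ in range(10):
        t = None
        while t is None or not 30 <= t.n_tips <= 90:
            t = eb.simulate_bd_forward(eb.BDParams(0.25), 15.0, rng)
        res = fit_rate_shifts(
            DiversityTree(t, np.ones(t.n_tips, dtype=int)), max_shifts=5
        )
        few += res.n_shifts <= 1
    assert few >= 7


def test_fixture_scan_finds_fast_clade(fixture_bundle):
    """On the study-shaped fixture the retained model gives the young
    species-rich clade a faster net rate than the background."""
    tree, _, richness = fixture_bundle
    res = fit_rate_shifts(DiversityTree(tree, richness), max_shifts=5)
    assert res.n_shifts >= 1
    assert res.delta_aicc > 0
    root = res.retained.regimes[0]
    root_lam = root.r / (1.0 - root.epsilon)
    shifted = [g for g in res.retained.regimes if g.shift_node is not None]
    fast_tips = {l for l in tree.tip_labels if l.startswith("fast_")}
    covers = []
    for g in shifted:
        tips = {tree.labels[int(i)] for i in tree.clade_tips(g.shift_node)}
        if fast_tips <= tips or tips == fast_tips:
            covers.append(g)
    assert covers, "no retained shift covers the fast clade"
    # speciation rate, not just net rate: regimes may sit on the
    # high-turnover ridge where r alone understates the tempo
    assert max(g.r / (1.0 - g.epsilon) for g in covers) > root_lam
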