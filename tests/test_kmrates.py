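"""Per-interval Kendall-Moran rates and simulated envelopes."""

import numpy as np
import pytest

import earlyburst as eb
from earlyburst.kmrates import STAGES, GeoInterval, interval_km_rate, rate_envelope
from earlyburst.treesim import BDParams, ConditioningSpec, SamplingScheme


def test_interval_validation():
    with pytest.raises(ValueError):
        GeoInterval("bad", 2.0, 3.0)
    with pytest.raises(ValueError):
        GeoInterval("bad", 2.0, -1.0)


def test_packaged_stages():
    names = [iv.name for iv in STAGES]
    assert names == ["Tortonian", "Messinian", "Zanclean", "Piacenzian", "Pleistocene"]
    assert STAGES[0].old_bound == 11.6 and STAGES[-1].young_bound == 0.0


def test_two_tip_zero_events():
    t = eb.TimeTree.from_newick("(A:10,B:10);")
    assert interval_km_rate(t, GeoInterval("x", 5.0, 0.0)) == 0.0


def test_hand_overlap_example():
    t = eb.TimeTree.from_newick("((A:1,B:1):9,C:10);")
    # B=1 (node at 1 Ma); L = 2*1 (A,B) + 1 (stem 1-2 Ma) + 2 (C) = 5
    assert interval_km_rate(t, GeoInterval("x", 2.0, 0.0)) == pytest.approx(0.2)


def test_interval_older_than_tree_raises():
    t = eb.TimeTree.from_newick("(A:10,B:10);")
    with pytest.raises(ValueError, match="older"):
        interval_km_rate(t, GeoInterval("x", 30.0, 20.0))


def test_partition_sums_exact(yule30):
    """Events and lineage-time partition exactly over adjacent intervals."""
    T = yule30.crown_age
    cuts = [T, 11.0, 6.5, 3.0, 0.0]
    parts = [GeoInterval(f"p{i}", a, b) for i, (a, b) in enumerate(zip(cuts, cuts[1:]))]
    bp = yule30.ages_before_present
    nodes = yule30.internal_ids[yule30.internal_ids != 0]
    b_total = 0
    l_total = 0.0
    for iv in parts:
        rate = interval_km_rate(yule30, iv)
        inside = (bp[nodes] > iv.young_bound) & (bp[nodes] <= iv.old_bound)
        b = int(inside.sum())
        b_total += b
        if b:
            l_total += b / rate
        else:
            child = np.arange(1, yule30.n_nodes)
            hi = np.minimum(bp[yule30.parent[child]], iv.old_bound)
            lo = np.maximum(bp[child], iv.young_bound)
            l_total += float(np.maximum(hi - lo, 0).sum())
    assert b_total == len(nodes)
    assert l_total == pytest.approx(yule30.total_branch_length, rel=1e-9)


def test_rate_invariant_to_relabelling(yule30):
    relabelled = eb.TimeTree(
        yule30.parent, yule30.age,
        [None if l is None else f"x_{l}" for l in yule30.labels],
    )
    iv = GeoInterval("mid", 10.0, 5.0)
    assert interval_km_rate(yule30, iv) == interval_km_rate(relabelled, iv)


def test_yule_rate_recovery_per_interval():
    """The pooled (events over lineage-time) estimate across replicates
    recovers the generating rate; single-tree B/L ratios carry a known
    small-sample Jensen bias at sparsely populated deep intervals, so
    recovery is asserted on the ensemble MLE."""
    lam, T = 0.2, 15.0
    rng = np.random.default_rng(8)
    iv = GeoInterval("mid", 10.0, 5.0)
    b_tot, l_tot = 0.0, 0.0
    for _ in range(300):
        t = eb.simulate_bd_forward(BDParams(lam), T, rng)
        rate = interval_km_rate(t, iv)
        bp = t.ages_before_present
        child = np.arange(1, t.n_nodes)
        hi = np.minimum(bp[t.parent[child]], iv.old_bound)
        lo = np.maximum(bp[child], iv.young_bound)
        L = float(np.maximum(hi - lo, 0).sum())
        b_tot += rate * L
        l_tot += L
    pooled = b_tot / l_tot
    se = np.sqrt(b_tot) / l_tot  # Poisson counting error
    assert abs(pooled - lam) < 3 * se


def _recent_burst_tree(rng, lam=0.15, T=15.0, factor=5.0, burst_start=2.6):
    """Pure-birth tree whose rate jumps by ``factor`` in the last
    ``burst_start`` myr (two-phase forward simulation oracle).

    Phase one runs at the base rate until ``burst_start`` Ma before
    present; each surviving lineage then continues at the elevated rate
    (first split after an exponential stem, then a crown subtree)."""
    lam_fast = lam * factor
    while True:
        base = eb.simulate_bd_forward(BDParams(lam), T - burst_start, rng)
        if base is None or base.n_tips > 40:
            continue
        parent = list(base.parent)
        age = list(base.age)
        labels = list(base.labels)
        for tip in list(base.tip_ids):
            t1 = float(rng.exponential(1.0 / lam_fast))
            phase_start = age[tip]
            if t1 >= burst_start - 1e-9:
                age[tip] = phase_start + burst_start  # no split before present
                continue
            sub = eb.simulate_bd_forward(BDParams(lam_fast), burst_start - t1, rng)
            n0 = len(parent)
            labels[tip] = None
            age[tip] = phase_start + t1  # the lineage's first burst-phase split
            for v in range(1, sub.n_nodes):
                gp = int(sub.parent[v])
                parent.append(tip if gp == 0 else n0 + gp - 1)
                age.append(phase_start + t1 + sub.age[v])
                labels.append(
                    None if sub.labels[v] is None else f"b{tip}_{v}"
                )
        t = eb.TimeTree(parent, age, labels)
        if 30 <= t.n_tips <= 200:
            return t


def test_recent_burst_exceeds_yule_envelope():
    """A five-fold speciation burst in the Pleistocene pushes the
    youngest-interval rate above the constant-rate 95% quantile."""
    rng = np.random.default_rng(13)
    emp = [_recent_burst_tree(rng) for _ in range(3)]
    cond = ConditioningSpec(15.0, emp[0].n_tips, (0.1, 0.4))
    env = rate_envelope(
        emp, STAGES, conditioning=cond, sampling=SamplingScheme("random"),
        k=emp[0].n_tips, n_sims=150, seed=14,
    )
    assert env.exceeds("Pleistocene", 0.95)


def test_envelope_quantiles_monotone(yule30):
    cond = ConditioningSpec(15.0, 60, (0.1, 0.4))
    env = rate_envelope(
        [yule30], STAGES, conditioning=cond, sampling=SamplingScheme("random"),
        k=30, n_sims=80, seed=15,
    )
    for iv in STAGES:
        q = env.sim_quantiles[iv.name]
        assert q[0.5] <= q[0.95] <= q[0.999]
    frame = env.to_frame()
    assert list(frame.index) == [iv.name for iv in STAGES]


def test_semidiversified_lowers_recent_rates():
    """Deep-clade over-retention depresses apparent recent rates
    relative to uniform random sampling."""
    cond = ConditioningSpec(15.0, 100, (0.1, 0.4))
    t = eb.simulate_conditioned_tree(cond, seed=16)
    env_r = rate_envelope(
        [t], STAGES, conditioning=cond, sampling=SamplingScheme("random"),
        k=40, n_sims=120, seed=17,
    )
    env_s = rate_envelope(
        [t], STAGES, conditioning=cond, sampling=SamplingScheme("semidiversified"),
        k=40, n_sims=120, seed=17,
    )
    assert (
        env_s.sim_quantiles["Pleistocene"][0.5]
        < env_r.sim_quantiles["Pleistocene"][0.5]
    )
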