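"""BM/OU likelihoods, ML fitting, AICc comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import earlyburst as eb
from earlyburst.modelfit import (
    TraitEvolutionModel,
    aicc,
    bm_loglik,
    compare_over_trees,
    fit_model,
    ou_loglik,
)
from earlyburst.traitsim import TraitModel, simulate_trait_matrix


@pytest.fixture(scope="module")
def tree120():
    spec = eb.ConditioningSpec(crown_age=15.0, n_extant=120, rate_sampler=(0.1, 0.4))
    return eb.simulate_conditioned_tree(spec, seed=42)


def test_bm_two_tip_closed_form():
    t = eb.TimeTree.from_newick("(A:4,B:4);")
    x = {"A": 0.3, "B": -1.2}
    s2, z0 = 1.7, 0.2
    expect = stats.norm.logpdf(0.3, z0, np.sqrt(s2 * 4)) + stats.norm.logpdf(
        -1.2, z0, np.sqrt(s2 * 4)
    )
    assert bm_loglik(t, x, s2, z0) == pytest.approx(expect, abs=1e-10)
    assert bm_loglik(t, x, s2, z0, method="dense") == pytest.approx(expect, abs=1e-10)


def test_ou_single_branch_closed_form():
    t = eb.TimeTree.from_newick("(A:6,B:6);")
    s2, a, z0 = 1.3, 0.4, 0.5
    var = s2 * (1 - np.exp(-2 * a * 6)) / (2 * a)
    x = {"A": 1.0, "B": 0.0}
    expect = stats.norm.logpdf(1.0, z0, np.sqrt(var)) + stats.norm.logpdf(
        0.0, z0, np.sqrt(var)
    )
    assert ou_loglik(t, x, s2, a, z0) == pytest.approx(expect, abs=1e-10)


def test_dense_vs_pruning_agreement(tree120, rng):
    x = simulate_trait_matrix(tree120, TraitModel("bm"), (), seed=0, n_sims=1)[:, 0]
    for s2, z0 in [(0.5, 0.0), (2.0, 1.3)]:
        assert bm_loglik(tree120, x, s2, z0) == pytest.approx(
            bm_loglik(tree120, x, s2, z0, method="dense"), abs=1e-8
        )
    for a in (0.05, 0.3, 2.0):
        assert ou_loglik(tree120, x, 1.0, a, 0.5) == pytest.approx(
            ou_loglik(tree120, x, 1.0, a, 0.5, method="dense"), abs=1e-8
        )


def test_ou_bm_limit(tree120):
    x = simulate_trait_matrix(tree120, TraitModel("bm"), (), seed=1, n_sims=1)[:, 0]
    assert abs(
        ou_loglik(tree120, x, 1.2, 1e-12, 0.3) - bm_loglik(tree120, x, 1.2, 0.3)
    ) < 1e-6


def test_ou_covariance_against_path_oracle():
    """5-tip tree: OU covariance assembled from explicit tip paths."""
    t = eb.TimeTree.from_newick("(((A:1,B:1):2,C:3):1,(D:2,E:2):2);")
    a, s2 = 0.35, 1.0
    from earlyburst.modelfit import _ou_cov

    V = _ou_cov(t, a)
    labels = t.tip_labels
    inc = t.tip_incidence()
    # shared path length = age of deepest node containing both tips
    for i, li in enumerate(labels):
        for j, lj in enumerate(labels):
            s = 0.0
            for v in t.internal_ids:
                tips = {t.labels[int(q)] for q in t.clade_tips(v)}
                if li in tips and lj in tips:
                    s = max(s, t.age[v])
            if i == j:
                s = t.age[t.tip_ids[i]]
            d = t.age[t.tip_ids[i]] + t.age[t.tip_ids[j]] - 2 * s
            expect = (1 - np.exp(-2 * a * s)) / (2 * a) * np.exp(-a * d)
            assert V[i, j] == pytest.approx(expect, abs=1e-10)


def test_profile_sigma2_identity(tree120):
    x = simulate_trait_matrix(tree120, TraitModel("bm"), (), seed=2, n_sims=1)[:, 0]
    f = fit_model(tree120, x, "bm")
    C = tree120.mrca_age_matrix()
    Ci = np.linalg.inv(C)
    one = np.ones(len(x))
    z0 = float(one @ Ci @ x / (one @ Ci @ one))
    s2 = float((x - z0) @ Ci @ (x - z0) / len(x))
    assert f.z0 == pytest.approx(z0, rel=1e-8)
    assert f.sigma2 == pytest.approx(s2, rel=1e-8)


def test_aicc_identity():
    ll, n = -100.0, 50
    assert aicc(ll, 2, n) == pytest.approx(-2 * ll + 4 + 12 / (n - 3))
    assert aicc(ll, 3, 4) == np.inf


def test_fit_requires_four_tips(cherry3):
    with pytest.raises(ValueError):
        TraitEvolutionModel(cherry3, {"A": 1.0, "B": 2.0, "C": 0.0})


def test_tip_permutation_invariance(yule30):
    x = simulate_trait_matrix(yule30, TraitModel("bm"), (), seed=3, n_sims=1)[:, 0]
    s = pd.Series(x, index=yule30.tip_labels)
    shuffled = s.sample(frac=1.0, random_state=0)
    f1 = fit_model(yule30, s, "ou")
    f2 = fit_model(yule30, shuffled, "ou")
    assert f1.sigma2 == pytest.approx(f2.sigma2, rel=1e-12)
    assert f1.alpha == pytest.approx(f2.alpha, rel=1e-12)
    assert f1.loglik == pytest.approx(f2.loglik, rel=1e-12)


def test_ou_never_below_bm(yule30):
    for seed in range(5):
        kind = TraitModel("ou", alpha=0.4) if seed % 2 else TraitModel("bm")
        x = simulate_trait_matrix(yule30, kind, (), seed=seed, n_sims=1)[:, 0]
        fb = fit_model(yule30, x, "bm")
        fo = fit_model(yule30, x, "ou")
        assert fo.loglik >= fb.loglik - 1e-9


def test_parameter_recovery_bm():
    rng = np.random.default_rng(4)
    spec = eb.ConditioningSpec(15.0, 50, (0.1, 0.4))
    s2_hat = []
    for _ in range(40):
        t = eb.simulate_conditioned_tree(spec, rng)
        x = simulate_trait_matrix(t, TraitModel("bm", sigma2=1.0), (), rng, 1)[:, 0]
        s2_hat.append(fit_model(t, x, "bm").sigma2)
    assert 0.8 < np.median(s2_hat) < 1.2


def test_model_selection_calibration():
    """AICc prefers the generating model in the majority of replicates."""
    rng = np.random.default_rng(5)
    spec = eb.ConditioningSpec(15.0, 60, (0.1, 0.4))
    wins_bm = wins_ou = 0
    n_rep = 30
    for _ in range(n_rep):
        t = eb.simulate_conditioned_tree(spec, rng)
        xb = simulate_trait_matrix(t, TraitModel("bm"), (), rng, 1)[:, 0]
        xo = simulate_trait_matrix(
            t, TraitModel("ou", alpha=0.3, sigma2=1.0), (), rng, 1
        )[:, 0]
        wins_bm += fit_model(t, xb, "bm").aicc < fit_model(t, xb, "ou").aicc
        wins_ou += fit_model(t, xo, "ou").aicc < fit_model(t, xo, "bm").aicc
    assert wins_bm > n_rep / 2
    assert wins_ou > n_rep / 2


def test_compare_over_trees_identical_trees(yule30):
    x = simulate_trait_matrix(yule30, TraitModel("bm"), (), seed=6, n_sims=1)[:, 0]
    s = pd.Series(x, index=yule30.tip_labels)
    table = compare_over_trees([yule30] * 5, s)
    counts = table.n_preferring
    assert sorted(counts.values()) == [0, 5]
    single = fit_model(yule30, s, "bm")
    assert table.medians["bm"]["sigma2"] == pytest.approx(single.sigma2, rel=1e-12)
    assert sum(counts.values()) == table.n_trees == 5


def test_missing_values_dropped_not_imputed(yule30):
    x = simulate_trait_matrix(yule30, TraitModel("bm"), (), seed=7, n_sims=1)[:, 0]
    frame = pd.DataFrame({"tr": x}, index=yule30.tip_labels)
    frame.iloc[0, 0] = np.nan
    m = TraitEvolutionModel.from_dataframe(yule30, frame, "tr")
    assert m.tree.n_tips == yule30.n_tips - 1


def test_summary_mentions_estimates(yule30):
    x = simulate_trait_matrix(yule30, TraitModel("bm"), (), seed=8, n_sims=1)[:, 0]
    txt = fit_model(yule30, x, "ou").summary()
    assert "alpha" in txt and "AICc" in txt
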