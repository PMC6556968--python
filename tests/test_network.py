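"""Co-expression network statistics against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import telomark as tm
from telomark import network as nw


def _frame(arr, prefix="g"):
    idx = [f"{prefix}{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=idx,
                        columns=[f"s{j}" for j in range(arr.shape[1])])


# ------------------------------------------------------------------- adjacency

def test_adjacency_beta_one_is_absolute_correlation():
    rng = np.random.default_rng(0)
    expr = _frame(rng.standard_normal((5, 40)))
    a = nw.adjacency(expr, 1).to_numpy()
    r = np.abs(np.corrcoef(expr.to_numpy()))
    np.fill_diagonal(r, 0)
    assert np.allclose(a, r)


def test_adjacency_perfect_pair_and_hand_computed_toy():
    x = np.arange(10.0)
    expr = _frame(np.vstack([x, 2 * x + 1, -x, np.sin(x)]))
    a6 = nw.adjacency(expr, 6)
    assert a6.iloc[0, 1] == pytest.approx(1.0)
    assert a6.iloc[0, 2] == pytest.approx(1.0)   # unsigned network
    # element-wise oracle at beta=3
    a3 = nw.adjacency(expr, 3).to_numpy()
    for i in range(4):
        for j in range(4):
            expect = 0.0 if i == j else abs(np.corrcoef(expr.iloc[i], expr.iloc[j])[0, 1]) ** 3
            assert a3[i, j] == pytest.approx(expect, abs=1e-12)


def test_adjacency_zero_variance_gene_rejected():
    expr = _frame(np.vstack([np.ones(10), np.arange(10.0)]))
    with pytest.raises(ValueError, match="zero-variance"):
        nw.adjacency(expr, 2)


# ------------------------------------------------------------------------- TOM

def test_tom_three_node_worked_example():
    a = pd.DataFrame(0.5 * (1 - np.eye(3)))
    tom = nw.topological_overlap(a).to_numpy()
    assert tom[0, 1] == pytest.approx((0.25 + 0.5) / (1 + 1 - 0.5))
    assert np.allclose(np.diag(tom), 1.0)


def test_tom_isolated_genes():
    a = pd.DataFrame(np.zeros((4, 4)))
    tom = nw.topological_overlap(a).to_numpy()
    assert tom[0, 1] == 0.0


def test_tom_matches_triple_loop_oracle():
    """Brute-force triple loop agreement to 1e-10 on a 50-gene graph."""
    rng = np.random.default_rng(3)
    expr = _frame(rng.standard_normal((50, 30)))
    a = nw.adjacency(expr, 2)
    tom = nw.topological_overlap(a).to_numpy()
    A = a.to_numpy()
    k = A.sum(axis=1)
    n = len(A)
    for i in range(n):
        for j in range(n):
            if i == j:
                assert tom[i, j] == 1.0
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n))
            expect = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
            assert abs(tom[i, j] - expect) < 1e-10
    assert np.allclose(tom, tom.T)
    assert tom.min() >= 0 and tom.max() <= 1


# ------------------------------------------------------------- module detection

def test_detect_modules_two_perfect_blocks():
    rng = np.random.default_rng(1)
    f1, f2 = rng.standard_normal((2, 60))
    expr = _frame(np.vstack([np.outer(np.ones(10), f1) + 1e-6 * rng.standard_normal((10, 60)),
                             np.outer(np.ones(10), f2) + 1e-6 * rng.standard_normal((10, 60))]))
    tom = nw.topological_overlap(nw.adjacency(expr, 2))
    labels = nw.detect_modules(tom, min_module_size=5, cut_height=0.5)
    assert len(set(labels) - {0}) == 2
    assert len(set(labels.iloc[:10])) == 1 and len(set(labels.iloc[10:])) == 1


def test_detect_modules_min_size_unassigns_everything():
    rng = np.random.default_rng(2)
    expr = _frame(rng.standard_normal((12, 30)))
    tom = nw.topological_overlap(nw.adjacency(expr, 2))
    labels = nw.detect_modules(tom, min_module_size=50, cut_height=0.99)
    assert (labels == 0).all()


def test_planted_modules_recovered_with_high_ari(module_expr, planted_cohort):
    """Planted 3-module structure recovered (ARI oracle vs generator truth)."""
    truth = planted_cohort.truth
    res = tm.CoexpressionNetwork(module_expr).fit(beta=4, min_module_size=15)
    mod_genes = list(truth.modules)
    ari = adjusted_rand_score([truth.modules[g] for g in mod_genes],
                              list(res.module_labels.loc[mod_genes]))
    assert ari >= 0.9


def test_module_labels_invariant_under_gene_reordering(module_expr):
    res1 = tm.CoexpressionNetwork(module_expr).fit(beta=4, min_module_size=15)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(module_expr))
    shuffled = module_expr.iloc[perm]
    res2 = tm.CoexpressionNetwork(shuffled).fit(beta=4, min_module_size=15)
    ari = adjusted_rand_score(list(res1.module_labels.loc[module_expr.index]),
                              list(res2.module_labels.loc[module_expr.index]))
    assert ari == pytest.approx(1.0)


# ------------------------------------------------------------------- eigengenes

def test_eigengene_identical_genes_and_kme_one():
    rng = np.random.default_rng(5)
    prof = rng.standard_normal(30)
    expr = _frame(np.vstack([prof, prof, prof]))
    labels = pd.Series([1, 1, 1], index=expr.index)
    me = nw.module_eigengene(expr, labels)
    z = (prof - prof.mean()) / prof.std()
    assert np.allclose(me.loc[1].to_numpy(), z, atol=1e-8)
    k = nw.kme(expr, me)
    assert np.allclose(k.to_numpy(), 1.0)


def test_eigengene_orientation_invariant_to_sign_flip():
    rng = np.random.default_rng(6)
    base = rng.standard_normal(25)
    genes = np.vstack([base + 0.1 * rng.standard_normal(25) for _ in range(5)])
    expr = _frame(genes)
    labels = pd.Series(1, index=expr.index)
    me1 = nw.module_eigengene(expr, labels)
    me2 = nw.module_eigengene(-expr, labels)
    # orientation is deterministic: each ME correlates positively with its
    # own (possibly flipped) genes, so the two MEs are exact mirror images
    assert np.allclose(me1.loc[1].to_numpy(), -me2.loc[1].to_numpy(), atol=1e-8)
    z1 = ((expr - expr.mean(axis=1).to_numpy()[:, None])
          .div(expr.std(axis=1), axis=0)).mean(axis=0)
    assert np.corrcoef(me1.loc[1], z1)[0, 1] > 0


def test_eigengene_matches_power_iteration_oracle():
    rng = np.random.default_rng(7)
    expr = _frame(rng.standard_normal((5, 40)))
    labels = pd.Series(1, index=expr.index)
    me = nw.module_eigengene(expr, labels).loc[1].to_numpy()
    # power iteration on the sample-by-sample covariance of z-scored genes
    X = expr.to_numpy()
    Xz = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
    C = Xz.T @ Xz
    v = rng.standard_normal(40)
    for _ in range(500):
        v = C @ v
        v /= np.linalg.norm(v)
    v = v / v.std()
    if np.corrcoef(v, me)[0, 1] < 0:
        v = -v
    assert np.allclose(me, v, atol=1e-6)


def test_eigengene_rayleigh_property(module_expr):
    """The ME explains at least as much variance as any single gene's
    standardized profile within its module."""
    labels = pd.Series([1] * 20, index=module_expr.index[:20])
    sub = module_expr.iloc[:20]
    me = nw.module_eigengene(sub, labels).loc[1].to_numpy()
    X = sub.to_numpy()
    Xz = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
    me_var = np.mean((Xz @ me / np.linalg.norm(me)) ** 2)
    for g in range(20):
        gv = Xz[g] / np.linalg.norm(Xz[g])
        assert me_var >= np.mean((Xz @ gv) ** 2) - 1e-9


# ----------------------------------------------------------------- module merge

def test_merge_modules_threshold_and_chain():
    rng = np.random.default_rng(8)
    n = 200
    base = rng.standard_normal(n)
    mk = lambda r: r * base + np.sqrt(1 - r ** 2) * rng.standard_normal(n)
    # modules A and B highly correlated, C orthogonal
    genes = [mk(0.98) for _ in range(5)] + [mk(0.95) for _ in range(5)] + \
            [rng.standard_normal(n) for _ in range(5)]
    expr = _frame(np.vstack(genes))
    labels = pd.Series([1] * 5 + [2] * 5 + [3] * 5, index=expr.index)
    merged, mes = nw.merge_modules(expr, labels, diss_threshold=0.25)
    assert len(set(merged.iloc[:10])) == 1          # A and B merged
    assert merged.iloc[12] != merged.iloc[0]        # C stays apart
    # orthogonal modules unchanged at a tight threshold
    merged2, _ = nw.merge_modules(expr, labels, diss_threshold=0.01)
    assert (merged2 == labels).all() or len(set(merged2)) == len(set(labels))


def test_merge_modules_single_linkage_chain_semantics():
    rng = np.random.default_rng(9)
    n = 400
    f1 = rng.standard_normal(n)
    f3 = rng.standard_normal(n)
    f2 = (f1 + f3) / np.sqrt(2)                     # B close to both A and C
    mk = lambda f: np.vstack([0.995 * f + 0.1 * rng.standard_normal(n) for _ in range(4)])
    expr = _frame(np.vstack([mk(f1), mk(f2), mk(f3)]))
    labels = pd.Series([1] * 4 + [2] * 4 + [3] * 4, index=expr.index)
    me = nw.module_eigengene(expr, labels).to_numpy()
    r = np.corrcoef(me)
    assert 1 - r[0, 1] < 0.4 and 1 - r[1, 2] < 0.4 and 1 - r[0, 2] > 0.4
    merged, _ = nw.merge_modules(expr, labels, diss_threshold=0.4)
    assert len(set(merged)) == 1                    # chained into one module


# ----------------------------------------------------------------- connectivity

def test_intramodular_connectivity_uniform_module():
    a = pd.DataFrame(0.5 * (1 - np.eye(3)), index=list("abc"), columns=list("abc"))
    labels = pd.Series(1, index=list("abc"))
    K, hub = nw.intramodular_connectivity(a, labels)
    assert np.allclose(K, 1.0)
    assert hub.sum() == 1 and hub["a"]              # tie broken by gene ID


def test_exactly_one_hub_in_twenty_gene_module():
    rng = np.random.default_rng(10)
    expr = _frame(rng.standard_normal((20, 30)))
    a = nw.adjacency(expr, 2)
    labels = pd.Series(1, index=expr.index)
    _, hub = nw.intramodular_connectivity(a, labels)
    assert hub.sum() == 1


def test_connectivity_matches_double_loop_oracle(module_expr, planted_cohort):
    a = nw.adjacency(module_expr.iloc[:40], 2)
    labels = pd.Series([1] * 20 + [2] * 20, index=a.index)
    K, _ = nw.intramodular_connectivity(a, labels)
    A = a.to_numpy()
    for i in range(40):
        mod = labels.iloc[i]
        expect = sum(A[i, j] for j in range(40)
                     if labels.iloc[j] == mod and j != i)
        assert K.iloc[i] == pytest.approx(expect, abs=1e-12)


def test_unassigned_genes_never_hubs():
    rng = np.random.default_rng(11)
    expr = _frame(rng.standard_normal((10, 30)))
    a = nw.adjacency(expr, 2)
    labels = pd.Series([1] * 5 + [0] * 5, index=a.index)
    K, hub = nw.intramodular_connectivity(a, labels)
    assert not hub.iloc[5:].any()
    # unassigned K computed over the whole network
    A = a.to_numpy()
    assert K.iloc[7] == pytest.approx(A[7].sum())


def test_kme_trivial_cases():
    rng = np.random.default_rng(12)
    me = rng.standard_normal(30)
    expr = _frame(np.vstack([me, -me]))
    mes = pd.DataFrame([me], index=[1], columns=expr.columns)
    k = nw.kme(expr, mes)
    assert k.iloc[0, 0] == pytest.approx(1.0)
    assert k.iloc[1, 0] == pytest.approx(-1.0)


# ------------------------------------------------------------------ soft power

def test_pick_soft_power_smallest_passing_and_fallback(monkeypatch):
    rng = np.random.default_rng(13)
    expr = _frame(rng.standard_normal((30, 40)))
    # stub the fit so candidate powers 1..6 score (0.3, 0.95, 0.97, ...)
    calls = []

    def fake_fit(k, n_bins=10):
        calls.append(None)
        return ({1: 0.3, 2: 0.95}.get(len(calls), 0.97), -1.0)

    monkeypatch.setattr(nw, "scale_free_fit", fake_fit)
    assert nw.pick_soft_power(expr, candidate_powers=range(1, 7)) == 2

    calls.clear()
    monkeypatch.setattr(nw, "scale_free_fit", lambda k, n_bins=10: (0.5, -1.0))
    assert nw.pick_soft_power(expr, candidate_powers=range(1, 7)) == 6


def test_scale_free_fit_on_power_law_degrees():
    """A Pareto degree sequence yields a decreasing log-log line; the signed
    R^2 is independently recomputed with a separate straight-line fit on the
    same binned histogram."""
    rng = np.random.default_rng(14)
    k = (1 - rng.random(5000)) ** (-1 / 2.0)     # Pareto alpha=2
    r2, slope = nw.scale_free_fit(k, n_bins=10)
    assert slope < 0 and 0 < r2 <= 1
    edges = np.linspace(k.min(), k.max(), 11)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
    xs, ys = [], []
    for b in range(10):
        selb = which == b
        if selb.sum():
            xs.append(np.log10(k[selb].mean()))
            ys.append(np.log10(selb.mean()))
    m, c = np.polyfit(xs, ys, 1)
    resid = np.array(ys) - np.polyval([m, c], xs)
    r2_expect = 1 - resid @ resid / np.sum((ys - np.mean(ys)) ** 2)
    assert m < 0
    assert r2 == pytest.approx(r2_expect, rel=1e-9)


# ----------------------------------------------------------------- preservation

def test_preservation_planted_high_random_not(module_expr, planted_cohort):
    truth = planted_cohort.truth
    labels = pd.Series([truth.modules.get(g, 0) for g in module_expr.index],
                       index=module_expr.index)
    rep = nw.module_preservation_z(module_expr, module_expr, labels,
                                   n_perm=200, seed=1, beta=4)
    assert (rep.table["Zsummary"].astype(float) >= 10).all()
    assert (rep.table["category"] == "high").all()
    rng = np.random.default_rng(1)
    rnd = pd.Series(0, index=module_expr.index)
    rnd.iloc[rng.choice(len(rnd), 30, replace=False)] = 1
    rep_rnd = nw.module_preservation_z(module_expr, module_expr, rnd,
                                       n_perm=200, seed=1, beta=4)
    assert float(rep_rnd.table["Zsummary"].iloc[0]) < 2
    assert rep_rnd.table["category"].iloc[0] == "not_preserved"


@pytest.mark.parametrize("z, cat", [
    (1.99, "not_preserved"), (2.0, "moderate"), (9.99, "moderate"), (10.0, "high"),
])
def test_preservation_category_boundaries(z, cat):
    assert nw.PreservationReport.categorize(z) == cat


# ----------------------------------------------------- hub tiers / activity link

@pytest.mark.parametrize("n_hub, tier", [
    (8, "strong"), (5, "strong"), (4, "median"), (3, "median"),
    (2, "weak"), (1, "weak"), (0, "none"),
])
def test_hub_strength_tiers(n_hub, tier):
    row = [True] * n_hub + [False] * (8 - n_hub)
    tab = pd.DataFrame([row], index=["g"])
    assert nw.classify_hub_strength(tab)["g"] == tier


def test_connectivity_activity_correlation_cases():
    K = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
    act = pd.Series([0.1 + 0.2 * k for k in K], index=K.index)
    r, p = nw.connectivity_activity_correlation(K, act)
    assert r == pytest.approx(1.0)
    r2, p2 = nw.connectivity_activity_correlation(
        pd.Series([1.0, 1, 1, 1], index=list("abcd")), act)
    assert np.isnan(r2)


def test_hubs_correlate_with_activity(planted_cohort, module_expr):
    """Hubs of the activity module load harder on the factor that drives the
    telomerase signature, so K correlates positively with each gene's
    activity correlation."""
    co = planted_cohort
    act = co.truth.activity_latent
    mod1 = [g for g, m in co.truth.modules.items() if m == 1]
    expr = co.layers["mrna"].values
    per_gene_r = pd.Series(
        {g: np.corrcoef(expr.loc[g], act)[0, 1] for g in mod1})
    a = nw.adjacency(expr.loc[mod1], 4)
    labels = pd.Series(1, index=a.index)
    K, _ = nw.intramodular_connectivity(a, labels)
    r, p = nw.connectivity_activity_correlation(K, per_gene_r)
    assert r > 0 and p < 0.05
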