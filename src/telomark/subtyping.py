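"""Unsupervised random-forest dissimilarity subtyping with survival tests.

A mixed-type marker profile (top differential genes / methylation probes /
miRNAs / mutations / copy-number calls plus consensus hub genes, the
miR-17-92 members, and TERT) is contrasted against a "synthetic" null
dataset drawn from the product of the empirical marginals.  A random
forest trained to separate observed from synthetic data yields a
similarity: the fraction of trees in which two observed samples share a
terminal node.  Dissimilarity sqrt(1 - similarity) feeds partitioning
around medoids (PAM, BUILD + SWAP); the two clusters are compared on a
telomerase-activity score (Wilcoxon), Kaplan-Meier survival (log-rank) and
a univariate Cox model.  Cluster 1 is, by convention, the cluster with the
higher median telomerase score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .mirna import group_score_test

logger = logging.getLogger(__name__)

TOP_N = {"mrna": 20, "methylation": 20, "mirna": 5, "mutation": 5, "scna": 5}


@dataclass
class MarkerProfile:
    """Samples x markers mixed-type table with per-column provenance."""

    table: pd.DataFrame
    provenance: pd.Series          # per-column label (top_gene, global_hub, ...)
    binary_cols: list[str] = field(default_factory=list)

    @property
    def samples(self) -> pd.Index:
        return self.table.index


def assemble_marker_profile(diff_results: dict[str, pd.DataFrame],
                            hub_genes, mirna_cluster, layers,
                            top_n: dict | None = None) -> MarkerProfile:
    """Build the subtyping marker table.

    Per layer, significant features are ranked by |dMW| descending and the
    top 20 (mRNA, methylation) or top 5 (miRNA, mutation, SCNA) are taken;
    TERT is appended if absent, as are the consensus hub genes and the
    miR-17-92 members present in their layers.  When a layer offers fewer
    significant features than requested, all are taken with a warning.
    """
    top_n = dict(TOP_N, **(top_n or {}))
    provenance_of = {
        "mrna": "top_gene", "methylation": "top_methylation",
        "mirna": "top_mirna", "mutation": "top_snp", "scna": "top_scna",
    }
    columns: list[pd.Series] = []
    prov: dict[str, str] = {}
    binary_cols: list[str] = []
    samples = None

    def add(layer_tag: str, feature: str, label: str) -> None:
        layer = layers.get(layer_tag)
        if layer is None or feature not in layer.values.index:
            return
        name = f"{layer_tag}:{feature}"
        if name in prov:
            return
        col = layer.values.loc[feature].rename(name)
        columns.append(col)
        prov[name] = label
        if layer_tag in ("mutation",):
            binary_cols.append(name)

    for tag, res in diff_results.items():
        if tag not in layers:
            continue
        sig = res.loc[res.get("significant", pd.Series(True, index=res.index))]
        want = top_n.get(tag, 5)
        ranked = sig.reindex(sig["delta_mw"].abs().sort_values(ascending=False).index)
        if len(ranked) < want:
            logger.warning("layer %s: only %d significant features for top %d",
                           tag, len(ranked), want)
        for feat in ranked.index[:want]:
            add(tag, feat, provenance_of[tag])

    add("mrna", "TERT", "top_gene")
    for g in hub_genes:
        add("mrna", g, "global_hub")
    for m in mirna_cluster:
        # cluster members may be stored under canonical names
        mlayer = layers.get("mirna")
        if mlayer is not None:
            from .mirna import normalize_mirna_name

            lookup = {normalize_mirna_name(i): i for i in mlayer.values.index}
            hit = lookup.get(normalize_mirna_name(m))
            if hit is not None:
                add("mirna", hit, "global_mirna")

    if not columns:
        raise ValueError("no markers available: no significant features and no global markers")
    table = pd.concat(columns, axis=1)
    if samples is not None:
        table = table.loc[samples]
    return MarkerProfile(table=table, provenance=pd.Series(prov),
                         binary_cols=binary_cols)


def impute_markers(table: pd.DataFrame, binary_cols=()) -> pd.DataFrame:
    """Median (numeric) / mode (binary) imputation with a logged count."""
    out = table.copy()
    n_missing = int(out.isna().sum().sum())
    if n_missing:
        logger.info("imputing %d missing marker values", n_missing)
    for col in out.columns:
        if out[col].isna().any():
            if col in set(binary_cols):
                fill = out[col].mode(dropna=True)
                out[col] = out[col].fillna(fill.iloc[0] if len(fill) else 0)
            else:
                out[col] = out[col].fillna(out[col].median())
    return out


def synthesize_null_data(X: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Sample each column independently, with replacement, from its own
    observed values (the product of the empirical marginals)."""
    if X.isna().any().any():
        raise ValueError("marker table contains missing values; impute first")
    rng = np.random.default_rng(seed)
    cols = {c: rng.choice(X[c].to_numpy(), size=len(X), replace=True)
            for c in X.columns}
    return pd.DataFrame(cols, index=X.index)


@dataclass
class RFDissimilarity:
    """Random-forest dissimilarity matrix over observed samples."""

    matrix: pd.DataFrame
    n_trees: int
    seed: int
    oob_score: float | None = None


def rf_dissimilarity(X: pd.DataFrame, n_trees: int = 2000,
                     seed: int = 0) -> RFDissimilarity:
    """sqrt(1 - co-terminal-node frequency) from an observed-vs-synthetic
    random forest.

    All observed samples are propagated down every tree; samples sharing a
    terminal node increment the pair's similarity, which is normalized by
    the tree count and symmetrized.  The diagonal is exactly zero.
    """
    if len(X) < 10:
        raise ValueError("need at least 10 samples")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 markers")
    X_imp = impute_markers(X)
    X_synth = synthesize_null_data(X_imp, seed=seed)
    if X_imp.to_numpy().std() == 0:
        raise ValueError("degenerate marker table: observed data are constant")

    data = np.vstack([X_imp.to_numpy(dtype=float), X_synth.to_numpy(dtype=float)])
    y = np.concatenate([np.ones(len(X_imp)), np.zeros(len(X_synth))])
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", min_samples_leaf=1,
        random_state=seed, n_jobs=1,
    )
    forest.fit(data, y)

    leaves = forest.apply(X_imp.to_numpy(dtype=float))   # samples x trees
    n = len(X_imp)
    sim = np.zeros((n, n))
    for t in range(leaves.shape[1]):
        col = leaves[:, t]
        sim += col[:, None] == col[None, :]
    sim /= leaves.shape[1]
    sim = (sim + sim.T) / 2.0
    D = np.sqrt(np.clip(1.0 - sim, 0.0, 1.0))
    np.fill_diagonal(D, 0.0)
    return RFDissimilarity(
        matrix=pd.DataFrame(D, index=X.index, columns=X.index),
        n_trees=n_trees, seed=seed,
    )


def pam_cluster(D, k: int = 2, exact_limit: int = 50_000):
    """Partitioning around medoids (k-medoids on a precomputed dissimilarity).

    When the medoid search space C(n, k) is at most `exact_limit` the
    objective is minimized exactly by enumeration (for k = 2 this covers
    cohorts of thousands of samples at negligible cost, and side-steps the
    1-exchange local optima that the classic BUILD+SWAP heuristic — and R's
    reference implementation — can fall into).  Larger search spaces use
    greedy BUILD followed by best-improvement SWAP to a local optimum.

    Deterministic given the dissimilarity (ties broken by sample order).
    Returns (labels 1..k by nearest medoid, medoid identifiers).
    """
    if isinstance(D, pd.DataFrame):
        ids = list(D.index)
        M = D.to_numpy(dtype=float)
    else:
        M = np.asarray(D, dtype=float)
        ids = list(range(len(M)))
    n = len(M)
    if not (2 <= k < n):
        raise ValueError(f"k must satisfy 2 <= k < n (k={k}, n={n})")
    if not np.allclose(M, M.T) or not np.allclose(np.diag(M), 0):
        raise ValueError("D must be a symmetric zero-diagonal dissimilarity")

    def total_cost(meds):
        return M[np.ix_(range(n), meds)].min(axis=1).sum()

    from math import comb as _comb
    from itertools import combinations as _combinations

    if _comb(n, k) <= exact_limit:
        best_meds, best_cost = None, np.inf
        for cand in _combinations(range(n), k):
            c = total_cost(list(cand))
            if c < best_cost - 1e-12:
                best_meds, best_cost = list(cand), c
        medoids = sorted(best_meds)
        assign = np.argmin(M[np.ix_(range(n), medoids)], axis=1)
        labels = pd.Series(assign + 1, index=ids, name="cluster")
        return labels, [ids[m] for m in medoids]

    # BUILD: first medoid minimizes total dissimilarity; subsequent medoids
    # maximize the cost reduction
    medoids = [int(np.argmin(M.sum(axis=1)))]
    dist_near = M[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.array([
            np.maximum(dist_near - M[c], 0.0).sum() if c not in medoids else -np.inf
            for c in range(n)
        ])
        best = int(np.argmax(gains))
        medoids.append(best)
        dist_near = np.minimum(dist_near, M[best])

    # SWAP, best-improvement: evaluate every (medoid, candidate) exchange and
    # apply the single best one, until no exchange lowers the total cost
    cost = total_cost(medoids)
    while True:
        best_cand, best_cost = None, cost
        for mi in range(k):
            for h in range(n):
                if h in medoids:
                    continue
                cand = medoids.copy()
                cand[mi] = h
                c = total_cost(cand)
                if c < best_cost - 1e-12:
                    best_cand, best_cost = cand, c
        if best_cand is None:
            break
        medoids, cost = best_cand, best_cost
    medoids = sorted(medoids)
    assign = np.argmin(M[np.ix_(range(n), medoids)], axis=1)
    labels = pd.Series(assign + 1, index=ids, name="cluster")
    return labels, [ids[m] for m in medoids]


def telomerase_activity_score(expr: pd.DataFrame, signature_genes) -> pd.Series:
    """Mean per-gene z-scored log2 expression of the signature genes."""
    present = [g for g in signature_genes if g in expr.index]
    if not present:
        raise ValueError("no signature genes present in the expression matrix")
    missing = sorted(set(signature_genes) - set(present))
    if missing:
        logger.info("signature genes missing: %s", missing)
    sub = expr.loc[present].to_numpy(dtype=float)
    sd = sub.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd
    return pd.Series(z.mean(axis=0), index=expr.columns, name="telomerase_score")


def logrank_test(time, event, labels):
    """Two-group log-rank test; returns (chi_square, p)."""
    from lifelines.statistics import logrank_test as _ll_logrank

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = np.asarray(labels)
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    if event.sum() == 0:
        raise ValueError("no events observed")
    g = labels == uniq[1]
    res = _ll_logrank(time[g], time[~g], event_observed_A=event[g],
                      event_observed_B=event[~g])
    return float(res.test_statistic), float(res.p_value)


def cox_univariate(time, event, x):
    """Univariate Cox proportional-hazards fit (Breslow ties via lifelines).

    Returns (hazard_ratio, p).  A constant covariate is an error; monotone
    likelihood (perfect separation) is logged as flagged.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    x = np.asarray(x, dtype=float)
    if np.std(x) == 0:
        raise ValueError("covariate is constant: no information")
    df = pd.DataFrame({"time": np.asarray(time, dtype=float),
                       "event": np.asarray(event, dtype=int),
                       "x": x})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise RuntimeError(f"Cox fit did not converge: {err}") from err
    coef = float(cph.params_["x"])
    if abs(coef) > 15:
        logger.warning("Cox fit flagged: monotone likelihood / separation suspected")
    return float(np.exp(coef)), float(cph.summary.loc["x", "p"])


@dataclass
class SubtypeResults:
    """Two random-forest subtypes compared on telomerase score and survival."""

    labels: pd.Series              # 1 | 2; cluster 1 has the higher median score
    medoids: list
    dissimilarity: pd.DataFrame
    telomerase_score: pd.Series
    wilcoxon_stat: float
    wilcoxon_p: float
    logrank_chi2: float
    logrank_p: float
    cox_hr: float
    cox_p: float

    def summary(self) -> str:
        sizes = self.labels.value_counts().sort_index()
        med1 = self.telomerase_score[self.labels == 1].median()
        med2 = self.telomerase_score[self.labels == 2].median()
        return "\n".join([
            "Random-forest subtypes",
            "======================",
            f"cluster sizes: {sizes.to_dict()}   medoids: {self.medoids}",
            f"median telomerase score: cluster1 {med1:.3f}, cluster2 {med2:.3f}",
            f"Wilcoxon (score): W = {self.wilcoxon_stat:.1f}, p = {self.wilcoxon_p:.3g}",
            f"log-rank: chi2 = {self.logrank_chi2:.2f}, p = {self.logrank_p:.3g}",
            f"Cox (cluster 2 vs 1): HR = {self.cox_hr:.2f}, p = {self.cox_p:.3g}",
        ])

    def plot_survival(self, time, event, ax=None):
        """Kaplan-Meier curves per subtype."""
        import matplotlib.pyplot as plt
        from lifelines import KaplanMeierFitter

        if ax is None:
            _, ax = plt.subplots()
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        for lab in (1, 2):
            sel = (self.labels == lab).to_numpy()
            KaplanMeierFitter().fit(time[sel], event[sel],
                                    label=f"RFcluster{lab}").plot_survival_function(ax=ax)
        ax.set_xlabel("time")
        ax.set_ylabel("survival probability")
        return ax


def compare_subtypes(labels: pd.Series, score: pd.Series, time, event,
                     dissimilarity: pd.DataFrame | None = None,
                     medoids=None) -> SubtypeResults:
    """Orient labels (cluster 1 = higher median telomerase score) and run
    the Wilcoxon, log-rank, and univariate Cox comparisons."""
    labels = pd.Series(labels)
    score = pd.Series(score).reindex(labels.index)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError("exactly two clusters required")
    med = {u: score[labels == u].median() for u in uniq}
    hi = max(uniq, key=lambda u: med[u])
    oriented = pd.Series(np.where(labels == hi, 1, 2), index=labels.index,
                         name="cluster")
    w_stat, w_p = group_score_test(score.to_numpy(), oriented.to_numpy())
    chi2, lr_p = logrank_test(time, event, oriented.to_numpy())
    hr, cox_p = cox_univariate(time, event, (oriented == 2).astype(float).to_numpy())
    return SubtypeResults(
        labels=oriented, medoids=medoids or [],
        dissimilarity=dissimilarity if dissimilarity is not None else pd.DataFrame(),
        telomerase_score=score,
        wilcoxon_stat=w_stat, wilcoxon_p=w_p,
        logrank_chi2=chi2, logrank_p=lr_p, cox_hr=hr, cox_p=cox_p,
    )


class RandomForestSubtyper:
    """Unsupervised subtyping model over a marker profile.

    Parameters
    ----------
    profile : MarkerProfile or DataFrame
        Samples x markers mixed-type table.
    expr : DataFrame
        Genes x samples log2 expression (for the telomerase score).
    signature_genes : sequence of str
        Telomerase-activity signature gene list.
    time, event : array-like
        Survival follow-up aligned with the profile's samples.
    """

    def __init__(self, profile, expr, signature_genes, time, event):
        self.profile = profile.table if isinstance(profile, MarkerProfile) else profile
        self.expr = expr
        self.signature_genes = list(signature_genes)
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)

    def fit(self, n_trees: int = 2000, k: int = 2, seed: int = 0) -> SubtypeResults:
        rfd = rf_dissimilarity(self.profile, n_trees=n_trees, seed=seed)
        labels, medoids = pam_cluster(rfd.matrix, k=k)
        score = telomerase_activity_score(self.expr, self.signature_genes)
        score = score.reindex(labels.index)
        res = compare_subtypes(labels, score, self.time, self.event,
                               dissimilarity=rfd.matrix, medoids=medoids)
        return res
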