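"""Weighted gene co-expression network construction and module statistics.

The network is unsigned: adjacency a_ij = |Pearson r_ij|^beta with zero
diagonal, where the soft power beta is the smallest candidate whose signed
scale-free-topology fit R^2 exceeds 0.9.  Topological overlap

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

measures shared neighborhoods; modules come from average-linkage
hierarchical clustering of 1 - TOM with a static tree cut (a deliberate
simplification of the dynamic tree cut; planted-truth recovery is the test
surface).  Each module is summarized by its eigengene (first principal
component of the z-scored member genes), close modules are merged on
eigengene correlation, and genes carry intramodular connectivity K (sum of
in-module edge weights), module-membership kME, and a hub flag for the top
5% K within their module.

Module preservation between a reference and a test expression matrix is a
permutation Z composite: Zsummary = median(Zdensity, Zconnectivity), read
against the standard cutoffs (< 2 not preserved, >= 10 highly preserved).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

DEFAULT_POWERS = tuple(range(1, 13))
PRESERVATION_CUTS = (2.0, 10.0)


def _corr_matrix(expr: pd.DataFrame) -> np.ndarray:
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = expr.index[sd == 0].tolist()
        raise ValueError(f"zero-variance genes: {bad}")
    return np.corrcoef(X)


def scale_free_fit(k: np.ndarray, n_bins: int = 10):
    """Signed R^2 of the log-log degree distribution fit.

    Connectivities are binned into `n_bins` equal-width bins; log10 bin
    frequency is regressed on log10 mean bin connectivity.  The R^2 carries
    the sign of -slope (scale-free topology requires a decreasing law).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 2:
        raise ValueError("fewer than 2 occupied connectivity bins")
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(np.sign(-slope) * r ** 2), float(slope)


def pick_soft_power(expr: pd.DataFrame, candidate_powers=DEFAULT_POWERS,
                    r2_min: float = 0.9) -> int:
    """Smallest candidate power with signed scale-free fit R^2 > r2_min.

    Falls back to the largest candidate (with a warning) when none passes.
    """
    candidates = sorted(candidate_powers)
    if len(candidates) < 3:
        raise ValueError("need at least 3 candidate powers")
    if expr.shape[0] < 20:
        raise ValueError("need at least 20 genes for a meaningful fit")
    absr = np.abs(_corr_matrix(expr))
    np.fill_diagonal(absr, 0.0)
    for beta in candidates:
        k = (absr ** beta).sum(axis=1)
        r2, _ = scale_free_fit(k)
        if r2 > r2_min:
            return int(beta)
    logger.warning("no candidate power reached scale-free R^2 > %.2f; "
                   "falling back to %d", r2_min, candidates[-1])
    return int(candidates[-1])


def adjacency(expr: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Unsigned adjacency |r|^beta with zero diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    a = np.abs(_corr_matrix(expr)) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij); diag 1."""
    a = adj.to_numpy(dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if not np.allclose(np.diag(a), 0.0):
        raise ValueError("adjacency diagonal must be zero")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def detect_modules(tom: pd.DataFrame, min_module_size: int = 30,
                   cut_height: float = 0.995) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static cut.

    `cut_height` is a fraction of the maximum merge height.  Clusters
    smaller than `min_module_size` are labeled 0 (unassigned); surviving
    modules are renumbered 1, 2, ... by decreasing size (ties by smallest
    member gene ID).
    """
    genes = tom.index
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    link = average(squareform(diss, checks=False))
    height = cut_height * link[:, 2].max()
    raw = fcluster(link, t=height, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    keep = sizes.index[sizes >= min_module_size]
    # order: decreasing size, ties by the smallest gene ID in the cluster
    order = sorted(
        keep,
        key=lambda c: (-sizes[c], genes[np.flatnonzero(raw == c)].min()),
    )
    relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series([relabel.get(c, 0) for c in raw], index=genes, name="module")
    if (labels == 0).all():
        logger.warning("all genes unassigned: no cluster reached min_module_size=%d",
                       min_module_size)
    return labels


def assign_by_kme(expr: pd.DataFrame, labels: pd.Series,
                  min_kme: float = 0.3) -> pd.Series:
    """Assign unassigned genes to the module whose eigengene they correlate
    with best, when that correlation reaches `min_kme`.

    This is the straggler-rescue pass of the simplified module detection:
    the static tree cut leaves weakly loading members unassigned, and module
    membership (kME) recovers them the way the dynamic-cut PAM stage does.
    """
    labels = labels.copy()
    mods = sorted(set(labels) - {0})
    if not mods or not (labels == 0).any():
        return labels
    mes = module_eigengene(expr, labels)
    unassigned = labels.index[labels == 0]
    k = kme(expr.loc[unassigned], mes)
    best = k.idxmax(axis=1).str.removeprefix("kME").astype(int)
    best_val = k.max(axis=1)
    accept = best_val >= min_kme
    labels.loc[unassigned[accept]] = best[accept]
    return labels


def module_eigengene(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component per module, per sample (modules x samples).

    Genes are z-scored first; the eigengene is scaled to unit variance and
    sign-oriented so its mean correlation with the module's genes is
    positive.  A single-gene module returns that gene's z-scored profile.
    """
    mes = {}
    for mod in sorted(set(labels) - {0}):
        sub = expr.loc[labels.index[labels == mod]]
        Xz = _zscore_rows(sub.to_numpy(dtype=float))
        if Xz.shape[0] == 1:
            me = Xz[0]
        else:
            # PC1 across samples of the gene-standardized submatrix
            _, _, vt = np.linalg.svd(Xz - Xz.mean(axis=1, keepdims=True),
                                     full_matrices=False)
            me = vt[0]
        me = me / me.std() if me.std() > 0 else me
        if np.mean([np.corrcoef(me, g)[0, 1] for g in Xz]) < 0:
            me = -me
        mes[mod] = me
    out = pd.DataFrame(mes, index=expr.columns).T
    out.index.name = "module"
    return out


def merge_modules(expr: pd.DataFrame, labels: pd.Series,
                  diss_threshold: float = 0.25):
    """Merge modules whose eigengene dissimilarity (1 - r) < threshold.

    Single-linkage semantics: modules connected through a chain of close
    pairs all merge.  Returns (merged labels renumbered by size, recomputed
    eigengenes).
    """
    mods = sorted(set(labels) - {0})
    if len(mods) < 2:
        return labels.copy(), module_eigengene(expr, labels)
    mes = module_eigengene(expr, labels)
    r = np.corrcoef(mes.to_numpy())
    diss = 1.0 - r
    # connected components of the "close" graph = single-linkage merge
    parent = {m: m for m in mods}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, mi in enumerate(mods):
        for j in range(i + 1, len(mods)):
            if diss[i, j] < diss_threshold:
                parent[find(mods[j])] = find(mi)
    groups: dict[int, list[int]] = {}
    for m in mods:
        groups.setdefault(find(m), []).append(m)

    merged = labels.copy()
    tmp = {}
    for root, members in groups.items():
        for m in members:
            tmp[m] = root
    merged = labels.map(lambda m: tmp.get(m, 0))
    sizes = merged[merged != 0].value_counts()
    order = sorted(sizes.index,
                   key=lambda c: (-sizes[c], labels.index[merged == c].min()))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    merged = merged.map(lambda m: relabel.get(m, 0)).rename("module")
    return merged, module_eigengene(expr, merged)


def intramodular_connectivity(adj: pd.DataFrame, labels: pd.Series):
    """Per-gene in-module connectivity K and hub flags.

    K_i sums adjacency to same-module genes; hubs are the ceil(5% x size)
    highest-K genes per module (at least one; ties broken by gene ID).
    Unassigned genes get whole-network K and are never hubs.
    """
    a = adj.to_numpy(dtype=float)
    genes = adj.index
    lab = labels.reindex(genes).to_numpy()
    K = np.empty(len(genes))
    hub = np.zeros(len(genes), dtype=bool)
    for mod in np.unique(lab):
        sel = np.flatnonzero(lab == mod)
        if mod == 0:
            K[sel] = a[sel].sum(axis=1)
            continue
        K[sel] = a[np.ix_(sel, sel)].sum(axis=1)
        n_hub = max(1, int(np.ceil(0.05 * len(sel))))
        order = sorted(sel, key=lambda i: (-K[i], genes[i]))
        hub[order[:n_hub]] = True
    return (pd.Series(K, index=genes, name="K"),
            pd.Series(hub, index=genes, name="hub"))


def kme(expr: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between every gene and every module eigengene."""
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1)
    Xz = np.where(sd[:, None] > 0, _zscore_rows(X), np.nan)
    E = _zscore_rows(eigengenes.to_numpy(dtype=float))
    vals = Xz @ E.T / X.shape[1]
    return pd.DataFrame(vals, index=expr.index,
                        columns=[f"kME{m}" for m in eigengenes.index])


@dataclass
class PreservationReport:
    """Permutation-Z module preservation between two expression matrices."""

    table: pd.DataFrame            # index module; Zdensity, Zconnectivity, Zsummary, category

    @staticmethod
    def categorize(zsummary: float) -> str:
        lo, hi = PRESERVATION_CUTS
        if zsummary < lo:
            return "not_preserved"
        if zsummary < hi:
            return "moderate"
        return "high"


def module_preservation_z(expr_ref: pd.DataFrame, expr_test: pd.DataFrame,
                          labels_ref: pd.Series, n_perm: int = 200,
                          seed: int = 0, beta: float = 6) -> PreservationReport:
    """Zsummary preservation of reference modules in a test network.

    For each module: density = mean intramodular adjacency in the test
    network; connectivity = Pearson r between the in-module connectivity
    vectors of the reference and test networks.  Both are Z-scored against
    `n_perm` random same-size gene sets drawn in the test network;
    Zsummary = median(Zdensity, Zconnectivity).
    """
    if not expr_ref.index.equals(expr_test.index):
        raise ValueError("reference and test matrices must share the same genes")
    mods = sorted(set(labels_ref) - {0})
    if not mods:
        raise ValueError("no modules to assess")
    if max(pd.Series(labels_ref).value_counts().drop(0, errors="ignore")) > len(expr_ref):
        raise ValueError("module larger than the gene universe")

    a_ref = adjacency(expr_ref, beta).to_numpy()
    a_test = adjacency(expr_test, beta).to_numpy()
    genes = expr_ref.index
    rng = np.random.default_rng(seed)
    n_genes = len(genes)

    def mod_stats(sel: np.ndarray):
        sub_t = a_test[np.ix_(sel, sel)]
        sub_r = a_ref[np.ix_(sel, sel)]
        m = len(sel)
        density = sub_t.sum() / (m * (m - 1)) if m > 1 else 0.0
        k_r = sub_r.sum(axis=1)
        k_t = sub_t.sum(axis=1)
        if np.std(k_r) == 0 or np.std(k_t) == 0:
            conn = 0.0
        else:
            conn = float(np.corrcoef(k_r, k_t)[0, 1])
        return density, conn

    rows = {}
    for mod in mods:
        sel = np.flatnonzero((labels_ref == mod).to_numpy())
        d_obs, c_obs = mod_stats(sel)
        d_null = np.empty(n_perm)
        c_null = np.empty(n_perm)
        for p in range(n_perm):
            rnd = rng.choice(n_genes, size=len(sel), replace=False)
            d_null[p], c_null[p] = mod_stats(rnd)
        zd = _zscore_obs(d_obs, d_null)
        zc = _zscore_obs(c_obs, c_null)
        # a zero-variance permutation null (e.g. ref and test are the same
        # matrix, where every connectivity correlation is exactly 1) makes
        # that Z undefined; it is dropped from the composite
        comps = [v for v in (zd, zc) if np.isfinite(v) or np.isinf(v)]
        comps = [v for v in comps if not np.isnan(v)]
        zsummary = float(np.median(comps)) if comps else 0.0
        rows[mod] = {
            "Zdensity": zd, "Zconnectivity": zc, "Zsummary": zsummary,
            "category": PreservationReport.categorize(zsummary),
        }
    return PreservationReport(pd.DataFrame(rows).T)


def classify_hub_strength(hub_table: pd.DataFrame) -> pd.Series:
    """Tier genes by the number of conditions in which they are hubs.

    5+ conditions -> strong, 3-4 -> median, 1-2 -> weak, 0 -> none.
    `hub_table` is genes x conditions boolean.
    """
    counts = hub_table.astype(bool).sum(axis=1)
    tiers = pd.cut(counts, bins=[-1, 0, 2, 4, np.inf],
                   labels=["none", "weak", "median", "strong"])
    return pd.Series(tiers.astype(str), index=hub_table.index, name="hub_strength")


def connectivity_activity_correlation(K: pd.Series, per_gene_activity_r: pd.Series):
    """Pearson correlation (with two-sided p) between intramodular
    connectivity and each gene's correlation with the telomerase-activity
    score.  Returns (nan, nan) when K is constant."""
    common = K.index.intersection(per_gene_activity_r.index)
    if len(common) < 3:
        raise ValueError("need at least 3 genes")
    k = K.loc[common].to_numpy(dtype=float)
    r = per_gene_activity_r.loc[common].to_numpy(dtype=float)
    if np.std(k) == 0 or np.std(r) == 0:
        logger.warning("constant connectivity or activity vector; correlation undefined")
        return float("nan"), float("nan")
    res = stats.pearsonr(k, r)
    return float(res.statistic), float(res.pvalue)


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def _zscore_obs(obs: float, null: np.ndarray) -> float:
    sd = null.std()
    if sd < 1e-9:  # degenerate up to floating-point jitter
        # degenerate null: undefined when the observation matches it,
        # +-inf when it clearly exceeds it
        if np.isclose(obs, null.mean()):
            return float("nan")
        return float(np.sign(obs - null.mean()) * np.inf)
    return float((obs - null.mean()) / sd)


# --------------------------------------------------------------------------
# Model / Results surface
# --------------------------------------------------------------------------

@dataclass
class CoexpressionNetworkResults:
    """A fitted co-expression network with module statistics."""

    beta: int
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    module_labels: pd.Series
    eigengenes: pd.DataFrame
    K: pd.Series
    kme: pd.DataFrame
    hub_flags: pd.Series

    @property
    def modules(self) -> list[int]:
        return sorted(set(self.module_labels) - {0})

    def hubs(self, module: int | None = None) -> pd.Index:
        flags = self.hub_flags
        if module is not None:
            flags = flags & (self.module_labels == module)
        return flags.index[flags]

    def gene_table(self) -> pd.DataFrame:
        tab = pd.DataFrame({
            "module": self.module_labels,
            "K": self.K,
            "hub": self.hub_flags,
        })
        return tab.join(self.kme)

    def summary(self) -> str:
        sizes = self.module_labels[self.module_labels != 0].value_counts().sort_index()
        lines = [
            "Weighted co-expression network",
            "==============================",
            f"genes: {len(self.module_labels)}   soft power beta: {self.beta}",
            f"modules: {len(sizes)} (sizes: {sizes.to_dict()}); "
            f"unassigned: {int((self.module_labels == 0).sum())}",
            f"hub genes: {int(self.hub_flags.sum())}",
        ]
        return "\n".join(lines)

    def plot_dendrogram(self, ax=None):
        import matplotlib.pyplot as plt
        from scipy.cluster.hierarchy import dendrogram

        if ax is None:
            _, ax = plt.subplots()
        diss = 1.0 - self.tom.to_numpy()
        np.fill_diagonal(diss, 0.0)
        link = average(squareform(np.clip((diss + diss.T) / 2, 0, None), checks=False))
        dendrogram(link, no_labels=True, ax=ax)
        ax.set_ylabel("1 - TOM")
        return ax


class CoexpressionNetwork:
    """Co-expression network model over a genes x samples expression matrix.

    `fit` picks the soft power (unless given), builds adjacency and TOM,
    detects and merges modules, and computes eigengenes, connectivity, kME
    and hub flags.
    """

    def __init__(self, expr: pd.DataFrame):
        if expr.shape[0] < 3:
            raise ValueError("need at least 3 genes")
        self.expr = expr

    @classmethod
    def from_layer(cls, layer) -> "CoexpressionNetwork":
        return cls(layer.values)

    def fit(self, beta: int | None = None, candidate_powers=DEFAULT_POWERS,
            r2_min: float = 0.9, min_module_size: int = 30,
            cut_height: float = 0.995, merge_diss: float = 0.25,
            kme_rescue: float = 0.3) -> CoexpressionNetworkResults:
        if beta is None:
            beta = pick_soft_power(self.expr, candidate_powers, r2_min)
        adj = adjacency(self.expr, beta)
        tom = topological_overlap(adj)
        labels = detect_modules(tom, min_module_size, cut_height)
        if (labels != 0).any():
            if kme_rescue is not None:
                labels = assign_by_kme(self.expr, labels, kme_rescue)
            labels, mes = merge_modules(self.expr, labels, merge_diss)
        else:
            mes = pd.DataFrame(columns=self.expr.columns)
        K, hub = intramodular_connectivity(adj, labels)
        kme_tab = kme(self.expr, mes) if len(mes) else pd.DataFrame(index=self.expr.index)
        return CoexpressionNetworkResults(
            beta=int(beta), adjacency=adj, tom=tom, module_labels=labels,
            eigengenes=mes, K=K, kme=kme_tab, hub_flags=hub,
        )
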