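"""miRNA target aggregation, multi-hit filtering, and cluster scoring.

Targets are merged across databases as (miRanda intersect miRDB) union
miRtarBase.  Genes targeted by at least 2 up-regulated miRNAs (or at least
4 down-regulated ones, a stricter bar because that group is larger) are
kept as high-confidence targets.  The miR-17-92 cluster score is the
per-sample mean log2 expression of its members, compared between groups by
the Wilcoxon rank-sum test and correlated against the tumor/normal
telomere-length ratio.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MIN_HITS_UP = 2
MIN_HITS_DOWN = 4

MIR_17_92 = (
    "miR-17", "miR-18a", "miR-19a", "miR-20a", "miR-19b-1", "miR-92a-1",
)


def normalize_mirna_name(name: str) -> str:
    """Lower-case, strip species prefix and version suffix for matching."""
    n = str(name).strip().lower()
    n = re.sub(r"^[a-z]{3}-(?=mir|let)", "", n)   # species prefix: hsa- etc.
    n = re.sub(r"\.\d+$", "", n)                  # .1 version suffix
    return n


@dataclass
class TargetMap:
    """Merged per-miRNA target sets with per-source provenance."""

    targets: dict[str, set[str]]
    sources: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def __getitem__(self, mirna: str) -> set[str]:
        return self.targets[normalize_mirna_name(mirna)]

    def __contains__(self, mirna: str) -> bool:
        return normalize_mirna_name(mirna) in self.targets

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.targets)


@dataclass
class ClusterScore:
    """Per-sample mean log2 expression of a miRNA cluster."""

    score: pd.Series
    members: list[str]
    missing: list[str] = field(default_factory=list)


def aggregate_targets(mirtarbase: dict, miranda: dict, mirdb: dict) -> TargetMap:
    """Merge databases: (miranda intersect mirdb) union mirtarbase, per miRNA."""
    def norm(db: dict) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for mir, genes in db.items():
            out.setdefault(normalize_mirna_name(mir), set()).update(map(str, genes))
        return out

    tb, ra, db_ = norm(mirtarbase), norm(miranda), norm(mirdb)
    merged: dict[str, set[str]] = {}
    for mir in sorted(set(tb) | set(ra) | set(db_)):
        tset = (ra.get(mir, set()) & db_.get(mir, set())) | tb.get(mir, set())
        if not tset:
            logger.info("miRNA %s has no merged targets", mir)
        merged[mir] = tset
    return TargetMap(targets=merged,
                     sources={"mirtarbase": tb, "miranda": ra, "mirdb": db_})


def filter_multi_hit_targets(target_map: TargetMap, direction: str,
                             min_hits_up: int = MIN_HITS_UP,
                             min_hits_down: int = MIN_HITS_DOWN) -> set[str]:
    """Genes targeted by >= 2 up-regulated miRNAs or >= 4 down-regulated ones."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    threshold = min_hits_up if direction == "up" else min_hits_down
    counts: dict[str, int] = {}
    for genes in target_map.targets.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c >= threshold}


def _oriented_pc1(expr: pd.DataFrame) -> np.ndarray:
    """PC1 across samples of the per-feature z-scored matrix, oriented to
    correlate positively with the set's mean profile."""
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = expr.index[sd == 0].tolist()
        raise ValueError(f"zero-variance features: {bad}")
    Xz = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    if Xz.shape[0] == 1:
        pc1 = Xz[0]
    else:
        _, _, vt = np.linalg.svd(Xz, full_matrices=False)
        pc1 = vt[0]
    mean_profile = Xz.mean(axis=0)
    if np.std(mean_profile) > 0 and np.corrcoef(pc1, mean_profile)[0, 1] < 0:
        pc1 = -pc1
    return pc1


def pc1_correlation(set_a_expr: pd.DataFrame, set_b_expr: pd.DataFrame):
    """Pearson r (and two-sided p) between the oriented first principal
    components of two feature sets over aligned samples."""
    if not set_a_expr.columns.equals(set_b_expr.columns):
        raise ValueError("sample columns must be aligned")
    pa = _oriented_pc1(set_a_expr)
    pb = _oriented_pc1(set_b_expr)
    res = stats.pearsonr(pa, pb)
    return float(res.statistic), float(res.pvalue)


def mirna_cluster_score(mirna_expr: pd.DataFrame,
                        members=MIR_17_92) -> ClusterScore:
    """Per-sample arithmetic mean of the cluster members' log2 expression."""
    wanted = {normalize_mirna_name(m): m for m in members}
    row_lookup = {normalize_mirna_name(i): i for i in mirna_expr.index}
    present = [row_lookup[k] for k in wanted if k in row_lookup]
    missing = [wanted[k] for k in wanted if k not in row_lookup]
    if not present:
        raise ValueError("no cluster members present in the expression matrix")
    for m in missing:
        logger.info("cluster member %s missing from matrix", m)
    score = mirna_expr.loc[present].mean(axis=0)
    return ClusterScore(score=score.rename("cluster_score"),
                        members=present, missing=missing)


def group_score_test(score, groups):
    """Wilcoxon rank-sum comparison of a score between two groups.

    Exact enumeration when both groups have <= 10 samples (and no ties
    prevent it); otherwise the normal approximation with tie correction.
    Returns (statistic, two-sided p).
    """
    score = np.asarray(score, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    a = score[groups == uniq[0]]
    b = score[groups == uniq[1]]
    method = "exact" if (len(a) <= 10 and len(b) <= 10) else "asymptotic"
    try:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def telomere_ratio_correlation(score, tl_ratio):
    """Pearson r and two-sided p over pairwise-complete observations."""
    s = np.asarray(score, dtype=float)
    t = np.asarray(tl_ratio, dtype=float)
    ok = np.isfinite(s) & np.isfinite(t)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    res = stats.pearsonr(s[ok], t[ok])
    return float(res.statistic), float(res.pvalue)
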