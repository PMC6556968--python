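"""Study-condition benchmark experiments on synthetic cohorts.

These functions encode the fixed evaluation designs the package is validated
against: type-I calibration on confounded null cohorts, covariate balance
across seeds, planted-feature recovery, module/hub recovery, module
preservation, subtype recovery, and survival-effect estimation.  They are
shared by the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from . import network as nw, psm, subtyping as st
from .cohort import CohortConfig, generate_cohort, generate_survival

#: soft power used for the synthetic cohorts (within-module |r| ~ 0.3; the
#: blocks are not globally scale-free, so the power is fixed rather than
#: picked by the scale-free criterion)
SYNTH_BETA = 4


def null_cohort_config(seed: int) -> CohortConfig:
    """Confounded cohort with no true group effects (type-I experiments)."""
    return CohortConfig(
        n_samples=200, n_mrna=100, n_modules=1, module_size=10,
        frac_differential=0.0, effect_size=0.0, cluster_group_shift=0.0,
        n_methylation=5, n_mirna=8, n_mutation=5, n_scna=5,
        n_subtype_markers=0, n_mirna_targets=0, n_signature_genes=5,
        seed=seed,
    )


def balance_cohort_config(seed: int) -> CohortConfig:
    """Well-specified confounded cohort; layers kept minimal (balance only
    involves the clinical covariates)."""
    return CohortConfig(
        n_samples=200, n_mrna=40, n_modules=1, module_size=5,
        frac_differential=0.0, effect_size=0.0, cluster_group_shift=0.0,
        n_methylation=5, n_mirna=8, n_mutation=5, n_scna=5,
        n_subtype_markers=0, n_mirna_targets=0, n_signature_genes=3,
        seed=seed,
    )


def typeI_experiment(n_cohorts: int = 50, n_perm: int = 200, seed: int = 0):
    """Permutation-test and naive t-test rejection rates at alpha = 0.05 on
    confounded null cohorts.

    Returns (weighted_rate, naive_rate, n_tests).
    """
    rng = np.random.default_rng(seed)
    rej_w = rej_t = total = 0
    for _ in range(n_cohorts):
        sub = int(rng.integers(0, 2 ** 31 - 1))
        co = generate_cohort(null_cohort_config(sub))
        z = co.clinical.group
        Y = co.layers["mrna"].values
        pp = psm.permutation_test(Y, z, co.clinical.covariates,
                                  n_perm=n_perm, seed=sub)
        rej_w += int((pp < 0.05).sum())
        t = stats.ttest_ind(Y.loc[:, z == 1], Y.loc[:, z == 0], axis=1)
        rej_t += int((t.pvalue < 0.05).sum())
        total += len(pp)
    return rej_w / total, rej_t / total, total


def balance_experiment(n_cohorts: int = 40, threshold: float = 10.0,
                       seed: int = 0) -> float:
    """Fraction of cohorts whose every confounder ends below `threshold`
    percent standardized difference after matching weighting."""
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_cohorts):
        co = generate_cohort(balance_cohort_config(int(rng.integers(0, 2 ** 31 - 1))))
        z = co.clinical.group
        model = psm.fit_propensity(co.clinical.covariates, z)
        w = psm.matching_weights(model.scores, z)
        rep = psm.balance_report(co.clinical.covariates, z, w)
        ok += rep.balanced(threshold)
    return ok / n_cohorts


def recovery_experiment(seed: int = 7, n_perm: int = 200):
    """Sensitivity and false-discovery proportion for planted 1.5 SD mRNA
    features at FDR < 0.05 AND permutation p < 0.05.

    False discoveries are calls outside the set of features with any true
    group dependence (planted differential plus cluster-coupled targets).
    """
    co = generate_cohort(CohortConfig(seed=seed))
    z = co.clinical.group
    model = psm.MatchingWeightDifferential(co.layers["mrna"], z,
                                           co.clinical.covariates)
    res = model.fit(n_perm=n_perm, seed=seed)
    called = set(res.significant.index)
    truth = set(co.truth.differential["mrna"])
    associated = co.truth.group_associated("mrna")
    sensitivity = len(called & truth) / len(truth)
    fdp = len(called - associated) / max(len(called), 1)
    return sensitivity, fdp, len(called)


def module_recovery_experiment(seeds=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10)):
    """Planted 3-module recovery: per-seed ARI over module genes and the
    fraction of planted hubs flagged as hubs."""
    aris, hub_fracs = [], []
    for seed in seeds:
        co = generate_cohort(CohortConfig(seed=seed))
        truth = co.truth
        mod_genes = list(truth.modules)
        bg = [g for g in co.layers["mrna"].features
              if g not in truth.modules and g != "TERT"][:60]
        expr = co.layers["mrna"].values.loc[mod_genes + bg]
        res = nw.CoexpressionNetwork(expr).fit(beta=SYNTH_BETA, min_module_size=15)
        aris.append(adjusted_rand_score(
            [truth.modules[g] for g in mod_genes],
            list(res.module_labels.loc[mod_genes])))
        planted = set(sum(truth.hubs.values(), []))
        hub_fracs.append(len(planted & set(res.hubs())) / len(planted))
    return np.array(aris), np.array(hub_fracs)


def preservation_experiment(seeds=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10),
                            n_perm: int = 200):
    """Per-seed outcome: planted modules all Zsummary >= 10 and a random
    same-size gene set Zsummary < 2."""
    outcomes = []
    z_planted, z_random = [], []
    for seed in seeds:
        co = generate_cohort(CohortConfig(seed=seed))
        truth = co.truth
        mod_genes = list(truth.modules)
        bg = [g for g in co.layers["mrna"].features
              if g not in truth.modules and g != "TERT"][:60]
        expr = co.layers["mrna"].values.loc[mod_genes + bg]
        labels = pd.Series([truth.modules.get(g, 0) for g in expr.index],
                           index=expr.index)
        rep = nw.module_preservation_z(expr, expr, labels, n_perm=n_perm,
                                       seed=seed, beta=SYNTH_BETA)
        rng = np.random.default_rng(seed)
        rnd = pd.Series(0, index=expr.index)
        rnd.iloc[rng.choice(len(rnd), 30, replace=False)] = 1
        rep_rnd = nw.module_preservation_z(expr, expr, rnd, n_perm=n_perm,
                                           seed=seed, beta=SYNTH_BETA)
        zp = rep.table["Zsummary"].astype(float)
        zr = float(rep_rnd.table["Zsummary"].iloc[0])
        z_planted.append(float(zp.min()))
        z_random.append(zr)
        outcomes.append(bool((zp >= 10).all() and zr < 2))
    return np.array(outcomes), np.array(z_planted), np.array(z_random)


def subtype_marker_table(cohort) -> pd.DataFrame:
    """Mixed-type marker profile: planted subtype markers across layers plus
    global markers (hub genes, miR-17-92 members, TERT)."""
    cols = []
    for tag, feats in cohort.truth.subtype_markers.items():
        for f in feats:
            cols.append(cohort.layers[tag].values.loc[f].rename(f"{tag}:{f}"))
    for g in sum(cohort.truth.hubs.values(), []):
        cols.append(cohort.layers["mrna"].values.loc[g].rename(f"mrna:{g}"))
    for m in cohort.truth.mirna_cluster_members:
        cols.append(cohort.layers["mirna"].values.loc[m].rename(f"mirna:{m}"))
    cols.append(cohort.layers["mrna"].values.loc["TERT"].rename("mrna:TERT"))
    return pd.concat(cols, axis=1)


def subtype_recovery_experiment(seeds=(1, 2, 3, 4, 5), n_samples: int = 100,
                                n_trees: int = 2000):
    """Per-seed adjusted Rand index between PAM labels on the RF
    dissimilarity and the planted subtypes."""
    aris = []
    for seed in seeds:
        co = generate_cohort(CohortConfig(seed=seed, n_samples=n_samples))
        X = subtype_marker_table(co)
        rfd = st.rf_dissimilarity(X, n_trees=n_trees, seed=seed)
        labels, _ = st.pam_cluster(rfd.matrix, k=2)
        aris.append(adjusted_rand_score(co.truth.subtype.to_numpy(),
                                        labels.to_numpy()))
    return np.array(aris)


def survival_benchmark(seed: int = 11, n_per_arm: int = 200,
                       hazard_ratio: float = 3.0, censor_rate: float = 0.2):
    """Log-rank p and Cox HR for planted exponential survival."""
    labels = np.repeat([1, 2], n_per_arm)
    t, e = generate_survival(labels, hazard_ratio, censor_rate, seed=seed)
    chi2, logrank_p = st.logrank_test(t, e, labels)
    hr, cox_p = st.cox_univariate(t, e, (labels == 2).astype(float))
    return {"logrank_chi2": chi2, "logrank_p": logrank_p,
            "cox_hr": hr, "cox_p": cox_p}
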