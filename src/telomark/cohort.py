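"""Synthetic multi-omics cohort with planted ground truth.

The generator emits the statistical structure the downstream stages assume:

* binary TERT group labels drawn from a logistic model on continuous
  confounders, so group membership is genuinely confounded;
* per-layer planted differential features (mean shift in within-group SD
  units for continuous layers, rate shifts for mutation / copy-number);
* a set of "spurious" genes that depend on the same confounders but carry
  no group effect — these are what the matching-weight stage must not call;
* block-correlated expression modules built from a per-module latent factor,
  with designated hub genes given a higher factor loading;
* a miRNA cluster (the canonical miR-17-92 members when the cluster size is
  six) whose latent is negatively coupled to designated mRNA targets and to
  a tumor/normal telomere-length ratio;
* two planted subtypes driving a mixed-type marker profile and exponential
  survival times with a configurable hazard ratio;
* a telomerase-activity construct: the first module's latent factor acts as
  the activity axis, and a designated signature gene set loads on it.

All continuous layers are emitted directly on log2 scale.  Identical config
and seed reproduce bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CohortClinical, OmicsLayer
from . import io as tio

MIR_17_92_MEMBERS = (
    "hsa-mir-17",
    "hsa-mir-18a",
    "hsa-mir-19a",
    "hsa-mir-20a",
    "hsa-mir-19b-1",
    "hsa-mir-92a-1",
)


@dataclass
class CohortConfig:
    """Tunable generator parameters.

    Counts must be >= 1, fractions within [0, 1], the hazard ratio positive.
    `effect_size` is the planted mean shift in within-group SD units for
    continuous layers; mutation and copy-number effects are rate shifts.
    """

    n_samples: int = 200
    n_confounders: int = 3
    confounder_effect: float = 0.5     # log-odds per confounder unit
    n_mrna: int = 600
    n_methylation: int = 300
    n_mirna: int = 80
    n_mutation: int = 60
    n_scna: int = 60
    frac_differential: float = 0.1
    effect_size: float = 1.5           # SD units, continuous layers
    n_modules: int = 3
    module_size: int = 30
    hub_loading: float = 0.9
    nonhub_loading: float = 0.55
    mirna_cluster_size: int = 6
    target_coupling: float = -0.8      # negative coefficient, cluster -> targets
    subtype_hazard_ratio: float = 3.0
    survival_censor_rate: float = 0.2
    seed: int = 0
    # secondary knobs
    confounded_frac: float = 0.3       # fraction of non-differential genes tied to confounders
    confounder_feature_effect: float = 0.6
    mutation_rate_shift: float = 0.25
    n_subtype_markers: int = 15
    subtype_marker_shift: float = 2.0
    subtype_activity_shift: float = 1.0
    n_mirna_targets: int = 30
    n_signature_genes: int = 12
    cluster_group_shift: float = 0.75  # miR cluster latent shift in TERT-high
    n_hypermutators: int = 0
    baseline_expression: float = 5.0

    def validate(self) -> None:
        counts = dict(
            n_samples=self.n_samples, n_confounders=self.n_confounders,
            n_mrna=self.n_mrna, n_methylation=self.n_methylation,
            n_mirna=self.n_mirna, n_mutation=self.n_mutation,
            n_scna=self.n_scna, n_modules=self.n_modules,
            module_size=self.module_size, mirna_cluster_size=self.mirna_cluster_size,
        )
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1 (got {v})")
        for name in ("frac_differential", "survival_censor_rate", "hub_loading",
                     "nonhub_loading", "confounded_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1] (got {v})")
        if self.subtype_hazard_ratio <= 0:
            raise ValueError("subtype_hazard_ratio must be > 0")
        if self.n_modules * self.module_size > self.n_mrna - 1:
            raise ValueError(
                f"module genes ({self.n_modules} x {self.module_size}) exceed "
                f"available genes ({self.n_mrna - 1} after TERT)"
            )
        if self.mirna_cluster_size > self.n_mirna:
            raise ValueError("mirna_cluster_size exceeds n_mirna")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator, for recovery tests."""

    differential: dict[str, dict[str, str]]     # layer -> feature -> "up"|"down" (in TERT-high)
    modules: dict[str, int]                     # gene -> module id (1-based)
    hubs: dict[int, list[str]]                  # module -> designated hub genes
    module_latents: pd.DataFrame                # modules x samples
    subtype: pd.Series                          # per-sample label in {1, 2}
    subtype_markers: dict[str, list[str]]       # layer -> features shifted by subtype
    confounder_coefficients: np.ndarray
    confounded_features: list[str]              # spurious (confounder-driven) genes
    mirna_cluster_members: list[str]
    mirna_targets: list[str]
    signature_genes: list[str]
    activity_latent: pd.Series                  # per-sample telomerase-activity axis
    hypermutators: list[str]

    def group_associated(self, layer: str) -> set[str]:
        """All features of a layer with any true group dependence.

        Beyond the planted differential set this includes the miRNA-cluster
        members (the cluster latent is shifted in TERT-high) and, in the
        mRNA layer, their coupled target genes — they differ between groups
        by construction, so calling them is not a false discovery.
        """
        out = set(self.differential.get(layer, {}))
        if layer == "mrna":
            out |= set(self.mirna_targets)
        if layer == "mirna":
            out |= set(self.mirna_cluster_members)
        return out

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["module_latents"] = self.module_latents.to_dict()
        d["subtype"] = self.subtype.to_dict()
        d["activity_latent"] = self.activity_latent.to_dict()
        d["confounder_coefficients"] = list(map(float, self.confounder_coefficients))
        return d


@dataclass
class SyntheticCohort:
    layers: dict[str, OmicsLayer]
    clinical: CohortClinical
    truth: PlantedTruth
    probe_map: pd.DataFrame                     # columns: probe, gene

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for tag, layer in self.layers.items():
            tio.write_layer(layer, outdir / f"{tag}.tsv")
        tio.write_clinical(self.clinical, outdir / "clinical.tsv")
        self.probe_map.to_csv(outdir / "probe_map.tsv", sep="\t", index=False)
        tio.write_json(self.truth.to_json_dict(), outdir / "truth.json")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_survival(subtype_labels, hazard_ratio: float, censor_rate: float,
                      seed: int, base_rate: float = 0.1):
    """Exponential survival times with a subtype hazard ratio.

    The higher of the two label values is taken as subtype 2, whose event
    rate is multiplied by `hazard_ratio`.  Censoring times are exponential
    with a per-arm rate chosen so the expected censored fraction equals
    `censor_rate` in each arm (and independent of the event time).

    Returns (time, event) arrays; event 1 = death observed.
    """
    labels = np.asarray(subtype_labels)
    uniq = np.unique(labels)
    if len(uniq) > 2:
        raise ValueError("subtype labels must be binary")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    is2 = labels == uniq.max() if len(uniq) == 2 else np.zeros(len(labels), bool)
    rate = base_rate * np.where(is2, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate == 0.0:
        return t_event, np.ones(len(labels), dtype=int)
    c_rate = rate * censor_rate / (1.0 - censor_rate)
    t_cens = rng.exponential(1.0 / c_rate)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate all five omics layers, clinical covariates, and truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = pd.Index([f"S{i:04d}" for i in range(n)], name="sample")

    # --- confounders and confounded group labels -------------------------
    conf_cols = [f"confounder{j + 1}" for j in range(config.n_confounders)]
    C = rng.standard_normal((n, config.n_confounders))
    gamma = np.full(config.n_confounders, config.confounder_effect)
    p_high = _sigmoid(C @ gamma)
    Z = (rng.random(n) < p_high).astype(int)
    # guarantee both groups occupied (relevant only at tiny n)
    if Z.sum() == 0:
        Z[int(np.argmax(p_high))] = 1
    if Z.sum() == n:
        Z[int(np.argmin(p_high))] = 0

    subtype = pd.Series(rng.integers(1, 3, size=n), index=samples, name="subtype")

    # --- gene universe and role assignment -------------------------------
    genes = ["TERT"] + [f"GENE{i:04d}" for i in range(1, config.n_mrna)]
    n_mod_genes = config.n_modules * config.module_size
    module_of: dict[str, int] = {}
    hubs: dict[int, list[str]] = {}
    for m in range(config.n_modules):
        block = genes[1 + m * config.module_size: 1 + (m + 1) * config.module_size]
        n_hub = max(1, math.ceil(0.05 * config.module_size))
        hubs[m + 1] = block[:n_hub]
        for g in block:
            module_of[g] = m + 1

    pool = list(genes[1 + n_mod_genes:])
    n_diff = int(round(config.frac_differential * config.n_mrna))
    need = max(0, n_diff - 1) + config.n_subtype_markers + config.n_mirna_targets
    if need > len(pool):
        raise ValueError(
            f"gene pool too small: need {need} non-module genes, have {len(pool)}; "
            "increase n_mrna or shrink modules/planted sets"
        )
    pool_idx = rng.permutation(len(pool))
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = [pool[i] for i in pool_idx[cursor:cursor + k]]
        cursor += k
        return out

    diff_genes = (["TERT"] + take(n_diff - 1)) if n_diff >= 1 else []
    subtype_genes = take(config.n_subtype_markers)
    target_genes = take(config.n_mirna_targets)
    remaining = [pool[i] for i in pool_idx[cursor:]]
    n_confounded = int(round(config.confounded_frac * len(remaining)))
    confounded_genes = remaining[:n_confounded]

    gene_dir = {}
    for i, g in enumerate(diff_genes):
        gene_dir[g] = "up" if (g == "TERT" or i % 2 == 1) else "down"

    # --- module latents and the telomerase-activity axis -----------------
    latents = rng.standard_normal((config.n_modules, n))
    # module 1 doubles as the activity axis, shifted by subtype (subtype 1 high)
    latents[0] += config.subtype_activity_shift * (subtype.to_numpy() == 1)
    latents = (latents - latents.mean(axis=1, keepdims=True)) / latents.std(axis=1, keepdims=True)
    module_latents = pd.DataFrame(
        latents, index=[f"M{m + 1}" for m in range(config.n_modules)], columns=samples
    )
    activity = pd.Series(latents[0], index=samples, name="activity")

    signature_genes = [g for g, m in module_of.items() if m == 1][: config.n_signature_genes]

    # --- mRNA layer ------------------------------------------------------
    baseline = config.baseline_expression + 1.5 * rng.standard_normal(len(genes))
    expr = np.empty((len(genes), n))
    noise = rng.standard_normal((len(genes), n))
    loadings = {}
    for gi, g in enumerate(genes):
        m = module_of.get(g)
        if m is None:
            expr[gi] = baseline[gi] + noise[gi]
        else:
            if g in hubs[m]:
                lam = config.hub_loading
            else:
                lo = max(0.05, config.nonhub_loading - 0.15)
                hi = min(0.95, config.nonhub_loading + 0.15)
                lam = rng.uniform(lo, hi)
            loadings[g] = lam
            expr[gi] = baseline[gi] + lam * latents[m - 1] + math.sqrt(1 - lam ** 2) * noise[gi]

    gidx = {g: i for i, g in enumerate(genes)}
    for g in diff_genes:
        sgn = 1.0 if gene_dir[g] == "up" else -1.0
        expr[gidx[g]] += sgn * config.effect_size * Z
    for g in subtype_genes:
        expr[gidx[g]] += config.subtype_marker_shift * (subtype.to_numpy() == 2)
    for g in confounded_genes:
        expr[gidx[g]] += config.confounder_feature_effect * C[:, 0]

    # --- miRNA layer (plus cluster latent) -------------------------------
    if config.mirna_cluster_size <= len(MIR_17_92_MEMBERS):
        members = list(MIR_17_92_MEMBERS[: config.mirna_cluster_size])
    else:
        members = list(MIR_17_92_MEMBERS) + [
            f"hsa-mir-x{i:03d}" for i in range(config.mirna_cluster_size - len(MIR_17_92_MEMBERS))
        ]
    other_mirnas = [f"hsa-mir-s{i:04d}" for i in range(config.n_mirna - len(members))]
    mirnas = members + other_mirnas
    M_latent = rng.standard_normal(n)
    M_latent = (M_latent - M_latent.mean()) / M_latent.std()
    M_shifted = M_latent + config.cluster_group_shift * Z

    mexpr = np.empty((len(mirnas), n))
    mnoise = rng.standard_normal((len(mirnas), n))
    mbase = 4.0 + rng.standard_normal(len(mirnas))
    for i, mir in enumerate(mirnas):
        if mir in members:
            mexpr[i] = mbase[i] + 0.8 * M_shifted + 0.6 * mnoise[i]
        else:
            mexpr[i] = mbase[i] + mnoise[i]
    n_diff_mirna = int(round(config.frac_differential * config.n_mirna))
    n_diff_mirna = min(n_diff_mirna, len(other_mirnas))
    diff_mirnas = other_mirnas[:n_diff_mirna]
    for i, mir in enumerate(diff_mirnas):
        sgn = 1.0 if i % 2 == 0 else -1.0
        mexpr[mirnas.index(mir)] += sgn * config.effect_size * Z
    mirna_dir = {mir: ("up" if i % 2 == 0 else "down") for i, mir in enumerate(diff_mirnas)}

    # miRNA cluster represses its mRNA targets
    for g in target_genes:
        expr[gidx[g]] += config.target_coupling * M_shifted

    # --- methylation layer ----------------------------------------------
    n_probes = config.n_methylation
    probes = [f"cg{i:08d}" for i in range(n_probes)]
    n_diff_meth = int(round(config.frac_differential * n_probes))
    n_diff_meth = min(n_diff_meth, max(0, len(diff_genes)))
    meth_logit = 0.8 * rng.standard_normal((n_probes, n)) - 0.5 + \
        1.2 * rng.standard_normal(n_probes)[:, None]
    probe_gene: list[str] = []
    meth_dir: dict[str, str] = {}
    # planted probes: anti-correlated with differential gene expression,
    # hence differential themselves (opposite direction)
    for i in range(n_diff_meth):
        g = diff_genes[i % len(diff_genes)]
        gz = (expr[gidx[g]] - expr[gidx[g]].mean()) / expr[gidx[g]].std()
        meth_logit[i] = -1.5 * gz + 0.5 * rng.standard_normal(n) - 0.5
        probe_gene.append(g)
        meth_dir[probes[i]] = "down" if gene_dir[g] == "up" else "up"
    # remaining probes map round-robin onto module / pool genes (2 per gene)
    cov_genes = [g for g in genes if g not in set(probe_gene)]
    for i in range(n_diff_meth, n_probes):
        probe_gene.append(cov_genes[(i - n_diff_meth) // 2 % len(cov_genes)])
    n_sub_meth = min(5, n_probes - n_diff_meth)
    subtype_probes = probes[n_diff_meth:n_diff_meth + n_sub_meth]
    for i in range(n_diff_meth, n_diff_meth + n_sub_meth):
        meth_logit[i] += config.subtype_marker_shift * (subtype.to_numpy() == 2)
    meth = _sigmoid(meth_logit)

    # --- mutation layer --------------------------------------------------
    mut_genes = [f"MGENE{i:04d}" for i in range(config.n_mutation)]
    n_diff_mut = int(round(config.frac_differential * config.n_mutation))
    base_rate = rng.uniform(0.05, 0.15, size=config.n_mutation)
    rate = np.tile(base_rate[:, None], (1, n))
    for i in range(n_diff_mut):
        rate[i] = base_rate[i] + config.mutation_rate_shift * Z
    n_sub_mut = min(3, config.n_mutation - n_diff_mut)
    subtype_mut = mut_genes[n_diff_mut:n_diff_mut + n_sub_mut]
    for i in range(n_diff_mut, n_diff_mut + n_sub_mut):
        rate[i] = base_rate[i] + 0.35 * (subtype.to_numpy() == 2)
    mut = (rng.random((config.n_mutation, n)) < np.clip(rate, 0, 0.95)).astype(int)
    diff_mut = mut_genes[:n_diff_mut]

    hypermutators = list(samples[: config.n_hypermutators])

    # --- SCNA layer -------------------------------------------------------
    scna_genes = [f"SGENE{i:04d}" for i in range(config.n_scna)]
    n_diff_scna = int(round(config.frac_differential * config.n_scna))
    scna = rng.choice([-1, 0, 1], size=(config.n_scna, n), p=[0.1, 0.8, 0.1])
    amp = rng.choice([0, 1, 2], size=(config.n_scna, n), p=[0.3, 0.4, 0.3])
    for i in range(n_diff_scna):
        scna[i] = np.where(Z == 1, amp[i], scna[i])
    n_sub_scna = min(3, config.n_scna - n_diff_scna)
    subtype_scna = scna_genes[n_diff_scna:n_diff_scna + n_sub_scna]
    for i in range(n_diff_scna, n_diff_scna + n_sub_scna):
        scna[i] = np.where(subtype.to_numpy() == 2, amp[i], scna[i])
    diff_scna = scna_genes[:n_diff_scna]

    # --- clinical ---------------------------------------------------------
    tl_ratio = 1.0 + 0.3 * config.target_coupling * M_shifted + 0.15 * rng.standard_normal(n)
    tert_reads = np.where(Z == 1, 2 + rng.poisson(20, size=n), rng.integers(0, 2, size=n))
    time, event = generate_survival(
        subtype.to_numpy(), config.subtype_hazard_ratio,
        config.survival_censor_rate, seed=int(rng.integers(0, 2 ** 31 - 1)),
    )
    clin = pd.DataFrame(
        {c: C[:, j] for j, c in enumerate(conf_cols)}
        | {
            "tert_group": Z,
            "tert_reads": tert_reads,
            "alt_flag": np.zeros(n, dtype=bool),
            "time": time,
            "event": event,
            "tl_ratio": tl_ratio,
        },
        index=samples,
    )

    layers = {
        "mrna": OmicsLayer(pd.DataFrame(expr, index=pd.Index(genes, name="feature"),
                                        columns=samples), "mrna"),
        "methylation": OmicsLayer(pd.DataFrame(meth, index=pd.Index(probes, name="feature"),
                                               columns=samples), "methylation"),
        "mirna": OmicsLayer(pd.DataFrame(mexpr, index=pd.Index(mirnas, name="feature"),
                                         columns=samples), "mirna"),
        "mutation": OmicsLayer(pd.DataFrame(mut, index=pd.Index(mut_genes, name="feature"),
                                            columns=samples), "mutation"),
        "scna": OmicsLayer(pd.DataFrame(scna, index=pd.Index(scna_genes, name="feature"),
                                        columns=samples), "scna"),
    }
    truth = PlantedTruth(
        differential={
            "mrna": dict(gene_dir),
            "mirna": dict(mirna_dir),
            "methylation": dict(meth_dir),
            "mutation": {g: "up" for g in diff_mut},
            "scna": {g: "up" for g in diff_scna},
        },
        modules=module_of,
        hubs=hubs,
        module_latents=module_latents,
        subtype=subtype,
        subtype_markers={
            "mrna": subtype_genes,
            "methylation": list(subtype_probes),
            "mutation": list(subtype_mut),
            "scna": list(subtype_scna),
        },
        confounder_coefficients=gamma,
        confounded_features=confounded_genes,
        mirna_cluster_members=members,
        mirna_targets=target_genes,
        signature_genes=signature_genes,
        activity_latent=activity,
        hypermutators=hypermutators,
    )
    probe_map = pd.DataFrame({"probe": probes, "gene": probe_gene})
    return SyntheticCohort(layers=layers, clinical=CohortClinical(clin, conf_cols),
                           truth=truth, probe_map=probe_map)


def mutation_layer_to_maf(layer: OmicsLayer, hypermutator_samples=(),
                          n_hyper_rows: int = 1200, seed: int = 0) -> pd.DataFrame:
    """Expand a binary mutation matrix into a MAF-like table.

    Samples listed in `hypermutator_samples` additionally receive
    `n_hyper_rows` mutations over synthetic filler genes, pushing them past
    the 1000-mutation exclusion threshold downstream.
    """
    if layer.tag != "mutation":
        raise ValueError("expected a mutation layer")
    rng = np.random.default_rng(seed)
    genes, samples = np.nonzero(layer.values.to_numpy())
    rows = {
        "Hugo_Symbol": layer.features[genes],
        "Tumor_Sample_Barcode": layer.samples[samples],
        "Variant_Classification": "Missense_Mutation",
    }
    maf = pd.DataFrame(rows)
    extra = []
    for s in hypermutator_samples:
        filler = rng.integers(0, 10 ** 6, size=n_hyper_rows)
        extra.append(pd.DataFrame({
            "Hugo_Symbol": [f"FILLER{i:06d}" for i in filler],
            "Tumor_Sample_Barcode": s,
            "Variant_Classification": "Missense_Mutation",
        }))
    if extra:
        maf = pd.concat([maf] + extra, ignore_index=True)
    return maf
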