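"""End-to-end orchestration: group assignment, layer filters, matching-weight
screening per layer, co-expression network, miRNA stages, marker assembly,
random-forest subtyping and survival comparison, driven by one config.

A single top-level seed is mandatory; each sampling stage receives a seed
derived deterministically from it, so a rerun with the same config is
byte-identical.  Any stage failure aborts with the stage name and cause.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import filters, io as tio, mirna as mr, network as nw, psm, subtyping as st
from .containers import CohortClinical, OmicsLayer

logger = logging.getLogger(__name__)

LAYER_ORDER = ("mrna", "methylation", "mirna", "mutation", "scna")


@dataclass
class PipelineConfig:
    """Paths and per-stage parameters for a full run."""

    layer_paths: dict[str, str] = field(default_factory=dict)
    clinical_path: str | None = None
    probe_map_path: str | None = None
    maf_path: str | None = None
    signature_path: str | None = None
    outdir: str = "telomark_out"
    seed: int = 0
    n_perm: int = 200
    fdr_alpha: float = 0.05
    perm_alpha: float = 0.05
    network_max_genes: int = 2000
    network_beta: int | None = None     # soft power; picked automatically if None
    min_module_size: int = 20
    cut_height: float = 0.995
    merge_diss: float = 0.25
    n_trees: int = 2000
    k_subtypes: int = 2
    confounder_cols: list[str] | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> list[str]:
        errors = []
        for tag, p in self.layer_paths.items():
            if tag not in LAYER_ORDER:
                errors.append(f"unknown layer tag {tag!r}")
            elif not Path(p).exists():
                errors.append(f"{tag} layer path does not exist: {p}")
        for name in ("clinical_path", "probe_map_path", "maf_path", "signature_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                errors.append(f"{name} does not exist: {p}")
        if self.clinical_path is None:
            errors.append("clinical_path is required")
        if self.n_perm < 1:
            errors.append("n_perm must be >= 1")
        return errors


@dataclass
class ValidationReport:
    errors: list[str]
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(layers: dict[str, OmicsLayer],
                    clinical: CohortClinical) -> ValidationReport:
    """Check sample alignment, duplicates, numeric cells, missingness."""
    errors: list[str] = []
    warnings: list[str] = []
    clin_samples = set(clinical.samples)
    for tag, layer in layers.items():
        lay_samples = set(layer.samples)
        if lay_samples != clin_samples:
            diff = sorted(lay_samples ^ clin_samples)
            errors.append(f"{tag}: sample sets differ from clinical "
                          f"(symmetric difference {diff[:10]}"
                          f"{'...' if len(diff) > 10 else ''})")
        if layer.values.index.has_duplicates:
            dups = layer.values.index[layer.values.index.duplicated()].unique().tolist()
            errors.append(f"{tag}: duplicate feature IDs {dups[:10]}")
        nonnum = layer.values.select_dtypes(exclude="number")
        if nonnum.shape[1]:
            errors.append(f"{tag}: non-numeric columns {list(nonnum.columns)[:10]}")
        miss = float(layer.values.isna().mean().mean())
        if miss > 0.2:
            errors.append(f"{tag}: missing-value rate {miss:.1%} exceeds 20%")
        elif miss > 0:
            warnings.append(f"{tag}: missing-value rate {miss:.1%}")
    return ValidationReport(errors=errors, warnings=warnings)


def _stage_seed(seed: int, stage: str) -> int:
    import zlib

    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode()) % (2 ** 31)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline from files; returns the run report dict."""
    errors = config.validate()
    if errors:
        raise ValueError("config validation failed:\n" + "\n".join(errors))
    layers = {tag: tio.read_layer(p, tag) for tag, p in config.layer_paths.items()}
    clinical = tio.read_clinical(config.clinical_path, config.confounder_cols)
    probe_map = (pd.read_csv(config.probe_map_path, sep="\t")
                 if config.probe_map_path else None)
    maf = tio.read_maf(config.maf_path) if config.maf_path else None
    signature = (tio.read_gene_list(config.signature_path)
                 if config.signature_path else None)
    return run(layers, clinical, config, probe_map=probe_map, maf=maf,
               signature_genes=signature)


def run(layers: dict[str, OmicsLayer], clinical: CohortClinical,
        config: PipelineConfig, probe_map=None, maf=None,
        signature_genes=None) -> dict:
    """Execute the pipeline on in-memory inputs; writes outputs to outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "significant_counts": {}}

    # --- validation -------------------------------------------------------
    vrep = validate_inputs(layers, clinical)
    if not vrep.ok:
        raise StageError("validate_inputs", ValueError("; ".join(vrep.errors)))
    report["stages"]["validate_inputs"] = {"warnings": vrep.warnings}

    # --- group assignment -------------------------------------------------
    n_total = len(clinical.samples)
    try:
        if "tert_reads" in clinical.table.columns:
            ga = filters.assign_tert_groups(
                clinical.table["tert_reads"],
                clinical.table.get("alt_flag", pd.Series(False, index=clinical.samples)),
            )
            kept = ga.binary()
        else:
            kept = clinical.table["tert_group"].astype(int)
        kept_samples = list(kept.index)
        z = kept.to_numpy()
        clinical = CohortClinical(clinical.table.loc[kept_samples],
                                  clinical.confounder_cols)
        layers = {t: lay.reindex_samples(kept_samples) for t, lay in layers.items()}
        report["stages"]["assign_groups"] = {
            "n_high": int(z.sum()), "n_low": int(len(z) - z.sum()),
            "n_excluded": int(n_total - len(kept_samples)),
        }
    except StageError:
        raise
    except Exception as err:
        raise StageError("assign_groups", err) from err

    # --- layer filters ----------------------------------------------------
    try:
        if "mrna" in layers:
            keep = filters.filter_expressed_mrna(layers["mrna"].values, z)
            layers["mrna"] = OmicsLayer(layers["mrna"].values.loc[keep], "mrna")
        if "methylation" in layers and probe_map is not None and "mrna" in layers:
            sel = filters.select_methylation_probe(
                layers["methylation"].values, probe_map, layers["mrna"].values)
            chosen = sel.table["probe"].tolist() if len(sel.table) else []
            if chosen:
                layers["methylation"] = OmicsLayer(
                    layers["methylation"].values.loc[
                        layers["methylation"].values.index.intersection(chosen)],
                    "methylation")
        if maf is not None:
            kept_s, kept_g, mat = filters.filter_mutations(maf)
            mat = mat.reindex(columns=kept_samples, fill_value=0)
            layers["mutation"] = OmicsLayer(mat, "mutation")
        report["stages"]["filters"] = {
            t: int(lay.n_features) for t, lay in layers.items()
        }
    except StageError:
        raise
    except Exception as err:
        raise StageError("layer_filters", err) from err

    # --- matching-weight differential screen per layer --------------------
    diff_results: dict[str, pd.DataFrame] = {}
    for tag in LAYER_ORDER:
        if tag not in layers:
            report["stages"][f"psm_{tag}"] = "skipped"
            continue
        try:
            model = psm.MatchingWeightDifferential(layers[tag], z, clinical.covariates)
            res = model.fit(n_perm=config.n_perm,
                            seed=_stage_seed(config.seed, f"psm_{tag}"),
                            fdr_alpha=config.fdr_alpha,
                            perm_alpha=config.perm_alpha)
            res.save(outdir / f"diff_{tag}.tsv", outdir / f"balance_{tag}.tsv")
            diff_results[tag] = res.table
            report["significant_counts"][tag] = int(res.table["significant"].sum())
            report["stages"][f"psm_{tag}"] = {
                "n_significant": int(res.table["significant"].sum()),
                "balanced": res.balance.balanced(),
            }
        except Exception as err:
            raise StageError(f"psm_{tag}", err) from err

    # --- methylation/expression enrichment --------------------------------
    if "methylation" in diff_results and "mrna" in diff_results and probe_map is not None:
        try:
            p2g = dict(zip(probe_map["probe"], probe_map["gene"]))
            meth_sig = diff_results["methylation"]
            meth_genes = {p2g.get(p) for p in
                          meth_sig.index[meth_sig["significant"]]} - {None}
            expr_sig = set(diff_results["mrna"].index[diff_results["mrna"]["significant"]])
            universe = set(diff_results["mrna"].index) | meth_genes
            orr, p = filters.methylation_expression_enrichment(
                meth_genes & universe, expr_sig & universe, universe)
            report["stages"]["meth_expr_enrichment"] = {"odds_ratio": orr, "p": p}
        except Exception as err:
            raise StageError("meth_expr_enrichment", err) from err
    else:
        report["stages"]["meth_expr_enrichment"] = "skipped"

    # --- co-expression network -------------------------------------------
    net_res = None
    if "mrna" in layers:
        try:
            expr = layers["mrna"].values
            if expr.shape[0] > config.network_max_genes:
                keep = expr.var(axis=1).sort_values(ascending=False) \
                    .index[: config.network_max_genes]
                expr = expr.loc[keep]
            net = nw.CoexpressionNetwork(expr)
            net_res = net.fit(beta=config.network_beta,
                              min_module_size=config.min_module_size,
                              cut_height=config.cut_height,
                              merge_diss=config.merge_diss)
            net_res.gene_table().to_csv(outdir / "network_genes.tsv", sep="\t")
            net_res.eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t")
            report["stages"]["network"] = {
                "beta": net_res.beta,
                "n_modules": len(net_res.modules),
                "n_hubs": int(net_res.hub_flags.sum()),
            }
        except Exception as err:
            raise StageError("network", err) from err
    else:
        report["stages"]["network"] = "skipped"

    # --- miRNA stages -----------------------------------------------------
    cluster_members: list[str] = []
    if "mirna" in layers:
        try:
            cs = mr.mirna_cluster_score(layers["mirna"].values)
            cluster_members = cs.members
            stat, p = mr.group_score_test(cs.score.to_numpy(), z)
            stage = {"wilcoxon_stat": stat, "wilcoxon_p": p}
            if "tl_ratio" in clinical.table.columns:
                r, rp = mr.telomere_ratio_correlation(
                    cs.score.to_numpy(),
                    clinical.table["tl_ratio"].to_numpy())
                stage["tl_ratio_r"] = r
                stage["tl_ratio_p"] = rp
            cs.score.to_csv(outdir / "mir17_92_score.tsv", sep="\t")
            report["stages"]["mirna_cluster"] = stage
        except Exception as err:
            raise StageError("mirna_cluster", err) from err
    else:
        report["stages"]["mirna_cluster"] = "skipped"

    # --- marker assembly + subtyping + survival ---------------------------
    if "mrna" in layers and {"time", "event"} <= set(clinical.table.columns):
        try:
            hub_genes = list(net_res.hubs()) if net_res is not None else []
            profile = st.assemble_marker_profile(
                diff_results, hub_genes, cluster_members or list(mr.MIR_17_92),
                layers)
            sig = signature_genes or hub_genes or list(layers["mrna"].values.index[:10])
            model = st.RandomForestSubtyper(
                profile, layers["mrna"].values, sig,
                clinical.table["time"].to_numpy(),
                clinical.table["event"].to_numpy(),
            )
            sres = model.fit(n_trees=config.n_trees, k=config.k_subtypes,
                             seed=_stage_seed(config.seed, "rf_subtyping"))
            sres.labels.to_csv(outdir / "subtype_labels.tsv", sep="\t")
            sres.dissimilarity.to_csv(outdir / "rf_dissimilarity.tsv", sep="\t")
            tio.write_json({
                "wilcoxon_stat": sres.wilcoxon_stat, "wilcoxon_p": sres.wilcoxon_p,
                "logrank_chi2": sres.logrank_chi2, "logrank_p": sres.logrank_p,
                "cox_hr": sres.cox_hr, "cox_p": sres.cox_p,
            }, outdir / "subtype_stats.json")
            report["stages"]["rf_subtyping"] = {
                "cluster_sizes": sres.labels.value_counts().sort_index().to_dict(),
                "wilcoxon_p": sres.wilcoxon_p,
                "logrank_p": sres.logrank_p,
                "cox_hr": sres.cox_hr,
            }
        except StageError:
            raise
        except Exception as err:
            raise StageError("rf_subtyping", err) from err
    else:
        report["stages"]["rf_subtyping"] = "skipped"

    tio.write_json(report, outdir / "run_report.json")
    return report
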