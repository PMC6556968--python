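"""Layer-specific preprocessing and cross-layer enrichment.

Group assignment splits tumors at 2 RNA-seq quantified TERT reads; low-read
samples carrying known ALT alterations (ATRX/DAXX) are excluded.  The mRNA
filter keeps genes with mean log2 expression > 1 in both groups; the
mutation filter drops hypermutated exomes (>= 1000 mutations) and keeps
genes mutated in at least 5% of the retained samples.  For genes with
several methylation probes the probe most anti-correlated with the gene's
expression is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OmicsLayer

logger = logging.getLogger(__name__)

TERT_READ_THRESHOLD = 2
MUTATION_SAMPLE_MAX = 1000
MUTATION_FREQ_MIN = 0.05

#: MAF Variant_Classification values treated as silent / non-coding.
SILENT_CLASSES = frozenset({
    "Silent", "Intron", "3'UTR", "5'UTR", "3'Flank", "5'Flank",
    "IGR", "RNA",
})


@dataclass
class GroupAssignment:
    """Per-sample TERT group labels with exclusion reasons."""

    labels: pd.Series              # high | low | excluded_alt | excluded_other
    threshold_reads: int = TERT_READ_THRESHOLD

    @property
    def high(self) -> pd.Index:
        return self.labels.index[self.labels == "high"]

    @property
    def low(self) -> pd.Index:
        return self.labels.index[self.labels == "low"]

    def binary(self) -> pd.Series:
        """1/0 labels over the retained (high/low) samples."""
        kept = self.labels[self.labels.isin(["high", "low"])]
        return (kept == "high").astype(int)


@dataclass
class ProbeSelection:
    """Chosen methylation probe per gene and its correlation with expression."""

    table: pd.DataFrame            # index gene; columns probe, r

    def probes(self) -> pd.Series:
        return self.table["probe"]


def assign_tert_groups(tert_reads: pd.Series, alt_flags: pd.Series,
                       threshold: int = TERT_READ_THRESHOLD) -> GroupAssignment:
    """Label samples high (reads >= 2), low, or excluded_alt (low + ALT)."""
    reads = pd.Series(tert_reads)
    alt = pd.Series(alt_flags).reindex(reads.index)
    if (reads < 0).any():
        bad = reads.index[reads < 0].tolist()
        raise ValueError(f"negative TERT read counts for samples {bad}")
    labels = pd.Series(
        np.where(reads >= threshold, "high",
                 np.where(alt.fillna(False).astype(bool), "excluded_alt", "low")),
        index=reads.index, name="tert_label",
    )
    return GroupAssignment(labels, threshold_reads=threshold)


def filter_expressed_mrna(log2_expr: pd.DataFrame, z) -> pd.Index:
    """Keep genes whose mean log2 expression is > 1 in BOTH groups (strict)."""
    z = np.asarray(z)
    m1 = log2_expr.loc[:, np.asarray(z) == 1].mean(axis=1)
    m0 = log2_expr.loc[:, np.asarray(z) == 0].mean(axis=1)
    return log2_expr.index[(m1 > 1.0) & (m0 > 1.0)]


def select_methylation_probe(probe_betas: pd.DataFrame, probe_map: pd.DataFrame,
                             gene_expr: pd.DataFrame) -> ProbeSelection:
    """Per gene, the probe most anti-correlated with the gene's expression.

    `probe_map` holds (probe, gene) rows; samples must be paired between the
    beta matrix and the expression matrix.  Zero-variance probes are treated
    as missing; a gene whose probes are all missing is dropped with a log
    entry.  Ties break on the lexicographically smallest probe ID.
    """
    if not probe_betas.columns.equals(gene_expr.columns):
        common = probe_betas.columns.intersection(gene_expr.columns)
        if len(common) < 3:
            raise ValueError("fewer than 3 paired samples between beta and expression")
        probe_betas = probe_betas[common]
        gene_expr = gene_expr[common]

    rows = {}
    for gene, grp in probe_map.groupby("gene"):
        if gene not in gene_expr.index:
            continue
        expr = gene_expr.loc[gene].to_numpy(dtype=float)
        if np.std(expr) == 0:
            logger.info("gene %s dropped: zero-variance expression", gene)
            continue
        best = None
        for probe in sorted(grp["probe"]):
            if probe not in probe_betas.index:
                continue
            beta = probe_betas.loc[probe].to_numpy(dtype=float)
            if np.std(beta) == 0:
                continue
            r = float(np.corrcoef(beta, expr)[0, 1])
            if best is None or r < best[1]:
                best = (probe, r)
        if best is None:
            logger.info("gene %s dropped: no usable methylation probe", gene)
            continue
        rows[gene] = {"probe": best[0], "r": best[1]}
    return ProbeSelection(pd.DataFrame(rows).T if rows else
                          pd.DataFrame(columns=["probe", "r"]))


def filter_mutations(maf: pd.DataFrame, include_silent: bool = False):
    """Apply the hypermutator and frequency filters to a MAF-like table.

    Drops samples with >= 1000 mutations (strict '<' retention), binarizes
    gene x sample incidence, and keeps genes mutated in >= 5% of retained
    samples.  Silent / non-coding rows are excluded by default.

    Returns (kept_samples, kept_genes, matrix) where `matrix` is the binary
    gene x retained-sample incidence restricted to the kept genes.
    """
    required = ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]
    missing = [c for c in required if c not in maf.columns]
    if missing:
        raise ValueError(f"MAF table missing columns {missing}")
    bad_rows = maf.index[maf[required].isna().any(axis=1)].tolist()
    if bad_rows:
        raise ValueError(f"malformed MAF rows (missing fields) at lines {bad_rows}")

    work = maf if include_silent else maf[~maf["Variant_Classification"].isin(SILENT_CLASSES)]
    per_sample = work.groupby("Tumor_Sample_Barcode").size()
    kept_samples = per_sample.index[per_sample < MUTATION_SAMPLE_MAX]
    work = work[work["Tumor_Sample_Barcode"].isin(kept_samples)]

    incidence = (
        work.assign(hit=1)
        .pivot_table(index="Hugo_Symbol", columns="Tumor_Sample_Barcode",
                     values="hit", aggfunc="max", fill_value=0)
        .reindex(columns=kept_samples, fill_value=0)
    )
    freq = incidence.sum(axis=1) / max(len(kept_samples), 1)
    kept_genes = incidence.index[freq >= MUTATION_FREQ_MIN]
    return kept_samples, kept_genes, incidence.loc[kept_genes].astype(int)


def methylation_expression_enrichment(meth_genes, expr_genes, universe):
    """One-sided Fisher enrichment of one gene set in another over a universe.

    Returns (odds_ratio, p); the odds ratio is the sample (cross-product)
    odds ratio, infinite when a zero cell makes it so.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    meth = set(meth_genes) & universe
    expr = set(expr_genes) & universe
    if not set(meth_genes) <= universe or not set(expr_genes) <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    a = len(meth & expr)
    b = len(meth - expr)
    c = len(expr - meth)
    d = len(universe) - a - b - c
    res = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    # sample (cross-product) odds ratio with an explicit infinite flag for
    # zero off-diagonal cells
    if b * c == 0:
        orr = float("inf") if a > 0 else float("nan")
    else:
        orr = a * d / (b * c)
    return float(orr), float(res.pvalue)


def binarize_layer(layer: OmicsLayer) -> OmicsLayer:
    """Collapse a GISTIC-style call matrix to 0/1 altered-vs-not."""
    if layer.tag not in ("scna", "mutation"):
        raise ValueError("binarize_layer expects a scna or mutation layer")
    return OmicsLayer((layer.values != 0).astype(int), layer.tag)
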