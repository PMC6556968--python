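"""TSV / GMT / JSON readers and writers with a fixed header convention.

All matrices are tab-separated with the first column holding feature IDs and
the header row holding sample IDs.  Gene sets use GMT (name, description,
members...).  miRNA target tables are two-column TSVs (mirna, gene).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import CohortClinical, OmicsLayer


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature IDs {dups}")
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


def read_layer(path, tag: str) -> OmicsLayer:
    return OmicsLayer(read_matrix(path), tag)


def write_layer(layer: OmicsLayer, path) -> None:
    write_matrix(layer.values, path)


def read_clinical(path, confounder_cols=None) -> CohortClinical:
    table = pd.read_csv(path, sep="\t", index_col=0)
    if confounder_cols is None:
        confounder_cols = [c for c in table.columns if c.startswith("confounder")]
    return CohortClinical(table, list(confounder_cols))


def write_clinical(clinical: CohortClinical, path) -> None:
    write_matrix(clinical.table, path)


def read_gene_list(path) -> list[str]:
    """One symbol per line, or the members of the first GMT record."""
    text = Path(path).read_text().strip()
    if not text:
        return []
    first = text.splitlines()[0]
    if "\t" in first:  # GMT: name <tab> description <tab> genes...
        return first.split("\t")[2:]
    return [line.strip() for line in text.splitlines() if line.strip()]


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: malformed GMT line {line!r}")
        sets[parts[0]] = parts[2:]
    return sets


def read_target_table(path) -> dict[str, set[str]]:
    """Two-column TSV (mirna, gene) -> mapping miRNA -> set of targets."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: target table needs (mirna, gene) columns")
    mirna_col, gene_col = df.columns[:2]
    out: dict[str, set[str]] = {}
    for mir, genes in df.groupby(mirna_col)[gene_col]:
        out[str(mir)] = set(map(str, genes))
    return out


def read_maf(path) -> pd.DataFrame:
    maf = pd.read_csv(path, sep="\t", comment="#")
    required = {"Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"}
    missing = required - set(maf.columns)
    if missing:
        raise ValueError(f"{path}: MAF missing required columns {sorted(missing)}")
    return maf


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
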