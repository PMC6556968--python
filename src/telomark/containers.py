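"""In-memory containers shared across the pipeline stages.

Every omics layer travels as a features x samples :class:`pandas.DataFrame`
wrapped in an :class:`OmicsLayer` that records which molecular type it holds,
because downstream stages apply layer-specific semantics (log2 expression
filters for mRNA, beta values for methylation, 0/1 incidence for mutations,
GISTIC-style -2..2 calls for copy number).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Recognised molecular layer tags.
LAYER_TAGS = ("mrna", "methylation", "mirna", "mutation", "scna")


@dataclass
class OmicsLayer:
    """A features x samples numeric matrix with a molecular-layer tag.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are features (genes, probes, miRNAs), columns are sample IDs.
        Continuous layers are on log2 scale; mutation is 0/1 incidence;
        scna holds integer calls in [-2, 2]; methylation holds beta values
        in (0, 1).
    tag : str
        One of :data:`LAYER_TAGS`.
    """

    values: pd.DataFrame
    tag: str

    def __post_init__(self) -> None:
        if self.tag not in LAYER_TAGS:
            raise ValueError(f"unknown layer tag {self.tag!r}; expected one of {LAYER_TAGS}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs in {self.tag} layer: {dups}")

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def reindex_samples(self, samples) -> "OmicsLayer":
        """Return a copy restricted to / ordered by `samples`."""
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples missing from {self.tag} layer: {missing}")
        return OmicsLayer(self.values.loc[:, list(samples)], self.tag)


@dataclass
class CohortClinical:
    """Per-sample clinical covariates and outcomes.

    `table` is indexed by sample ID and may carry:

    - confounder columns (listed in `confounder_cols`),
    - `tert_group`: 1 for TERT-high, 0 for TERT-low,
    - `tert_reads`: RNA-seq quantified TERT read count,
    - `alt_flag`: boolean, known ALT-related alteration (ATRX/DAXX),
    - `time`, `event`: survival follow-up (event 1 = death),
    - `tl_ratio`: tumor/normal telomere-length ratio (optional).
    """

    table: pd.DataFrame
    confounder_cols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample IDs in clinical table")
        missing = [c for c in self.confounder_cols if c not in self.table.columns]
        if missing:
            raise KeyError(f"confounder columns missing from clinical table: {missing}")

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    @property
    def covariates(self) -> pd.DataFrame:
        return self.table[self.confounder_cols]

    @property
    def group(self) -> np.ndarray:
        """Binary TERT group labels (1 = high) as an int array."""
        return self.table["tert_group"].to_numpy(dtype=int)


def check_binary_labels(z: np.ndarray) -> np.ndarray:
    """Validate and coerce a binary 0/1 label vector; both groups non-empty."""
    z = np.asarray(z)
    if not np.isin(z, (0, 1)).all():
        raise ValueError("group labels must be binary 0/1")
    z = z.astype(int)
    if z.sum() == 0 or z.sum() == len(z):
        raise ValueError("both groups must be non-empty")
    return z
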