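import numpy as np
import pandas as pd
import pytest

import telomark as tm


@pytest.fixture(scope="session")
def planted_cohort():
    """Default study-conditions cohort (n=200, 1.5 SD effects, 3 modules)."""
    return tm.generate_cohort(tm.CohortConfig(seed=7))


@pytest.fixture(scope="session")
def null_cohort():
    """Confounded cohort with no planted group effects."""
    return tm.generate_cohort(null_config(99))


def null_config(seed: int) -> tm.CohortConfig:
    return tm.CohortConfig(
        n_samples=200, n_mrna=100, n_modules=1, module_size=10,
        frac_differential=0.0, effect_size=0.0, cluster_group_shift=0.0,
        n_methylation=5, n_mirna=8, n_mutation=5, n_scna=5,
        n_subtype_markers=0, n_mirna_targets=0, n_signature_genes=5,
        seed=seed,
    )


@pytest.fixture(scope="session")
def module_expr(planted_cohort):
    """Expression over the planted module genes plus 60 background genes."""
    truth = planted_cohort.truth
    mod_genes = list(truth.modules)
    bg = [g for g in planted_cohort.layers["mrna"].features
          if g not in truth.modules and g != "TERT"][:60]
    return planted_cohort.layers["mrna"].values.loc[mod_genes + bg]


from telomark.evaluation import subtype_marker_table  # noqa: E402,F401
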