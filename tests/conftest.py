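import numpy as np
import pandas as pd
import pytest

from splsero import NPXMatrix, SimulationConfig, generate_cohort
from splsero import preprocess as pp


@pytest.fixture(scope="session")
def default_study():
    """Full-size discovery + replication cohorts at the default conditions."""
    config = SimulationConfig(seed=1)
    disc = generate_cohort(config, "discovery")
    rep = generate_cohort(config, "replication")
    return {"config": config, "discovery": disc, "replication": rep}


@pytest.fixture(scope="session")
def processed_discovery(default_study):
    """Discovery cohort after exclusion, quantile normalization, LOD reset."""
    matrix, meta, annot, truth = default_study["discovery"]
    exclusion = pp.detect_excludable_proteins(matrix, annot)
    retained = matrix.drop_proteins(exclusion.index[exclusion["excluded"]])
    normalized, reference = pp.quantile_normalize(retained)
    processed = pp.reset_below_lod(normalized)
    return {
        "matrix": processed,
        "annotations": annot,
        "reference": reference,
        "exclusion": exclusion,
        "truth": truth,
    }


@pytest.fixture
def small_matrix():
    """Tiny deterministic NPX matrix with a hand-set LOD mask."""
    values = pd.DataFrame(
        [[1.0, 5.0, 2.0], [3.0, 4.0, 0.5], [2.0, 6.0, 1.5]],
        index=["S1", "S2", "S3"],
        columns=["P1", "P2", "P3"],
    )
    below = pd.DataFrame(
        [[True, False, False], [False, False, True], [False, False, False]],
        index=values.index,
        columns=values.columns,
    )
    return NPXMatrix(values, below)


@pytest.fixture
def three_group_annot():
    def build(n_per_group: int, prefix: str = "S") -> pd.DataFrame:
        rows = []
        for g in ("CD", "UC", "HC"):
            for i in range(n_per_group):
                rows.append(
                    {
                        "sample_id": f"{prefix}-{g}-{i}",
                        "cohort": "discovery",
                        "group": g,
                        "location": "none",
                        "activity": "unknown",
                        "prior_resection": "unknown",
                    }
                )
        return pd.DataFrame(rows).set_index("sample_id", drop=False)

    return build
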