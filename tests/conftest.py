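import warnings

import numpy as np
import pandas as pd
import pytest

from immunomark import synthetic

# sklearn >= 1.8 emits FutureWarnings from LogisticRegression internals on
# some codepaths; they are irrelevant to the properties under test.
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient, 8-feature cohort with one strong feature (index 0)."""
    spec = synthetic.CohortSpec(
        n_patients=60,
        n_features=8,
        informative_indices=(0,),
        effect_sizes=(2.5,),
        seed=11,
    )
    fm, clinical = synthetic.generate_cohort(spec)
    return fm, clinical["non_progressor"].to_numpy()


@pytest.fixture
def toy_scores():
    """Deterministic 1-D separable data for logistic fits."""
    x = np.array([-2.0, -1.5, -1.0, 1.0, 1.5, 2.0])
    y = np.array([0, 0, 0, 1, 1, 1])
    return x, y


@pytest.fixture
def qc_record():
    """A record sitting exactly on every inclusion boundary."""
    return {
        "sample_id": "S1",
        "rna_yield_ng": 40.0,
        "dv200_pct": 20.0,
        "exonic_alignment_frac": 0.30,
        "unique_dedup_counts": 800_000,
        "tumor_cellularity_frac": 0.10,
        "biopsy_to_treatment_months": 2.0,
    }


@pytest.fixture
def expression_toy():
    """3-sample counts matrix with hand-checkable CPM values."""
    return pd.DataFrame(
        {
            "s1": [1000, 2000, 997000],
            "s2": [500, 1000, 998500],
            "s3": [250, 500, 999250],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
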