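import numpy as np
import pandas as pd
import pytest

from methdet.preprocess import MethylationMatrix, build_matrix, preprocess_sample
from methdet.synthetic import (
    CohortConfig,
    SimulatedCohort,
    default_effect_table,
    generate_cohort,
    panel_effect_table,
)


def cohort_matrix(cohort: SimulatedCohort, normalize: bool = False) -> MethylationMatrix:
    """Full array-level processing chain for a simulated cohort."""
    summaries = {
        sid: preprocess_sample(arr) for sid, arr in cohort.arrays.items()
    }
    return build_matrix(summaries, normalize=normalize)


def make_matrix(X: np.ndarray, n_relapse: int, gene_ids=None):
    """Wrap a genes x samples value array into a matrix plus labels."""
    n = X.shape[1]
    samples = [f"R{i + 1:02d}" for i in range(n_relapse)] + [
        f"C{i + 1:03d}" for i in range(n - n_relapse)
    ]
    genes = gene_ids or [f"g{i}" for i in range(X.shape[0])]
    values = pd.DataFrame(X, index=genes, columns=samples)
    labels = pd.Series(
        ["relapse"] * n_relapse + ["control"] * (n - n_relapse), index=samples
    )
    return MethylationMatrix(values=values), labels


@pytest.fixture(scope="session")
def small_cohort() -> SimulatedCohort:
    """A matched 10/10 cohort with the 21 published effects at tight spread."""
    cfg = CohortConfig(
        n_relapse=10,
        n_control=10,
        effects=default_effect_table(sd_relapse=0.4, sd_control=0.4),
        null_sd=0.4,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_panel_cohort() -> SimulatedCohort:
    """Default-size cohort (19/104) with only the 7 panel genes planted."""
    cfg = CohortConfig(
        effects=panel_effect_table(sd_relapse=0.5, sd_control=0.5),
        null_sd=0.5,
        seed=11,
    )
    return generate_cohort(cfg)
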