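import numpy as np
import pandas as pd
import pytest

from tepseq.core_io import CountMatrix, SampleAnnotation
from tepseq.synthetic_data import ConfounderSpec, simulate_counts


@pytest.fixture(scope="session")
def small_cohort():
    """Mid-size simulated cohort with all planted structure, shared."""
    return simulate_counts(
        n_genes=500, n_samples=100, frac_de=0.1, logfc=1.0, dispersion=0.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_cohort():
    """Cohort without batch/age confounding for clean DE checks."""
    return simulate_counts(
        n_genes=500, n_samples=100, frac_de=0.1, logfc=1.0, dispersion=0.2,
        confounders=ConfounderSpec(batch_strength=0.0, age_strength=0.0),
        seed=12,
    )


def tiny_matrix(values, genes=None, samples=None) -> CountMatrix:
    arr = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples))


def annotation_for(matrix: CountMatrix, groups=None, ages=None) -> SampleAnnotation:
    n = matrix.n_samples
    groups = groups if groups is not None else ["a", "b"] * (n // 2) + ["a"] * (n % 2)
    ages = ages if ages is not None else [60.0] * n
    return SampleAnnotation(
        pd.DataFrame(
            {
                "group": groups,
                "age": ages,
                "storage": "<12hr",
                "gender": "f",
                "smoking": "never",
                "cohort_role": "training",
                "site": "test",
            },
            index=pd.Index(matrix.sample_ids, name="sample_id"),
        )
    )
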