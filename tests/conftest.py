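import numpy as np
import pytest

from pqkit import (
    EntryQualityRecord,
    PopulationSpec,
    fit_reference,
    generate_reference_population,
)


def make_record(entry_id="9abc", rfree=0.22, rsrz=2.0, clash=5.0, rama=0.3,
                rota=2.0, **kwargs):
    defaults = dict(
        entry_id=entry_id,
        resolution=2.0,
        rfree_dcc=rfree,
        rsrz_outlier_pct=rsrz,
        clashscore=clash,
        rama_outlier_pct=rama,
        rotamer_outlier_pct=rota,
    )
    defaults.update(kwargs)
    return EntryQualityRecord(**defaults)


@pytest.fixture(scope="session")
def synthetic_records():
    return generate_reference_population(PopulationSpec(n=300, seed=20260929))


@pytest.fixture(scope="session")
def fitted_population(synthetic_records):
    return fit_reference(synthetic_records, label="synthetic-300")


def brute_force_percentile(value, reference, orientation):
    """Independent mid-rank counting oracle (no sorting, no searchsorted)."""
    worse = ties = 0
    for r in reference:
        if r == value:
            ties += 1
        elif (orientation == "lower" and r > value) or (
            orientation == "higher" and r < value
        ):
            worse += 1
    return (worse + 0.5 * ties) / len(reference)


def brute_force_pc1(matrix):
    """First eigenvector of the sample covariance via direct eigendecomposition."""
    cov = np.cov(matrix, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    v = eigvecs[:, np.argmax(eigvals)]
    return v / np.linalg.norm(v)
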