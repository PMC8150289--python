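import numpy as np
import pandas as pd
import pytest

from pannet_radiomics import (
    CohortSpec,
    PhantomSpec,
    extract_feature_vector,
    generate_cohort,
    generate_lesion,
)


@pytest.fixture(scope="session")
def phantom():
    """One eligible textured lesion phantom (volume, mask)."""
    return generate_lesion(PhantomSpec(seed=11, lesion_radius_mm=15.0))


@pytest.fixture(scope="session")
def default_cohort():
    """A full default 51-patient synthetic cohort: (phantoms, metadata table)."""
    return generate_cohort(CohortSpec(seed=5))


@pytest.fixture(scope="session")
def cohort_features(default_cohort):
    """Metadata table joined with the 60-feature vector of every patient."""
    phantoms, table = default_cohort
    rows = [{"id": pid, **extract_feature_vector(*phantoms[pid])} for pid in table["id"]]
    return table.merge(pd.DataFrame(rows), on="id")


def make_feature_table(seed=0, n_per_cell=(13, 12, 18, 8), effect=1.5, n_features=4):
    """A purely numeric cohort-shaped table: gaussian features with a grade shift.

    Cheap stand-in for phantom-derived features where only the table structure
    and a controllable class separation matter (CV bookkeeping, fold tests).
    """
    rng = np.random.default_rng(seed)
    rows = []
    cells = [("HS", "G1", n_per_cell[0]), ("HS", "G2", n_per_cell[1]),
             ("BS", "G1", n_per_cell[2]), ("BS", "G2", n_per_cell[3])]
    i = 0
    for source, grade, n in cells:
        for _ in range(n):
            i += 1
            shift = effect if grade == "G2" else 0.0
            row = {"id": f"P{i:03d}", "grade": grade, "source": source}
            for f in range(n_features):
                row[f"f{f}"] = rng.normal(shift if f < 2 else 0.0, 1.0)
            rows.append(row)
    return pd.DataFrame(rows)
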