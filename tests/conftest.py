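import numpy as np
import pytest

from metabostrat import (
    CohortTable,
    SampleRecord,
    default_spec,
    generate_cohort,
)


def make_cohort(rows):
    """Build a cohort from (sample_id, subtype, formate, glucose) tuples,
    optionally with a trailing extras dict."""
    records = []
    for row in rows:
        extra = row[4] if len(row) > 4 else {}
        records.append(
            SampleRecord(
                sample_id=row[0],
                subtype=row[1],
                formate=row[2],
                glucose=row[3],
                extra=extra,
            )
        )
    return CohortTable(records)


@pytest.fixture
def toy_cohort():
    """9 samples, 3 per merged class, fully separable by (glucose, formate)."""
    return make_cohort(
        [
            ("h1", "H", 0.080, 9.0e7),
            ("h2", "H", 0.095, 8.5e7),
            ("h3", "H", 0.070, 1.0e8),
            ("c1", "BC", 0.030, 8.0e7),
            ("c2", "BC", 0.040, 9.5e7),
            ("c3", "LC", 0.025, 1.1e8),
            ("o1", "ODminus", 0.060, 1.9e8),
            ("o2", "ODplus", 0.045, 2.2e8),
            ("o3", "ODplus", 0.085, 1.7e8),
        ]
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded cohort from the calibrated default spec (n = 255)."""
    return generate_cohort(default_spec(), seed=20240917)


def random_small_cohort(rng, n_max=12, require_classes=("h", "c", "o"), n_min=None):
    """A random cohort of <= n_max samples containing the required merged
    classes, with deliberately coarse values so threshold ties occur."""
    subtype_for = {"h": "H", "c": "BC", "o": "ODplus"}
    n = int(rng.integers(max(len(require_classes), n_min or 0), n_max + 1))
    while True:
        subtypes = [subtype_for[c] for c in require_classes]
        subtypes += list(
            rng.choice(["H", "BC", "LC", "ODminus", "ODplus"], size=n - len(subtypes))
        )
        rows = []
        for i, st in enumerate(subtypes):
            formate = float(rng.choice([0.02, 0.04, 0.06, 0.08, 0.10]))
            glucose = float(rng.choice([8e7, 1.0e8, 1.4e8, 2.0e8]))
            rows.append((f"s{i}", st, formate, glucose))
        return make_cohort(rows)
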