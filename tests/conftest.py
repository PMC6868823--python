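import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True)
settings.load_profile("default")

from edscreen import (
    BmiClass,
    BroadCategory,
    ConfusionMatrix4,
    PatientRecord,
    ScoffResponse,
    Sex,
    default_rule_table,
)
from edscreen.reference import REFERENCE_CONFUSION
from edscreen.simulate import CATEGORY_MEMBERS

#: A representative BMI value inside each class.
BMI_IN_CLASS = {
    BmiClass.UNDERWEIGHT: 16.0,
    BmiClass.NORMAL: 21.0,
    BmiClass.OVERWEIGHT: 27.0,
    BmiClass.OBESE: 34.0,
}


@pytest.fixture(scope="session")
def table():
    return default_rule_table()


@pytest.fixture(scope="session")
def reference_cm():
    return ConfusionMatrix4(np.array(REFERENCE_CONFUSION))


def cohort_from_counts(counts, table):
    """Build a cohort whose physician/algorithm label pairs tally to ``counts``.

    For target algorithm category j we use any rule-table cell mapping to
    j; the physician label comes from a DSM-5 member of category i.
    """
    cell_for = {}
    for (pattern, bmi_class), category in sorted(table.cells.items()):
        cell_for.setdefault(category, (pattern, bmi_class))
    records = []
    k = 0
    for i, truth in enumerate(BroadCategory):
        for j, predicted in enumerate(BroadCategory):
            pattern, bmi_class = cell_for[predicted]
            for _ in range(int(counts[i][j])):
                k += 1
                records.append(
                    PatientRecord(
                        id=f"T{k:04d}",
                        sex=Sex.FEMALE,
                        age=30.0,
                        bmi=BMI_IN_CLASS[bmi_class],
                        scoff=ScoffResponse.from_pattern(pattern),
                        dsm5=CATEGORY_MEMBERS[truth.value][0],
                    )
                )
    return records


def multinomial_hdr_contains(counts, n, probs, coverage=0.99):
    """Exact highest-density multinomial region membership check.

    Enumerates every 4-part composition of ``n``, sorts by probability,
    and accumulates mass until ``coverage`` is reached; returns whether
    ``counts`` lies inside that smallest covering set.
    """
    from scipy.stats import multinomial

    a = np.arange(n + 1)
    grid = [
        (i, j, k, n - i - j - k)
        for i in a
        for j in range(n - i + 1)
        for k in range(n - i - j + 1)
    ]
    grid = np.array(grid, dtype=np.int64)
    logp = multinomial.logpmf(grid, n, probs)
    order = np.argsort(logp)[::-1]
    cum = np.cumsum(np.exp(logp[order]))
    cutoff_idx = int(np.searchsorted(cum, coverage)) + 1
    threshold = logp[order[cutoff_idx - 1]]
    observed_logp = multinomial.logpmf(np.array(counts, dtype=np.int64), n, probs)
    return bool(observed_logp >= threshold - 1e-12)


@pytest.fixture(scope="session")
def reference_cohort(table):
    """A fixture cohort tallying exactly to the published confusion matrix."""
    return cohort_from_counts(REFERENCE_CONFUSION, table)
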