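import numpy as np
import pytest

from gompspan import Cohort, LifespanRecord, StudyDesign, generate_study


def make_cohort(group, death_ages, entry_age=21.5, events=None):
    """Build a cohort from raw death/censoring ages (test helper)."""
    if events is None:
        events = [True] * len(death_ages)
    records = tuple(
        LifespanRecord(f"{group}-{i}", group, entry_age, float(a), bool(e))
        for i, (a, e) in enumerate(zip(death_ages, events))
    )
    return Cohort(group=group, records=records, entry_age=entry_age)


def counting_survival_pct(death_ages, t):
    """Brute-force oracle: percent of subjects still alive just after t."""
    ages = np.asarray(death_ages, dtype=float)
    return 100.0 * float(np.sum(ages > t)) / len(ages)


@pytest.fixture()
def paper_cohorts():
    """One draw of the default study design (9 control / 8 treated, entry
    at 21.5 months, target 50%-survival ages 25.1 / 26.5)."""
    return generate_study(StudyDesign(seed=42))


@pytest.fixture()
def table_path(tmp_path, paper_cohorts):
    from gompspan import write_lifespan_table

    path = tmp_path / "study.csv"
    write_lifespan_table(paper_cohorts, path)
    return path
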