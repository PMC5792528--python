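"""Shared fixtures: one small synthetic cohort reused across the suite."""

import pytest

import socbond as sb


@pytest.fixture(scope="session")
def small_params():
    # study-like scale (~80 females) with moderate class contrasts keeps
    # every class populated with events, so the fixture's fits are well-posed
    return sb.GeneratorParams(
        n_groups=8,
        group_size_range=(8, 12),
        years=5,
        obs_hours_mean=30.0,
        obs_hours_sd=8.0,
        baseline_hazard=0.25,
        class_log_hr={1: -0.9, 2: -0.7, 3: 0.0, 4: -1.2},
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return sb.generate_cohort(small_params)


@pytest.fixture(scope="session")
def small_study(small_cohort):
    tables, _ = small_cohort
    return sb.Study(tables, sb.StudyConfig(seed=42))
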