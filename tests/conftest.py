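import pytest

import weightband as wb


def make_constant_drop_course(
    animal_id: str = "r1",
    n_days: int = 16,
    baseline: float = 300.0,
    drop_pct: float = 10.0,
    scores: bool = True,
) -> wb.WeightCourse:
    """Constant weight with a single terminal drop on the last day."""
    weights = [baseline] * (n_days - 1) + [baseline * (1 - drop_pct / 100.0)]
    score_seq = None
    if scores:
        score_seq = [0] * (n_days - 2) + [1, 2]
    return wb.WeightCourse(
        animal_id=animal_id,
        days=tuple(range(n_days)),
        weights=tuple(weights),
        scores=None if score_seq is None else tuple(score_seq),
    )


@pytest.fixture
def simple_course():
    return make_constant_drop_course()


@pytest.fixture
def constant_cohort():
    courses = tuple(
        make_constant_drop_course(f"r{i}", n_days=14 + i, drop_pct=8 + i)
        for i in range(4)
    )
    return wb.Cohort(courses=courses, label="constant")


@pytest.fixture(scope="session")
def training_cohort():
    return wb.simulate_cohort(wb.study_like_config("training"))


@pytest.fixture(scope="session")
def validation_cohort():
    return wb.simulate_cohort(wb.study_like_config("validation"))
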