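import hypothesis
import pytest

from amhage import PowerFit, Subject, Cohort

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")

#: The study's printed coefficients per group (beta0, beta1).
PRINTED = {"pcos": (41.41, 0.17), "eumenorrheic": (35.49, 0.15)}


@pytest.fixture
def printed_fits():
    return {
        g: PowerFit.from_coefficients(b0, b1, g) for g, (b0, b1) in PRINTED.items()
    }


def make_subject(i=0, group="pcos", **kw):
    defaults = dict(
        subject_id=f"s{i:03d}", group=group, age=33.0, bmi=27.0, amh=4.0
    )
    defaults.update(kw)
    return Subject(**defaults)


@pytest.fixture
def tiny_cohort():
    subjects = tuple(
        make_subject(i, age=30.0 + i, amh=float(2 ** (i - 1))) for i in range(3)
    )
    return Cohort(subjects=subjects, group="pcos")
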