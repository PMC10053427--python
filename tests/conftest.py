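import numpy as np
import pytest

from paindraw import (
    BodyTemplate,
    Cohort,
    PainDrawing,
    make_synthetic_template,
)


@pytest.fixture(scope="session")
def tpl4() -> BodyTemplate:
    """Small 4-band template shared by most tests."""
    return make_synthetic_template(32, 32, n_regions=4, seed=0)


def make_drawing(y, subject_id="s", label="A", template_id="t") -> PainDrawing:
    return PainDrawing(
        subject_id=subject_id,
        label=label,
        y=np.asarray(y, dtype=np.uint8),
        template_id=template_id,
    )


@pytest.fixture()
def tiny_template() -> BodyTemplate:
    """Fully-inside 4x4 template: m = 16, no regions."""
    return BodyTemplate(template_id="t", inside_mask=np.ones((4, 4), bool))


def random_binary_cohort(rng, template, n_per_class=5, labels=("P", "Q")):
    """Random non-empty binary drawings on ``template`` for oracle tests."""
    drawings = []
    for label in labels:
        for i in range(n_per_class):
            y = (rng.random(template.m) < rng.uniform(0.2, 0.8)).astype(np.uint8)
            if not y.any():
                y[rng.integers(template.m)] = 1
            drawings.append(
                PainDrawing(
                    subject_id=f"{label}{i}",
                    label=label,
                    y=y,
                    template_id=template.template_id,
                )
            )
    return Cohort(template=template, drawings=tuple(drawings))
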