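import numpy as np
import pandas as pd
import pytest

from fdqp import (
    AttributeMeasures,
    AttributeSpec,
    DataType,
    EdgeDataset,
    QualityDimension,
    default_rules,
    initialize_profile,
)


@pytest.fixture
def three_attr_profile():
    """Small valid baseline profile: 3 numeric attributes, default rules,
    a 70% completeness tolerance everywhere."""
    specs = [
        AttributeSpec(
            name=name,
            data_type=DataType.NUMERIC,
            tolerances={QualityDimension.COMPLETENESS: 0.70},
        )
        for name in ("heart_rate", "variability", "accelerations")
    ]
    return initialize_profile(
        specs,
        {QualityDimension.COMPLETENESS, QualityDimension.CONSISTENCY},
        default_rules(),
    )


@pytest.fixture
def measured_profile(three_attr_profile):
    """The same profile with handcrafted measures attached (edge-like)."""
    p = three_attr_profile.copy()
    p.measures = {
        "heart_rate": AttributeMeasures(
            observed_min=110.0, observed_max=160.0, mode=133.0, skewness=0.4,
            missing_fraction=0.1, unique_fraction=0.8, outlier_fraction=0.02,
            completeness=0.9, cv=0.12,
        ),
        "variability": AttributeMeasures(
            observed_min=0.5, observed_max=7.25, mode=2.0, skewness=-1.3,
            missing_fraction=0.0, unique_fraction=0.55, outlier_fraction=0.0,
            completeness=1.0, cv=0.4,
        ),
        "accelerations": AttributeMeasures(
            observed_min=0.0, observed_max=26.0, mode=1.0, skewness=2.1,
            missing_fraction=0.25, unique_fraction=0.3, outlier_fraction=0.05,
            completeness=0.75, cv=1.1,
        ),
    }
    p.row_count = 200
    return p


@pytest.fixture
def small_edge():
    rng = np.random.default_rng(7)
    table = pd.DataFrame(
        {
            "a": rng.normal(10, 2, 40),
            "b": rng.normal(-3, 1, 40),
            "c": rng.normal(0, 5, 40),
        }
    )
    labels = pd.Series(rng.choice(["N", "S"], size=40), name="fetal_state")
    return EdgeDataset("edge-test", table, labels)
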