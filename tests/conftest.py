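import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hedoseg.datamodel import ATTRIBUTES, RatingTable, default_chocolate_series

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_rating_records(subject_values: dict, session_split: bool = True) -> pd.DataFrame:
    """Build a long rating frame from {subject: {attribute: 4 values}}.

    Attributes omitted for a subject are filled with a default varying
    series so the subject stays complete unless explicitly truncated.
    """
    codes = [s.code for s in default_chocolate_series()]
    rows = []
    for subject, attrs in subject_values.items():
        for attr in ATTRIBUTES:
            values = attrs.get(attr)
            if values is None:
                values = [20.0, 30.0, 40.0, 50.0]
            session = 1 if (attr == "liking" and session_split) else 2
            for code, v in zip(codes, values):
                rows.append((subject, code, attr, float(v), session))
    return pd.DataFrame(
        rows, columns=["subject_id", "sample_code", "attribute", "value", "session"]
    )


@pytest.fixture
def one_subject_table() -> RatingTable:
    return RatingTable(make_rating_records({"s1": {}}))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
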