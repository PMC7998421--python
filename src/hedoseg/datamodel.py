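"""Cohort data model and tabular I/O.

The canonical on-disk representation for ratings is long (tidy) CSV:
one row per (subject, sample, attribute, session) observation. Wide
matrices used by the numerical code are derived in memory. Missing data
are explicit (empty cell / NaN), never zero — a zero is a meaningful
rating on a general Labelled Magnitude Scale (gLMS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Closed attribute vocabulary: hedonic response plus the four rated
#: sensory properties of the chocolate-pudding series.
ATTRIBUTES = ("liking", "sweet", "bitter", "astringent", "overall_flavour")

#: Sensory attributes paired with liking when building correlation vectors.
SENSORY_ATTRIBUTES = ("sweet", "bitter", "astringent", "overall_flavour")

SUCROSE_MOLAR_MASS = 342.30  # g/mol

RATING_COLUMNS = ["subject_id", "sample_code", "attribute", "value", "session"]


class ValidationError(ValueError):
    """A table failed schema or range validation."""


@dataclass(frozen=True)
class ProductSample:
    """One member of a spiked product series.

    Parameters
    ----------
    code : str
        Short identifier, unique within a series (e.g. ``"CHOC1"``).
    sucrose_conc : float
        Added sucrose as a mass fraction in g/kg; must be positive.
    """

    code: str
    sucrose_conc: float

    def __post_init__(self) -> None:
        if self.sucrose_conc <= 0:
            raise ValidationError(
                f"sucrose_conc must be > 0, got {self.sucrose_conc} for {self.code!r}"
            )

    def molarity(self, density: float = 1.0) -> float:
        """Molar sucrose concentration assuming the given density (kg/L)."""
        return self.sucrose_conc * density / SUCROSE_MOLAR_MASS


def default_chocolate_series(choc4: float = 223.0) -> list[ProductSample]:
    """The four-sample chocolate pudding sucrose series (g/kg).

    The top concentration is configurable because printed sources differ
    (233 vs 223 g/kg); 223 is the default.
    """
    return [
        ProductSample("CHOC1", 38.0),
        ProductSample("CHOC2", 83.0),
        ProductSample("CHOC3", 119.0),
        ProductSample("CHOC4", choc4),
    ]


def sucrose_molarity(conc_g_per_kg: float, density: float = 1.0) -> float:
    """Convert sucrose g/kg to mol/L assuming unit density by default."""
    return conc_g_per_kg * density / SUCROSE_MOLAR_MASS


def _check_series(samples: list[ProductSample]) -> None:
    codes = [s.code for s in samples]
    if len(set(codes)) != len(codes):
        raise ValidationError(f"duplicate sample codes in series: {codes}")


@dataclass
class RatingTable:
    """Long-format subject x sample x attribute observations on 0-100 scales.

    ``records`` holds columns ``subject_id, sample_code, attribute, value,
    session``. A subject is *complete* iff it has one value for every
    (sample, attribute) combination of the series.
    """

    records: pd.DataFrame
    samples: list[ProductSample] = field(default_factory=default_chocolate_series)

    def __post_init__(self) -> None:
        _check_series(self.samples)
        self.records = validate_rating_frame(self.records, self.samples)

    @property
    def sample_codes(self) -> list[str]:
        return [s.code for s in self.samples]

    @property
    def subjects(self) -> list[str]:
        return sorted(self.records["subject_id"].unique())

    def completeness(self) -> pd.Series:
        """Boolean per subject: all samples x attributes present."""
        expected = len(self.samples) * len(ATTRIBUTES)
        counts = (
            self.records.drop_duplicates(["subject_id", "sample_code", "attribute"])
            .groupby("subject_id")
            .size()
        )
        return counts.eq(expected).reindex(self.subjects, fill_value=False)

    def complete_subjects(self) -> list[str]:
        comp = self.completeness()
        return sorted(comp.index[comp])

    def wide(self, attribute: str) -> pd.DataFrame:
        """Subjects x samples matrix for one attribute (NaN where missing).

        When a subject rated the same sample in several sessions the
        values are averaged; pairing across attributes is by sample code
        regardless of session.
        """
        if attribute not in ATTRIBUTES:
            raise ValidationError(f"unknown attribute {attribute!r}")
        sub = self.records[self.records["attribute"] == attribute]
        mat = sub.pivot_table(
            index="subject_id", columns="sample_code", values="value", aggfunc="mean"
        )
        return mat.reindex(columns=self.sample_codes)


def validate_rating_frame(
    df: pd.DataFrame, samples: list[ProductSample]
) -> pd.DataFrame:
    """Validate a long rating frame: columns, vocabulary, bounds, duplicates."""
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"rating table missing columns: {missing}")
    df = df[RATING_COLUMNS].copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    df["session"] = df["session"].astype(int)

    bad_attr = set(df["attribute"]) - set(ATTRIBUTES)
    if bad_attr:
        raise ValidationError(
            f"unknown attributes {sorted(bad_attr)}; allowed: {list(ATTRIBUTES)}"
        )
    codes = {s.code for s in samples}
    bad_code = set(df["sample_code"]) - codes
    if bad_code:
        raise ValidationError(f"unknown sample codes {sorted(bad_code)}")

    out = df[(df["value"] < 0) | (df["value"] > 100)]
    if not out.empty:
        row = out.iloc[0]
        raise ValidationError(
            f"value {row['value']} out of bounds 0-100 for subject "
            f"{row['subject_id']}, sample {row['sample_code']}, "
            f"attribute {row['attribute']} (row {out.index[0]})"
        )

    dup = df.duplicated(["subject_id", "sample_code", "attribute", "session"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            "duplicate record for (subject, sample, attribute, session) = "
            f"({row['subject_id']}, {row['sample_code']}, {row['attribute']}, "
            f"{row['session']})"
        )
    return df.reset_index(drop=True)


def read_rating_table(
    path, samples: list[ProductSample] | None = None
) -> RatingTable:
    """Read a long-format rating CSV into a validated :class:`RatingTable`."""
    df = pd.read_csv(path)
    return RatingTable(df, samples or default_chocolate_series())


def write_rating_table(table: RatingTable, path) -> None:
    table.records.to_csv(path, index=False)


@dataclass
class SubjectProfile:
    """Per-subject demographics and habits; missing values are NaN/None."""

    subject_id: str
    gender: str | None = None
    age: float | None = None
    bmi: float | None = None
    sugar_in_coffee: float | None = None
    coffee_consumer: bool | None = None
    appetite: float | None = None

    def __post_init__(self) -> None:
        if self.age is not None and not np.isnan(self.age) and self.age < 18:
            raise ValidationError(f"age must be >= 18, got {self.age}")
        if self.bmi is not None and not np.isnan(self.bmi) and self.bmi <= 0:
            raise ValidationError(f"bmi must be > 0, got {self.bmi}")


PROFILE_COLUMNS = [
    "subject_id",
    "gender",
    "age",
    "bmi",
    "sugar_in_coffee",
    "coffee_consumer",
    "appetite",
]


def profiles_to_frame(profiles: list[SubjectProfile]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in profiles], columns=PROFILE_COLUMNS)


ITEM_COLUMNS = ["subject_id", "instrument", "item_index", "response"]


def read_item_responses(path) -> pd.DataFrame:
    """Read questionnaire item responses (long CSV).

    Columns: ``subject_id, instrument, item_index, response``. Bound
    checks against each instrument's scale happen at scoring time, when
    the instrument spec is known.
    """
    df = pd.read_csv(path)
    missing = [c for c in ITEM_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"item response table missing columns: {missing}")
    df = df[ITEM_COLUMNS].copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df["item_index"] = df["item_index"].astype(int)
    return df


def write_report(report: pd.DataFrame, path, float_format: str | None = None) -> None:
    """Write a report table as CSV with a deterministic column order.

    Round-trip through :func:`read_report` preserves values to machine
    precision (full ``repr`` float formatting unless overridden).
    """
    report.to_csv(path, index=False, float_format=float_format)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path)
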