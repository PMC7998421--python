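"""Synthetic consumer cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: three sweet-liker phenotypes with distinct liking curves over a
four-level sucrose series, shared intensity curves (sweetness rising,
bitterness/astringency falling with concentration) with a
phenotype-specific flavour slope, a small subpopulation of raters who
give constant near-zero astringency (and so cannot be assigned a
correlation vector), phenotype-shifted trait scores and demographics,
and group-separated CATA citation probabilities over a vegetable list.

Every draw is Gaussian-with-truncation onto the rating scale; identical
seed and config give a bit-identical cohort. Defaults are the study
conditions (cohort size 1208, phenotype weights 0.389/0.405/0.206,
zero-variance fraction 70/1208); curve magnitudes and noise levels are
realistic invented values documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import (
    ATTRIBUTES,
    ProductSample,
    RatingTable,
    default_chocolate_series,
)

PHENOTYPES = ("HighSweetLiker", "ModerateSweetLiker", "InvertedUShaped")

#: Mean liking (LAM units) per concentration, by phenotype. Shapes follow
#: the three phenotype definitions: monotone increase; increase then
#: plateau at the third concentration; inverted U peaking at the 2nd-3rd.
DEFAULT_LIKING_CURVES = {
    "HighSweetLiker": (40.0, 55.0, 65.0, 75.0),
    "ModerateSweetLiker": (35.0, 55.0, 70.0, 70.0),
    "InvertedUShaped": (45.0, 62.0, 60.0, 40.0),
}

#: Mean gLMS intensity per concentration. Sweetness rises and
#: bitterness/astringency fall with added sucrose for every phenotype;
#: the overall-flavour slope is phenotype-specific (rising for High,
#: falling for Moderate, weakly peaked for Inverted-U).
DEFAULT_INTENSITY_CURVES = {
    "sweet": (16.0, 26.0, 36.0, 48.0),
    "bitter": (35.0, 28.0, 21.0, 16.0),
    "astringent": (24.0, 20.0, 17.0, 13.0),
}
DEFAULT_FLAVOUR_CURVES = {
    "HighSweetLiker": (28.0, 33.0, 38.0, 43.0),
    "ModerateSweetLiker": (43.0, 38.0, 33.0, 28.0),
    "InvertedUShaped": (31.0, 35.0, 34.0, 30.0),
}

#: Trait means by phenotype (High, Moderate, InvertedU), within-cluster
#: sd, and the clip range of the instrument. Means of the discriminating
#: traits follow the reported cluster orderings; the remaining traits
#: are order-free.
DEFAULT_TRAIT_EFFECTS = {
    "DS": {"means": (28.85, 30.05, 28.55), "sd": 4.0, "range": (8, 40)},
    "SP": {"means": (9.17, 9.93, 8.79), "sd": 3.5, "range": (0, 23)},
    "DIF": {"means": (15.57, 15.60, 14.63), "sd": 4.0, "range": (7, 35)},
    "DDF": {"means": (12.46, 13.26, 13.49), "sd": 3.5, "range": (5, 25)},
    "EOT": {"means": (20.0, 20.0, 20.0), "sd": 5.0, "range": (8, 40)},
    "PBC": {"means": (17.0, 17.0, 17.0), "sd": 4.0, "range": (5, 25)},
    "FNS": {"means": (28.0, 28.0, 28.0), "sd": 9.0, "range": (10, 70)},
    "SR": {"means": (9.0, 9.0, 9.0), "sd": 3.5, "range": (0, 18)},
    "PROP": {"means": (42.18, 44.91, 38.63), "sd": 20.0, "range": (0, 100)},
}

#: Demographics: age means follow the reported ordering (Inverted-U
#: oldest); women share by phenotype derived from the reported
#: gender x cluster margins; sugar-in-coffee lowest for Inverted-U.
DEFAULT_PROFILE_EFFECTS = {
    "age": {"means": (35.53, 34.22, 38.29), "sd": 12.9, "range": (18, 69)},
    "p_woman": (0.527, 0.623, 0.611),
    "sugar_in_coffee": {"means": (0.83, 0.77, 0.56), "sd": 0.6, "range": (0, 5)},
    "bmi": {"means": (23.5, 23.5, 23.5), "sd": 3.5, "range": (15, 45)},
    "appetite": {"means": (50.0, 50.0, 50.0), "sd": 20.0, "range": (0, 100)},
    "p_coffee_consumer": (0.79, 0.79, 0.79),
}

VEGETABLE_GROUPS = {
    "chicory": "more_bitter_astringent",
    "rocket_radicchio": "more_bitter_astringent",
    "artichoke": "more_bitter_astringent",
    "radish": "more_bitter_astringent",
    "asparagus": "medium",
    "spinach": "medium",
    "broccoli": "medium",
    "cauliflower": "medium",
    "cucumber": "medium",
    "carrot": "sweeter",
    "fennel": "sweeter",
    "lettuce_valerian": "sweeter",
    "soybean_sprout": "sweeter",
    "beetroot": "sweeter",
    "zucchini": "sweeter",
    "chard": "sweeter",
    "tomato": "sweeter",
}

CATA_ATTRIBUTES = (
    "sweet", "bitter", "astringent", "mild_flavour", "salty",
    "sour", "flavourful", "pungent", "stinging",
)

#: Citation probability of each attribute by product group, separating
#: the bitter/astringent pole from the sweet pole.
DEFAULT_CATA_PROBS = {
    "more_bitter_astringent": {
        "sweet": 0.05, "bitter": 0.60, "astringent": 0.45, "mild_flavour": 0.10,
        "salty": 0.05, "sour": 0.15, "flavourful": 0.50, "pungent": 0.35,
        "stinging": 0.25,
    },
    "medium": {
        "sweet": 0.20, "bitter": 0.20, "astringent": 0.20, "mild_flavour": 0.40,
        "salty": 0.07, "sour": 0.12, "flavourful": 0.35, "pungent": 0.10,
        "stinging": 0.08,
    },
    "sweeter": {
        "sweet": 0.55, "bitter": 0.05, "astringent": 0.08, "mild_flavour": 0.50,
        "salty": 0.06, "sour": 0.10, "flavourful": 0.30, "pungent": 0.04,
        "stinging": 0.03,
    },
}

#: Mean total polyphenol content (mg/100 g) by product group, used to
#: synthesize a phenol table whose gradient tracks astringency.
DEFAULT_PHENOL_MEANS = {
    "more_bitter_astringent": 180.0,
    "medium": 80.0,
    "sweeter": 40.0,
}


class ConfigError(ValueError):
    """A cohort configuration violates a structural constraint."""


@dataclass
class CohortConfig:
    """Generator parameters; defaults are the study conditions."""

    n_subjects: int = 1208
    mixture_weights: tuple = (0.389, 0.405, 0.206)
    liking_curves: dict = field(default_factory=lambda: dict(DEFAULT_LIKING_CURVES))
    intensity_curves: dict = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_CURVES)
    )
    flavour_curves: dict = field(default_factory=lambda: dict(DEFAULT_FLAVOUR_CURVES))
    subject_sd: float = 5.0
    residual_sd: float = 7.0
    zero_variance_fraction: float = 70.0 / 1208.0
    trait_effects: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_EFFECTS))
    profile_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_PROFILE_EFFECTS)
    )
    cata_probs: dict = field(default_factory=lambda: dict(DEFAULT_CATA_PROBS))
    n_cata_respondents: int = 201
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.mixture_weights, dtype=float)
        if len(w) != 3 or not np.isclose(w.sum(), 1.0):
            raise ConfigError(f"mixture weights must be 3 values summing to 1, got {w}")
        if self.subject_sd < 0 or self.residual_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        if not 0 <= self.zero_variance_fraction < 1:
            raise ConfigError("zero_variance_fraction must be in [0, 1)")
        validate_curve_shapes(self.liking_curves)
        for grp, probs in self.cata_probs.items():
            for a, p in probs.items():
                if not 0 <= p <= 1:
                    raise ConfigError(f"cata_probs[{grp}][{a}] = {p} outside [0, 1]")
        for trait, eff in self.trait_effects.items():
            lo, hi = eff["range"]
            for m in eff["means"]:
                if not lo <= m <= hi:
                    raise ConfigError(
                        f"trait {trait}: mean {m} outside instrument range ({lo}, {hi})"
                    )


def validate_curve_shapes(liking_curves: dict) -> None:
    """Enforce the phenotype liking-curve shape constraints."""
    for name in PHENOTYPES:
        if name not in liking_curves:
            raise ConfigError(f"missing liking curve for {name}")
        c = list(liking_curves[name])
        if len(c) != 4:
            raise ConfigError(f"{name}: liking curve needs 4 concentrations")
        if name == "HighSweetLiker":
            if not (c[0] < c[1] < c[2] < c[3]):
                raise ConfigError("HighSweetLiker curve must be monotone increasing")
        elif name == "ModerateSweetLiker":
            if not (c[0] < c[1] < c[2] and abs(c[3] - c[2]) <= 0.05 * max(abs(c[2]), 1)):
                raise ConfigError(
                    "ModerateSweetLiker curve must increase then plateau at the 3rd concentration"
                )
        else:  # InvertedUShaped
            peak = int(np.argmax(c))
            if peak not in (1, 2) or not (c[0] < max(c[1], c[2]) and c[3] < max(c[1], c[2])):
                raise ConfigError(
                    "InvertedUShaped curve must peak at the 2nd-3rd concentration"
                )


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    phenotypes: pd.Series  # subject_id -> phenotype name
    zero_variance_subjects: list
    product_groups: pd.Series  # product -> group
    config: CohortConfig
    truncation_fraction: float = 0.0


def _subject_ids(n: int) -> list:
    width = len(str(n))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def generate_ratings(
    config: CohortConfig | None = None,
    samples: list[ProductSample] | None = None,
    seed: int | None = None,
) -> tuple[RatingTable, GroundTruth]:
    """Generate the chocolate-pudding rating table with known phenotypes.

    Each observation is phenotype curve + subject intercept + residual
    noise, truncated to the 0-100 scale. A ``zero_variance_fraction``
    subpopulation rates astringency with one constant near-zero value
    across all samples, which later places them on the exclusion roster.
    Liking is recorded as session 1, intensities as session 2.
    """
    config = config or CohortConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    samples = samples or default_chocolate_series()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    subjects = _subject_ids(n)

    membership = rng.choice(3, size=n, p=np.asarray(config.mixture_weights))
    phenotypes = pd.Series(
        [PHENOTYPES[m] for m in membership], index=subjects, name="phenotype"
    )
    zero_var = rng.random(n) < config.zero_variance_fraction
    zv_value = rng.uniform(0.0, 7.0, size=n)  # "nil or very low" astringency

    curves = np.empty((n, len(ATTRIBUTES), 4))
    for i, ph in enumerate(phenotypes):
        curves[i, 0] = config.liking_curves[ph]
        curves[i, 1] = config.intensity_curves["sweet"]
        curves[i, 2] = config.intensity_curves["bitter"]
        curves[i, 3] = config.intensity_curves["astringent"]
        curves[i, 4] = config.flavour_curves[ph]

    intercepts = rng.normal(0.0, config.subject_sd, size=(n, len(ATTRIBUTES), 1))
    noise = rng.normal(0.0, config.residual_sd, size=curves.shape)
    values = curves + intercepts + noise

    zv_idx = np.flatnonzero(zero_var)
    values[zv_idx, 3, :] = zv_value[zv_idx, None]

    truncated = (values < 0) | (values > 100)
    values = np.clip(values, 0.0, 100.0)

    records = []
    for i, subj in enumerate(subjects):
        for a, attr in enumerate(ATTRIBUTES):
            session = 1 if attr == "liking" else 2
            for s, sample in enumerate(samples):
                records.append((subj, sample.code, attr, values[i, a, s], session))
    table = RatingTable(
        pd.DataFrame(records, columns=["subject_id", "sample_code", "attribute", "value", "session"]),
        samples,
    )
    truth = GroundTruth(
        phenotypes=phenotypes,
        zero_variance_subjects=[subjects[i] for i in zv_idx],
        product_groups=pd.Series(VEGETABLE_GROUPS, name="group"),
        config=config,
        truncation_fraction=float(truncated.mean()),
    )
    return table, truth


def generate_traits(
    config: CohortConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate trait scores and subject profiles from the ground truth.

    Trait draws are phenotype mean + Gaussian noise clipped to the
    instrument range; demographics follow the configured phenotype
    shifts. Returns ``(traits, profiles)`` indexed/keyed by subject.
    """
    rng = np.random.default_rng(config.seed + 1)
    ph_index = truth.phenotypes.map({p: i for i, p in enumerate(PHENOTYPES)}).to_numpy()
    n = len(ph_index)

    traits = {}
    for trait, eff in config.trait_effects.items():
        means = np.asarray(eff["means"])[ph_index]
        lo, hi = eff["range"]
        traits[trait] = np.clip(rng.normal(means, eff["sd"]), lo, hi)
    trait_frame = pd.DataFrame(traits, index=truth.phenotypes.index)

    pe = config.profile_effects
    def draw(key):
        eff = pe[key]
        lo, hi = eff["range"]
        return np.clip(rng.normal(np.asarray(eff["means"])[ph_index], eff["sd"]), lo, hi)

    p_woman = np.asarray(pe["p_woman"])[ph_index]
    p_coffee = np.asarray(pe["p_coffee_consumer"])[ph_index]
    coffee = rng.random(n) < p_coffee
    sugar = draw("sugar_in_coffee")
    sugar[~coffee] = np.nan
    profiles = pd.DataFrame(
        {
            "subject_id": truth.phenotypes.index,
            "gender": np.where(rng.random(n) < p_woman, "woman", "man"),
            "age": np.round(draw("age")),
            "bmi": draw("bmi"),
            "sugar_in_coffee": sugar,
            "coffee_consumer": coffee,
            "appetite": draw("appetite"),
        }
    )
    return trait_frame, profiles


def generate_cata(
    config: CohortConfig,
    product_groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Generate a long-format CATA citation table.

    Independent Bernoulli citations with group-specific attribute
    probabilities; defaults separate the bitter/astringent and sweet
    poles so correspondence analysis reproduces a three-group vegetable
    topology.
    """
    rng = np.random.default_rng(config.seed + 2)
    groups = (
        product_groups
        if product_groups is not None
        else pd.Series(VEGETABLE_GROUPS, name="group")
    )
    respondents = [f"R{i + 1:03d}" for i in range(config.n_cata_respondents)]
    rows = []
    for product, group in groups.items():
        probs = config.cata_probs[group]
        for attr in CATA_ATTRIBUTES:
            cited = rng.random(len(respondents)) < probs.get(attr, 0.0)
            rows.extend(
                (resp, product, attr, int(c)) for resp, c in zip(respondents, cited)
            )
    return pd.DataFrame(rows, columns=["respondent", "product", "attribute", "cited"])


def generate_phenol_table(
    config: CohortConfig,
    product_groups: pd.Series | None = None,
    sd: float = 30.0,
) -> pd.Series:
    """Synthetic product-level total polyphenol table (mg/100 g).

    Group means descend from the bitter/astringent group to the sweeter
    group so that astringency citation rates and phenol content are
    positively related, as in phenol-composition databases.
    """
    rng = np.random.default_rng(config.seed + 3)
    groups = (
        product_groups
        if product_groups is not None
        else pd.Series(VEGETABLE_GROUPS, name="group")
    )
    vals = {
        product: max(1.0, rng.normal(DEFAULT_PHENOL_MEANS[group], sd))
        for product, group in groups.items()
    }
    return pd.Series(vals, name="phenol_mg_per_100g")
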