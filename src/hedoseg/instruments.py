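"""Questionnaire scoring engine.

Each instrument is declared as data (item count, item scale, reverse
items, aggregation rule, domain -> item mapping with its declared score
range) and scored uniformly: reverse-coded items are mapped through
``low + high - x`` before aggregation, then each domain is aggregated by
sum, mean, or yes-count. Shipped specs for the seven questionnaires used
to profile the cohort live in ``data/instruments.yaml`` and are validated
against their declared ranges on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .datamodel import ValidationError

AGGREGATIONS = ("sum", "mean", "yes_count")


@dataclass(frozen=True)
class Domain:
    name: str
    items: tuple
    declared_range: tuple  # (min, max) of the domain score


@dataclass(frozen=True)
class InstrumentSpec:
    """Declarative description of one questionnaire."""

    name: str
    item_count: int
    scale_low: float
    scale_high: float
    reverse_items: frozenset
    aggregation: str
    domains: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.aggregation not in AGGREGATIONS:
            raise ValidationError(f"{self.name}: unknown aggregation {self.aggregation!r}")
        seen: set[int] = set()
        for d in self.domains:
            overlap = seen & set(d.items)
            if overlap:
                raise ValidationError(
                    f"{self.name}: domain item sets overlap on items {sorted(overlap)}"
                )
            seen |= set(d.items)
            bad = [i for i in d.items if not 1 <= i <= self.item_count]
            if bad:
                raise ValidationError(f"{self.name}/{d.name}: items {bad} out of 1..{self.item_count}")

    def validate_ranges(self) -> None:
        """Check every domain's min/max achievable score equals its declared range."""
        for d in self.domains:
            lo = min_achievable_score(self, d.name)
            hi = max_achievable_score(self, d.name)
            if (lo, hi) != tuple(d.declared_range):
                raise ValidationError(
                    f"{self.name}/{d.name}: achievable range ({lo}, {hi}) "
                    f"!= declared {tuple(d.declared_range)}"
                )

    def domain(self, name: str) -> Domain:
        for d in self.domains:
            if d.name == name:
                return d
        raise KeyError(f"{self.name} has no domain {name!r}")


def reverse_score(x, low: float, high: float):
    """Map a response through the reverse-coding reflection low+high-x."""
    return low + high - np.asarray(x, dtype=float)


def _aggregate(values: np.ndarray, how: str) -> float:
    if how == "mean":
        return float(np.mean(values)) if values.size else float("nan")
    # yes_count is a sum of 1/0 codes
    return float(np.sum(values))


def min_achievable_score(spec: InstrumentSpec, domain: str) -> float:
    """Minimum of the scoring function over admissible response patterns."""
    d = spec.domain(domain)
    if not d.items:
        return _aggregate(np.array([]), spec.aggregation)
    # every item attains the scale minimum after possible reversal
    vals = np.full(len(d.items), spec.scale_low)
    return _aggregate(vals, spec.aggregation)


def max_achievable_score(spec: InstrumentSpec, domain: str) -> float:
    """Maximum of the scoring function; reverse items peak at the scale minimum."""
    d = spec.domain(domain)
    if not d.items:
        return _aggregate(np.array([]), spec.aggregation)
    vals = np.full(len(d.items), spec.scale_high)
    return _aggregate(vals, spec.aggregation)


def score_instrument(responses: pd.DataFrame, spec: InstrumentSpec) -> pd.DataFrame:
    """Score one instrument for every subject in an item-response table.

    Parameters
    ----------
    responses : DataFrame
        Long table with columns ``subject_id, instrument, item_index,
        response``; only rows matching ``spec.name`` are used.
    spec : InstrumentSpec

    Returns
    -------
    DataFrame indexed by ``subject_id`` with one column per domain.

    Raises
    ------
    ValidationError
        If any subject misses items (the missing indices are listed) or
        answers outside the item scale bounds.
    """
    sub = responses[responses["instrument"] == spec.name]
    if sub.empty:
        raise ValidationError(f"no responses for instrument {spec.name!r}")
    out_of_range = sub[
        (sub["response"] < spec.scale_low) | (sub["response"] > spec.scale_high)
    ]
    if not out_of_range.empty:
        row = out_of_range.iloc[0]
        raise ValidationError(
            f"{spec.name}: response {row['response']} for subject "
            f"{row['subject_id']} item {row['item_index']} outside "
            f"[{spec.scale_low}, {spec.scale_high}]"
        )

    wide = sub.pivot_table(
        index="subject_id", columns="item_index", values="response", aggfunc="first"
    )
    need = set(range(1, spec.item_count + 1))
    for subject, row in wide.iterrows():
        have = set(row.dropna().index)
        missing = sorted(need - have)
        if missing:
            raise ValidationError(
                f"{spec.name}: subject {subject} missing items {missing}"
            )
    wide = wide.reindex(columns=sorted(need))

    vals = wide.to_numpy(dtype=float)
    rev = [i - 1 for i in sorted(spec.reverse_items)]
    if rev:
        vals[:, rev] = spec.scale_low + spec.scale_high - vals[:, rev]

    scores = {}
    for d in spec.domains:
        cols = [i - 1 for i in d.items]
        block = vals[:, cols]
        if spec.aggregation == "mean":
            scores[d.name] = block.mean(axis=1)
        else:
            scores[d.name] = block.sum(axis=1)
    return pd.DataFrame(scores, index=wide.index)


def _spec_from_dict(name: str, raw: dict) -> InstrumentSpec:
    domains = tuple(
        Domain(dn, tuple(dv["items"]), tuple(dv["range"]))
        for dn, dv in raw["domains"].items()
    )
    return InstrumentSpec(
        name=name,
        item_count=int(raw["item_count"]),
        scale_low=float(raw["scale"]["low"]),
        scale_high=float(raw["scale"]["high"]),
        reverse_items=frozenset(raw.get("reverse_items", [])),
        aggregation=raw["aggregation"],
        domains=domains,
    )


def load_instrument_specs(path=None, validate: bool = True) -> dict[str, InstrumentSpec]:
    """Load instrument specs from YAML (the shipped set by default)."""
    if path is None:
        text = resources.files("hedoseg.data").joinpath("instruments.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    specs = {name: _spec_from_dict(name, d) for name, d in raw.items()}
    if validate:
        for s in specs.values():
            s.validate_ranges()
    return specs


def score_all(responses: pd.DataFrame, specs=None) -> pd.DataFrame:
    """Score every instrument present in the response table; join on subject."""
    specs = specs or load_instrument_specs()
    present = [n for n in specs if n in set(responses["instrument"])]
    frames = [score_instrument(responses, specs[n]) for n in present]
    if not frames:
        raise ValidationError("no known instruments in response table")
    return pd.concat(frames, axis=1)
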