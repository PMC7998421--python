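"""Rating-scale semantics and PROP taster-status classification.

Two psychophysical scales drive the sensory data model:

* **LAM** (Labelled Affective Magnitude): 0-100 hedonic scale anchored
  "greatest imaginable dislike" (0) to "greatest imaginable like" (100),
  neutral at 50.
* **gLMS** (general Labelled Magnitude Scale): 0-100 intensity scale from
  "no sensation" (0) to "strongest imaginable sensation of any kind"
  (100), with quasi-logarithmic verbal labels.

The gLMS verbal-label positions beyond the two taster-status cutoffs are
documentation/plotting aids only; no computation depends on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Standard gLMS verbal label positions on the 0-100 scale.
GLMS_LABELS = [
    ("no sensation", 0.0),
    ("barely detectable", 1.4),
    ("weak", 6.0),
    ("moderate", 17.0),
    ("strong", 35.0),
    ("very strong", 53.0),
    ("strongest imaginable", 100.0),
]

LAM_LABELS = [
    ("greatest imaginable dislike", 0.0),
    ("neither liked nor disliked", 50.0),
    ("greatest imaginable like", 100.0),
]

#: PROP bitterness cutoffs on the gLMS: non-taster at/below "moderate",
#: super-taster at/above "very strong".
PROP_NT_CUTOFF = 17.0
PROP_ST_CUTOFF = 53.0


@dataclass(frozen=True)
class ScaleDefinition:
    """A bounded response scale with optional labelled points."""

    name: str
    low: float
    high: float
    labeled_points: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"scale {self.name}: low must be < high")
        pos = [p for _, p in self.labeled_points]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"scale {self.name}: label positions must increase")
        if pos and (pos[0] < self.low or pos[-1] > self.high):
            raise ValueError(f"scale {self.name}: labels outside range")
        if self.name == "LAM" and ("neither liked nor disliked", 50.0) not in self.labeled_points:
            raise ValueError("LAM scale requires the neutral point at 50")
        if self.name == "gLMS" and pos and pos[0] != 0.0:
            raise ValueError("gLMS low anchor must sit at 0")

    def contains(self, x: float) -> bool:
        return self.low <= x <= self.high


LAM = ScaleDefinition("LAM", 0.0, 100.0, LAM_LABELS)
GLMS = ScaleDefinition("gLMS", 0.0, 100.0, GLMS_LABELS)


@dataclass(frozen=True)
class PROPStatus:
    """PROP (6-n-propylthiouracil) taster status from two gLMS replicates.

    ``status`` is NT (non-taster) iff the replicate mean is <= 17, ST
    (super-taster) iff >= 53, MT (medium taster) otherwise. ``flagged``
    marks classifications computed from a single replicate.
    """

    subject_id: str
    replicate_ratings: tuple
    summary: float
    status: str
    flagged: bool = False


def classify_prop(r1: float, r2: float | None = None, subject_id: str = "") -> PROPStatus:
    """Classify PROP taster status from one or two gLMS bitterness ratings.

    The summary value is the arithmetic mean of the two replicates; with
    a single available replicate the classification is computed from that
    value alone and flagged.
    """
    reps = [r for r in (r1, r2) if r is not None and not np.isnan(r)]
    if not reps:
        raise ValueError("at least one PROP replicate is required")
    for r in reps:
        if not GLMS.contains(r):
            raise ValueError(f"PROP rating {r} outside gLMS range 0-100")
    summary = float(np.mean(reps))
    if summary <= PROP_NT_CUTOFF:
        status = "NT"
    elif summary >= PROP_ST_CUTOFF:
        status = "ST"
    else:
        status = "MT"
    return PROPStatus(
        subject_id=subject_id,
        replicate_ratings=tuple(reps),
        summary=summary,
        status=status,
        flagged=len(reps) < 2,
    )
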