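"""Numerical NTCP comparison of an automated plan against a reference plan.

Differences are expressed in absolute percentage points of NTCP (auto minus
reference).  A 1-point threshold filters out low-magnitude differences; a
difference of exactly +/- 1.0 counts as a change.  The four categories
partition all possible difference vectors:

    improved   min diff <= -1 and max diff <  +1
    inferior   max diff >= +1 and min diff >  -1
    trade_off  min diff <= -1 and max diff >= +1
    neutral    all |diff| < 1
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .cost_ntcp import ENDPOINTS
from .errors import OcugazeError

CATEGORIES = ("improved", "neutral", "trade_off", "inferior")

DEFAULT_THRESHOLD = 1.0  # percentage points of NTCP


@dataclass
class NTCPProfile:
    """Five toxicity probabilities in percent."""

    maculopathy: float
    optic_neuropathy: float
    nvg: float
    retinal_detachment: float
    cataract: float

    def __post_init__(self):
        for ep in ENDPOINTS:
            v = getattr(self, ep)
            if not 0.0 <= v <= 100.0:
                raise OcugazeError(f"NTCP '{ep}' = {v} outside [0, 100]%")

    @classmethod
    def from_dict(cls, d: dict) -> "NTCPProfile":
        missing = set(ENDPOINTS) - set(d)
        if missing:
            raise OcugazeError(f"NTCP profile missing endpoints: {sorted(missing)}")
        return cls(**{ep: float(d[ep]) for ep in ENDPOINTS})

    def as_dict(self) -> dict:
        return {ep: getattr(self, ep) for ep in ENDPOINTS}


@dataclass
class ComparisonResult:
    """Per-endpoint NTCP differences (auto - reference) and the plan category."""

    differences: dict
    category: str
    annotation: str = ""    # optional free-text physicist note


def classify(auto: NTCPProfile, reference: NTCPProfile,
             threshold: float = DEFAULT_THRESHOLD,
             annotation: str = "") -> ComparisonResult:
    """Four-way classification of the automated plan against the reference."""
    diffs = {ep: getattr(auto, ep) - getattr(reference, ep) for ep in ENDPOINTS}
    lo = min(diffs.values())
    hi = max(diffs.values())
    has_gain = lo <= -threshold
    has_loss = hi >= threshold
    if has_gain and has_loss:
        category = "trade_off"
    elif has_gain:
        category = "improved"
    elif has_loss:
        category = "inferior"
    else:
        category = "neutral"
    return ComparisonResult(differences=diffs, category=category, annotation=annotation)


@dataclass
class CohortSummary:
    counts: dict = field(default_factory=dict)
    percentages: dict = field(default_factory=dict)
    n: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "category": list(CATEGORIES),
            "count": [self.counts[c] for c in CATEGORIES],
            "percent": [self.percentages[c] for c in CATEGORIES],
        })


def summarize_cohort(results: list[ComparisonResult]) -> CohortSummary:
    """Category counts and percentages over a cohort of comparisons."""
    if not results:
        raise OcugazeError("cohort summary needs at least one comparison")
    counter = Counter(r.category for r in results)
    n = len(results)
    counts = {c: counter.get(c, 0) for c in CATEGORIES}
    pct = {c: 100.0 * counts[c] / n for c in CATEGORIES}
    return CohortSummary(counts=counts, percentages=pct, n=n)
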