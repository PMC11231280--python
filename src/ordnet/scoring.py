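"""Domain ratings: map item responses to healthy / fair / poor per domain.

The rating rubric is configuration, not science: the instrument's clinical
cutoffs are proprietary, so a documented synthetic default ships for
end-to-end runs and tests. Each domain aggregates its items (sum of 0-based
codes by default) and two ordered cutoffs partition the aggregate; a value
exactly at a cutoff is assigned to the *less severe* category.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import OrdinalDataset

__all__ = [
    "RatingRubric",
    "CohortSummary",
    "default_rubric",
    "rate_domains",
    "summarize",
    "round_half_up_pct",
]

RATINGS = ("healthy", "fair", "poor")


def round_half_up_pct(count: int, total: int) -> int:
    """Integer percentage with half-up rounding (0.5 always rounds up)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(np.floor(100.0 * count / total + 0.5))


@dataclass
class RatingRubric:
    """Per-domain aggregation rule and healthy/fair cutoffs.

    ``cutoffs[d] = (c1, c2)`` with c1 <= c2: aggregate <= c1 is healthy,
    <= c2 is fair, otherwise poor.
    """

    cutoffs: dict[str, tuple[float, float]] = field(default_factory=dict)
    aggregation: str = "sum"

    def __post_init__(self) -> None:
        if self.aggregation not in ("sum", "mean"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        for d, (c1, c2) in self.cutoffs.items():
            if c1 > c2:
                raise ValueError(f"domain {d!r}: cutoffs must be ordered")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"aggregation": self.aggregation, "cutoffs": self.cutoffs}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RatingRubric":
        obj = json.loads(Path(path).read_text())
        cutoffs = {d: tuple(c) for d, c in obj["cutoffs"].items()}
        return cls(cutoffs=cutoffs, aggregation=obj.get("aggregation", "sum"))


def default_rubric(data: OrdinalDataset) -> RatingRubric:
    """Synthetic default rubric: cutoffs at 40% and 70% of each domain's range.

    Stands in for the instrument's unavailable clinical thresholds; suitable
    for exercising the pipeline, not for clinical interpretation.
    """
    cutoffs = {}
    for d in data.domains:
        idx = [data.item_names.index(it) for it in data.items_in_domain(d)]
        max_agg = sum(data.n_categories[j] - 1 for j in idx)
        cutoffs[d] = (float(np.floor(0.4 * max_agg)), float(np.floor(0.7 * max_agg)))
    return RatingRubric(cutoffs=cutoffs)


def rate_domains(data: OrdinalDataset, rubric: RatingRubric) -> pd.DataFrame:
    """Rate every respondent on every domain. Deterministic.

    Returns an n x (number of domains) frame of 'healthy' / 'fair' / 'poor'.
    """
    if not data.domain_map:
        raise ValueError("dataset has no domain map")
    missing = [d for d in data.domains if d not in rubric.cutoffs]
    if missing:
        raise ValueError(f"rubric lacks cutoffs for domains: {missing}")
    out = {}
    for d in data.domains:
        idx = [data.item_names.index(it) for it in data.items_in_domain(d)]
        block = data.responses[:, idx]
        if (block < 0).any():
            raise ValueError(f"missing responses in domain {d!r}; cannot aggregate")
        agg = block.sum(axis=1).astype(float)
        if rubric.aggregation == "mean":
            agg /= len(idx)
        c1, c2 = rubric.cutoffs[d]
        # boundary goes to the less-severe category
        rating = np.where(agg <= c1, "healthy", np.where(agg <= c2, "fair", "poor"))
        out[d] = rating
    return pd.DataFrame(out)


@dataclass
class CohortSummary:
    """Counts and half-up rounded percentages of poor ratings."""

    n: int
    poor_by_domain: dict[str, int]
    poor_pct_by_domain: dict[str, int]
    n_zero_poor: int
    n_one_poor: int
    n_multi_poor: int

    @property
    def pct_zero_poor(self) -> int:
        return round_half_up_pct(self.n_zero_poor, self.n)

    @property
    def pct_one_poor(self) -> int:
        return round_half_up_pct(self.n_one_poor, self.n)

    @property
    def pct_multi_poor(self) -> int:
        return round_half_up_pct(self.n_multi_poor, self.n)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "poor_by_domain": self.poor_by_domain,
            "poor_pct_by_domain": self.poor_pct_by_domain,
            "multimorbidity": {
                "zero_poor": {"count": self.n_zero_poor, "pct": self.pct_zero_poor},
                "one_poor": {"count": self.n_one_poor, "pct": self.pct_one_poor},
                "multi_poor": {"count": self.n_multi_poor, "pct": self.pct_multi_poor},
            },
        }


def summarize(ratings: pd.DataFrame) -> CohortSummary:
    """Per-domain poor counts and the 0 / exactly 1 / >= 2 poor-domain split.

    The three multimorbidity counts partition the cohort exactly.
    """
    if ratings.empty:
        raise ValueError("ratings frame is empty")
    n = len(ratings)
    poor = (ratings == "poor")
    poor_by_domain = {d: int(poor[d].sum()) for d in ratings.columns}
    poor_pct = {d: round_half_up_pct(c, n) for d, c in poor_by_domain.items()}
    n_poor = poor.sum(axis=1)
    summary = CohortSummary(
        n=n,
        poor_by_domain=poor_by_domain,
        poor_pct_by_domain=poor_pct,
        n_zero_poor=int((n_poor == 0).sum()),
        n_one_poor=int((n_poor == 1).sum()),
        n_multi_poor=int((n_poor >= 2).sum()),
    )
    assert summary.n_zero_poor + summary.n_one_poor + summary.n_multi_poor == n
    return summary
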