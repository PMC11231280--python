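"""Ordinal response datasets: the pipeline's raw input.

An :class:`OrdinalDataset` holds an ``n x p`` matrix of integer category
codes (0-based) for *p* questionnaire items answered by *n* respondents,
together with item names and a map assigning each item to a health domain.
Datasets round-trip through plain CSV (one header row of item names,
integer cells) plus a JSON sidecar carrying the domain map and, for
simulated cohorts, the generating thresholds and true network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["OrdinalDataset", "read_responses", "write_responses", "DEFAULT_DOMAIN_SIZES"]

# Item counts per domain of the seven-domain mental-fitness questionnaire:
# social connection (3), daily activities (3), psychological distress / K6 (6),
# sleep & circadian rhythms (4), physical activity (4), substance use (4),
# nutrition (2) -- 26 items in total.
DEFAULT_DOMAIN_SIZES: dict[str, int] = {
    "social_connection": 3,
    "daily_activities": 3,
    "psychological_distress": 6,
    "sleep_circadian": 4,
    "physical_activity": 4,
    "substance_use": 4,
    "nutrition": 2,
}


@dataclass
class OrdinalDataset:
    """Rectangular table of per-respondent ordinal item responses.

    Parameters
    ----------
    responses : ndarray of shape (n, p)
        Integer category codes, 0-based. Missing values are encoded as -1.
    item_names : list of str
        Column labels, length p.
    domain_map : dict, optional
        Item name -> domain label. May be empty for undomained data.
    n_categories : list of int, optional
        Number of categories per item; inferred as ``max+1`` when omitted.
    """

    responses: np.ndarray
    item_names: list[str]
    domain_map: dict[str, str] = field(default_factory=dict)
    n_categories: list[int] | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a 2-D array")
        if not np.issubdtype(self.responses.dtype, np.integer):
            raise ValueError("responses must be integer category codes")
        if len(self.item_names) != self.responses.shape[1]:
            raise ValueError("item_names length must match number of columns")
        if self.n_categories is None:
            self.n_categories = [
                int(self.responses[:, j][self.responses[:, j] >= 0].max()) + 1
                if (self.responses[:, j] >= 0).any()
                else 0
                for j in range(self.p)
            ]
        for j, k in enumerate(self.n_categories):
            col = self.responses[:, j]
            obs = col[col >= 0]
            if obs.size and obs.max() >= k:
                raise ValueError(
                    f"item {self.item_names[j]!r} has code {obs.max()} outside its "
                    f"{k}-category range"
                )
        if self.domain_map:
            unknown = set(self.domain_map) - set(self.item_names)
            if unknown:
                raise ValueError(f"domain_map references unknown items: {sorted(unknown)}")

    @property
    def n(self) -> int:
        return self.responses.shape[0]

    @property
    def p(self) -> int:
        return self.responses.shape[1]

    @property
    def n_missing(self) -> int:
        return int((self.responses < 0).sum())

    @property
    def domains(self) -> list[str]:
        """Domain labels in order of first appearance among the items."""
        seen: list[str] = []
        for name in self.item_names:
            d = self.domain_map.get(name)
            if d is not None and d not in seen:
                seen.append(d)
        return seen

    def items_in_domain(self, domain: str) -> list[str]:
        return [it for it in self.item_names if self.domain_map.get(it) == domain]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.responses, columns=self.item_names)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        domain_map: dict[str, str] | None = None,
        n_categories: list[int] | None = None,
    ) -> "OrdinalDataset":
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            filled = df.fillna(-1)
            arr = filled.to_numpy()
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("non-integer responses in dataframe")
            arr = arr.astype(np.int64)
        return cls(arr, list(df.columns), domain_map or {}, n_categories)

    def aggregate_domains(self) -> "OrdinalDataset":
        """Sum item codes within each domain, yielding one ordinal score per domain.

        The aggregate for a domain with items of ``k_1..k_m`` categories lives on
        ``0 .. sum(k_i - 1)`` and is treated as an ordinal variable in its own
        right; this is how the 7-node domain-level network is built from the
        26-item table.
        """
        if not self.domain_map:
            raise ValueError("dataset has no domain_map; cannot aggregate")
        if self.n_missing:
            raise ValueError("cannot aggregate domains with missing responses")
        cols = []
        cats = []
        doms = self.domains
        for d in doms:
            idx = [self.item_names.index(it) for it in self.items_in_domain(d)]
            cols.append(self.responses[:, idx].sum(axis=1))
            cats.append(sum(self.n_categories[j] - 1 for j in idx) + 1)
        agg = np.column_stack(cols).astype(np.int64)
        return OrdinalDataset(agg, doms, {d: d for d in doms}, cats)


def write_responses(data: OrdinalDataset, path: str | Path, sidecar: dict | None = None) -> None:
    """Write a dataset to CSV with a JSON sidecar at ``<path>.meta.json``."""
    path = Path(path)
    data.to_dataframe().to_csv(path, index=False)
    meta = {"domain_map": data.domain_map, "n_categories": data.n_categories}
    if sidecar:
        meta.update(sidecar)
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_responses(path: str | Path, domain_map: dict[str, str] | None = None) -> OrdinalDataset:
    """Read an ordinal response CSV (header row; integer or blank cells).

    Blank cells become missing codes (-1) and are counted. A sidecar file
    ``<path>.meta.json``, if present, supplies the domain map and category
    counts; an explicit ``domain_map`` argument overrides it.
    """
    path = Path(path)
    df = pd.read_csv(path)
    arr = np.full(df.shape, -1, dtype=np.int64)
    for j, col in enumerate(df.columns):
        vals = df[col]
        for i, v in enumerate(vals):
            if pd.isna(v):
                continue
            fv = float(v)
            if fv != int(fv):
                raise ValueError(
                    f"non-integer cell at row {i + 2}, column {col!r}: {v!r}"
                )
            arr[i, j] = int(fv)
    meta_path = Path(str(path) + ".meta.json")
    n_categories = None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if domain_map is None:
            domain_map = meta.get("domain_map") or None
        n_categories = meta.get("n_categories")
    return OrdinalDataset(arr, list(df.columns), domain_map or {}, n_categories)
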