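"""Bootstrap accuracy and stability for estimated networks.

Two resampling procedures: a nonparametric row bootstrap giving percentile
intervals for every edge weight, and a case-dropping subset bootstrap
summarizing how far the sample can be thinned before centrality orderings
degrade (the CS-coefficient). Both re-run the *entire* estimator —
polychoric matrix, lambda path, EBIC selection — on every replicate, so
model-selection uncertainty is propagated honestly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import centrality as _centrality
from .datasets import OrdinalDataset
from .glasso import select_network
from .polychoric import polychoric_matrix

__all__ = ["EdgeBootstrapResult", "StabilityResult", "edge_accuracy_bootstrap", "case_dropping_bootstrap"]

CS_CORRELATION = 0.7  # subset-to-full correlation threshold
CS_PROBABILITY = 0.95  # fraction of replicates that must clear it


@dataclass
class EdgeBootstrapResult:
    """Percentile intervals for every possible edge."""

    B: int
    seed: int
    edges: pd.DataFrame  # node_i, node_j, estimate, boot_mean, ci_lower, ci_upper
    samples: np.ndarray  # (B, n_pairs) replicate weights, pair order as in edges
    n_redraws: int = 0


@dataclass
class StabilityResult:
    """Case-dropping subset bootstrap summary for one centrality index."""

    index: str
    drop_fractions: np.ndarray
    correlations: dict[float, np.ndarray]  # fraction -> per-replicate correlations (NaN = degenerate)
    cs_coefficient: float
    skipped_fractions: list[float] = field(default_factory=list)

    def mean_correlations(self) -> pd.DataFrame:
        rows = [
            (f, float(np.nanmean(self.correlations[f])), int(np.isnan(self.correlations[f]).sum()))
            for f in self.drop_fractions
        ]
        return pd.DataFrame(rows, columns=["drop_fraction", "mean_correlation", "n_degenerate"])


def _subset(data: OrdinalDataset, rows: np.ndarray) -> OrdinalDataset:
    return OrdinalDataset(
        data.responses[rows], list(data.item_names), dict(data.domain_map), list(data.n_categories)
    )


def _degenerate(data: OrdinalDataset) -> bool:
    for j in range(data.p):
        col = data.responses[:, j]
        if np.unique(col[col >= 0]).size < 2:
            return True
    return False


def _fit_weights(data: OrdinalDataset, **est_kwargs) -> np.ndarray:
    S = polychoric_matrix(data)
    return select_network(S, n=data.n, **est_kwargs).W


def edge_accuracy_bootstrap(
    data: OrdinalDataset,
    B: int = 1000,
    seed: int = 0,
    gamma: float = 0.5,
    **est_kwargs,
) -> EdgeBootstrapResult:
    """Nonparametric bootstrap of edge weights with 95% percentile intervals.

    Each of the B replicates resamples rows with replacement and re-runs
    polychoric estimation and EBIC-glasso selection. Replicates in which an
    item collapses to a single observed category are redrawn (counted); if
    redraws exceed 10% of B the sample is judged too small and an error is
    raised. Deterministic under a fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if _degenerate(data):
        raise ValueError("an item has fewer than 2 observed categories in the full data")
    W_hat = _fit_weights(data, gamma=gamma, **est_kwargs)
    p = data.p
    iu = np.triu_indices(p, k=1)
    samples = np.empty((B, len(iu[0])))
    n = data.n
    max_redraws = max(1, int(0.1 * B))
    redraws = 0
    for b in range(B):
        attempt = 0
        while True:
            rng = np.random.default_rng([seed, b, attempt])
            rows = rng.integers(0, n, size=n)
            boot = _subset(data, rows)
            if not _degenerate(boot):
                break
            redraws += 1
            attempt += 1
            if redraws > max_redraws:
                raise RuntimeError(
                    "more than 10% of bootstrap resamples were degenerate; "
                    "the sample is too small for stable resampling"
                )
        samples[b] = _fit_weights(boot, gamma=gamma, **est_kwargs)[iu]
    lo = np.percentile(samples, 2.5, axis=0)
    hi = np.percentile(samples, 97.5, axis=0)
    names = data.item_names
    edges = pd.DataFrame(
        {
            "node_i": [names[i] for i in iu[0]],
            "node_j": [names[j] for j in iu[1]],
            "estimate": W_hat[iu],
            "boot_mean": samples.mean(axis=0),
            "ci_lower": lo,
            "ci_upper": hi,
        }
    )
    return EdgeBootstrapResult(B=B, seed=seed, edges=edges, samples=samples, n_redraws=redraws)


def case_dropping_bootstrap(
    data: OrdinalDataset,
    drop_fractions: np.ndarray | list[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7),
    B: int = 500,
    seed: int = 0,
    index: str = "strength",
    gamma: float = 0.5,
    min_rows: int = 50,
    **est_kwargs,
) -> StabilityResult:
    """Case-dropping subset bootstrap and CS-coefficient for one index.

    For each drop fraction f, B subsets of ``round((1-f) n)`` rows are drawn
    without replacement, the network re-estimated, and the subset centrality
    correlated (Pearson) with the full-sample centrality. The
    CS-coefficient is the largest f in the grid at which at least 95% of
    replicates correlate >= 0.7; 0 when no fraction qualifies. Replicates
    with zero centrality variance are flagged NaN and excluded from the
    tally. Fractions leaving fewer than ``min_rows`` rows are skipped with a
    warning.
    """
    if index not in ("strength", "expected_influence"):
        raise ValueError(f"unknown centrality index {index!r}")
    stat = getattr(_centrality, index)
    W_full = _fit_weights(data, gamma=gamma, **est_kwargs)
    c_full = stat(W_full)
    n = data.n
    fractions = np.asarray(sorted(drop_fractions), dtype=float)
    correlations: dict[float, np.ndarray] = {}
    skipped: list[float] = []
    for fi, f in enumerate(fractions):
        size = int(round((1.0 - f) * n))
        if size < min_rows:
            warnings.warn(
                f"drop fraction {f:g} leaves {size} < {min_rows} rows; skipped",
                stacklevel=2,
            )
            skipped.append(float(f))
            continue
        corrs = np.empty(B)
        for b in range(B):
            rng = np.random.default_rng([seed, fi, b])
            rows = rng.choice(n, size=size, replace=False)
            boot = _subset(data, rows)
            if _degenerate(boot):
                corrs[b] = np.nan
                continue
            c_sub = stat(_fit_weights(boot, gamma=gamma, **est_kwargs))
            if np.array_equal(c_sub, c_full):
                corrs[b] = 1.0  # identical sample (e.g. drop fraction 0)
                continue
            if np.std(c_sub) == 0 or np.std(c_full) == 0:
                corrs[b] = np.nan
                continue
            corrs[b] = np.corrcoef(c_full, c_sub)[0, 1]
        correlations[float(f)] = corrs
    cs = 0.0
    for f in fractions:
        f = float(f)
        if f not in correlations:
            continue
        corrs = correlations[f]
        valid = corrs[~np.isnan(corrs)]
        if valid.size and np.mean(valid >= CS_CORRELATION) >= CS_PROBABILITY:
            cs = max(cs, f)
    return StabilityResult(
        index=index,
        drop_fractions=np.array([f for f in fractions if float(f) in correlations]),
        correlations=correlations,
        cs_coefficient=cs,
        skipped_fractions=skipped,
    )
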