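"""Node centrality on partial-correlation networks.

Two indices: *strength*, the sum of absolute incident edge weights, and
*expected influence*, the signed sum. Strength always dominates the
absolute expected influence (triangle inequality), and the two coincide
when every edge is positive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["strength", "expected_influence", "centrality_table", "rank_nodes"]


def _check_weights(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("W must be symmetric")
    if not np.allclose(np.diag(W), 0.0, atol=1e-12):
        raise ValueError("W must have zero diagonal")
    return W


def strength(W: np.ndarray) -> np.ndarray:
    """Per-node sum of absolute edge weights."""
    W = _check_weights(W)
    return np.abs(W).sum(axis=1)


def expected_influence(W: np.ndarray) -> np.ndarray:
    """Per-node signed sum of edge weights (one-step)."""
    W = _check_weights(W)
    return W.sum(axis=1)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def centrality_table(W: np.ndarray, node_names: list[str] | None = None) -> pd.DataFrame:
    """Strength and expected influence per node, raw and z-standardized.

    Indices are computed on the raw weights; z-scores (within-network
    standardization) are provided for plotting and cross-network display.
    """
    W = _check_weights(W)
    p = W.shape[0]
    names = node_names or [f"node_{i + 1}" for i in range(p)]
    s = strength(W)
    ei = expected_influence(W)
    return pd.DataFrame(
        {
            "node": names,
            "strength": s,
            "expected_influence": ei,
            "z_strength": _zscore(s),
            "z_ei": _zscore(ei),
        }
    )


def rank_nodes(table: pd.DataFrame, by: str = "strength") -> list[str]:
    """Node names in descending order of a centrality index.

    Ties break lexicographically by node name.
    """
    if by not in table.columns or by == "node":
        raise ValueError(f"unknown centrality index {by!r}")
    ordered = table.sort_values([by, "node"], ascending=[False, True], kind="mergesort")
    return list(ordered["node"])
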