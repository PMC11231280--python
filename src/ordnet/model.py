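"""Model / Results interface over the ordinal network pipeline.

:class:`OrdinalNetwork` is constructed from an ordinal dataset (or a
DataFrame) at either the item level (one node per questionnaire item) or
the domain level (items summed within domains, one node per domain);
``fit()`` estimates the polychoric correlation matrix, runs the graphical
lasso over a lambda path, selects the penalty by EBIC, and returns an
:class:`OrdinalNetworkResults` carrying the partial-correlation weight
matrix, the selection trace, centrality indices, bootstrap procedures, and
a text summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bootstrap as _boot
from .centrality import centrality_table, rank_nodes
from .datasets import OrdinalDataset
from .glasso import NetworkModel, select_network
from .netio import export_network, layout, plot_network
from .polychoric import CorrelationMatrix, polychoric_matrix

__all__ = ["OrdinalNetwork", "OrdinalNetworkResults"]


class OrdinalNetwork:
    """Partial-correlation network model for ordinal questionnaire data.

    Parameters
    ----------
    data : OrdinalDataset
        Respondent-by-item integer responses.
    level : {"item", "domain"}
        Node granularity. ``"domain"`` sums item codes within each domain
        of ``data.domain_map`` and treats the aggregates as ordinal.

    Examples
    --------
    >>> from ordnet import simulate, OrdinalNetwork
    >>> data, truth = simulate.recovery_cohort(seed=1)
    >>> res = OrdinalNetwork(data).fit()
    >>> res.edge_count <= res.network.possible_edges
    True
    """

    def __init__(self, data: OrdinalDataset, level: str = "item"):
        if level not in ("item", "domain"):
            raise ValueError("level must be 'item' or 'domain'")
        self.raw_data = data
        self.level = level
        self.data = data.aggregate_domains() if level == "domain" else data

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, domain_map: dict[str, str] | None = None,
                       level: str = "item") -> "OrdinalNetwork":
        return cls(OrdinalDataset.from_dataframe(df, domain_map), level=level)

    def fit(self, gamma: float = 0.5, n_lambda: int = 100,
            lambda_min_ratio: float = 0.01, tol: float = 1e-6,
            max_iter: int = 500) -> "OrdinalNetworkResults":
        """Estimate the EBIC-selected graphical-lasso network."""
        S = polychoric_matrix(self.data)
        net = select_network(S, n=self.data.n, gamma=gamma, n_lambda=n_lambda,
                             lambda_min_ratio=lambda_min_ratio, tol=tol,
                             max_iter=max_iter)
        return OrdinalNetworkResults(self, S, net,
                                     dict(gamma=gamma, n_lambda=n_lambda,
                                          lambda_min_ratio=lambda_min_ratio,
                                          tol=tol, max_iter=max_iter))


@dataclass
class OrdinalNetworkResults:
    """Fitted network with centrality, bootstrap, layout and export."""

    model: OrdinalNetwork
    corr: CorrelationMatrix
    network: NetworkModel
    fit_options: dict

    @property
    def weights(self) -> pd.DataFrame:
        names = self.network.node_names
        return pd.DataFrame(self.network.W, index=names, columns=names)

    @property
    def edge_count(self) -> int:
        return self.network.edge_count

    def edges(self) -> pd.DataFrame:
        return self.network.edges()

    def centrality(self) -> pd.DataFrame:
        return centrality_table(self.network.W, self.network.node_names)

    def rank_nodes(self, by: str = "strength") -> list[str]:
        return rank_nodes(self.centrality(), by=by)

    def bootstrap_edges(self, B: int = 1000, seed: int = 0, **est_kwargs) -> _boot.EdgeBootstrapResult:
        opts = self._est_options() | est_kwargs
        return _boot.edge_accuracy_bootstrap(self.model.data, B=B, seed=seed, **opts)

    def bootstrap_stability(self, drop_fractions=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7),
                            B: int = 500, seed: int = 0,
                            index: str = "strength", **est_kwargs) -> _boot.StabilityResult:
        opts = self._est_options() | est_kwargs
        return _boot.case_dropping_bootstrap(self.model.data, drop_fractions=drop_fractions,
                                             B=B, seed=seed, index=index, **opts)

    def layout(self, iterations: int = 500, seed: int = 0) -> dict[str, tuple[float, float]]:
        return layout(self.network.W, iterations=iterations, seed=seed,
                      node_names=self.network.node_names)

    def export(self, path, fmt: str = "graphml") -> None:
        export_network(self.network, path, fmt=fmt,
                       domain_map=self.model.raw_data.domain_map or None)

    def plot(self, path, seed: int = 0) -> None:
        plot_network(self.network, path, seed=seed,
                     domain_map=self.model.raw_data.domain_map or None)

    def _est_options(self) -> dict:
        o = self.fit_options
        return dict(gamma=o["gamma"], n_lambda=o["n_lambda"],
                    lambda_min_ratio=o["lambda_min_ratio"], tol=o["tol"],
                    max_iter=o["max_iter"])

    def summary(self) -> str:
        """Plain-text summary in the style of a regression results table."""
        net = self.network
        lines = []
        title = f"Ordinal Partial-Correlation Network ({self.model.level}-level)"
        lines.append(title)
        lines.append("=" * 64)
        lines.append(f"{'Nodes:':<28}{net.p:>8}    {'Respondents:':<16}{net.n:>8}")
        lines.append(f"{'Edges (nonzero):':<28}{net.edge_count:>8}    "
                     f"{'Possible edges:':<16}{net.possible_edges:>8}")
        lines.append(f"{'Lambda (EBIC-selected):':<28}{net.lambda_selected:>8.4f}    "
                     f"{'EBIC gamma:':<16}{net.gamma:>8.2f}")
        lines.append(f"{'Min EBIC:':<28}{np.min(net.ebic_trace):>8.1f}    "
                     f"{'PSD repaired:':<16}{str(self.corr.psd_repaired):>8}")
        lines.append("-" * 64)
        lines.append(f"{'node':<26}{'strength':>12}{'exp. influence':>16}")
        cent = self.centrality()
        for _, row in cent.iterrows():
            lines.append(f"{row['node']:<26}{row['strength']:>12.3f}"
                         f"{row['expected_influence']:>16.3f}")
        lines.append("=" * 64)
        return "\n".join(lines)
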