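"""Synthetic ordinal cohorts with known partial-correlation structure.

Ground truth is a sparse precision matrix K whose off-diagonal pattern
encodes a partial-correlation network; respondents are i.i.d. draws of a
latent multivariate normal with covariance equal to the *standardized*
inverse of K, discretized item-by-item through fixed thresholds. Because
the latent variable is exactly Gaussian, generated data satisfy the
polychoric model by construction, so the polychoric -> glasso pipeline can
be tested against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datasets import DEFAULT_DOMAIN_SIZES, OrdinalDataset

__all__ = [
    "PrecisionSpec",
    "TrueNetwork",
    "ThresholdSpec",
    "make_sparse_precision",
    "make_block_precision",
    "balanced_thresholds",
    "sample_ordinal",
    "simulate_cohort",
    "recovery_cohort",
]


@dataclass
class PrecisionSpec:
    """Recipe for a random sparse precision matrix.

    density is the fraction of the p(p-1)/2 off-diagonal pairs carrying an
    edge; weight_range bounds the absolute pre-standardization edge weights;
    neg_fraction is the fraction of edges given a negative partial
    correlation.
    """

    p: int
    density: float
    weight_range: tuple[float, float] = (0.15, 0.35)
    neg_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0, 1]")
        lo, hi = self.weight_range
        if not 0.0 <= lo < hi < 1.0:
            raise ValueError("weight_range must satisfy 0 <= lo < hi < 1")
        if not 0.0 <= self.neg_fraction <= 1.0:
            raise ValueError("neg_fraction must lie in [0, 1]")


@dataclass
class TrueNetwork:
    """A ground-truth Gaussian graphical model."""

    K: np.ndarray
    W_true: np.ndarray
    edge_set: list[tuple[int, int]] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.K.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.edge_set)

    def latent_correlation(self) -> np.ndarray:
        """Standardized inverse of K: the latent correlation matrix."""
        cov = np.linalg.inv(self.K)
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)


@dataclass
class ThresholdSpec:
    """Per-item latent-scale cutpoints.

    Item j with ``len(cutpoints[j]) + 1`` categories maps a latent z to the
    category counting how many cutpoints lie below z.
    """

    cutpoints: list[np.ndarray]

    def __post_init__(self) -> None:
        self.cutpoints = [np.asarray(c, dtype=float) for c in self.cutpoints]
        for j, c in enumerate(self.cutpoints):
            if not np.all(np.isfinite(c)):
                raise ValueError(f"item {j}: cutpoints must be finite")
            if c.size > 1 and not np.all(np.diff(c) > 0):
                raise ValueError(f"item {j}: cutpoints must be strictly increasing")

    @property
    def p(self) -> int:
        return len(self.cutpoints)

    @property
    def categories_per_item(self) -> list[int]:
        return [len(c) + 1 for c in self.cutpoints]


def _assemble_truth(K: np.ndarray) -> TrueNetwork:
    d = np.sqrt(np.diag(K))
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    p = K.shape[0]
    edges = [(i, j) for i in range(p) for j in range(i + 1, p) if K[i, j] != 0.0]
    return TrueNetwork(K=K, W_true=W, edge_set=edges)


def _fill_precision(p: int, edges: list[tuple[int, int]], weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    K = np.zeros((p, p))
    for (i, j), w in zip(edges, weights):
        # K_ij = -w so that the partial correlation -K_ij/sqrt(KiiKjj) carries
        # the sign of w
        K[i, j] = K[j, i] = -w
    # positive definiteness by strict diagonal dominance
    jitter = rng.uniform(0.01, 0.1)
    np.fill_diagonal(K, 1.0 + np.abs(K).sum(axis=1) + jitter)
    return K


def _signed_weights(m: int, weight_range: tuple[float, float], neg_fraction: float, rng: np.random.Generator) -> np.ndarray:
    lo, hi = weight_range
    w = rng.uniform(lo, hi, size=m)
    n_neg = int(round(neg_fraction * m))
    if n_neg:
        neg_idx = rng.choice(m, size=n_neg, replace=False)
        w[neg_idx] *= -1.0
    return w


def make_sparse_precision(spec: PrecisionSpec) -> TrueNetwork:
    """Draw a random sparse symmetric positive-definite precision matrix.

    Edges are chosen uniformly among the p(p-1)/2 pairs; the realized edge
    count is ``round(density * p(p-1)/2)``. The diagonal is set to
    ``1 + row sum of |off-diagonal| + jitter`` which guarantees positive
    definiteness deterministically (no rejection sampling).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    p = spec.p
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    m = int(round(spec.density * len(pairs)))
    chosen = [pairs[k] for k in rng.choice(len(pairs), size=m, replace=False)] if m else []
    weights = _signed_weights(m, spec.weight_range, spec.neg_fraction, rng)
    K = _fill_precision(p, chosen, weights, rng)
    return _assemble_truth(K)


def make_block_precision(
    sizes: list[int],
    within_density: float = 0.6,
    between_density: float = 0.08,
    weight_range: tuple[float, float] = (0.15, 0.35),
    neg_fraction: float = 1 / 15,
    seed: int = 0,
) -> TrueNetwork:
    """Block-structured truth: items cluster into domains.

    Pairs within the same block carry an edge with probability
    ``within_density``, pairs across blocks with probability
    ``between_density`` — emulating a questionnaire whose items cohere
    within domains but still connect across them.
    """
    rng = np.random.default_rng(seed)
    p = sum(sizes)
    block_of = np.repeat(np.arange(len(sizes)), sizes)
    edges = []
    for i in range(p):
        for j in range(i + 1, p):
            prob = within_density if block_of[i] == block_of[j] else between_density
            if rng.random() < prob:
                edges.append((i, j))
    weights = _signed_weights(len(edges), weight_range, neg_fraction, rng)
    K = _fill_precision(p, edges, weights, rng)
    return _assemble_truth(K)


def balanced_thresholds(p: int, categories: int | list[int] = 5) -> ThresholdSpec:
    """Equal-probability cutpoints: category k gets mass 1/K under N(0,1)."""
    if isinstance(categories, int):
        categories = [categories] * p
    cuts = [stats.norm.ppf(np.arange(1, k) / k) for k in categories]
    return ThresholdSpec(cuts)


def sample_ordinal(
    truth: TrueNetwork,
    thresholds: ThresholdSpec,
    n: int,
    seed: int = 0,
    item_names: list[str] | None = None,
    domain_map: dict[str, str] | None = None,
) -> OrdinalDataset:
    """Draw n i.i.d. respondents from the latent Gaussian copula model.

    Latent rows are N(0, Sigma) with Sigma the standardized inverse of the
    true precision matrix; item j's response is the count of its cutpoints
    below the latent value. Deterministic under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if thresholds.p != truth.p:
        raise ValueError("thresholds must cover all items")
    sigma = truth.latent_correlation()
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(sigma)
    z = rng.standard_normal((n, truth.p)) @ L.T
    resp = np.empty((n, truth.p), dtype=np.int64)
    for j, cuts in enumerate(thresholds.cutpoints):
        resp[:, j] = np.searchsorted(cuts, z[:, j])
    names = item_names or [f"item_{j + 1}" for j in range(truth.p)]
    return OrdinalDataset(
        resp, names, domain_map or {}, thresholds.categories_per_item
    )


def _default_item_names() -> tuple[list[str], dict[str, str]]:
    names, dmap = [], {}
    for dom, size in DEFAULT_DOMAIN_SIZES.items():
        for k in range(size):
            name = f"{dom}_{k + 1}"
            names.append(name)
            dmap[name] = dom
    return names, dmap


def simulate_cohort(
    n: int = 4901,
    seed: int = 0,
    categories: int | list[int] = 5,
    within_density: float = 0.6,
    between_density: float = 0.08,
    weight_range: tuple[float, float] = (0.15, 0.35),
    neg_fraction: float = 1 / 15,
) -> tuple[OrdinalDataset, TrueNetwork]:
    """Default 26-item cohort: 7 domains with 3/3/6/4/4/4/2 items.

    Defaults mirror the study cohort size (n = 4901) and its two network
    scales: within-domain connectivity is denser than between-domain, and
    roughly one edge in fifteen is negative. Five response categories per
    item by default.
    """
    names, dmap = _default_item_names()
    truth = make_block_precision(
        list(DEFAULT_DOMAIN_SIZES.values()),
        within_density=within_density,
        between_density=between_density,
        weight_range=weight_range,
        neg_fraction=neg_fraction,
        seed=seed,
    )
    thr = balanced_thresholds(truth.p, categories)
    data = sample_ordinal(truth, thr, n, seed=seed + 1, item_names=names, domain_map=dmap)
    return data, truth


def recovery_cohort(
    n: int = 4000,
    p: int = 7,
    density: float = 0.5,
    weight_range: tuple[float, float] = (0.15, 0.35),
    neg_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[OrdinalDataset, TrueNetwork]:
    """Seven-node recovery fixture with alternating 5/4-category items.

    Used throughout the test battery: moderate density, partial-correlation
    weights strong enough that sign recovery and edge-count recovery are
    well-posed at n = 4000.
    """
    spec = PrecisionSpec(p=p, density=density, weight_range=weight_range,
                         neg_fraction=neg_fraction, seed=seed)
    truth = make_sparse_precision(spec)
    cats = [5 if j % 2 == 0 else 4 for j in range(p)]
    thr = balanced_thresholds(p, cats)
    data = sample_ordinal(truth, thr, n, seed=seed + 1)
    return data, truth
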