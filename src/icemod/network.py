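"""Co-expression network construction.

All pairwise Pearson correlations of a standardized expression matrix are
computed, candidate thresholds are proposed (Bonferroni-significant
correlation, top 1%, top 0.1% of the signed correlation distribution), and
the network is built by connecting gene pairs whose correlation reaches the
chosen threshold.  Topology diagnostics (mean clustering coefficient, degree
histogram) support the sanity checks expected of biological networks.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import networkx as nx
from scipy import stats

from .preprocess import ExpressionMatrix

__all__ = [
    "CorrelationTable",
    "ThresholdCandidates",
    "pairwise_correlation",
    "threshold_candidates",
    "build_network",
    "top_fraction_threshold",
    "clustering_coefficient",
    "degree_distribution",
    "write_edge_list",
    "read_edge_list",
    "network_summary",
]


@dataclass
class CorrelationTable:
    """All n(n-1)/2 pairwise Pearson correlations in condensed (i<j) order."""

    gene_ids: list[str]
    r: np.ndarray  # condensed upper triangle, row-major
    n_samples: int

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_pairs(self) -> int:
        return len(self.r)

    def iter_pairs(self) -> Iterator[tuple[str, str, float]]:
        idx = 0
        n = self.n_genes
        for i in range(n):
            gi = self.gene_ids[i]
            for j in range(i + 1, n):
                yield gi, self.gene_ids[j], float(self.r[idx])
                idx += 1


def pairwise_correlation(expr: ExpressionMatrix, block_size: int = 1024) -> CorrelationTable:
    """Exact Pearson correlation for every unordered gene pair.

    Rows are centered and scaled to unit norm, then correlations are taken
    block-wise as inner products so memory stays bounded for large gene
    counts; the result is identical to a dense corrcoef up to float error.
    """
    if not expr.standardized:
        raise ValueError("pairwise_correlation expects a standardized matrix")
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples for meaningful correlations")
    x = expr.values - expr.values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    if (norms == 0).any():
        bad = [g for g, nz in zip(expr.gene_ids, norms == 0) if nz]
        raise ValueError(f"zero-variance rows present (remove upstream): {bad[:5]}")
    x /= norms[:, None]

    n = expr.n_genes
    r = np.empty(n * (n - 1) // 2, dtype=float)
    pos = 0
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        block = x[start:stop] @ x.T  # (stop-start) x n
        for local, i in enumerate(range(start, stop)):
            row = block[local, i + 1 :]
            r[pos : pos + row.size] = row
            pos += row.size
    np.clip(r, -1.0, 1.0, out=r)
    return CorrelationTable(list(expr.gene_ids), r, expr.n_samples)


@dataclass
class ThresholdCandidates:
    """Candidate correlation thresholds for network construction.

    ``bonferroni_p01_r`` is the smallest r whose two-sided correlation-test
    p-value times the number of pairs is at most 0.01 (None when undefined);
    ``top1pct_r`` / ``top01pct_r`` cut the signed correlation distribution at
    its top 1% / 0.1%.
    """

    bonferroni_p01_r: float | None
    top1pct_r: float
    top01pct_r: float


def top_fraction_threshold(r: np.ndarray, fraction: float) -> float:
    """The k-th largest correlation with k = floor(fraction * n_pairs), at least 1."""
    k = max(1, int(np.floor(fraction * r.size)))
    return float(np.partition(r, r.size - k)[r.size - k])


def threshold_candidates(corr: CorrelationTable) -> ThresholdCandidates:
    if corr.n_pairs == 0:
        raise ValueError("empty correlation table")
    m = corr.n_samples
    bonf: float | None = None
    if m > 2:
        # invert the t-test of r with m-2 df: r = t / sqrt(m - 2 + t^2)
        p_per_pair = 0.01 / corr.n_pairs
        tcrit = stats.t.isf(p_per_pair / 2.0, df=m - 2)
        bonf = float(tcrit / np.sqrt(m - 2 + tcrit**2))
    return ThresholdCandidates(
        bonferroni_p01_r=bonf,
        top1pct_r=top_fraction_threshold(corr.r, 0.01),
        top01pct_r=top_fraction_threshold(corr.r, 0.001),
    )


def build_network(
    corr: CorrelationTable, threshold: float, absolute: bool = False
) -> nx.Graph:
    """Connect gene pairs with r >= threshold (|r| >= threshold when absolute).

    Positive-correlation thresholding is the default: strongly negative
    correlations do not track functional similarity, so only positive
    co-expression defines edges.  Genes left without any edge are excluded
    from the network.  The threshold is recorded as a graph attribute.
    """
    if not -1.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (-1, 1]")
    values = np.abs(corr.r) if absolute else corr.r
    net = nx.Graph(threshold=float(threshold), absolute=bool(absolute))
    hits = np.flatnonzero(values >= threshold)
    if hits.size == 0:
        warnings.warn("threshold exceeds every correlation; returning empty network",
                      stacklevel=2)
        return net
    n = corr.n_genes
    # map condensed index back to (i, j)
    row_starts = np.cumsum([0] + [n - 1 - i for i in range(n)])
    for idx in hits:
        i = int(np.searchsorted(row_starts, idx, side="right") - 1)
        j = int(idx - row_starts[i] + i + 1)
        net.add_edge(corr.gene_ids[i], corr.gene_ids[j])
    return net


def clustering_coefficient(net: nx.Graph) -> float:
    """Mean local clustering coefficient; nodes of degree < 2 contribute 0."""
    if net.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    return float(nx.average_clustering(net))


def degree_distribution(net: nx.Graph) -> dict[int, int]:
    """Histogram degree -> node count."""
    if net.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    return dict(Counter(d for _, d in net.degree()))


def write_edge_list(net: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{u}\t{v}\n")


def read_edge_list(path) -> nx.Graph:
    net = nx.Graph()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed edge at line {ln}: {line!r}")
            net.add_edge(parts[0], parts[1])
    return net


def network_summary(net: nx.Graph) -> dict:
    """JSON-serializable sidecar: threshold, counts, clustering coefficient."""
    summary = {
        "threshold": net.graph.get("threshold"),
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
    }
    if net.number_of_nodes() > 0:
        summary["clustering_coefficient"] = clustering_coefficient(net)
    return summary
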