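"""Hypergeometric over-representation of modules against gene-set collections.

For a module of n genes and a gene set covering K of the N reference genes
(all genes on the platform), the significance of an overlap of k genes is
the upper hypergeometric tail P(X >= k).  Collections come in as GMT files
(GO categories, transcription-factor binding-motif target sets, positional
cytoband sets); motif sets are merged per transcription factor before
testing.  P-values are Bonferroni-adjusted over the sets tested for a
module, with B-adjp < 0.05 the conventional significance call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "merge_motif_sets",
    "hypergeom_tail",
    "expected_overlap",
    "enrich_module",
]


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    """Named gene sets with a source tag (GO | TFBS | positional | custom)."""

    sets: dict[str, GeneSet]
    source: str = "custom"

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]


def read_gmt(path, source: str = "custom") -> GeneSetCollection:
    """Read a GMT file: set_id<TAB>description<TAB>gene... per line.

    Duplicate genes within a set are collapsed; a line without at least one
    gene is malformed and reported with its line number.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3 or not cols[0]:
                raise ValueError(f"malformed GMT line {ln}: need id, description, >=1 gene")
            genes = frozenset(g for g in cols[2:] if g)
            if not genes:
                raise ValueError(f"malformed GMT line {ln}: set {cols[0]!r} has no genes")
            sets[cols[0]] = GeneSet(cols[0], cols[1], genes)
    return GeneSetCollection(sets=sets, source=source)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.set_id, gs.description, *sorted(gs.genes)]) + "\n")


def merge_motif_sets(
    collection: GeneSetCollection, motif_to_tf: Mapping[str, str | Iterable[str]]
) -> GeneSetCollection:
    """Union motif target sets that share a transcription factor.

    A motif mapping to several factors contributes its genes to each; motif
    sets with no known factor are dropped.
    """
    merged: dict[str, set[str]] = {}
    for gs in collection:
        tfs = motif_to_tf.get(gs.set_id)
        if tfs is None:
            continue
        if isinstance(tfs, str):
            tfs = (tfs,)
        for tf in tfs:
            merged.setdefault(tf, set()).update(gs.genes)
    return GeneSetCollection(
        sets={
            tf: GeneSet(tf, f"targets of {tf}", frozenset(genes))
            for tf, genes in merged.items()
        },
        source="TFBS",
    )


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    N reference genes of which K belong to the set; n genes drawn (the
    module); k the overlap.  The sum over the support is evaluated with
    log-gamma binomials and logsumexp so that p-values far below float
    underflow of individual factors remain accurate.
    """
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid parameters N={N}, K={K}, n={n}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"overlap k={k} outside [0, min(n={n}, K={K})]")
    if k == 0:
        return 1.0
    hi = min(n, K)
    ks = np.arange(k, hi + 1)
    # pmf support also requires n - k <= N - K
    ks = ks[n - ks <= N - K]
    if ks.size == 0:
        return 0.0
    log_terms = _log_binom(K, ks) + _log_binom(N - K, n - ks) - _log_binom(N, n)
    return float(np.exp(min(0.0, logsumexp(log_terms))))


def expected_overlap(N: int, K: int, n: int) -> float:
    """Expected overlap n*K/N when n genes are drawn at random from N."""
    if N <= 0:
        raise ValueError("reference size N must be positive")
    return n * K / N


@dataclass
class EnrichmentResult:
    module_id: Hashable
    set_id: str
    N: int
    K: int
    n: int
    k: int
    expected: float
    p: float
    p_adj: float

    @property
    def significant(self) -> bool:
        """Conventional call: Bonferroni-adjusted p below 0.05."""
        return self.p_adj < 0.05


def enrich_module(
    module: Iterable[str],
    collection: GeneSetCollection,
    reference: Iterable[str],
    module_id: Hashable = None,
    family: str = "tested",
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of one module against a collection.

    The reference is all genes on the platform after preprocessing; module
    genes outside it are dropped with a warning and every set is intersected
    with it.  One result is returned per set with nonzero overlap, sorted by
    p.  ``family`` controls the Bonferroni multiplier: the sets actually
    tested for this module (default) or all sets in the collection.
    """
    ref = set(reference)
    if not ref:
        raise ValueError("reference gene set is empty")
    mod = set(module)
    outside = mod - ref
    if outside:
        warnings.warn(
            f"{len(outside)} module gene(s) outside the reference were dropped",
            stacklevel=2,
        )
        mod &= ref
    results: list[EnrichmentResult] = []
    big_n = len(ref)
    for gs in collection:
        genes = gs.genes & ref
        if not genes:
            continue
        k = len(mod & genes)
        if k == 0:
            continue
        big_k = len(genes)
        n = len(mod)
        results.append(
            EnrichmentResult(
                module_id=module_id,
                set_id=gs.set_id,
                N=big_n,
                K=big_k,
                n=n,
                k=k,
                expected=expected_overlap(big_n, big_k, n),
                p=hypergeom_tail(big_n, big_k, n, k),
                p_adj=0.0,
            )
        )
    if family == "tested":
        multiplier = len(results)
    elif family == "all":
        multiplier = len(collection)
    else:
        raise ValueError(f"unknown family {family!r}")
    for res in results:
        res.p_adj = min(1.0, res.p * multiplier)
    results.sort(key=lambda r: (r.p, r.set_id))
    return results
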