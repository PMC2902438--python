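"""Resnik semantic similarity over the Gene Ontology and the correlation-binned
functional-similarity curve used to pick a co-expression threshold.

The information content (IC) of a term is -ln of the fraction of annotated
genes that are annotated to the term or any of its descendants.  Resnik
similarity of two terms is the IC of their most informative common ancestor;
gene-level similarity aggregates the term-pair values across the two genes'
annotation sets.  Binning the pairwise expression correlations and averaging
the gene-pair similarity inside each bin yields the curve whose sharp rise
marks a biologically meaningful correlation threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Ontology",
    "AnnotationMap",
    "InformationContent",
    "SimilarityCurve",
    "compute_ic",
    "resnik_pair",
    "gene_similarity",
    "similarity_curve",
    "read_annotations",
]

#: relations traversed when walking towards the root
_DEFAULT_RELATIONS = ("is_a",)


@dataclass
class Ontology:
    """A rooted DAG of terms connected by is_a (optionally part_of) edges."""

    parents: dict[str, frozenset[str]]
    root: str
    _ancestors: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.root not in self.parents:
            raise ValueError(f"root {self.root!r} not among the terms")
        # Eagerly compute ancestor closures; doubles as an acyclicity check.
        for term in self.parents:
            self.ancestors(term)

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` including the term itself."""
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        return self._close(term, set())

    def _close(self, term: str, active: set[str]) -> frozenset[str]:
        if term in active:
            raise ValueError(f"cycle detected through term {term!r}")
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        active.add(term)
        anc: set[str] = {term}
        for parent in self.parents[term]:
            if parent not in self.parents:
                raise ValueError(f"parent {parent!r} of {term!r} is not a term")
            anc |= self._close(parent, active)
        active.discard(term)
        closed = frozenset(anc)
        self._ancestors[term] = closed
        return closed

    @classmethod
    def from_parent_map(cls, parents: Mapping[str, Iterable[str]]) -> "Ontology":
        """Build from a term -> parents mapping; the unique parentless term is the root."""
        norm = {t: frozenset(p) for t, p in parents.items()}
        roots = [t for t, p in norm.items() if not p]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        return cls(parents=norm, root=roots[0])

    @classmethod
    def from_obo(
        cls,
        path,
        namespace: str | None = "biological_process",
        include_part_of: bool = False,
    ) -> "Ontology":
        """Read an OBO 1.2 file, keeping one namespace and is_a (+ optional part_of) edges."""
        import obonet

        graph = obonet.read_obo(path)
        relations = set(_DEFAULT_RELATIONS) | ({"part_of"} if include_part_of else set())
        keep = {
            n
            for n, data in graph.nodes(data=True)
            if namespace is None or data.get("namespace") == namespace
        }
        parents: dict[str, set[str]] = {t: set() for t in keep}
        for child, parent, rel in graph.edges(keys=True):
            if rel in relations and child in keep and parent in keep:
                parents[child].add(parent)
        roots = [t for t, p in parents.items() if not p]
        if len(roots) != 1:
            raise ValueError(
                f"namespace {namespace!r} has {len(roots)} parentless terms, expected 1"
            )
        return cls(parents={t: frozenset(p) for t, p in parents.items()}, root=roots[0])


@dataclass
class AnnotationMap:
    """Direct gene -> GO term annotations (pre-propagation)."""

    gene_to_terms: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.gene_to_terms = {
            g: frozenset(t) for g, t in self.gene_to_terms.items() if t
        }

    def terms_for(self, gene: str) -> frozenset[str]:
        return self.gene_to_terms.get(gene, frozenset())

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_to_terms


def read_annotations(path, fmt: str = "auto") -> AnnotationMap:
    """Read annotations from GAF 2.x or a two-column gene<TAB>term TSV.

    GAF is detected by the ``!gaf-version`` header or by 15+ tab-separated
    columns; gene symbol is taken from column 3 and term from column 5, with
    aspect column 9 restricted to 'P' (biological process).
    """
    gene_to_terms: dict[str, set[str]] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    is_gaf = fmt == "gaf"
    if fmt == "auto":
        for line in lines:
            if line.startswith("!gaf-version"):
                is_gaf = True
                break
            if line and not line.startswith("!"):
                is_gaf = len(line.split("\t")) >= 15
                break
    for line in lines:
        if not line or line.startswith("!") or line.startswith("#"):
            continue
        cols = line.split("\t")
        if is_gaf:
            if len(cols) < 9 or cols[8] != "P":
                continue
            gene, term = cols[2], cols[4]
        else:
            if len(cols) < 2:
                continue
            gene, term = cols[0], cols[1]
        gene_to_terms.setdefault(gene, set()).add(term)
    return AnnotationMap({g: frozenset(t) for g, t in gene_to_terms.items()})


@dataclass
class InformationContent:
    """Per-term IC = -ln(count(term)/count(root)) after ancestor propagation."""

    ic: dict[str, float]
    counts: dict[str, int]
    n_genes: int

    def __getitem__(self, term: str) -> float:
        return self.ic[term]

    def __contains__(self, term: str) -> bool:
        return term in self.ic


def compute_ic(ont: Ontology, ann: AnnotationMap) -> InformationContent:
    """Propagate annotations to ancestors and compute term information content.

    A gene annotated to a term counts towards that term and every ancestor
    up to the root, so ``count(root)`` equals the number of annotated genes.
    Terms annotated to no gene (directly or via descendants) have undefined
    IC and are left out of the table.  Annotations to unknown terms are
    skipped with a warning.
    """
    counts: dict[str, int] = {}
    n_genes = 0
    skipped: set[str] = set()
    for gene, terms in ann.gene_to_terms.items():
        reach: set[str] = set()
        for term in terms:
            if term not in ont:
                skipped.add(term)
                continue
            reach |= ont.ancestors(term)
        if not reach:
            continue
        n_genes += 1
        for term in reach:
            counts[term] = counts.get(term, 0) + 1
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} annotation term(s) absent from the ontology",
            stacklevel=2,
        )
    if n_genes == 0:
        raise ValueError("no gene carries a usable annotation")
    ic = {t: -math.log(c / n_genes) for t, c in counts.items()}
    return InformationContent(ic=ic, counts=counts, n_genes=n_genes)


def resnik_pair(ic: InformationContent, ont: Ontology, t1: str, t2: str) -> float:
    """IC of the most informative common ancestor of two terms (0 if none has IC)."""
    if t1 not in ont or t2 not in ont:
        raise KeyError(f"term not in ontology: {t1 if t1 not in ont else t2!r}")
    common = ont.ancestors(t1) & ont.ancestors(t2)
    best = 0.0
    for term in common:
        value = ic.ic.get(term)
        if value is not None and value > best:
            best = value
    return best


def gene_similarity(
    ic: InformationContent,
    ont: Ontology,
    ann: AnnotationMap,
    g1: str,
    g2: str,
    method: str = "max",
) -> float:
    """Aggregate Resnik term similarity over two genes' annotation sets.

    ``method='max'`` (default) takes the maximum over all cross term pairs;
    ``method='bma'`` is the best-match average: each term is matched to its
    best counterpart on the other gene and the matches are averaged.
    """
    terms1 = [t for t in ann.terms_for(g1) if t in ont]
    terms2 = [t for t in ann.terms_for(g2) if t in ont]
    if not terms1 or not terms2:
        raise ValueError(f"gene {g1 if not terms1 else g2!r} has no usable annotation")
    sims = np.array(
        [[resnik_pair(ic, ont, a, b) for b in terms2] for a in terms1], dtype=float
    )
    if method == "max":
        return float(sims.max())
    if method == "bma":
        return float(
            (sims.max(axis=1).sum() + sims.max(axis=0).sum()) / (len(terms1) + len(terms2))
        )
    raise ValueError(f"unknown aggregation method {method!r}")


@dataclass
class SimilarityCurve:
    """Mean gene-pair functional similarity per 0.1-wide correlation bin on [-1, 1]."""

    bin_edges: np.ndarray  # 21 edges
    bin_means: np.ndarray  # 20 means, NaN where a bin is empty
    bin_counts: np.ndarray  # scored pairs per bin

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "mean_similarity": self.bin_means,
                "n_pairs": self.bin_counts,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _bin_index(r: float) -> int:
    """Right-closed 0.1 bins on [-1, 1]; the lowest bin is closed on both ends."""
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    idx = math.ceil((r + 1.0) / 0.1 - 1e-9) - 1
    return min(max(idx, 0), 19)


def similarity_curve(
    correlations: Mapping[tuple[str, str], float],
    simfn: Callable[[str, str], float | None],
) -> SimilarityCurve:
    """Bin gene-pair correlations and average their functional similarity per bin.

    ``simfn`` returns the gene-pair similarity or None for pairs that cannot
    be scored (e.g. an unannotated gene); unscorable pairs are excluded from
    both the mean and the count.
    """
    edges = np.round(np.linspace(-1.0, 1.0, 21), 10)
    sums = np.zeros(20)
    counts = np.zeros(20, dtype=int)
    for (g1, g2), r in correlations.items():
        sim = simfn(g1, g2)
        if sim is None:
            continue
        b = _bin_index(float(r))
        sums[b] += sim
        counts[b] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return SimilarityCurve(bin_edges=edges, bin_means=means, bin_counts=counts)
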