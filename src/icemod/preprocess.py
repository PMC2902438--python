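"""Expression preprocessing: probe-set collapsing and per-gene z-standardization.

Microarray platforms measure each gene with one or more probe sets.  Before
any network analysis the probe-level matrix is reduced to one row per gene
(median over that gene's probe sets, per sample) and every gene row is
z-standardized across samples so that expression levels are comparable
between genes and so that a module's overall expression can be taken as a
plain mean of its member rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RawExpression",
    "ExpressionMatrix",
    "collapse_probesets",
    "standardize",
    "read_expression_tsv",
    "read_probe_map_tsv",
]


def _normalize_mapping(
    probe_to_gene: Mapping[str, str | Iterable[str]],
) -> dict[str, tuple[str, ...]]:
    """Coerce mapping values to tuples of gene symbols (probes may map to several genes)."""
    out: dict[str, tuple[str, ...]] = {}
    for probe, genes in probe_to_gene.items():
        if isinstance(genes, str):
            out[probe] = (genes,)
        else:
            out[probe] = tuple(dict.fromkeys(genes))
    return out


@dataclass
class RawExpression:
    """Probe-level expression with a (possibly partial) probe-to-gene mapping.

    Parameters
    ----------
    probe_ids, sample_ids
        Unique row / column identifiers matching ``values``.
    values
        Probe x sample matrix of real expression values (complete, no NaN).
    probe_to_gene
        Map from probe id to one gene symbol or an iterable of gene symbols.
        Probes absent from the mapping are dropped during collapsing.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    probe_to_gene: Mapping[str, str | Iterable[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("probe_ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        self.probe_to_gene = _normalize_mapping(self.probe_to_gene)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression matrix, optionally z-standardized per gene."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self._index[gene]]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, standardized: bool = False) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
            standardized=standardized,
        )

    def write_tsv(self, path) -> None:
        frame = self.to_frame()
        frame.index.name = "gene"
        frame.to_csv(path, sep="\t")


def read_expression_tsv(path, standardized: bool = False) -> ExpressionMatrix:
    """Read a TSV whose first column holds gene/probe ids and header holds sample ids."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix.from_frame(frame, standardized=standardized)


def read_probe_map_tsv(path) -> dict[str, tuple[str, ...]]:
    """Read a probe_id<TAB>gene_symbol mapping; repeated probe rows accumulate genes."""
    mapping: dict[str, list[str]] = {}
    frame = pd.read_csv(path, sep="\t", header=None, names=["probe", "gene"], dtype=str)
    for probe, gene in zip(frame["probe"], frame["gene"]):
        if pd.isna(probe) or pd.isna(gene):
            continue
        mapping.setdefault(probe, [])
        if gene not in mapping[probe]:
            mapping[probe].append(gene)
    return {p: tuple(g) for p, g in mapping.items()}


def collapse_probesets(raw: RawExpression) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene by per-sample median.

    Probes without a gene mapping are dropped.  A probe mapping to several
    genes contributes its row to every one of them.  The output is never
    standardized; call :func:`standardize` afterwards.
    """
    mapping: Mapping[str, tuple[str, ...]] = raw.probe_to_gene  # normalized in __post_init__
    if not mapping:
        raise ValueError("probe_to_gene mapping is empty")

    gene_rows: dict[str, list[int]] = {}
    for i, probe in enumerate(raw.probe_ids):
        for gene in mapping.get(probe, ()):
            gene_rows.setdefault(gene, []).append(i)
    if not gene_rows:
        raise ValueError("no probe in the matrix has a gene mapping")

    genes = sorted(gene_rows)
    values = np.empty((len(genes), len(raw.sample_ids)), dtype=float)
    for gi, gene in enumerate(genes):
        values[gi] = np.median(raw.values[gene_rows[gene]], axis=0)
    return ExpressionMatrix(genes, list(raw.sample_ids), values, standardized=False)


def standardize(expr: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Z-standardize each gene row: (x - mean) / sd with sample sd (ddof=1).

    Zero-variance rows carry no correlation information and are removed with
    a warning.  Requires at least two samples.
    """
    if expr.standardized:
        raise ValueError("matrix is already standardized")
    if expr.n_samples < 2:
        raise ValueError("standardization requires at least 2 samples")

    means = expr.values.mean(axis=1, keepdims=True)
    sds = expr.values.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sds[:, 0] == 0.0) | ~np.isfinite(sds[:, 0])
    if constant.any():
        dropped = [g for g, c in zip(expr.gene_ids, constant) if c]
        warnings.warn(
            f"dropping {len(dropped)} constant gene(s): {', '.join(dropped[:5])}"
            + ("..." if len(dropped) > 5 else ""),
            stacklevel=2,
        )
    keep = ~constant
    z = (expr.values[keep] - means[keep]) / sds[keep]
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    return ExpressionMatrix(genes, list(expr.sample_ids), z, standardized=True)
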