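"""Module-level phenotype screening.

A module's overall expression in a sample is the mean of its member genes'
z-standardized values.  The Jonckheere-Terpstra (JT) test then asks whether
that overall expression trends monotonically across ordered phenotype
categories (e.g. tumor grade 1 < 2 < 3): W sums, over all ordered category
pairs i < j, the number of observation pairs with X_i < X_j (ties counted
1/2).  Under the null W is approximately normal with

    E[W]   = (N^2 - sum n_i^2) / 4
    Var[W] = [N^2 (2N + 3) - sum n_i^2 (2 n_i + 3)] / 72

where n_i are the category sizes and N their total.  Screening applies the
JT test to every module, adjusts the p-values with Benjamini-Hochberg across
the module family, and flags modules below an FDR cut.  Cross-cohort
reproducibility is the percentage of discovery-significant modules (or
genes) that remain significant in an independent validation cohort.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix

__all__ = [
    "ModuleExpression",
    "OrderedPhenotype",
    "TrendResult",
    "ScreenedModule",
    "ReproducibilityReport",
    "module_expression",
    "jt_statistic",
    "jt_test",
    "jt_exact_p",
    "bh_fdr",
    "screen_modules",
    "reproducibility",
]


@dataclass
class ModuleExpression:
    """Per-sample overall expression of a module (mean over present member genes)."""

    module_id: Hashable
    sample_ids: list[str]
    values: np.ndarray
    n_missing_genes: int = 0
    n_genes_used: int = 0


def module_expression(
    expr: ExpressionMatrix, module: Iterable[str], module_id: Hashable = None
) -> ModuleExpression:
    """Mean standardized expression of the module's genes, per sample.

    Genes absent from the matrix (e.g. not on the validation platform) are
    skipped and counted; a module with no present gene is untestable and
    raises.
    """
    if not expr.standardized:
        raise ValueError("module expression requires a standardized matrix")
    genes = sorted(set(module))
    present = [g for g in genes if g in expr]
    if not present:
        raise ValueError(f"no gene of module {module_id!r} is present in the matrix")
    rows = np.vstack([expr.row(g) for g in present])
    return ModuleExpression(
        module_id=module_id,
        sample_ids=list(expr.sample_ids),
        values=rows.mean(axis=0),
        n_missing_genes=len(genes) - len(present),
        n_genes_used=len(present),
    )


@dataclass
class OrderedPhenotype:
    """Sample -> category labels with an explicit category order; missing allowed."""

    labels: Mapping[str, object]
    order: Sequence[object]

    def __post_init__(self) -> None:
        self._rank = {c: i for i, c in enumerate(self.order)}
        if len(self._rank) != len(self.order):
            raise ValueError("category order contains duplicates")

    def rank_of(self, sample: str) -> int | None:
        """0-based category rank, or None when the sample is missing/unlabelled."""
        cat = self.labels.get(sample)
        if cat is None or (isinstance(cat, float) and math.isnan(cat)):
            return None
        if cat not in self._rank:
            raise KeyError(f"category {cat!r} of sample {sample!r} not in order")
        return self._rank[cat]

    @classmethod
    def read_tsv(cls, path, order: Sequence[str], missing: tuple[str, ...] = ("NA", "")):
        frame = pd.read_csv(
            path, sep="\t", header=None, names=["sample", "category"], dtype=str
        )
        labels = {
            str(s): (None if (pd.isna(c) or c in missing) else str(c))
            for s, c in zip(frame["sample"], frame["category"])
        }
        return cls(labels=labels, order=[str(c) for c in order])


@dataclass
class TrendResult:
    """JT statistic with its normal-approximation z and two-sided p."""

    W: float
    mean0: float
    var0: float
    z: float
    p: float
    n_used: int
    group_sizes: tuple[int, ...]
    fdr: float | None = None


def _grouped(values: Sequence[float], ranks: Sequence[int]) -> list[np.ndarray]:
    n_cat = max(ranks) + 1
    groups: list[list[float]] = [[] for _ in range(n_cat)]
    for v, r in zip(values, ranks):
        groups[r].append(v)
    return [np.asarray(g, dtype=float) for g in groups if len(g) > 0]


def jt_statistic(groups: Sequence[np.ndarray]) -> float:
    """W = sum over category pairs i<j of #(X_i < X_j) + 0.5 #(X_i = X_j).

    Computed per pair via midranks: U_ij = n_i n_j + n_i(n_i+1)/2 - R_i,
    with R_i the midrank sum of group i in the pooled pair, which counts
    tied pairs as one half each.
    """
    w = 0.0
    for i, j in itertools.combinations(range(len(groups)), 2):
        gi, gj = groups[i], groups[j]
        pooled = np.concatenate([gi, gj])
        ranks = stats.rankdata(pooled)
        r_i = ranks[: len(gi)].sum()
        w += len(gi) * len(gj) + len(gi) * (len(gi) + 1) / 2.0 - r_i
    return float(w)


def jt_null_moments(group_sizes: Sequence[int]) -> tuple[float, float]:
    """Null mean and variance of W (no-tie forms)."""
    n = np.asarray(group_sizes, dtype=float)
    total = n.sum()
    mean0 = (total**2 - (n**2).sum()) / 4.0
    var0 = (total**2 * (2 * total + 3) - (n**2 * (2 * n + 3)).sum()) / 72.0
    return float(mean0), float(var0)


def jt_test(
    values: Sequence[float] | ModuleExpression,
    pheno: OrderedPhenotype | Sequence[int],
    sample_ids: Sequence[str] | None = None,
) -> TrendResult:
    """Two-sided JT trend test of per-sample values against ordered categories.

    ``values`` may be a :class:`ModuleExpression` (sample ids taken from it)
    or a plain sequence with either an :class:`OrderedPhenotype` plus
    ``sample_ids``, or a parallel sequence of 0-based category ranks.
    Samples with missing phenotype are dropped.  All values tied gives
    z = 0, p = 1; fewer than two non-empty categories raises.
    """
    if isinstance(values, ModuleExpression):
        sample_ids = values.sample_ids
        values = values.values
    vals = np.asarray(values, dtype=float)
    if isinstance(pheno, OrderedPhenotype):
        if sample_ids is None:
            raise ValueError("sample_ids required with an OrderedPhenotype")
        pairs = [
            (v, pheno.rank_of(s))
            for v, s in zip(vals, sample_ids)
        ]
        kept = [(v, r) for v, r in pairs if r is not None]
        if not kept:
            raise ValueError("no sample has a phenotype label")
        vals = np.array([v for v, _ in kept])
        ranks = [r for _, r in kept]
    else:
        ranks = [int(r) for r in pheno]
        if len(ranks) != len(vals):
            raise ValueError("values and category ranks differ in length")

    groups = _grouped(vals, ranks)
    if len(groups) < 2:
        raise ValueError("JT test needs at least 2 non-empty ordered categories")
    sizes = tuple(len(g) for g in groups)
    w = jt_statistic(groups)
    mean0, var0 = jt_null_moments(sizes)
    if var0 <= 0:
        raise ValueError("degenerate design: null variance is zero")
    z = (w - mean0) / math.sqrt(var0)
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return TrendResult(
        W=w, mean0=mean0, var0=var0, z=z, p=p, n_used=int(sum(sizes)), group_sizes=sizes
    )


def jt_exact_p(
    values: Sequence[float],
    ranks: Sequence[int],
    alternative: str = "two-sided",
    max_n: int = 12,
) -> float:
    """Exact permutation p-value of the JT statistic for small samples.

    Enumerates every distinct assignment of the observed values to the group
    sizes (N!/prod n_i! arrangements); intended for N <= ``max_n``.
    """
    vals = np.asarray(values, dtype=float)
    groups = _grouped(vals, [int(r) for r in ranks])
    sizes = [len(g) for g in groups]
    total = sum(sizes)
    if total > max_n:
        raise ValueError(f"exact enumeration limited to N <= {max_n} (got {total})")
    w_obs = jt_statistic(groups)

    pooled = np.concatenate(groups)
    count_ge = 0
    count_le = 0
    count_all = 0

    def assignments(remaining: tuple[int, ...], sizes_left: list[int], acc: list[tuple[int, ...]]):
        if not sizes_left:
            yield list(acc)
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(x for x in remaining if x not in set(combo))
            acc.append(combo)
            yield from assignments(rest, sizes_left[1:], acc)
            acc.pop()

    for assign in assignments(tuple(range(total)), sizes, []):
        perm_groups = [pooled[list(ix)] for ix in assign]
        w = jt_statistic(perm_groups)
        count_all += 1
        if w >= w_obs - 1e-9:
            count_ge += 1
        if w <= w_obs + 1e-9:
            count_le += 1

    if alternative == "greater":
        return count_ge / count_all
    if alternative == "less":
        return count_le / count_all
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(count_ge, count_le) / count_all)
    raise ValueError(f"unknown alternative {alternative!r}")


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    pvals = list(pvalues)
    if not pvals:
        return []
    arr = np.asarray(pvals, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])


@dataclass
class ScreenedModule:
    module_id: Hashable
    trend: TrendResult | None
    significant: bool
    error: str | None = None


def screen_modules(
    expr: ExpressionMatrix,
    modules: Mapping[Hashable, Iterable[str]],
    pheno: OrderedPhenotype,
    fdr_cut: float = 0.01,
) -> list[ScreenedModule]:
    """JT-test every module's overall expression and BH-adjust across the family.

    Untestable modules (no gene on the platform, degenerate design) are
    reported with their error and excluded from the FDR family.  The family
    is all modules tested in this call.
    """
    results: list[ScreenedModule] = []
    tested: list[ScreenedModule] = []
    for module_id, genes in modules.items():
        try:
            me = module_expression(expr, genes, module_id=module_id)
            trend = jt_test(me, pheno)
        except (ValueError, KeyError) as exc:
            results.append(ScreenedModule(module_id, None, False, error=str(exc)))
            continue
        sm = ScreenedModule(module_id, trend, False)
        results.append(sm)
        tested.append(sm)
    if tested:
        adjusted = bh_fdr([sm.trend.p for sm in tested])
        for sm, fdr in zip(tested, adjusted):
            sm.trend.fdr = float(fdr)
            sm.significant = fdr < fdr_cut
    return results


@dataclass
class ReproducibilityReport:
    """Fraction of discovery-significant biomarkers still significant in validation."""

    n_discovery_significant: int
    n_validation_significant: int
    percentage: float


def _count(flags) -> int:
    if isinstance(flags, (int, np.integer)):
        return int(flags)
    return int(sum(bool(f) for f in flags))


def reproducibility(discovery_flags, validation_flags) -> ReproducibilityReport:
    """Percentage (2 decimals) of discovery-significant biomarkers that validate.

    Arguments are counts or iterables of booleans.  Validation is evaluated
    only on discovery-significant biomarkers, so the validation count can
    never exceed the discovery count.
    """
    n_disc = _count(discovery_flags)
    n_val = _count(validation_flags)
    if n_disc == 0:
        raise ValueError("reproducibility undefined: no discovery-significant biomarker")
    if n_val > n_disc:
        raise ValueError("validation count exceeds discovery count")
    return ReproducibilityReport(
        n_discovery_significant=n_disc,
        n_validation_significant=n_val,
        percentage=round(100.0 * n_val / n_disc, 2),
    )
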