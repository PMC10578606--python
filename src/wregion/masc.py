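"""Transcriptome-masculinization statistic: panel fold-change correlation
with a random-gene-panel permutation null.

A knockout of the female-determining gene in a genetic female should shift
sex-related gene expression toward the wildtype male profile. The statistic
quantifying this is the correlation, across a panel of sex-related genes
(74 in the motivating study), between the log2 fold changes of two contrasts
— typically knockout-female vs wildtype-female against wildtype-male vs
wildtype-female. Tukey-fence (1.5 x IQR) outliers are excluded before
correlating, and significance is assessed against a null built by repeatedly
drawing equally sized random gene panels from all genes quantified in both
contrasts, re-applying the outlier rule inside every draw. The permutation
p-value is ``1 - r/(n_perm + 1)`` with ``r`` the number of permutation
correlations strictly below the observed one, so ties count against
significance and p is never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counts_de import ContrastResult

__all__ = [
    "GenePanel",
    "PairedLogFC",
    "MascResult",
    "read_panel",
    "iqr_outlier_mask",
    "panel_logfc_pairs",
    "correlation",
    "correlation_pvalue_t",
    "permutation_masc_test",
    "pairwise_masc_matrix",
    "PairwiseMasc",
]


@dataclass(frozen=True)
class GenePanel:
    """An ordered panel of gene ids (the sex-related gene list)."""

    gene_ids: tuple[str, ...]
    name: str = "panel"

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("panel contains duplicate gene ids")
        if len(self.gene_ids) < 3:
            raise ValueError("panel needs at least 3 genes")

    def __len__(self) -> int:
        return len(self.gene_ids)


def read_panel(path, name: "str | None" = None) -> GenePanel:
    """Read a panel file: one gene id per line, '#' starts a comment."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if entry:
                genes.append(entry)
    return GenePanel(tuple(genes), name=name or str(path))


def iqr_outlier_mask(
    values: Sequence[float], quantile_method: str = "linear"
) -> np.ndarray:
    """Tukey-fence outlier mask: True where v < Q1 - 1.5*IQR or v > Q3 + 1.5*IQR.

    Quartiles use linear interpolation between order statistics by default
    (``quantile_method`` is passed to :func:`numpy.quantile`). Requires at
    least 4 finite values; non-finite entries are never flagged.
    """
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if finite.sum() < 4:
        raise ValueError("IQR outlier rule needs at least 4 finite values")
    q1, q3 = np.quantile(arr[finite], [0.25, 0.75], method=quantile_method)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask = np.zeros(arr.shape, dtype=bool)
    mask[finite] = (arr[finite] < lo) | (arr[finite] > hi)
    return mask


@dataclass
class PairedLogFC:
    """Panel log2 fold changes paired across two analyses.

    Only panel genes with finite values in both analyses enter ``x``/``y``;
    ``outlier_mask`` is the union of the per-vector IQR masks (True = outlier
    in either coordinate); ``missing_genes`` lists panel genes absent or
    non-finite in at least one analysis.
    """

    gene_ids: tuple[str, ...]
    x: np.ndarray
    y: np.ndarray
    outlier_mask: np.ndarray
    missing_genes: tuple[str, ...] = ()

    @property
    def n_used(self) -> int:
        return int((~self.outlier_mask).sum())

    @property
    def outlier_genes(self) -> tuple[str, ...]:
        return tuple(g for g, o in zip(self.gene_ids, self.outlier_mask) if o)


def _finite_logfc(res: ContrastResult) -> pd.Series:
    lfc = res.log2fc
    return lfc[np.isfinite(lfc)]


def panel_logfc_pairs(
    res_x: ContrastResult, res_y: ContrastResult, panel: GenePanel
) -> PairedLogFC:
    """Pair a panel's log2 fold changes across two contrasts.

    No abundance filtering is applied to the panel; instead outliers are
    flagged by the IQR rule in each coordinate and a gene is excluded when it
    is an outlier in either. Panel genes missing (or non-finite) in either
    analysis are reported, not silently dropped.
    """
    x_all, y_all = _finite_logfc(res_x), _finite_logfc(res_y)
    usable, missing = [], []
    for g in panel.gene_ids:
        if g in x_all.index and g in y_all.index:
            usable.append(g)
        else:
            missing.append(g)
    if len(usable) < 3:
        raise ValueError(
            f"only {len(usable)} panel genes usable in both analyses (need >= 3)"
        )
    x = x_all[usable].to_numpy()
    y = y_all[usable].to_numpy()
    if len(usable) < 4:  # quartile fences undefined; nothing can be flagged
        mask = np.zeros(len(usable), dtype=bool)
    else:
        mask = iqr_outlier_mask(x) | iqr_outlier_mask(y)
    return PairedLogFC(
        gene_ids=tuple(usable), x=x, y=y, outlier_mask=mask,
        missing_genes=tuple(missing),
    )


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def correlation(x: Sequence[float], y: Sequence[float], method: str = "spearman") -> float:
    """Pearson or Spearman correlation; errors on constant input.

    Spearman is Pearson on average-tie ranks, so it is invariant to strictly
    monotone transforms of either vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    if method == "pearson":
        return float(np.corrcoef(x, y)[0, 1])
    if method == "spearman":
        return _spearman(x, y)
    raise ValueError(f"unknown correlation method {method!r}")


def correlation_pvalue_t(r: float, n: int) -> float:
    """Two-sided p-value for a correlation coefficient via the t transform.

    ``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` degrees of freedom,
    assuming independent normal samples. ``|r| = 1`` returns p = 0 with a
    warning (the statistic is degenerate there) instead of raising.
    """
    if n < 4:
        raise ValueError("t-based correlation p-value needs n >= 4")
    if abs(r) > 1:
        raise ValueError("correlation must lie in [-1, 1]")
    if abs(r) == 1:
        warnings.warn("|r| = 1: degenerate t statistic, returning p = 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@dataclass
class MascResult:
    """Result of the masculinization permutation test for one pair of contrasts."""

    method: str
    r_obs: float
    n_used: int
    outlier_genes: tuple[str, ...]
    n_perm: int
    perm_r: np.ndarray
    p_perm: float
    p_analytic: float
    seed: "int | None"
    n_redrawn: int = 0
    missing_genes: tuple[str, ...] = ()
    pair: tuple[str, str] = ("x", "y")

    def summary(self) -> dict:
        return {
            "pair": list(self.pair),
            "method": self.method,
            "r_obs": self.r_obs,
            "n_used": self.n_used,
            "outlier_genes": list(self.outlier_genes),
            "missing_genes": list(self.missing_genes),
            "n_perm": self.n_perm,
            "p_perm": self.p_perm,
            "p_analytic": self.p_analytic,
            "n_redrawn": self.n_redrawn,
            "seed": self.seed,
        }


def _masked_pair(x: np.ndarray, y: np.ndarray) -> "tuple[np.ndarray, np.ndarray] | None":
    mask = iqr_outlier_mask(x) | iqr_outlier_mask(y)
    xs, ys = x[~mask], y[~mask]
    if xs.size < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return None
    return xs, ys


def permutation_masc_test(
    res_x: ContrastResult,
    res_y: ContrastResult,
    panel: GenePanel,
    n_perm: int = 1000,
    method: str = "spearman",
    seed: "int | None" = 0,
    max_redraws: int = 10_000,
) -> MascResult:
    """Random-gene-panel permutation test of the panel fold-change correlation.

    The permutation universe is every gene with a finite log2 fold change in
    both contrasts (panel genes included). Each replicate draws ``len(panel)``
    genes without replacement, applies the IQR union mask within the
    replicate, and records the correlation of the survivors; replicates left
    with fewer than 3 points or a constant vector are redrawn (counted in
    ``n_redrawn``). The observed correlation uses the true panel the same
    way. ``p_perm = 1 - r/(n_perm + 1)`` with ``r`` the number of permutation
    correlations strictly below ``r_obs``.
    """
    pairs = panel_logfc_pairs(res_x, res_y, panel)
    xs, ys = pairs.x[~pairs.outlier_mask], pairs.y[~pairs.outlier_mask]
    r_obs = correlation(xs, ys, method=method)

    x_all, y_all = _finite_logfc(res_x), _finite_logfc(res_y)
    shared = x_all.index.intersection(y_all.index)
    universe_x = x_all[shared].to_numpy()
    universe_y = y_all[shared].to_numpy()
    panel_n = len(pairs.gene_ids)
    if shared.size <= panel_n:
        raise ValueError(
            f"permutation universe ({shared.size} genes) must exceed the panel size "
            f"({panel_n})"
        )

    rng = np.random.default_rng(seed)
    corr = _spearman if method == "spearman" else (
        lambda a, b: float(np.corrcoef(a, b)[0, 1]))
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")

    perm_r = np.empty(n_perm)
    n_redrawn = 0
    for i in range(n_perm):
        while True:
            idx = rng.choice(shared.size, size=panel_n, replace=False)
            kept = _masked_pair(universe_x[idx], universe_y[idx])
            if kept is not None:
                break
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError("too many degenerate permutation replicates")
        perm_r[i] = corr(*kept)

    rank = int(np.sum(perm_r < r_obs))
    p_perm = 1.0 - rank / (n_perm + 1)
    p_analytic = correlation_pvalue_t(r_obs, xs.size) if xs.size >= 4 else float("nan")
    return MascResult(
        method=method,
        r_obs=r_obs,
        n_used=int(xs.size),
        outlier_genes=pairs.outlier_genes,
        n_perm=n_perm,
        perm_r=perm_r,
        p_perm=p_perm,
        p_analytic=p_analytic,
        seed=seed,
        n_redrawn=n_redrawn,
        missing_genes=pairs.missing_genes,
    )


@dataclass
class PairwiseMasc:
    """All pairwise masculinization tests among a set of named contrasts."""

    names: tuple[str, ...]
    results: Mapping[tuple[str, str], MascResult]

    def r_frame(self) -> pd.DataFrame:
        """Correlation matrix (r = 1 on the diagonal by convention)."""
        mat = pd.DataFrame(np.eye(len(self.names)), index=self.names,
                           columns=self.names)
        for (a, b), res in self.results.items():
            mat.loc[a, b] = res.r_obs
            mat.loc[b, a] = res.r_obs
        return mat

    def p_frame(self) -> pd.DataFrame:
        mat = pd.DataFrame(np.nan, index=self.names, columns=self.names)
        for (a, b), res in self.results.items():
            mat.loc[a, b] = res.p_perm
            mat.loc[b, a] = res.p_perm
        return mat

    def __getitem__(self, pair: tuple[str, str]) -> MascResult:
        a, b = pair
        return self.results[(a, b)] if (a, b) in self.results else self.results[(b, a)]


def pairwise_masc_matrix(
    results: Mapping[str, ContrastResult],
    panel: GenePanel,
    n_perm: int = 1000,
    method: str = "spearman",
    seed: "int | None" = 0,
) -> PairwiseMasc:
    """Masculinization test for every unordered pair of named contrasts.

    One :class:`MascResult` per unordered pair; r is symmetric and the
    diagonal is 1 by convention. Per-pair seeds are spawned deterministically
    from ``seed``.
    """
    names = list(results)
    if len(names) != len(set(names)):
        raise ValueError("duplicate analysis names")
    if len(names) < 2:
        raise ValueError("pairwise matrix needs at least 2 analyses")
    ss = np.random.SeedSequence(seed)
    pair_list = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    children = ss.spawn(len(pair_list))
    out: dict[tuple[str, str], MascResult] = {}
    for (a, b), child in zip(pair_list, children):
        pair_seed = int(child.generate_state(1)[0] % (2**31))
        res = permutation_masc_test(
            results[a], results[b], panel, n_perm=n_perm, method=method,
            seed=pair_seed,
        )
        res.pair = (a, b)
        out[(a, b)] = res
    return PairwiseMasc(names=tuple(names), results=out)
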