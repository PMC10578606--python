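"""Lightweight count-based differential expression for gonad transcriptomes.

Implements the filtering and calling rules used downstream of transcript
quantification: genes averaging fewer than ``min_mean`` raw reads per sample
are removed, library composition is normalised by median-of-ratios size
factors, per-gene fold changes are tested with a moderated negative-binomial
Wald test, and genes are called differentially expressed when the
Benjamini-Hochberg adjusted p-value falls below 0.10 (wildtype female
expression is the reference throughout). Parity with full GLM-based DE
packages is explicitly not a goal; the stage is self-contained and
analytically transparent so its operating characteristics can be verified by
simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "ContrastSpec",
    "ContrastResult",
    "filter_low_counts",
    "median_ratio_size_factors",
    "log2_cpm",
    "nb_two_group_test",
    "bh_adjust",
    "de_overlap",
]

_SAMPLE_COLUMNS = ("group", "genotype", "phenotype", "batch")


@dataclass
class CountMatrix:
    """Gene x sample integer counts with per-sample metadata.

    ``counts`` is genes-as-rows / samples-as-columns; ``samples`` is indexed
    by sample id and must at least carry a ``group`` label per sample.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        values = self.counts.to_numpy()
        if values.size and (not np.isfinite(values).all() or (values < 0).any()):
            raise ValueError("counts must be finite and non-negative")
        if "group" not in self.samples.columns:
            raise ValueError("sample metadata must have a 'group' column")
        if list(self.samples.index) != list(self.counts.columns):
            raise ValueError("sample metadata index must match count columns")
        if self.samples["group"].isna().any():
            raise ValueError("every sample needs a group label")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def group_samples(self, group: str) -> list[str]:
        return list(self.samples.index[self.samples["group"] == group])

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        ids = list(sample_ids)
        return CountMatrix(self.counts[ids], self.samples.loc[ids])

    def subset_genes(self, gene_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.samples)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, counts_path, samples_path) -> None:
        self.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
        self.samples.rename_axis("sample_id").to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0, dtype=str)
        return cls(counts, samples)


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group comparison; fold changes are test over reference."""

    test_group: str
    reference_group: str

    def __post_init__(self) -> None:
        if self.test_group == self.reference_group:
            raise ValueError("test and reference groups must differ")

    def validate_against(self, cm: CountMatrix) -> None:
        for group in (self.test_group, self.reference_group):
            n = len(cm.group_samples(group))
            if n < 1:
                raise ValueError(f"group {group!r} has no samples")
            if n < 2:
                warnings.warn(
                    f"group {group!r} has a single sample; dispersion cannot be "
                    "estimated from it", UserWarning, stacklevel=3,
                )


@dataclass
class ContrastResult:
    """Per-gene statistics for one contrast.

    ``table`` has one row per input gene with columns log2fc, base_mean,
    p_value, fdr, de_flag and filtered. Genes removed by the low-count filter
    are kept with ``filtered=True`` and NaN statistics rather than silently
    dropped.
    """

    table: pd.DataFrame
    test_group: str
    reference_group: str
    alpha: float = 0.10

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    @property
    def de_genes(self) -> list[str]:
        return list(self.table.index[self.table["de_flag"]])

    def to_tsv(self, path) -> None:
        self.table.rename_axis("gene_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, test_group: str = "", reference_group: str = "",
                 alpha: float = 0.10) -> "ContrastResult":
        table = pd.read_csv(path, sep="\t", index_col=0)
        return cls(table, test_group, reference_group, alpha)


def filter_low_counts(cm: CountMatrix, min_mean: float = 2.0) -> CountMatrix:
    """Remove genes averaging fewer than ``min_mean`` raw reads per sample.

    A gene is retained exactly when its raw-count mean across all samples of
    ``cm`` is at least ``min_mean``; gene order is preserved.
    """
    if cm.counts.empty:
        raise ValueError("cannot filter an empty count matrix")
    keep = cm.counts.mean(axis=1) >= min_mean
    return CountMatrix(cm.counts.loc[keep], cm.samples)


def median_ratio_size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors (per-sample library composition scaling).

    For genes with a positive geometric mean across samples, each sample's
    factor is the median of count / geometric-mean ratios. Factors are
    positive; an all-zero sample is an error naming the sample.
    """
    counts = cm.counts.to_numpy(dtype=float)
    col_sums = counts.sum(axis=0)
    for sid, total in zip(cm.sample_ids, col_sums):
        if total == 0:
            raise ValueError(f"sample {sid!r} has zero counts for every gene")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has nonzero counts in every sample")
    sub = counts[positive]
    geomean = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / geomean[:, None], axis=0)
    return pd.Series(factors, index=cm.sample_ids, name="size_factor")


def log2_cpm(cm: CountMatrix, prior: float = 0.5,
             lib_sizes: "pd.Series | None" = None) -> pd.DataFrame:
    """log2 counts per million with a prior count; finite everywhere.

    Library sizes default to median-of-ratios size factors rescaled to the
    geometric mean of the raw column totals, so composition outliers do not
    distort the per-million scaling. A zero count maps to ``log2(prior)``.
    """
    if prior <= 0:
        raise ValueError("prior must be positive")
    if lib_sizes is None:
        factors = median_ratio_size_factors(cm)
        col_sums = cm.counts.sum(axis=0).astype(float)
        lib_sizes = factors * np.exp(np.log(col_sums).mean())
    else:
        lib_sizes = pd.Series(lib_sizes, index=cm.sample_ids).astype(float)
        if (lib_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
    cpm = cm.counts.to_numpy(dtype=float) / lib_sizes.to_numpy() * 1e6
    return pd.DataFrame(np.log2(cpm + prior), index=cm.gene_ids, columns=cm.sample_ids)


def bh_adjust(p: "np.ndarray | pd.Series | Iterable[float]") -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Missing values propagate as missing and do not enter the number of tests.
    Output is monotone in the sorted order, never below the raw p-value, and
    capped at 1.
    """
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    ps = arr[mask]
    if ((ps < 0) | (ps > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps, kind="mergesort")
    scaled = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    unsorted = np.empty(m)
    unsorted[order] = adj
    out[mask] = unsorted
    return out


def _mom_dispersion(norm: np.ndarray) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion from one group's normalized counts.

    Under var = mu + phi * mu^2, phi-hat = (s^2 - m) / m^2, clipped at 0.
    NaN where undefined (single sample or zero mean).
    """
    n = norm.shape[1]
    if n < 2:
        return np.full(norm.shape[0], np.nan)
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (var - mean) / mean**2
    phi = np.where(mean > 0, np.maximum(phi, 0.0), np.nan)
    return phi


def nb_two_group_test(
    cm: CountMatrix,
    spec: ContrastSpec,
    prior_count: float = 0.5,
    dispersion_prior_weight: float = 10.0,
    alpha: float = 0.10,
    min_mean: "float | None" = 2.0,
) -> ContrastResult:
    """Moderated negative-binomial Wald test between two sample groups.

    Pipeline per gene (on the samples of the two groups only): the low-count
    filter is applied unless ``min_mean`` is None, counts are normalized by
    median-of-ratios size factors, and

    * ``log2fc = log2((mean_norm_test + prior_count) / (mean_norm_ref + prior_count))``
    * dispersion is estimated by method of moments per gene and shrunk toward
      the common (trend-free) dispersion with weight ``dispersion_prior_weight``
      against the residual degrees of freedom,
    * a two-sided Wald p-value is computed from the natural-log fold change
      with delta-method variance ``(1/mu_t + phi)/n_t + (1/mu_r + phi)/n_r``
      (group means stabilized by the same prior count),
    * FDR by Benjamini-Hochberg; ``de_flag`` at ``fdr < alpha``.

    Genes with zero counts in both groups get log2fc 0 and p 1. Filtered
    genes stay in the output with ``filtered=True`` and NaN statistics.
    """
    spec.validate_against(cm)
    sample_ids = cm.group_samples(spec.test_group) + cm.group_samples(spec.reference_group)
    sub = cm.subset_samples(sample_ids)
    for group in (spec.test_group, spec.reference_group):
        cols = sub.counts[sub.group_samples(group)]
        if cols.to_numpy().sum() == 0:
            raise ValueError(f"group {group!r} has all-zero counts for every gene")

    all_genes = sub.gene_ids
    if min_mean is not None:
        kept = filter_low_counts(sub, min_mean=min_mean)
    else:
        kept = sub
    filtered_flag = pd.Series(
        [g not in set(kept.gene_ids) for g in all_genes], index=all_genes, dtype=bool
    )

    factors = median_ratio_size_factors(kept)
    norm = kept.counts.to_numpy(dtype=float) / factors.to_numpy()
    test_idx = [kept.sample_ids.index(s) for s in kept.group_samples(spec.test_group)]
    ref_idx = [kept.sample_ids.index(s) for s in kept.group_samples(spec.reference_group)]
    n_t, n_r = len(test_idx), len(ref_idx)
    norm_t, norm_r = norm[:, test_idx], norm[:, ref_idx]
    mu_t, mu_r = norm_t.mean(axis=1), norm_r.mean(axis=1)

    log2fc = np.log2((mu_t + prior_count) / (mu_r + prior_count))
    base_mean = norm.mean(axis=1)

    phi_t, phi_r = _mom_dispersion(norm_t), _mom_dispersion(norm_r)
    df_t, df_r = max(n_t - 1, 0), max(n_r - 1, 0)
    weights = np.array([df_t, df_r], dtype=float)
    stacked = np.vstack([phi_t, phi_r])
    num = np.nansum(stacked * weights[:, None], axis=0)
    den = (weights[:, None] * ~np.isnan(stacked)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_gene = np.where(den > 0, num / den, np.nan)
    finite = np.isfinite(phi_gene)
    phi_common = float(phi_gene[finite].mean()) if finite.any() else 0.0
    df_resid = df_t + df_r
    phi_hat = np.where(finite, phi_gene, phi_common)
    phi = (df_resid * phi_hat + dispersion_prior_weight * phi_common) / (
        df_resid + dispersion_prior_weight
    )

    se2 = (1.0 / (mu_t + prior_count) + phi) / n_t + (1.0 / (mu_r + prior_count) + phi) / n_r
    ln_fc = log2fc * np.log(2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = ln_fc / np.sqrt(se2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    both_zero = (mu_t == 0) & (mu_r == 0)
    log2fc = np.where(both_zero, 0.0, log2fc)
    p = np.where(both_zero, 1.0, p)

    fdr = bh_adjust(p)
    stats_table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "base_mean": base_mean,
            "p_value": p,
            "fdr": fdr,
            "de_flag": fdr < alpha,
        },
        index=kept.gene_ids,
    )
    table = stats_table.reindex(all_genes)
    table["de_flag"] = table["de_flag"].astype("boolean").fillna(False).astype(bool)
    table["filtered"] = filtered_flag
    return ContrastResult(
        table=table,
        test_group=spec.test_group,
        reference_group=spec.reference_group,
        alpha=alpha,
    )


def de_overlap(sets: "Mapping[str, Iterable[str]] | Iterable[tuple[str, Iterable[str]]]"
               ) -> dict[str, int]:
    """Counts for every exclusive region of a 2- or 3-set Venn partition.

    Region labels join the member set names with ``&`` (e.g. ``"MF1&MF2"`` is
    the region in MF1 and MF2 but outside any third set). Region counts sum
    to the size of the union.
    """
    if isinstance(sets, Mapping):
        items = list(sets.items())
    else:
        items = list(sets)
        names = [name for name, _ in items]
        if len(names) != len(set(names)):
            raise ValueError("duplicate set names")
    if not 2 <= len(items) <= 3:
        raise ValueError("de_overlap needs 2 or 3 named sets")
    named = {name: frozenset(members) for name, members in items}
    names = list(named)

    regions: dict[str, int] = {}
    universe = frozenset().union(*named.values())
    for r in range(1, len(names) + 1):
        for combo in _combinations_in_order(names, r):
            inside = frozenset.intersection(*(named[n] for n in combo))
            outside = frozenset().union(
                *(named[n] for n in names if n not in combo), frozenset()
            )
            regions["&".join(combo)] = len(inside - outside)
    assert sum(regions.values()) == len(universe)
    return regions


def _combinations_in_order(names: list[str], r: int):
    from itertools import combinations

    return combinations(names, r)
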