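"""Count filtering, normalization and sample QC.

Pipeline order is fixed: low-expression filter -> median-of-ratios size
factors -> log2 normalization -> connectivity-based outlier removal ->
clone merge.  Gene and sample order are canonicalized (lexicographic) so
downstream results do not depend on input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "filter_low_expression",
    "size_factors",
    "normalized_log",
    "merge_clones",
    "remove_outlier_samples",
    "preprocess",
    "PreprocessResult",
]


def filter_low_expression(counts: pd.DataFrame, min_count: int = 10,
                          low_fraction: float = 0.90) -> pd.DataFrame:
    """Drop genes with fewer than ``min_count`` counts in more than
    ``low_fraction`` of samples.

    A gene is removed iff the fraction of samples with count < ``min_count``
    is strictly greater than ``low_fraction``; a gene low in exactly
    ``low_fraction`` of samples is retained.  Samples are never removed.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if not 0.0 < low_fraction <= 1.0:
        raise ValueError("low_fraction must be in (0, 1]")
    frac_low = (counts.values < min_count).mean(axis=1)
    return counts.loc[frac_low <= low_fraction]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    For each gene expressed in every sample, the ratio of its count to its
    geometric mean across samples is formed; the per-sample factor is the
    median of these ratios.
    """
    positive = (counts.values > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "apply filter_low_expression first"
        )
    logc = np.log(counts.values[positive].astype(float))
    log_geomean = logc.mean(axis=1)
    factors = np.exp(np.median(logc - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_log(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1) normalized expression."""
    factors = factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be positive and cover every sample")
    return pd.DataFrame(
        np.log2(counts.values / factors.values[None, :] + 1.0),
        index=counts.index, columns=counts.columns,
    )


def _resolve_clone_map(clone_map: dict[str, str]) -> dict[str, str]:
    resolved = {}
    for key in clone_map:
        seen = {key}
        target = clone_map[key]
        while target in clone_map:
            if target in seen:
                raise ValueError(f"cycle in clone_map involving {target!r}")
            seen.add(target)
            target = clone_map[target]
        resolved[key] = target
    return resolved


def merge_clones(meta: pd.DataFrame, clone_map: dict[str, str]) -> pd.DataFrame:
    """Re-code clonal genotypes, e.g. ``{"G63": "G62"}``; idempotent."""
    if not clone_map:
        return meta.copy()
    known = set(meta["genotype"].unique())
    unknown = (set(clone_map) | set(clone_map.values())) - known - set(clone_map)
    if unknown:
        warnings.warn(f"clone_map targets not present in metadata: {sorted(unknown)}")
    resolved = _resolve_clone_map(clone_map)
    out = meta.copy()
    out["genotype"] = out["genotype"].replace(resolved)
    return out


def remove_outlier_samples(expr: pd.DataFrame, z_cut: float = -2.5
                           ) -> tuple[pd.DataFrame, list[str]]:
    """Flag samples with anomalously low network connectivity.

    Per-sample connectivity is the row sum of the inter-sample Pearson
    correlation matrix; samples whose standardized connectivity falls below
    ``z_cut`` are removed.
    """
    if expr.shape[1] < 4:
        raise ValueError("need at least 4 samples for outlier detection")
    corr = np.corrcoef(expr.values.T)
    k = corr.sum(axis=1)
    sd = k.std(ddof=1)
    z = (k - k.mean()) / sd if sd > 0 else np.zeros_like(k)
    flagged = z < z_cut
    if flagged.all():
        raise ValueError("all samples flagged as outliers; check z_cut")
    removed = list(expr.columns[flagged])
    return expr.loc[:, ~flagged], removed


@dataclass
class PreprocessResult:
    """Filtered, normalized log2 expression plus a QC report."""

    expr: pd.DataFrame
    meta: pd.DataFrame
    factors: pd.Series
    removed_samples: list[str]
    n_genes_in: int
    n_genes_out: int
    params: dict = field(default_factory=dict)

    def report(self) -> dict:
        return {
            "n_genes_in": self.n_genes_in,
            "n_genes_out": self.n_genes_out,
            "n_samples": int(self.expr.shape[1]),
            "removed_samples": list(self.removed_samples),
            "size_factors": {k: float(v) for k, v in self.factors.items()},
            "params": self.params,
        }


def preprocess(counts: pd.DataFrame, meta: pd.DataFrame,
               min_count: int = 10, low_fraction: float = 0.90,
               z_cut: float = -2.5,
               clone_map: dict[str, str] | None = None) -> PreprocessResult:
    """Run the full preprocessing chain on raw counts."""
    missing = set(counts.columns) - set(meta.index)
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]} ...")
    filtered = filter_low_expression(counts, min_count, low_fraction)
    factors = size_factors(filtered)
    expr = normalized_log(filtered, factors)
    expr, removed = remove_outlier_samples(expr, z_cut)
    out_meta = merge_clones(meta.loc[expr.columns], clone_map or {})
    expr = expr.sort_index(axis=0).sort_index(axis=1)
    out_meta = out_meta.loc[expr.columns]
    return PreprocessResult(
        expr=expr, meta=out_meta, factors=factors.loc[expr.columns],
        removed_samples=removed,
        n_genes_in=int(counts.shape[0]), n_genes_out=int(expr.shape[0]),
        params={"min_count": min_count, "low_fraction": low_fraction,
                "z_cut": z_cut, "clone_map": dict(clone_map or {})},
    )
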