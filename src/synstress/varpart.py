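"""Distance-based variance partitioning (PERMANOVA).

Sequential (Type I) partitioning of a Gower-centred squared Euclidean
distance matrix into factor sums of squares, with pseudo-F statistics and
p-values by free permutation of sample labels — the adonis procedure.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "expression_distance",
    "combined_factor",
    "permanova",
    "VarPartResult",
    "Permanova",
]


def expression_distance(expr: pd.DataFrame,
                        subset: list[str] | None = None) -> pd.DataFrame:
    """Euclidean distances between sample expression profiles."""
    if subset is not None:
        missing = set(subset) - set(expr.columns)
        if missing:
            raise ValueError(f"samples not in matrix: {sorted(missing)[:5]}")
        expr = expr[list(subset)]
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    d = squareform(pdist(expr.values.T, metric="euclidean"))
    return pd.DataFrame(d, index=expr.columns, columns=expr.columns)


def combined_factor(meta: pd.DataFrame) -> pd.Series:
    """Genotype x treatment interaction factor, e.g. ``G01.heat``."""
    out = meta["genotype"].astype(str) + "." + meta["treatment"].astype(str)
    out.name = "genotype_treatment"
    return out


def _gower_center(dist: np.ndarray) -> np.ndarray:
    a = -0.5 * dist ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def _term_projectors(factors: list[np.ndarray], n: int
                     ) -> tuple[list[np.ndarray], list[int], np.ndarray, int]:
    """Sequential difference projectors H_k - H_{k-1} and term df."""
    design = np.ones((n, 1))
    h_prev = _hat(design)
    rank_prev = 1
    projectors, dfs = [], []
    for labels in factors:
        dummies = pd.get_dummies(pd.Series(labels)).values.astype(float)
        design = np.hstack([design, dummies])
        rank = int(np.linalg.matrix_rank(design))
        h = _hat(design)
        projectors.append(h - h_prev)
        dfs.append(rank - rank_prev)
        h_prev, rank_prev = h, rank
    resid_proj = np.eye(n) - h_prev
    df_resid = n - rank_prev
    return projectors, dfs, resid_proj, df_resid


@dataclass
class VarPartResult:
    """ANOVA-style PERMANOVA table."""

    table: pd.DataFrame      # rows: terms, Residual, Total
    n_perm: int | str
    seed: int | None = None

    def summary(self) -> pd.DataFrame:
        return self.table.round(6)

    def r2(self, term: str) -> float:
        return float(self.table.loc[term, "R2"])


def permanova(dist: pd.DataFrame, factors: dict[str, pd.Series],
              n_perm: int | str = 999, seed: int | None = None
              ) -> VarPartResult:
    """Sequential PERMANOVA of a distance matrix on ordered factors.

    ``factors`` maps term name -> per-sample labels, fitted in insertion
    order (Type I sums of squares).  p-values use free permutation of sample
    labels: p = (#{F_perm >= F_obs} + 1) / (n_perm + 1).  ``n_perm="all"``
    enumerates every permutation exhaustively (small n only) and divides by
    n! without the +1 adjustment.
    """
    samples = dist.index
    n = len(samples)
    labels = []
    for name, f in factors.items():
        lab = pd.Series(f).reindex(samples)
        if lab.isna().any():
            raise ValueError(f"factor {name!r} missing labels for some samples")
        counts = lab.value_counts()
        if len(counts) < 2:
            raise ValueError(f"factor {name!r} has fewer than 2 levels")
        if (counts == 1).all():
            raise ValueError(f"factor {name!r} is fully confounded "
                             "(every level is a singleton)")
        labels.append(lab.values)
    if n_perm != "all" and int(n_perm) < 99:
        raise ValueError("n_perm must be >= 99 (or 'all')")

    g = _gower_center(dist.values.astype(float))
    projectors, dfs, resid_proj, df_resid = _term_projectors(labels, n)
    if df_resid <= 0:
        raise ValueError("model saturates the samples; no residual df")

    def stats(gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.array([float(np.tensordot(p, gm)) for p in projectors])
        ss_resid = float(np.tensordot(resid_proj, gm))
        return ss_terms, ss_resid

    ss_terms, ss_resid = stats(g)
    ss_total = float(np.trace(g))
    f_obs = (ss_terms / np.array(dfs)) / (ss_resid / df_resid)

    if n_perm == "all":
        if n > 8:
            raise ValueError("exhaustive permutation only supported for n <= 8")
        exceed = np.zeros(len(dfs))
        total = 0
        for perm in itertools.permutations(range(n)):
            gp = g[np.ix_(perm, perm)]
            ss_p, ss_r = stats(gp)
            f_p = (ss_p / np.array(dfs)) / (ss_r / df_resid)
            exceed += f_p >= f_obs - 1e-12
            total += 1
        pvals = exceed / total
        n_perm_out: int | str = "all"
        assert total == math.factorial(n)
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(dfs))
        for _ in range(int(n_perm)):
            perm = rng.permutation(n)
            gp = g[np.ix_(perm, perm)]
            ss_p, ss_r = stats(gp)
            f_p = (ss_p / np.array(dfs)) / (ss_r / df_resid)
            exceed += f_p >= f_obs - 1e-12
        pvals = (exceed + 1.0) / (int(n_perm) + 1.0)
        n_perm_out = int(n_perm)

    rows = []
    for name, df, ss, f, p in zip(factors, dfs, ss_terms, f_obs, pvals):
        rows.append({"term": name, "df": df, "SS": ss, "R2": ss / ss_total,
                     "F": f, "p": p})
    rows.append({"term": "Residual", "df": df_resid, "SS": ss_resid,
                 "R2": ss_resid / ss_total, "F": np.nan, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total, "R2": 1.0,
                 "F": np.nan, "p": np.nan})
    table = pd.DataFrame(rows).set_index("term")
    return VarPartResult(table=table, n_perm=n_perm_out, seed=seed)


class Permanova:
    """PERMANOVA model over an expression matrix or distance matrix.

    Parameters
    ----------
    data : genes x samples expression matrix (distances are Euclidean) or a
        precomputed sample x sample distance matrix (``is_distance=True``).
    factors : ordered mapping term name -> per-sample labels.
    """

    def __init__(self, data: pd.DataFrame, factors: dict[str, pd.Series],
                 is_distance: bool = False):
        self.dist = data if is_distance else expression_distance(data)
        self.factors = factors

    def fit(self, n_perm: int | str = 999, seed: int | None = None) -> VarPartResult:
        return permanova(self.dist, self.factors, n_perm=n_perm, seed=seed)
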