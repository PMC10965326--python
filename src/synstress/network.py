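"""Signed weighted co-expression network analysis.

Implements the WGCNA-style core: signed adjacency ``((1 + r) / 2) ** beta``,
topological overlap (TOM) smoothing, average-linkage clustering of
``1 - TOM`` with a height-based tree cut and a minimum module size, module
eigengenes (first principal component of each module's standardized
submatrix), module membership (kME), module-trait Pearson correlations, and
rank-based (Mann-Whitney) category enrichment on kME.

The model-style entry point is :class:`CoexpressionNetwork`; the
module-level functions expose each step individually.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu, pearsonr

__all__ = [
    "NetworkParams",
    "signed_adjacency",
    "tom_similarity",
    "detect_modules",
    "module_eigengenes",
    "EigengeneMatrix",
    "module_trait_correlations",
    "ModuleTraitCorrelation",
    "treatment_indicators",
    "module_membership_kme",
    "rank_enrichment",
    "CoexpressionNetwork",
    "CoexpressionResults",
]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class NetworkParams:
    """Network construction knobs.

    ``beta`` is the soft-threshold power of the signed adjacency;
    ``min_module_size`` is the smallest cluster kept as a module;
    ``cut_height`` is the dissimilarity at which the dendrogram is cut,
    expressed as a fraction of the dendrogram height range (0.99 by default,
    the community-standard tree-cut setting).  Module merging is not
    performed.
    """

    beta: int = 14
    min_module_size: int = 35
    merge_modules: bool = False
    cut_height: float = 0.99

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if self.merge_modules:
            raise NotImplementedError("module merging is not supported")
        if not 0.0 < self.cut_height <= 1.0:
            raise ValueError("cut_height must be in (0, 1]")


def _drop_zero_variance(expr: pd.DataFrame) -> pd.DataFrame:
    sd = expr.values.std(axis=1)
    bad = sd == 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} zero-variance gene(s)")
        expr = expr.loc[~bad]
    return expr


def signed_adjacency(expr: pd.DataFrame, beta: int = 14) -> pd.DataFrame:
    """Signed adjacency a_ij = ((1 + cor(x_i, x_j)) / 2) ** beta."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    expr = _drop_zero_variance(expr)
    corr = np.corrcoef(expr.values)
    adj = np.clip((1.0 + corr) / 2.0, 0.0, 1.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=expr.index, columns=expr.index)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with the
    sum over u != i, j and k_i the connectivity sum_{u != i} a_iu; TOM_ii = 1.
    """
    a = adjacency.values.astype(float)
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    shared = a0 @ a0
    k = a0.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a0
    tom = (shared + a0) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(tom: pd.DataFrame, params: NetworkParams | None = None
                   ) -> pd.Series:
    """Cluster genes into modules from the TOM.

    Average-linkage hierarchical clustering on ``1 - TOM``; the tree is cut
    at ``params.cut_height`` of the dendrogram height range and clusters
    smaller than ``min_module_size`` are labelled ``"unassigned"``.  Kept
    modules are named by decreasing size: M01, M02, ...
    """
    params = params or NetworkParams()
    genes = tom.index
    if len(genes) < params.min_module_size:
        return pd.Series(UNASSIGNED, index=genes, name="module")
    dissim = 1.0 - tom.values
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    heights = z[:, 2]
    cut = heights.min() + params.cut_height * (heights.max() - heights.min())
    raw = fcluster(z, t=cut, criterion="distance")
    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    kept = sizes[sizes >= params.min_module_size]
    # deterministic naming: by decreasing size, ties by first gene position
    first_pos = {c: int(np.argmax(raw == c)) for c in kept.index}
    order = sorted(kept.index, key=lambda c: (-kept[c], first_pos[c]))
    rename = {c: f"M{i + 1:02d}" for i, c in enumerate(order)}
    out = labels.map(lambda c: rename.get(c, UNASSIGNED))
    out.name = "module"
    return out


@dataclass
class EigengeneMatrix:
    """Samples x modules eigengene scores with per-module variance explained."""

    scores: pd.DataFrame
    var_explained: pd.Series

    @property
    def modules(self) -> list[str]:
        return list(self.scores.columns)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    return (x - mu) / sd


def module_eigengenes(expr: pd.DataFrame, assignment: pd.Series
                      ) -> EigengeneMatrix:
    """First principal component of each module's standardized submatrix.

    Each eigengene is scaled to unit sample variance and oriented so that
    its correlation with the module's mean standardized expression profile
    is non-negative.  Zero-variance member genes are dropped with a warning.
    """
    assignment = assignment.reindex(expr.index)
    modules = sorted(m for m in assignment.dropna().unique() if m != UNASSIGNED)
    cols, var_exp = {}, {}
    for m in modules:
        sub = expr.loc[assignment == m]
        sub = _drop_zero_variance(sub)
        if sub.shape[0] == 0:
            raise ValueError(f"module {m} has no genes with variance")
        x = _standardize_rows(sub.values)          # genes x samples
        u, s, _ = np.linalg.svd(x.T, full_matrices=False)
        e = u[:, 0]
        mean_profile = x.mean(axis=0)
        c = float(np.dot(e - e.mean(), mean_profile - mean_profile.mean()))
        if c < 0:
            e = -e
        e = e / e.std(ddof=1)
        cols[m] = e
        var_exp[m] = float(s[0] ** 2 / (s ** 2).sum())
    scores = pd.DataFrame(cols, index=expr.columns)
    return EigengeneMatrix(scores=scores,
                           var_explained=pd.Series(var_exp, name="var_explained"))


@dataclass
class ModuleTraitCorrelation:
    """Module x trait Pearson correlations with Student-t p-values."""

    r: pd.DataFrame
    p: pd.DataFrame

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.p <= alpha


def treatment_indicators(meta: pd.DataFrame, scheme: str = "one-vs-rest"
                         ) -> pd.DataFrame:
    """0/1 indicator columns per treatment level.

    ``one-vs-rest`` codes each treatment against all other samples;
    ``one-vs-control`` codes it against control samples only (other samples
    are NaN and pairwise-dropped in correlations).
    """
    levels = sorted(meta["treatment"].unique())
    out = {}
    for t in levels:
        ind = (meta["treatment"] == t).astype(float)
        if scheme == "one-vs-control" and t != "control":
            ind = ind.where(meta["treatment"].isin([t, "control"]))
        elif scheme not in ("one-vs-rest", "one-vs-control"):
            raise ValueError(f"unknown scheme {scheme!r}")
        out[t] = ind
    return pd.DataFrame(out, index=meta.index)


def module_trait_correlations(eigengenes: EigengeneMatrix | pd.DataFrame,
                              traits: pd.DataFrame) -> ModuleTraitCorrelation:
    """Pearson r and p per module x trait, pairwise-dropping missing values."""
    scores = eigengenes.scores if isinstance(eigengenes, EigengeneMatrix) else eigengenes
    traits = traits.reindex(scores.index)
    r = pd.DataFrame(index=scores.columns, columns=traits.columns, dtype=float)
    p = pd.DataFrame(index=scores.columns, columns=traits.columns, dtype=float)
    for trait in traits.columns:
        y = traits[trait]
        ok = y.notna()
        for m in scores.columns:
            x, yy = scores.loc[ok, m], y[ok]
            if len(yy) < 4 or yy.std() == 0 or x.std() == 0:
                continue  # undefined; left missing
            res = pearsonr(x, yy)
            r.loc[m, trait] = res.statistic
            p.loc[m, trait] = res.pvalue
    return ModuleTraitCorrelation(r=r, p=p)


def module_membership_kme(expr: pd.DataFrame,
                          eigengenes: EigengeneMatrix | pd.DataFrame
                          ) -> pd.DataFrame:
    """kME_gm = cor(gene g, eigengene m) for every gene and module."""
    scores = eigengenes.scores if isinstance(eigengenes, EigengeneMatrix) else eigengenes
    expr = _drop_zero_variance(expr)
    x = _standardize_rows(expr.values)
    e = scores.loc[expr.columns].values
    e = (e - e.mean(axis=0)) / e.std(axis=0, ddof=1)
    n = x.shape[1]
    kme = (x @ e) / (n - 1)
    return pd.DataFrame(np.clip(kme, -1.0, 1.0), index=expr.index,
                        columns=scores.columns)


def rank_enrichment(kme_column: pd.Series,
                    categories: dict[str, set[str] | list[str]]) -> pd.DataFrame:
    """Mann-Whitney U test of in-category vs out-of-category kME.

    Two-sided; exact null for small tie-free categories, normal
    approximation with tie and continuity correction otherwise.  Returns a
    DataFrame with columns ``n_in``, ``U``, ``p``.
    """
    universe = kme_column.dropna()
    rows = {}
    for name, members in categories.items():
        members = set(members) & set(universe.index)
        if len(members) < 2:
            raise ValueError(f"category {name!r} has fewer than 2 genes in universe")
        if len(members) >= len(universe):
            raise ValueError(f"category {name!r} equals the whole gene universe")
        mask = universe.index.isin(members)
        x, y = universe[mask], universe[~mask]
        method = "exact" if min(len(x), len(y)) <= 25 and \
            len(np.unique(universe.values)) == len(universe) else "asymptotic"
        res = mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows[name] = {"n_in": len(x), "U": float(res.statistic),
                      "p": float(res.pvalue)}
    return pd.DataFrame.from_dict(rows, orient="index")


class CoexpressionNetwork:
    """Signed co-expression network model of a log-expression matrix.

    Parameters
    ----------
    expr : DataFrame, genes x samples normalized log expression.
    params : NetworkParams, network construction settings.
    """

    def __init__(self, expr: pd.DataFrame, params: NetworkParams | None = None):
        self.expr = expr
        self.params = params or NetworkParams()

    def fit(self) -> "CoexpressionResults":
        adj = signed_adjacency(self.expr, self.params.beta)
        tom = tom_similarity(adj)
        assignment = detect_modules(tom, self.params)
        expr = self.expr.loc[assignment.index]
        eig = module_eigengenes(expr, assignment)
        kme = module_membership_kme(expr, eig)
        return CoexpressionResults(model=self, expr=expr, assignment=assignment,
                                   eigengenes=eig, kme=kme)


@dataclass
class CoexpressionResults:
    model: CoexpressionNetwork
    expr: pd.DataFrame
    assignment: pd.Series
    eigengenes: EigengeneMatrix
    kme: pd.DataFrame
    _trait_corr: ModuleTraitCorrelation | None = field(default=None, repr=False)

    @property
    def module_sizes(self) -> pd.Series:
        sizes = self.assignment[self.assignment != UNASSIGNED].value_counts()
        return sizes.sort_index()

    def trait_correlations(self, traits: pd.DataFrame) -> ModuleTraitCorrelation:
        self._trait_corr = module_trait_correlations(self.eigengenes, traits)
        return self._trait_corr

    def enrichment(self, module: str,
                   categories: dict[str, set[str]]) -> pd.DataFrame:
        return rank_enrichment(self.kme[module], categories)

    def summary(self) -> pd.DataFrame:
        sizes = self.module_sizes
        return pd.DataFrame({
            "size": sizes,
            "var_explained": self.eigengenes.var_explained.reindex(sizes.index),
        })
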