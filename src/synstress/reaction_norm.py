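"""DAPC ordination and expression reaction norms.

Discriminant analysis of principal components (DAPC) reduces the expression
matrix by PCA and fits a linear discriminant analysis to predefined groups
(by default genotype x treatment combinations).  The discriminant axis that
best separates treatment from control is used as a one-dimensional summary
of the stress response; each genotype's baseline expression is the median of
its control samples along that axis, and each treated sample's plasticity is
its signed displacement from its genotype's baseline.  Baseline and
plasticity are then regressed on symbiont density retention — the bleaching
phenotype, defined per treated sample as its density minus the mean control
density of the same genotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "DapcModel",
    "fit_dapc",
    "select_treatment_axis",
    "baseline_and_plasticity",
    "ReactionNormResult",
    "symbiont_retention",
    "regress_performance",
    "RegressionResult",
    "Dapc",
    "ReactionNorm",
    "ReactionNormResults",
]


@dataclass
class DapcModel:
    """Fitted DAPC: per-sample scores on each discriminant axis."""

    n_pcs: int
    scores: pd.DataFrame          # samples x LD axes
    groups: pd.Series
    pca: PCA = field(repr=False, default=None)
    lda: LinearDiscriminantAnalysis = field(repr=False, default=None)

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


def fit_dapc(expr: pd.DataFrame, groups: pd.Series,
             n_pcs: int | str = "auto") -> DapcModel:
    """PCA followed by LDA on the retained principal-component scores.

    ``n_pcs="auto"`` retains the smallest number of components explaining
    >= 80% of the variance, capped at n_samples / 3 (a guard against
    overfitting the discriminant axes).
    """
    groups = groups.reindex(expr.columns)
    if groups.isna().any():
        raise ValueError("groups missing for some samples")
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        # singleton groups contribute a mean but no within-group scatter;
        # fine for pooled-covariance LDA, but worth surfacing
        small = counts[counts < 2]
        warnings.warn(f"groups with a single sample: {list(small.index)}")
    x = expr.values.T                      # samples x genes
    n = x.shape[0]
    max_pcs = min(n - 1, x.shape[1])
    pca = PCA(n_components=max_pcs, svd_solver="full", random_state=0)
    pc_scores = pca.fit_transform(x - x.mean(axis=0))
    if n_pcs == "auto":
        cum = np.cumsum(pca.explained_variance_ratio_)
        wanted = int(np.searchsorted(cum, 0.80) + 1)
        n_pcs = max(1, min(wanted, max(1, n // 3)))
    n_pcs = int(n_pcs)
    if not 1 <= n_pcs <= max_pcs:
        raise ValueError(f"n_pcs must be in [1, {max_pcs}]")
    lda = LinearDiscriminantAnalysis(solver="svd")
    lda.fit(pc_scores[:, :n_pcs], groups.values)
    ld_scores = lda.transform(pc_scores[:, :n_pcs])
    cols = [f"LD{i + 1}" for i in range(ld_scores.shape[1])]
    scores = pd.DataFrame(ld_scores, index=expr.columns, columns=cols)
    return DapcModel(n_pcs=n_pcs, scores=scores, groups=groups, pca=pca, lda=lda)


def select_treatment_axis(model: DapcModel, is_treated: pd.Series
                          ) -> tuple[int, int]:
    """Pick the LD axis best separating treated from control samples.

    Returns ``(axis_index, orientation)`` where the axis maximizes the
    absolute point-biserial correlation between score and the 0/1 treatment
    indicator, and orientation (+1/-1) makes the treated-group mean exceed
    the control-group mean (positive = toward the stress response).  Ties go
    to the lower axis index.
    """
    ind = is_treated.reindex(model.scores.index).astype(float)
    if ind.isna().any():
        raise ValueError("treatment indicator missing for some samples")
    best_axis, best_r = 0, -1.0
    for i in range(model.n_axes):
        s = model.scores.iloc[:, i]
        r = abs(np.corrcoef(s, ind)[0, 1])
        if r > best_r + 1e-12:
            best_axis, best_r = i, r
    s = model.scores.iloc[:, best_axis]
    orientation = 1 if s[ind == 1].mean() >= s[ind == 0].mean() else -1
    return best_axis, orientation


@dataclass
class ReactionNormResult:
    """Genotype baselines and per-sample plasticities on one oriented axis."""

    axis: int
    orientation: int
    baseline: pd.Series       # genotype -> median oriented control score
    plasticity: pd.Series     # treated sample -> oriented score - own baseline

    def genotype_mean_plasticity(self, meta: pd.DataFrame) -> pd.Series:
        geno = meta["genotype"].reindex(self.plasticity.index)
        return self.plasticity.groupby(geno).mean()


def baseline_and_plasticity(model: DapcModel, axis: int, orientation: int,
                            meta: pd.DataFrame,
                            baseline_stat: str = "median") -> ReactionNormResult:
    """Extract reaction-norm components from oriented DAPC scores.

    ``baseline_stat`` is ``"median"`` (default) or ``"mean"``; with the mean
    the identity baseline + mean(plasticity) = mean treated score holds
    exactly per genotype.
    """
    scores = orientation * model.scores.iloc[:, axis]
    meta = meta.reindex(scores.index)
    is_ctrl = meta["treatment"] == "control"
    stat = {"median": np.median, "mean": np.mean}[baseline_stat]
    baseline = {}
    for geno, idx in meta.groupby("genotype").groups.items():
        ctrl_scores = scores[idx][is_ctrl[idx]]
        if ctrl_scores.empty:
            warnings.warn(f"genotype {geno} has no control samples; excluded")
            continue
        baseline[geno] = float(stat(ctrl_scores.values))
    baseline = pd.Series(baseline, name="baseline")
    treated = scores.index[~is_ctrl]
    plasticity = {}
    for s in treated:
        geno = meta.at[s, "genotype"]
        if geno in baseline.index:
            plasticity[s] = float(scores[s] - baseline[geno])
    return ReactionNormResult(axis=axis, orientation=orientation,
                              baseline=baseline,
                              plasticity=pd.Series(plasticity, name="plasticity"))


def symbiont_retention(traits: pd.DataFrame, meta: pd.DataFrame,
                       treatment: str,
                       trait: str = "symbiont_density_per_cm2") -> pd.Series:
    """Per-sample symbiont density retained relative to genotype control mean.

    retention_i = density_i - mean(control densities of genotype(i)); defined
    only for samples of the requested treatment whose genotype has at least
    one control measurement.
    """
    density = traits[trait].reindex(meta.index)
    if (density.dropna() < 0).any():
        raise ValueError("symbiont densities must be nonnegative")
    ctrl = density[(meta["treatment"] == "control") & density.notna()]
    ctrl_mean = ctrl.groupby(meta["genotype"]).mean()
    out = {}
    for s in meta.index[meta["treatment"] == treatment]:
        geno = meta.at[s, "genotype"]
        if geno not in ctrl_mean.index:
            warnings.warn(f"genotype {geno} has no control trait values; excluded")
            continue
        if pd.notna(density[s]):
            out[s] = float(density[s] - ctrl_mean[geno])
    return pd.Series(out, name="retention")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    pvalue: float       # two-sided t-test on the slope
    n: int


def regress_performance(x: pd.Series, y: pd.Series) -> RegressionResult:
    """OLS of performance ``y`` on expression summary ``x`` (aligned by index)."""
    df = pd.concat([x.rename("x"), y.rename("y")], axis=1).dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 paired observations")
    if df["x"].std() == 0:
        raise ValueError("zero variance in predictor")
    fit = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
    return RegressionResult(
        slope=float(fit.params["x"]), intercept=float(fit.params["const"]),
        r2=float(fit.rsquared), adj_r2=float(fit.rsquared_adj),
        pvalue=float(fit.pvalues["x"]), n=int(len(df)),
    )


class Dapc:
    """DAPC model of an expression matrix with predefined groups."""

    def __init__(self, expr: pd.DataFrame, groups: pd.Series,
                 n_pcs: int | str = "auto"):
        self.expr = expr
        self.groups = groups
        self.n_pcs = n_pcs

    def fit(self) -> DapcModel:
        return fit_dapc(self.expr, self.groups, self.n_pcs)


class ReactionNorm:
    """Baseline/plasticity decomposition for one control-vs-treatment contrast.

    Parameters
    ----------
    expr : genes x samples normalized log expression.
    meta : sample metadata with ``genotype`` and ``treatment`` columns.
    traits : per-sample trait table with symbiont densities.
    treatment : focal stress treatment contrasted with control.
    genes : optional gene subset (e.g. one module's members).
    groups : "genotype_treatment" (default) or "treatment" DAPC grouping.
    """

    def __init__(self, expr: pd.DataFrame, meta: pd.DataFrame,
                 traits: pd.DataFrame | None, treatment: str,
                 genes: list[str] | None = None,
                 groups: str = "genotype_treatment",
                 n_pcs: int | str = "auto",
                 baseline_stat: str = "median"):
        keep = meta.index[meta["treatment"].isin(["control", treatment])]
        keep = [s for s in keep if s in expr.columns]
        self.expr = expr.loc[genes if genes is not None else expr.index, keep]
        self.meta = meta.loc[keep]
        self.traits = traits
        self.treatment = treatment
        self.grouping = groups
        self.n_pcs = n_pcs
        self.baseline_stat = baseline_stat

    def fit(self) -> "ReactionNormResults":
        if self.grouping == "genotype_treatment":
            groups = self.meta["genotype"] + "." + self.meta["treatment"]
        elif self.grouping == "treatment":
            groups = self.meta["treatment"]
        else:
            raise ValueError(f"unknown grouping {self.grouping!r}")
        model = fit_dapc(self.expr, groups, self.n_pcs)
        is_treated = (self.meta["treatment"] == self.treatment).astype(int)
        axis, orientation = select_treatment_axis(model, is_treated)
        rn = baseline_and_plasticity(model, axis, orientation, self.meta,
                                     self.baseline_stat)
        retention = baseline_reg = plasticity_reg = None
        if self.traits is not None:
            retention = symbiont_retention(self.traits, self.meta, self.treatment)
            geno = self.meta["genotype"]
            geno_retention = retention.groupby(geno.reindex(retention.index)).mean()
            baseline_reg = regress_performance(rn.baseline, geno_retention)
            plasticity_reg = regress_performance(rn.plasticity, retention)
        return ReactionNormResults(
            model=model, norm=rn, treatment=self.treatment,
            retention=retention, baseline_regression=baseline_reg,
            plasticity_regression=plasticity_reg, meta=self.meta,
        )


@dataclass
class ReactionNormResults:
    model: DapcModel
    norm: ReactionNormResult
    treatment: str
    meta: pd.DataFrame
    retention: pd.Series | None = None
    baseline_regression: RegressionResult | None = None
    plasticity_regression: RegressionResult | None = None

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, reg in (("baseline~retention (genotype)", self.baseline_regression),
                          ("plasticity~retention (sample)", self.plasticity_regression)):
            if reg is not None:
                rows.append({"regression": name, "slope": reg.slope,
                             "intercept": reg.intercept, "R2": reg.r2,
                             "adj_R2": reg.adj_r2, "p": reg.pvalue, "n": reg.n})
        return pd.DataFrame(rows)
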