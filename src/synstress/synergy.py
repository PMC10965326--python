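"""Additive-null synergy test on module eigengenes.

For each module, the expected additive median under the combined treatment is

    mu = med_ctrl + (med_heat - med_ctrl) + (med_pH - med_ctrl)

i.e. the control median plus the sum of the single-stressor median shifts.
The combined-treatment eigengene values are then tested against ``mu`` with
a one-sample Wilcoxon signed-rank test, one-tailed in the direction of the
expected shift: a small p-value means the combined response overshoots the
additive expectation (synergy); antagonistic modules give p near 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .network import EigengeneMatrix, ModuleTraitCorrelation

__all__ = [
    "additive_expectation",
    "wilcoxon_signed_rank_one_sample",
    "WilcoxonResult",
    "synergy_test",
    "select_synergy_candidates",
    "SynergyTest",
    "SynergyResults",
]

EXACT_MAX_N = 14


def additive_expectation(values: pd.Series, treatment: pd.Series
                         ) -> tuple[float, dict[str, float]]:
    """Group medians per treatment and the additive expected median ``mu``."""
    treatment = treatment.reindex(values.index)
    medians = {}
    for t in ("control", "heat", "pH", "combined"):
        group = values[treatment == t]
        if t != "combined" and group.empty:
            raise ValueError(f"missing treatment group {t!r}")
        medians[t] = float(group.median()) if not group.empty else float("nan")
    mu = medians["heat"] + medians["pH"] - medians["control"]
    return mu, medians


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float        # W+ (sum of positive signed ranks)
    pvalue: float
    n: int                  # observations used after dropping zeros
    method: str             # "exact" or "approx"


def _exact_sf_counts(n: int) -> np.ndarray:
    """Counts of the null W+ distribution over 0..n(n+1)/2 (tie-free case)."""
    counts = np.zeros(n * (n + 1) // 2 + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank_one_sample(x, mu: float = 0.0,
                                    alternative: str = "two-sided"
                                    ) -> WilcoxonResult:
    """One-sample Wilcoxon signed-rank test of location ``mu``.

    Differences equal to ``mu`` are dropped (Wilcoxon convention).  The exact
    null distribution (full enumeration over sign assignments) is used for
    tie-free samples with n <= 14; otherwise a normal approximation with tie
    and continuity correction.  ``alternative`` in {"greater", "less",
    "two-sided"} refers to the location of ``x`` relative to ``mu``.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = np.asarray(x, dtype=float) - mu
    if d.size == 0:
        raise ValueError("empty sample")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn("all observations equal mu; p = 1")
        return WilcoxonResult(statistic=0.0, pvalue=1.0, n=0, method="degenerate")
    absd = np.abs(d)
    ranks = rankdata(absd)
    w_plus = float(ranks[d > 0].sum())
    has_ties = len(np.unique(absd)) < n
    if n <= EXACT_MAX_N and not has_ties:
        counts = _exact_sf_counts(n)
        total = 2.0 ** n
        w = int(round(w_plus))
        p_greater = counts[w:].sum() / total
        p_less = counts[: w + 1].sum() / total
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
        return WilcoxonResult(statistic=w_plus, pvalue=float(p), n=n, method="exact")
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(absd, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts ** 3 - tie_counts).sum() / 48.0
    sd = np.sqrt(var)
    p_greater = norm.sf((w_plus - 0.5 - mean) / sd)
    p_less = norm.cdf((w_plus + 0.5 - mean) / sd)
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return WilcoxonResult(statistic=w_plus, pvalue=float(p), n=n, method="approx")


def synergy_test(eigengenes: EigengeneMatrix | pd.DataFrame, meta: pd.DataFrame,
                 modules: list[str] | None = None) -> pd.DataFrame:
    """Test each module's combined-treatment response against the additive null.

    The one-tailed alternative follows the expected direction: ``greater``
    when mu > med_ctrl (expected up-regulation), ``less`` when mu < med_ctrl,
    two-sided in the degenerate mu = med_ctrl case.  Returns one row per
    module with medians, mu, direction, W, raw p and Bonferroni-adjusted p.
    """
    scores = eigengenes.scores if isinstance(eigengenes, EigengeneMatrix) else eigengenes
    treatment = meta["treatment"].reindex(scores.index)
    if not set(("control", "heat", "pH", "combined")) <= set(treatment.dropna()):
        raise ValueError("all four treatments must be present")
    modules = list(modules) if modules is not None else list(scores.columns)
    rows = []
    for m in modules:
        values = scores[m]
        mu, med = additive_expectation(values, treatment)
        combined = values[treatment == "combined"].dropna()
        if len(combined) < 3:
            warnings.warn(f"module {m}: fewer than 3 combined samples (low power)")
        if mu > med["control"]:
            direction, alternative = "up", "greater"
        elif mu < med["control"]:
            direction, alternative = "down", "less"
        else:
            direction, alternative = "none", "two-sided"
        res = wilcoxon_signed_rank_one_sample(combined.values, mu, alternative)
        rows.append({
            "module": m, "n": len(combined),
            "med_ctrl": med["control"], "med_heat": med["heat"],
            "med_pH": med["pH"], "med_combined": med["combined"],
            "mu": mu, "direction": direction,
            "W": res.statistic, "p_raw": res.pvalue,
        })
    out = pd.DataFrame(rows).set_index("module")
    out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * len(out))
    return out


def select_synergy_candidates(module_sizes: pd.Series,
                              trait_corr: ModuleTraitCorrelation,
                              alpha: float = 0.05, top_n: int | None = 15
                              ) -> list[str]:
    """Modules significantly correlated with every treatment indicator.

    Optionally restricted to the ``top_n`` largest modules (the reporting
    convention of focusing on large, well-annotated modules); pass
    ``top_n=None`` to consider all modules.
    """
    treatments = [c for c in trait_corr.p.columns
                  if c in ("control", "heat", "pH", "combined")]
    pool = module_sizes.sort_values(ascending=False)
    if top_n is not None:
        pool = pool.iloc[:top_n]
    keep = []
    for m in pool.index:
        pvals = trait_corr.p.loc[m, treatments]
        if pvals.notna().all() and (pvals <= alpha).all():
            keep.append(m)
    return keep


class SynergyTest:
    """Additive-null synergy model over an eigengene matrix.

    Parameters
    ----------
    eigengenes : EigengeneMatrix or samples x modules DataFrame.
    meta : sample metadata with a ``treatment`` column.
    modules : optional subset of modules to test.
    """

    def __init__(self, eigengenes, meta: pd.DataFrame,
                 modules: list[str] | None = None):
        self.eigengenes = eigengenes
        self.meta = meta
        self.modules = modules

    def fit(self) -> "SynergyResults":
        return SynergyResults(synergy_test(self.eigengenes, self.meta, self.modules))


@dataclass
class SynergyResults:
    table: pd.DataFrame

    def significant(self, alpha: float = 0.05, adjusted: bool = False) -> pd.DataFrame:
        col = "p_bonferroni" if adjusted else "p_raw"
        return self.table[self.table[col] <= alpha]

    def summary(self) -> pd.DataFrame:
        cols = ["n", "med_ctrl", "med_heat", "med_pH", "med_combined",
                "mu", "direction", "W", "p_raw", "p_bonferroni"]
        out = self.table[cols].copy()
        for c in ("med_ctrl", "med_heat", "med_pH", "med_combined", "mu", "W"):
            out[c] = out[c].round(6)
        return out
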