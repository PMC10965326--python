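"""Synthetic multi-stressor RNA-seq experiments with planted ground truth.

The generator emulates a common-garden stress experiment: clonal replicates
of ``n_genotypes`` genotypes are exposed to one of four treatments
(``control``, ``heat``, ``pH``, ``combined``).  Genes are organised into
co-expressed modules whose log-scale activity responds to treatment; the
response in the combined treatment may exceed the sum of the single-stressor
responses (synergy).  Genotypes differ in baseline module activity and in a
multiplicative plasticity scalar, and a bleaching-like phenotype (symbiont
density retention) is linearly coupled to those genotype parameters.

Counts are negative binomial with a shared dispersion; sample library sizes
are log-normal.  Every planted parameter is recorded in
:class:`SimulationTruth` so downstream estimators can be validated by
parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TREATMENTS = ("control", "heat", "pH", "combined")
STRESSORS = ("heat", "pH")

__all__ = [
    "TREATMENTS",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_experiment",
    "write_fixture",
    "read_fixture",
]


def _default_treatment_effects() -> tuple[dict[str, float], ...]:
    # Three planted modules mirroring the archetypes seen in coral
    # multi-stressor data: one up-regulated synergistic, one down-regulated
    # synergistic, one heat-dominated and purely additive.
    return (
        {"heat": 0.4, "pH": 0.2},
        {"heat": -0.4, "pH": -0.2},
        {"heat": 0.6, "pH": 0.1},
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated experiment.

    ``treatment_effects[m][t]`` is the log-scale activity shift of module
    ``m`` under single stressor ``t``; ``synergy_coeffs[m]`` is the extra
    log-scale shift in the combined treatment beyond the additive sum.
    ``dropout_rate`` may be a scalar or a per-treatment mapping; dropout
    removes whole samples (stratified so no genotype x treatment cell is
    emptied).  ``phenotype_coeffs`` is (intercept, slope_baseline,
    slope_plasticity, noise_sd) in cells/cm^2.
    """

    n_genes: int = 2000
    n_genotypes: int = 11
    replicates_per_cell: int = 5
    dropout_rate: float | Mapping[str, float] = 0.14
    module_sizes: Sequence[int] = (300, 200, 120)
    treatment_effects: Sequence[Mapping[str, float]] = field(
        default_factory=_default_treatment_effects
    )
    synergy_coeffs: Sequence[float] = (0.6, -0.6, 0.0)
    genotype_baseline_sd: float = 0.3
    genotype_plasticity_sd: float = 0.25
    nb_dispersion: float = 0.25
    library_size_lognormal_sd: float = 0.3
    loading_jitter_sd: float = 0.0
    phenotype_coeffs: Sequence[float] = (-2.0e5, 3.0e5, -2.0e5, 5.0e4)
    control_density: float = 1.0e6
    control_density_genotype_sd: float = 8.0e4
    base_mean_log_mu: float = math.log(50.0)
    base_mean_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_genotypes < 1 or self.replicates_per_cell < 1:
            raise ValueError("n_genes, n_genotypes and replicates_per_cell must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"sum(module_sizes)={sum(self.module_sizes)} exceeds n_genes={self.n_genes}"
            )
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if len(self.treatment_effects) != len(self.module_sizes):
            raise ValueError("treatment_effects must have one entry per module")
        if len(self.synergy_coeffs) != len(self.module_sizes):
            raise ValueError("synergy_coeffs must have one entry per module")
        for rate in self._dropout_rates().values():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"dropout rate {rate} outside [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for name in ("genotype_baseline_sd", "genotype_plasticity_sd",
                     "library_size_lognormal_sd", "loading_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        flat = [v for eff in self.treatment_effects for v in eff.values()]
        flat += list(self.synergy_coeffs) + list(self.phenotype_coeffs)
        if not all(math.isfinite(v) for v in flat):
            raise ValueError("non-finite parameter value")
        if len(self.phenotype_coeffs) != 4:
            raise ValueError("phenotype_coeffs must be (intercept, slope_baseline, "
                             "slope_plasticity, noise_sd)")

    def _dropout_rates(self) -> dict[str, float]:
        if isinstance(self.dropout_rate, Mapping):
            return {t: float(self.dropout_rate.get(t, 0.0)) for t in TREATMENTS}
        return {t: float(self.dropout_rate) for t in TREATMENTS}

    @property
    def module_names(self) -> list[str]:
        return [f"M{i + 1}" for i in range(len(self.module_sizes))]

    @property
    def genotype_names(self) -> list[str]:
        return [f"G{i + 1:02d}" for i in range(self.n_genotypes)]


@dataclass
class SimulationTruth:
    """Planted parameters of one simulated experiment.

    ``delta`` holds the log-scale activity shift of each module in each
    treatment; by construction
    ``delta[m, combined] = delta[m, heat] + delta[m, pH] + synergy[m]``.
    Module activity of module ``m`` in a sample of genotype ``j`` under
    treatment ``t`` is ``A = baseline[j] + plasticity[j] * delta[m, t]``.
    """

    gene_modules: pd.Series            # gene id -> module label ("background" allowed)
    baseline: pd.Series                # genotype -> additive offset a_j
    plasticity: pd.Series              # genotype -> multiplicative scalar g_j
    delta: pd.DataFrame                # module x treatment activity shifts
    synergy: pd.Series                 # module -> synergy coefficient s_m
    expected_retention: pd.Series      # treated sample -> expected retention (cells/cm^2)

    def module_activity(self, module: str, genotype: str, treatment: str) -> float:
        return float(
            self.baseline[genotype]
            + self.plasticity[genotype] * self.delta.loc[module, treatment]
        )

    def to_dict(self) -> dict:
        return {
            "gene_modules": self.gene_modules.to_dict(),
            "baseline": self.baseline.to_dict(),
            "plasticity": self.plasticity.to_dict(),
            "delta": {m: self.delta.loc[m].to_dict() for m in self.delta.index},
            "synergy": self.synergy.to_dict(),
            "expected_retention": self.expected_retention.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        delta = pd.DataFrame.from_dict(d["delta"], orient="index")[list(TREATMENTS)]
        delta.index.name = "module"
        return cls(
            gene_modules=pd.Series(d["gene_modules"], name="module"),
            baseline=pd.Series(d["baseline"], name="baseline", dtype=float),
            plasticity=pd.Series(d["plasticity"], name="plasticity", dtype=float),
            delta=delta,
            synergy=pd.Series(d["synergy"], name="synergy", dtype=float),
            expected_retention=pd.Series(
                d["expected_retention"], name="expected_retention", dtype=float
            ),
        )


def _planted_delta(config: SimulationConfig) -> pd.DataFrame:
    rows = {}
    for name, eff, s in zip(config.module_names, config.treatment_effects,
                            config.synergy_coeffs):
        heat = float(eff.get("heat", 0.0))
        ph = float(eff.get("pH", 0.0))
        rows[name] = {
            "control": 0.0,
            "heat": heat,
            "pH": ph,
            "combined": heat + ph + float(s),
        }
    delta = pd.DataFrame.from_dict(rows, orient="index")[list(TREATMENTS)]
    delta.index.name = "module"
    return delta


def _apply_dropout(meta: pd.DataFrame, rates: Mapping[str, float],
                   rng: np.random.Generator) -> pd.DataFrame:
    """Remove whole samples per treatment at the requested rate.

    Removal counts are deterministic (``round(rate * n)``); which samples go
    is random but stratified so no genotype x treatment cell is emptied
    unless the rate forces it.
    """
    keep = pd.Series(True, index=meta.index)
    for t, rate in rates.items():
        idx = meta.index[meta["treatment"] == t]
        n_remove = int(round(rate * len(idx)))
        if n_remove == 0:
            continue
        order = rng.permutation(len(idx))
        cell_counts = meta.loc[idx].groupby("genotype").size().to_dict()
        removed = 0
        for pos in order:
            if removed == n_remove:
                break
            sample = idx[pos]
            g = meta.at[sample, "genotype"]
            if cell_counts[g] <= 1:
                continue
            keep[sample] = False
            cell_counts[g] -= 1
            removed += 1
        if removed < n_remove:  # stratification exhausted; drop unconditionally
            for pos in order:
                if removed == n_remove:
                    break
                sample = idx[pos]
                if keep[sample]:
                    keep[sample] = False
                    removed += 1
    return meta.loc[keep].copy()


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Simulate one experiment.

    Returns ``(counts, metadata, traits, truth)`` where ``counts`` is a
    genes x samples integer DataFrame, ``metadata`` has columns
    ``genotype``/``treatment``/``replicate`` indexed by sample id, ``traits``
    has ``symbiont_density_per_cm2`` indexed by sample id, and ``truth``
    records every planted parameter.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genotypes = config.genotype_names
    modules = config.module_names
    delta = _planted_delta(config)

    a = pd.Series(rng.normal(0.0, config.genotype_baseline_sd, len(genotypes)),
                  index=genotypes, name="baseline")
    g = pd.Series(np.exp(rng.normal(0.0, config.genotype_plasticity_sd, len(genotypes))),
                  index=genotypes, name="plasticity")

    # gene -> module assignment: modules occupy the leading genes
    gene_ids = [f"gene{i + 1:05d}" for i in range(config.n_genes)]
    labels = np.array(["background"] * config.n_genes, dtype=object)
    start = 0
    for name, size in zip(modules, config.module_sizes):
        labels[start:start + size] = name
        start += size
    gene_modules = pd.Series(labels, index=gene_ids, name="module")

    base_log_mean = rng.normal(config.base_mean_log_mu, config.base_mean_log_sd,
                               config.n_genes)
    loading = np.where(labels != "background", 1.0, 0.0)
    if config.loading_jitter_sd > 0:
        loading = loading * (1.0 + rng.normal(0.0, config.loading_jitter_sd,
                                              config.n_genes))

    # full design before dropout
    records = []
    for geno in genotypes:
        for t in TREATMENTS:
            for r in range(1, config.replicates_per_cell + 1):
                records.append((f"{geno}_{t}_r{r}", geno, t, r))
    meta = pd.DataFrame(records, columns=["sample", "genotype", "treatment",
                                          "replicate"]).set_index("sample")
    meta = _apply_dropout(meta, config._dropout_rates(), rng)
    samples = meta.index.to_numpy()

    lib = np.exp(rng.normal(0.0, config.library_size_lognormal_sd, len(samples)))

    # module activity per sample: A[m] = a_j + g_j * delta[m, t]
    activity = np.zeros((len(modules), len(samples)))
    for si, s in enumerate(samples):
        geno, t = meta.at[s, "genotype"], meta.at[s, "treatment"]
        for mi, m in enumerate(modules):
            activity[mi, si] = a[geno] + g[geno] * delta.loc[m, t]

    module_idx = np.full(config.n_genes, -1)
    for mi, m in enumerate(modules):
        module_idx[labels == m] = mi
    gene_activity = np.zeros((config.n_genes, len(samples)))
    member = module_idx >= 0
    gene_activity[member] = activity[module_idx[member]]

    log_mu = (base_log_mean[:, None] + loading[:, None] * gene_activity
              + np.log(lib)[None, :])
    mu = np.exp(log_mu)
    r_nb = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    counts_df.index.name = "gene_id"

    # phenotype: symbiont density; retention coupled to genotype parameters
    c0, cb, cp, noise_sd = (float(v) for v in config.phenotype_coeffs)
    ctrl_density = pd.Series(
        config.control_density + rng.normal(0.0, config.control_density_genotype_sd,
                                            len(genotypes)),
        index=genotypes,
    )
    focal = modules[0] if modules else None
    density = np.empty(len(samples))
    expected = {}
    for si, s in enumerate(samples):
        geno, t = meta.at[s, "genotype"], meta.at[s, "treatment"]
        if t == "control":
            density[si] = ctrl_density[geno] + rng.normal(0.0, noise_sd)
        else:
            shift = float(delta.loc[focal, t]) if focal is not None else 0.0
            retention = c0 + cb * a[geno] + cp * (g[geno] * shift)
            expected[s] = retention
            density[si] = ctrl_density[geno] + retention + rng.normal(0.0, noise_sd)
    density = np.maximum(density, 0.0)
    traits = pd.DataFrame({"symbiont_density_per_cm2": density}, index=samples)
    traits.index.name = "sample"

    truth = SimulationTruth(
        gene_modules=gene_modules,
        baseline=a,
        plasticity=g,
        delta=delta,
        synergy=pd.Series(np.asarray(config.synergy_coeffs, dtype=float),
                          index=modules, name="synergy"),
        expected_retention=pd.Series(expected, name="expected_retention", dtype=float),
    )
    return counts_df, meta.drop(columns=[]), traits, truth


def write_fixture(dir_path: str | Path, counts: pd.DataFrame, meta: pd.DataFrame,
                  traits: pd.DataFrame, truth: SimulationTruth) -> dict[str, Path]:
    """Write ``counts.tsv``, ``metadata.csv``, ``traits.csv`` and ``truth.json``.

    Read-back with :func:`read_fixture` round-trips losslessly.
    """
    if counts.shape[0] == 0:
        raise ValueError("refusing to write fixture with an empty gene set")
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": d / "counts.tsv",
        "metadata": d / "metadata.csv",
        "traits": d / "traits.csv",
        "truth": d / "truth.json",
    }
    counts.to_csv(paths["counts"], sep="\t")
    meta.to_csv(paths["metadata"])
    traits.to_csv(paths["traits"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
    return paths


def read_fixture(dir_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame,
                                                pd.DataFrame, SimulationTruth]:
    d = Path(dir_path)
    counts = pd.read_csv(d / "counts.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(d / "metadata.csv", index_col=0)
    traits = pd.read_csv(d / "traits.csv", index_col=0)
    with open(d / "truth.json") as fh:
        truth = SimulationTruth.from_dict(json.load(fh))
    return counts, meta, traits, truth
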