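"""End-to-end pipeline: preprocess -> network -> synergy -> varpart -> reaction norms.

Every table is written with a provenance header (package version, seed,
config hash) as ``#``-prefixed comment lines; identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .network import CoexpressionNetwork, NetworkParams, treatment_indicators
from .preprocess import preprocess
from .reaction_norm import ReactionNorm
from .synergy import SynergyTest, select_synergy_candidates
from .varpart import Permanova, combined_factor, expression_distance, permanova

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

# defaults that stand in for choices the experimental protocol leaves open
UNSPECIFIED_DEFAULTS = [
    "preprocess.z_cut", "network.cut_height", "synergy.top_n",
    "varpart.n_perm", "varpart.term_order", "reaction_norm.n_pcs",
    "indicator_scheme",
]


@dataclass
class PipelineConfig:
    counts: str
    metadata: str
    outdir: str
    traits: str | None = None
    seed: int = 0
    min_count: int = 10
    low_fraction: float = 0.90
    z_cut: float = -2.5
    clone_map: dict = field(default_factory=dict)
    beta: int = 14
    min_module_size: int = 35
    cut_height: float = 0.99
    indicator_scheme: str = "one-vs-rest"
    synergy_alpha: float = 0.05
    synergy_top_n: int | None = 15
    n_perm: int = 999
    contrasts: tuple = ("heat", "combined")
    rxnorm_modules: tuple = ()      # module labels for module-specific reaction norms

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contrasts"] = list(self.contrasts)
        d["rxnorm_modules"] = list(self.rxnorm_modules)
        return d

    def digest(self) -> str:
        """Hash of the analysis parameters (file locations excluded)."""
        d = {k: v for k, v in self.to_dict().items()
             if k not in ("counts", "metadata", "traits", "outdir")}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_table(df: pd.DataFrame, path: Path, header: list[str], sep: str = ",",
                 index_label: str | None = None) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index_label=index_label)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle into ``config.outdir``.

    Returns the in-memory results keyed by stage name.
    """
    for name in ("counts", "metadata"):
        p = getattr(config, name)
        if not Path(p).exists():
            raise FileNotFoundError(f"{name} file not found: {p}")
    if config.traits is not None and not Path(config.traits).exists():
        raise FileNotFoundError(f"traits file not found: {config.traits}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [f"synstress {__version__}", f"seed: {config.seed}",
              f"config: {config.digest()}"]
    results: dict = {}

    counts = pd.read_csv(config.counts, sep="\t", index_col=0, comment="#")
    meta = pd.read_csv(config.metadata, index_col=0, comment="#")
    traits = (pd.read_csv(config.traits, index_col=0, comment="#")
              if config.traits is not None else None)

    try:
        prep = preprocess(counts, meta, min_count=config.min_count,
                          low_fraction=config.low_fraction, z_cut=config.z_cut,
                          clone_map=dict(config.clone_map))
    except Exception as e:
        raise PipelineError("preprocess", e) from e
    results["preprocess"] = prep
    _write_table(prep.expr, outdir / "expression.tsv", header, sep="\t",
                 index_label="gene_id")
    with open(outdir / "preprocess_report.json", "w") as fh:
        json.dump(prep.report(), fh, indent=1, sort_keys=True)

    try:
        params = NetworkParams(beta=config.beta,
                               min_module_size=config.min_module_size,
                               cut_height=config.cut_height)
        net = CoexpressionNetwork(prep.expr, params).fit()
    except Exception as e:
        raise PipelineError("comodule", e) from e
    results["network"] = net
    assign = net.assignment.to_frame()
    assign["kME"] = [
        net.kme.at[g, m] if m in net.kme.columns else float("nan")
        for g, m in net.assignment.items()
    ]
    _write_table(assign, outdir / "modules.csv", header, index_label="gene_id")
    _write_table(net.eigengenes.scores, outdir / "eigengenes.tsv", header,
                 sep="\t", index_label="sample")

    trait_cols = treatment_indicators(prep.meta, config.indicator_scheme)
    if traits is not None:
        trait_cols = pd.concat([trait_cols, traits.reindex(prep.meta.index)], axis=1)
    corr = net.trait_correlations(trait_cols)
    _write_table(corr.r, outdir / "module_trait_r.csv", header, index_label="module")
    _write_table(corr.p, outdir / "module_trait_p.csv", header, index_label="module")

    try:
        candidates = select_synergy_candidates(net.module_sizes, corr,
                                               alpha=config.synergy_alpha,
                                               top_n=config.synergy_top_n)
        syn = SynergyTest(net.eigengenes, prep.meta,
                          modules=candidates or None).fit()
    except Exception as e:
        raise PipelineError("synergy", e) from e
    results["synergy"] = syn
    _write_table(syn.table, outdir / "synergy.csv", header, index_label="module")

    varpart_results = {}
    for treatment in config.contrasts:
        subset = prep.meta.index[prep.meta["treatment"].isin(["control", treatment])]
        sub_meta = prep.meta.loc[subset]
        try:
            dist = expression_distance(prep.expr, list(subset))
            vp = permanova(dist, {"treatment": sub_meta["treatment"],
                                  "genotype": sub_meta["genotype"]},
                           n_perm=config.n_perm, seed=config.seed)
            vp_comb = permanova(dist,
                                {"genotype_treatment": combined_factor(sub_meta)},
                                n_perm=config.n_perm, seed=config.seed)
        except Exception as e:
            raise PipelineError(f"varpart[{treatment}]", e) from e
        varpart_results[treatment] = {"main": vp, "combined_factor": vp_comb}
        _write_table(vp.table, outdir / f"varpart_{treatment}.csv", header,
                     index_label="term")
        _write_table(vp_comb.table, outdir / f"varpart_{treatment}_interaction.csv",
                     header, index_label="term")
    results["varpart"] = varpart_results

    rxnorm_results = {}
    for treatment in config.contrasts:
        gene_sets: dict[str, list[str] | None] = {"transcriptome": None}
        for m in config.rxnorm_modules:
            gene_sets[m] = list(net.assignment.index[net.assignment == m])
        for label, genes in gene_sets.items():
            try:
                rn = ReactionNorm(prep.expr, prep.meta, traits, treatment,
                                  genes=genes).fit()
            except Exception as e:
                raise PipelineError(f"reaction_norm[{treatment}:{label}]", e) from e
            rxnorm_results[(treatment, label)] = rn
            tag = f"{treatment}_{label}"
            _write_table(rn.model.scores, outdir / f"dapc_scores_{tag}.tsv",
                         header, sep="\t", index_label="sample")
            _write_table(rn.norm.baseline.to_frame(),
                         outdir / f"baseline_{tag}.csv", header,
                         index_label="genotype")
            _write_table(rn.norm.plasticity.to_frame(),
                         outdir / f"plasticity_{tag}.csv", header,
                         index_label="sample")
            if rn.baseline_regression is not None:
                regs = {
                    "baseline_vs_retention": dataclasses.asdict(rn.baseline_regression),
                    "plasticity_vs_retention": dataclasses.asdict(rn.plasticity_regression),
                    "axis": rn.norm.axis, "orientation": rn.norm.orientation,
                }
                with open(outdir / f"regressions_{tag}.json", "w") as fh:
                    json.dump(regs, fh, indent=1, sort_keys=True)
    results["reaction_norm"] = rxnorm_results

    effective = {"config": config.to_dict(), "version": __version__,
                 "defaults_not_protocol_specified": UNSPECIFIED_DEFAULTS}
    with open(outdir / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(effective, fh, sort_keys=True)
    return results
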