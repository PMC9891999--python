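"""End-to-end pipeline: simulate/load -> depth filter -> fit -> CLR summary
-> pathway analysis, with a manifest and a human-readable report.

The pipeline is a pure function of (inputs, config, seed): rerunning with the
same configuration and seed reproduces every output table exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import DegeneratePartitionError, PipelineError
from .inference import (DifferentialAbundanceResult, MCMCConfig, PosteriorDraws,
                        fit_zinb, summarize)
from .model import PriorConfig
from .pathways import (CompletenessMatrix, compare_groups_lsd, complete_incomplete_log_ratio,
                       compute_completeness, correlate_completeness_with_beta)
from .synthetic import SimulationConfig, generate_truth, simulate_count_table, \
    simulate_genome_annotations
from .table_io import (CountTable, SampleMetadata, filter_samples_by_depth,
                       read_annotations, read_count_table, read_metadata,
                       read_pathway_definitions, write_annotations, write_count_table,
                       write_metadata, write_pathway_definitions, write_posterior_draws)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunOutputs", "run_pipeline", "make_report"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable; CLI flags override)."""

    outdir: str = "zinbda_run"
    seed: int = 0
    counts: str | None = None
    metadata: str | None = None
    simulate: dict | None = None  # SimulationConfig overrides; used when counts is None
    annotations: str | None = None
    pathway_definitions: str | None = None
    simulate_annotations: dict | None = None
    min_depth: int = 0
    reference_diet: str | None = None
    reference_feature: str | None = None
    priors: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)
    covariate: str | None = None  # effect used for pathway correlation
    pseudocount: float = 1.0
    credible_level: float = 0.95
    force: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


@dataclass
class RunOutputs:
    """In-memory results of a pipeline run (everything is also written to disk)."""

    outdir: Path
    table: CountTable
    metadata: SampleMetadata
    removed_samples: list[str]
    draws: PosteriorDraws
    result: DifferentialAbundanceResult
    completeness: CompletenessMatrix | None = None
    pathway_correlations: pd.DataFrame | None = None
    log_ratios: pd.DataFrame | None = None
    group_comparisons: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _stage(name: str, hint: str = ""):
    """Decorator-free stage wrapper: re-raise failures with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc), hint) from exc
            return False
    return _Ctx()


def run_pipeline(config: RunConfig) -> RunOutputs:
    """Execute every stage in order and write all declared artifacts."""
    outdir = Path(config.outdir)
    if (outdir / "manifest.json").exists() and not config.force:
        raise PipelineError("setup", f"output directory {outdir} already holds a run",
                            "pass force=True / --force to overwrite")
    outdir.mkdir(parents=True, exist_ok=True)

    sim_config = None
    truth = None
    with _stage("inputs", "provide counts+metadata paths or a simulate section"):
        if config.counts is not None:
            if config.metadata is None:
                raise ValueError("counts given without metadata")
            for label, path in (("counts", config.counts), ("metadata", config.metadata)):
                if not Path(path).exists():
                    raise FileNotFoundError(f"{label} file not found: {path}")
            table = read_count_table(config.counts)
            metadata = read_metadata(config.metadata, table)
        else:
            sim_config = SimulationConfig(**{**(config.simulate or {}), "seed": config.seed})
            truth = generate_truth(sim_config)
            table, metadata = simulate_count_table(truth, sim_config)
            write_count_table(table, outdir / "simulated_counts.tsv")
            write_metadata(metadata, outdir / "simulated_metadata.tsv")
            with open(outdir / "simulation_truth.json", "w") as fh:
                json.dump({"config": sim_config.to_dict(), "truth": truth.to_dict()},
                          fh, indent=1)

    with _stage("filter", "lower min_depth or check the table's column sums"):
        before = set(table.sample_ids)
        table = filter_samples_by_depth(table, config.min_depth)
        removed = sorted(before - set(table.sample_ids))
        keep = metadata.frame["sample_id"].isin(table.sample_ids)
        metadata = SampleMetadata(metadata.frame[keep].reset_index(drop=True))

    with _stage("fit", "check diets/cages in the metadata and MCMC settings"):
        priors = PriorConfig(**config.priors)
        mcmc = MCMCConfig(**{**config.mcmc, "seed": config.seed})
        draws = fit_zinb(table, metadata, priors, mcmc,
                         reference_level=config.reference_diet)
        write_posterior_draws(draws, outdir / "draws.tsv")
        draws.diagnostics.to_csv(outdir / "diagnostics.tsv", sep="\t", index=False)

    with _stage("summarize"):
        reference_feature = config.reference_feature or table.feature_ids[0]
        result = summarize(draws, level=config.credible_level,
                           reference_feature=reference_feature)
        result.frame.to_csv(outdir / "summary.tsv", sep="\t", index=False,
                            float_format="%.6g")

    completeness = None
    correlations = None
    log_ratios = None
    comparisons = None
    with _stage("pathways", "provide annotations/pathway_definitions paths "
                            "or a simulate_annotations section"):
        ann = defs = None
        if config.annotations is not None and config.pathway_definitions is not None:
            ann = read_annotations(config.annotations)
            defs = read_pathway_definitions(config.pathway_definitions)
        elif config.simulate_annotations is not None:
            if truth is None:
                raise ValueError("simulate_annotations requires simulated counts")
            ann_truth = simulate_genome_annotations(truth, sim_config,
                                                    **config.simulate_annotations)
            ann, defs = ann_truth.annotations, ann_truth.pathway_definitions
            write_annotations(ann, outdir / "simulated_annotations.tsv")
            write_pathway_definitions(defs, outdir / "simulated_pathways.tsv")
        if ann is not None:
            completeness = compute_completeness(ann, defs, genomes=table.feature_ids)
            covariate = config.covariate or next(
                (c for c in draws.covariate_names if c != "intercept"), "intercept")
            correlations = correlate_completeness_with_beta(completeness, result, covariate)
            lr_rows, cmp_rows = [], []
            diets = metadata.diet.to_numpy()
            for pathway in completeness.frame.columns:
                try:
                    series = complete_incomplete_log_ratio(
                        table, completeness, pathway, pseudocount=config.pseudocount)
                except DegeneratePartitionError as err:
                    logger.warning("log ratio skipped: %s", err)
                    continue
                for sid, val in series.values.items():
                    lr_rows.append((pathway, sid, val))
                f_stat, pairs = compare_groups_lsd(series.values.to_numpy(), diets)
                for row in pairs.itertuples(index=False):
                    cmp_rows.append((pathway, f_stat, row.group_a, row.group_b,
                                     row.mean_diff, row.t, row.p))
            log_ratios = pd.DataFrame(lr_rows, columns=["pathway", "sample_id", "log_ratio"])
            comparisons = pd.DataFrame(
                cmp_rows, columns=["pathway", "anova_F", "group_a", "group_b",
                                   "mean_diff", "t", "lsd_p"])
            correlations.to_csv(outdir / "pathway_correlations.tsv", sep="\t",
                                index=False, float_format="%.6g")
            log_ratios.to_csv(outdir / "log_ratios.tsv", sep="\t", index=False,
                              float_format="%.6g")
            comparisons.to_csv(outdir / "group_comparisons.tsv", sep="\t", index=False,
                               float_format="%.6g")

    outputs = RunOutputs(outdir=outdir, table=table, metadata=metadata,
                         removed_samples=removed, draws=draws, result=result,
                         completeness=completeness, pathway_correlations=correlations,
                         log_ratios=log_ratios, group_comparisons=comparisons)

    with _stage("report"):
        manifest = {
            "zinbda_version": __version__,
            "numpy_version": np.__version__,
            "config": config.to_dict(),
            "seed": config.seed,
            "n_features": table.n_features,
            "n_samples": table.n_samples,
            "removed_samples": removed,
            "reference_diet": draws.reference_level,
            "reference_feature": result.reference_feature,
            "credible_level": result.level,
            "mcmc": {"chains": draws.n_chains, "draws": draws.n_draws,
                     "rhat_max_observed": float(np.nanmax(draws.diagnostics["rhat"])),
                     "ess_min_observed": float(np.nanmin(draws.diagnostics["ess"]))},
        }
        outputs.manifest = manifest
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        (outdir / "report.txt").write_text(make_report(outputs))
    return outputs


def make_report(outputs: RunOutputs, top: int = 10) -> str:
    """Human-readable run summary: top CLR effects, pathway results, diagnostics."""
    lines = []
    m = outputs.manifest
    lines.append("zinbda run report")
    lines.append("=" * 60)
    if m:
        lines.append(f"seed={m['seed']}  features={m['n_features']}  "
                     f"samples={m['n_samples']}  reference diet={m['reference_diet']!r}  "
                     f"ALR reference feature={m['reference_feature']!r}")
    if outputs.removed_samples:
        lines.append(f"depth filter removed {len(outputs.removed_samples)} samples: "
                     + ", ".join(outputs.removed_samples))
    diag = outputs.draws.diagnostics
    worst_rhat = float(np.nanmax(diag["rhat"]))
    worst_ess = float(np.nanmin(diag["ess"]))
    lines.append("")
    lines.append(f"convergence: max split R-hat {worst_rhat:.3f}, min bulk ESS {worst_ess:.0f}")
    if worst_rhat > 1.05 or worst_ess < 100:
        lines.append("!" * 60)
        lines.append("! WARNING: convergence diagnostics outside thresholds    !")
        lines.append("! (R-hat > 1.05 or ESS < 100); increase warmup/draws.    !")
        lines.append("!" * 60)
    level = int(round(outputs.result.level * 100))
    for cov in sorted(outputs.result.frame["covariate"].unique()):
        if cov == "intercept":
            continue
        sub = outputs.result.frame[outputs.result.frame["covariate"] == cov].head(top)
        lines.append("")
        lines.append(f"top CLR effects for {cov} ({level}% credible intervals):")
        for row in sub.itertuples(index=False):
            lines.append(f"  {row.feature_id:>12s}  clr_mean={row.clr_mean:+.3f}  "
                         f"[{row.lo:+.3f}, {row.hi:+.3f}]")
    if outputs.pathway_correlations is not None:
        lines.append("")
        lines.append("pathway completeness vs CLR effect (Spearman, ranked by |rho|):")
        for row in outputs.pathway_correlations.itertuples(index=False):
            lines.append(f"  {row.pathway:>10s}  rho={row.rho:+.3f}  p={row.p:.4g}  n={row.n}")
        if outputs.group_comparisons is not None and len(outputs.group_comparisons):
            lines.append("")
            lines.append("complete-vs-incomplete log-ratio group comparison (ANOVA + Fisher LSD):")
            for pathway, sub in outputs.group_comparisons.groupby("pathway", sort=False):
                f_stat = sub["anova_F"].iloc[0]
                lines.append(f"  {pathway}: F={f_stat:.3f}")
                for row in sub.itertuples(index=False):
                    lines.append(f"    {row.group_a} vs {row.group_b}: "
                                 f"diff={row.mean_diff:+.3f}  p={row.lsd_p:.4g}")
    else:
        lines.append("")
        lines.append("pathway section omitted: no annotations were provided.")
    return "\n".join(lines) + "\n"
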