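"""End-to-end orchestration: simulate -> match -> enrich -> direction -> report.

One ``RunConfig`` drives a reproducible run: a single top-level seed
(stage substreams are derived by fixed labels), every design-decision
flag echoed into ``summary.json``, and all result tables written as TSV
into the run directory.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import directionality, enrichment, matched_controls, synthetic_data, tables_io
from .errors import ClineSeasError, ConfigError
from .resampling_stats import bonferroni_threshold, format_emp_p
from .tables_io import DeGeneSet, InversionDef

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run.

    Exactly one of ``sim`` (synthetic mode) or the four input paths
    must be provided.
    """

    out_dir: str
    sim: synthetic_data.SimConfig | None = None
    snp_path: str | None = None
    eqtl_path: str | None = None
    de_path: str | None = None
    design_path: str | None = None
    inversions_path: str | None = None
    seed: int = 0
    alpha: float = 0.05
    n_sets: int = 1000
    grid: Sequence[float] = enrichment.DEFAULT_GRID
    top_quantile: float = enrichment.TOP_QUANTILE
    block_window: int = enrichment.BLOCK_WINDOW
    block_reps: int = enrichment.BLOCK_REPS
    run_block: bool = True
    run_partition: bool = True
    run_gene: bool = True
    run_pairwise: bool = True
    universe: str = "union"
    bonferroni_enrich_m: int | None = None     # default: tests in the run
    bonferroni_direction_m: int | None = None
    write_controls: bool = False

    def __post_init__(self) -> None:
        synthetic = self.sim is not None
        has_paths = self.snp_path is not None
        if synthetic == has_paths:
            raise ConfigError(
                "RunConfig needs either a SimConfig (synthetic mode) or input "
                "table paths, and not both"
            )


def _load_inputs(config: RunConfig, out: Path):
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        data = synthetic_data.simulate_dataset(sim)
        tables_io.write_table(data.snps, out / "snps.tsv")
        tables_io.write_table(data.eqtls, out / "eqtls.tsv")
        tables_io.write_de_sets(data.de_sets, out / "de_sets.tsv")
        tables_io.write_table(data.design, out / "sample_design.tsv")
        tables_io.write_inversions_bed(sim.inversions, out / "inversions.bed")
        tables_io.write_run_summary(data.ground_truth.to_dict(), out / "ground_truth.json")
        return data.snps, data.eqtls, data.de_sets, data.design, list(sim.inversions)
    for name in ("snp_path", "eqtl_path", "de_path", "inversions_path"):
        if getattr(config, name) is None:
            raise ConfigError(f"RunConfig.{name} is required outside synthetic mode")
    snps = tables_io.read_snp_table(config.snp_path)
    eqtls = tables_io.read_eqtl_table(config.eqtl_path)
    tables_io.validate_eqtl_table(eqtls, snps)
    de_sets = tables_io.read_de_sets(config.de_path)
    design = (
        tables_io.read_sample_design(config.design_path)
        if config.design_path
        else pd.DataFrame(columns=["sample_id", "locality", "role", "latitude", "pair_id"])
    )
    inversions = tables_io.read_inversions_bed(config.inversions_path)
    return snps, eqtls, de_sets, design, inversions


def _direction_comparisons(design: pd.DataFrame, run_pairwise: bool,
                           snps: pd.DataFrame) -> list[str]:
    comps = ["crosspop_clinal", "crosspop_seasonal"]
    if not run_pairwise:
        return comps
    have_freqs = any(c.startswith(tables_io.FREQ_PREFIX) for c in snps.columns)
    if not have_freqs:
        return comps
    if (design["role"] == "clinal").sum() >= 2:
        comps.append("fl_me")
    pairs = design.loc[design["role"] == "spring", "pair_id"].dropna()
    comps.extend(f"locality:{p}" for p in pairs)
    return comps


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict (also on disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("clineseas")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    t0 = time.time()
    stage = "load_inputs"
    try:
        snps, eqtls, de_sets, design, inversions = _load_inputs(config, out)
        log.info("inputs: %d SNPs (%d eQTL), %d annotations, %d DE sets, %d samples",
                 len(snps), int(snps["is_eqtl"].sum()), len(eqtls), len(de_sets),
                 len(design))

        stage = "matched_controls"
        control_sets = matched_controls.build_control_sets(
            snps, inversions, n_sets=config.n_sets, seed=config.seed
        )
        if config.write_controls:
            control_sets.write(out / "control_sets.tsv")
        pd.DataFrame(
            {"eqtl_id": control_sets.eqtl_ids,
             "pool_size": control_sets.pool_sizes,
             "with_replacement": control_sets.with_replacement}
        ).to_csv(out / "control_pools.tsv", sep="\t", index=False)

        stage = "enrichment"
        enrich_results = []
        for model in enrichment.MODELS:
            enrich_results += enrichment.genome_wide_enrichment(
                snps, eqtls, control_sets, model, grid=config.grid,
                alpha=config.alpha, bonferroni_m=config.bonferroni_enrich_m,
                universe=config.universe,
            )
            if config.run_block:
                enrich_results += enrichment.block_downsampled_enrichment(
                    snps, eqtls, control_sets, model, grid=config.grid,
                    window=config.block_window, n_rep=config.block_reps,
                    seed=config.seed, alpha=config.alpha,
                    bonferroni_m=config.bonferroni_enrich_m, universe=config.universe,
                )
            if config.run_partition:
                enrich_results += enrichment.partitioned_enrichment(
                    snps, eqtls, control_sets, inversions, model,
                    threshold=config.top_quantile, alpha=config.alpha,
                    universe=config.universe,
                )
        tables_io.write_results(enrich_results, out / "enrichment.tsv")

        gene_summaries = {}
        if config.run_gene:
            stage = "gene_enrichment"
            for model in enrichment.MODELS:
                gene_results, excess = enrichment.gene_enrichment(
                    snps, eqtls, control_sets, model,
                    threshold=config.top_quantile, alpha=config.alpha,
                    universe=config.universe,
                )
                tables_io.write_results(gene_results, out / f"gene_enrichment_{model}.tsv")
                gene_summaries[model] = dataclasses.asdict(excess)

        stage = "directionality"
        comparisons = _direction_comparisons(design, config.run_pairwise, snps)
        m_dir = config.bonferroni_direction_m
        if m_dir is None:
            m_dir = max(1, len(comparisons) * len(de_sets))
        direction_results = []
        for label in sorted(de_sets):
            de_set = de_sets[label]
            for comp in comparisons:
                if comp.startswith("crosspop_"):
                    res = directionality.concordance_crosspop(
                        snps, eqtls, de_set, control_sets,
                        model=comp.split("_", 1)[1], alpha=config.alpha,
                        bonferroni_m=m_dir,
                    )
                else:
                    res = directionality.concordance_pairwise(
                        snps, eqtls, de_set, control_sets, comp, design,
                        alpha=config.alpha, bonferroni_m=m_dir,
                    )
                direction_results.append(res)
        tables_io.write_results(direction_results, out / "concordance.tsv")

        gene_scores = []
        for label in sorted(de_sets):
            for model in directionality.AXES:
                gene_scores.append(
                    directionality.gene_concordance(
                        snps, eqtls, de_sets[label], control_sets, model
                    )
                )
        tables_io.write_table(pd.concat(gene_scores, ignore_index=True),
                              out / "gene_concordance.tsv")

        stage = "summary"
        n_enrich_tests = sum(1 for r in enrich_results if r.testable)
        summary = {
            "seed": config.seed,
            "alpha": config.alpha,
            "n_control_sets": config.n_sets,
            "n_snps": len(snps),
            "n_eqtl_snps": int(snps["is_eqtl"].sum()),
            "n_eqtl_annotations": len(eqtls),
            "quantile_grid": list(config.grid),
            "top_quantile": config.top_quantile,
            "universe": config.universe,
            "bonferroni": {
                "enrichment_m": config.bonferroni_enrich_m,
                "direction_m": m_dir,
                "direction_threshold": bonferroni_threshold(config.alpha, m_dir).display,
            },
            "decision_flags": {
                "quantile_ties": "max-rank, at-or-below cutoff counts as below",
                "control_sampling": "without replacement when pool >= n_sets, "
                                    "with replacement (warned) otherwise",
                "controls_shared_across_eqtls": True,
                "zero_cell_rule": "Haldane-Anscombe +0.5, flagged",
                "zero_omega_rule": "excluded from concordance denominator",
                "pairwise_nulls_reuse_control_sets": True,
                "spring_is_positive_seasonal_pole": True,
            },
            "counts": {
                "enrichment_tests": n_enrich_tests,
                "enrichment_significant": sum(
                    1 for r in enrich_results if r.testable and r.adj_significant
                ),
                "direction_tests": sum(1 for r in direction_results if r.testable),
                "direction_verdicts": {
                    v: sum(1 for r in direction_results if r.verdict == v and r.testable)
                    for v in directionality.VERDICTS
                },
            },
            "gene_enrichment": gene_summaries,
            "runtime_s": round(time.time() - t0, 2),
        }
        tables_io.write_run_summary(summary, out / "summary.json")
        return summary
    except ClineSeasError as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def report(run_dir) -> str:
    """Human-readable digest of a completed run (also written to report.md)."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise ConfigError(f"incomplete run: missing {summary_path}")
    summary = tables_io.read_run_summary(summary_path)
    n = summary["n_control_sets"]
    lines = [
        "# clineseas run digest",
        f"seed: {summary['seed']}; control sets per eQTL: {n}; "
        f"SNPs: {summary['n_snps']} ({summary['n_eqtl_snps']} eQTLs)",
        "",
        "## Enrichment (log2 odds ratio, mean over control sets +/- 1.96 SD)",
    ]
    enr_path = run_dir / "enrichment.tsv"
    if not enr_path.exists():
        raise ConfigError(f"incomplete run: missing {enr_path}")
    enr = pd.read_csv(enr_path, sep="\t")
    for r in enr.itertuples(index=False):
        if not r.testable:
            lines.append(
                f"- {r.model} {r.stratum} {r.sex_class} q<={r.quantile_threshold}: not testable"
            )
            continue
        verdict = "enriched" if r.log2_or_mean > 0 else "depleted"
        star = " *" if r.adj_significant else ""
        lines.append(
            f"- {r.model} {r.stratum} {r.sex_class} q<={r.quantile_threshold}: "
            f"log2 OR = {r.log2_or_mean:.3f} +/- {r.ci_half_width:.3f} "
            f"({verdict}, emp_p {format_emp_p(r.emp_p, n)}){star}"
        )
    lines += ["", "## Directionality (concordance score vs null of 50%)"]
    conc = pd.read_csv(run_dir / "concordance.tsv", sep="\t")
    for r in conc.itertuples(index=False):
        if not r.testable:
            lines.append(f"- {r.de_label} {r.comparison}: not testable")
            continue
        lines.append(
            f"- {r.de_label} {r.comparison}: score = {r.score:.3f} "
            f"(n = {r.n_eqtls}, emp_p {format_emp_p(r.emp_p, n)}, {r.verdict})"
        )
    text = "\n".join(lines) + "\n"
    (run_dir / "report.md").write_text(text)
    return text
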