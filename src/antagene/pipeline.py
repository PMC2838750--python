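"""End-to-end pipeline: fitness genetics -> expression -> enrichment.

Stages run in study order: relative fitness and the bivariate genetic
architecture, line selection, per-transcript variance partitioning,
moderated sex-by-fitness regression with antagonism calls, tissue
specificity/enrichment of the called sets, and chromosomal + GO
over-representation.  Each stage writes its own TSV outputs; a JSON
summary collects the headline counts.  A stage failure raises
:class:`PipelineStageError` naming the stage; outputs of completed
stages are retained.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, anova, enrich, fitness, io, regression, tissue

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: io.PipelineConfig) -> dict:
    """Run every configured stage and return the summary dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "alpha_anova": config.alpha_anova,
            "alpha_regression": config.alpha_regression,
            "fold": config.fold,
            "unexpressed": config.unexpressed,
            "n_tissues": config.n_tissues,
        },
    }

    def _stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineStageError(name, exc) from exc
        return deco

    state: dict = {}

    if config.assays:
        @_stage("fitness")
        def _():
            assays = io.read_fitness_assays(config.assays)
            relfit = fitness.compute_relative_fitness(assays)
            arch = fitness.fit_bivariate_components(
                relfit, n_iter=config.n_iter, burn_in=config.burn_in,
                thin=config.thin, n_chains=config.n_chains, seed=config.seed,
            )
            state["relfit"] = relfit
            rows = {
                k: getattr(arch, k)
                for k in ("V_line_f", "V_line_m", "V_resid_f", "V_resid_m",
                          "cov_fm", "r_MF", "h2_f", "h2_m", "CV_A_f", "CV_A_m",
                          "CV_R_f", "CV_R_m", "mu_f", "mu_m")
            }
            tab = pd.DataFrame(
                [
                    {"parameter": k, "estimate": v,
                     "ci_low": arch.ci.get(k, (None, None))[0],
                     "ci_high": arch.ci.get(k, (None, None))[1]}
                    for k, v in rows.items()
                ]
            )
            tab.to_csv(out / "architecture.tsv", sep="\t", index=False)
            arch.chains.to_csv(out / "chains.tsv", sep="\t", index=False)
            summary["r_MF"] = arch.r_MF
            summary["r_MF_ci"] = list(arch.ci["r_MF"])
            summary["h2_f"] = arch.h2_f
            summary["h2_m"] = arch.h2_m
            summary["sampler_converged"] = bool(arch.converged)

        @_stage("selection")
        def _():
            sel = fitness.select_lines(state["relfit"])
            rows = [{"line": l, "group": g}
                    for g, ls in (("high_m_low_f", sel.high_m_low_f),
                                  ("low_m_high_f", sel.low_m_high_f),
                                  ("average", sel.average))
                    for l in ls]
            pd.DataFrame(rows).to_csv(out / "selection.tsv", sep="\t", index=False)
            state["selection"] = sel

    if config.matrix and config.samples:
        @_stage("anova")
        def _():
            matrix = io.read_expression_matrix(config.matrix)
            samples = io.read_sample_sheet(config.samples)
            res = anova.run_anova(matrix, samples, alpha=config.alpha_anova,
                                  log2_threshold=config.log2_threshold)
            res.to_csv(out / "anova.tsv", sep="\t", index=False)
            state["matrix"], state["samples"] = matrix, samples
            a = config.alpha_anova
            summary["n_transcripts"] = len(res)
            summary["n_sex_significant"] = int((res["q_sex"] < a).sum())
            summary["n_male_biased"] = int((res["sex_bias_class"] == "male_biased").sum())
            summary["n_female_biased"] = int(
                (res["sex_bias_class"] == "female_biased").sum())
            summary["n_line_variable"] = int((res["q_line"] < a).sum())
            summary["n_interaction"] = int((res["q_sexline"] < a).sum())

        @_stage("antagonism")
        def _():
            matrix, samples = state["matrix"], state["samples"]
            if "relfit" in state:
                fitcov = state["relfit"].to_long()
            else:
                fitcov = io.read_fitness_covariate(config.assays)
            design = regression.build_design(samples, fitcov)
            fits = regression.fit_per_transcript_ols(matrix, design)
            stats_ = regression.moderated_t(fits)
            calls = regression.call_antagonistic(stats_, config.alpha_regression)
            per_sex = regression.sex_specific_association(
                matrix, samples, fitcov, config.alpha_regression)
            calls.table.to_csv(out / "antagonism.tsv", sep="\t")
            for sex, t in per_sex.items():
                t.to_csv(out / f"fitness_assoc_{sex}.tsv", sep="\t")
            male_set = set(per_sex["M"].index[per_sex["M"]["significant"]])
            female_set = set(per_sex["F"].index[per_sex["F"]["significant"]])
            ant_set = set(calls.table.index[calls.table["antagonistic"]])
            venn = regression.overlap_summary(male_set, female_set, ant_set)
            venn.to_csv(out / "venn.tsv", sep="\t", index=False)
            state["sets"] = {
                "antag": ant_set,
                "antag.mplus": set(
                    calls.table.index[calls.table["antagonistic"]
                                      & (calls.table["direction"]
                                         == "male_benefit_female_detriment")]),
                "antag.fplus": set(
                    calls.table.index[calls.table["antagonistic"]
                                      & (calls.table["direction"]
                                         == "female_benefit_male_detriment")]),
                "m": male_set,
                "m.pos": set(per_sex["M"].index[per_sex["M"]["significant"]
                                                & (per_sex["M"]["slope"] > 0)]),
                "m.neg": set(per_sex["M"].index[per_sex["M"]["significant"]
                                                & (per_sex["M"]["slope"] < 0)]),
                "f": female_set,
                "f.pos": set(per_sex["F"].index[per_sex["F"]["significant"]
                                                & (per_sex["F"]["slope"] > 0)]),
                "f.neg": set(per_sex["F"].index[per_sex["F"]["significant"]
                                                & (per_sex["F"]["slope"] < 0)]),
            }
            summary["n_fitness_assoc_m"] = len(male_set)
            summary["n_fitness_assoc_f"] = len(female_set)
            summary["n_antagonistic"] = len(ant_set)
            summary["n_male_benefit"] = calls.n_male_benefit
            summary["n_female_benefit"] = calls.n_female_benefit

    if config.atlas and "sets" in state:
        @_stage("tissue")
        def _():
            atlas = io.read_atlas(config.atlas)
            rescaled = tissue.rescale_to_baseline(atlas, config.unexpressed)
            flags = tissue.flag_tissue_specific(rescaled, config.fold)
            enr = tissue.tissue_enrichment(flags, state["sets"], config.n_tissues)
            enr.to_csv(out / "tissue_enrichment.tsv", sep="\t", index=False)
            summary["n_enriched_tissues"] = int(
                (enr[enr["set"] == "antag"]["p_bonferroni"] < 0.01).sum())

    if config.chrom_annotations and "sets" in state:
        @_stage("enrichment")
        def _():
            results = []
            chrom = enrich.chromosome_annotation(
                io.read_annotations(config.chrom_annotations))
            interest = state["sets"]["antag"] & chrom.universe
            res = enrich.test_categories(interest, chrom)
            res["annotation"] = "chromosome"
            results.append(res)
            if config.go_annotations:
                go = enrich.go_annotation(io.read_annotations(config.go_annotations))
                res2 = enrich.test_categories(interest & go.universe, go)
                res2["annotation"] = "go"
                results.append(res2)
            allres = pd.concat(results, ignore_index=True)
            allres.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            summary["n_enriched_categories"] = int(allres["significant"].sum())

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
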