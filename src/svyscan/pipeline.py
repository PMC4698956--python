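"""End-to-end orchestration of the analysis stages.

Stage order: simulate (optional) -> include -> transform -> scan ->
nested -> validate -> misclass-mc -> trend -> report. Each stage writes
its own CSV under the output directory; the closing markdown report
only collects numbers the stage CSVs already contain. All randomness
descends from the single configured seed.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import SurveyDesign
from .misclass import MCConfig, run_misclass_mc
from .scan import (METABOLITES, default_model_sequence, encode_covariates,
                   molar_sum_dnop, nested_models, univariate_scan)
from .synthetic import GeneratorConfig, apply_inclusion_criteria, generate_cohort
from .transform import dilution_correct, inverse_normal, substitute_lod, transform_exposures
from .trend import trend_analysis
from .validation import cohens_kappa, crosstab, extract_misclass_rates, weighted_agreement_table

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES", "read_cohort"]

ALL_STAGES = ["simulate", "include", "transform", "scan", "nested",
              "validate", "misclass-mc", "trend", "report"]

log = logging.getLogger("svyscan")


def _setup_logging():
    if not log.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(name)s: %(message)s",
            datefmt="%Y-%m-%dT%H:%M:%S"))
        log.addHandler(h)
        log.setLevel(logging.INFO)


@dataclass
class PipelineConfig:
    """Run configuration; loadable from a YAML file.

    With no ``input_path`` a synthetic cohort is generated from
    ``generator`` (seeded by ``seed``). Column names below are the
    generator's; point them elsewhere for external data.
    """

    output_dir: str = "svyscan_out"
    seed: int = 0
    input_path: str | None = None
    input_format: str = "auto"          # auto | csv | tsv | xpt
    stratum_col: str = "stratum"
    psu_col: str = "psu"
    weight_col: str = "weight"
    creatinine_col: str = "creatinine"
    outcome_col: str = "selfreport_outcome"
    metabolites: list[str] = field(default_factory=lambda: list(METABOLITES))
    lods: dict | None = None
    exposure_of_interest: str = "MOP"
    cycle_count: int = 1
    rank_offset: str = "n+1"
    mc: MCConfig = field(default_factory=MCConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    ci_level: float = 0.95

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        mc = MCConfig(**raw.pop("mc", {}))
        gen = GeneratorConfig(**raw.pop("generator", {}))
        cfg = cls(mc=mc, generator=gen, **raw)
        cfg.generator.seed = cfg.seed
        cfg.mc.seed = cfg.seed
        return cfg


def read_cohort(path, fmt: str = "auto") -> pd.DataFrame:
    """Read a subject-level table from CSV/TSV (delimiter sniffed) or SAS XPORT."""
    path = Path(path)
    if fmt == "auto":
        fmt = {".tsv": "tsv", ".xpt": "xpt"}.get(path.suffix.lower(), "csv")
    if fmt == "xpt":
        return pd.read_sas(path, format="xport")
    sep = "\t" if fmt == "tsv" else ","
    if fmt == "csv":    # sniff: tab-delimited files named .csv happen
        with open(path) as fh:
            first = fh.readline()
        if "\t" in first and "," not in first:
            sep = "\t"
    return pd.read_csv(path, sep=sep)


def _write(df: pd.DataFrame, outdir: Path, name: str, seed: int, **kwargs):
    path = outdir / name
    with open(path, "w") as fh:
        fh.write(f"# svyscan {__version__} seed={seed}\n")
        df.to_csv(fh, float_format="%.10g", **kwargs)
    log.info("wrote %s", path)
    return path


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages; returns a dict of stage results.

    Later stages re-derive what they need from earlier in-memory results,
    so a partial ``stages`` list must be a prefix-closed subset of
    :data:`ALL_STAGES` (validated here).
    """
    _setup_logging()
    stages = list(ALL_STAGES) if stages is None else list(stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    stages = [s for s in ALL_STAGES if s in stages]
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"seed": config.seed}
    seed = config.seed

    # --- obtain data ----------------------------------------------------
    if config.input_path is not None:
        cohort = read_cohort(config.input_path, config.input_format)
        log.info("loaded %d subjects from %s", len(cohort), config.input_path)
    else:
        config.generator.seed = config.seed
        cohort = generate_cohort(config.generator)
        log.info("generated synthetic cohort of %d subjects", len(cohort))
        if "simulate" in stages:
            _write(cohort, outdir, "cohort.csv", seed, index=False)
    results["cohort"] = cohort

    try:
        if "include" in stages:
            cohort, flow = apply_inclusion_criteria(cohort, return_flow=True)
            results["cohort"], results["selection_flow"] = cohort, flow
            log.info("inclusion flow: %s", flow)
            _write(pd.DataFrame(flow.items(), columns=["stage", "n"]),
                   outdir, "selection_flow.csv", seed, index=False)
            _write(cohort, outdir, "included.csv", seed, index=False)

        lods = config.lods or config.generator.resolve().lods
        design = SurveyDesign(
            cohort[config.stratum_col].to_numpy(),
            cohort[config.psu_col].to_numpy(),
            cohort[config.weight_col].to_numpy(dtype=float) / config.cycle_count,
        )
        results["design"] = design

        if "transform" in stages:
            z = transform_exposures(cohort, config.metabolites, lods,
                                    config.creatinine_col, offset=config.rank_offset)
            coded = encode_covariates(cohort)
            # coded identity columns (age, male, ...) replace their raw versions
            keep = cohort.drop(columns=coded.columns.intersection(cohort.columns))
            cohort = pd.concat([keep, z, coded], axis=1)
            results["cohort"] = cohort
            _write(pd.concat([cohort[["subject_id"]], z, coded], axis=1),
                   outdir, "transformed.csv", seed, index=False)
            _write(_histogram_export(cohort, config, lods), outdir,
                   "exposure_histograms.csv", seed, index=False)

        expo_z = f"z_{config.exposure_of_interest}"

        if "scan" in stages:
            scan_res = univariate_scan(cohort, design, outcome=config.outcome_col,
                                       exposures=[f"z_{m}" for m in config.metabolites],
                                       level=config.ci_level)
            # DnOP molar-sum specificity analysis rides along with the scan
            msum = molar_sum_dnop(
                substitute_lod(cohort["MOP"], lods["MOP"],
                               cohort.get("MOP_below_lod")),
                substitute_lod(cohort["MCPP"], lods["MCPP"],
                               cohort.get("MCPP_below_lod")),
            ) if {"MOP", "MCPP"} <= set(cohort.columns) else None
            if msum is not None:
                zsum = inverse_normal(
                    dilution_correct(msum, cohort[config.creatinine_col]),
                    config.rank_offset)
                dn = univariate_scan(cohort.assign(z_dnop_molar=zsum), design,
                                     outcome=config.outcome_col,
                                     exposures=["z_dnop_molar"], m=1)
                scan_res = pd.concat([scan_res, dn])
            results["scan"] = scan_res
            _write(scan_res, outdir, "univariate_scan.csv", seed)

        if "nested" in stages:
            nested = nested_models(cohort, design, outcome=config.outcome_col,
                                   exposure=expo_z, level=config.ci_level)
            results["nested"] = nested
            _write(nested, outdir, "nested_models.csv", seed)

        if "validate" in stages:
            sub = cohort["imaging_grade"].ne("missing") & cohort["imaging_grade"].notna()
            tab = crosstab(cohort.loc[sub, config.outcome_col],
                           cohort.loc[sub, "imaging_grade"],
                           design.subset(sub.to_numpy()))
            wtab = weighted_agreement_table(
                cohort.loc[sub, config.outcome_col].to_numpy(),
                cohort.loc[sub, "imaging_grade"].to_numpy(),
                design.subset(sub.to_numpy()))
            agree = cohens_kappa(tab.collapsed_2x2.to_numpy(), weights_table=wtab)
            rates = extract_misclass_rates(
                cohort.loc[sub, config.outcome_col].to_numpy(),
                cohort.loc[sub, "imaging_grade"].to_numpy(),
                design.subset(sub.to_numpy()))
            results["validation_table"] = tab
            results["agreement"] = agree
            results["misclass_rates"] = rates
            four = tab.counts_4x2.copy()
            four["weighted_prop_selfreport"] = tab.row_prop_selfreport
            coll = tab.collapsed_2x2.copy()
            coll["weighted_prop_selfreport"] = tab.collapsed_row_prop
            _write(pd.concat([four, coll]), outdir, "validation_table.csv", seed)
            _write(pd.DataFrame([{
                "percent_agreement": agree.percent_agreement,
                "percent_agreement_weighted": agree.percent_agreement_weighted,
                "kappa": agree.kappa, "kappa_se": agree.kappa_se,
                "kappa_p": agree.kappa_p, "kappa_weighted": agree.kappa_weighted,
                "fp_rate_weighted": rates.fp_rate, "fn_rate_weighted": rates.fn_rate,
                "fp_rate_raw": rates.fp_rate_raw, "fn_rate_raw": rates.fn_rate_raw,
                "n_substudy": tab.n_total,
            }]), outdir, "validation_summary.csv", seed, index=False)

        if "misclass-mc" in stages:
            config.mc.seed = config.seed
            mc = run_misclass_mc(cohort, design, config.mc,
                                 outcome=config.outcome_col, exposure=expo_z)
            results["mc"] = mc
            _write(pd.DataFrame({"replicate": np.arange(1, mc.n_replicates + 1),
                                 "beta": mc.betas}),
                   outdir, "misclass_mc_replicates.csv", seed, index=False)
            _write(pd.DataFrame([{
                "mean_beta": mc.mean_beta, "sd_beta": mc.sd_beta,
                "odds_ratio": mc.odds_ratio, "ci_low": mc.ci_low,
                "ci_high": mc.ci_high, "ci_pct_low": mc.ci_percentile[0],
                "ci_pct_high": mc.ci_percentile[1], "n_failed": mc.n_failed,
            }]), outdir, "misclass_mc_summary.csv", seed, index=False)
            _write(mc.histogram, outdir, "misclass_mc_histogram.csv", seed, index=False)

        if "trend" in stages:
            tr = trend_analysis(cohort, design, z_col=expo_z, outcome=config.outcome_col)
            results["trend"] = tr
            out = tr.table.copy()
            out.attrs = {}
            _write(out.assign(trend_chi2=tr.statistic, trend_p=tr.p_value),
                   outdir, "trend.csv", seed)

        if "report" in stages:
            _write_report(results, outdir, config)
    except Exception as exc:
        stage = getattr(exc, "_svyscan_stage", "pipeline")
        log.error("stage failed: %s (%s)", stage, exc)
        raise
    return results


def _histogram_export(cohort, config, lods, bins: int = 25) -> pd.DataFrame:
    """Raw / dilution-corrected / inverse-normalised histograms per metabolite."""
    rows = []
    crea = cohort[config.creatinine_col].to_numpy(dtype=float)
    for m in config.metabolites:
        conc = substitute_lod(cohort[m].to_numpy(dtype=float), lods[m],
                              cohort.get(f"{m}_below_lod"))
        stages = {
            "raw": conc,
            "dilution_corrected": dilution_correct(conc, crea),
            "inverse_normalized": inverse_normal(dilution_correct(conc, crea),
                                                 config.rank_offset),
        }
        for stage, vals in stages.items():
            counts, edges = np.histogram(vals[~np.isnan(vals)], bins=bins)
            rows.extend({"metabolite": m, "stage": stage, "bin_left": l,
                         "bin_right": r, "count": int(c)}
                        for l, r, c in zip(edges[:-1], edges[1:], counts))
    return pd.DataFrame(rows)


def _fmt(x, nd=4):
    return "NA" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.{nd}g}"


def _write_report(results: dict, outdir: Path, config: PipelineConfig):
    lines = [f"# svyscan report (seed={config.seed})", ""]
    if "selection_flow" in results:
        lines += ["## Subject selection", ""]
        lines += [f"- {k}: {v}" for k, v in results["selection_flow"].items()] + [""]
    if "scan" in results:
        top = results["scan"].sort_values("p").iloc[0]
        lines += ["## Univariate scan", "",
                  f"Lowest nominal p: {top.name} "
                  f"(OR {_fmt(top['odds_ratio'])}, p {_fmt(top['p'])}, "
                  f"Bonferroni p {_fmt(top['p_bonferroni'])}).", ""]
    if "nested" in results:
        last = results["nested"].iloc[-1]
        lines += ["## Nested models", "",
                  f"Final model {results['nested'].index[-1]}: exposure OR "
                  f"{_fmt(last['odds_ratio'])} "
                  f"(95% CI {_fmt(last['or_low'])}-{_fmt(last['or_high'])}, "
                  f"p {_fmt(last['p'])}).", ""]
    if "agreement" in results:
        a = results["agreement"]
        r = results["misclass_rates"]
        lines += ["## Outcome validation", "",
                  f"Agreement {_fmt(a.percent_agreement)}% "
                  f"(weighted {_fmt(a.percent_agreement_weighted)}%), "
                  f"kappa {_fmt(a.kappa)} (weighted {_fmt(a.kappa_weighted)}, "
                  f"p {_fmt(a.kappa_p)}).",
                  f"Misclassification rates (weighted): fp {_fmt(r.fp_rate)}, "
                  f"fn {_fmt(r.fn_rate)} (raw {_fmt(r.fp_rate_raw)}, "
                  f"{_fmt(r.fn_rate_raw)}).", ""]
    if "mc" in results:
        mc = results["mc"]
        lines += ["## Misclassification Monte Carlo", "",
                  f"{mc.n_replicates} replicates: mean beta {_fmt(mc.mean_beta)}, "
                  f"SD {_fmt(mc.sd_beta)}, OR {_fmt(mc.odds_ratio)} "
                  f"(95% CI {_fmt(mc.ci_low)}-{_fmt(mc.ci_high)}).", ""]
    if "trend" in results:
        tr = results["trend"]
        prev = ", ".join(f"{i}: {_fmt(p)}" for i, p in
                         tr.table["prevalence_weighted"].items())
        lines += ["## Dose-response", "",
                  f"Weighted prevalence by bin — {prev}.",
                  f"Cochran-Armitage chi2 {_fmt(tr.statistic)}, p {_fmt(tr.p_value)}.", ""]
    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    log.info("wrote %s", path)
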