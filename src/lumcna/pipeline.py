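"""End-to-end orchestration: score -> quartiles -> KM/log-rank -> screening
-> multivariable Cox -> PH diagnostics -> survival tree -> crosstab, plus
rendering of the tabular report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, assoc, cna_score, stratify, survkit, synth, tree
from .io import (
    ClinicalTable,
    QuantileLabels,
    read_clinical,
    read_cna_matrix,
    read_quantile_labels,
    write_clinical,
    write_cna_matrix,
    write_quantile_labels,
)

logger = logging.getLogger("lumcna")

SIGNIFICANCE_LEGEND = "Signif. codes: 0(***) 0.001(**) 0.01(*) 0.05(.) 0.1()"


def significance_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""


def format_p(p: float) -> str:
    """Display truncation only; stored p-values keep full precision."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


@dataclass
class PipelineConfig:
    """Either input paths or a synthetic-cohort config, plus analysis knobs."""

    cna_path: str | None = None
    clinical_path: str | None = None
    quantiles_path: str | None = None
    synth_config: synth.CohortConfig | None = None
    outcomes: tuple = ("OS", "DSS")
    formula: str = survkit.PAPER_FORMULA
    alpha: float = 0.05
    tree_alpha: float = 0.05
    tree_min_node: int = 20
    tree_predictors: list = field(
        default_factory=lambda: [
            "pam50",
            "grade",
            "tumour_size",
            "positive_lymph_nodes",
            "age_at_diagnosis",
            "her2_status",
            "cna_score",
        ]
    )
    outdir: str = "lumcna_out"
    seed: int = 0

    def __post_init__(self) -> None:
        have_paths = self.cna_path is not None and self.clinical_path is not None
        have_synth = self.synth_config is not None
        if have_paths == have_synth:
            raise ValueError(
                "supply exactly one of (cna_path + clinical_path) or synth_config"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "synth_config" in data and data["synth_config"] is not None:
            sc = data["synth_config"]
            data["synth_config"] = (
                synth.CohortConfig(**sc) if isinstance(sc, dict) else sc
            )
        if "outcomes" in data:
            data["outcomes"] = tuple(data["outcomes"])
        return cls(**data)


def render_cox_table(fit: survkit.CoxFit) -> str:
    """Model summary table: Beta, SE, HR, 95% CI, P-value, significance."""
    lines = [
        f"{'Term':<32}{'Beta':>8}{'SE':>8}{'HR':>8}{'95% CI':>18}{'P-value':>9}  Sig"
    ]
    summ = fit.summary()
    for term, row in summ.iterrows():
        ci = f"({row.ci_low:.3f}-{row.ci_high:.3f})"
        lines.append(
            f"{term:<32}{row.beta:>8.3f}{row.se:>8.3f}{row.hr:>8.3f}"
            f"{ci:>18}{format_p(row.p):>9}  {significance_code(row.p)}"
        )
    for name, (stat, df, p) in (
        ("Likelihood Ratio Test", fit.lr_test),
        ("Wald Test", fit.wald_test),
        ("Score (logrank) Test", fit.score_test),
    ):
        lines.append(
            f"{name:<32}stat={stat:.2f} df={df} p={format_p(p)} {significance_code(p)}"
        )
    lines.append(SIGNIFICANCE_LEGEND)
    return "\n".join(lines)


def km_table(curve: survkit.SurvivalCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_months": curve.event_times,
            "survival": curve.survival,
            "at_risk": curve.at_risk,
            "events": curve.n_events if curve.n_events is not None else 0,
        }
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; write all artifacts under ``config.outdir``.

    Returns the report bundle: a dict of in-memory results keyed by stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config}
    stage = "load"
    try:
        if config.synth_config is not None:
            sc = config.synth_config
            cna, clinical, labels = synth.generate_cohort(sc)
        else:
            cna = read_cna_matrix(config.cna_path)
            clinical = read_clinical(config.clinical_path)
            labels = (
                read_quantile_labels(config.quantiles_path)
                if config.quantiles_path
                else None
            )
        shared = [p for p in cna.patient_ids if p in set(clinical.patient_ids)]
        if not shared:
            raise ValueError("no patients shared between CNA matrix and clinical table")

        stage = "score"
        score = cna_score.score_and_quartile(cna)
        cna_score.write_score_table(score, outdir / "cna_scores.tsv")
        with open(outdir / "quartile_thresholds.json", "w") as fh:
            json.dump(
                {"thresholds": [float(t) for t in score.thresholds]}, fh
            )
        logger.info("quartile thresholds: %s", score.thresholds)
        bundle["score"] = score

        stage = "survival"
        bundle["km"] = {}
        bundle["logrank"] = {}
        bundle["median"] = {}
        quart = score.quartiles.loc[clinical.data.index]
        for outcome in config.outcomes:
            t, e = clinical.survival(outcome)
            lr = survkit.logrank_test(t, e, quart.astype(str).to_numpy())
            bundle["logrank"][outcome] = lr
            curves = {}
            medians = {}
            for q in ("Q1", "Q2", "Q3", "Q4"):
                mask = (quart == q).to_numpy()
                if mask.sum() == 0:
                    continue
                curve = survkit.km_estimate(t[mask], e[mask])
                curves[q] = curve
                medians[q] = survkit.median_survival(curve)
                km_table(curve).to_csv(
                    outdir / f"km_{outcome.lower()}_{q}.tsv", sep="\t", index=False
                )
            bundle["km"][outcome] = curves
            bundle["median"][outcome] = medians

        stage = "screening"
        bundle["screening"] = {}
        for outcome in config.outcomes:
            rep = assoc.screen_survival_variables(clinical, outcome, alpha=config.alpha)
            rep.write(outdir / f"screening_{outcome.lower()}.tsv")
            bundle["screening"][outcome] = rep
        conf = assoc.screen_confounders(clinical, score, alpha=config.alpha, seed=config.seed)
        conf.write(outdir / "confounders_vs_quartile.tsv")
        bundle["confounders"] = conf

        stage = "cox"
        bundle["cox"] = {}
        bundle["ph"] = {}
        for outcome in config.outcomes:
            fit = survkit.fit_cox_model(
                clinical, score, formula=config.formula, outcome=outcome
            )
            bundle["cox"][outcome] = fit
            with open(outdir / f"cox_{outcome.lower()}.json", "w") as fh:
                json.dump(fit.to_dict(), fh, indent=1)
            (outdir / f"cox_{outcome.lower()}.txt").write_text(render_cox_table(fit))
            diag = survkit.ph_diagnostics(fit)
            bundle["ph"][outcome] = diag
            diag.summary().to_csv(outdir / f"ph_{outcome.lower()}.tsv", sep="\t")

        stage = "tree"
        surv_tree = tree.fit_survival_tree(
            clinical,
            score,
            predictors=config.tree_predictors,
            outcome="DSS",
            alpha=config.tree_alpha,
            min_node=config.tree_min_node,
        )
        surv_tree.to_json(outdir / "tree_dss.json")
        (outdir / "tree_dss.txt").write_text(surv_tree.render())
        bundle["tree"] = surv_tree

        stage = "crosstab"
        if labels is not None:
            xtab = stratify.crosstab(score, labels)
            xtab.write(outdir / "crosstab.tsv")
            bundle["crosstab"] = xtab
            count, frac = stratify.high_risk_overlap(
                xtab, {"Q3", "Q4"}, {"q2", "q3", "q4"}
            )
            bundle["high_risk_overlap"] = {"count": count, "fraction": frac}

        stage = "report"
        run_log = {
            "lumcna_version": __version__,
            "seed": config.seed,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(run_log, fh, indent=1)
        report = render_report(bundle)
        (outdir / "report.md").write_text(report)
        bundle["report"] = report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return bundle


def render_report(bundle: dict) -> str:
    """Human-readable markdown summary of a (possibly partial) bundle."""
    lines = ["# CNA burden survival analysis", ""]
    warn: list[str] = []
    score = bundle.get("score")
    if score is not None:
        t1, t2, t3 = score.thresholds
        lines += [
            f"Cohort: {len(score.table)} patients; quartile thresholds "
            f"{t1:g} / {t2:g} / {t3:g}.",
            "",
        ]
    else:
        warn.append("score table missing")
    medians = bundle.get("median", {})
    for outcome, med in medians.items():
        lr = bundle.get("logrank", {}).get(outcome)
        lines.append(f"## {outcome}")
        for q in ("Q1", "Q2", "Q3", "Q4"):
            if q in med:
                m = med[q]
                text = "not reached" if m is None else f"{m:.2f} months"
                lines.append(f"- median {outcome} in {q}: {text}")
        if lr is not None:
            lines.append(
                f"- log-rank across quartiles: chi2={lr.statistic:.2f}, "
                f"df={lr.df}, p={format_p(lr.p_value)}"
            )
        lines.append("")
    for outcome, fit in bundle.get("cox", {}).items():
        lines += [f"## Cox model ({outcome})", "", "```", render_cox_table(fit), "```", ""]
        diag = bundle.get("ph", {}).get(outcome)
        if diag is not None:
            lines.append(
                f"PH global test: chi2={diag.global_statistic:.2f} "
                f"df={diag.global_df} p={format_p(diag.global_p_value)}"
            )
            lines.append("")
    surv_tree = bundle.get("tree")
    if surv_tree is not None:
        lines += ["## Survival tree (DSS)", "", "```", surv_tree.render(), "```", ""]
    else:
        warn.append("tree missing")
    overlap = bundle.get("high_risk_overlap")
    if overlap is not None:
        lines.append(
            f"High-risk overlap (Q3-Q4 x q2-q4): {overlap['count']} patients "
            f"({100 * overlap['fraction']:.1f}% of the shared cohort)."
        )
        lines.append("")
    if warn:
        lines += ["> Warnings: " + "; ".join(warn), ""]
    return "\n".join(lines)


def simulate_to_dir(config: synth.CohortConfig, outdir) -> None:
    """Write a synthetic cohort in the exact dialects the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cna, clinical, labels = synth.generate_cohort(config)
    write_cna_matrix(cna, outdir / "data_CNA.txt")
    write_clinical(clinical, outdir / "clinical.tsv")
    write_quantile_labels(labels, outdir / "quantile_labels.tsv")
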