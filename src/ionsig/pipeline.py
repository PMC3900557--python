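"""End-to-end orchestration of the signature analysis from a YAML config.

Stages (in order): panel-restricted differential-expression screen on the
paired discovery cohort; signature construction; scoring, dichotomization
and survival modelling on each survival cohort; smoking-stratified score
comparison; random-signature resampling test; subtype screen with PCA and
hierarchical clustering.  Every stage persists its intermediate as TSV so it
can be inspected or re-run independently, and a machine-readable
``summary.json`` collects the headline numbers.  The run is a pure function
of (input files, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, resampling, validation
from .cohort import (ClinicalTable, ExpressionCohort, read_clinical,
                     read_expression)
from .model import SignatureRiskModel
from .signature import RiskScoreResult, build_signature, write_signature
from .survival import km_logrank

__all__ = ["PipelineConfig", "PipelineError", "run_all",
           "compare_scores_by_group"]

log = logging.getLogger("ionsig")


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class CohortSpec:
    name: str
    expression: str
    clinical: str | None = None
    pairing: str | None = None
    outcome: str = "overall"


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration (see ``PipelineConfig.from_yaml``)."""

    discovery: CohortSpec
    survival_cohorts: list[CohortSpec] = field(default_factory=list)
    subtype: CohortSpec | None = None
    panel: str | None = None
    alpha_discovery: float = 0.001
    alpha_subtype: float = 0.05
    resampling_B: int = 1000
    seed: int = 0
    covariates: list[str] = field(default_factory=list)
    outdir: str = "ionsig_out"

    def __post_init__(self) -> None:
        for alpha in (self.alpha_discovery, self.alpha_subtype):
            if not 0.0 < alpha <= 1.0:
                raise ValueError(f"threshold {alpha} outside (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        try:
            discovery = CohortSpec(name="discovery", **raw["discovery"])
            survival_cohorts = [
                CohortSpec(**c) for c in raw.get("survival_cohorts", [])
            ]
            subtype = (CohortSpec(name="subtype", **raw["subtype"])
                       if "subtype" in raw else None)
            cfg = cls(
                discovery=discovery,
                survival_cohorts=survival_cohorts,
                subtype=subtype,
                panel=raw.get("panel"),
                alpha_discovery=raw.get("alpha_discovery", 0.001),
                alpha_subtype=raw.get("alpha_subtype", 0.05),
                resampling_B=raw.get("resampling", {}).get("B", 1000),
                seed=raw.get("resampling", {}).get("seed", raw.get("seed", 0)),
                covariates=raw.get("covariates", []),
                outdir=raw.get("outdir", "ionsig_out"),
            )
        except (KeyError, TypeError) as err:
            raise PipelineError("config", f"invalid configuration: {err}")
        for spec in [discovery, *survival_cohorts,
                     *([subtype] if subtype else [])]:
            for p in (spec.expression, spec.clinical, spec.pairing):
                if p is not None and not Path(p).exists():
                    raise PipelineError("config", f"missing input file: {p}")
        return cfg


def compare_scores_by_group(result: RiskScoreResult,
                            labels: pd.Series) -> dict:
    """Group summary statistics and a Welch-t p for a 2-level split.

    Used e.g. to compare risk scores of ever- vs never-smokers.
    """
    labels = labels.reindex(result.scores.index)
    levels = sorted(labels.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {levels}")
    out = {"groups": {}}
    samples = []
    for lev in levels:
        s = result.scores[labels == lev]
        if len(s) == 0:
            raise ValueError(f"group {lev!r} is empty")
        samples.append(s.to_numpy())
        out["groups"][str(lev)] = {
            "n": int(len(s)),
            "mean": float(s.mean()),
            "median": float(s.median()),
            "sd": float(s.std(ddof=1)),
        }
    _, p = diffexpr.two_sample_t(samples[0], samples[1])
    out["p"] = float(p)
    return out


def _load_cohort(spec: CohortSpec) -> tuple[ExpressionCohort, ClinicalTable | None]:
    expr = read_expression(spec.expression, cohort_name=spec.name,
                           pairing_path=spec.pairing)
    clin = (read_clinical(spec.clinical, cohort_name=spec.name)
            if spec.clinical else None)
    return expr, clin


def run_all(config: PipelineConfig) -> dict:
    """Run the full analysis; returns (and persists) the summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    # ---- discovery screen ------------------------------------------------
    stage = "discovery-screen"
    try:
        log.info("stage %s", stage)
        discovery_expr, _ = _load_cohort(config.discovery)
        panel = None
        if config.panel:
            panel = [ln.strip() for ln in open(config.panel)
                     if ln.strip() and not ln.startswith("#")]
        de = diffexpr.de_screen(discovery_expr, design="paired",
                                alpha=config.alpha_discovery, genes=panel)
        de.to_csv(outdir / "discovery_de.tsv", sep="\t")
        # unrestricted fold changes over all genes, for the resampling universe
        de_all = diffexpr.de_screen(discovery_expr, design="paired", alpha=1.0)
        summary[stage] = {"n_significant": int(len(de)),
                          "alpha": config.alpha_discovery}
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(stage, str(err)) from err

    # ---- signature -------------------------------------------------------
    stage = "signature"
    try:
        log.info("stage %s", stage)
        if len(de) == 0:
            raise PipelineError(stage, "empty signature: no gene passed the "
                                       "discovery threshold")
        sig = build_signature(de, source_cohort=config.discovery.name)
        write_signature(sig, outdir / "signature.tsv")
        summary[stage] = {"n_genes": len(sig), "n_positive": sig.n_positive,
                          "n_negative": sig.n_negative}
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(stage, str(err)) from err

    # ---- survival cohorts ------------------------------------------------
    survival_inputs = []
    summary["survival"] = {}
    for spec in config.survival_cohorts:
        stage = f"survival:{spec.name}"
        try:
            log.info("stage %s", stage)
            expr, clin = _load_cohort(spec)
            if clin is None:
                raise ValueError("survival cohort needs a clinical table")
            model = SignatureRiskModel(expr, clin, sig, outcome=spec.outcome)
            covs = [c for c in config.covariates if clin.has(c)]
            res = model.fit(covariates=covs or None)
            scores = pd.DataFrame({"score": res.risk.scores,
                                   "status": res.risk.status})
            scores.index.name = "sample_id"
            scores.to_csv(outdir / f"scores_{spec.name}.tsv", sep="\t")
            res.cox_status.table.to_csv(
                outdir / f"cox_status_{spec.name}.tsv", sep="\t")
            if res.cox_multivariate is not None:
                res.cox_multivariate.table.to_csv(
                    outdir / f"cox_multivariate_{spec.name}.tsv", sep="\t")
            entry = {
                "outcome": spec.outcome,
                "n": res.n,
                "n_events": res.n_events,
                "logrank_p": res.logrank_p,
                "hazard_ratio": res.hazard_ratio,
                "hr_ci95": [res.cox_status.table.loc["status", "ci_low"],
                            res.cox_status.table.loc["status", "ci_high"]],
                "hr_p": res.cox_status.p("status"),
                "per_point_increase": res.per_point_increase,
            }
            if res.cox_multivariate is not None:
                entry["multivariate_status_hr"] = res.cox_multivariate.hr("status")
                entry["multivariate_status_p"] = res.cox_multivariate.p("status")
            # smoking-stratified analysis where smoking history is recorded
            if clin.has("smoking"):
                smoking = clin.data["smoking"]
                entry["score_by_smoking"] = compare_scores_by_group(
                    res.risk, smoking)
                strata = {}
                for lev in ("ever", "never"):
                    sel = smoking[smoking == lev].index.intersection(
                        res.risk.scores.index)
                    t, e = clin.outcome(spec.outcome)
                    grp = res.risk.status.loc[sel]
                    if grp.nunique() == 2 and e.loc[sel].sum() > 0:
                        km = km_logrank(t.loc[sel], e.loc[sel], grp)
                        strata[lev] = {"n": int(len(sel)),
                                       "logrank_p": km.logrank_p}
                entry["km_by_smoking"] = strata
            summary["survival"][spec.name] = entry
            survival_inputs.append((spec, expr, clin))
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(stage, str(err)) from err

    # ---- resampling non-randomicity test ---------------------------------
    stage = "resampling"
    try:
        log.info("stage %s", stage)
        discovery_fc = de_all["fold_change"]
        summary[stage] = {}
        for outcome in ("overall", "recurrence"):
            cohorts = [
                (expr, clin, spec.outcome)
                for spec, expr, clin in survival_inputs
                if spec.outcome == outcome
            ]
            if not cohorts:
                continue
            res = resampling.non_randomicity_test(
                cohorts, sig, discovery_fc, B=config.resampling_B,
                seed=config.seed)
            np.savetxt(outdir / f"z_null_{outcome}.tsv", res.z_null)
            summary[stage][outcome] = {
                "z_observed": res.z_observed,
                "p_empirical": res.p_empirical,
                "B": res.B,
                "universe_size": res.universe_size,
                "weight_rule": res.weight_rule,
            }
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(stage, str(err)) from err

    # ---- subtype contrast ------------------------------------------------
    if config.subtype is not None:
        stage = "subtype"
        try:
            log.info("stage %s", stage)
            expr, clin = _load_cohort(config.subtype)
            if clin is None or not clin.has("subtype"):
                raise ValueError("subtype cohort needs a clinical table with "
                                 "a 'subtype' column")
            labels = clin.data["subtype"]
            sub_de = diffexpr.de_screen(
                expr, design="two_group", alpha=config.alpha_subtype,
                groups=labels, group_order=("AC", "SCC"))
            sub_de.to_csv(outdir / "subtype_de.tsv", sep="\t")
            entry = {"n_significant": int(len(sub_de)),
                     "alpha": config.alpha_subtype}
            if len(sub_de) >= 2:
                coords = validation.pca_project(expr, genes=list(sub_de.index))
                coords.to_csv(outdir / "subtype_pca.tsv", sep="\t")
                clust = validation.hier_cluster(expr, genes=list(sub_de.index))
                pd.Series(clust["sample_order"]).to_csv(
                    outdir / "subtype_sample_order.tsv", sep="\t",
                    index=False, header=["sample_id"])
                entry["pca_explained"] = [
                    float(v) for v in
                    coords.attrs["explained_variance_ratio"]]
            summary[stage] = entry
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(stage, str(err)) from err

    # ---- stage-distribution comparison across cohorts --------------------
    staged = [(spec.name, clin) for spec, _, clin in survival_inputs
              if clin.has("stage")]
    if len(staged) >= 2:
        stage = "stage-distribution"
        try:
            (name_a, clin_a), (name_b, clin_b) = staged[0], staged[1]
            counts_a = clin_a.data["stage"].value_counts().sort_index()
            counts_b = clin_b.data["stage"].value_counts().reindex(
                counts_a.index, fill_value=0)
            stat, p = validation.categorical_chisq(counts_a, counts_b)
            summary[stage] = {"cohorts": [name_a, name_b],
                              "chi_square": stat, "p": p}
        except ValueError as err:
            log.warning("stage-distribution comparison skipped: %s", err)

    with open(outdir / "summary.json", "wt", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return summary
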