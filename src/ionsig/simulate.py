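"""Synthetic cohort generation.

The generators emulate the statistical structure the downstream analysis
assumes, so every stage can be exercised with a known ground truth:

* a paired normal/tumor design with per-gene log2 fold changes planted on a
  background of null genes (the discovery-cohort layout, 56 patient pairs by
  default);
* a two-subtype design with planted between-group differences (the
  adenocarcinoma vs squamous-cell layout, 50 + 28 samples by default);
* survival / recurrence outcomes drawn from an exponential proportional-
  hazards model driven by a per-patient risk score plus clinical covariates.

Everything is deterministic under the config seed; each generator draws from
its own child stream so adding a call never perturbs another generator's
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import ClinicalTable, ExpressionCohort

__all__ = ["SimulationConfig", "generate_paired", "generate_survival",
           "generate_two_subtypes"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohorts.

    Defaults mirror the discovery-study conditions: 56 normal/tumor pairs on
    a 1000-gene background with 37 planted ion-channel-like effects whose
    |log2 fold change| spans roughly the printed discovery range, log2 noise
    SD 0.5, and an exponential survival model with ~6-year median survival
    and 10-year administrative censoring.
    """

    n_genes: int = 1000
    n_de: int = 37
    n_pairs: int = 56              # patients (paired) or group-A size (two-group)
    n_group_b: int | None = None   # group-B size; defaults to 28 for two-group
    log2fc_range: tuple[float, float] = (0.5, 2.5)
    sigma_gene: float = 0.5        # per-gene noise SD, log2 scale
    baseline_range: tuple[float, float] = (4.0, 12.0)  # log2 baseline means
    beta_score: float = 0.03       # Cox log-hazard per unit of true score
    baseline_hazard: float = 3e-4  # events per day
    censor_window: float = 3650.0  # days
    covariate_effects: dict = field(default_factory=dict)  # name -> log HR
    # covariate marginals
    age_mean: float = 65.0
    age_sd: float = 8.0
    p_male: float = 0.5
    stage_levels: tuple[int, ...] = (1, 2, 3)
    p_smoker: float = 0.5
    p_myc_high: float = 0.3
    p_mutation: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")
        if self.sigma_gene <= 0:
            raise ValueError("sigma_gene must be positive")
        if self.censor_window <= 0:
            raise ValueError("censor_window must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


def _planted_effects(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-gene planted log2 fold changes; signs alternate +/-."""
    delta = np.zeros(cfg.n_genes)
    lo, hi = cfg.log2fc_range
    mags = rng.uniform(lo, hi, size=cfg.n_de)
    signs = np.where(np.arange(cfg.n_de) % 2 == 0, 1.0, -1.0)
    delta[: cfg.n_de] = signs * mags
    return delta


def generate_paired(cfg: SimulationConfig) -> tuple[ExpressionCohort, pd.DataFrame]:
    """Simulate a paired normal/tumor cohort.

    Returns the cohort (with pairing) and a truth table indexed by gene with
    the planted ``planted_log2fc`` (0 for null genes).  The first ``n_de``
    genes carry the planted effects.
    """
    rng = cfg.rng(1)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    baseline = rng.uniform(*cfg.baseline_range, size=cfg.n_genes)
    delta = _planted_effects(cfg, rng)

    normal = baseline[:, None] + rng.normal(0, cfg.sigma_gene,
                                            (cfg.n_genes, cfg.n_pairs))
    tumor = (baseline + delta)[:, None] + rng.normal(
        0, cfg.sigma_gene, (cfg.n_genes, cfg.n_pairs))

    normal_ids = [f"P{i:03d}N" for i in range(cfg.n_pairs)]
    tumor_ids = [f"P{i:03d}T" for i in range(cfg.n_pairs)]
    matrix = pd.DataFrame(np.hstack([normal, tumor]), index=genes,
                          columns=normal_ids + tumor_ids)
    pairing = {f"P{i:03d}": (normal_ids[i], tumor_ids[i])
               for i in range(cfg.n_pairs)}
    truth = pd.DataFrame({"planted_log2fc": delta}, index=pd.Index(genes, name="gene"))
    cohort = ExpressionCohort(matrix, pairing=pairing, cohort_name="synthetic-paired")
    return cohort, truth


def generate_two_subtypes(
    cfg: SimulationConfig,
) -> tuple[ExpressionCohort, pd.Series, pd.DataFrame]:
    """Simulate a two-subtype cohort (e.g. adenocarcinoma vs squamous).

    Returns the cohort, per-sample subtype labels ("AC"/"SCC"), and the
    planted log2(AC/SCC) truth table.  Group sizes are ``n_pairs`` and
    ``n_group_b`` (default 28).
    """
    rng = cfg.rng(2)
    n_a = cfg.n_pairs
    n_b = cfg.n_group_b if cfg.n_group_b is not None else 28
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    baseline = rng.uniform(*cfg.baseline_range, size=cfg.n_genes)
    delta = _planted_effects(cfg, rng)

    group_a = (baseline + delta)[:, None] + rng.normal(
        0, cfg.sigma_gene, (cfg.n_genes, n_a))
    group_b = baseline[:, None] + rng.normal(0, cfg.sigma_gene, (cfg.n_genes, n_b))

    ids_a = [f"AC{i:03d}" for i in range(n_a)]
    ids_b = [f"SCC{i:03d}" for i in range(n_b)]
    matrix = pd.DataFrame(np.hstack([group_a, group_b]), index=genes,
                          columns=ids_a + ids_b)
    labels = pd.Series(["AC"] * n_a + ["SCC"] * n_b, index=ids_a + ids_b,
                       name="subtype")
    truth = pd.DataFrame({"planted_log2fc": delta}, index=pd.Index(genes, name="gene"))
    cohort = ExpressionCohort(matrix, cohort_name="synthetic-subtypes")
    return cohort, labels, truth


def generate_survival(cfg: SimulationConfig, scores: pd.Series,
                      outcome: str = "overall") -> ClinicalTable:
    """Simulate survival outcomes from a proportional-hazards model.

    Event times are exponential with rate
    ``baseline_hazard * exp(beta_score * score + sum(covariate effects))``;
    censoring is uniform on (0, censor_window); the observed time is the
    minimum with the event flag set accordingly.  Covariates are drawn from
    the marginals declared in the config.
    """
    scores = pd.Series(scores)
    if not np.isfinite(scores.to_numpy(dtype=float)).all():
        raise ValueError("scores must be finite")
    rng = cfg.rng(3)
    n = len(scores)

    age = rng.normal(cfg.age_mean, cfg.age_sd, n)
    gender = np.where(rng.random(n) < cfg.p_male, "M", "F")
    stage = rng.choice(cfg.stage_levels, size=n)
    smoking = np.where(rng.random(n) < cfg.p_smoker, "ever", "never")
    myc = np.where(rng.random(n) < cfg.p_myc_high, "high", "low")
    mutation = np.where(rng.random(n) < cfg.p_mutation, "+", "-")

    linpred = cfg.beta_score * scores.to_numpy(dtype=float)
    numeric = {
        "age": age,
        "gender": (gender == "M").astype(float),
        "stage": stage.astype(float),
        "smoking": (smoking == "ever").astype(float),
        "myc": (myc == "high").astype(float),
        "mutation": (mutation == "+").astype(float),
    }
    for name, beta in cfg.covariate_effects.items():
        if name not in numeric:
            raise KeyError(f"unknown covariate {name!r} in covariate_effects")
        linpred = linpred + beta * numeric[name]

    rate = cfg.baseline_hazard * np.exp(linpred)
    event_time = rng.exponential(1.0 / rate)
    censor_time = rng.uniform(0.0, cfg.censor_window, n)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    df = pd.DataFrame(
        {
            f"{outcome}_time": observed,
            f"{outcome}_event": event,
            "age": np.round(age, 1),
            "gender": gender,
            "stage": stage,
            "smoking": smoking,
            "myc": myc,
            "mutation": mutation,
        },
        index=scores.index,
    )
    return ClinicalTable(df, cohort_name="synthetic-survival")
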