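"""Model/Results interface tying scoring and survival analysis together.

:class:`SignatureRiskModel` is constructed from an expression cohort, a
clinical table and a sign-weighted signature; :meth:`~SignatureRiskModel.fit`
scores every patient, dichotomizes at the cohort median, and estimates the
signature's survival association (Kaplan–Meier with log-rank, univariate Cox
on the dichotomized status, Cox on the continuous score, and optionally a
multivariate Cox adjusting for clinical covariates).  The returned
:class:`SignatureRiskResults` carries the estimates, confidence intervals
and p-values and renders them as a summary table.

Example
-------
>>> from ionsig import SignatureRiskModel, ilas_signature
>>> model = SignatureRiskModel(expr, clin, ilas_signature(), outcome="overall")
>>> res = model.fit(covariates=["age", "gender", "stage"])
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cohort import ClinicalTable, ExpressionCohort
from .signature import (RiskScoreResult, Signature, dichotomize,
                        ilas_signature, read_signature, score)
from .survival import (KMEstimate, SurvivalFit, cox_continuous_score,
                       cox_multivariate, cox_univariate, encode_clinical,
                       km_logrank)

__all__ = ["SignatureRiskModel", "SignatureRiskResults"]


class SignatureRiskModel:
    """Signature-based survival risk model for one cohort.

    Parameters
    ----------
    expression
        Log2 expression cohort to score.
    clinical
        Clinical table carrying the requested outcome (and any covariates
        used in the multivariate fit).  Samples are matched to the
        expression cohort by identifier; samples missing from either side
        are excluded from survival fits (scores are computed on the full
        expression cohort, as the median split is cohort-wide).
    signature
        A :class:`~ionsig.signature.Signature`; defaults to the packaged
        37-gene ion-channel signature.
    outcome
        ``"overall"`` or ``"recurrence"``.
    """

    def __init__(self, expression: ExpressionCohort, clinical: ClinicalTable,
                 signature: Signature | None = None, outcome: str = "overall"):
        if outcome not in ("overall", "recurrence"):
            raise ValueError(f"unknown outcome {outcome!r}")
        self.expression = expression
        self.clinical = clinical
        self.signature = signature if signature is not None else ilas_signature()
        self.outcome = outcome

    @classmethod
    def from_files(cls, expression_path, clinical_path, signature_path=None,
                   outcome: str = "overall") -> "SignatureRiskModel":
        from .cohort import read_clinical, read_expression

        sig = read_signature(signature_path) if signature_path else None
        return cls(read_expression(expression_path),
                   read_clinical(clinical_path), sig, outcome=outcome)

    def fit(self, covariates: list[str] | None = None) -> "SignatureRiskResults":
        """Score, stratify and fit the survival models.

        ``covariates`` names clinical columns for an additional multivariate
        Cox fit alongside the signature status (e.g. ``["age", "gender",
        "stage", "smoking", "myc", "mutation"]``); omit for univariate-only.
        """
        risk = dichotomize(score(self.expression, self.signature))
        times, events = self.clinical.outcome(self.outcome)
        common = risk.scores.index.intersection(times.index)
        if len(common) < 2:
            raise ValueError("fewer than 2 samples shared by expression and "
                             "clinical tables")
        t = times.loc[common]
        e = events.loc[common]
        status = risk.status_indicator().loc[common]

        km = km_logrank(t, e, risk.status.loc[common])
        uni = cox_univariate(t, e, status, name="status", outcome=self.outcome)
        cont = cox_continuous_score(t, e, risk.scores.loc[common],
                                    outcome=self.outcome)
        multi = None
        if covariates:
            design = encode_clinical(self.clinical.data.loc[common], covariates)
            design.insert(0, "status", status)
            multi = cox_multivariate(t, e, design, outcome=self.outcome)
        return SignatureRiskResults(
            model=self, risk=risk, km=km, cox_status=uni,
            cox_score=cont, cox_multivariate=multi, n=len(common),
            n_events=int(e.sum()),
        )


@dataclass
class SignatureRiskResults:
    """Fitted signature-risk results for one cohort and outcome."""

    model: SignatureRiskModel
    risk: RiskScoreResult
    km: KMEstimate
    cox_status: SurvivalFit
    cox_score: SurvivalFit
    cox_multivariate: SurvivalFit | None = None
    n: int = 0
    n_events: int = 0

    @property
    def hazard_ratio(self) -> float:
        """Univariate HR of signature-positive vs -negative patients."""
        return self.cox_status.hr("status")

    @property
    def logrank_p(self) -> float:
        return self.km.logrank_p

    @property
    def per_point_increase(self) -> float:
        """Hazard increase per one-point increment of the continuous score."""
        return self.cox_score.per_point_increase("score")

    def summary(self) -> str:
        sig = self.model.signature
        lines = [
            "Signature risk model",
            "=" * 60,
            f"cohort:            {self.model.expression.cohort_name or '<unnamed>'}",
            f"outcome:           {self.model.outcome} survival",
            f"signature:         {len(sig)} genes "
            f"({sig.n_positive} up, {sig.n_negative} down; "
            f"{len(self.risk.dropped_genes)} absent from platform)",
            f"patients (events): {self.n} ({self.n_events})",
            f"median risk score: {self.risk.median:+.3f}",
            f"log-rank P:        {self.km.logrank_p:.4g}",
            "",
            "Univariate Cox (status positive vs negative):",
            self.cox_status.summary().to_string(),
            "",
            f"Continuous score: +{100 * self.per_point_increase:.1f}% hazard "
            f"per point (P = {self.cox_score.p('score'):.4g})",
        ]
        if self.cox_multivariate is not None:
            lines += ["", "Multivariate Cox:",
                      self.cox_multivariate.summary().to_string()]
        return "\n".join(lines)

    def plot_km(self, ax=None):
        """Kaplan–Meier curves for the positive/negative strata."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        colors = {"positive": "tab:red", "negative": "tab:blue"}
        for label, curve in self.km.curves.items():
            ax.step(curve["time"], curve["survival"], where="post",
                    label=str(label), color=colors.get(str(label)))
        ax.set_xlabel(f"{self.model.outcome} survival time (days)")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.legend(title=f"log-rank P = {self.km.logrank_p:.3g}")
        return ax
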