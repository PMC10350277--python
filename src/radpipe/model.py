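"""Top-level modelling interface.

:class:`RadiomicSignature` is the model object: it holds a patients x
features table and the survival outcome, and ``fit()`` runs the
(optional) bootstrap wrapper-forward feature selection followed by the
final multivariate Cox fit, returning a :class:`RadiomicSignatureResults`
with coefficients, Wald inference, the stored normalization statistics
and risk threshold, a ``summary()`` table, and evaluation helpers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coxph import CoxFit
from .selection import SelectionConfig, SelectionResult, bootstrap_select
from .survival_eval import (EvalReport, SignatureModel, SurvivalData,
                            compute_signature, evaluate_signature,
                            harrell_cindex, stratify, train_signature)

__all__ = ["RadiomicSignature", "RadiomicSignatureResults"]


class RadiomicSignature:
    """Radiomic prognostic-signature model for overall survival.

    Parameters
    ----------
    features : DataFrame
        Raw (un-normalized) patients x features table, e.g. the output of
        the extraction stage after stability screening.
    survival : SurvivalData
        Follow-up times (months) and event indicators, row-aligned with
        ``features``.
    selection : SelectionConfig, optional
        Parameters of the bootstrap wrapper-forward selection; defaults
        follow the development protocol (100 bootstraps x 20 repeats,
        univariate p < 0.05 screen, top 20, final 5).
    selected_features : list of str, optional
        Skip selection and fit the final Cox model on these features.
    """

    def __init__(self, features: pd.DataFrame, survival: SurvivalData,
                 selection: SelectionConfig | None = None,
                 selected_features: list[str] | None = None):
        if len(features) != len(survival):
            raise ValueError("features and survival lengths differ")
        self.features = features
        self.survival = survival
        self.selection_config = selection or SelectionConfig()
        self.selected_features = selected_features

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str = "time_months",
                       event_col: str = "event",
                       feature_cols: list[str] | None = None,
                       **kwargs) -> "RadiomicSignature":
        """Build the model from a single tidy frame holding outcome
        columns next to feature columns."""
        surv = SurvivalData(df[time_col].to_numpy(), df[event_col].to_numpy(),
                            df["patient_id"].to_numpy() if "patient_id" in df
                            else None)
        if feature_cols is None:
            drop = {time_col, event_col, "patient_id"}
            feature_cols = [c for c in df.columns if c not in drop]
        return cls(df[feature_cols].copy(), surv, **kwargs)

    def fit(self, seed: int = 0) -> "RadiomicSignatureResults":
        """Run selection (unless features were fixed) and the final Cox
        fit; deterministic given ``seed``."""
        selection_result = None
        if self.selected_features is not None:
            final = list(self.selected_features)
        else:
            # selection operates on the Z-scored table (training statistics)
            x = self.features.to_numpy(dtype=float)
            sd = x.std(axis=0)
            keep = sd > 0
            z = pd.DataFrame(
                (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep],
                columns=self.features.columns[keep])
            selection_result = bootstrap_select(z, self.survival,
                                                self.selection_config,
                                                base_seed=seed)
            final = selection_result.final_features
            if not final:
                raise RuntimeError("selection returned no features")
        sig, cox_fit = train_signature(self.features, self.survival, final)
        return RadiomicSignatureResults(self, sig, cox_fit, selection_result)


class RadiomicSignatureResults:
    """Fitted signature: coefficients, inference, and evaluation."""

    def __init__(self, model: RadiomicSignature, signature: SignatureModel,
                 cox_fit: CoxFit, selection: SelectionResult | None):
        self.model = model
        self.signature = signature
        self.cox_fit = cox_fit
        self.selection = selection

    # -- statsmodels-like accessors -------------------------------------
    @property
    def params(self) -> pd.Series:
        """Cox coefficients on the Z-scored feature scale."""
        return pd.Series(self.signature.coef, index=self.signature.features)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.cox_fit.se, index=self.signature.features)

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(self.cox_fit.pvalues, index=self.signature.features)

    @property
    def threshold(self) -> float:
        """Training-median signature score (risk threshold)."""
        return self.signature.threshold

    def predict(self, features: pd.DataFrame | None = None) -> np.ndarray:
        """Signature scores for new (or the training) patients."""
        if features is None:
            features = self.model.features
        return compute_signature(self.signature, features)

    def risk_groups(self, features: pd.DataFrame | None = None) -> np.ndarray:
        return stratify(self.predict(features), self.signature.threshold)

    def training_cindex(self) -> float:
        return harrell_cindex(self.predict(), self.model.survival)

    def evaluate(self, features: pd.DataFrame | None = None,
                 survival: SurvivalData | None = None,
                 n_boot: int = 100, rng=None) -> EvalReport:
        """Bootstrap C-index, hazard ratio and log-rank on a cohort
        (training cohort by default)."""
        if features is None:
            features = self.model.features
            survival = self.model.survival
        if survival is None:
            raise ValueError("survival must accompany external features")
        return evaluate_signature(self.signature, features, survival,
                                  n_boot=n_boot, rng=rng)

    def summary(self) -> str:
        """Human-readable fit summary table."""
        hrci = self.cox_fit.hr_ci()
        rows = []
        for i, name in enumerate(self.signature.features):
            rows.append(
                f"{name:<48s} {self.signature.mean[i]:>9.4g} "
                f"{self.signature.sd[i]:>9.4g} {self.signature.coef[i]:>9.4g} "
                f"{hrci[i, 0]:>9.3g} {self.cox_fit.pvalues[i]:>9.3g}")
        head = (f"{'feature':<48s} {'mean':>9s} {'sd':>9s} {'coef':>9s} "
                f"{'HR':>9s} {'p':>9s}")
        n = len(self.model.survival)
        lines = [
            "Radiomic prognostic signature (Cox PH, Efron ties)",
            f"n patients: {n}   events: {self.model.survival.n_events}   "
            f"censoring: {self.model.survival.censoring_fraction:.1%}",
            f"partial log-likelihood: {self.cox_fit.loglik:.3f}   "
            f"training C-index: {self.training_cindex():.3f}",
            f"risk threshold (training median score): {self.threshold:.4f}",
            "-" * len(head), head, "-" * len(head), *rows, "-" * len(head),
        ]
        if self.selection is not None:
            top = self.selection.counts.head(len(self.signature.features))
            lines.append("selection counts: "
                         + ", ".join(f"{k}={v}" for k, v in top.items()))
        return "\n".join(lines)
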