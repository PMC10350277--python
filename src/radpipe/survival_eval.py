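"""Signature training, risk stratification and survival statistics.

Covers Cox signature training (via :mod:`radpipe.coxph`), the linear
Z-scored signature score, median-threshold high/low risk stratification,
Harrell's concordance index (with bootstrap distribution), Kaplan-Meier
curves with Greenwood bands, the two-group log-rank test, hazard ratios,
and rank-based comparisons of C-index distributions (Mann-Whitney /
Kruskal-Wallis with Tukey-Kramer correction on rank means).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .coxph import CoxFit, fit_cox

__all__ = [
    "SurvivalData", "SignatureModel", "KmCurve", "EvalReport",
    "compute_signature", "train_signature", "stratify", "harrell_cindex",
    "bootstrap_cindex", "kaplan_meier", "logrank_test", "group_hr",
    "compare_models", "signature_vs_stage", "load_published_signature",
    "evaluate_signature",
]


@dataclass
class SurvivalData:
    """Per-patient overall-survival follow-up.

    ``time`` is months from diagnosis to death or last follow-up;
    ``event`` is 1 for death, 0 for censored.
    """

    time: np.ndarray
    event: np.ndarray
    patient_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have the same length")
        if np.any(self.time <= 0):
            raise ValueError("follow-up times must be positive")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event indicators must be 0/1")
        if self.patient_id is None:
            self.patient_id = np.array(
                [f"P{i:04d}" for i in range(len(self.time))])
        else:
            self.patient_id = np.asarray(self.patient_id)

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def censoring_fraction(self) -> float:
        return 1.0 - self.event.mean()

    def subset(self, idx) -> "SurvivalData":
        return SurvivalData(self.time[idx], self.event[idx],
                           self.patient_id[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"patient_id": self.patient_id,
                             "time_months": self.time, "event": self.event})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalData":
        pid = df["patient_id"].to_numpy() if "patient_id" in df else None
        return cls(df["time_months"].to_numpy(), df["event"].to_numpy(), pid)


@dataclass
class SignatureModel:
    """A fitted radiomic prognostic signature.

    The score of a patient is sum_f beta_f * (x_f - mu_f) / s_f over the
    ordered signature features; ``threshold`` is the training-median score
    used for high/low risk stratification (None when unknown, as for the
    published model whose source does not report it).
    """

    features: list[str]
    mean: np.ndarray
    sd: np.ndarray
    coef: np.ndarray
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.coef = np.asarray(self.coef, dtype=float)
        k = len(self.features)
        if not (len(self.mean) == len(self.sd) == len(self.coef) == k):
            raise ValueError("features/mean/sd/coef must have equal length")
        if np.any(self.sd <= 0):
            raise ValueError("normalization SDs must be positive")

    def to_json(self, path: str) -> None:
        obj = {"features": list(self.features), "mean": self.mean.tolist(),
               "sd": self.sd.tolist(), "coef": self.coef.tolist(),
               "threshold": self.threshold}
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path_or_obj) -> "SignatureModel":
        if isinstance(path_or_obj, dict):
            obj = path_or_obj
        else:
            with open(path_or_obj) as fh:
                obj = json.load(fh)
        return cls(obj["features"], obj["mean"], obj["sd"], obj["coef"],
                   obj.get("threshold"))


def load_published_signature() -> SignatureModel:
    """The published 5-feature T2w waveletLLL signature shipped with the
    package (normalization statistics and Cox coefficients; the training
    median threshold was not reported and is None)."""
    ref = resources.files("radpipe") / "assets" / "published_signature.json"
    return SignatureModel.from_json(json.loads(ref.read_text()))


def compute_signature(model: SignatureModel, raw_features) -> np.ndarray:
    """Signature scores = beta . zscore(x) for one or many patients.

    ``raw_features`` may be a DataFrame (rows = patients), a Series or a
    dict of feature name -> value.  All model features must be present.
    """
    if isinstance(raw_features, dict):
        raw_features = pd.Series(raw_features)
    if isinstance(raw_features, pd.Series):
        raw_features = raw_features.to_frame().T
    missing = [f for f in model.features if f not in raw_features.columns]
    if missing:
        raise KeyError(f"missing signature feature(s): {missing}")
    x = raw_features[model.features].to_numpy(dtype=float)
    z = (x - model.mean) / model.sd
    return z @ model.coef


def train_signature(features: pd.DataFrame, survival: SurvivalData,
                    selected_names: list[str], ties: str = "efron"
                    ) -> tuple[SignatureModel, CoxFit]:
    """Fit the final multivariate Cox model on raw feature values.

    Stores the training per-feature mean/SD (used to Z-score), the fitted
    coefficients on the Z-scored scale, and the training-median score as
    the risk threshold.
    """
    missing = [f for f in selected_names if f not in features.columns]
    if missing:
        raise KeyError(f"selected feature(s) not in table: {missing}")
    x = features[selected_names].to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = [selected_names[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant feature(s) cannot be Z-scored: {bad}")
    z = (x - mu) / sd
    fit = fit_cox(z, survival.time, survival.event, ties=ties)
    model = SignatureModel(list(selected_names), mu, sd, fit.coef)
    scores = compute_signature(model, features)
    model.threshold = float(np.median(scores))
    return model, fit


def stratify(scores: np.ndarray, threshold: float) -> np.ndarray:
    """High/low risk labels: score > threshold -> 'high', else 'low'."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    return np.where(scores > threshold, "high", "low")


def harrell_cindex(scores: np.ndarray, survival: SurvivalData) -> float:
    """Harrell's concordance index between risk scores and survival.

    Comparable pairs: the earlier time carries an event; concordant when
    the shorter time has the higher score; score ties count 0.5.
    """
    s = np.asarray(scores, dtype=float)
    t, e = survival.time, survival.event
    # pair (i, j) comparable iff t_i < t_j and e_i == 1 (plus ties in t
    # with one event, handled by evaluating both orderings)
    ti, tj = t[:, None], t[None, :]
    ei = e[:, None]
    comparable = (ti < tj) & (ei == 1)
    si, sj = s[:, None], s[None, :]
    concordant = comparable & (si > sj)
    tied = comparable & (si == sj)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    return float((concordant.sum() + 0.5 * tied.sum()) / n_comp)


def bootstrap_cindex(scores: np.ndarray, survival: SurvivalData,
                     n_boot: int = 100, rng=None
                     ) -> tuple[float, tuple[float, float], np.ndarray]:
    """Bootstrap distribution of the C-index over patient resamples.

    Returns (median, (q25, q75), full distribution).  Resamples with no
    comparable pair are redrawn.
    """
    rng = np.random.default_rng(rng)
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    out = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            try:
                out[b] = harrell_cindex(scores[idx], survival.subset(idx))
                break
            except ValueError:
                continue
        else:
            raise ValueError("could not draw a resample with comparable pairs")
    q25, q50, q75 = np.percentile(out, [25, 50, 75])
    return float(q50), (float(q25), float(q75)), out


@dataclass
class KmCurve:
    """Kaplan-Meier product-limit estimate with Greenwood 95% band."""

    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(survival: SurvivalData) -> KmCurve:
    """Product-limit estimator over the distinct event times, with the
    plain Greenwood 95% pointwise confidence band (clipped to [0, 1])."""
    t, e = survival.time, survival.event
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])

    surv, var_sum = [], []
    s = 1.0
    gw = 0.0
    at_risk = []
    for et in event_times:
        n_at = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d / n_at
        if n_at > d:
            gw += d / (n_at * (n_at - d))
        else:
            gw = np.inf
        at_risk.append(n_at)
        surv.append(s)
        var_sum.append(gw)

    surv = np.asarray(surv)
    with np.errstate(invalid="ignore"):  # S=0 with exhausted risk set
        se = surv * np.sqrt(np.asarray(var_sum))
    se = np.where(np.isfinite(se), se, 0.0)
    lo = np.clip(surv - 1.96 * se, 0.0, 1.0)
    hi = np.clip(surv + 1.96 * se, 0.0, 1.0)
    return KmCurve(event_times, np.asarray(at_risk), surv, lo, hi)


def logrank_test(groups: np.ndarray, survival: SurvivalData
                 ) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 nonempty groups, got {len(labels)}")
    if survival.n_events == 0:
        raise ValueError("log-rank requires at least one event")
    a = groups == labels[0]
    res = _ll_logrank(survival.time[a], survival.time[~a],
                      event_observed_A=survival.event[a],
                      event_observed_B=survival.event[~a])
    return float(res.test_statistic), float(res.p_value)


def group_hr(groups: np.ndarray, survival: SurvivalData,
             reference: str = "low") -> tuple[float, tuple[float, float]]:
    """Hazard ratio of the non-reference group from a univariate Cox fit
    on the group indicator, with Wald 95% CI."""
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("need exactly 2 groups")
    other = [l for l in labels if l != reference]
    if len(other) != 1:
        raise ValueError(f"reference {reference!r} not among groups {labels}")
    ind = (groups == other[0]).astype(float)[:, None]
    for g in labels:
        if survival.event[groups == g].sum() == 0:
            raise ValueError(f"group {g!r} has no events")
    fit = fit_cox(ind, survival.time, survival.event)
    hr, lo, hi = fit.hr_ci()[0]
    return float(hr), (float(lo), float(hi))


def _tukey_kramer_ranks(samples: list[np.ndarray]) -> np.ndarray:
    """Pairwise Tukey-Kramer-adjusted p-values on rank means (the
    post-hoc conventionally paired with Kruskal-Wallis)."""
    k = len(samples)
    all_vals = np.concatenate(samples)
    n_total = len(all_vals)
    ranks = stats.rankdata(all_vals)
    # tie-corrected variance of the ranks
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (n_total - 1)
    s2 = (n_total * (n_total + 1) / 12.0) - tie_term / 12.0

    means, sizes = [], []
    pos = 0
    for s in samples:
        means.append(ranks[pos:pos + len(s)].mean())
        sizes.append(len(s))
        pos += len(s)

    pvals = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(s2 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            q = abs(means[i] - means[j]) / se * np.sqrt(2.0)
            p = float(stats.studentized_range.sf(q, k, np.inf))
            pvals[i, j] = pvals[j, i] = min(1.0, p)
    return pvals


def compare_models(cindex_distributions: list[np.ndarray],
                   labels: list[str]) -> pd.DataFrame:
    """Compare bootstrap C-index distributions between models.

    Two models: Mann-Whitney U.  More: Kruskal-Wallis omnibus followed by
    Tukey-Kramer pairwise comparison of rank means.  Returns a tidy frame
    with one row per model pair and the (adjusted) p-value.
    """
    dists = [np.asarray(d, dtype=float) for d in cindex_distributions]
    if len(dists) < 2:
        raise ValueError("need at least 2 distributions")
    n0 = len(dists[0])
    if any(len(d) != n0 for d in dists):
        raise ValueError("distributions must have equal bootstrap length")
    if len(labels) != len(dists):
        raise ValueError("labels must match distributions")

    rows = []
    if len(dists) == 2:
        stat, p = stats.mannwhitneyu(dists[0], dists[1],
                                     alternative="two-sided")
        rows.append((labels[0], labels[1], float(p)))
    else:
        pmat = _tukey_kramer_ranks(dists)
        for i in range(len(dists)):
            for j in range(i + 1, len(dists)):
                rows.append((labels[i], labels[j], float(pmat[i, j])))
    return pd.DataFrame(rows, columns=["model_a", "model_b", "p_adjusted"])


def signature_vs_stage(scores: np.ndarray, stage_labels: np.ndarray,
                       survival: SurvivalData,
                       advanced_stages: tuple[str, ...] = ("IVa", "IVb")
                       ) -> dict:
    """Relate the signature to TNM stage.

    Compares score distributions across stages (Mann-Whitney for two,
    Kruskal-Wallis + Tukey-Kramer for more; singleton stages excluded
    with a warning entry) and fits a joint Cox model with the signature
    and a binary advanced-stage covariate, reporting both hazard ratios.
    """
    scores = np.asarray(scores, dtype=float)
    stage_labels = np.asarray(stage_labels)
    stages, counts = np.unique(stage_labels, return_counts=True)
    kept = [s for s, c in zip(stages, counts) if c >= 2]
    excluded = [s for s, c in zip(stages, counts) if c < 2]
    if len(kept) < 2:
        raise ValueError("need at least 2 represented stages")

    samples = [scores[stage_labels == s] for s in kept]
    if len(kept) == 2:
        _, omnibus_p = stats.mannwhitneyu(*samples, alternative="two-sided")
        pairwise = pd.DataFrame([(kept[0], kept[1], float(omnibus_p))],
                                columns=["model_a", "model_b", "p_adjusted"])
    else:
        _, omnibus_p = stats.kruskal(*samples)
        pmat = _tukey_kramer_ranks(samples)
        rows = [(kept[i], kept[j], float(pmat[i, j]))
                for i in range(len(kept)) for j in range(i + 1, len(kept))]
        pairwise = pd.DataFrame(rows,
                                columns=["model_a", "model_b", "p_adjusted"])

    advanced = np.isin(stage_labels, advanced_stages).astype(float)
    if len(np.unique(advanced)) < 2:
        raise ValueError("stage covariate is constant in this cohort")
    x = np.column_stack([scores, advanced])
    fit = fit_cox(x, survival.time, survival.event)
    hr = fit.hr_ci()

    return {
        "stages": kept,
        "excluded_singleton_stages": excluded,
        "omnibus_p": float(omnibus_p),
        "pairwise": pairwise,
        "hr_signature": tuple(hr[0]),
        "hr_stage": tuple(hr[1]),
        "cox_pvalues": fit.pvalues.tolist(),
    }


@dataclass
class EvalReport:
    """Headline evaluation of a signature on one cohort."""

    cindex_median: float
    cindex_iqr: tuple[float, float]
    hazard_ratio: float
    hr_ci: tuple[float, float]
    logrank_stat: float
    logrank_p: float
    n_high: int
    n_low: int
    cindex_distribution: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {"cindex_median": self.cindex_median,
                "cindex_iqr": list(self.cindex_iqr),
                "hazard_ratio": self.hazard_ratio,
                "hr_ci": list(self.hr_ci),
                "logrank_stat": self.logrank_stat,
                "logrank_p": self.logrank_p,
                "n_high": self.n_high, "n_low": self.n_low}


def evaluate_signature(model: SignatureModel, features: pd.DataFrame,
                       survival: SurvivalData, n_boot: int = 100,
                       rng=None) -> EvalReport:
    """Full evaluation: bootstrap C-index distribution, high/low HR and
    log-rank p at the model's stored threshold."""
    if model.threshold is None:
        raise ValueError("model has no risk threshold; supply one by "
                         "setting model.threshold (e.g. a training median)")
    scores = compute_signature(model, features)
    med, iqr, dist = bootstrap_cindex(scores, survival, n_boot, rng)
    labels = stratify(scores, model.threshold)
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold produced a single risk group")
    hr, ci = group_hr(labels, survival)
    lr_stat, lr_p = logrank_test(labels, survival)
    return EvalReport(med, iqr, hr, ci, lr_stat, lr_p,
                      int((labels == "high").sum()), int((labels == "low").sum()),
                      dist)
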