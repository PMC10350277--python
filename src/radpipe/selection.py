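"""Bootstrap wrapper-forward Cox feature selection.

The second selection step of the pipeline: repeated random 70/30
partitions of the training cohort; per partition a univariate Cox screen
(Wald p < 0.05, 20 lowest p retained) followed by greedy forward
multivariate Cox selection maximizing the validation C-index; selection
counts accumulated over 100 partitions x 20 repeat seeds; the 5
most-selected features form the final signature set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coxph import CoxConvergenceError, fit_cox
from .survival_eval import SurvivalData, harrell_cindex

__all__ = ["SelectionConfig", "SelectionResult", "split_bootstrap",
           "univariate_screen", "forward_wrapper", "bootstrap_select"]

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    """Parameters of the bootstrap wrapper-forward selection protocol."""

    n_bootstrap: int = 100
    train_fraction: float = 0.70
    univariate_alpha: float = 0.05
    top_k_univariate: int = 20
    n_repeats: int = 20
    final_k: int = 5
    seeds: list[int] | None = None
    #: evaluate wrapper C-index on the held-out 30% (True) or on the
    #: training side (False, for sensitivity analysis)
    eval_on_validation: bool = True
    improvement_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.final_k > self.top_k_univariate:
            raise ValueError("final_k cannot exceed top_k_univariate")
        if self.seeds is not None and len(self.seeds) != self.n_repeats:
            raise ValueError("seeds must have length n_repeats")

    def resolved_seeds(self, base_seed: int = 0) -> list[int]:
        if self.seeds is not None:
            return list(self.seeds)
        ss = np.random.SeedSequence(base_seed)
        return [int(s) for s in
                ss.generate_state(self.n_repeats) % (2 ** 31)]


@dataclass
class SelectionResult:
    """Selection counts and the final feature list."""

    counts: pd.Series  # per-feature selection count, descending
    final_features: list[str]
    iteration_log: list[dict] = field(repr=False, default_factory=list)
    n_iterations: int = 0
    n_empty_iterations: int = 0

    @property
    def total_selections(self) -> int:
        return int(self.counts.sum())


def split_bootstrap(survival: SurvivalData, train_fraction: float,
                    rng: np.random.Generator, min_events: int = 2,
                    max_tries: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint train/validation partition by patient count
    (train size = round(train_fraction * n)), redrawn until each side
    has at least ``min_events`` events."""
    n = len(survival)
    if n < 10:
        raise ValueError("need at least 10 patients to split")
    n_train = int(round(train_fraction * n))
    for _ in range(max_tries):
        perm = rng.permutation(n)
        tr, va = perm[:n_train], perm[n_train:]
        if (survival.event[tr].sum() >= min_events
                and survival.event[va].sum() >= min_events):
            return np.sort(tr), np.sort(va)
    raise ValueError(
        f"could not draw a split with >= {min_events} events per side "
        f"in {max_tries} tries (total events: {survival.n_events})")


def univariate_screen(features: pd.DataFrame, survival: SurvivalData,
                      alpha: float = 0.05, top_k: int = 20) -> list[str]:
    """Per-feature univariate Cox Wald screen.

    Keeps features with p < alpha, ordered by ascending p, truncated to
    ``top_k``.  Non-convergent or degenerate fits are skipped with a log
    entry.
    """
    pvals = {}
    t, e = survival.time, survival.event
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)[:, None]
        try:
            fit = fit_cox(x, t, e)
        except (CoxConvergenceError, ValueError) as exc:
            logger.debug("univariate fit skipped for %s: %s", name, exc)
            continue
        pvals[name] = float(fit.pvalues[0])
    passing = sorted((p, name) for name, p in pvals.items() if p < alpha)
    return [name for _, name in passing[:top_k]]


def forward_wrapper(candidates: list[str], features: pd.DataFrame,
                    survival: SurvivalData, train_idx: np.ndarray,
                    val_idx: np.ndarray, eval_on_validation: bool = True,
                    tol: float = 1e-6) -> tuple[list[str], float]:
    """Greedy forward selection maximizing the C-index of the Cox fit.

    Models are fitted on the training side; the C-index used to accept a
    step is evaluated on the validation side (default).  The empty model
    has C-index 0.5 by definition; the search stops at the first step
    with no strict improvement (> tol) and returns the best set found.
    """
    eval_idx = val_idx if eval_on_validation else train_idx
    eval_surv = survival.subset(eval_idx)
    train_surv = survival.subset(train_idx)

    selected: list[str] = []
    best_c = 0.5
    remaining = list(candidates)
    while remaining:
        step_best = None
        for name in remaining:
            cols = selected + [name]
            x_tr = features.iloc[train_idx][cols].to_numpy(dtype=float)
            try:
                fit = fit_cox(x_tr, train_surv.time, train_surv.event)
            except (CoxConvergenceError, ValueError) as exc:
                logger.debug("wrapper fit skipped for %s: %s", cols, exc)
                continue
            scores = features.iloc[eval_idx][cols].to_numpy(dtype=float) @ fit.coef
            try:
                c = harrell_cindex(scores, eval_surv)
            except ValueError:
                continue
            if step_best is None or c > step_best[0]:
                step_best = (c, name)
        if step_best is None or step_best[0] <= best_c + tol:
            break
        best_c, chosen = step_best
        selected.append(chosen)
        remaining.remove(chosen)
    return selected, best_c


def bootstrap_select(features: pd.DataFrame, survival: SurvivalData,
                     cfg: SelectionConfig | None = None,
                     base_seed: int = 0) -> SelectionResult:
    """Run the full repeated-bootstrap selection protocol.

    For each repeat seed, ``n_bootstrap`` iterations of split -> screen ->
    forward wrapper increment per-feature selection counts; the final
    list is the ``final_k`` highest-count features over all repeats.
    Count ties are broken by higher full-cohort univariate C-index, then
    feature name.  Deterministic given the seed list.
    """
    cfg = cfg or SelectionConfig()
    if len(features) != len(survival):
        raise ValueError("feature table and survival lengths differ")
    seeds = cfg.resolved_seeds(base_seed)

    counts = pd.Series(0, index=features.columns, dtype=int)
    log: list[dict] = []
    n_empty = 0
    for rep, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        for it in range(cfg.n_bootstrap):
            tr, va = split_bootstrap(survival, cfg.train_fraction, rng)
            cand = univariate_screen(features.iloc[tr], survival.subset(tr),
                                     cfg.univariate_alpha,
                                     cfg.top_k_univariate)
            if not cand:
                n_empty += 1
                log.append({"repeat": rep, "iteration": it,
                            "selected": [], "val_cindex": np.nan})
                continue
            sel, c = forward_wrapper(cand, features, survival, tr, va,
                                     cfg.eval_on_validation,
                                     cfg.improvement_tol)
            for name in sel:
                counts[name] += 1
            log.append({"repeat": rep, "iteration": it,
                        "selected": sel, "val_cindex": c})

    # tie-break: full-cohort univariate C-index, then name
    uni_c = {}
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        try:
            uni_c[name] = harrell_cindex(x, survival)
        except ValueError:
            uni_c[name] = 0.5
    ranking = sorted(counts.index,
                     key=lambda f: (-counts[f], -uni_c[f], f))
    final = [f for f in ranking[:cfg.final_k] if counts[f] > 0]

    counts_sorted = counts.loc[ranking]
    return SelectionResult(counts_sorted, final, log,
                           n_iterations=cfg.n_repeats * cfg.n_bootstrap,
                           n_empty_iterations=n_empty)
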