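"""Agreement between a selected feature set and the clinically established set.

Treats the domain-knowledge list as ground truth over the candidate-feature
universe and scores any selection as a binary classification of features:
a 2x2 matrix (selected vs established) and the standard accuracy /
precision / recall / F1 read off it.  Also provides the conventional
comparator: per-coefficient Wald tests from a single unpenalized logistic
regression on all features, which in near-saturated designs (p close to n,
correlated blocks) is typically unstable and selects nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .cohort import CohortTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgreementMatrix:
    """Counts over the candidate universe (selected vs established)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def universe_size(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def compare_selection(
    selected: set[str], established: set[str], universe: set[str]
) -> AgreementMatrix:
    """Cross-tabulate a selection against the established set."""
    selected, established, universe = set(selected), set(established), set(universe)
    stray = sorted(selected - universe) or sorted(established - universe)
    if stray:
        raise ValueError(f"feature(s) outside the universe: {stray}")
    tp = len(selected & established)
    fp = len(selected - established)
    fn = len(established - selected)
    tn = len(universe - (selected | established))
    return AgreementMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def agreement_metrics(
    m: AgreementMatrix,
) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, f1) in percent over the universe.

    Degenerate precision (no features selected) is reported as 0.
    """
    if m.universe_size == 0:
        raise ValueError("empty universe")
    acc = 100.0 * (m.tp + m.tn) / m.universe_size
    prec = 100.0 * m.tp / (m.tp + m.fp) if m.tp + m.fp else 0.0
    rec = 100.0 * m.tp / (m.tp + m.fn) if m.tp + m.fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return acc, prec, rec, f1


@dataclass(frozen=True)
class LogisticSelection:
    """Result of the conventional comparator, with stability diagnostics."""

    selected: tuple[str, ...]
    converged: bool
    flagged: bool  # separation / non-convergence / near-singular design
    message: str = ""


def baseline_logistic_selection(
    cohort: CohortTable, alpha: float = 0.05
) -> LogisticSelection:
    """Single all-features maximum-likelihood logistic fit; returns features
    whose Wald p-value is below ``alpha``.

    With p close to n and correlated predictors the unpenalized fit is
    frequently unstable (quasi-separation, huge standard errors); such fits
    are flagged and typically yield an empty selection.
    """
    cohort.require_both_classes()
    x = sm.add_constant(cohort.values, has_constant="add")
    names = ["const"] + cohort.schema.names
    flagged = False
    message = ""
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(cohort.outcome, x).fit(disp=False, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", False))
        pvals = np.asarray(fit.pvalues)
        bse = np.asarray(fit.bse)
        if not converged:
            flagged, message = True, "maximum-likelihood fit did not converge"
        elif not np.isfinite(pvals).all() or np.nanmax(bse) > 1e3:
            flagged, message = True, "unstable fit: non-finite or huge standard errors"
        selected = tuple(
            n for n, p in zip(names[1:], pvals[1:]) if np.isfinite(p) and p < alpha
        )
    except Exception as exc:  # separation, singular Hessian, ...
        log.warning("logistic baseline failed: %s", exc)
        return LogisticSelection(
            selected=(), converged=False, flagged=True, message=str(exc)
        )
    if flagged:
        log.warning("logistic baseline flagged: %s", message)
    return LogisticSelection(
        selected=selected, converged=converged, flagged=flagged, message=message
    )
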