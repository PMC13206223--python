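"""Two-sample Hotelling T-squared machinery.

T² generalizes the squared pooled two-sample t statistic to d dimensions:

    T² = (n0 n1 / (n0+n1)) · δᵀ S⁻¹ δ,

with δ the mean difference between groups and S the pooled sample
covariance (denominator n0+n1−2).  Under multivariate normality and equal
covariances, F = ((n0+n1−d−1)/(d (n0+n1−2))) · T² follows an F distribution
with (d, n0+n1−d−1) degrees of freedom, giving exact p-values.  A seeded
permutation fallback covers the regime where the F degrees of freedom are
invalid (n0+n1−d−1 < 1).

``feature_significance`` applies the test per feature to the d-dimensional
encoded token vectors of a trained selector, producing the learned
("OURS") feature set at a per-feature significance level with no
multiplicity correction; Bonferroni and Benjamini–Hochberg adjusted
p-values are reported alongside for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PINV_RTOL = 1e-10  # singular values below this fraction of the largest are dropped


@dataclass(frozen=True)
class HotellingResult:
    """Per-feature test result."""

    feature: str
    t2: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    significant: bool
    singular: bool = False  # pseudo-inverse fallback was used


@dataclass(frozen=True)
class SelectionReport:
    """All per-feature results plus the selected ("OURS") feature list,
    ordered by descending T² with name as the deterministic tie-break."""

    alpha: float
    results: tuple[HotellingResult, ...]
    selected: tuple[str, ...]
    p_bonferroni: tuple[float, ...]
    p_bh: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature": [r.feature for r in self.results],
                "t2": [r.t2 for r in self.results],
                "f": [r.f_stat for r in self.results],
                "df1": [r.df1 for r in self.results],
                "df2": [r.df2 for r in self.results],
                "p": [r.p_value for r in self.results],
                "p_bonferroni": self.p_bonferroni,
                "p_bh": self.p_bh,
                "selected": [r.significant for r in self.results],
            }
        )
        return df


def _validate_groups(group_a: np.ndarray, group_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be 2-D with a common feature dimension")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 rows")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    return a, b


def hotelling_t2(
    group_a: np.ndarray, group_b: np.ndarray, ridge: float = 0.0
) -> float:
    """Two-sample T² with optional ridge regularization of the pooled
    covariance.  With ``ridge=0`` and a singular covariance the
    Moore–Penrose pseudo-inverse is used (see :func:`hotelling_t2_flagged`
    to learn whether that happened)."""
    t2, _ = hotelling_t2_flagged(group_a, group_b, ridge)
    return t2


def hotelling_t2_flagged(
    group_a: np.ndarray, group_b: np.ndarray, ridge: float = 0.0
) -> tuple[float, bool]:
    a, b = _validate_groups(group_a, group_b)
    n0, n1 = a.shape[0], b.shape[0]
    d = a.shape[1]
    delta = a.mean(axis=0) - b.mean(axis=0)
    s_pooled = (
        (n0 - 1) * np.cov(a, rowvar=False, ddof=1).reshape(d, d)
        + (n1 - 1) * np.cov(b, rowvar=False, ddof=1).reshape(d, d)
    ) / (n0 + n1 - 2)
    m = s_pooled + ridge * np.eye(d)
    singular = False
    if ridge > 0:
        y = np.linalg.solve(m, delta)
    else:
        try:
            y = np.linalg.solve(m, delta)
            # reject solutions from numerically singular systems
            if not np.isfinite(y).all() or np.linalg.cond(m) > 1.0 / PINV_RTOL:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            y = np.linalg.pinv(m, rcond=PINV_RTOL) @ delta
            singular = True
    t2 = float(n0 * n1 / (n0 + n1) * delta @ y)
    return max(t2, 0.0), singular


def t2_pvalue(t2: float, n0: int, n1: int, d: int) -> tuple[float, float]:
    """F-transform of T² and its upper-tail p-value.

    Raises if the error degrees of freedom n0+n1−d−1 fall below 1, in which
    case :func:`permutation_pvalue` is the appropriate fallback.
    """
    df1 = d
    df2 = n0 + n1 - d - 1
    if df2 < 1:
        raise ValueError(
            f"invalid F degrees of freedom (df2={df2}); "
            "use permutation_pvalue instead"
        )
    f = (df2 / (df1 * (n0 + n1 - 2))) * t2
    p = float(stats.f.sf(f, df1, df2))
    return f, p


def permutation_pvalue(
    group_a: np.ndarray,
    group_b: np.ndarray,
    ridge: float = 0.0,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for T²: p = (1 + #{T²_perm ≥ T²_obs}) / (n_perm + 1)."""
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    a, b = _validate_groups(group_a, group_b)
    n0 = a.shape[0]
    pooled = np.vstack([a, b])
    observed = hotelling_t2(a, b, ridge)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        pa, pb = pooled[perm[:n0]], pooled[perm[n0:]]
        if hotelling_t2(pa, pb, ridge) >= observed - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


def test_features(
    encoded: np.ndarray,
    outcome: np.ndarray,
    feature_names: list[str],
    alpha: float = 0.05,
    ridge: float = 0.0,
) -> SelectionReport:
    """Per-feature T² test on encoded token vectors.

    Parameters
    ----------
    encoded
        (n, p, d) array of per-feature representations (CLS excluded).
    outcome
        length-n 0/1 vector; both classes must be present with ≥ 2 members.
    """
    encoded = np.asarray(encoded, dtype=float)
    y = np.asarray(outcome).astype(int)
    if encoded.ndim != 3 or encoded.shape[0] != y.shape[0]:
        raise ValueError("encoded must be (n, p, d) aligned with outcome")
    if len(feature_names) != encoded.shape[1]:
        raise ValueError("feature_names length mismatch")
    mask1 = y == 1
    n1, n0 = int(mask1.sum()), int((~mask1).sum())
    if min(n0, n1) < 2:
        raise ValueError("each outcome class needs at least 2 samples")
    d = encoded.shape[2]
    results = []
    for j, name in enumerate(feature_names):
        xj = encoded[:, j, :]
        t2, singular = hotelling_t2_flagged(xj[~mask1], xj[mask1], ridge)
        f, p = t2_pvalue(t2, n0, n1, d)
        results.append(
            HotellingResult(
                feature=name, t2=t2, f_stat=f, df1=d, df2=n0 + n1 - d - 1,
                p_value=p, significant=p < alpha, singular=singular,
            )
        )
    pvals = np.array([r.p_value for r in results])
    p_bonf = np.minimum(pvals * len(pvals), 1.0)
    p_bh = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else np.array([])
    selected = sorted(
        (r for r in results if r.significant), key=lambda r: (-r.t2, r.feature)
    )
    return SelectionReport(
        alpha=alpha,
        results=tuple(results),
        selected=tuple(r.feature for r in selected),
        p_bonferroni=tuple(p_bonf),
        p_bh=tuple(p_bh),
    )


# the name looks like a pytest item when imported into test modules
test_features.__test__ = False  # type: ignore[attr-defined]


def feature_significance(selector, cohort, alpha: float = 0.05) -> SelectionReport:
    """Encode the full cohort with a trained selector and test each
    feature's token representations between outcome groups, yielding the
    learned ("OURS") feature set at the given per-feature level."""
    cohort.require_both_classes()
    encoded = selector.encode_cohort(cohort)  # (n, p+1, d), CLS at index 0
    return test_features(
        encoded[:, 1:, :],
        cohort.outcome,
        cohort.schema.names,
        alpha=alpha,
        ridge=selector.hp.posthoc_ridge,
    )
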