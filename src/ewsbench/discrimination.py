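"""ROC / AUROC machinery with tie handling and paired comparison of
correlated AUROCs via per-subject placement values (DeLong).

Scores follow the fixed convention higher = higher predicted risk.  Ties,
ubiquitous with small-integer clinical scores, receive half credit — the
AUROC here is exactly the tie-corrected Mann-Whitney statistic and equals
the trapezoidal area under the empirical ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RocCurve",
    "AurocEstimate",
    "PairedAurocTest",
    "compute_roc",
    "auroc",
    "paired_delong_test",
    "global_delong_test",
    "compare_systems",
]


class DegenerateOutcomeError(ValueError):
    """Outcome vector contains only cases or only controls."""


def _as_arrays(scores, outcomes):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if s.ndim != 1 or y.ndim != 1 or len(s) != len(y):
        raise ValueError("scores and outcomes must be 1-D sequences of equal length")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if y.all() or not y.any():
        raise DegenerateOutcomeError(
            "need at least one case and one control to form an ROC curve"
        )
    return s, y


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC operating points for the criterion ``score >= threshold``."""

    thresholds: np.ndarray  # descending, +inf first
    fpr: np.ndarray  # 1 - specificity, non-decreasing
    tpr: np.ndarray  # sensitivity, non-decreasing

    def area(self) -> float:
        """Trapezoidal area under the curve."""
        return float(np.trapezoid(self.tpr, self.fpr))


@dataclass(frozen=True)
class AurocEstimate:
    """AUROC with DeLong variance and the placements needed for paired tests."""

    auroc: float
    variance: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    case_placements: np.ndarray = field(repr=False)
    control_placements: np.ndarray = field(repr=False)

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "variance": self.variance,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
        }


@dataclass(frozen=True)
class PairedAurocTest:
    """Chi-square test of equality of two correlated AUROCs."""

    delta: float
    variance: float
    chi2: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "delta": self.delta,
            "variance": self.variance,
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
        }


def compute_roc(scores, outcomes) -> RocCurve:
    """Empirical ROC: one operating point per unique score value.

    The first point is the empty criterion (threshold +inf, at (0, 0));
    the last, the all-positive criterion at (1, 1).
    """
    s, y = _as_arrays(scores, outcomes)
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    m = int(y.sum())
    n = len(y) - m
    # cumulative cases/controls at each distinct threshold
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(~y)[distinct]
    thresholds = np.r_[np.inf, s[distinct]]
    tpr = np.r_[0.0, tp / m]
    fpr = np.r_[0.0, fp / n]
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr)


def _placements(scores: np.ndarray, outcomes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject placement values via midranks (handles ties in O(N log N)).

    case placement V10_i  = P(case_i outranks a random control), half credit for ties;
    control placement V01_j = P(a random case outranks control_j).
    """
    cases = scores[outcomes]
    controls = scores[~outcomes]
    m, n = len(cases), len(controls)
    tx = stats.rankdata(cases)
    ty = stats.rankdata(controls)
    tz = stats.rankdata(np.r_[cases, controls])
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return v10, v01


def auroc(scores, outcomes, alpha: float = 0.05, ci_scale: str = "linear") -> AurocEstimate:
    """Tie-corrected AUROC with DeLong variance and a Wald confidence interval.

    ``ci_scale='logit'`` transforms the Wald interval through the logistic
    function instead of clipping on the probability scale.
    """
    s, y = _as_arrays(scores, outcomes)
    v10, v01 = _placements(s, y)
    m, n = len(v10), len(v01)
    theta = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(var)
    if ci_scale == "logit" and 0 < theta < 1 and se > 0:
        logit = np.log(theta / (1 - theta))
        lse = se / (theta * (1 - theta))
        lo, hi = (1 / (1 + np.exp(-(logit + sgn * z * lse))) for sgn in (-1, 1))
    else:
        lo = max(0.0, theta - z * se)
        hi = min(1.0, theta + z * se)
    return AurocEstimate(
        auroc=theta,
        variance=var,
        ci_low=float(lo),
        ci_high=float(hi),
        n_cases=m,
        n_controls=n,
        case_placements=v10,
        control_placements=v01,
    )


def _delta_variance(a: AurocEstimate, b: AurocEstimate) -> float:
    """DeLong variance of the AUROC difference for two scores on the same subjects."""
    if a.n_cases != b.n_cases or a.n_controls != b.n_controls:
        raise ValueError("paired comparison requires identical subjects under both scores")
    m, n = a.n_cases, a.n_controls
    s10 = np.cov(a.case_placements, b.case_placements, ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(a.control_placements, b.control_placements, ddof=1) if n > 1 else np.zeros((2, 2))
    return float(
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )


def paired_delong_test(score_a, score_b, outcomes) -> PairedAurocTest:
    """Chi-square (df=1) test of AUROC(a) = AUROC(b) on the same subjects."""
    est_a = auroc(score_a, outcomes)
    est_b = auroc(score_b, outcomes)
    delta = est_a.auroc - est_b.auroc
    var = _delta_variance(est_a, est_b)
    if var <= 0:
        if abs(delta) < 1e-12:
            return PairedAurocTest(delta=0.0, variance=0.0, chi2=0.0, df=1, p_value=1.0)
        raise ValueError(
            f"zero variance of the AUROC difference with nonzero delta {delta:g}"
        )
    chi2 = delta**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return PairedAurocTest(delta=float(delta), variance=var, chi2=float(chi2), df=1, p_value=p)


def global_delong_test(score_table: dict, outcomes) -> PairedAurocTest:
    """Global contrast that all k AUROCs are equal (chi-square, df = k-1)."""
    names = list(score_table)
    ests = [auroc(score_table[nm], outcomes) for nm in names]
    k = len(ests)
    if k < 2:
        raise ValueError("need at least two scores for a global contrast")
    m, n = ests[0].n_cases, ests[0].n_controls
    v10 = np.vstack([e.case_placements for e in ests])
    v01 = np.vstack([e.control_placements for e in ests])
    cov = np.cov(v10, ddof=1) / m + np.cov(v01, ddof=1) / n
    theta = np.array([e.auroc for e in ests])
    L = np.hstack([np.ones((k - 1, 1)), -np.eye(k - 1)])  # theta_1 - theta_j
    d = L @ theta
    mid = L @ cov @ L.T
    chi2 = float(d @ np.linalg.pinv(mid) @ d)
    df = int(np.linalg.matrix_rank(mid))
    p = float(stats.chi2.sf(chi2, df=df)) if df > 0 else 1.0
    return PairedAurocTest(
        delta=float(np.max(np.abs(d))), variance=float(np.trace(mid)), chi2=chi2, df=df, p_value=p
    )


def compare_systems(cohort, alpha: float = 0.05, include_global: bool = True) -> dict:
    """Full discrimination report for a scored cohort.

    ``cohort`` is either a list of objects with ``scores`` (name -> int) and
    ``died_7d`` attributes, or a pandas DataFrame with score columns and a
    boolean ``died_7d`` column.  Returns AUROC estimates per system and the
    pairwise DeLong tests for every system pair on the identical subject set.
    """
    if hasattr(cohort, "columns"):
        y = np.asarray(cohort["died_7d"], dtype=bool)
        names = [c for c in cohort.columns if c != "died_7d"]
        table = {nm: np.asarray(cohort[nm], dtype=float) for nm in names}
    else:
        cohort = list(cohort)
        y = np.array([c.died_7d for c in cohort], dtype=bool)
        names = list(cohort[0].scores)
        table = {nm: np.array([c.scores[nm] for c in cohort], dtype=float) for nm in names}
    estimates = {nm: auroc(table[nm], y, alpha=alpha) for nm in names}
    tests = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            tests[f"{a}_vs_{b}"] = paired_delong_test(table[a], table[b], y)
    report = {
        "n": int(len(y)),
        "n_cases": int(y.sum()),
        "alpha": alpha,
        "estimates": {nm: est.to_dict() for nm, est in estimates.items()},
        "tests": {nm: t.to_dict() for nm, t in tests.items()},
    }
    if include_global and len(names) > 2:
        report["global_test"] = global_delong_test(table, y).to_dict()
    report["_estimates"] = estimates
    report["_tests"] = tests
    return report
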