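import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, ndtr

from ewsbench.discrimination import (
    DegenerateOutcomeError,
    auroc,
    compare_systems,
    compute_roc,
    global_delong_test,
    paired_delong_test,
)
from ewsbench.simulate import make_fixture


def auroc_bruteforce(scores, outcomes):
    """All-pairs Mann-Whitney oracle: 1 / 0.5 / 0 per (case, control) pair."""
    s = np.asarray(scores, float)
    y = np.asarray(outcomes, bool)
    cases, controls = s[y], s[~y]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


def rank_auroc(scores, y):
    """Independent fast formula used inside bootstrap loops."""
    r = stats.rankdata(scores)
    m = y.sum()
    return (r[y].sum() - m * (m + 1) / 2) / (m * (len(y) - m))


# ---------------------------------------------------------------------------
# ROC curve
# ---------------------------------------------------------------------------

def test_roc_hand_example():
    curve = compute_roc([1, 2, 3, 4], [False, False, True, True])
    np.testing.assert_allclose(curve.fpr, [0, 0, 0, 0.5, 1])
    np.testing.assert_allclose(curve.tpr, [0, 0.5, 1, 1, 1])
    assert curve.thresholds[0] == np.inf
    assert curve.area() == pytest.approx(1.0)


def test_roc_constant_scores():
    curve = compute_roc([2, 2, 2, 2], [True, False, True, False])
    np.testing.assert_allclose(curve.fpr, [0, 1])
    np.testing.assert_allclose(curve.tpr, [0, 1])
    assert curve.area() == pytest.approx(0.5)


def test_roc_endpoints_and_monotone():
    rng = np.random.default_rng(0)
    s = rng.integers(0, 10, 200).astype(float)
    y = rng.random(200) < 0.3
    curve = compute_roc(s, y)
    assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
    assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)
    assert (np.diff(curve.fpr) >= 0).all()
    assert (np.diff(curve.tpr) >= 0).all()


def test_reversed_labels_mirror():
    rng = np.random.default_rng(1)
    s = rng.normal(size=100)
    y = rng.random(100) < 0.4
    a = auroc(s, y).auroc
    b = auroc(s, ~y).auroc
    assert a + b == pytest.approx(1.0)


def test_degenerate_outcomes_error():
    with pytest.raises(DegenerateOutcomeError):
        compute_roc([1, 2], [True, True])
    with pytest.raises(DegenerateOutcomeError):
        auroc([1, 2], [False, False])


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

def test_perfect_separation():
    est = auroc([0, 0, 1, 1], [False, False, True, True])
    assert est.auroc == 1.0


def test_worked_six_observation_fixture():
    fx = make_fixture("roc_worked")
    # cases {2, 4, 5} vs controls {1, 2, 3}: 9 pairs, one tie -> 7.5 / 9
    expected = auroc_bruteforce(fx["score"], fx["died"])
    assert expected == pytest.approx(7.5 / 9)
    est = auroc(fx["score"], fx["died"])
    assert est.auroc == pytest.approx(expected, abs=1e-12)


def test_auroc_equals_bruteforce_small_n():
    rng = np.random.default_rng(2)
    for _ in range(100):
        n = int(rng.integers(4, 31))
        y = np.zeros(n, bool)
        y[rng.choice(n, int(rng.integers(1, n)), replace=False)] = True
        s = rng.integers(0, 5, n).astype(float)  # heavy ties
        if y.all() or not y.any():
            continue
        assert auroc(s, y).auroc == pytest.approx(auroc_bruteforce(s, y), abs=1e-12)


def test_auroc_equals_trapezoid_area():
    rng = np.random.default_rng(3)
    for _ in range(20):
        s = rng.integers(0, 8, 300).astype(float)
        y = rng.random(300) < 0.2
        assert auroc(s, y).auroc == pytest.approx(compute_roc(s, y).area(), abs=1e-12)


def test_complement_symmetry():
    rng = np.random.default_rng(4)
    s = rng.integers(0, 12, 500).astype(float)
    y = rng.random(500) < 0.3
    assert auroc(-s, y).auroc == pytest.approx(1 - auroc(s, y).auroc, abs=1e-12)


def test_rank_invariance():
    rng = np.random.default_rng(5)
    s = rng.normal(size=400)
    y = rng.random(400) < expit(s - 1.5)
    if y.sum() < 2:
        y[:2] = True
    base = auroc(s, y)
    for transform in (lambda x: np.exp(x / 3), lambda x: 2 * x + 1, lambda x: x**3):
        t = auroc(transform(s), y)
        assert t.auroc == pytest.approx(base.auroc, abs=1e-12)
        assert t.variance == pytest.approx(base.variance, rel=1e-9)


def test_ci_contains_estimate_and_is_clipped():
    rng = np.random.default_rng(6)
    s = rng.integers(0, 20, 300).astype(float)
    y = rng.random(300) < 0.1
    est = auroc(s, y)
    assert 0 <= est.ci_low <= est.auroc <= est.ci_high <= 1
    logit = auroc(s, y, ci_scale="logit")
    assert 0 < logit.ci_low <= logit.auroc <= logit.ci_high < 1


def test_binormal_closed_form_recovery():
    rng = np.random.default_rng(7)
    delta = 1.2
    n = 3000
    s = np.r_[rng.normal(delta, 1, n), rng.normal(0, 1, n)]
    y = np.r_[np.ones(n, bool), np.zeros(n, bool)]
    est = auroc(s, y)
    assert abs(est.auroc - ndtr(delta / np.sqrt(2))) < 3 * est.se


# ---------------------------------------------------------------------------
# paired DeLong test
# ---------------------------------------------------------------------------

def test_identical_scores_give_p_one():
    rng = np.random.default_rng(8)
    s = rng.integers(0, 10, 200).astype(float)
    y = rng.random(200) < 0.2
    t = paired_delong_test(s, s, y)
    assert t.chi2 == 0.0 and t.p_value == 1.0 and t.delta == 0.0


def test_zero_variance_nonzero_delta_errors():
    y = np.array([True, True, False, False])
    a = np.array([1.0, 1.0, 0.0, 0.0])  # AUROC 1
    b = np.array([0.0, 0.0, 1.0, 1.0])  # AUROC 0
    with pytest.raises(ValueError, match="zero variance"):
        paired_delong_test(a, b, y)


def test_delong_variance_matches_bootstrap():
    rng = np.random.default_rng(9)
    n = 200
    z = rng.normal(size=n)
    a = z + rng.normal(size=n)
    b = 0.8 * z + rng.normal(size=n)
    y = rng.random(n) < expit(-1.5 + 1.6 * z)
    t = paired_delong_test(a, b, y)
    se_delong = np.sqrt(t.variance)
    deltas = []
    for _ in range(2000):
        idx = rng.integers(0, n, n)
        yy = y[idx]
        if yy.sum() < 2 or yy.sum() > n - 2:
            continue
        deltas.append(rank_auroc(a[idx], yy) - rank_auroc(b[idx], yy))
    se_boot = np.std(deltas)
    assert abs(se_delong - se_boot) / se_boot < 0.2


def test_null_pvalues_uniform():
    rng = np.random.default_rng(10)
    pvals = []
    for _ in range(500):
        n = 300
        y = np.zeros(n, bool)
        y[rng.choice(n, 30, replace=False)] = True
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        pvals.append(paired_delong_test(a, b, y).p_value)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_rank_invariance_of_test():
    rng = np.random.default_rng(11)
    n = 300
    z = rng.normal(size=n)
    a = z + rng.normal(size=n)
    b = z + rng.normal(size=n)
    y = rng.random(n) < expit(-1 + z)
    t1 = paired_delong_test(a, b, y)
    t2 = paired_delong_test(np.exp(a), 3 * b - 7, y)
    assert t2.chi2 == pytest.approx(t1.chi2, rel=1e-9)


def test_unpaired_subjects_rejected():
    from ewsbench.discrimination import _delta_variance

    a = auroc([1, 2, 3, 4], [True, True, False, False])
    b = auroc([1, 2, 3, 4, 5, 6], [True, True, True, False, False, False])
    with pytest.raises(ValueError, match="identical subjects"):
        _delta_variance(a, b)


# ---------------------------------------------------------------------------
# compare_systems
# ---------------------------------------------------------------------------

def _toy_cohort_frame(rng, n=400, oxygen=True):
    import pandas as pd

    z = rng.normal(size=n)
    toks = np.clip(np.round(3 + 2 * z + rng.normal(0, 1, n)), 0, 18)
    ox = (rng.random(n) < expit(z - 1)) if oxygen else np.zeros(n, bool)
    mtoks = toks + 2 * ox
    news = np.clip(np.round(3.5 + 2.2 * z + rng.normal(0, 1, n)), 0, 20)
    died = rng.random(n) < expit(-3 + 1.5 * z)
    if died.sum() < 2:
        died[:2] = True
    return pd.DataFrame(
        {"TOKS": toks, "mTOKS": mtoks, "NEWS": news, "died_7d": died}
    )


def test_compare_systems_structure():
    rng = np.random.default_rng(13)
    rep = compare_systems(_toy_cohort_frame(rng))
    assert set(rep["estimates"]) == {"TOKS", "mTOKS", "NEWS"}
    assert set(rep["tests"]) == {"TOKS_vs_mTOKS", "TOKS_vs_NEWS", "mTOKS_vs_NEWS"}
    assert "global_test" in rep and rep["global_test"]["df"] == 2
    for est in rep["estimates"].values():
        assert est["ci_low"] <= est["auroc"] <= est["ci_high"]


def test_no_oxygen_users_makes_toks_mtoks_identical():
    rng = np.random.default_rng(14)
    rep = compare_systems(_toy_cohort_frame(rng, oxygen=False))
    t = rep["tests"]["TOKS_vs_mTOKS"]
    assert t["delta"] == 0.0 and t["p_value"] == 1.0


def test_global_test_self_consistent():
    rng = np.random.default_rng(15)
    df = _toy_cohort_frame(rng)
    y = df["died_7d"].to_numpy()
    g = global_delong_test(
        {"a": df["TOKS"].to_numpy(), "b": df["TOKS"].to_numpy()}, y
    )
    assert g.chi2 == pytest.approx(0.0, abs=1e-9) and g.p_value == pytest.approx(1.0)


def test_compare_systems_accepts_case_objects():
    from types import SimpleNamespace

    rng = np.random.default_rng(16)
    df = _toy_cohort_frame(rng, n=200)
    cases = [
        SimpleNamespace(
            scores={"TOKS": r.TOKS, "mTOKS": r.mTOKS, "NEWS": r.NEWS}, died_7d=r.died_7d
        )
        for r in df.itertuples()
    ]
    rep = compare_systems(cases)
    assert rep["estimates"]["TOKS"]["auroc"] == pytest.approx(
        auroc(df["TOKS"], df["died_7d"]).auroc
    )
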