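"""The statistics battery against brute-force and closed-form oracles."""

import numpy as np
import pytest
from scipy.stats import binom

from pelvisal.evalstats import (
    ReaderStudy,
    ScoredCohort,
    auprc,
    auroc,
    balanced_accuracy,
    bootstrap_ci,
    confusion_metrics,
    evaluate_cohort,
    mcnemar_test,
    per_category_breakdown,
    read_cohort_csv,
    reader_study_report,
    write_cohort_csv,
    youden_cutoff,
)


# ---------------------------------------------------------------------------
# independent oracles

def auroc_pairs_oracle(scores, labels):
    """O(n^2) Mann-Whitney concordance with half-credit ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def auprc_sweep_oracle(scores, labels):
    """Exhaustive threshold sweep of the PR step curve."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    s = np.asarray(scores)[order]
    y = np.asarray(labels)[order]
    n_pos = y.sum()
    area, prev_recall = 0.0, 0.0
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


def youden_sweep_oracle(scores, labels):
    best_j, best_t = -np.inf, None
    uniq = np.unique(scores)
    cands = np.concatenate([[uniq[0] - 0.5], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 0.5]])
    for t in cands:
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        if sens + spec - 1 > best_j + 1e-15:
            best_j, best_t = sens + spec - 1, t
    return best_j


# ---------------------------------------------------------------------------

def _random_cohort(rng, n=40):
    labels = rng.integers(0, 2, size=n)
    if labels.sum() in (0, n):
        labels[0], labels[1] = 0, 1
    scores = rng.choice(np.round(np.linspace(0, 1, 11), 2), size=n)
    return ScoredCohort(scores=scores, labels=labels)


def test_auroc_trivial_cases():
    assert auroc(ScoredCohort(scores=[1, 1, 0, 0], labels=[1, 1, 0, 0])) == 1.0
    assert auroc(ScoredCohort(scores=[0.5] * 6, labels=[1, 0, 1, 0, 1, 0])) == 0.5
    with pytest.raises(ValueError, match="both classes"):
        auroc(ScoredCohort(scores=[0.1, 0.2], labels=[1, 1]))


def test_auroc_matches_pairwise_oracle():
    rng = np.random.default_rng(0)
    for _ in range(25):
        c = _random_cohort(rng, n=50)
        assert auroc(c) == pytest.approx(
            auroc_pairs_oracle(c.scores, c.labels), abs=1e-12
        )


def test_auprc_trivial_cases():
    assert auprc(ScoredCohort(scores=[0.9, 0.8, 0.1, 0.2], labels=[1, 1, 0, 0])) == 1.0
    # constant scores: one threshold, precision = prevalence
    c = ScoredCohort(scores=[0.5] * 10, labels=[1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
    assert auprc(c) == pytest.approx(0.3)
    with pytest.raises(ValueError, match="positive"):
        auprc(ScoredCohort(scores=[0.1], labels=[0]))


def test_auprc_matches_threshold_sweep_oracle():
    rng = np.random.default_rng(1)
    for _ in range(25):
        c = _random_cohort(rng, n=30)
        assert auprc(c) == pytest.approx(
            auprc_sweep_oracle(c.scores, c.labels), abs=1e-12
        )


def test_bootstrap_degenerate_metric_collapses():
    c = ScoredCohort(scores=[0.2, 0.8, 0.4, 0.9], labels=[0, 1, 0, 1])
    lo, hi = bootstrap_ci(lambda _: 0.77, c, n_boot=50, seed=0)
    assert lo == hi == 0.77


def test_bootstrap_runs_exactly_n_boot_evaluations():
    c = ScoredCohort(scores=[0.2, 0.8, 0.4, 0.9], labels=[0, 1, 0, 1])
    calls = {"n": 0}

    def metric(sub):
        calls["n"] += 1
        return float(np.mean(sub.scores))

    bootstrap_ci(metric, c, n_boot=2000, seed=1)
    assert calls["n"] == 2000


def test_bootstrap_seed_contract():
    rng = np.random.default_rng(2)
    c = _random_cohort(rng, n=30)
    a = bootstrap_ci(auroc, c, n_boot=200, seed=1)
    b = bootstrap_ci(auroc, c, n_boot=200, seed=1)
    d = bootstrap_ci(auroc, c, n_boot=200, seed=2)
    assert a == b
    assert a != d


def test_bootstrap_brackets_point_and_widens_with_small_n():
    rng = np.random.default_rng(3)
    big = _random_cohort(rng, n=200)
    small = big.subset(np.arange(20))
    if len(np.unique(small.labels)) < 2:
        small = big.subset(np.arange(25))
    for c in (big, small):
        lo, hi = bootstrap_ci(auroc, c, n_boot=300, seed=0)
        assert lo <= auroc(c) <= hi
    wb = np.subtract(*bootstrap_ci(auroc, big, n_boot=300, seed=0)[::-1])
    ws = np.subtract(*bootstrap_ci(auroc, small, n_boot=300, seed=0)[::-1])
    assert ws > wb


def test_youden_matches_sweep_and_tie_break():
    rng = np.random.default_rng(4)
    for _ in range(20):
        c = _random_cohort(rng, n=20)
        t = youden_cutoff(c)
        pred = c.scores >= t
        sens = (pred & (c.labels == 1)).sum() / (c.labels == 1).sum()
        spec = (~pred & (c.labels == 0)).sum() / (c.labels == 0).sum()
        assert sens + spec - 1 == pytest.approx(youden_sweep_oracle(c.scores, c.labels))
    # perfect separation: the midpoint threshold achieves J = 1
    c = ScoredCohort(scores=[0.9, 0.8, 0.2, 0.1], labels=[1, 1, 0, 0])
    t = youden_cutoff(c)
    assert 0.2 < t < 0.8
    m = confusion_metrics(c, t)
    assert m["sensitivity"] + m["specificity"] - 1 == 1.0
    # all scores tied: J = 0 at the degenerate threshold
    c = ScoredCohort(scores=[0.5] * 4, labels=[1, 0, 1, 0])
    t = youden_cutoff(c)
    m = confusion_metrics(c, t)
    assert m["sensitivity"] + m["specificity"] - 1 == 0.0


def test_confusion_metrics_symmetric_table():
    scores = [1.0] * 9 + [0.0] * 1 + [0.0] * 9 + [1.0] * 1
    labels = [1] * 10 + [0] * 10
    m = confusion_metrics(ScoredCohort(scores=scores, labels=labels), 0.5)
    for k in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
        assert m[k] == pytest.approx(0.9)


def test_confusion_metrics_all_predicted_positive():
    c = ScoredCohort(scores=[1.0, 1.0, 1.0, 1.0], labels=[1, 0, 1, 0])
    m = confusion_metrics(c, 0.5)
    assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0


def test_confusion_metrics_random_counts_match_formulas():
    rng = np.random.default_rng(5)
    for _ in range(10):
        tp, fn, tn, fp = rng.integers(1, 20, size=4)
        scores = [1.0] * tp + [0.0] * fn + [0.0] * tn + [1.0] * fp
        labels = [1] * (tp + fn) + [0] * (tn + fp)
        m = confusion_metrics(ScoredCohort(scores=scores, labels=labels), 0.5)
        assert m["accuracy"] == pytest.approx((tp + tn) / (tp + fn + tn + fp))
        assert m["sensitivity"] == pytest.approx(tp / (tp + fn))
        assert m["specificity"] == pytest.approx(tn / (tn + fp))
        assert m["ppv"] == pytest.approx(tp / (tp + fp))
        assert m["npv"] == pytest.approx(tn / (tn + fn))


def test_per_category_counts():
    scores = [0.9, 0.9, 0.1, 0.9, 0.2, 0.1]
    labels = [1, 1, 1, 1, 1, 0]
    cats = [["a"], ["a", "b"], ["a"], ["b"], ["b"], []]
    df = per_category_breakdown(ScoredCohort(scores=scores, labels=labels, categories=cats), 0.5)
    overall = df[df.category == "overall"].iloc[0]
    assert overall.n_detected == 3 and overall.n_missed == 2
    a = df[df.category == "a"].iloc[0]
    assert a.n_detected == 2 and a.n_missed == 1
    assert a.sensitivity == pytest.approx(2 / 3)
    b = df[df.category == "b"].iloc[0]
    assert b.n_detected == 2 and b.n_missed == 1


def test_mcnemar_closed_forms():
    truth = [1] * 20
    a = [1] * 20
    assert mcnemar_test(a, a, truth) == 1.0
    # b=10, c=0: exact two-sided p = 2 * 0.5^10
    a = [1] * 10 + [0] * 10
    b = [0] * 10 + [0] * 10
    truth = [1] * 20
    assert mcnemar_test(a, b, truth) == pytest.approx(2 * 0.5**10, rel=1e-12)
    # b=5, c=3 against the binomial closed form
    a = [1] * 5 + [0] * 3 + [1] * 4
    b = [0] * 5 + [1] * 3 + [1] * 4
    truth = [1] * 12
    expected = min(1.0, 2 * binom.cdf(3, 8, 0.5))
    assert mcnemar_test(a, b, truth) == pytest.approx(expected, rel=1e-12)


def test_mcnemar_symmetric_and_chi2_branch():
    rng = np.random.default_rng(6)
    n = 60
    truth = [1] * n
    a = [1] * 20 + [0] * 15 + [1] * 25
    b = [0] * 20 + [1] * 15 + [1] * 25
    p_ab = mcnemar_test(a, b, truth)
    p_ba = mcnemar_test(b, a, truth)
    assert p_ab == pytest.approx(p_ba)
    # b+c = 35 >= 25: chi-square with continuity correction
    from scipy.stats import chi2

    expected = float(chi2.sf((abs(20 - 15) - 1) ** 2 / 35, 1))
    assert p_ab == pytest.approx(expected, rel=1e-9)


def _perfect_study():
    truth = ["hip_fracture"] * 50 + ["pelvic_fracture"] * 50 + ["normal"] * 50
    ids = [f"c{i}" for i in range(150)]
    return ReaderStudy(
        case_ids=ids, truth=truth, readers={"r1": list(truth)}, model=list(truth)
    )


def test_reader_study_perfect_agreement():
    df = reader_study_report(_perfect_study())
    for _, row in df.iterrows():
        assert row["hip_accuracy"] == 1.0 and row["pelvic_accuracy"] == 1.0
        assert row["balanced_accuracy"] == 1.0
        assert row["hip_mcnemar_p"] == 1.0
        assert row["hip_misdiagnosis_detected"] == 0


def test_reader_study_misdiagnosis_counting():
    """A reader missing 5/50 pelvic fractures the model catches shows a
    misdiagnosis-detected count of 5."""
    truth = ["hip_fracture"] * 50 + ["pelvic_fracture"] * 50 + ["normal"] * 50
    ids = [f"c{i}" for i in range(150)]
    reader = list(truth)
    for i in range(50, 55):
        reader[i] = "normal"
    study = ReaderStudy(case_ids=ids, truth=truth, readers={"r1": reader}, model=list(truth))
    df = reader_study_report(study).set_index("reader")
    assert df.loc["r1", "pelvic_misdiagnosis_detected"] == 5
    assert df.loc["r1", "pelvic_sensitivity"] == pytest.approx(0.9)
    assert df.loc["r1", "pelvic_accuracy"] == pytest.approx(95 / 100)


def test_balanced_accuracy_is_mean_recall():
    truth = ["hip_fracture"] * 4 + ["pelvic_fracture"] * 4 + ["normal"] * 2
    preds = ["hip_fracture"] * 3 + ["normal"] + ["pelvic_fracture"] * 2 + ["normal"] * 2 + ["normal"] * 2
    # recalls: hip 3/4, pelvic 2/4, normal 2/2
    assert balanced_accuracy(truth, preds) == pytest.approx(np.mean([0.75, 0.5, 1.0]))


def test_incomplete_reader_study_rejected():
    truth = ["hip_fracture", "normal"]
    with pytest.raises(ValueError):
        ReaderStudy(case_ids=["a", "b"], truth=truth, readers={"r": ["hip_fracture"]}, model=truth)
    with pytest.raises(ValueError, match="invalid"):
        ReaderStudy(
            case_ids=["a", "b"], truth=truth,
            readers={"r": ["hip_fracture", "bogus"]}, model=truth,
        )


def test_cohort_csv_roundtrip(tmp_path):
    c = ScoredCohort(
        scores=[0.9, 0.1, 0.5],
        labels=[1, 0, 1],
        categories=[["fracture_line"], [], ["dislocation", "shaft_fracture"]],
        difficult=[True, False, False],
    )
    path = tmp_path / "scores.csv"
    write_cohort_csv(path, ["a", "b", "c"], c)
    ids, back = read_cohort_csv(path)
    assert ids == ["a", "b", "c"]
    np.testing.assert_allclose(back.scores, c.scores)
    np.testing.assert_array_equal(back.labels, c.labels)
    assert back.categories[2] == ["dislocation", "shaft_fracture"]
    assert back.categories[1] == []


def test_evaluate_cohort_report_consistency():
    rng = np.random.default_rng(7)
    scores = np.clip(rng.normal(0.3, 0.2, 60) + 0.4 * rng.integers(0, 2, 60), 0, 1)
    labels = (scores + rng.normal(0, 0.2, 60) > 0.5).astype(int)
    if labels.sum() in (0, 60):
        labels[:2] = [0, 1]
    c = ScoredCohort(scores=scores, labels=labels)
    rep = evaluate_cohort(c, n_boot=100, seed=0)
    assert rep.auroc_ci[0] <= rep.auroc <= rep.auroc_ci[1]
    assert 0 <= rep.auprc <= 1
    for k, v in rep.metrics.items():
        assert 0 <= v <= 1
    md = rep.to_markdown()
    assert "AUROC" in md
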