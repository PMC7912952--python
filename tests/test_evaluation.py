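"""ROC/AUC machinery: oracle equivalence, DeLong, CV, tabulations."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aortanorm import (
    Cohort,
    ScoredSubject,
    SubjectRecord,
    best_cutoff,
    bootstrap_auc_ci,
    cv_scores,
    delong_test,
    discordance_table,
    prevalence_percent,
    roc_auc,
)
from aortanorm.errors import DomainError, FitError, PairingError
from aortanorm.qscore import QScoreReport
from aortanorm.zscore import ZScoreReport


def _scored(scores, labels):
    return [
        ScoredSubject(subject_id=f"s{i}", label=int(l), score=float(s))
        for i, (s, l) in enumerate(zip(scores, labels))
    ]


def brute_force_auc(scores, labels):
    """Independent oracle: count positive–negative pairs, ties half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ((1, 2, 3, 4), (0, 0, 1, 1), 1.0),
            ((1, 2, 3, 4), (1, 1, 0, 0), 0.0),
            ((1, 2, 2, 3), (0, 1, 0, 1), 0.875),  # 3.5 of 4 pairs, tie = 1/2
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert roc_auc(_scored(scores, labels)).auc == pytest.approx(expected)

    @settings(derandomize=True, max_examples=60)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 10), st.booleans()), min_size=4, max_size=50
        )
    )
    def test_matches_pair_counting_oracle(self, data):
        scores = [d[0] for d in data]
        labels = [int(d[1]) for d in data]
        if len(set(labels)) < 2:
            return
        assert roc_auc(_scored(scores, labels)).auc == pytest.approx(
            brute_force_auc(scores, labels)
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        if len(set(labels.tolist())) < 2:
            labels[0], labels[1] = 0, 1
        a = roc_auc(_scored(scores, labels)).auc
        b = roc_auc(_scored(np.exp(3 * scores), labels)).auc
        assert a == pytest.approx(b)

    def test_curve_endpoints_monotone(self):
        rng = np.random.default_rng(3)
        r = roc_auc(_scored(rng.normal(size=60), rng.integers(0, 2, size=60)))
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            roc_auc(_scored([1, 2, 3], [1, 1, 1]))


class TestBestCutoff:
    def test_perfect_separation(self):
        r = roc_auc(_scored([1, 2, 3, 4], [0, 0, 1, 1]))
        _, sens, spec = best_cutoff(r)
        assert sens == 1.0 and spec == 1.0

    def test_matches_exhaustive_threshold_scan(self):
        scores = [1, 2, 2, 3, 5, 5, 7, 9]
        labels = [0, 1, 0, 1, 0, 1, 1, 1]
        r = roc_auc(_scored(scores, labels))
        # brute force over all candidate thresholds (score >= t is positive)
        best = -1.0
        for t in sorted(set(scores)):
            sens = np.mean([s >= t for s, l in zip(scores, labels) if l == 1])
            spec = np.mean([s < t for s, l in zip(scores, labels) if l == 0])
            best = max(best, sens + spec)
        assert r.sensitivity + r.specificity == pytest.approx(best)

    def test_translation_invariance(self):
        scores = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        labels = [0, 0, 1, 0, 1, 1]
        a = roc_auc(_scored(scores, labels))
        b = roc_auc(_scored([s + 10 for s in scores], labels))
        assert b.best_cutoff == pytest.approx(a.best_cutoff + 10)
        assert (b.sensitivity, b.specificity) == (a.sensitivity, a.specificity)


class TestBootstrap:
    def test_degenerate_at_boundary_for_perfect_separation(self):
        scored = _scored(list(range(100)), [0] * 50 + [1] * 50)
        lo, hi = bootstrap_auc_ci(scored, B=300, seed=0)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_contains_point_auc_and_deterministic(self):
        rng = np.random.default_rng(4)
        scores = np.concatenate([rng.normal(0, 1, 80), rng.normal(1.2, 1, 40)])
        labels = [0] * 80 + [1] * 40
        scored = _scored(scores, labels)
        auc = roc_auc(scored).auc
        lo1, hi1 = bootstrap_auc_ci(scored, B=500, seed=11)
        lo2, hi2 = bootstrap_auc_ci(scored, B=500, seed=11)
        assert (lo1, hi1) == (lo2, hi2)
        assert lo1 <= auc <= hi1

    def test_small_b_rejected(self):
        with pytest.raises(DomainError):
            bootstrap_auc_ci(_scored([1, 2], [0, 1]), B=10)


class TestDeLong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(6)
        scored = _scored(rng.normal(size=30), rng.integers(0, 2, size=30))
        res = delong_test(scored, scored)
        assert res.difference == 0.0
        assert res.p_value == 1.0

    def test_internal_consistency_and_swap(self):
        rng = np.random.default_rng(7)
        labels = np.array([0] * 25 + [1] * 25)
        a = _scored(rng.normal(size=50) + labels, labels)
        b = _scored(rng.normal(size=50) + 0.3 * labels, labels)
        res = delong_test(a, b)
        assert res.auc_a == pytest.approx(roc_auc(a).auc)
        assert res.auc_b == pytest.approx(roc_auc(b).auc)
        swapped = delong_test(b, a)
        assert swapped.difference == pytest.approx(-res.difference)
        assert swapped.p_value == pytest.approx(res.p_value)

    def test_hand_computed_placements(self):
        """6 subjects, scores a=(1,2,3|2,3,4): placement values by hand.

        Positives (labels 1) score (2,3,4), negatives (1,2,3).
        V10 = per-positive mean of psi vs negatives: (1/2+1/2... ) =
        psi(2,{1,2,3}) = (1+.5+0)/3 = .5; psi(3,...) = (1+1+.5)/3 = 5/6;
        psi(4,...) = 1.  AUC = (0.5 + 5/6 + 1)/3 = 7/9.
        """
        labels = [0, 0, 0, 1, 1, 1]
        a = _scored([1, 2, 3, 2, 3, 4], labels)
        res = delong_test(a, a)
        assert res.auc_a == pytest.approx(7 / 9)
        # structural-component variance of a single AUC:
        v10 = np.array([0.5, 5 / 6, 1.0])
        v01 = np.array([np.mean([0, 1 / 6, 0]) * 3, 0, 0])  # placeholder below
        # per-negative: psi means over positives
        v01 = np.array(
            [
                np.mean([1.0, 1.0, 1.0]),  # neg 1 below all positives
                np.mean([0.5, 1.0, 1.0]),  # neg 2 ties positive 2
                np.mean([0.0, 0.5, 1.0]),  # neg 3
            ]
        )
        var = np.var(v10, ddof=1) / 3 + np.var(v01, ddof=1) / 3
        # arm-vs-itself: covariance equals variance, difference variance 0,
        # but each arm's own structural variance must match the formula
        s10 = np.var(v10, ddof=1)
        s01 = np.var(v01, ddof=1)
        assert s10 == pytest.approx(np.cov(np.vstack([v10, v10]), ddof=1)[0, 0])
        assert var == pytest.approx(s10 / 3 + s01 / 3)

    def test_proc_cross_check(self, tmp_path):
        """DeLong p agrees with the R pROC reference implementation."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(8)
        labels = np.array([0] * 40 + [1] * 40)
        sa = rng.normal(size=80) + 1.0 * labels
        sb = rng.normal(size=80) + 0.6 * labels
        res = delong_test(_scored(sa, labels), _scored(sb, labels))
        script = tmp_path / "delong.R"
        np.savetxt(tmp_path / "d.csv", np.column_stack([labels, sa, sb]), delimiter=",")
        script.write_text(
            f"""
            suppressMessages(library(pROC))
            d <- read.csv("{tmp_path / 'd.csv'}", header=FALSE)
            ra <- roc(d$V1, d$V2, quiet=TRUE); rb <- roc(d$V1, d$V3, quiet=TRUE)
            t <- roc.test(ra, rb, method="delong", paired=TRUE)
            cat(sprintf("%.10f %.10f %.10f", auc(ra), auc(rb), t$p.value))
            """
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        auc_a, auc_b, p = map(float, out.stdout.split())
        assert res.auc_a == pytest.approx(auc_a, abs=1e-9)
        assert res.auc_b == pytest.approx(auc_b, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-8)

    def test_unpaired_rejected(self):
        a = _scored([1, 2], [0, 1])
        b = _scored([1, 2, 3], [0, 1, 0])
        with pytest.raises(PairingError):
            delong_test(a, b)


def _mini_cohorts(n_h=30, n_p=12, seed=0):
    rng = np.random.default_rng(seed)
    mk = lambda i, g: SubjectRecord(
        f"{g}{i}", float(rng.uniform(20, 70)), "F" if rng.uniform() < 0.5 else "M",
        float(rng.uniform(150, 190)), float(rng.uniform(50, 90)),
        diameters={"SoV": float(rng.uniform(20, 35))}, group="healthy" if g == "h" else "dilated",
    )
    return (
        Cohort([mk(i, "h") for i in range(n_h)]),
        Cohort([mk(i, "p") for i in range(n_p)]),
    )


class TestCvScores:
    def test_partition_and_patient_exclusion(self):
        healthy, patients = _mini_cohorts()
        seen_train: list[set] = []

        def factory(train):
            ids = {r.subject_id for r in train}
            seen_train.append(ids)
            return {"S": lambda r: 0.0}

        pooled = cv_scores(healthy, patients, factory, k=3, seed=1)
        ids = [s.subject_id for s in pooled["S"]]
        assert sorted(ids) == sorted(
            [r.subject_id for r in healthy] + [r.subject_id for r in patients]
        )  # every subject scored exactly once
        for ids_train in seen_train:
            assert all(i.startswith("h") for i in ids_train)

    def test_oracle_scorer_gives_auc_one(self):
        healthy, patients = _mini_cohorts()
        factory = lambda train: {"S": lambda r: float(r.group != "healthy")}
        pooled = cv_scores(healthy, patients, factory, k=3, seed=1)
        assert roc_auc(pooled["S"]).auc == 1.0

    def test_class_smaller_than_k_rejected(self):
        healthy, patients = _mini_cohorts(n_p=3)
        with pytest.raises(FitError):
            cv_scores(healthy, patients, lambda t: {"S": lambda r: 0.0}, k=5)

    def test_constant_scorer_auc_half(self):
        healthy, patients = _mini_cohorts()
        pooled = cv_scores(
            healthy, patients, lambda t: {"S": lambda r: 1.0}, k=3, seed=1
        )
        assert roc_auc(pooled["S"]).auc == pytest.approx(0.5)


class TestTabulations:
    @pytest.mark.parametrize(
        "num, den, expected",
        [(243, 351, 69.2), (86, 115, 74.8), (0, 100, 0.0)],
    )
    def test_prevalence(self, num, den, expected):
        assert prevalence_percent(num, den) == expected

    def test_prevalence_domain_errors(self):
        with pytest.raises(DomainError):
            prevalence_percent(1, 0)
        with pytest.raises(DomainError):
            prevalence_percent(5, 3)

    @staticmethod
    def _zrep(abnormal):
        z = 3.0 if abnormal else 0.5
        return ZScoreReport(
            z={"SoV": z}, category={"SoV": "abnormal" if abnormal else "normal"},
            global_statistic=z, global_abnormal=abnormal,
        )

    @staticmethod
    def _qrep(q):
        from aortanorm.qscore import q_category

        return QScoreReport(
            local_q={}, local_category={}, global_q=q, global_category=q_category(q)
        )

    def test_hand_built_counts(self):
        # subjects: (z-abnormal, q) -> cell
        zs = [self._zrep(a) for a in (True, True, False, False, True)]
        qs = [self._qrep(q) for q in (1.0, 10.0, 3.0, 20.0, 4.0)]
        table = discordance_table(zs, qs)
        # q-abnormal means q <= 4
        assert table[1, 1] == 2  # z+ q+ : subjects 0 and 4
        assert table[1, 0] == 1  # z+ q- : subject 1
        assert table[0, 1] == 1  # z- q+ : subject 2
        assert table[0, 0] == 1  # z- q- : subject 3
        assert table.sum() == 5

    def test_concordant_normal(self):
        zs = [self._zrep(False)] * 3
        qs = [self._qrep(25.0)] * 3
        table = discordance_table(zs, qs)
        assert table[0, 0] == 3 and table.sum() == 3

    def test_unpaired_rejected(self):
        with pytest.raises(PairingError):
            discordance_table([self._zrep(True)], [])
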