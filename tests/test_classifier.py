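"""Risk scoring, ROC/AUC, cutoff selection, evaluation and LOOCV."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mstrisk import (
    ClassifierModel,
    Genotype,
    MicrosatelliteRiskModel,
    evaluate,
    loocv,
    optimal_cutoff,
    roc_auc,
    score_sample,
)


def concordance_auc(scores, labels):
    """Brute-force pairwise concordance: P(case > control) + 0.5 P(tie)."""
    cases = [s for s, l in zip(scores, labels) if l == "case"]
    controls = [s for s, l in zip(scores, labels) if l == "control"]
    total = 0.0
    for c in cases:
        for k in controls:
            total += 1.0 if c > k else 0.5 if c == k else 0.0
    return total / (len(cases) * len(controls))


def _model(n_loci, cutoff=0.5, mode="validation"):
    return ClassifierModel(
        signature=[(f"L{i}", Genotype(13, 13)) for i in range(n_loci)],
        cutoff=cutoff,
        mode=mode,
    )


class TestScoreSample:
    def test_eight_of_thirteen_is_at_risk_at_061(self):
        model = _model(13, cutoff=0.61)
        calls = {f"L{i}": Genotype(13, 13) for i in range(8)}
        calls.update({f"L{i}": Genotype(12, 12) for i in range(8, 13)})
        score = score_sample(calls, model)
        assert score == pytest.approx(8 / 13)
        assert score == pytest.approx(0.6154, abs=5e-5)
        assert score >= model.cutoff
        # seven risk genotypes fall below the cutoff
        calls["L7"] = Genotype(12, 12)
        assert score_sample(calls, model) < model.cutoff

    def test_zero_risk_genotypes(self):
        model = _model(13)
        calls = {f"L{i}": Genotype(11, 11) for i in range(13)}
        assert score_sample(calls, model) == 0.0

    def test_twelve_of_twentyone_at_057(self):
        model = _model(21, cutoff=0.57)
        calls = {f"L{i}": Genotype(13, 13) for i in range(12)}
        calls.update({f"L{i}": Genotype(12, 12) for i in range(12, 21)})
        score = score_sample(calls, model)
        assert score == pytest.approx(12 / 21)
        assert score == pytest.approx(0.5714, abs=5e-5)
        assert score >= model.cutoff

    def test_missing_calls_drop_from_denominator(self):
        model = _model(4)
        calls = {"L0": Genotype(13, 13), "L1": Genotype(12, 12), "L2": None, "L3": None}
        assert score_sample(calls, model) == 0.5

    def test_all_missing_is_unscorable(self):
        assert score_sample({}, _model(3)) is None

    def test_discovery_mode_counts_non_modal(self):
        model = _model(4, mode="discovery")  # stored genotypes are the control modal
        calls = {
            "L0": Genotype(13, 13),  # modal -> not counted
            "L1": Genotype(12, 12),
            "L2": Genotype(12, 14),
            "L3": None,
        }
        assert score_sample(calls, model) == pytest.approx(2 / 3)

    def test_permutation_invariance_and_missing_neutrality(self):
        model = _model(6)
        calls = {f"L{i}": Genotype(13, 13) if i % 2 else Genotype(11, 11) for i in range(6)}
        base = score_sample(calls, model)
        for perm in itertools.permutations(model.signature):
            shuffled = ClassifierModel(signature=list(perm), cutoff=0.5, mode="validation")
            assert score_sample(calls, shuffled) == base
        calls["L6"] = None  # a missing-call locus never changes the score
        wider = ClassifierModel(
            signature=model.signature + [("L6", Genotype(13, 13))], cutoff=0.5
        )
        assert score_sample(calls, wider) == base


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([0.9, 0.8, 0.2, 0.1], ["case", "case", "control", "control"])
        assert res.auc == 1.0

    def test_partial_overlap(self):
        res = roc_auc([0.8, 0.4, 0.6, 0.2], ["case", "case", "control", "control"])
        assert res.auc == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        res = roc_auc([0.5] * 6, ["case"] * 3 + ["control"] * 3)
        assert res.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], ["case", "case"])

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(7)
        scores = rng.random(40).round(2)
        labels = ["case" if x else "control" for x in rng.integers(0, 2, 40)]
        res = roc_auc(scores, labels)
        assert np.all(np.diff(res.tpr) >= 0) and np.all(np.diff(res.fpr) >= 0)
        assert res.tpr[0] == res.fpr[0] == 0.0
        assert res.tpr[-1] == res.fpr[-1] == 1.0

    @pytest.mark.parametrize("seed", range(40))
    def test_equals_concordance_oracle_exhaustively(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        scores = (rng.integers(0, 5, n) / 4).tolist()  # heavy ties on purpose
        labels = (["case", "control"] + ["case" if x else "control"
                                         for x in rng.integers(0, 2, n - 2)])
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(concordance_auc(scores, labels), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sklearn(self, seed):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(100 + seed)
        scores = rng.random(30)
        labels = ["case", "control"] + [
            "case" if x else "control" for x in rng.integers(0, 2, 28)
        ]
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(
            roc_auc_score([l == "case" for l in labels], scores), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_label_flip_complements_auc(self, seed):
        rng = np.random.default_rng(200 + seed)
        scores = rng.random(20)  # continuous: ties almost surely absent
        labels = ["case", "control"] + [
            "case" if x else "control" for x in rng.integers(0, 2, 18)
        ]
        flipped = ["control" if l == "case" else "case" for l in labels]
        assert roc_auc(scores, labels).auc + roc_auc(scores, flipped).auc == pytest.approx(1.0)


class TestOptimalCutoff:
    def test_separable(self):
        assert optimal_cutoff(
            [0.9, 0.8, 0.2, 0.1], ["case", "case", "control", "control"]
        ) == (0.8, 1.0)

    def test_tie_resolved_to_larger_cutoff(self):
        cutoff, acc = optimal_cutoff(
            [0.7, 0.3, 0.6, 0.2], ["case", "case", "control", "control"]
        )
        assert (cutoff, acc) == (0.7, 0.75)

    def test_degenerate_scores(self):
        cutoff, acc = optimal_cutoff([0.4] * 5, ["case"] * 2 + ["control"] * 3)
        assert acc == pytest.approx(max(2, 3) / 5)

    @pytest.mark.parametrize("seed", range(20))
    def test_accuracy_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(300 + seed)
        n = int(rng.integers(4, 25))
        scores = (rng.integers(0, 8, n) / 7).tolist()
        labels = ["case", "control"] + [
            "case" if x else "control" for x in rng.integers(0, 2, n - 2)
        ]
        cutoff, acc = optimal_cutoff(scores, labels)
        accs = {t: evaluate(scores, labels, t)[0].accuracy for t in set(scores) | {1.0}}
        assert acc == pytest.approx(max(accs.values()))
        assert accs[cutoff] == pytest.approx(acc)
        assert cutoff == max(t for t, a in accs.items() if a == pytest.approx(acc))


class TestEvaluate:
    def test_study_sized_confusion_matrix(self):
        scores = [0.9] * 27 + [0.1] * 3 + [0.9] * 5 + [0.1] * 84
        labels = ["case"] * 30 + ["control"] * 89
        cm, sens, spec, odds = evaluate(scores, labels, cutoff=0.5)
        assert (cm.TP, cm.FP, cm.FN, cm.TN) == (27, 5, 3, 84)
        assert sens == pytest.approx(0.90)
        assert spec == pytest.approx(0.9438, abs=5e-5)
        assert odds == pytest.approx((27 / 5) / (3 / 84)) == pytest.approx(151.2)

    def test_perfect_classification_has_finite_or(self):
        scores = [0.9] * 30 + [0.1] * 89
        labels = ["case"] * 30 + ["control"] * 89
        cm, sens, spec, odds = evaluate(scores, labels, cutoff=0.5)
        assert sens == 1.0 and spec == 1.0
        assert np.isfinite(odds) and odds == pytest.approx((30.5 / 0.5) / (0.5 / 89.5))

    def test_cutoff_zero_calls_everything_at_risk(self):
        scores = [0.7, 0.0, 0.3, 0.0]
        labels = ["case", "case", "control", "control"]
        _, sens, spec, _ = evaluate(scores, labels, cutoff=0.0)
        assert sens == 1.0 and spec == 0.0


class TestLoocv:
    def test_fold_count_equals_sample_count(self, loocv_cohort):
        _, matrix, _ = loocv_cohort
        result = loocv(matrix, mode="validation")
        assert result.n_folds == 119
        assert len(result.predictions) == 119
        assert len(result.fold_metrics) == 119

    def test_separable_cohort_is_perfectly_predicted(self):
        from mstrisk import GenotypeMatrix

        samples = [f"c{i}" for i in range(6)] + [f"k{i}" for i in range(8)]
        labels = {s: ("case" if s.startswith("c") else "control") for s in samples}
        calls = {}
        for s in samples:
            for j in range(5):
                g = Genotype(14, 14) if labels[s] == "case" else Genotype(13, 13)
                calls[(s, f"L{j}")] = g
        matrix = GenotypeMatrix(
            sample_ids=samples, labels=labels, loci=[f"L{j}" for j in range(5)], calls=calls
        )
        result = loocv(matrix, mode="validation")
        assert result.pooled_sensitivity == 1.0
        assert result.pooled_specificity == 1.0
        assert not result.unpredictable

    def test_planted_cohort_pooled_metrics(self, loocv_cohort):
        """Refit-per-fold LOOCV keeps high pooled sensitivity/specificity
        on a planted cohort at the study's effect sizes."""
        _, matrix, _ = loocv_cohort
        result = loocv(matrix, mode="validation")
        assert result.pooled_sensitivity >= 0.9
        assert result.pooled_specificity >= 0.9
        assert result.fold_metrics["train_sensitivity"].mean() >= 0.9

    def test_fixed_signature_variant_runs(self, loocv_cohort):
        _, matrix, _ = loocv_cohort
        result = loocv(matrix, mode="validation", fixed_signature=True)
        assert result.n_folds == 119
        assert result.fold_metrics["n_signature"].nunique() == 1

    def test_too_few_samples_rejected(self):
        from mstrisk import GenotypeMatrix

        matrix = GenotypeMatrix(
            sample_ids=["a", "b", "c"],
            labels={"a": "case", "b": "control", "c": "control"},
            loci=["L0"],
            calls={},
        )
        with pytest.raises(ValueError, match="at least 2"):
            loocv(matrix)


class TestModelResultsFacade:
    def test_fit_recovers_planted_signature(self, loocv_cohort):
        _, matrix, manifest = loocv_cohort
        res = MicrosatelliteRiskModel(matrix, mode="validation").fit()
        assert {lid for lid, _ in res.signature} == set(manifest.informative_loci)
        assert 0 <= res.cutoff <= 1
        assert res.auc >= 0.9
        assert res.confusion.TP + res.confusion.FN == 30
        assert res.confusion.FP + res.confusion.TN == 89

    def test_min_risk_loci_interpretation(self, loocv_cohort):
        """ceil(cutoff * n) is the smallest at-risk locus count on a
        fully called sample."""
        _, matrix, _ = loocv_cohort
        res = MicrosatelliteRiskModel(matrix).fit()
        n = len(res.signature)
        k = res.min_risk_loci
        assert k / n >= res.cutoff
        assert k == 0 or (k - 1) / n < res.cutoff

    def test_summary_and_predict(self, loocv_cohort):
        _, matrix, _ = loocv_cohort
        res = MicrosatelliteRiskModel(matrix).fit()
        text = res.summary()
        assert "signature loci" in text and "AUC" in text
        preds = res.predict(matrix)
        assert set(preds["call"]) <= {"at-risk", "healthy", "unscorable"}
        assert len(preds) == 119

    def test_model_round_trip(self, tmp_path, loocv_cohort):
        _, matrix, _ = loocv_cohort
        res = MicrosatelliteRiskModel(matrix).fit()
        path = tmp_path / "model.json"
        res.classifier.save(path)
        back = ClassifierModel.load(path)
        assert back.signature == res.classifier.signature
        assert back.cutoff == res.classifier.cutoff
        assert back.mode == res.classifier.mode


def test_end_to_end_auc_over_seeds():
    """Genotype-level pipeline at the full default study design: planted
    signatures are recovered and AUC stays high across 20 seeds."""
    from mstrisk import SimulationConfig, simulate_cohort_genotypes, simulate_reference

    aucs, recalls = [], []
    config0 = SimulationConfig(seed=0)
    _, catalog = simulate_reference(config0)  # reference reused across seeds
    for seed in range(20):
        config = SimulationConfig(seed=3000 + seed)
        matrix, manifest = simulate_cohort_genotypes(config, catalog)
        res = MicrosatelliteRiskModel(matrix, mode="validation").fit()
        found = {lid for lid, _ in res.signature}
        planted = set(manifest.informative_loci)
        recalls.append(len(found & planted) / len(planted))
        aucs.append(res.auc)
    assert np.mean(recalls) >= 0.9
    assert np.mean(aucs) >= 0.95
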