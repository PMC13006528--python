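"""Labelled insertion-variant encoding, splitting, fitting and metrics."""

import numpy as np
import pytest

from tagsite.benchmark import (
    InsertionVariant,
    SimulationParams,
    confusion_metrics,
    encode_design_matrix,
    fit_eval_logistic,
    repeat_eval,
    run_benchmark,
    simulate_benchmark,
    split_train_test,
)


def _variant(label, ss_code="C", **kw):
    defaults = dict(entropy=0.5, rsa=0.5, ss_score=1.0, dbr=0.5,
                    s_weighted=2.75, e_min=0.5)
    defaults.update(kw)
    return InsertionVariant(protein_id="p", position=1, label=label,
                            ss_code=ss_code, **defaults)


class TestEncoding:
    def test_one_hot_drops_reference_level(self):
        X, y, cols = encode_design_matrix(
            [_variant("pathogenic", "H"), _variant("benign", "C")])
        assert cols == ["entropy", "rsa", "ss_score", "dbr", "s_weighted",
                        "e_min", "ss_H"]
        assert y.tolist() == [1, 0]

    def test_out_of_range_feature_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            _variant("benign", entropy=1.2)

    def test_single_shared_code_gives_no_one_hot(self):
        X, _, cols = encode_design_matrix(
            [_variant("pathogenic"), _variant("benign")])
        assert cols == ["entropy", "rsa", "ss_score", "dbr", "s_weighted",
                        "e_min"]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            encode_design_matrix([_variant("benign"), _variant("benign")])


class TestSplit:
    def _dataset(self, n_each=100):
        return ([_variant("pathogenic") for _ in range(n_each)]
                + [_variant("benign") for _ in range(n_each)])

    def test_stratified_80_20_arithmetic(self):
        train, test = split_train_test(self._dataset(100), seed=0)
        assert len(train) == 160 and len(test) == 40
        assert sum(1 for v in train if v.label == "pathogenic") == 80
        assert sum(1 for v in test if v.label == "pathogenic") == 20

    def test_same_seed_gives_identical_partition(self):
        variants = simulate_benchmark(SimulationParams(seed=5))
        a = split_train_test(variants, seed=11)
        b = split_train_test(variants, seed=11)
        assert a == b

    def test_fraction_one_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            split_train_test(self._dataset(), fraction=1.0)

    def test_tiny_class_rejected(self):
        data = [_variant("pathogenic")] + [_variant("benign")] * 10
        with pytest.raises(ValueError, match="fewer than 2"):
            split_train_test(data)


class TestMetrics:
    def test_hand_computed_confusion(self):
        precision, recall, f1 = confusion_metrics(tp=3, fp=1, fn=1, tn=5)
        assert (precision, recall, f1) == (0.75, 0.75, 0.75)

    def test_zero_denominators_give_zero(self):
        assert confusion_metrics(0, 0, 0, 10) == (0.0, 0.0, 0.0)

    def test_f1_swap_symmetry_only_for_symmetric_confusion(self):
        # symmetric confusion matrix: swapping the positive class preserves F1
        _, _, f1_pos = confusion_metrics(tp=4, fp=2, fn=2, tn=4)
        _, _, f1_neg = confusion_metrics(tp=4, fp=2, fn=2, tn=4)
        assert f1_pos == f1_neg
        # asymmetric counterexample
        _, _, a = confusion_metrics(tp=8, fp=1, fn=3, tn=2)
        _, _, b = confusion_metrics(tp=2, fp=3, fn=1, tn=8)
        assert a != b

    def test_confusion_counts_sum_to_test_size(self):
        for seed in range(5):
            r = run_benchmark(SimulationParams(seed=seed))
            assert r.tp + r.fp + r.fn + r.tn == r.n_test


class TestLogisticProtocol:
    def test_separable_simulation_reaches_perfect_f1(self):
        record = run_benchmark(SimulationParams.separable(seed=3))
        assert record.f1 == 1.0

    def test_null_simulation_hovers_at_chance(self):
        # balanced classes with identical distributions: F1 of noise-driven
        # predictions averages near the 0.5 harmonic-mean regime
        f1s = [run_benchmark(SimulationParams.null(seed=s)).f1
               for s in range(20)]
        assert abs(np.mean(f1s) - 0.5) < 0.1

    def test_separation_ladder_is_monotone_in_f1(self):
        means = []
        for sep in (0.0, 0.12, 0.3, 0.6):
            f1s = [
                run_benchmark(
                    SimulationParams(
                        n_pathogenic=200, n_benign=200,
                        benign_mean=0.5 + sep / 2,
                        pathogenic_mean=0.5 - sep / 2,
                        benign_coil_prob=0.5 + sep / 2,
                        pathogenic_coil_prob=0.5 - sep / 2,
                        seed=s,
                    )
                ).f1
                for s in range(5)
            ]
            means.append(np.mean(f1s))
        noise = 0.05
        assert all(b >= a - noise for a, b in zip(means, means[1:]))

    def test_coefficient_signs_recover_generative_effects(self):
        # benign (y=0) has higher entropy/rsa/dbr, so pathogenic-class
        # coefficients on those features must come out negative
        from sklearn.linear_model import LogisticRegression

        params = SimulationParams(n_pathogenic=1000, n_benign=1000, seed=2)
        X, y, cols = encode_design_matrix(simulate_benchmark(params))
        model = LogisticRegression(C=np.inf, max_iter=5000).fit(X, y)
        coef = dict(zip(cols, model.coef_[0]))
        for name in ("entropy", "rsa", "dbr"):
            assert coef[name] < 0

    def test_empty_test_set_rejected(self):
        variants = simulate_benchmark(SimulationParams(seed=0))
        with pytest.raises(ValueError, match="empty"):
            fit_eval_logistic(variants, [])


class TestSimulator:
    def test_fixed_seed_is_reproducible(self):
        a = simulate_benchmark(SimulationParams(seed=9))
        b = simulate_benchmark(SimulationParams(seed=9))
        assert a == b

    def test_derived_scores_come_from_the_scorer(self):
        from tagsite.scoring import min_score, weighted_score

        for v in simulate_benchmark(SimulationParams(seed=1))[:50]:
            vec = (v.entropy, v.ss_score, v.rsa, v.dbr)
            assert v.e_min == pytest.approx(min_score(vec))
            assert v.s_weighted == pytest.approx(weighted_score(vec))

    def test_default_class_structure(self):
        variants = simulate_benchmark(SimulationParams(seed=0))
        assert sum(1 for v in variants if v.label == "pathogenic") == 401
        assert sum(1 for v in variants if v.label == "benign") == 433

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(n_pathogenic=0)
        with pytest.raises(ValueError):
            SimulationParams(concentration=-1)


class TestRepeatEval:
    def test_separable_dataset_gives_mean_one_sd_zero(self):
        variants = simulate_benchmark(SimulationParams.separable(seed=4))
        mean, sd, records = repeat_eval(variants, 5, base_seed=0)
        assert mean == 1.0 and sd == 0.0
        assert len(records) == 5

    def test_null_dataset_has_sampling_variability(self):
        variants = simulate_benchmark(SimulationParams.null(seed=2))
        _, sd, _ = repeat_eval(variants, 10, base_seed=0)
        assert sd > 0

    def test_too_few_repeats_rejected(self):
        variants = simulate_benchmark(SimulationParams(seed=0))
        with pytest.raises(ValueError, match="n_repeats"):
            repeat_eval(variants, 1)
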