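import dataclasses

import numpy as np
import pandas as pd
import pytest

from synmtl import pipeline, training
from synmtl.config import Config
from synmtl.predictor import PredictorSpec
from synmtl.training import (CvPlan, LossBreakdown, OrderedRows, SynergySample,
                             TrainOptions, assign_combo_folds,
                             assign_drug_folds, bce_loss, build_ordered_rows,
                             grid_search, leakage_filter, pair_key,
                             select_best_cell, total_loss, train_model)

from conftest import TINY_CFG


def make_samples(pairs, cells=("c1",)):
    return [SynergySample(a, b, c, 10.0) for a, b in pairs for c in cells]


class TestFoldAssignment:
    def test_round_robin_balance(self):
        pairs = [(f"d{i}", f"d{i+1}") for i in range(0, 20, 2)]  # 10 pairs
        plan = assign_combo_folds(make_samples(pairs), n_folds=5, seed=0)
        sizes = np.bincount(list(plan.combo_folds.values()), minlength=5)
        assert (sizes == 2).all()

    def test_pair_spellings_share_a_fold(self):
        samples = [SynergySample("A", "B", "c1", 1.0),
                   SynergySample("B", "A", "c2", 2.0)]
        samples += make_samples([("C", "D"), ("E", "F"), ("G", "H"), ("I", "J")])
        assign_combo_folds(samples, n_folds=5, seed=1)
        assert samples[0].combo_fold == samples[1].combo_fold

    def test_no_pair_spans_two_folds(self, tiny_samples):
        samples = [dataclasses.replace(s) for s in tiny_samples]
        plan = assign_combo_folds(samples, n_folds=5, seed=2)
        seen = {}
        for s in samples:  # brute-force audit over every sample
            key = pair_key(s.drug_row, s.drug_col)
            assert seen.setdefault(key, s.combo_fold) == s.combo_fold
            assert plan.combo_folds[key] == s.combo_fold

    def test_deterministic_under_seed(self, tiny_samples):
        # operate on copies: fold assignment mutates the samples it is given
        a = assign_combo_folds([dataclasses.replace(s) for s in tiny_samples],
                               n_folds=5, seed=7)
        b = assign_combo_folds([dataclasses.replace(s) for s in tiny_samples],
                               n_folds=5, seed=7)
        assert a.combo_folds == b.combo_folds

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            assign_combo_folds(make_samples([("A", "B")]), n_folds=5)

    def test_drug_folds_partition_and_balance(self):
        drugs = [f"d{i}" for i in range(12)]
        plan = assign_drug_folds(drugs, n_folds=5, seed=0)
        sizes = np.bincount(list(plan.drug_folds.values()), minlength=5)
        assert sizes.max() - sizes.min() <= 1
        assert set(plan.drug_folds) == set(drugs)

    def test_drug_folds_deterministic(self):
        drugs = [f"d{i}" for i in range(9)]
        assert (assign_drug_folds(drugs, seed=3).drug_folds
                == assign_drug_folds(drugs, seed=3).drug_folds)


class TestLosses:
    def test_bce_perfect_prediction_limit(self):
        assert bce_loss([1.0], [1.0 - 1e-9]) < 1e-5

    def test_bce_closed_form_half(self):
        assert bce_loss([1.0, 0.0], [0.5, 0.5]) == pytest.approx(np.log(2.0))

    def test_bce_matches_brute_force_loop(self, rng):
        y = rng.integers(0, 2, size=7).astype(float)
        p = rng.uniform(0.05, 0.95, size=7)
        total = 0.0
        for yi, pi in zip(y, p):
            total += yi * np.log(pi) + (1 - yi) * np.log(1 - pi)
        assert bce_loss(y, p) == pytest.approx(-total / 7)

    def test_bce_length_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss([1.0], [0.5, 0.5])

    def test_total_loss_component_sum(self):
        lb = LossBreakdown(1.0, 2.0, 3.0, 4.0)
        assert lb.total == pytest.approx(10.0, rel=1e-9)

    def test_total_loss_perfect_predictions(self):
        preds = {"syn_score": [1.0, 2.0], "syn_prob": [0.999999, 1e-7],
                 "sen_score": [5.0], "sen_prob": [0.999999]}
        targs = {"syn_score": [1.0, 2.0], "syn_label": [1.0, 0.0],
                 "sen_score": [5.0], "sen_label": [1.0]}
        assert total_loss(preds, targs).total == pytest.approx(0.0, abs=1e-4)

    def test_total_loss_matches_independent_terms(self, rng):
        n, m = 8, 3
        preds = {"syn_score": rng.normal(size=n),
                 "syn_prob": rng.uniform(0.1, 0.9, size=n),
                 "sen_score": rng.normal(size=m),
                 "sen_prob": rng.uniform(0.1, 0.9, size=m)}
        targs = {"syn_score": rng.normal(size=n),
                 "syn_label": rng.integers(0, 2, size=n).astype(float),
                 "sen_score": rng.normal(size=m),
                 "sen_label": rng.integers(0, 2, size=m).astype(float)}
        lb = total_loss(preds, targs)
        assert lb.mse_syn == pytest.approx(
            np.mean((np.asarray(preds["syn_score"]) - targs["syn_score"]) ** 2))
        assert lb.bce_syn == pytest.approx(bce_loss(targs["syn_label"], preds["syn_prob"]))
        assert lb.mse_sen == pytest.approx(
            np.mean((np.asarray(preds["sen_score"]) - targs["sen_score"]) ** 2))
        assert lb.total == pytest.approx(lb.mse_syn + lb.mse_sen + lb.bce_syn + lb.bce_sen)

    def test_empty_sensitivity_contributes_zero(self):
        preds = {"syn_score": [1.0], "syn_prob": [0.5]}
        targs = {"syn_score": [0.0], "syn_label": [1.0], "sen_score": []}
        lb = total_loss(preds, targs)
        assert lb.mse_sen == 0.0 and lb.bce_sen == 0.0
        assert lb.mse_syn == pytest.approx(1.0)

    def test_empty_synergy_batch_errors(self):
        with pytest.raises(ValueError):
            total_loss({"syn_score": []}, {"syn_score": []})


class TestOrderedRowsAndLeakage:
    @pytest.fixture()
    def rows(self, tiny_run):
        data = tiny_run.data
        return build_ordered_rows(data, data.samples[:50]), data

    def test_duplication_doubles_rows_and_preserves_targets(self, rows):
        ordered, data = rows
        assert len(ordered) == 100
        first, second = ordered.take(np.arange(0, 100, 2)), ordered.take(np.arange(1, 100, 2))
        assert np.array_equal(first.syn_score, second.syn_score)
        assert np.array_equal(first.syn_label, second.syn_label)
        assert np.array_equal(first.row_idx, second.col_idx)
        assert np.array_equal(first.col_idx, second.row_idx)

    def test_leakage_filter_removes_only_sensitivity_rows(self, rows):
        ordered, data = rows
        fold = 0
        filtered = leakage_filter(ordered, fold)
        # synergy sub-batch untouched
        assert np.array_equal(filtered.syn_score, ordered.syn_score)
        assert len(filtered) == len(ordered)
        # brute-force row scan for the surviving sensitivity set
        expected = ordered.sen_mask & (ordered.drug_row_fold != fold)
        assert np.array_equal(filtered.sen_mask, expected)
        assert not filtered.sen_mask[ordered.drug_row_fold == fold].any()

    def test_filter_with_absent_fold_is_identity(self, rows):
        ordered, _ = rows
        filtered = leakage_filter(ordered, held_out_drug_fold=99)
        assert np.array_equal(filtered.sen_mask, ordered.sen_mask)

    def test_all_rows_held_out_empties_sensitivity(self, rows):
        ordered, data = rows
        everything = ordered
        for f in range(data.plan.n_folds):
            everything = leakage_filter(everything, f)
        assert not everything.sen_mask.any()
        assert np.array_equal(everything.syn_score, ordered.syn_score)


def _split(data, test_fold=0, val_fold=1):
    train = [s for s in data.samples if s.combo_fold not in (test_fold, val_fold)]
    val = [s for s in data.samples if s.combo_fold == val_fold]
    return train, val


class TestTrainModel:
    def test_patience_zero_stops_at_first_non_improvement(self, tiny_run):
        data = tiny_run.data
        train, val = _split(data)
        spec = pipeline.predictor_spec(TINY_CFG, data)
        opts = TrainOptions(batch_size=64, max_epochs=50, patience=0, seed=0)
        result = train_model(data, train, val, spec, opts)
        totals = [h.total for h in result.history]
        # every epoch except the last strictly improved on the best so far
        best = totals[0]
        for t in totals[1:-1]:
            assert t < best
            best = t
        assert len(totals) == 1 or totals[-1] >= min(totals[:-1]) or len(totals) == 50

    def test_identical_seeds_identical_history(self, tiny_run):
        data = tiny_run.data
        train, val = _split(data)
        spec = pipeline.predictor_spec(TINY_CFG, data)
        opts = TrainOptions(batch_size=64, max_epochs=3, patience=3, seed=5)
        r1 = train_model(data, train, val, spec, opts)
        r2 = train_model(data, train, val, spec, opts)
        assert r1.history == r2.history
        for a, b in zip(r1.model.state(), r2.model.state()):
            assert np.array_equal(a, b)

    def test_planted_signal_halves_validation_loss(self, tiny_run):
        data = tiny_run.data
        train, val = _split(data)
        spec = pipeline.predictor_spec(TINY_CFG, data)
        opts = TrainOptions(batch_size=64, max_epochs=40, patience=40, seed=0)
        result = train_model(data, train, val, spec, opts)
        assert result.best_loss < 0.5 * result.history[0].total


class TestGridSearch:
    def test_reduced_grid_returns_argmin(self, tiny_run):
        data = tiny_run.data
        train, val = _split(data)
        base = pipeline.predictor_spec(TINY_CFG, data)
        opts = TrainOptions(batch_size=64, max_epochs=3, patience=3, seed=0)
        best, table = grid_search(data, train, val, base,
                                  first_layer_grid=(16, 32),
                                  lr_grid=(1e-3, 1e-2), opts=opts)
        assert len(table) == 4
        argmin = table.loc[table.val_loss.idxmin()]
        assert best.resolved_shared_sizes[0] == argmin.first_layer
        assert best.learning_rate == argmin.learning_rate

    def test_degenerate_single_cell_grid(self, tiny_run):
        data = tiny_run.data
        train, val = _split(data)
        base = pipeline.predictor_spec(TINY_CFG, data)
        opts = TrainOptions(batch_size=64, max_epochs=2, patience=2, seed=0)
        best, table = grid_search(data, train, val, base,
                                  first_layer_grid=(16,), lr_grid=(1e-3,),
                                  opts=opts)
        assert len(table) == 1
        assert best.resolved_shared_sizes[0] == 16

    def test_tie_break_prefers_lower_lr_then_smaller_layer(self):
        table = pd.DataFrame({
            "first_layer": [4096, 2048, 2048],
            "learning_rate": [1e-4, 5e-4, 1e-4],
            "val_loss": [1.0, 1.0, 1.0],
        })
        best = select_best_cell(table)
        assert best.learning_rate == 1e-4
        assert best.first_layer == 2048


@pytest.fixture(scope="module")
def tiny_cv(tiny_run):
    data = tiny_run.data
    spec = pipeline.predictor_spec(TINY_CFG, data)
    opts = TrainOptions(batch_size=64, max_epochs=8, patience=4, seed=3)
    return training.cross_validate(data, spec, opts), data


class TestCrossValidate:
    def test_every_sample_predicted_exactly_once(self, tiny_cv):
        result, data = tiny_cv
        preds = result.synergy_predictions
        assert len(preds) == len(data.samples)
        keys = {(r.drug_row, r.drug_col, r.cell_id) for r in preds.itertuples()}
        assert len(keys) == len(data.samples)
        # each prediction was made by the model of the sample's own fold
        for r in preds.itertuples():
            key = pair_key(r.drug_row, r.drug_col)
            assert data.plan.combo_folds[key] == r.fold

    def test_sensitivity_predictions_only_for_held_out_drugs(self, tiny_cv):
        result, data = tiny_cv
        for r in result.sensitivity_predictions.itertuples():
            assert data.plan.drug_folds[r.drug_id] == r.fold

    def test_reproducible_under_fixed_seed(self, tiny_run):
        data = tiny_run.data
        spec = pipeline.predictor_spec(TINY_CFG, data)
        opts = TrainOptions(batch_size=64, max_epochs=2, patience=2, seed=11)
        r1 = training.cross_validate(data, spec, opts)
        r2 = training.cross_validate(data, spec, opts)
        pd.testing.assert_frame_equal(r1.synergy_predictions, r2.synergy_predictions)
        pd.testing.assert_frame_equal(r1.fold_metrics, r2.fold_metrics)
        assert r1.histories == r2.histories


class TestVariantLossStructure:
    @pytest.mark.parametrize("variant,zeroed", [
        ("only-synergy", ("mse_sen", "bce_sen")),
        ("only-sensitivity", ("mse_syn", "bce_syn")),
        ("regression-only", ("bce_syn", "bce_sen")),
    ])
    def test_excluded_components_are_structurally_zero(self, tiny_run, variant, zeroed):
        data = tiny_run.data
        train, val = _split(data)
        cfg = dataclasses.replace(TINY_CFG, variant=variant)
        spec = pipeline.predictor_spec(cfg, data)
        opts = TrainOptions(batch_size=64, max_epochs=2, patience=2, seed=0)
        result = train_model(data, train, val, spec, opts)
        for h in result.history:
            for name in zeroed:
                assert getattr(h, name) == 0.0
        if variant != "only-sensitivity":
            assert all(h.mse_syn > 0 for h in result.history)
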