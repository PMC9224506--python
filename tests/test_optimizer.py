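import dataclasses
import math

import numpy as np
import pytest

from cwqsar.chem_io import DatasetRecord
from cwqsar.descriptor import CorrelationWeights, DegenerateDescriptorError, ModelConfig
from cwqsar.metrics import r2
from cwqsar.optimizer import (
    SplitDataset,
    combine_tf,
    select_hyperparams,
    split_dataset,
    target_function,
    train,
)
from cwqsar.synthetic import generate_library, plant_and_label


def _records(n):
    return [
        DatasetRecord(id=str(i), cas="", smiles="C" * (1 + i % 9), value=float(i))
        for i in range(n)
    ]


class TestSplit:
    def test_equal_quarters_of_561(self):
        split = split_dataset(_records(561), seed=0)
        assert split.sizes == (140, 140, 140, 141)

    def test_partition_is_exact(self):
        records = _records(101)
        split = split_dataset(records, seed=3)
        ids = [r.id for subset in split.subsets().values() for r in subset]
        assert sorted(ids) == sorted(r.id for r in records)
        assert len(set(ids)) == len(records)

    def test_same_seed_same_partition(self):
        a = split_dataset(_records(100), seed=9)
        b = split_dataset(_records(100), seed=9)
        assert [r.id for r in a.active_training] == [r.id for r in b.active_training]
        assert [r.id for r in a.validation] == [r.id for r in b.validation]

    def test_different_seeds_differ(self):
        base = [r.id for r in split_dataset(_records(100), seed=0).active_training]
        assert any(
            [r.id for r in split_dataset(_records(100), seed=s).active_training] != base
            for s in range(1, 6)
        )

    def test_uneven_fractions(self):
        split = split_dataset(_records(100), fractions=(0.4, 0.4, 0.1, 0.1), seed=0)
        assert split.sizes == (40, 40, 10, 10)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_dataset(_records(100), fractions=(0.3, 0.3, 0.3, 0.3))

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            split_dataset(_records(5))


class TestTargetFunction:
    def test_combination_arithmetic(self):
        config = ModelConfig(tf_balance=0.1, iic_weight=0.0, cii_weight=0.0)
        assert combine_tf(1.0, 0.0, 0.0, 0.0, config) == pytest.approx(0.9)
        config = ModelConfig(tf_balance=0.1, iic_weight=0.25, cii_weight=0.30)
        assert combine_tf(0.8, 0.6, 0.5, 0.9, config) == pytest.approx(
            0.8 + 0.6 - 0.1 * 0.2 + 0.25 * 0.5 + 0.30 * 0.9
        )

    def test_perfect_correlation_gives_two(self):
        # endpoint equals the token count, so unit weights on S attributes
        # correlate perfectly on every subset
        config = ModelConfig(
            alpha=1, gamma=0, delta=0, x2=0, x3=0, iic_weight=0.0, cii_weight=0.0
        )
        records = [
            DatasetRecord(id=str(i), cas="", smiles="C" * (1 + i), value=float(1 + i))
            for i in range(16)
        ]
        split = SplitDataset(
            active_training=records[:4],
            passive_training=records[4:8],
            calibration=records[8:12],
            validation=records[12:],
        )
        from cwqsar.attributes import AttributeKey

        weights = {AttributeKey("S", "C"): 1.0}
        report = target_function(weights, split, config)
        assert report.tf == pytest.approx(2.0)
        assert report.r_at == pytest.approx(1.0)
        assert report.r_pt == pytest.approx(1.0)

    def test_report_invariant(self, noise_free_run, default_config):
        split, model, _ = noise_free_run
        report = target_function(model.cw, split, default_config)
        assert report.tf == pytest.approx(
            combine_tf(report.r_at, report.r_pt, report.iic_c, report.cii_c, default_config)
        )

    def test_degenerate_descriptor_rejected(self):
        config = ModelConfig(alpha=1, gamma=0, delta=0, x2=0, x3=0)
        records = [
            DatasetRecord(id=str(i), cas="", smiles="CC", value=float(i)) for i in range(16)
        ]
        split = SplitDataset(
            active_training=records[:4],
            passive_training=records[4:8],
            calibration=records[8:12],
            validation=records[12:],
        )
        from cwqsar.attributes import AttributeKey

        with pytest.raises(DegenerateDescriptorError):
            target_function({AttributeKey("S", "C"): 1.0}, split, config)


class TestTrain:
    def test_accepted_tf_trace_non_decreasing(self, noise_free_run):
        _, model, _ = noise_free_run
        trace = model.provenance["accepted_tf"]
        assert len(trace) > 1
        assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_seed_determinism_bit_identical(self, default_config):
        library = generate_library(80, seed=21)
        records, _ = plant_and_label(library, default_config, noise_sigma=0.2, seed=21)
        split = split_dataset(records, seed=21)
        config = dataclasses.replace(default_config, n_epochs=5)
        m1 = train(split, config, seed=4)
        m2 = train(split, config, seed=4)
        assert m1.cw.weights == m2.cw.weights
        assert (m1.c0, m1.c1) == (m2.c0, m2.c1)

    def test_noise_free_recovery(self, noise_free_run):
        split, model, planted = noise_free_run
        y = np.array([r.value for r in split.validation])
        yhat = np.array([model.describe(r.smiles).value for r in split.validation])
        assert r2(y, yhat) >= 0.95

    def test_learned_dcw_tracks_planted_dcw(self, noise_free_run, default_config):
        from cwqsar.attributes import extract_all
        from cwqsar.chem_io import build_hsg
        from cwqsar.descriptor import compute_dcw

        split, model, planted = noise_free_run
        true_cw = CorrelationWeights(weights=planted.true_weights)
        learned, truth = [], []
        for rec in split.validation:
            attrs = extract_all(build_hsg(rec.smiles), default_config)
            learned.append(compute_dcw(attrs, model.cw, default_config))
            truth.append(compute_dcw(attrs, true_cw, default_config))
        assert np.corrcoef(learned, truth)[0, 1] >= 0.97

    def test_epoch_log_shape(self, noise_free_run, default_config):
        _, model, _ = noise_free_run
        log = model.provenance["epoch_log"]
        assert len(log) == default_config.n_epochs
        assert set(log[0]) == {"epoch", "tf", "r_at", "r_pt", "iic_c", "cii_c", "cal_r2"}

    def test_best_snapshot_maximizes_calibration_r2(self, noise_free_run):
        _, model, _ = noise_free_run
        log = model.provenance["epoch_log"]
        best = model.provenance["best_calibration_r2"]
        assert best == pytest.approx(max(e["cal_r2"] for e in log))


@pytest.fixture(scope="module")
def planted_records(default_config):
    library = generate_library(80, seed=31)
    records, _ = plant_and_label(library, default_config, noise_sigma=0.2, seed=31)
    return records


class TestHyperparamSearch:
    def test_grid_matches_exhaustive_argmax(self, planted_records, default_config):
        config = dataclasses.replace(default_config, n_epochs=3)
        t_star, n_star, model = select_hyperparams(
            planted_records, config, t_values=[1, 2], n_values=[2, 3], seed=7
        )
        split = split_dataset(planted_records, seed=7)
        scores = {}
        for t in (1, 2):
            for n in (2, 3):
                cfg = dataclasses.replace(config, threshold=t, n_epochs=n)
                m = train(split, cfg, seed=7)
                scores[(t, n)] = m.provenance["best_calibration_r2"]
        best_score = max(scores.values())
        assert scores[(t_star, n_star)] == pytest.approx(best_score)
        assert model.provenance["best_calibration_r2"] == pytest.approx(best_score)

    def test_single_cell_grid(self, planted_records, default_config):
        config = dataclasses.replace(default_config, n_epochs=2)
        t_star, n_star, model = select_hyperparams(
            planted_records, config, t_values=[1], n_values=[2], seed=7
        )
        assert (t_star, n_star) == (1, 2)
        assert model.config.threshold == 1
        assert model.config.n_epochs == 2

    def test_empty_ranges_rejected(self, planted_records, default_config):
        with pytest.raises(ValueError):
            select_hyperparams(planted_records, default_config, [], [1], seed=0)
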