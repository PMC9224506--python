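import csv
import math
from pathlib import Path

import numpy as np
import pytest

from cwqsar.metrics import (
    UndefinedMetricError,
    ccc,
    cii,
    f_ratio,
    iic,
    mae,
    q2_f3,
    q2_loo,
    r2,
    rmse,
    subset_report,
    write_metrics_tsv,
)

from oracles import (
    ccc_oracle,
    cii_oracle,
    f_oracle,
    iic_oracle,
    q2_f3_oracle,
    q2_loo_oracle,
    r2_oracle,
)

DATA = Path(__file__).parent / "data"


def _random_vectors(seed, n=10):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = 0.5 * x + rng.normal(scale=0.8, size=n)
    return x, y


class TestOracleAgreement:
    """Each statistic matches an explicit-loop oracle to 1e-10 on random data."""

    @pytest.mark.parametrize("seed", range(20))
    def test_all_metrics(self, seed):
        x, y = _random_vectors(seed)
        c0, c1 = np.polynomial.polynomial.polyfit(x, y, 1)
        yhat = c0 + c1 * x
        assert r2(y, yhat) == pytest.approx(r2_oracle(list(y), list(yhat)), abs=1e-10)
        assert q2_loo(x, y) == pytest.approx(q2_loo_oracle(list(x), list(y)), abs=1e-10)
        assert ccc(y, yhat) == pytest.approx(ccc_oracle(list(y), list(yhat)), abs=1e-10)
        assert iic(y, yhat) == pytest.approx(iic_oracle(list(y), list(yhat)), abs=1e-10)
        assert cii(x, y) == pytest.approx(cii_oracle(list(x), list(y)), abs=1e-10)
        y_tr = list(_random_vectors(seed + 100)[1])
        assert q2_f3(y, yhat, y_tr) == pytest.approx(
            q2_f3_oracle(list(y), list(yhat), y_tr), abs=1e-10
        )
        r2v = r2(y, yhat)
        assert f_ratio(r2v, len(y)) == pytest.approx(f_oracle(r2v, len(y)), abs=1e-10)

    def test_sklearn_pearson_cross_check(self):
        from scipy.stats import pearsonr

        x, y = _random_vectors(123, n=50)
        assert r2(y, x) == pytest.approx(pearsonr(y, x).statistic ** 2, abs=1e-12)


class TestR2:
    def test_identical_vectors(self):
        assert r2([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_anticorrelation_squares_to_one(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r2(y, -y) == pytest.approx(1.0)

    def test_hand_computed(self):
        assert r2([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9643, abs=1e-4)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedMetricError):
            r2([1, 1, 1], [1, 2, 3])


class TestQ2:
    def test_exact_linear_data(self):
        x = np.arange(6.0)
        assert q2_loo(x, 2 + 3 * x) == pytest.approx(1.0)

    def test_never_exceeds_r2(self):
        for seed in range(10):
            x, y = _random_vectors(seed, n=12)
            c0, c1 = np.polynomial.polynomial.polyfit(x, y, 1)
            assert q2_loo(x, y) <= r2(y, c0 + c1 * x) + 1e-12


class TestQ2F3:
    def test_perfect_external_predictions(self):
        y = [1.0, 2.0, 3.0]
        assert q2_f3(y, y, [0.0, 1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_mean_prediction_near_zero(self):
        rng = np.random.default_rng(5)
        y_train = rng.normal(size=2000)
        y_ext = rng.normal(size=2000)
        yhat = np.full_like(y_ext, y_train.mean())
        assert q2_f3(y_ext, yhat, y_train) == pytest.approx(0.0, abs=0.1)

    def test_worse_than_mean_is_negative(self):
        y_train = [0.0, 1.0, 2.0, 3.0]
        assert q2_f3([0.0, 3.0], [3.0, 0.0], y_train) < 0


class TestCCC:
    def test_identical_vectors(self):
        assert ccc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_shift_penalized(self):
        y = np.array([-1.0, 0.0, 1.0]) * math.sqrt(1.5)  # population variance 1
        assert ccc(y, y + 5) == pytest.approx(2 / 27, abs=1e-10)

    def test_centered_anticorrelation(self):
        y = np.array([-1.0, 0.0, 1.0])
        assert ccc(y, -y) == pytest.approx(-1.0)


class TestIIC:
    def test_symmetric_residuals_give_r(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        yhat = y + np.array([-1.0, 1.0, -1.0, 1.0])
        from oracles import pearson_oracle

        assert iic(y, yhat) == pytest.approx(pearson_oracle(list(y), list(yhat)))

    def test_asymmetric_residuals_halve(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        yhat = y + np.array([-2.0, 1.0, -2.0, 1.0])
        from oracles import pearson_oracle

        assert iic(y, yhat) == pytest.approx(0.5 * pearson_oracle(list(y), list(yhat)))

    def test_one_signed_residuals_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert iic(y, y - 1.0) == 0.0


class TestCII:
    def test_exact_linear_data(self):
        x = np.arange(8.0)
        assert cii(x, 1 + 2 * x) == pytest.approx(1.0)

    def test_outlier_lowers_cii(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = 1 + 2 * x
        y[5] += 8.0  # gross outlier: removing it raises R2
        assert cii(x, y) < 1.0

    def test_small_n_rejected(self):
        with pytest.raises(UndefinedMetricError):
            cii([1, 2, 3, 4], [1, 2, 3, 4])


class TestFRatio:
    def test_reference_scale(self):
        # R2 = 0.51 over 140 compounds sits near the published F for that row
        assert f_ratio(0.51, 140) == pytest.approx(143.6, abs=0.1)

    def test_zero_r2(self):
        assert f_ratio(0.0, 50) == 0.0

    def test_perfect_fit_guarded(self):
        assert f_ratio(1.0, 50) == math.inf


class TestScaleInvariance:
    def test_r2_and_iic_under_common_affine(self):
        x, y = _random_vectors(7, n=15)
        for a, b in ((2.0, 1.0), (0.5, -3.0)):
            assert r2(a * y + b, a * x + b) == pytest.approx(r2(y, x), abs=1e-10)
            assert iic(a * y + b, a * x + b) == pytest.approx(iic(y, x), abs=1e-10)

    def test_ccc_only_under_identical_transform(self):
        x, y = _random_vectors(8, n=15)
        assert ccc(2 * y + 1, 2 * x + 1) == pytest.approx(ccc(y, x), abs=1e-10)
        assert ccc(y + 3, x) != pytest.approx(ccc(y, x), abs=1e-3)


class TestPublishedTableConsistency:
    """The published per-subset (R2, n, F) triples must be internally
    consistent with F = R2(n-2)/(1-R2), given that R2 is printed to two
    decimals: the printed F must lie within 3 of the F interval attainable
    from any R2 that rounds to the printed value."""

    def _rows(self):
        with open(DATA / "reference_model_stats.csv") as fh:
            return list(csv.DictReader(fh))

    def test_all_32_rows(self):
        rows = self._rows()
        assert len(rows) == 32
        for row in rows:
            n = int(row["n"])
            r2p = float(row["r2"])
            fp = float(row["f"])
            f_lo = f_ratio(max(r2p - 0.005, 0.0), n)
            f_hi = f_ratio(min(r2p + 0.005, 0.999999), n)
            gap = max(0.0, f_lo - fp, fp - f_hi)
            assert gap <= 3.0, f"{row['model']}/{row['set']}: gap {gap:.2f}"


class TestReport:
    def test_noise_free_training_r2(self, noise_free_run):
        split, model, _ = noise_free_run
        y = np.array([r.value for r in split.active_training])
        yhat = np.array([model.describe(r.smiles).value for r in split.active_training])
        rep = subset_report("active_training", y, yhat)
        assert rep.r2 >= 0.99

    def test_q2f3_only_with_training_anchor(self, noise_free_run):
        split, model, _ = noise_free_run
        y = np.array([r.value for r in split.calibration])
        yhat = np.array([model.describe(r.smiles).value for r in split.calibration])
        internal = subset_report("calibration", y, yhat)
        assert internal.q2f3 is None
        y_tr = np.array([r.value for r in split.active_training])
        external = subset_report("calibration", y, yhat, y_train=y_tr)
        assert external.q2f3 is not None

    def test_mae_never_exceeds_rmse(self):
        for seed in range(5):
            x, y = _random_vectors(seed, n=30)
            rep = subset_report("s", y, x)
            assert rep.mae <= rep.rmse + 1e-12

    def test_tsv_writer_layout(self, tmp_path):
        x, y = _random_vectors(0, n=20)
        rep = subset_report("validation", y, x, dcw=x, y_train=list(y))
        out = tmp_path / "metrics.tsv"
        write_metrics_tsv([rep], out)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == [
            "set", "n", "R2", "CCC", "IIC", "Q2", "Q2F3", "RMSE", "MAE", "F",
        ]
        assert lines[1].startswith("validation\t20\t")
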