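import numpy as np
import pytest

from qab.evaluation import (
    ReplicateLossTable,
    ci95,
    jackknife_se,
    probability_optimal,
    result_record,
    run_experiment,
    summarize,
    total_model_score,
    write_results,
)
from qab.models import ModelSpec
from qab.resampling import SplitSpec


class TestJackknife:
    def test_hand_value(self):
        assert jackknife_se([1.0, 2.0, 3.0]) == pytest.approx(1 / np.sqrt(3))

    def test_constant_vector(self):
        assert jackknife_se(np.full(50, 0.3)) == 0.0

    def test_reduces_to_standard_error_of_mean(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 200))
            assert jackknife_se(x) == pytest.approx(
                np.std(x, ddof=1) / np.sqrt(x.size), abs=1e-12
            )

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            jackknife_se([1.0])


class TestCi95:
    def test_degenerate_for_constant(self):
        assert ci95(np.full(30, 0.7)) == (0.7, 0.7)

    def test_percentile_rule(self):
        lo, hi = ci95(np.arange(1.0, 101.0))
        assert lo == pytest.approx(3.475)
        assert hi == pytest.approx(97.525)

    def test_contains_mean_for_symmetric_sample(self):
        x = np.random.default_rng(1).normal(size=500)
        lo, hi = ci95(x)
        assert lo < x.mean() < hi


def table(losses, names=("m1", "m2")):
    return ReplicateLossTable(
        losses=np.asarray(losses, dtype=float), model_names=names, loss_name="lmin"
    )


class TestProbabilityOptimal:
    def test_tie_splitting(self):
        t = table(np.c_[[0.1, 0.2, 0.3, 0.2], [0.2, 0.1, 0.3, 0.4]])
        np.testing.assert_allclose(probability_optimal(t), [0.625, 0.375])

    def test_strict_winner(self):
        t = table(np.c_[[0.1, 0.1], [0.2, 0.3]])
        np.testing.assert_allclose(probability_optimal(t), [1.0, 0.0])

    def test_identical_models_split_evenly(self):
        t = table(np.c_[[0.1, 0.5], [0.1, 0.5]])
        np.testing.assert_allclose(probability_optimal(t), [0.5, 0.5])

    def test_sums_to_one(self):
        rng = np.random.default_rng(2)
        t = table(rng.random((50, 3)), names=("a", "b", "c"))
        assert probability_optimal(t).sum() == pytest.approx(1.0)

    def test_invariant_to_monotone_transform_per_iteration(self):
        rng = np.random.default_rng(3)
        losses = rng.random((40, 3))
        t1 = table(losses, names=("a", "b", "c"))
        t2 = table(np.exp(5 * losses) + 1, names=("a", "b", "c"))
        np.testing.assert_allclose(probability_optimal(t1), probability_optimal(t2))

    def test_missing_iterations_dropped(self):
        losses = np.array([[0.1, 0.2], [np.nan, 0.1], [0.3, 0.4]])
        np.testing.assert_allclose(probability_optimal(table(losses)), [1.0, 0.0])


class TestTotalModelScore:
    def test_sums_across_datasets(self):
        total = total_model_score([np.array([0.6, 0.4]), np.array([0.2, 0.8])])
        np.testing.assert_allclose(total, [0.8, 1.2])

    def test_conservation(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(25):
            p = rng.random(4)
            ps.append(p / p.sum())
        assert total_model_score(ps).sum() == pytest.approx(25.0)

    def test_model_set_mismatch(self):
        with pytest.raises(ValueError, match="differ"):
            total_model_score([np.array([1.0]), np.array([0.5, 0.5])])


class TestRunExperiment:
    def test_table_shapes(self, linear_data):
        fps, ds, _ = linear_data
        tables = run_experiment(
            ds, fps,
            [ModelSpec("ridge"), ModelSpec("rf", seed=0)],
            SplitSpec(q=0.4, gamma=0.99, n_iterations=3, seed=1),
            gamma_grid=[0.1, 0.05],
        )
        assert set(tables) == {("mse", None), ("lmin", 0.1), ("lmin", 0.05),
                               ("lsum", 0.1), ("lsum", 0.05)}
        for t in tables.values():
            assert t.losses.shape == (3, 2)
            assert np.isfinite(t.losses).all()

    def test_model_order_only_permutes_columns(self, linear_data):
        # paired design: every model sees the same draw, so reordering the
        # model list permutes columns without changing any value
        fps, ds, _ = linear_data
        spec = SplitSpec(q=0.6, gamma=0.99, n_iterations=3, seed=2)
        ab = run_experiment(ds, fps, [ModelSpec("ridge"), ModelSpec("rf", seed=0)],
                            spec, losses=["mse"], gamma_grid=[0.1])
        ba = run_experiment(ds, fps, [ModelSpec("rf", seed=0), ModelSpec("ridge")],
                            spec, losses=["mse"], gamma_grid=[0.1])
        np.testing.assert_allclose(
            ab[("mse", None)].losses, ba[("mse", None)].losses[:, ::-1]
        )

    def test_dataset_quantile_gamma_mode(self, linear_data):
        fps, ds, _ = linear_data
        tables = run_experiment(
            ds, fps, [ModelSpec("ridge")],
            SplitSpec(q=0.4, gamma=0.95, n_iterations=2, seed=3),
            losses=["lmin"], gamma_grid=[0.95], gamma_mode="dataset_quantile",
        )
        # floor(80 * 0.05) = 4 actives out of 48 test molecules
        assert ("lmin", 0.95) in tables

    def test_unknown_loss_rejected(self, linear_data):
        fps, ds, _ = linear_data
        with pytest.raises(ValueError, match="unknown losses"):
            run_experiment(ds, fps, [ModelSpec("ridge")],
                           SplitSpec(n_iterations=2), losses=["auc"])

    def test_result_files_round_trip(self, linear_data, tmp_path):
        import json

        fps, ds, _ = linear_data
        tables = run_experiment(
            ds, fps, [ModelSpec("ridge"), ModelSpec("rf", seed=0)],
            SplitSpec(q=0.4, gamma=0.99, n_iterations=25, seed=4),
            losses=["lmin"], gamma_grid=[0.1], dataset_id="toy",
        )
        paths = write_results(tables, tmp_path, provenance={"seed": 4})
        rec = json.loads(paths[0].read_text())
        assert rec["dataset_id"] == "toy"
        assert rec["provenance"] == {"seed": 4}
        got = np.array(rec["replicate_losses"], dtype=float)
        np.testing.assert_allclose(got, tables[("lmin", 0.1)].losses)
        assert abs(sum(rec["summary"][m]["p_optimal"] for m in rec["model_names"]) - 1) < 1e-12


class TestSummarize:
    def test_summary_fields_consistent(self):
        rng = np.random.default_rng(5)
        t = table(rng.random((100, 2)))
        s = summarize(t)
        np.testing.assert_allclose(s.mean_loss, t.losses.mean(axis=0))
        for col in range(2):
            assert s.ci95[col, 0] <= s.mean_loss[col] <= s.ci95[col, 1]
        assert s.p_optimal.sum() == pytest.approx(1.0)
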