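import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alfaspec import (
    SimulationConfig,
    compare_models,
    fit_calibration,
    generate_dataset,
    r2_score,
    rmse,
    run_combination,
    run_matrix,
    split_dataset,
)
from alfaspec.evaluation import derive_seeds


def small_study(seed=3):
    """Reduced-axis study population exercising the full pipeline cheaply."""
    cfg = SimulationConfig(n_samples=30, n_points=300, seed=seed)
    return generate_dataset(cfg)[0]


class TestSplit:
    def test_reference_split_sizes(self):
        plan = split_dataset(90, (7, 1.5, 1.5), seed=0)
        assert plan.sizes == (63, 13, 14)

    def test_small_n_floor_rule(self):
        assert split_dataset(20, (7, 1.5, 1.5), seed=1).sizes == (14, 3, 3)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(10, 200), st.integers(0, 2**31 - 1))
    def test_partition_property(self, n, seed):
        plan = split_dataset(n, (7, 1.5, 1.5), seed=seed)
        combined = np.concatenate([plan.calibration, plan.validation, plan.prediction])
        assert sorted(combined) == list(range(n))
        assert sum(plan.sizes) == n

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(4, (20, 1, 1), seed=0)
        with pytest.raises(ValueError):
            split_dataset(2, (7, 1.5, 1.5), seed=0)


class TestMetrics:
    def test_perfect_and_mean_predictors(self):
        obs = np.array([1.0, 2.0, 4.0])
        assert r2_score(obs, obs) == pytest.approx(1.0)
        assert rmse(obs, obs) == 0.0
        assert r2_score(obs, np.full(3, obs.mean())) == pytest.approx(0.0)

    def test_hand_computed_fixtures(self):
        assert rmse(np.array([10.0, 12.0]), np.array([11.0, 13.0])) == pytest.approx(1.0)
        r2 = r2_score(np.array([1.0, 2.0, 3.0]), np.array([1.1, 2.0, 2.9]))
        assert r2 == pytest.approx(0.99)

    def test_reference_mean_override(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.array([1.5, 2.0, 2.5])
        default = r2_score(obs, pred)
        literal = r2_score(obs, pred, reference_mean=float(pred.mean()))
        assert default == pytest.approx(literal)  # means coincide here
        shifted = r2_score(obs, pred, reference_mean=0.0)
        assert shifted > default  # larger denominator

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            r2_score(np.full(3, 2.0), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            rmse(np.array([1.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            rmse(np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0]))


class TestRunCombination:
    def test_full_spectrum_combination_finite(self):
        sset = small_study()
        rep = run_combination(sset, recipe=(), selector="none", model_kind="plsr", seed=0)
        assert rep.n_features == sset.n_points
        for v in (rep.rmsec, rep.rc2, rep.rmsep, rep.rp2, rep.mae_prediction):
            assert np.isfinite(v)
        assert rep.details["split_sizes"] == (21, 4, 5)

    def test_metrics_recompute_exactly_from_pairs(self):
        rep = run_combination(
            small_study(), recipe=("to_absorbance",), selector="fgm",
            model_kind="plsr", cv=False, seed=2,
        )
        again = rep.recompute()
        assert again["rmsec"] == rep.rmsec
        assert again["rc2"] == rep.rc2
        assert again["rmsep"] == rep.rmsep
        assert again["rp2"] == rep.rp2
        assert again["mae_prediction"] == rep.mae_prediction

    def test_identical_seed_bit_identical_report(self):
        sset = small_study()
        kw = dict(recipe=("to_absorbance", "airpls"), selector="cars",
                  model_kind="plsr", cv=True, seed=5)
        r1 = run_combination(sset, **kw)
        r2 = run_combination(sset, **kw)
        assert r1.rmsep == r2.rmsep and r1.rp2 == r2.rp2
        np.testing.assert_array_equal(r1.selected_wavenumbers, r2.selected_wavenumbers)
        for subset in ("calibration", "validation", "prediction"):
            np.testing.assert_array_equal(r1.pairs[subset][1], r2.pairs[subset][1])

    def test_selection_and_fit_use_calibration_rows_only(self):
        sset = small_study(seed=9)
        rep = run_combination(
            sset, recipe=("to_absorbance",), selector="cars",
            model_kind="plsr", cv=True, seed=4,
        )
        # refit from the calibration subset alone (prediction rows deleted)
        # and compare: selection and coefficients must be unchanged
        seeds = derive_seeds(4)
        plan = split_dataset(sset.n_samples, (7, 1.5, 1.5), seeds["split"])
        from alfaspec.preprocessing import apply_recipe

        pre = apply_recipe(sset, ("to_absorbance",))
        pipe = fit_calibration(
            pre.X[plan.calibration], pre.y[plan.calibration], pre,
            selector="cars", model_kind="plsr", cv=True, seeds=seeds,
        )
        np.testing.assert_array_equal(
            pre.axis.values[pipe.selected], rep.selected_wavenumbers
        )
        np.testing.assert_array_equal(
            pipe.predict(pre.X[plan.prediction]), rep.pairs["prediction"][1]
        )

    def test_unknown_selector_or_model_rejected(self):
        sset = small_study()
        with pytest.raises(ValueError):
            run_combination(sset, selector="uve", seed=0)
        with pytest.raises(ValueError):
            run_combination(sset, model_kind="svm", seed=0)


class TestCompareModels:
    def _mk(self, label, rp2, rmsep):
        rep = run_combination(small_study(), recipe=(), selector="none",
                              model_kind="plsr", seed=0)
        return dataclasses.replace(rep, label=label, rp2=rp2, rmsep=rmsep)

    def test_single_report_single_row(self):
        df = compare_models([self._mk("only", 0.9, 0.5)])
        assert len(df) == 1 and df.loc[0, "Model"] == "only"

    def test_rp2_desc_then_rmsep_asc(self):
        df = compare_models(
            [
                self._mk("worse", 0.90, 0.50),
                self._mk("best", 0.95, 0.40),
                self._mk("tie_hi_rmsep", 0.95, 0.45),
            ]
        )
        assert list(df["Model"]) == ["best", "tie_hi_rmsep", "worse"]

    def test_matrix_produces_fully_populated_table(self):
        sset = small_study(seed=6)
        combos = (
            {"recipe": (), "selector": "none", "model_kind": "plsr", "cv": False},
            {"recipe": ("to_absorbance", "airpls"), "selector": "cars",
             "model_kind": "plsr", "cv": True},
            {"recipe": ("to_absorbance", "airpls"), "selector": "fgm",
             "model_kind": "plsr", "cv": True},
            {"recipe": ("to_absorbance", "airpls"), "selector": "fgm",
             "model_kind": "rfr", "cv": False},
        )
        reports = run_matrix(sset, combos, seed=1)
        df = compare_models(reports)
        assert len(df) == 4
        assert not df.isna().any().any()

    def test_matrix_reuse_matches_direct_run(self):
        sset = small_study(seed=8)
        combos = (
            {"recipe": ("to_absorbance", "airpls"), "selector": "cars",
             "model_kind": "plsr", "cv": True},
        )
        via_matrix = run_matrix(sset, combos, seed=7)[0]
        direct = run_combination(sset, recipe=("to_absorbance", "airpls"),
                                 selector="cars", model_kind="plsr", cv=True, seed=7)
        assert via_matrix.rmsep == direct.rmsep
        np.testing.assert_array_equal(
            via_matrix.selected_wavenumbers, direct.selected_wavenumbers
        )


def test_cli_simulate_and_run_all(tmp_path):
    from click.testing import CliRunner

    from alfaspec.cli import main

    runner = CliRunner()
    out = tmp_path / "spec.csv"
    refs = tmp_path / "refs.csv"
    r = runner.invoke(
        main,
        ["simulate", "--n", "12", "--n-points", "120", "--seed", "1",
         "--out", str(out), "--refs", str(refs), "--truth", str(tmp_path / "truth.csv")],
    )
    assert r.exit_code == 0, r.output
    assert out.exists() and refs.exists()

    r2 = runner.invoke(
        main,
        ["run-all", "--n", "24", "--n-points", "150", "--seed", "2",
         "--outdir", str(tmp_path / "res")],
    )
    assert r2.exit_code == 0, r2.output
    assert (tmp_path / "res" / "comparison.csv").exists()
    assert (tmp_path / "res" / "reports.json").exists()
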