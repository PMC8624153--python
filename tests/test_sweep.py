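"""Parameter sweeps, classification, hyperplane fits and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import dmmsort as dm
from dmmsort.cli import main as cli_main
from dmmsort.sweep import CONVERGENCE_TRIPLES, beta_columns

TINY = dict(n_switches=500, side=8)


def synthetic_table(n_types, n_rows, seed=0):
    """Run table with analytically generated labels sign(beta_star), no
    simulation involved.  Draws with |beta_star| < 1 are discarded: at the
    critical plane the class is physically ambiguous, and the margin makes
    the labels separable so the estimator check isolates the fit itself."""
    rng = np.random.default_rng(seed)
    dim = n_types + n_types * (n_types - 1) // 2
    flats = rng.uniform(-10, 10, size=(4 * n_rows, dim))
    stars = flats @ dm.a_star_vector(n_types)
    keep = np.abs(stars) >= 1.0
    flats, stars = flats[keep][:n_rows], stars[keep][:n_rows]
    assert len(flats) == n_rows
    table = pd.DataFrame(flats, columns=beta_columns(n_types))
    table["n_types"] = n_types
    table["beta_star"] = stars
    table["omega_bar"] = 1 / n_types + 0.2 * np.sign(stars)
    table["label"] = np.sign(stars).astype(int)
    return table


class TestSweep:
    def test_shape_columns_reproducibility(self):
        a = dm.sweep(2, 6, master_seed=5, **TINY)
        b = dm.sweep(2, 6, master_seed=5, **TINY)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 6
        for col in ("beta_00", "beta_11", "beta_01", "beta_s", "beta_star",
                    "beta_delta", "omega_bar", "seed"):
            assert col in a.columns
        assert a["seed"].nunique() == 6
        assert a["omega_bar"].between(0, 1).all()

    def test_master_seed_changes_draws(self):
        a = dm.sweep(2, 4, master_seed=5, **TINY)
        b = dm.sweep(2, 4, master_seed=6, **TINY)
        assert not np.allclose(a["beta_star"], b["beta_star"])

    def test_constraint_rejection_enforced(self):
        table = dm.sweep(3, 8, max_beta_delta=3.0, master_seed=1, **TINY)
        assert (table["beta_delta"] < 3.0).all()

    def test_impossible_constraint_raises(self):
        with pytest.raises(RuntimeError, match="constraint rejected"):
            dm.sweep(2, 2, constraint=lambda p: False, master_seed=0, **TINY)

    def test_first_passage_columns(self):
        table = dm.sweep(2, 3, first_passage_thresholds=(0.7,), master_seed=2,
                         **TINY)
        assert "fp_0.7" in table.columns


class TestRankCorrelations:
    def test_monotone_relation_is_perfect(self):
        t = pd.DataFrame({"beta_star": np.arange(20.0),
                          "omega_bar": np.linspace(0.1, 0.9, 20) ** 2})
        sp, kt = dm.rank_correlations(t)
        assert sp == 1.0 and kt == 1.0

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(3)
        t = pd.DataFrame({"beta_star": rng.normal(size=400),
                          "omega_bar": rng.normal(size=400)})
        sp, _ = dm.rank_correlations(t)
        assert abs(sp) < 0.15

    def test_too_few_rows(self):
        t = pd.DataFrame({"beta_star": [1.0, 2.0], "omega_bar": [0.1, 0.2]})
        with pytest.raises(ValueError, match="at least 10"):
            dm.rank_correlations(t)

    def test_constant_column_undefined(self):
        t = pd.DataFrame({"beta_star": np.ones(20), "omega_bar": np.arange(20.0)})
        with pytest.raises(ValueError, match="constant"):
            dm.rank_correlations(t)


class TestClassifyRuns:
    def test_strict_threshold(self):
        t = pd.DataFrame({"n_types": [2, 2, 2],
                          "omega_bar": [0.6, 0.5, 0.4]})
        out = dm.classify_runs(t, threshold=0.5)
        assert out["label"].tolist() == [1, -1, -1]
        assert out.attrs["threshold"] == 0.5

    def test_default_threshold_is_random_level(self):
        t = pd.DataFrame({"n_types": [3] * 3, "omega_bar": [0.5, 0.34, 0.2]})
        out = dm.classify_runs(t)
        assert out["label"].tolist() == [1, 1, -1]
        assert out.attrs["threshold"] == pytest.approx(1 / 3)


class TestFitHyperplane:
    @pytest.mark.parametrize("n_types", [2, 3])
    @pytest.mark.parametrize("method", ["svm", "logit"])
    def test_recovers_analytic_direction(self, n_types, method):
        """On labels generated exactly as sign(beta_star), both estimators
        recover the heterotypic-to-homotypic coefficient ratio -2/(N-1)."""
        table = synthetic_table(n_types, 2000, seed=n_types)
        fit = dm.fit_hyperplane(table, method, cv_seed=0)
        expected = -2.0 / (n_types - 1)
        assert fit.b_rel == pytest.approx(expected, rel=0.02)
        assert fit.cv_accuracy == 1.0
        assert fit.a_rel == 1.0
        assert fit.n_points == 2000

    def test_unclassified_table_rejected(self):
        table = synthetic_table(2, 50)
        table["label"] = np.nan
        with pytest.raises(ValueError, match="not classified"):
            dm.fit_hyperplane(table)

    def test_single_class_rejected(self):
        table = synthetic_table(2, 50)
        table["label"] = 1
        with pytest.raises(ValueError, match="both classes"):
            dm.fit_hyperplane(table)

    def test_unknown_method(self):
        table = synthetic_table(2, 50)
        with pytest.raises(ValueError, match="unknown method"):
            dm.fit_hyperplane(table, "forest")


class TestPresets:
    def test_fig3_uses_exactly_the_five_triples(self, tmp_path):
        table, summary = dm.preset_experiment(
            "fig3", n_switches=1500, side=8, seed=1, outdir=tmp_path
        )
        assert len(table) == 15  # 5 parameter sets x 3 repeats
        assert set(table["beta_delta"]) == {0, 2, 4, 6, 8}
        for bdelta, flat in CONVERGENCE_TRIPLES.items():
            rows = table[table["beta_delta"] == bdelta]
            assert len(rows) == 3
            assert np.allclose(
                rows[["beta_00", "beta_11", "beta_01"]].iloc[0], flat
            )
        assert (table["beta_star"] == 3.0).all()
        assert (tmp_path / "fig3_runs.csv").exists()
        assert (tmp_path / "fig3_summary.json").exists()

    def test_table1_preset_reports_both_fits(self):
        _, summary = dm.preset_experiment(
            "table1a", n_runs=40, n_switches=2000, side=8, seed=3
        )
        assert summary["theoretical_b_rel"] == -2.0
        assert {"svm", "logit"} <= set(summary)
        assert -4 < summary["svm"]["b_rel"] < 0

    def test_appd_preset_has_first_passage_columns(self):
        table, summary = dm.preset_experiment(
            "appD", n_runs=5, n_switches=1000, side=8, seed=2
        )
        assert {"fp_0.7", "fp_0.8", "fp_0.9"} <= set(table.columns)

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown preset"):
            dm.preset_experiment("fig9")


class TestCli:
    def test_simulate_reports_omega_bar(self):
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "simulate", "--beta", "1.0,1.0,-1.0", "--side", "8",
            "--n-switches", "2000", "--seed", "3",
        ])
        assert res.exit_code == 0, res.output
        out = json.loads(res.output)
        assert out["beta_star"] == 4.0
        assert 0 <= out["omega_bar"] <= 1

    def test_sweep_then_fit(self, tmp_path):
        runner = CliRunner()
        runs = str(tmp_path / "runs.csv")
        res = runner.invoke(cli_main, [
            "sweep", "--n-types", "2", "--n-runs", "40", "--n-switches", "800",
            "--side", "8", "--seed", "1", "--out", runs,
        ])
        assert res.exit_code == 0, res.output
        res = runner.invoke(cli_main, ["fit", "--runs", runs, "--method", "logit"])
        assert res.exit_code == 0, res.output
        fit = json.loads(res.output)
        assert fit["method"] == "logit"
        assert fit["b_rel"] < 0

    def test_sweep_config_file_defaults(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("n_types: 2\nn_runs: 5\nn_switches: 400\nside: 8\nseed: 9\n")
        runs = str(tmp_path / "runs.csv")
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "sweep", "--config", str(cfg), "--out", runs,
        ])
        assert res.exit_code == 0, res.output
        assert len(pd.read_csv(runs)) == 5

    def test_metrics_on_stored_grid(self, tmp_path):
        grid = tmp_path / "grid.txt"
        dm.reference_config("stripes", 8, 2).to_text(grid)
        runner = CliRunner()
        res = runner.invoke(cli_main, ["metrics", str(grid)])
        assert res.exit_code == 0, res.output
        out = json.loads(res.output)
        assert out["omega"] == 1.0
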