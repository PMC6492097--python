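"""File I/O, configuration, end-to-end workflow, CLI, and plotting."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from fpmeta import (
    AnalysisConfig,
    ColumnMap,
    SchemaError,
    ValidationError,
    make_erfc_like,
    read_ipd,
    run_analysis,
    sensitivity_reference,
    write_ipd,
)
from fpmeta.cli import main as cli_main

CMAP = ColumnMap(confounders=("age", "sex", "smoking"))


@pytest.fixture(scope="module")
def cohorts():
    studies, _ = make_erfc_like(n_cohorts=4, mean_size=1500, size_sigma=0.3,
                                seed=17)
    return studies


class TestIO:
    def test_round_trip_identity(self, cohorts, tmp_path):
        path = tmp_path / "ipd.csv"
        write_ipd(cohorts, path, CMAP)
        back = read_ipd(path, CMAP, winsor=None)
        assert [s.study_id for s in back] == [s.study_id for s in cohorts]
        for a, b in zip(cohorts, back):
            np.testing.assert_allclose(a.exposure, b.exposure)
            np.testing.assert_allclose(a.time, b.time)
            np.testing.assert_array_equal(a.event, b.event)
            np.testing.assert_allclose(a.confounders, b.confounders)

    def test_winsorization_applied_on_read(self, cohorts, tmp_path):
        path = tmp_path / "ipd.csv"
        write_ipd(cohorts, path, CMAP)
        raw = np.concatenate([s.exposure for s in cohorts])
        back = read_ipd(path, CMAP, winsor=(0.05, 0.95))
        pooled = np.concatenate([s.exposure for s in back])
        assert pooled.min() > raw.min() and pooled.max() < raw.max()

    def test_malformed_exposure_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "study,time,event,exposure\nA,1.0,1,24.0\nA,2.0,0,oops\nA,1.5,1,26.0\n"
        )
        with pytest.raises(SchemaError, match="row 1"):
            read_ipd(path)

    def test_missing_column_reported(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("study,time,exposure\nA,1.0,24.0\n")
        with pytest.raises(SchemaError, match="event"):
            read_ipd(path)

    def test_zero_event_study_loads_with_warning(self, tmp_path, caplog):
        path = tmp_path / "z.csv"
        rows = ["study,time,event,exposure"]
        rows += [f"A,1.0,0,{20 + i}" for i in range(5)]
        rows += [f"B,1.0,1,{20 + i}" for i in range(5)]
        path.write_text("\n".join(rows) + "\n")
        with caplog.at_level("WARNING", logger="fpmeta"):
            studies = read_ipd(path, winsor=None)
        assert any("zero events" in m for m in caplog.messages)
        assert {s.study_id for s in studies} == {"A", "B"}


class TestRunAnalysis:
    def test_metacurve_bundle_contents(self, cohorts):
        cfg = AnalysisConfig(method="metacurve", model="re", powers=(1, 2),
                             grid=30)
        bundle = run_analysis(cfg, cohorts)
        assert bundle.curve.method == "metacurve"
        assert bundle.curve.weights.shape[0] == len(bundle.fits)
        at_ref = np.isclose(bundle.curve.grid, cfg.x0)
        assert bundle.curve.se[at_ref] == 0.0
        assert bundle.heterogeneity is not None

    def test_common_power_selection_trace_is_complete(self, cohorts):
        cfg = AnalysisConfig(method="mvmeta", powers="common", dimension=2,
                             grid=25)
        bundle = run_analysis(cfg, cohorts)
        assert len(bundle.selection) == 44
        assert bundle.spec.degree == 2
        assert bundle.mvmeta is not None

    def test_study_specific_powers_with_mvmeta_rejected(self, cohorts):
        with pytest.raises(ValidationError, match="common powers"):
            run_analysis(AnalysisConfig(method="mvmeta", powers="by-study"),
                         cohorts)

    def test_reference_outside_data_range_rejected(self, cohorts):
        with pytest.raises(ValidationError, match="outside"):
            run_analysis(AnalysisConfig(x0=99.0, powers=(1, 2)), cohorts)

    def test_categorize_route(self, cohorts):
        cfg = AnalysisConfig(method="categorize", k_groups=4)
        bundle = run_analysis(cfg, cohorts)
        assert bundle.categories is not None
        assert bundle.categories.table.reference.sum() == 1

    def test_degree_selection_entry_point(self, cohorts):
        cfg = AnalysisConfig(method="metacurve", powers="common",
                             degree="select", alpha=0.05, grid=20)
        bundle = run_analysis(cfg, cohorts)
        assert bundle.degree in (0, "linear", 1, 2)


class TestSensitivity:
    def test_mvmeta_reference_shift_is_exact(self, cohorts):
        cfg = AnalysisConfig(method="mvmeta", powers=(1, 2))
        res = sensitivity_reference(cfg, cohorts, references=(22.0, 25.0, 28.0))
        assert np.all(res.differences.max_abs_difference.values < 1e-10)

    def test_metacurve_differences_reported(self, cohorts):
        cfg = AnalysisConfig(method="metacurve", powers=(1, 2), grid=30)
        res = sensitivity_reference(cfg, cohorts, references=(22.0, 25.0, 28.0))
        assert len(res.curves) == 3
        assert res.differences.max_abs_difference.iloc[0] == 0.0

    def test_single_reference_is_trivial(self, cohorts):
        cfg = AnalysisConfig(method="metacurve", powers=(1, 2), grid=20)
        res = sensitivity_reference(cfg, cohorts, references=(25.0,))
        assert len(res.differences) == 1
        assert res.differences.max_abs_difference.iloc[0] == 0.0


class TestPlots:
    def test_figure_files_written_and_nonempty(self, cohorts, tmp_path):
        from fpmeta.plots import plot_outputs

        cfg = AnalysisConfig(method="metacurve", powers=(1, 2), grid=25)
        bundle = run_analysis(cfg, cohorts)
        files = plot_outputs(bundle, tmp_path / "figs")
        assert {f.suffix for f in files} == {".svg", ".png"}
        assert all(f.stat().st_size > 0 for f in files)

    def test_weight_plot_data_sums_to_100(self, cohorts):
        from fpmeta import weight_profiles

        cfg = AnalysisConfig(method="metacurve", powers=(1, 2), grid=15)
        bundle = run_analysis(cfg, cohorts)
        wp = weight_profiles(bundle.curve)
        np.testing.assert_allclose(wp.sum(axis=0).values, 100.0)


class TestCLI:
    def test_simulate_run_plot_pipeline(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "d.csv"
        out = tmp_path / "out"
        r = runner.invoke(cli_main, ["simulate", "--example", "1",
                                     "--scale", "0.002", "--seed", "4",
                                     "--out", str(data)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, ["run", "--data", str(data),
                                     "--method", "mvmeta", "--powers", "1,2",
                                     "--ref", "25", "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert (out / "curve.csv").exists()
        curve = pd.read_csv(out / "curve.csv")
        assert {"x", "estimate", "se", "ci_low", "ci_high"} <= set(curve.columns)
        r = runner.invoke(cli_main, ["plot", "--curve", str(out / "curve.csv"),
                                     "--out", str(tmp_path / "fig.png")])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "fig.png").stat().st_size > 0

    def test_exit_codes_distinguish_error_classes(self, tmp_path):
        runner = CliRunner()
        bad = tmp_path / "bad.csv"
        bad.write_text("study,time,event\nA,1.0,1\n")
        r = runner.invoke(cli_main, ["run", "--data", str(bad),
                                     "--powers", "1,2",
                                     "--out", str(tmp_path / "o")])
        assert r.exit_code == 3  # schema error
        good = tmp_path / "good.csv"
        r0 = runner.invoke(cli_main, ["simulate", "--example", "1",
                                      "--scale", "0.001", "--seed", "0",
                                      "--out", str(good)])
        assert r0.exit_code == 0
        r = runner.invoke(cli_main, ["run", "--data", str(good),
                                     "--method", "mvmeta",
                                     "--powers", "by-study",
                                     "--out", str(tmp_path / "o")])
        assert r.exit_code == 2  # configuration error
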