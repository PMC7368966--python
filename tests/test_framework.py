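import numpy as np
import pytest

import nirband as nb
from nirband.synthetic_data import Component, GaussianBand, SyntheticConfig


def small_config(seed):
    """Reduced-scale planted-band dataset: 120 channels, 80 samples."""
    return SyntheticConfig(
        axis=nb.WavelengthAxis(1100.0, 2.0, 120),  # 1100-1338 nm
        n_samples=80,
        analyte=Component(
            name="analyte",
            bands=(GaussianBand(1240.0, 8.0, 0.010),),
            conc_mean=60.7, conc_sd=4.36, conc_bounds=(53.0, 67.0),
            family="scaled_beta"),
        interferents=(
            Component(name="matrix", conc_mean=1.0, conc_sd=0.0,
                      bands=(GaussianBand(1160.0, 40.0, 0.40),
                             GaussianBand(1290.0, 50.0, 0.35))),
            Component(name="interferent", conc_mean=10.0, conc_sd=2.0,
                      corr_with_analyte=0.3,
                      bands=(GaussianBand(1180.0, 12.0, 0.012),)),
        ),
        baseline_offset_sd=0.05, baseline_slope_sd=5e-5,
        noise_sd=0.00436, seed=seed)


def small_framework_config(**kw):
    base = dict(
        n_cal=36, n_val=20, n_test=24, split_seed=0,
        grid=nb.WindowGrid.from_spec("6:6:18"),
        k=2, crossover_pct_grid=(50.0,), mutation_pct_grid=(1.2,),
        ga_max_iterations=60, ga_seed=0,
        baseline_population=30, baseline_max_iterations=40)
    base.update(kw)
    return nb.FrameworkConfig(**base)


@pytest.fixture(scope="module")
def small_run(tmp_path_factory):
    ds, _ = nb.generate(small_config(seed=0))
    outdir = tmp_path_factory.mktemp("run")
    report = nb.run_framework(ds, small_framework_config(), outdir=outdir)
    return ds, report, outdir


class TestRunFramework:
    def test_report_structure(self, small_run):
        _, report, _ = small_run
        frame = report.to_frame()
        assert len(frame) == 2
        assert report.testing.n == 24 and report.validation.n == 20
        assert (frame.post_ga_rmsev > 0).all()

    def test_full_scale_recovery_and_ga_improvement(self):
        """End-to-end on the full-scale planted-band data: the winning
        waveband overlaps 1980-2050 nm and the GA-refined model is at least
        as good as the window model, in a majority of seeds."""
        overlaps = improvements = 0
        for seed in range(3):
            ds, _ = nb.generate(nb.SyntheticConfig(seed=300 + seed))
            cfg = nb.FrameworkConfig(
                n_cal=90, n_val=50, n_test=54, split_seed=seed,
                grid=nb.WindowGrid.from_spec("24:12:48"), k=1,
                crossover_pct_grid=(50.0,), mutation_pct_grid=(1.2,),
                ga_max_iterations=100, ga_seed=seed)
            report = nb.run_framework(ds, cfg)
            row = report.to_frame().iloc[report.best_index]
            overlaps += row.start_nm <= 2050 and row.end_nm >= 1980
            improvements += row.post_ga_rmsev <= row.pre_ga_rmsev + 1e-9
        assert overlaps >= 2
        assert improvements >= 2

    def test_post_ga_not_worse_than_pre_ga(self, small_run):
        _, report, _ = small_run
        best = report.best
        assert best.ga_trace.best_rmsev <= best.record.rmsev + 1e-9

    def test_artifacts_written(self, small_run):
        _, report, outdir = small_run
        for name in ("report.csv", "manifest.txt", "gsmw_surface.csv",
                     "top_windows.csv", "ga_trace_band1.csv"):
            assert (outdir / name).exists()
        surface = (outdir / "gsmw_surface.csv").read_text()
        assert surface.count("\n") - 1 == len(report.gsmw.records)

    def test_degenerate_config_single_row(self):
        ds, _ = nb.generate(small_config(seed=1))
        cfg = small_framework_config(k=1)
        report = nb.run_framework(ds, cfg)
        assert len(report.to_frame()) == 1

    def test_stage_failure_names_stage(self):
        ds, _ = nb.generate(small_config(seed=0))
        bad = small_framework_config(n_cal=37)  # sizes no longer sum to n
        with pytest.raises(RuntimeError, match="split"):
            nb.run_framework(ds, bad)

    def test_byte_identical_reruns(self, tmp_path):
        ds, _ = nb.generate(small_config(seed=2))
        cfg = small_framework_config(split_seed=3, ga_seed=3)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        nb.run_framework(ds, cfg, outdir=d1)
        nb.run_framework(ds, cfg, outdir=d2)
        for name in ("report.csv", "manifest.txt", "gsmw_surface.csv",
                     "top_windows.csv", "ga_trace_band1.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name


class TestBaselineGA:
    def test_mutation_off_uniform_population_is_inert(self):
        # with no mutation, crossover of identical parents creates nothing new
        rng = np.random.default_rng(0)
        sc, sv = rng.normal(size=(20, 6)), rng.normal(size=(10, 6))
        beta = np.array([1.0, 2.0, 0.0, 0.0, 0.0, 0.0])
        yc, yv = sc @ beta, sv @ beta
        start = np.tile(rng.integers(0, 2, size=6).astype(bool), (20, 1))
        if not start[0].any():
            start[:, 0] = True
        cfg = nb.GAConfig(p_crossover=0.6, p_mutation=0.0, population_size=20,
                          max_iterations=30, seed=4)
        trace = nb.evolve(sc, yc, sv, yv, cfg, initial_population=start)
        assert np.array_equal(trace.best_chromosome, start[0])
        assert np.ptp(trace.best_rmsev_per_iteration) == 0.0

    def test_baseline_chromosome_spans_full_axis(self, small_run, monkeypatch):
        ds, _, _ = small_run
        captured = {}
        import nirband.framework as fw
        orig = nb.evolve

        def spy(sc, yc, sv, yv, cfg, **kw):
            trace = orig(sc, yc, sv, yv, cfg, **kw)
            captured["m"] = trace.best_chromosome.size
            return trace

        monkeypatch.setattr(fw, "evolve", spy)
        cfg = small_framework_config(baseline_max_iterations=3,
                                     baseline_population=10)
        nb.run_baseline_ga(ds, cfg)
        assert captured["m"] == ds.axis.count

    def test_paired_comparison_reports_both_models(self):
        """The baseline comparison runs on the same split and yields finite
        testing metrics for both routes.  (Which route wins is an empirical,
        data-dependent question, not a contract.)"""
        ds, _ = nb.generate(small_config(seed=100))
        cfg = small_framework_config(split_seed=0, ga_seed=0, run_baseline=True)
        report = nb.run_framework(ds, cfg)
        assert report.baseline_testing is not None
        assert np.isfinite(report.baseline_testing.rmse)
        assert report.baseline_testing.n == report.testing.n == 24

    def test_baseline_deterministic(self):
        ds, _ = nb.generate(small_config(seed=101))
        cfg = small_framework_config(baseline_max_iterations=10,
                                     baseline_population=10)
        a = nb.run_baseline_ga(ds, cfg)
        b = nb.run_baseline_ga(ds, cfg)
        assert a.rmse == b.rmse and a.r == b.r
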