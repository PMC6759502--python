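"""Generator-level checks: exact noise-free behaviour, stationarity,
reproducibility, and the statistical structure downstream stages assume."""

import numpy as np
import pytest

import flucdyn as fd
from flucdyn.config import ConfigError
from flucdyn.datasets import MOLECULES_PER_NM_FL


class TestFluctuationTraces:
    def test_noise_free_molecule_counts_double_each_cycle(self, noise_free_config):
        traces = fd.make_fluctuation_traces(noise_free_config, 4, 3)
        kappa = noise_free_config.kappa
        for (_, _), grp in traces.data.groupby(["cell_id", "cycle_id"]):
            v = grp.sort_values("frame")["intensity"].to_numpy()
            bg = grp.sort_values("frame")["background"].to_numpy()
            molecules = (v - bg) / kappa
            assert molecules[-1] == pytest.approx(2.0 * molecules[0], rel=1e-12)

    def test_zero_log_sd_gives_constant_concentration(self, config):
        cfg = config.replace(log_sd=0.0, obs_cv=0.0)
        traces = fd.make_fluctuation_traces(cfg, 3, 2)
        sync = fd.synchronize(_to_mol(traces, cfg))
        conc = fd.to_concentration(sync, cfg.v0_fl)
        assert np.allclose(conc.values.to_numpy(), cfg.base_conc_nm)

    def test_division_flag_marks_each_cycle_end_once(self, config):
        traces = fd.make_fluctuation_traces(config, 5, 3)
        for (_, _), grp in traces.data.groupby(["cell_id", "cycle_id"]):
            grp = grp.sort_values("frame")
            assert grp["division_flag"].sum() == 1
            assert grp["division_flag"].iloc[-1] == 1

    def test_stationary_log_sd_recovered(self, config):
        cfg = config.replace(obs_cv=0.0)
        traces = fd.make_fluctuation_traces(cfg, 500, 1, seed=7)
        mol = _to_mol(traces, cfg)
        sync = fd.synchronize(mol, grid_size=20)
        conc = fd.to_concentration(sync, cfg.v0_fl)
        pooled_sd = np.log(conc.values.to_numpy()).std()
        assert pooled_sd == pytest.approx(cfg.log_sd, rel=0.10)

    def test_median_concentration_range_two_to_three_fold(self, config):
        traces = fd.make_fluctuation_traces(config, 60, 2, seed=11)
        mol = _to_mol(traces, config)
        conc = fd.to_concentration(fd.synchronize(mol), config.v0_fl)
        mat, _ = conc.per_cell_matrix(2)
        ratios = mat.max(axis=1) / mat.min(axis=1)
        assert 2.0 <= np.median(ratios) <= 3.0

    def test_same_seed_bit_identical_serialization(self, config, tmp_path):
        from flucdyn.io import write_trace_table

        payloads = []
        for _ in range(2):
            traces = fd.make_fluctuation_traces(config, 5, 2, seed=99)
            path = tmp_path / "t.tsv"
            write_trace_table(traces, path, seed=99)
            payloads.append(path.read_bytes())
        assert payloads[0] == payloads[1]

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            fd.GeneratorConfig(v0_fl=-1.0)
        with pytest.raises(ConfigError):
            fd.GeneratorConfig(log_sd=-0.1)

    def test_time_strictly_increasing_per_cell(self, config):
        traces = fd.make_fluctuation_traces(config, 4, 2)
        for _, grp in traces.data.groupby(["cell_id", "channel"]):
            assert np.all(np.diff(grp["time_h"].to_numpy()) > 0)


def _to_mol(traces, cfg):
    """Direct conversion with the generator's own kappa (no calibration fit)."""
    from flucdyn.calibration import ConversionModel, to_molecules

    return to_molecules(traces, ConversionModel(cfg.kappa, 1, 0.0))


class TestDecayTraces:
    def test_noise_free_half_life_exact(self, noise_free_config):
        traces = fd.make_decay_traces(noise_free_config, 1, 8.0, 12.5, 0.25)
        grp = traces.data.sort_values("frame")
        v = grp["intensity"].to_numpy() - grp["background"].to_numpy()
        t = grp["time_h"].to_numpy()
        at8 = v[np.isclose(t, 8.0)][0]
        assert at8 == pytest.approx(0.5 * v[0], rel=1e-12)

    def test_infinite_half_life_constant_trace(self, noise_free_config):
        traces = fd.make_decay_traces(noise_free_config, 2, float("inf"), 5.0, 0.5)
        for _, grp in traces.data.groupby("cell_id"):
            v = grp["intensity"].to_numpy() - grp["background"].to_numpy()
            assert np.allclose(v, v[0])

    def test_interval_longer_than_duration_rejected(self, config):
        with pytest.raises(ConfigError):
            fd.make_decay_traces(config, 1, 8.0, duration_h=1.0, interval_h=2.0)

    def test_division_partitions_signal(self, noise_free_config):
        traces = fd.make_decay_traces(
            noise_free_config, 10, 8.0, 12.5, 0.25, division_prob=1.0, seed=3
        )
        cells = set(traces.data["cell_id"])
        assert any(c.endswith(".1") for c in cells)
        # daughters sum to the undivided exponential continuation
        d1 = traces.data[traces.data["cell_id"] == "c0000.1"].sort_values("frame")
        d2 = traces.data[traces.data["cell_id"] == "c0000.2"].sort_values("frame")
        parent = traces.data[traces.data["cell_id"] == "c0000"].sort_values("frame")
        v0 = parent["intensity"].iloc[0] - parent["background"].iloc[0]
        summed = (
            d1["intensity"].to_numpy()
            - d1["background"].to_numpy()
            + d2["intensity"].to_numpy()
            - d2["background"].to_numpy()
        )
        expected = v0 * np.exp(-np.log(2) / 8.0 * d1["time_h"].to_numpy())
        assert np.allclose(summed, expected, rtol=1e-9)


class TestCommitmentTraces:
    def test_large_effect_raises_sox2_in_committed(self, config):
        traces, truth = fd.make_commitment_traces(
            config, 60, effect_size=5.0, seed=5, return_truth=True
        )
        sox2 = traces.select_channel("SOX2")
        starts = sox2.groupby(["cell_id", "cycle_id"]).first().reset_index()
        committed = set(truth.loc[truth["commit_cycle"] >= 0, "cell_id"])
        start0 = starts[starts["cycle_id"] == 0]
        mean_committed = start0[start0["cell_id"].isin(committed)]["intensity"].mean()
        mean_neg = start0[~start0["cell_id"].isin(committed)]["intensity"].mean()
        assert mean_committed > mean_neg

    def test_plateau_below_threshold_never_classified_positive(self, config):
        traces = fd.make_commitment_traces(
            config, 30, effect_size=0.0, plateau_molecules=400.0, seed=6
        )
        labels = fd.classify_reporter(traces, threshold=500.0, min_hours=4.0)
        assert set(labels.labels["label"]) == {"negative"}

    def test_null_effect_groups_indistinguishable(self, config):
        pvals = []
        for seed in range(8):
            traces, truth = fd.make_commitment_traces(
                config, 50, effect_size=0.0, seed=100 + seed, return_truth=True
            )
            sox2 = traces.select_channel("SOX2")
            start0 = (
                sox2[sox2["cycle_id"] == 0].groupby("cell_id").first().reset_index()
            )
            committed = set(truth.loc[truth["commit_cycle"] >= 0, "cell_id"])
            a = start0[start0["cell_id"].isin(committed)]["intensity"]
            b = start0[~start0["cell_id"].isin(committed)]["intensity"]
            res = fd.compare_two_samples(a, b)
            pvals.append(res.pvalue)
        # no systematic separation: p-values not concentrated near zero
        assert np.median(pvals) > 0.05


class TestSnapshotPopulation:
    def test_all_g1_dna_within_2n_component(self, config):
        snap = fd.make_snapshot_population(config, 5000, 1.0, seed=2)
        dna = snap["dna_content"].to_numpy()
        # 2N peak at 100 with 5% CV: essentially everything below 1.3 * 2N
        assert np.quantile(dna, 0.999) < 130.0

    def test_zero_correlation_levels_uncorrelated(self, config):
        n = 20000
        snap = fd.make_snapshot_population(config, n, 0.6, correlation=0.0, seed=3)
        r = np.corrcoef(np.log(snap["sox2_level"]), np.log(snap["oct4_level"]))[0, 1]
        assert abs(r) < 3.0 / np.sqrt(n)

    def test_g1_fraction_controls_mixture(self, config):
        snap = fd.make_snapshot_population(config, 50000, 0.3, seed=4)
        assert snap["g1_truth"].mean() == pytest.approx(0.3, abs=0.02)


class TestCalibrationFrames:
    def test_noise_free_arithmetic(self, noise_free_config):
        cfg = noise_free_config.replace(kappa=4.0, phi_f=2.0)
        cal = fd.make_calibration_frames(cfg, 3, molecules_mean=500.0, molecules_cv=0.0)
        assert np.allclose(cal.data["nluc_intensity"], 2000.0)
        assert np.allclose(cal.data["fluc_intensity"], 1000.0)

    def test_equal_constants_give_equal_intensities(self, noise_free_config):
        cfg = noise_free_config.replace(kappa=3.0, phi_f=3.0)
        cal = fd.make_calibration_frames(cfg, 10)
        assert np.allclose(cal.data["nluc_intensity"], cal.data["fluc_intensity"])

    def test_noisy_recovery_within_three_percent(self, config):
        cfg = config.replace(obs_cv=0.05, kappa=4.0)
        cal = fd.make_calibration_frames(cfg, 50, seed=8)
        model = fd.fit_conversion_factor(cal)
        assert model.kappa_hat == pytest.approx(4.0, rel=0.03)
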