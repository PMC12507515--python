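"""Ground-truth generators: determinism, invariants, closed forms."""

import numpy as np
import pandas as pd
import pytest

from cas12akin import cis_kinetics as ck
from cas12akin import domain_dynamics as dd
from cas12akin import synthetic_data as sd

PCT = ["pct_supercoiled", "pct_nicked", "pct_linear"]


class TestSynthSpec:
    def test_invalid_specs_rejected(self):
        good = dict(seed=1, time_grid=(0.0, 1.0, 2.0))
        sd.SynthSpec(**good)
        with pytest.raises(ValueError, match="strictly increasing"):
            sd.SynthSpec(seed=1, time_grid=(0.0, 2.0, 1.0))
        with pytest.raises(ValueError, match="noise_sd"):
            sd.SynthSpec(**good, noise_sd=-1.0)
        with pytest.raises(ValueError, match="dye_bias"):
            sd.SynthSpec(**good, dye_bias=(1.0, 0.0, 1.0))


class TestTimecourse:
    def test_zero_rates_flat(self):
        spec = sd.SynthSpec(seed=0, time_grid=(0.0, 10.0, 100.0), n_replicates=2)
        for tc in sd.gen_timecourse(ck.CleavageParams(0, 0, 0, 0),
                                    ck.InitialState(100.0), spec):
            assert np.allclose(tc["pct_supercoiled"], 100.0)
            assert np.allclose(tc[["pct_nicked", "pct_linear"]], 0.0)

    def test_noiseless_matches_closed_form(self):
        spec = sd.SynthSpec(seed=0, time_grid=(0.0, 10.0), n_replicates=1)
        tc = sd.gen_timecourse(ck.CleavageParams(0.1, 0, 0, 0),
                               ck.InitialState(100.0), spec)[0]
        assert tc["pct_supercoiled"].iloc[1] == pytest.approx(
            100 * np.exp(-1.0), abs=1e-9)

    def test_determinism_and_replicate_independence(self, log_time_grid, true_params):
        spec = sd.SynthSpec(seed=7, time_grid=log_time_grid, noise_sd=2.0)
        a = sd.gen_timecourse(true_params, ck.InitialState(100.0), spec)
        b = sd.gen_timecourse(true_params, ck.InitialState(100.0), spec)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)
        assert not np.allclose(a[0][PCT], a[1][PCT])  # replicates differ

    def test_noisy_fractions_renormalized(self, log_time_grid, true_params):
        spec = sd.SynthSpec(seed=7, time_grid=log_time_grid, noise_sd=5.0)
        tc = sd.gen_timecourse(true_params, ck.InitialState(100.0), spec)[0]
        vals = tc[PCT].to_numpy()
        assert np.allclose(vals.sum(axis=1), 100.0, atol=1e-9)
        assert (vals >= 0).all() and (vals <= 100 + 1e-9).all()
        assert tc.attrs["ground_truth"]["ka"] == true_params.ka


class TestGelLanes:
    def _tc(self, fracs):
        n, l, s = fracs
        return pd.DataFrame({"replicate": [1], "time_s": [0.0],
                             "pct_nicked": [n], "pct_linear": [l],
                             "pct_supercoiled": [s]})

    def test_unbiased_lane_intensities(self):
        spec = sd.SynthSpec(seed=0, time_grid=(0.0,), dye_bias=(1, 1, 1),
                            total_signal=1000.0)
        lanes = sd.gen_gel_lanes(self._tc((20, 30, 50)), spec)
        assert lanes[["I_nicked", "I_linear", "I_supercoiled"]].iloc[0].tolist() == \
            [200.0, 300.0, 500.0]

    def test_biased_pure_supercoiled_lane(self):
        spec = sd.SynthSpec(seed=0, time_grid=(0.0,),
                            dye_bias=(1.2547, 1.1696, 0.5747), total_signal=1000.0)
        lanes = sd.gen_gel_lanes(self._tc((0, 0, 100)), spec)
        assert lanes["I_supercoiled"].iloc[0] == pytest.approx(574.7)
        assert lanes["I_nicked"].iloc[0] == 0.0

    def test_bad_fraction_sum_rejected(self):
        spec = sd.SynthSpec(seed=0, time_grid=(0.0,))
        with pytest.raises(ValueError, match="sum to 100"):
            sd.gen_gel_lanes(self._tc((10, 10, 10)), spec)

    def test_noise_clipping_flagged(self):
        spec = sd.SynthSpec(seed=1, time_grid=(0.0,), noise_sd=50.0)
        lanes = sd.gen_gel_lanes(self._tc((0, 0, 100)), spec)
        assert (lanes[["I_nicked", "I_linear", "I_supercoiled"]] >= 0).all().all()
        assert lanes.attrs["n_clipped"] >= 0


class TestDilutionSeries:
    def test_unbiased_topologies_identical(self):
        t = sd.gen_dilution_series((1, 1, 1), [1, 2, 4])
        assert (t["I_nicked"] == t["I_linear"]).all()
        assert (t["I_nicked"] == t["I_supercoiled"]).all()

    def test_slope_ratios_match_bias(self):
        bias = (1.2547, 1.1696, 0.5747)
        t = sd.gen_dilution_series(bias, [1, 2, 4])
        a = t["amount"].to_numpy()
        slopes = [a @ t[c].to_numpy() / (a @ a)
                  for c in ("I_nicked", "I_linear", "I_supercoiled")]
        assert np.allclose(np.array(slopes) / slopes[0],
                           np.array(bias) / bias[0], atol=1e-12)

    def test_seeded_noise_reproducible(self):
        a = sd.gen_dilution_series((1, 1, 1), [1, 2], seed=5, noise_sd=10.0)
        b = sd.gen_dilution_series((1, 1, 1), [1, 2], seed=5, noise_sd=10.0)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_amounts_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            sd.gen_dilution_series((1, 1, 1), [])


class TestFluorescence:
    def test_zero_rate_flat_at_background(self):
        cur = sd.gen_fluorescence(0.0, 1000.0, 77.0, np.arange(0, 301, 30))
        assert np.allclose(cur["rfu"], 77.0)

    def test_saturation_plateau(self):
        cur = sd.gen_fluorescence(10.0, 1000.0, 50.0, [2.0, 10.0, 100.0])
        assert np.allclose(cur["rfu"], 1050.0, atol=1e-3)

    def test_closed_form_values(self):
        t = np.arange(30, 301, 30)
        cur = sd.gen_fluorescence(0.001, 1000.0, 0.0, t)
        assert np.allclose(cur["rfu"], 1000.0 * (1 - np.exp(-0.001 * t)), atol=1e-12)

    def test_noiseless_monotone(self):
        cur = sd.gen_fluorescence(0.003, 500.0, 10.0, np.arange(0, 600, 15))
        assert (np.diff(cur["rfu"]) >= 0).all()

    def test_preconditions(self):
        with pytest.raises(ValueError, match="rate"):
            sd.gen_fluorescence(-1.0, 1.0, 0.0, [0, 1])
        with pytest.raises(ValueError, match="f_max"):
            sd.gen_fluorescence(1.0, -1.0, 0.0, [0, 1])


class TestMeltCurve:
    def test_peaked_argmax_at_tm(self):
        cur = sd.gen_melt_curve(48.0, 4.0)
        assert cur["temperature_C"].iloc[cur["fluorescence"].idxmax()] == 48.0

    def test_monotonic_has_no_interior_maximum(self):
        cur = sd.gen_melt_curve(48.0, 4.0, shape="monotonic")
        assert (np.diff(cur["fluorescence"]) > 0).all()

    def test_same_seed_identical(self):
        a = sd.gen_melt_curve(40.0, 3.0, noise_sd=5.0, seed=9)
        b = sd.gen_melt_curve(40.0, 3.0, noise_sd=5.0, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_args(self):
        with pytest.raises(ValueError, match="width"):
            sd.gen_melt_curve(48.0, 0.0)
        with pytest.raises(ValueError, match="within the grid"):
            sd.gen_melt_curve(150.0, 4.0)


class TestTrajectory:
    FN_A = dd.DomainSelection.builtin("FnCas12a", "REC2")
    FN_B = dd.DomainSelection.builtin("FnCas12a", "Nuc")

    def test_sd_zero_com_distance_constant(self):
        traj = sd.gen_trajectory(6, 25, 70.0, 0.0, seed=3)
        assert np.allclose(dd.com_distance(traj, self.FN_A, self.FN_B),
                           70.0, atol=1e-6)

    def test_planted_contacts_exact_count(self):
        traj = sd.gen_trajectory(4, 25, 70.0, 0.0, n_planted_contacts=5, seed=3)
        counts = dd.contact_count(traj, self.FN_A, self.FN_B)
        assert counts[0] == 5 and (counts[1:] == 0).all()

    def test_distance_distribution_recovered(self):
        traj = sd.gen_trajectory(500, 10, 43.5, 1.5, seed=11)
        d = dd.com_distance(traj, self.FN_A, self.FN_B)
        se = 1.5 / np.sqrt(500)
        assert abs(d.mean() - 43.5) < 2 * se

    def test_too_many_contacts_rejected(self):
        with pytest.raises(ValueError, match="cannot plant"):
            sd.gen_trajectory(2, 3, 80.0, 0.0, n_planted_contacts=4)

    def test_writes_valid_multi_model_pdb(self, tmp_path):
        traj = sd.gen_trajectory(3, 8, 60.0, 1.0, seed=2)
        p = tmp_path / "toy.pdb"
        traj.to_pdb(p)
        text = p.read_text()
        assert text.count("MODEL") == 3 and text.count("ENDMDL") == 3
        assert dd.Trajectory.from_pdb(p).n_frames == 3
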