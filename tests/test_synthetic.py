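"""Generator tests: sampling schemes, noise models, histology fields, studies."""

import numpy as np
import pandas as pd
import pytest

from imerelax.relaxometry import PoolSystem, QMTParams
from imerelax.synthetic import (
    EchoScheme,
    HistologyGenParams,
    generate_histology_image,
    generate_study,
    make_echo_times,
    make_inversion_times,
    simulate_roi_decay,
    simulate_sir_series,
)
from imerelax.histology import CLASS_EDEMA

from oracles import sir_signal_ode


class TestEchoScheme:
    def test_default_scheme_times(self):
        t = make_echo_times(EchoScheme())
        assert t[0] == pytest.approx(7.4)
        assert len(t) == 40
        assert t[31] == pytest.approx(7.4 + 31 * 9.0)  # 286.4 ms
        assert t[39] == pytest.approx(286.4 + 8 * 50.0)  # 686.4 ms
        assert np.all(np.diff(t) > 0)

    def test_single_spacing_when_no_late_echoes(self):
        t = make_echo_times(EchoScheme(n1=10, te1=5.0, esp1=5.0, n2=0))
        np.testing.assert_allclose(np.diff(t), 5.0)
        assert len(t) == 10

    def test_invalid_scheme(self):
        with pytest.raises(ValueError):
            EchoScheme(n1=0)


class TestInversionTimes:
    def test_default_range_and_count(self):
        t = make_inversion_times()
        assert len(t) == 25
        assert t[0] == pytest.approx(0.0035)
        assert t[-1] == pytest.approx(10.0)
        assert np.all(np.diff(t) > 0)

    def test_two_points_are_endpoints(self):
        np.testing.assert_allclose(make_inversion_times(2, 0.0035, 10.0), [0.0035, 10.0])

    def test_log_spacing_ratio_before_rounding(self):
        raw = np.geomspace(0.0035, 10.0, 25)
        np.testing.assert_allclose(raw[1:] / raw[:-1], (10.0 / 0.0035) ** (1.0 / 24.0))
        # rounding to 0.1 ms never moves a time by more than 0.05 ms
        assert np.max(np.abs(make_inversion_times() - raw)) <= 5e-5

    def test_rounding_collision_raises(self):
        with pytest.raises(ValueError, match="reduce n"):
            make_inversion_times(50, 0.0001, 0.001)


class TestDecaySimulator:
    def test_noiseless_is_exact_forward_model(self, echo_times_s, worked_two_pool):
        a = simulate_roi_decay(worked_two_pool, echo_times_s, snr=np.inf, seed=1)
        b = simulate_roi_decay(worked_two_pool, echo_times_s, snr=np.inf, seed=99)
        np.testing.assert_array_equal(a, b)
        expected = 0.5 * np.exp(-echo_times_s / 0.04456294353) + 0.5 * np.exp(
            -echo_times_s / 0.09180069283
        )
        np.testing.assert_allclose(a, expected, rtol=1e-8)

    def test_seed_determinism(self, echo_times_s, worked_two_pool):
        a = simulate_roi_decay(worked_two_pool, echo_times_s, snr=100, seed=5)
        b = simulate_roi_decay(worked_two_pool, echo_times_s, snr=100, seed=5)
        c = simulate_roi_decay(worked_two_pool, echo_times_s, snr=100, seed=6)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_rician_floor_matches_closed_form(self):
        """Late-time magnitude floor of pure noise is sigma*sqrt(pi/2)."""
        mono = PoolSystem(fractions=[1.0], t2=[0.005])
        t = np.array([1.0])  # signal fully decayed: pure Rician noise
        snr = 500.0
        rng = np.random.default_rng(0)
        floors = np.array(
            [simulate_roi_decay(mono, t, snr, rng)[0] for _ in range(10000)]
        )
        expected = (1.0 / snr) * np.sqrt(np.pi / 2.0)
        assert floors.mean() == pytest.approx(expected, rel=0.02)

    def test_noise_sd_scales_inversely_with_snr(self, echo_times_s):
        mono = PoolSystem(fractions=[1.0], t2=[0.08])
        resid_sd = {}
        for snr in (250.0, 500.0):
            sims = np.array(
                [
                    simulate_roi_decay(
                        mono, echo_times_s, snr, seed=i, noise="gaussian"
                    )
                    for i in range(1000)
                ]
            )
            resid_sd[snr] = sims.std(axis=0).mean()
        assert resid_sd[250.0] / resid_sd[500.0] == pytest.approx(2.0, rel=0.1)


class TestSIRSimulator:
    def test_noiseless_mono_ir(self):
        p = QMTParams(m0=1.0, psr=0.0, kmf=0.0, r1=0.8, sf=-1.0)
        t = make_inversion_times()
        s = simulate_sir_series(p, t, snr=np.inf)
        np.testing.assert_allclose(s, 1.0 - 2.0 * np.exp(-0.8 * t), rtol=1e-10)

    def test_pre_delay_matches_ode_oracle(self):
        p = QMTParams(m0=1.0, psr=0.15, kmf=10.0, r1=0.6, sf=-0.95, sm=0.83)
        t = np.array([0.01, 0.5, 10.0])
        finite = simulate_sir_series(p, t, snr=np.inf, pre_delay=3.5)
        infinite = simulate_sir_series(p, t, snr=np.inf)
        oracle = sir_signal_ode(p.m0, p.psr, p.kmf, p.r1, p.sf, p.sm, t, pre_delay=3.5)
        np.testing.assert_allclose(finite, oracle, atol=1e-8)
        # the finite pre-delay starts from a less-recovered state
        assert finite[0] > infinite[0]


class TestHistologyGenerator:
    def test_zero_density_gives_no_edema(self):
        p = HistologyGenParams(grid=(300, 400), fov_um=(22.5, 30.0), lesion_density=0.0)
        img, labelmap, truth = generate_histology_image(p, seed=0)
        assert truth["v_ed"] == 0.0
        assert not np.any(labelmap.labels == CLASS_EDEMA)
        assert img.shape == (300, 400)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_default_preset_density_within_ten_percent(self):
        img, labelmap, truth = generate_histology_image(HistologyGenParams(), seed=3)
        assert truth["lesion_density_per_mm2"] == pytest.approx(1651.0, rel=0.10)

    def test_lesion_diameter_mean_recovered(self):
        """Pooled over seeds, the placed lesion diameters match the request."""
        p = HistologyGenParams()
        means, counts = [], 0
        for seed in range(12):
            _, _, truth = generate_histology_image(p, seed=seed)
            means.append(truth["mean_placed_diameter_um"] * truth["n_lesions_placed"])
            counts += truth["n_lesions_placed"]
        pooled_mean = sum(means) / counts
        assert counts >= 200
        assert pooled_mean == pytest.approx(3.1, rel=0.05)

    def test_label_fractions_sum_to_one(self):
        _, _, truth = generate_histology_image(
            HistologyGenParams(grid=(300, 400), fov_um=(22.5, 30.0)), seed=1
        )
        assert truth["v_my"] + truth["v_ie"] + truth["v_ed"] == pytest.approx(1.0)

    def test_determinism(self):
        p = HistologyGenParams(grid=(200, 200), fov_um=(15.0, 15.0))
        img1, lm1, _ = generate_histology_image(p, seed=9)
        img2, lm2, _ = generate_histology_image(p, seed=9)
        np.testing.assert_array_equal(img1, img2)
        np.testing.assert_array_equal(lm1.labels, lm2.labels)


class TestStudyGenerator:
    def test_truth_tables_reproducible(self, tmp_path):
        cfg = {"n_animals": 1, "n_histology": 0, "n_voxels": 2}
        generate_study(cfg, seed=3, out_dir=tmp_path / "a")
        generate_study(cfg, seed=3, out_dir=tmp_path / "b")
        a = (tmp_path / "a" / "truth_rois.csv").read_bytes()
        b = (tmp_path / "b" / "truth_rois.csv").read_bytes()
        assert a == b

    def test_refuses_to_clobber(self, tmp_path):
        cfg = {"n_animals": 1, "n_histology": 0, "n_voxels": 2}
        generate_study(cfg, seed=3, out_dir=tmp_path / "a")
        with pytest.raises(FileExistsError):
            generate_study(cfg, seed=3, out_dir=tmp_path / "a")

    def test_bundle_contents_and_fraction_sums(self, small_bundle):
        truth = pd.read_csv(small_bundle / "truth_rois.csv")
        assert len(truth) == 3 * 2 * 4  # groups x animals x tracts
        np.testing.assert_allclose(
            truth[["v_my", "v_ie", "v_ed"]].sum(axis=1), 1.0, atol=1e-9
        )
        np.testing.assert_allclose(
            truth[["w_my", "w_ie", "w_ed"]].sum(axis=1), 1.0, atol=1e-9
        )
        # control tracts carry no edema; dosed tracts do
        assert (truth.loc[truth.group == "control", "v_ed"] == 0).all()
        assert (truth.loc[truth.group == "HCP600", "v_ed"] > 0).all()
        for rid in truth["roi_id"]:
            assert (small_bundle / "decays" / f"{rid}_roi.csv").exists()
            assert (small_bundle / "sir" / f"{rid}.csv").exists()
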