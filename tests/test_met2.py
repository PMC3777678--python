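"""MET2 spectral fitting, model selection, clustering and water fractions."""

import numpy as np
import pytest

from imerelax.met2 import (
    ComponentFit,
    GaussianComponent,
    Met2Options,
    WaterFractions,
    assign_t2_classes,
    cluster_t2_classes,
    compute_water_fractions,
    fit_gaussian_components,
    met2_ladder,
    select_n_components,
    voxelwise_uncertainty,
)
from imerelax.relaxometry import PoolSystem
from imerelax.synthetic import simulate_roi_decay

from oracles import best_1d_partition_sse


def _dummy_fit(chi2: float, n_comp: int) -> ComponentFit:
    comps = tuple(
        GaussianComponent(center=-2.0 + 0.5 * i, width=0.02, amplitude=1.0)
        for i in range(n_comp)
    )
    return ComponentFit(
        components=comps, chi2=chi2, n_params=2 * n_comp,
        spectrum=np.zeros(4), grid=np.logspace(-3, 0.5, 4),
    )


class TestGaussianComponentFit:
    def test_mono_exponential_exact_with_narrow_line(self, echo_times_s):
        signal = np.exp(-echo_times_s / 0.05)
        fit = fit_gaussian_components(
            signal, echo_times_s, 1, Met2Options(width=1e-3)
        )
        assert fit.components[0].center == pytest.approx(np.log10(0.05), abs=1e-6)
        assert fit.components[0].amplitude == pytest.approx(1.0, abs=1e-6)
        assert fit.chi2 < 1e-12

    def test_mono_exponential_default_width(self, echo_times_s):
        signal = np.exp(-echo_times_s / 0.05)
        fit = fit_gaussian_components(signal, echo_times_s, 1)
        assert fit.components[0].center == pytest.approx(np.log10(0.05), abs=5e-3)
        assert fit.components[0].amplitude == pytest.approx(1.0, abs=5e-3)

    def test_two_component_noiseless_recovery(self, echo_times_s):
        signal = 0.25 * np.exp(-echo_times_s / 0.015) + 0.75 * np.exp(-echo_times_s / 0.060)
        fit = fit_gaussian_components(signal, echo_times_s, 2)
        np.testing.assert_allclose(fit.amplitudes, [0.25, 0.75], atol=0.01)
        np.testing.assert_allclose(fit.t2s_s, [0.015, 0.060], rtol=0.05)

    def test_chi2_non_increasing_in_component_count(self, echo_times_s):
        rng = np.random.default_rng(2)
        signal = np.exp(-echo_times_s / 0.04) + rng.normal(0, 2e-3, echo_times_s.size)
        signal = np.abs(signal)
        fits, _ = met2_ladder(signal, echo_times_s)
        assert fits[1].chi2 >= fits[2].chi2 >= fits[3].chi2

    def test_spectrum_nonnegative_and_centers_ordered(self, echo_times_s):
        signal = 0.3 * np.exp(-echo_times_s / 0.02) + 0.7 * np.exp(-echo_times_s / 0.1)
        fit = fit_gaussian_components(signal, echo_times_s, 3)
        assert np.all(fit.spectrum >= 0)
        centers = [c.center for c in fit.components]
        assert centers == sorted(centers)
        assert np.all(np.diff(centers) > 0)

    def test_invalid_inputs(self, echo_times_s):
        with pytest.raises(ValueError):
            fit_gaussian_components(np.ones(3), echo_times_s[:3], 2)
        with pytest.raises(Exception):
            fit_gaussian_components(np.zeros_like(echo_times_s), echo_times_s, 1)


class TestModelSelection:
    def test_no_improvement_keeps_one_component(self):
        fits = {1: _dummy_fit(1.0, 1), 2: _dummy_fit(1.0, 2), 3: _dummy_fit(1.0, 3)}
        assert select_n_components(fits, 40) == 1

    def test_perfect_fit_branch_adopts_larger_model(self):
        fits = {1: _dummy_fit(1.0, 1), 2: _dummy_fit(0.0, 2)}
        assert select_n_components(fits, 40) == 2

    def test_huge_improvement_adopts_larger_model(self):
        fits = {1: _dummy_fit(100.0, 1), 2: _dummy_fit(1.0, 2), 3: _dummy_fit(0.99, 3)}
        assert select_n_components(fits, 40) == 2

    def test_noiseless_nested_signal_never_overselects(self, echo_times_s):
        signal = 0.3 * np.exp(-echo_times_s / 0.015) + 0.7 * np.exp(-echo_times_s / 0.06)
        fits, n = met2_ladder(signal, echo_times_s)
        assert n <= 2 or fits[2].chi2 == 0.0

    def test_three_pool_power_at_high_snr(self, echo_times_s):
        """Edema-bearing 3-pool decays at ROI SNR select 3 components."""
        system = PoolSystem(fractions=[0.13, 0.64, 0.23], t2=[0.015, 0.05, 0.3])
        hits = 0
        for seed in range(25):
            y = simulate_roi_decay(system, echo_times_s, 1000.0, seed, noise="gaussian")
            _, n = met2_ladder(y, echo_times_s, early_stop=True)
            hits += n == 3
        assert hits >= 23


class TestClustering:
    def test_well_separated_clusters(self):
        t2 = np.array([0.015, 0.018, 0.045, 0.050, 0.150, 0.160])
        labels, centers = cluster_t2_classes(t2, 3)
        assert list(labels) == ["short", "short", "intermediate", "intermediate", "long", "long"]
        assert centers["short"] < centers["intermediate"] < centers["long"]

    def test_permutation_invariance(self):
        t2 = np.array([0.15, 0.018, 0.05, 0.015, 0.16, 0.045])
        labels, _ = cluster_t2_classes(t2, 3)
        perm = np.array([3, 1, 5, 2, 0, 4])
        labels_perm, _ = cluster_t2_classes(t2[perm], 3)
        assert list(labels_perm) == list(labels[perm])

    def test_matches_exhaustive_partition_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            t2 = 10 ** rng.uniform(-2.0, -0.5, 10)
            labels, _ = cluster_t2_classes(t2, 3)
            x = np.log10(t2)
            sse = sum(
                float(((x[labels == name] - x[labels == name].mean()) ** 2).sum())
                for name in ("short", "intermediate", "long")
            )
            assert sse == pytest.approx(best_1d_partition_sse(x, 3), abs=1e-10)

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            cluster_t2_classes(np.array([0.05, 0.05]), 3)


class TestWaterFractions:
    def test_normalization(self):
        fit = ComponentFit(
            components=(
                GaussianComponent(-1.8, 0.02, 0.25),
                GaussianComponent(-1.3, 0.02, 0.60),
                GaussianComponent(-0.8, 0.02, 0.15),
            ),
            chi2=0.0, n_params=6, spectrum=np.zeros(4), grid=np.logspace(-3, 0.5, 4),
        )
        wf = compute_water_fractions(fit, np.array(["short", "intermediate", "long"]))
        assert wf.mwf == pytest.approx(0.25)
        assert wf.ewf == pytest.approx(0.15)
        assert wf.intermediate == pytest.approx(0.60)

    def test_absent_long_class_gives_zero_ewf(self):
        fit = ComponentFit(
            components=(
                GaussianComponent(-1.8, 0.02, 0.2),
                GaussianComponent(-1.3, 0.02, 0.8),
            ),
            chi2=0.0, n_params=4, spectrum=np.zeros(4), grid=np.logspace(-3, 0.5, 4),
        )
        wf = compute_water_fractions(fit, np.array(["short", "intermediate"]))
        assert wf.ewf == 0.0
        assert wf.mwf + wf.intermediate + wf.ewf == pytest.approx(1.0)

    def test_exchange_coupled_worked_system_doubles_ewf(
        self, worked_two_pool, echo_times_s
    ):
        """Fitting the two-pool exchange decay recovers EWF ~ 0.5, twice the
        25% long-pool volume fraction."""
        y = simulate_roi_decay(worked_two_pool, echo_times_s, snr=np.inf)
        fit = fit_gaussian_components(y, echo_times_s, 2)
        labels = assign_t2_classes(fit.t2s_s, {"intermediate": 0.045, "long": 0.092})
        wf = compute_water_fractions(fit, labels)
        assert wf.ewf == pytest.approx(0.50, abs=0.02)

    def test_fraction_invariants_enforced(self):
        with pytest.raises(ValueError):
            WaterFractions(mwf=0.5, intermediate=0.2, ewf=0.2, total=1.0)


class TestVoxelwiseUncertainty:
    def test_identical_voxels_have_zero_se(self, echo_times_s):
        y = 0.3 * np.exp(-echo_times_s / 0.02) + 0.7 * np.exp(-echo_times_s / 0.06)
        vox = np.tile(y, (4, 1))
        out = voxelwise_uncertainty(
            vox, echo_times_s, 2, {"short": 0.02, "intermediate": 0.06}
        )
        assert out["se_mwf"] == pytest.approx(0.0, abs=1e-12)
        assert out["se_ewf"] == 0.0

    def test_hand_computed_se_for_two_voxels(self):
        """SE of two voxel EWFs 0.4 and 0.6 is SD/sqrt(2) = 0.1."""
        values = np.array([0.4, 0.6])
        se = np.std(values, ddof=1) / np.sqrt(2)
        assert se == pytest.approx(0.1, abs=1e-12)

    def test_se_shrinks_with_voxel_count(self, echo_times_s):
        system = PoolSystem(fractions=[0.25, 0.75], t2=[0.02, 0.08])
        def se_for(n):
            vox = np.stack([
                simulate_roi_decay(system, echo_times_s, 150.0, seed=i, noise="gaussian")
                for i in range(n)
            ])
            out = voxelwise_uncertainty(
                vox, echo_times_s, 2, {"short": 0.02, "long": 0.08},
                Met2Options(), warm_starts=[np.log10([0.02, 0.08])],
            )
            return out["se_ewf"]
        assert se_for(32) < se_for(8)

    def test_rejects_single_voxel(self, echo_times_s):
        with pytest.raises(ValueError):
            voxelwise_uncertainty(
                np.ones((1, echo_times_s.size)), echo_times_s, 1, {"short": 0.05}
            )
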