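import numpy as np
import pytest
from hypothesis import given, strategies as st

from dermalight.msp import (
    ChromatophoreMSP,
    MSPScan,
    average_by_type,
    default_grid,
    sws1_attenuation,
    transition_wavelength,
    transmittance,
)
from dermalight.simulate import default_pigment_models
from dermalight.spectra import Spectrum, uniform_grid
from dermalight.templates import a1_template

from _oracles import logistic_T, logistic_tangent_intercept


def _scan(sample_vals, reference_vals, grid=None, ctype="melanophore", cell="c1"):
    grid = uniform_grid(400, 700, 1.0) if grid is None else grid
    return MSPScan(
        sample=Spectrum(grid, np.broadcast_to(sample_vals, grid.shape).copy()),
        reference=Spectrum(grid, np.broadcast_to(reference_vals, grid.shape).copy()),
        cell_id=cell,
        fish_id="f1",
        chromatophore_type=ctype,
    )


class TestTransmittance:
    def test_identical_scans_give_100_percent(self):
        T = transmittance(_scan(5000.0, 5000.0))
        np.testing.assert_allclose(T.values, 100.0)

    def test_half_counts_give_50_percent(self):
        T = transmittance(_scan(2500.0, 5000.0))
        np.testing.assert_allclose(T.values, 50.0)

    @given(st.floats(1e-3, 1e3))
    def test_scale_invariant_in_overall_intensity(self, scale):
        grid = uniform_grid(400, 700, 5.0)
        rng = np.random.default_rng(7)
        ref = rng.uniform(1000, 2000, grid.shape)
        samp = ref * rng.uniform(0.1, 0.9, grid.shape)
        base = transmittance(_scan(samp, ref, grid))
        scaled = transmittance(_scan(samp * scale, ref * scale, grid))
        np.testing.assert_allclose(scaled.values, base.values, rtol=1e-9)

    def test_nonpositive_reference_is_an_error_naming_wavelength(self):
        grid = uniform_grid(400, 700, 1.0)
        ref = np.full(grid.shape, 1000.0)
        ref[50] = 0.0  # 450 nm
        with pytest.raises(ValueError, match="450"):
            transmittance(_scan(500.0, ref, grid), grid)

    def test_noiseless_melanophore_is_monotone_increasing(self, grid):
        model = default_pigment_models()["melanophore"]
        T = model.spectrum(grid)
        assert np.all(np.diff(T.values) >= 0)
        assert T.values[0] < T.values[-1]


class TestAverageByType:
    def test_single_scan_mean_is_the_scan_and_sem_zero(self):
        scan = _scan(3000.0, 6000.0)
        summary = average_by_type([scan])
        np.testing.assert_allclose(summary.mean_T.values, 50.0)
        np.testing.assert_allclose(summary.sem_T.values, 0.0)
        assert summary.n_cells == 1

    def test_two_flat_scans_mean_and_sem(self):
        # 40% and 60% flat: mean 50%, sem = sd/sqrt(2) = 10%
        scans = [_scan(4000.0, 10000.0, cell="a"), _scan(6000.0, 10000.0, cell="b")]
        summary = average_by_type(scans)
        np.testing.assert_allclose(summary.mean_T.values, 50.0, rtol=1e-12)
        np.testing.assert_allclose(summary.sem_T.values, 10.0, rtol=1e-12)
        assert summary.n_cells == 2

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError, match="no scans"):
            average_by_type([], chromatophore_type="erythrophore")

    def test_mixed_types_require_a_selector(self):
        scans = [_scan(1.0, 2.0, ctype="melanophore"),
                 _scan(1.0, 2.0, ctype="xanthophore")]
        with pytest.raises(ValueError, match="type"):
            average_by_type(scans)


class TestTransitionWavelength:
    @pytest.mark.parametrize("m,s", [(560.0, 10.0), (520.0, 5.0), (600.0, 15.0)])
    def test_logistic_closed_form_oracle(self, m, s):
        # tangent at the steepest point crosses zero at m - 2s exactly
        wl = uniform_grid(400, 700, 0.3)
        spec = Spectrum(wl, logistic_T(wl, m, s), "transmittance_percent")
        est = transition_wavelength(spec)
        assert est == pytest.approx(logistic_tangent_intercept(m, s), abs=0.5)

    def test_logistic_with_floor_matches_generalized_intercept(self):
        wl = uniform_grid(400, 700, 0.3)
        spec = Spectrum(wl, logistic_T(wl, 560.0, 8.0, T_hi=90.0, T_lo=15.0),
                        "transmittance_percent")
        expected = logistic_tangent_intercept(560.0, 8.0, 90.0, 15.0)
        assert transition_wavelength(spec) == pytest.approx(expected, abs=0.5)

    def test_shallow_slope_returns_absent(self):
        wl = uniform_grid(400, 700, 0.3)
        spec = Spectrum(wl, 8.0 + 0.0667 * (wl - 400.0), "transmittance_percent")
        assert transition_wavelength(spec) is None

    def test_non_uniform_grid_rejected(self):
        wl = np.sort(np.random.default_rng(0).uniform(400, 700, 200))
        spec = Spectrum(wl, np.linspace(0, 99, 200), "transmittance_percent")
        with pytest.raises(ValueError, match="uniform"):
            transition_wavelength(spec)

    def test_noiseless_default_transitions(self, noiseless_results):
        # sharp steps near 550 nm (erythrophore) and 488 nm (xanthophore);
        # melanophores rise too slowly to show a transition
        assert noiseless_results["erythrophore"].transition_nm == pytest.approx(550.0, abs=1.0)
        assert noiseless_results["xanthophore"].transition_nm == pytest.approx(488.0, abs=1.0)
        assert noiseless_results["melanophore"].transition_nm is None


class TestAttenuation:
    def test_fully_transparent_cell_attenuates_nothing(self, grid):
        T = Spectrum(grid, np.full(grid.shape, 100.0), "transmittance_percent")
        assert sws1_attenuation(T, a1_template(415.0, grid)) == pytest.approx(0.0, abs=1e-12)

    def test_opaque_cell_attenuates_everything(self, grid):
        T = Spectrum(grid, np.zeros(grid.shape), "transmittance_percent")
        assert sws1_attenuation(T, a1_template(415.0, grid)) == pytest.approx(1.0, abs=1e-12)

    def test_zero_template_is_an_error(self, grid):
        T = Spectrum(grid, np.full(grid.shape, 50.0), "transmittance_percent")
        dead = Spectrum(grid, np.zeros(grid.shape), "sensitivity")
        with pytest.raises(ValueError, match="zero"):
            sws1_attenuation(T, dead)

    def test_default_attenuation_ordering(self, noiseless_results):
        mel = noiseless_results["melanophore"].attenuation_fraction
        ery = noiseless_results["erythrophore"].attenuation_fraction
        xan = noiseless_results["xanthophore"].attenuation_fraction
        assert mel > ery > xan


class TestModelResults:
    def test_summary_table_lists_all_types(self, noiseless_results):
        text = noiseless_results.summary()
        for ctype in ("melanophore", "erythrophore", "xanthophore"):
            assert ctype in text
        assert "absent" in text  # the melanophore row

    def test_results_save_writes_tables_and_spectra(self, noiseless_results, tmp_path):
        noiseless_results.save(tmp_path)
        assert (tmp_path / "type_summary.tsv").exists()
        assert (tmp_path / "erythrophore_mean_T.tsv").exists()
        assert (tmp_path / "melanophore_sem_T.tsv").exists()

    def test_empty_scan_list_rejected(self):
        with pytest.raises(ValueError, match="no scans"):
            ChromatophoreMSP([])


def test_noisy_transition_spread_is_small(noisy_transition_samples):
    # at the study's replication (n = 60 cells) and default noise, repeated
    # experiments agree on the transition to well within 5 nm
    for ctype, samples in noisy_transition_samples.items():
        assert np.all(np.isfinite(samples))
        assert samples.max() - samples.min() < 5.0
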