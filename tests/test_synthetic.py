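"""Generator behaviour: band shapes, bilinearity, noise determinism,
monolayer competition and the batch-level enhancement effect."""

import numpy as np
import pytest

from sersquant import (
    NoiseModel,
    PeakDefinition,
    apply_batch_effect,
    apply_monolayer_competition,
    build_pure_spectrum,
    default_axis,
    default_thiol_library,
    dilution_design,
    lhs_design,
    simulate_dilution_series,
    simulate_mixture_set,
)
from sersquant.design import MixtureDesign, THIOLS
import pandas as pd


class TestBuildPureSpectrum:
    @pytest.mark.parametrize("shape", ["gaussian", "lorentzian"])
    def test_apex_equals_amplitude_at_nearest_channel(self, axis, shape):
        amp = 7.5
        spec = build_pure_spectrum([PeakDefinition(596.0, 12.0, amp, shape)], axis)
        k = np.argmin(np.abs(axis - 596.0))
        assert spec.intensities.max() == pytest.approx(amp)
        assert np.argmax(spec.intensities) == k

    def test_empty_peak_list_gives_zero_spectrum(self, axis):
        assert not build_pure_spectrum([], axis).intensities.any()

    def test_two_identical_peaks_double_the_spectrum(self, axis):
        pk = PeakDefinition(700.0, 10.0, 2.0)
        one = build_pure_spectrum([pk], axis).intensities
        two = build_pure_spectrum([pk, pk], axis).intensities
        np.testing.assert_allclose(two, 2 * one, rtol=1e-12)

    def test_off_axis_center_rejected_naming_peak(self, axis):
        with pytest.raises(ValueError, match="2500"):
            build_pure_spectrum([PeakDefinition(2500.0, 10.0, 1.0)], axis)

    def test_invalid_fwhm_and_shape_rejected(self):
        with pytest.raises(ValueError, match="fwhm"):
            PeakDefinition(600.0, 0.0, 1.0)
        with pytest.raises(ValueError, match="shape"):
            PeakDefinition(600.0, 5.0, 1.0, "voigt")


class TestSimulateMixtureSet:
    def test_zero_noise_matrix_has_rank_four(self, library, zero_noise):
        design = lhs_design(8, THIOLS, (0.05, 1.0), seed=3)
        sset = simulate_mixture_set(library, design, zero_noise, replicates=1)
        assert np.linalg.matrix_rank(sset.intensities, tol=1e-8) == 4

    def test_zero_everything_gives_zero_spectra(self, library, zero_noise):
        design = MixtureDesign(
            pd.DataFrame(np.zeros((3, 4)), columns=list(THIOLS)), "explicit"
        )
        sset = simulate_mixture_set(library, design, zero_noise, replicates=2)
        assert not sset.intensities.any()

    def test_unit_concentration_recovers_pure_spectrum(self, library, zero_noise):
        design = MixtureDesign(
            pd.DataFrame([[1.0, 0, 0, 0]], columns=list(THIOLS)), "explicit"
        )
        sset = simulate_mixture_set(library, design, zero_noise, replicates=1)
        np.testing.assert_allclose(
            sset.intensities[0], library.pure_spectrum("3M3MH").intensities,
            rtol=1e-12,
        )

    def test_bilinearity_of_concentration_response(self, library, zero_noise):
        rng = np.random.default_rng(0)
        c1, c2 = rng.uniform(0, 1, 4), rng.uniform(0, 1, 4)

        def spectrum(c):
            d = MixtureDesign(pd.DataFrame([c], columns=list(THIOLS)), "explicit")
            return simulate_mixture_set(library, d, zero_noise, replicates=1).intensities[0]

        np.testing.assert_allclose(
            spectrum(c1 + c2), spectrum(c1) + spectrum(c2), rtol=1e-10, atol=1e-12
        )

    def test_identical_seed_reproduces_bit_for_bit(self, library):
        design = lhs_design(5, THIOLS, (0.05, 1.0), seed=1)
        noise = NoiseModel(seed=99)
        a = simulate_mixture_set(library, design, noise, replicates=2)
        b = simulate_mixture_set(library, design, noise, replicates=2)
        assert np.array_equal(a.intensities, b.intensities)

    def test_unknown_design_analyte_rejected_with_names(self, library, zero_noise):
        design = MixtureDesign(pd.DataFrame({"XX": [1.0]}), "explicit")
        with pytest.raises(ValueError, match="XX"):
            simulate_mixture_set(library, design, zero_noise)

    def test_replicate_structure(self, library, zero_noise):
        design = lhs_design(4, THIOLS, (0.05, 1.0), seed=0)
        sset = simulate_mixture_set(library, design, zero_noise, replicates=3)
        assert sset.n_samples == 12
        assert list(sset.metadata["replicate"][:3]) == [1, 2, 3]
        # concentrations replicated per replicate
        assert (sset.concentrations.iloc[0] == sset.concentrations.iloc[2]).all()


class TestDilutionSeries:
    def test_blank_zero_and_unit_equals_pure(self, library, zero_noise):
        sset = simulate_dilution_series(
            library, "3MH", [1.0], zero_noise, replicates=1, include_blank=True
        )
        assert not sset.intensities[0].any()
        np.testing.assert_allclose(
            sset.intensities[1], library.pure_spectrum("3MH").intensities, rtol=1e-12
        )

    def test_dominant_channel_height_linear_in_concentration(self, library, zero_noise):
        concs = [0.1, 0.3, 0.5, 1.0, 2.0]
        sset = simulate_dilution_series(
            library, "2M3MB", concs, zero_noise, replicates=1, include_blank=False
        )
        band = library.dominant_band("2M3MB")
        k = np.argmin(np.abs(sset.axis - band.center))
        heights = sset.intensities[:, k]
        slope = np.polyfit(np.array(concs), heights, 1)[0]
        # the 639 cm^-1 centre falls between 2 cm^-1 channels; the apex
        # channel carries the band profile evaluated 1 cm^-1 off-centre
        pure_at_k = library.pure_spectrum("2M3MB").intensities[k]
        assert slope == pytest.approx(pure_at_k, rel=1e-6)
        assert slope == pytest.approx(band.amplitude, rel=0.05)

    def test_unknown_analyte_rejected(self, library, zero_noise):
        with pytest.raises(KeyError, match="nope"):
            simulate_dilution_series(library, "nope", [1.0], zero_noise)


class TestMonolayerCompetition:
    def test_below_capacity_is_identity(self):
        c = np.array([4.0, 6.0])
        np.testing.assert_array_equal(
            apply_monolayer_competition(c, capacity=20.0), c
        )

    def test_symmetric_overload_splits_capacity(self):
        out = apply_monolayer_competition(np.array([30.0, 30.0]), capacity=20.0)
        np.testing.assert_allclose(out, [10.0, 10.0])

    def test_affinity_weighted_reallocation(self):
        out = apply_monolayer_competition(
            np.array([30.0, 10.0]), affinities=np.array([3.0, 1.0]), capacity=20.0
        )
        np.testing.assert_allclose(out, [18.0, 2.0])

    def test_capacity_conserved_with_equality_iff_overloaded(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            c = rng.uniform(0, 15, 4)
            out = apply_monolayer_competition(c, capacity=20.0)
            assert out.sum() <= 20.0 + 1e-9
            if c.sum() >= 20.0:
                assert out.sum() == pytest.approx(20.0)
            else:
                np.testing.assert_array_equal(out, c)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            apply_monolayer_competition(np.array([-1.0, 2.0]))


class TestBatchEffect:
    def _set(self, library):
        design = lhs_design(4, THIOLS, (0.05, 1.0), seed=2)
        return simulate_mixture_set(library, design, NoiseModel(seed=5), replicates=2)

    def test_zero_gain_is_identity(self, library):
        sset = self._set(library)
        out = apply_batch_effect(sset, 0.0, seed=1)
        np.testing.assert_array_equal(out.intensities, sset.intensities)

    def test_single_batch_shares_one_signal_factor(self, library):
        sset = self._set(library)
        out = apply_batch_effect(sset, 0.05, seed=1)
        delta = out.intensities - sset.intensities
        factors = 1.0 + delta / np.where(sset.clean_signal == 0, np.nan, sset.clean_signal)
        vals = factors[np.isfinite(factors)]
        assert vals.std() < 1e-9
        assert abs(abs(vals.mean() - 1.0) - 0.05) < 1e-9

    def test_concentrations_unchanged(self, library):
        sset = self._set(library)
        out = apply_batch_effect(sset, 0.1, seed=3)
        assert out.concentrations.equals(sset.concentrations)
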