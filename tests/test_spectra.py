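"""Spectral table orderings, mixture linearity, and linear unmixing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidmsot import (
    ChromophoreMixture,
    absorption_at,
    load_spectral_table,
    mixture_mu_a,
    unmix_linear,
)
from lipidmsot.spectra import ChromophoreError, GridError, mixture_spectrum

TABLE = load_spectral_table()


class TestSpectralOrderings:
    """The qualitative NIR contrast the tissue identification relies on."""

    def test_lipid_peaks_at_930(self):
        lipid_930 = absorption_at(TABLE, "lipid", 930)
        assert lipid_930 > absorption_at(TABLE, "lipid", 750)
        assert lipid_930 > absorption_at(TABLE, "lipid", 850)

    def test_hb_dominates_750_hbo2_dominates_850(self):
        assert absorption_at(TABLE, "Hb", 750) > absorption_at(TABLE, "HbO2", 750)
        assert absorption_at(TABLE, "HbO2", 850) > absorption_at(TABLE, "Hb", 850)

    def test_grid_and_positivity(self):
        assert np.array_equal(TABLE.wavelengths, np.arange(700, 971, 10))
        for name in ("Hb", "HbO2", "lipid", "water"):
            assert np.all(TABLE.spectrum(name) > 0)
            assert TABLE.spectrum(name).size == 28


class TestAbsorptionAt:
    def test_off_grid_error_names_nearest_points(self):
        with pytest.raises(GridError, match="930.*940"):
            absorption_at(TABLE, "lipid", 935)

    def test_unknown_chromophore(self):
        with pytest.raises(ChromophoreError, match="melanin"):
            absorption_at(TABLE, "melanin", 930)


class TestMixtureMuA:
    def test_zero_mixture_and_identity(self):
        assert mixture_mu_a(ChromophoreMixture({}), TABLE, 930) == 0.0
        assert mixture_mu_a(ChromophoreMixture({"lipid": 1.0}), TABLE, 930) == (
            absorption_at(TABLE, "lipid", 930)
        )

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ChromophoreMixture({"Hb": -0.1})

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        c=st.dictionaries(
            st.sampled_from(["Hb", "HbO2", "lipid", "water"]),
            st.floats(0, 10, allow_nan=False),
            min_size=1,
        ),
        a=st.floats(0, 5, allow_nan=False),
        wl=st.sampled_from([700, 750, 850, 930, 970]),
    )
    def test_exact_linearity(self, c, a, wl):
        mix = ChromophoreMixture(c)
        scaled = mix.scaled(a)
        assert mixture_mu_a(scaled, TABLE, wl) == pytest.approx(
            a * mixture_mu_a(mix, TABLE, wl), rel=1e-12, abs=1e-12
        )


def brute_force_two_weight_unmix(spectrum, names, resolution=1e-3):
    """Exhaustive grid-search oracle over 2-chromophore weights in [0, 1]."""
    grid = np.arange(0.0, 1.0 + resolution / 2, resolution)
    basis = np.column_stack([TABLE.spectrum(n) for n in names])
    best, best_res = None, np.inf
    for w0 in grid:
        residuals = spectrum[:, None] - np.outer(basis[:, 0], np.full_like(grid, w0)) \
            - np.outer(basis[:, 1], grid)
        norms = np.linalg.norm(residuals, axis=0)
        i = int(np.argmin(norms))
        if norms[i] < best_res:
            best_res, best = norms[i], (w0, grid[i])
    return best, best_res


class TestUnmixLinear:
    def test_exact_basis_member(self):
        weights, residual = unmix_linear(TABLE.spectrum("lipid"), TABLE)
        assert weights["lipid"] == pytest.approx(1.0, abs=1e-9)
        assert residual == pytest.approx(0.0, abs=1e-9)
        for other in ("Hb", "HbO2", "water"):
            assert weights[other] == pytest.approx(0.0, abs=1e-9)

    def test_noise_free_hb_hbo2_mixture_matches_grid_search_oracle(self):
        true = {"Hb": 0.3, "HbO2": 0.7}
        spectrum = mixture_spectrum(ChromophoreMixture(true), TABLE)
        weights, residual = unmix_linear(spectrum, TABLE, ["Hb", "HbO2"])
        assert weights["Hb"] == pytest.approx(0.3, abs=1e-6)
        assert weights["HbO2"] == pytest.approx(0.7, abs=1e-6)
        assert residual == pytest.approx(0.0, abs=1e-8)
        (w_hb, w_hbo2), _ = brute_force_two_weight_unmix(spectrum, ["Hb", "HbO2"])
        assert abs(w_hb - weights["Hb"]) <= 1e-3
        assert abs(w_hbo2 - weights["HbO2"]) <= 1e-3

    def test_zero_spectrum_gives_zero_weights(self):
        weights, residual = unmix_linear(np.zeros(28), TABLE)
        assert all(w == 0.0 for w in weights.values())
        assert residual == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="entries"):
            unmix_linear(np.ones(10), TABLE)
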