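"""Forward model: Hill pigment switches, subtractive rendering, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zincolor import (
    CircuitParams,
    DomainError,
    GeometryError,
    OpticalModel,
    PigmentState,
    pigment_response,
    render_pellet_image,
    rgb_from_pigments,
    simulate_assay_images,
)


class TestPigmentResponse:
    def test_zero_zinc_limits(self, params):
        p = pigment_response(0.0, params)
        assert p.violacein == pytest.approx(params.v_max)
        assert p.beta_carotene == 0.0
        assert p.lycopene == pytest.approx(params.c_tot)

    def test_uninduced_cells_are_colorless(self):
        off = CircuitParams(induced=False)
        for zinc in (0.0, 1.0, 10.0):
            p = pigment_response(zinc, off)
            assert (p.violacein, p.lycopene, p.beta_carotene) == (0.0, 0.0, 0.0)

    def test_hill_half_points(self, params):
        p = pigment_response(params.k_vio, params)
        assert p.violacein == pytest.approx(params.v_max / 2)
        q = pigment_response(params.k_crty, params)
        assert q.beta_carotene == pytest.approx(params.c_tot / 2)
        assert q.lycopene == pytest.approx(params.c_tot / 2)

    def test_closed_form_at_1p5_uM(self):
        # v_max * k^n / (k^n + z^n) with z = k = 1.5, n = 4 → v_max / 2 = 0.25
        p = pigment_response(1.5, CircuitParams(v_max=0.5, k_vio=1.5, n_vio=4))
        assert p.violacein == pytest.approx(0.25)

    def test_negative_zinc_rejected(self, params):
        with pytest.raises(DomainError):
            pigment_response(-0.1, params)

    @settings(derandomize=True, max_examples=100)
    @given(zinc=st.floats(min_value=0.0, max_value=50.0))
    def test_carotenoid_conservation(self, zinc):
        p = pigment_response(zinc)
        assert p.lycopene + p.beta_carotene == pytest.approx(1.0, abs=1e-12)

    def test_violacein_decreasing_beta_increasing(self, params):
        zs = np.linspace(0.01, 20, 200)
        states = [pigment_response(z, params) for z in zs]
        vio = np.array([s.violacein for s in states])
        beta = np.array([s.beta_carotene for s in states])
        assert (np.diff(vio) < 0).all()
        assert (np.diff(beta) > 0).all()


class TestRgbFromPigments:
    def test_no_pigment_gives_background(self, noiseless_optics):
        rgb = rgb_from_pigments(PigmentState(0, 0, 0), noiseless_optics)
        assert rgb == tuple(int(round(c)) for c in noiseless_optics.background_rgb)

    @settings(derandomize=True, max_examples=50)
    @given(
        vio=st.floats(min_value=0, max_value=2),
        lyc=st.floats(min_value=0, max_value=2),
        beta=st.floats(min_value=0, max_value=2),
    )
    def test_more_pigment_never_brightens(self, vio, lyc, beta):
        base = rgb_from_pigments(PigmentState(vio, lyc, beta))
        doubled = rgb_from_pigments(PigmentState(2 * vio, lyc, beta))
        assert all(d <= b for d, b in zip(doubled, base))

    def test_channelwise_scalar_oracle(self, noiseless_optics):
        pigments = PigmentState(0.3, 0.7, 0.2)
        levels = [0.3, 0.7, 0.2]
        expected = []
        for c in range(3):
            absorbance = sum(
                noiseless_optics.absorptivity[p][c] * levels[p] for p in range(3)
            )
            val = noiseless_optics.background_rgb[c] * np.exp(-absorbance)
            expected.append(int(np.clip(round(val), 0, 255)))
        assert rgb_from_pigments(pigments, noiseless_optics) == tuple(expected)

    def test_negative_pigments_rejected(self):
        with pytest.raises(DomainError):
            PigmentState(-0.1, 0.0, 0.0)


class TestRenderPelletImage:
    def test_noiseless_pellet_is_exact(self, noiseless_optics):
        img = render_pellet_image(
            (120, 30, 200), width=64, height=64, pellet_center=(32, 32),
            pellet_radius=10, optics=noiseless_optics, seed=0,
        )
        rows, cols = np.ogrid[:64, :64]
        mask = (rows - 32) ** 2 + (cols - 32) ** 2 <= 100
        assert (img[mask] == (120, 30, 200)).all()
        bg = tuple(int(round(c)) for c in noiseless_optics.background_rgb)
        assert (img[~mask] == bg).all()

    def test_same_seed_is_bit_identical(self, noisy_optics):
        kwargs = dict(width=64, height=64, pellet_center=(32, 32),
                      pellet_radius=10, optics=noisy_optics)
        a = render_pellet_image((120, 30, 200), seed=42, **kwargs)
        b = render_pellet_image((120, 30, 200), seed=42, **kwargs)
        assert (a == b).all()
        c = render_pellet_image((120, 30, 200), seed=43, **kwargs)
        assert (a != c).any()

    def test_noisy_window_mean_near_truth(self):
        # CLT: the 20x20 window mean should sit within ~3 sigma/sqrt(400)
        optics = OpticalModel(noise_sigma=3.0)
        rgb = (150.0, 60.0, 90.0)
        img = render_pellet_image(
            rgb, width=80, height=80, pellet_center=(40, 40),
            pellet_radius=20, optics=optics, seed=5,
        )
        window = img[30:50, 30:50].astype(float)
        bound = 3 * 3.0 / np.sqrt(400) + 0.5  # CLT band plus quantization
        for c in range(3):
            assert abs(window[:, :, c].mean() - rgb[c]) < bound

    def test_disc_outside_bounds_rejected(self, noiseless_optics):
        with pytest.raises(GeometryError):
            render_pellet_image(
                (0, 0, 0), width=32, height=32, pellet_center=(2, 16),
                pellet_radius=8, optics=noiseless_optics, seed=0,
            )


class TestSimulateAssayImages:
    def test_default_scenario_layout(self, noiseless_assay):
        image, table = noiseless_assay
        assert len(table) == 6
        assert (table["role"] == "standard").sum() == 5
        assert (table["role"] == "test").sum() == 1
        assert image.dtype == np.uint8 and image.ndim == 3

    def test_test_matching_standard_shares_color(self, noiseless_optics):
        _, table = simulate_assay_images(
            standards_zinc=[0, 1, 2, 3.5, 5], test_zinc=2.0,
            optics=noiseless_optics, seed=0,
        )
        std = table[(table.role == "standard") & (table.zinc_uM == 2.0)].iloc[0]
        test = table[table.role == "test"].iloc[0]
        assert (std[["r", "g", "b"]] == test[["r", "g", "b"]]).all()

    def test_ground_truth_matches_composed_forward_model(self, noiseless_assay, params, noiseless_optics):
        _, table = noiseless_assay
        for _, row in table.iterrows():
            expected = rgb_from_pigments(
                pigment_response(row.zinc_uM, params), noiseless_optics
            )
            assert (row.r, row.g, row.b) == expected

    def test_overlapping_discs_rejected(self):
        with pytest.raises(GeometryError):
            simulate_assay_images(spacing=20, pellet_radius=16)

    def test_fewer_than_two_standards_rejected(self):
        with pytest.raises(DomainError):
            simulate_assay_images(standards_zinc=[1.0])
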