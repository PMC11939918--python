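"""Film-physics unit tests: Sauerbrey relations, decay length, Voigt limit."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qcmdslb import (
    InvalidParameterError,
    PhysicalConstants,
    ViscoelasticFilm,
    WATER_25C,
    bilayer_thickness_corrected,
    decay_length,
    dissipation_from_moduli,
    rigid_film_response,
    sauerbrey_mass,
    sauerbrey_thickness,
    viscoelastic_film_response,
)


class TestSauerbrey:
    @pytest.mark.parametrize(
        "df,expected",
        [(-30.0, 534.0), (0.0, 0.0), (-113.0, 2011.4)],
    )
    def test_mass(self, df, expected):
        assert sauerbrey_mass(df) == pytest.approx(expected, abs=1e-9)

    def test_positive_shift_signals_mass_loss(self):
        assert sauerbrey_mass(10.0) == pytest.approx(-178.0)

    @given(df=st.floats(-500, 500), a=st.floats(-10, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mass_is_linear(self, df, a):
        assert sauerbrey_mass(a * df) == pytest.approx(a * sauerbrey_mass(df), rel=1e-12, abs=1e-9)

    @pytest.mark.parametrize(
        "df,rho,expected",
        [(-113.0, 1.0, 20.114), (0.0, 1.0, 0.0), (-25.1, 1.0, 4.4678)],
    )
    def test_thickness(self, df, rho, expected):
        assert sauerbrey_thickness(df, rho) == pytest.approx(expected, abs=1e-3)

    def test_thickness_rejects_bad_density(self):
        with pytest.raises(InvalidParameterError):
            sauerbrey_thickness(-10.0, rho=0.0)

    @pytest.mark.parametrize(
        "df,expected,clipped",
        [
            (-30.0, 4.32, False),           # 534 - 102 = 432 ng/cm^2
            (-102.0 / 17.8, 0.0, None),     # boundary: Sauerbrey mass == hydration
            (-25.0, 3.43, False),           # (445 - 102) / 1
            (-2.0, 0.0, True),              # below the hydration layer: clipped
        ],
    )
    def test_bilayer_thickness_hydration_corrected(self, df, expected, clipped):
        h, flag = bilayer_thickness_corrected(df)
        assert h == pytest.approx(expected, abs=5e-3)
        if clipped is not None:  # at the exact boundary the flag is FP-sensitive
            assert flag is clipped


class TestDecayLength:
    def test_water_25c_fundamental(self):
        # frozen from an independent arbitrary-precision evaluation
        assert decay_length(1, WATER_25C) == pytest.approx(238.3897, abs=1e-3)

    def test_scales_as_inverse_sqrt_n(self):
        assert decay_length(3) / decay_length(1) == pytest.approx(1 / math.sqrt(3))
        assert decay_length(11) < decay_length(7) < decay_length(3)

    def test_doubling_viscosity_scales_sqrt2(self):
        c = PhysicalConstants()
        c2 = PhysicalConstants(eta_l=2 * c.eta_l)
        assert decay_length(3, c2) / decay_length(3, c) == pytest.approx(math.sqrt(2))

    def test_rejects_nonpositive_overtone(self):
        with pytest.raises(InvalidParameterError):
            decay_length(0)


class TestRigidFilm:
    def test_inverse_of_sauerbrey_mass(self):
        df, dd = rigid_film_response(534.0)
        assert df == pytest.approx(-30.0)
        assert dd == 0.0

    def test_zero_mass(self):
        assert rigid_film_response(0.0) == (0.0, 0.0)

    def test_overtone_independent_to_machine_precision(self):
        responses = [rigid_film_response(700.0, n) for n in (3, 7, 11)]
        assert responses[0] == responses[1] == responses[2]

    @given(m=st.floats(0, 5000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_thickness_round_trip(self, m):
        df, _ = rigid_film_response(m)
        assert sauerbrey_thickness(df, rho=1.0) == pytest.approx(m * 0.01, rel=1e-12, abs=1e-12)


class TestViscoelasticFilm:
    def test_frozen_reference_point(self):
        # frozen from an independent term-by-term mpmath evaluation:
        # m_f=2000 ng/cm^2, rho_f=1, G'=1e5 Pa, G''=3e4 Pa, n=3, water 25 C
        film = ViscoelasticFilm(m_f=2000.0, rho_f=1.0, g_storage=1e5, g_loss=3e4)
        df, dd = viscoelastic_film_response(film, 3, WATER_25C)
        assert df == pytest.approx(-86.49761397, rel=1e-9)
        assert dd == pytest.approx(34.48258212, rel=1e-9)

    @pytest.mark.parametrize("n", [3, 7, 11])
    def test_stiff_limit_matches_rigid(self, n):
        film = ViscoelasticFilm(m_f=534.0, g_storage=1e12, g_loss=1e6)
        df, dd = viscoelastic_film_response(film, n)
        df_rigid, _ = rigid_film_response(534.0, n)
        assert abs(df - df_rigid) / abs(df_rigid) < 1e-3
        assert dd < 1e-8 * 1e6  # < 1e-8 dimensionless

    def test_stiff_limit_property_sweep(self):
        for g in (1e10, 1e11, 1e12):
            for n in (3, 7, 11):
                film = ViscoelasticFilm(m_f=1000.0, g_storage=g, g_loss=g / 100)
                df, dd = viscoelastic_film_response(film, n)
                df_rigid, _ = rigid_film_response(1000.0, n)
                assert abs(df - df_rigid) / abs(df_rigid) < 1e-3
                assert dd < 1e-2  # 1e-8 dimensionless in 1e-6 units

    def test_soft_film_splits_across_overtones(self):
        film = ViscoelasticFilm(m_f=2000.0, g_storage=1e5, g_loss=3e4)
        dfs = [viscoelastic_film_response(film, n)[0] for n in (3, 7, 11)]
        assert max(dfs) - min(dfs) > 0.0
        assert dfs[0] < dfs[1] < dfs[2]  # magnitude shrinks toward the surface

    def test_dissipation_decreasesing_in_g_storage_beyond_peak(self):
        # brute-force scan: with G'' fixed, dD peaks at G' = G'' then falls
        g_loss = 5e4
        grid = [g_loss * f for f in (1.0, 2.0, 5.0, 10.0, 50.0, 100.0)]
        dds = [
            viscoelastic_film_response(
                ViscoelasticFilm(m_f=1500.0, g_storage=g, g_loss=g_loss), 3
            )[1]
            for g in grid
        ]
        assert all(a > b for a, b in zip(dds, dds[1:]))

    def test_dissipation_nonnegative(self):
        film = ViscoelasticFilm(m_f=100.0, g_storage=1e4, g_loss=0.0)
        _, dd = viscoelastic_film_response(film, 7)
        assert dd >= 0.0

    def test_invalid_film_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            ViscoelasticFilm(m_f=-1.0)
        with pytest.raises(InvalidParameterError):
            ViscoelasticFilm(m_f=1.0, g_storage=0.0)


class TestDissipationFromModuli:
    def test_zero_loss(self):
        assert dissipation_from_moduli(1e5, 0.0) == 0.0

    def test_algebraic_identity(self):
        g = 3.7e4
        assert dissipation_from_moduli(g, 2 * math.pi * g) == pytest.approx(1.0)

    def test_hand_value(self):
        assert dissipation_from_moduli(1e5, 3e4) == pytest.approx(4.7746e-2, rel=1e-4)

    def test_rejects_nonpositive_storage(self):
        with pytest.raises(InvalidParameterError):
            dissipation_from_moduli(0.0, 1.0)


def test_constants_mq_consistency():
    c = PhysicalConstants()
    assert c.m_q_ng_cm2 == pytest.approx(c.sauerbrey_c * c.f0_hz)
    assert c.m_q_kg_m2 == pytest.approx(0.89)
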