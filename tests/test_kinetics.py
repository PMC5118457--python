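"""Kinetic-constant arithmetic, temperature scaling, and packaged tables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acifit.kinetics import (
    GasSolubility,
    KineticsError,
    NonIdentifiableError,
    PEPCKineticSet,
    RubiscoKineticSet,
    concentration_to_partial_pressure,
    gamma_star_from_sco,
    kc_apparent,
    kinetics_at_temperature,
    ko_from_kc_pair,
    load_constants_table,
    own_kinetics,
    partial_pressure_to_concentration,
    sco_from_gamma_star,
    solubility,
    standard_kinetics,
)

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


class TestGammaStar:
    @pytest.mark.parametrize(
        "sco,o_pa,expected,tol",
        [
            (2506, 21000.0, 4.19, 0.005),   # rice 25 degC, printed rounding
            (1, 2.0, 1.0, 1e-12),           # identity scale
            (1623, 21000.0, 6.47, 0.005),   # maize 38 degC
        ],
    )
    def test_values(self, sco, o_pa, expected, tol):
        assert gamma_star_from_sco(sco, o_pa) == pytest.approx(expected, abs=tol)

    def test_decreasing_in_sco(self):
        assert gamma_star_from_sco(2000, 21000) > gamma_star_from_sco(3000, 21000)

    @pytest.mark.parametrize("sco,o", [(0, 21000), (-1, 21000), (2000, 0)])
    def test_domain_errors(self, sco, o):
        with pytest.raises(KineticsError):
            gamma_star_from_sco(sco, o)

    @settings(derandomize=True, max_examples=100)
    @given(sco=positive, o=positive)
    def test_round_trip(self, sco, o):
        back = sco_from_gamma_star(gamma_star_from_sco(sco, o), o)
        assert back == pytest.approx(sco, rel=1e-12)


class TestKcApparent:
    @pytest.mark.parametrize(
        "kc0,ko,o,expected",
        [
            (29.1, 45.7, 21.0, 42.5),    # rice 25 degC
            (10.0, 33.3, 0.0, 10.0),     # zero-oxygen identity
            (85.8, 39.8, 21.0, 131.1),   # maize 25 degC
        ],
    )
    def test_values(self, kc0, ko, o, expected):
        assert kc_apparent(kc0, ko, o) == pytest.approx(expected, abs=0.05)

    def test_zero_ko_is_domain_error(self):
        with pytest.raises(KineticsError):
            kc_apparent(10.0, 0.0, 21.0)

    @pytest.mark.parametrize(
        "kc0,kc21,o,expected",
        [(29.1, 42.5, 21.0, 45.7), (1.0, 2.0, 21.0, 21.0)],
    )
    def test_ko_inverse_values(self, kc0, kc21, o, expected):
        assert ko_from_kc_pair(kc0, kc21, o) == pytest.approx(expected, abs=0.1)

    def test_degenerate_pair_not_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            ko_from_kc_pair(5.0, 5.0, 21.0)

    @settings(derandomize=True, max_examples=100)
    @given(kc0=positive, ko=positive, o=positive)
    def test_compose_identity(self, kc0, ko, o):
        kc21 = kc_apparent(kc0, ko, o)
        assert ko_from_kc_pair(kc0, kc21, o) == pytest.approx(ko, rel=1e-9)


class TestSolubilityConversion:
    @pytest.mark.parametrize(
        "conc,gas,t,expected",
        [
            (9.72, "CO2", 25.0, 29.1),
            (0.0, "CO2", 25.0, 0.0),
            (2.13, "CO2", 38.0, 8.8),
        ],
    )
    def test_to_partial_pressure(self, conc, gas, t, expected):
        p = concentration_to_partial_pressure(conc, solubility(gas, t))
        assert p == pytest.approx(expected, abs=0.05)

    def test_unknown_pair_errors(self):
        with pytest.raises(KineticsError):
            solubility("CO2", 30.0)

    @settings(derandomize=True, max_examples=50)
    @given(conc=st.floats(min_value=0, max_value=1e4))
    def test_round_trip(self, conc):
        sol = solubility("O2", 25.0)
        p = concentration_to_partial_pressure(conc, sol)
        assert partial_pressure_to_concentration(p, sol) == pytest.approx(
            conc, rel=1e-12, abs=1e-15
        )

    def test_solubility_decreases_with_temperature(self):
        for gas in ("CO2", "O2"):
            assert solubility(gas, 38.0).solubility < solubility(gas, 25.0).solubility


class TestTemperatureScaling:
    def test_endpoints_bit_exact(self):
        tab = load_constants_table()
        for sp in ("rice", "wheat", "maize"):
            k25, k38 = own_kinetics(sp, 25.0), own_kinetics(sp, 38.0)
            if isinstance(k25, tuple):
                k25, k38 = k25[0], k38[0]
            row25 = tab[(tab.species == sp) & (tab.temperature_C == 25)].iloc[0]
            row38 = tab[(tab.species == sp) & (tab.temperature_C == 38)].iloc[0]
            assert k25.Kc_Pa == row25.Kc_Pa and k38.Kc_Pa == row38.Kc_Pa
            assert k25.Ko_kPa == row25.Ko_kPa and k38.Ko_kPa == row38.Ko_kPa
            assert k25.gamma_star_Pa == row25.gammastar_Pa

    def test_interior_value_frozen_oracle(self):
        # two-point Arrhenius, ln k linear in 1/T_K: hand evaluation for rice Kc
        k = own_kinetics("rice", 31.5)
        assert k.Kc_Pa == pytest.approx(51.116, abs=0.01)
        assert 29.1 < k.Kc_Pa < 87.7

    def test_monotone_between_endpoints(self):
        temps = np.linspace(25.5, 37.5, 13)
        kcs = [own_kinetics("wheat", float(t)).Kc_Pa for t in temps]
        assert np.all(np.diff(kcs) > 0)

    def test_mismatched_species_error(self):
        a = own_kinetics("rice", 25.0)
        b = own_kinetics("wheat", 38.0)
        with pytest.raises(KineticsError):
            kinetics_at_temperature(a, b, 30.0)

    def test_q10_mode_agrees_at_endpoints(self):
        a, b = own_kinetics("rice", 25.0), own_kinetics("rice", 38.0)
        assert kinetics_at_temperature(a, b, 25.0, mode="q10").Kc_Pa == a.Kc_Pa
        assert kinetics_at_temperature(a, b, 38.0, mode="q10").Kc_Pa == b.Kc_Pa

    def test_maize_carries_pepc(self):
        rub, pepc = own_kinetics("maize", 30.0)
        assert isinstance(pepc, PEPCKineticSet)
        assert 8.0 < pepc.Kp_Pa < 13.2


class TestStandardKinetics:
    def test_c4_standard_at_25(self):
        rub, pepc = standard_kinetics("voncaemmerer", 25.0)
        assert rub.Kc_Pa == pytest.approx(65.0)
        assert rub.Ko_kPa == pytest.approx(45.0)
        assert pepc.Kp_Pa == pytest.approx(8.0)
        # dimensionless gamma* = Gamma*/O = 0.000193 at 210 mbar O2
        assert rub.gamma_star_Pa / 21000.0 == pytest.approx(0.000193)

    def test_kp_invariant_with_temperature(self):
        _, p25 = standard_kinetics("voncaemmerer", 25.0)
        _, p38 = standard_kinetics("voncaemmerer", 38.0)
        assert p25.Kp_Pa == p38.Kp_Pa

    @pytest.mark.parametrize("variant,kc,ko,gs", [
        ("cc_basis", 27.238, 16.582, 3.743),
        ("ci_basis", 40.49, 27.84, 4.275),
    ])
    def test_tobacco_reference_values_at_25(self, variant, kc, ko, gs):
        k = standard_kinetics("bernacchi", 25.0, variant=variant)
        assert (k.Kc_Pa, k.Ko_kPa, k.gamma_star_Pa) == (kc, ko, gs)

    def test_tobacco_constants_increase_with_temperature(self):
        k25 = standard_kinetics("bernacchi", 25.0)
        k38 = standard_kinetics("bernacchi", 38.0)
        assert k38.Kc_Pa > k25.Kc_Pa and k38.gamma_star_Pa > k25.gamma_star_Pa

    def test_unknown_source_errors(self):
        with pytest.raises(KineticsError):
            standard_kinetics("collatz", 25.0)


# Verbatim transcription of the in vitro constants table (printed values).
_TABLE1 = {
    ("rice", 25): (29.1, 1.6, 45.7, 4.6, 4.19, 0.19, None, None),
    ("rice", 38): (87.7, 5.2, 58.3, 5.7, 6.34, 0.36, None, None),
    ("wheat", 25): (31.6, 1.1, 39.2, 3.8, 3.87, 0.21, None, None),
    ("wheat", 38): (89.3, 3.6, 50.3, 4.5, 5.32, 0.32, None, None),
    ("maize", 25): (85.8, 7.0, 39.8, 3.5, 4.30, 0.30, 8.0, 3.0),
    ("maize", 38): (188.3, 5.7, 74.5, 7.5, 6.47, 0.26, 13.2, 5.0),
}


def test_packaged_table_matches_transcription_verbatim():
    tab = load_constants_table().set_index(["species", "temperature_C"])
    cols = ["Kc_Pa", "Kc_SE", "Ko_kPa", "Ko_SE", "gammastar_Pa", "gammastar_SE",
            "Kp_Pa", "Kp_SE"]
    for key, vals in _TABLE1.items():
        row = tab.loc[key]
        for col, val in zip(cols, vals):
            if val is None:
                assert np.isnan(row[col])
            else:
                assert row[col] == val


def test_kc_increases_with_temperature_for_every_species():
    tab = load_constants_table()
    for sp, grp in tab.groupby("species"):
        g = grp.set_index("temperature_C")
        assert g.loc[38, "Kc_Pa"] > g.loc[25, "Kc_Pa"]


def test_kinetic_set_validates_gamma_star_sco_consistency():
    with pytest.raises(KineticsError):
        RubiscoKineticSet(
            species="x", temperature_C=25.0, Kc_Pa=30.0, Ko_kPa=40.0,
            gamma_star_Pa=4.0, Sco=9999.0,
        )
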