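"""Enzyme kinetic constants for photosynthesis models and their temperature scaling.

This module houses Michaelis–Menten constants of Rubisco (Kc, Ko), its
CO2/O2 specificity (Sco) and the associated CO2 compensation point in the
absence of mitochondrial respiration (Gamma*), plus the PEPC constant for
CO2 (Kp) used by the C4 model.  Constants come from two kinds of source:

* ``own`` — species-specific values measured in vitro at 25 and 38 degC
  (rice, wheat, maize), packaged as a human-readable CSV table;
* ``standard`` — the tobacco constants with their published exponential
  temperature-response functions (two variants: intercellular-CO2 basis
  and chloroplastic-CO2 basis), and the C4-model defaults (Kc = 65 Pa,
  Ko = 45 kPa, Kp = 8 Pa, dimensionless gamma* = 0.000193 at 25 degC).

All partial pressures are Pa for CO2-like quantities and kPa for O2;
dissolved-phase constants convert through gas solubilities
(mol L-1 bar-1).  Temperature scaling of the species-specific sets uses an
exactly-constrained two-point Arrhenius law through the 25/38 degC pair.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "R_KJ",
    "T0_K",
    "OXYGEN_KPA_C3",
    "OXYGEN_MBAR_C4",
    "RubiscoKineticSet",
    "PEPCKineticSet",
    "GasSolubility",
    "OxygenReference",
    "KineticsError",
    "NonIdentifiableError",
    "gamma_star_from_sco",
    "sco_from_gamma_star",
    "kc_apparent",
    "ko_from_kc_pair",
    "concentration_to_partial_pressure",
    "partial_pressure_to_concentration",
    "solubility",
    "kinetics_at_temperature",
    "standard_kinetics",
    "own_kinetics",
    "load_constants_table",
]

#: Universal gas constant, kJ mol-1 K-1.
R_KJ = 8.314e-3
#: Reference temperature for the standard exponential responses, K.
T0_K = 298.15
#: Ambient O2 partial pressure used for C3 leaf-level calculations, kPa.
OXYGEN_KPA_C3 = 21.0
#: O2 partial pressure assumed in the C4 model (mesophyll and bundle sheath), mbar.
OXYGEN_MBAR_C4 = 210.0


class KineticsError(ValueError):
    """Domain error for kinetic-constant arithmetic."""


class NonIdentifiableError(KineticsError):
    """Raised when a constant cannot be inferred from the given measurements
    (e.g. no apparent O2 inhibition in a Kc pair)."""


def gamma_star_from_sco(sco: float, o_pa: float) -> float:
    """CO2 compensation point without mitochondrial respiration, Pa.

    Gamma* = 0.5 * O / Sco, with the specificity factor Sco on a
    partial-pressure basis and O the O2 partial pressure in Pa.
    """
    if sco <= 0 or o_pa <= 0:
        raise KineticsError(f"Sco and O must be positive (got {sco}, {o_pa})")
    return 0.5 * o_pa / sco


def sco_from_gamma_star(gamma_star_pa: float, o_pa: float) -> float:
    """Inverse of :func:`gamma_star_from_sco`."""
    if gamma_star_pa <= 0 or o_pa <= 0:
        raise KineticsError(
            f"Gamma* and O must be positive (got {gamma_star_pa}, {o_pa})"
        )
    return 0.5 * o_pa / gamma_star_pa


def kc_apparent(kc0_pa: float, ko_kpa: float, o_kpa: float) -> float:
    """Apparent Kc in the presence of O2: Kc0 * (1 + O/Ko).

    ``kc0_pa`` is the Kc measured at zero O2 (Pa), ``ko_kpa`` the O2
    inhibition constant (kPa) and ``o_kpa`` the O2 partial pressure (kPa).
    """
    if kc0_pa <= 0 or ko_kpa <= 0 or o_kpa < 0:
        raise KineticsError("kc_apparent requires Kc0, Ko > 0 and O >= 0")
    return kc0_pa * (1.0 + o_kpa / ko_kpa)


def ko_from_kc_pair(kc0_pa: float, kc21_pa: float, o_kpa: float = OXYGEN_KPA_C3) -> float:
    """Ko (kPa) inferred from Kc assayed at 0% and 21% O2.

    Inverts Kc(21%) = Kc(0%) * (1 + O/Ko).  If the 21%-O2 assay shows no
    inhibition (Kc21 <= Kc0) Ko is not identifiable.
    """
    if kc0_pa <= 0 or o_kpa <= 0:
        raise KineticsError("ko_from_kc_pair requires Kc0, O > 0")
    if kc21_pa <= kc0_pa:
        raise NonIdentifiableError(
            f"no O2 inhibition detected (Kc21={kc21_pa} <= Kc0={kc0_pa}); "
            "Ko is not identifiable"
        )
    return o_kpa / (kc21_pa / kc0_pa - 1.0)


@dataclass(frozen=True)
class GasSolubility:
    """Solubility of a gas in water, mol L-1 bar-1, at a given temperature."""

    gas: str
    temperature_C: float
    solubility: float

    def __post_init__(self) -> None:
        if self.solubility <= 0:
            raise KineticsError("solubility must be positive")


# Solubilities used to convert dissolved-phase Michaelis constants to
# partial pressures at the two assay temperatures.
_SOLUBILITIES = {
    ("CO2", 25.0): GasSolubility("CO2", 25.0, 0.0334),
    ("CO2", 38.0): GasSolubility("CO2", 38.0, 0.0243),
    ("O2", 25.0): GasSolubility("O2", 25.0, 0.00126),
    ("O2", 38.0): GasSolubility("O2", 38.0, 0.00102),
}


def solubility(gas: str, temperature_C: float) -> GasSolubility:
    """Packaged solubility for (gas, temperature); raises for unknown pairs."""
    key = (gas.upper(), float(temperature_C))
    try:
        return _SOLUBILITIES[key]
    except KeyError:
        raise KineticsError(
            f"no packaged solubility for {gas} at {temperature_C} degC; "
            "provide a GasSolubility explicitly"
        ) from None


def concentration_to_partial_pressure(conc_uM: float, sol: GasSolubility) -> float:
    """Convert a dissolved concentration (µM) to partial pressure (Pa).

    p[bar] = c[mol/L] / s[mol/(L bar)]; returned in Pa (1 bar = 1e5 Pa).
    """
    if conc_uM < 0:
        raise KineticsError("concentration must be non-negative")
    return conc_uM * 1e-6 / sol.solubility * 1e5


def partial_pressure_to_concentration(p_pa: float, sol: GasSolubility) -> float:
    """Inverse of :func:`concentration_to_partial_pressure` (returns µM)."""
    if p_pa < 0:
        raise KineticsError("partial pressure must be non-negative")
    return p_pa * 1e-5 * sol.solubility * 1e6


@dataclass(frozen=True)
class OxygenReference:
    """O2 partial pressure reference (kPa) with its model basis."""

    O_kPa: float
    basis: str = "ambient"

    def __post_init__(self) -> None:
        if self.O_kPa <= 0:
            raise KineticsError("O must be positive")


@dataclass(frozen=True)
class RubiscoKineticSet:
    """Rubisco kinetic constants at one temperature.

    Gamma* and Sco are stored redundantly and must satisfy
    Gamma* = 0.5 * O / Sco at the set's oxygen reference.
    """

    species: str
    temperature_C: float
    Kc_Pa: float
    Ko_kPa: float
    gamma_star_Pa: float
    Sco: float
    source: str = "own"
    oxygen_ref_kPa: float = OXYGEN_KPA_C3

    def __post_init__(self) -> None:
        for name in ("Kc_Pa", "Ko_kPa", "gamma_star_Pa", "Sco"):
            if getattr(self, name) <= 0:
                raise KineticsError(f"{name} must be positive")
        implied = gamma_star_from_sco(self.Sco, self.oxygen_ref_kPa * 1e3)
        if abs(implied - self.gamma_star_Pa) > 1e-9 * self.gamma_star_Pa:
            raise KineticsError(
                "gamma_star and Sco are inconsistent with Gamma* = 0.5 O/Sco "
                f"({self.gamma_star_Pa} Pa vs implied {implied} Pa)"
            )

    @classmethod
    def from_gamma_star(
        cls,
        species: str,
        temperature_C: float,
        Kc_Pa: float,
        Ko_kPa: float,
        gamma_star_Pa: float,
        source: str = "own",
        oxygen_ref_kPa: float = OXYGEN_KPA_C3,
    ) -> "RubiscoKineticSet":
        """Build a set deriving Sco from Gamma* (the packaged tables print
        Gamma*, not Sco; the stored Sco is flagged as derived)."""
        sco = sco_from_gamma_star(gamma_star_Pa, oxygen_ref_kPa * 1e3)
        return cls(
            species=species,
            temperature_C=temperature_C,
            Kc_Pa=Kc_Pa,
            Ko_kPa=Ko_kPa,
            gamma_star_Pa=gamma_star_Pa,
            Sco=sco,
            source=source,
            oxygen_ref_kPa=oxygen_ref_kPa,
        )

    def kc_app_Pa(self, o_kpa: float = OXYGEN_KPA_C3) -> float:
        """Apparent Kc(1 + O/Ko) at the given O2 partial pressure, Pa."""
        return kc_apparent(self.Kc_Pa, self.Ko_kPa, o_kpa)


@dataclass(frozen=True)
class PEPCKineticSet:
    """PEPC Michaelis–Menten constant for CO2 at one temperature."""

    species: str
    temperature_C: float
    Kp_Pa: float
    source: str = "own"

    def __post_init__(self) -> None:
        if self.Kp_Pa <= 0:
            raise KineticsError("Kp must be positive")


def _arrhenius_two_point(k25: float, k38: float, t25_C: float, t38_C: float, t_C: float) -> float:
    # ln k linear in 1/T_K through the two endpoints; exact at both.
    t1, t2, t = t25_C + 273.15, t38_C + 273.15, t_C + 273.15
    ea_over_r = math.log(k38 / k25) / (1.0 / t1 - 1.0 / t2)
    return k25 * math.exp(ea_over_r * (1.0 / t1 - 1.0 / t))


def _q10_two_point(k25: float, k38: float, t25_C: float, t38_C: float, t_C: float) -> float:
    q10 = (k38 / k25) ** (10.0 / (t38_C - t25_C))
    return k25 * q10 ** ((t_C - t25_C) / 10.0)


def kinetics_at_temperature(
    set25: RubiscoKineticSet,
    set38: RubiscoKineticSet,
    t_C: float,
    mode: str = "arrhenius",
    pepc25: Optional[PEPCKineticSet] = None,
    pepc38: Optional[PEPCKineticSet] = None,
) -> RubiscoKineticSet | tuple[RubiscoKineticSet, PEPCKineticSet]:
    """Interpolate species-specific constants between the two assay temperatures.

    Each constant follows a two-point law (default Arrhenius,
    ``exp(c - Ea/(R T_K))`` with c and Ea solved from the pair; ``mode="q10"``
    as an alternative).  The input sets are returned exactly at their own
    temperatures.  If a PEPC pair is supplied a scaled PEPC set is returned
    alongside.
    """
    if set25.species != set38.species or set25.source != set38.source:
        raise KineticsError("the two sets must share species and source")
    if not (0.0 < t_C < 60.0):
        raise KineticsError(f"temperature {t_C} degC outside supported range (0, 60)")
    if mode not in ("arrhenius", "q10"):
        raise KineticsError(f"unknown interpolation mode {mode!r}")

    if t_C == set25.temperature_C:
        out = set25
    elif t_C == set38.temperature_C:
        out = set38
    else:
        interp = _arrhenius_two_point if mode == "arrhenius" else _q10_two_point
        t1, t2 = set25.temperature_C, set38.temperature_C
        out = RubiscoKineticSet.from_gamma_star(
            species=set25.species,
            temperature_C=t_C,
            Kc_Pa=interp(set25.Kc_Pa, set38.Kc_Pa, t1, t2, t_C),
            Ko_kPa=interp(set25.Ko_kPa, set38.Ko_kPa, t1, t2, t_C),
            gamma_star_Pa=interp(set25.gamma_star_Pa, set38.gamma_star_Pa, t1, t2, t_C),
            source=set25.source,
            oxygen_ref_kPa=set25.oxygen_ref_kPa,
        )
    if pepc25 is None:
        return out
    if pepc38 is None or pepc25.species != pepc38.species:
        raise KineticsError("PEPC interpolation needs a matched 25/38 pair")
    if t_C == pepc25.temperature_C:
        pep = pepc25
    elif t_C == pepc38.temperature_C:
        pep = pepc38
    else:
        interp = _arrhenius_two_point if mode == "arrhenius" else _q10_two_point
        pep = PEPCKineticSet(
            species=pepc25.species,
            temperature_C=t_C,
            Kp_Pa=interp(
                pepc25.Kp_Pa, pepc38.Kp_Pa, pepc25.temperature_C, pepc38.temperature_C, t_C
            ),
            source=pepc25.source,
        )
    return out, pep


def _load_json(name: str) -> dict:
    with resources.files("acifit.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return json.load(fh)


def _exp_response(k25: float, dha: float, t_C: float) -> float:
    return k25 * math.exp(dha / R_KJ * (1.0 / T0_K - 1.0 / (t_C + 273.15)))


def standard_kinetics(
    source: str,
    t_C: float,
    variant: str = "cc_basis",
) -> RubiscoKineticSet | tuple[RubiscoKineticSet, PEPCKineticSet]:
    """Standard (tobacco / C4-default) kinetic constants at temperature ``t_C``.

    ``source="bernacchi"`` returns the tobacco Rubisco constants with their
    published exponential temperature responses; ``variant`` selects the
    intercellular-CO2 ("ci_basis") or chloroplastic-CO2 ("cc_basis",
    default — appropriate for fits on a Cc basis) parameter set.

    ``source="voncaemmerer"`` returns the C4-model defaults (Kc 65 Pa,
    Ko 45 kPa, dimensionless gamma* 0.000193 converted through the model's
    210 mbar O2, Kp 8 Pa) together with a PEPC set; the Rubisco constants
    follow the tobacco ci-basis activation energies with temperature while
    Kp is held invariant.
    """
    cfg = _load_json("tobacco_temperature_responses.json")
    if source == "bernacchi":
        try:
            v = cfg["variants"][variant]
        except KeyError:
            raise KineticsError(f"unknown tobacco response variant {variant!r}") from None
        return RubiscoKineticSet.from_gamma_star(
            species="tobacco",
            temperature_C=t_C,
            Kc_Pa=_exp_response(v["Kc_Pa_25"], v["dHa_Kc_kJ_mol"], t_C),
            Ko_kPa=_exp_response(v["Ko_kPa_25"], v["dHa_Ko_kJ_mol"], t_C),
            gamma_star_Pa=_exp_response(
                v["gammastar_Pa_25"], v["dHa_gammastar_kJ_mol"], t_C
            ),
            source="bernacchi",
        )
    if source == "voncaemmerer":
        c4 = cfg["c4_standard"]
        ci = cfg["variants"]["ci_basis"]
        o_pa = OXYGEN_MBAR_C4 * 100.0  # mbar -> Pa
        gamma_star_25 = c4["gammastar_ratio_25"] * o_pa
        rub = RubiscoKineticSet.from_gamma_star(
            species="C4-standard",
            temperature_C=t_C,
            Kc_Pa=_exp_response(c4["Kc_Pa_25"], ci["dHa_Kc_kJ_mol"], t_C),
            Ko_kPa=_exp_response(c4["Ko_kPa_25"], ci["dHa_Ko_kJ_mol"], t_C),
            gamma_star_Pa=_exp_response(gamma_star_25, ci["dHa_gammastar_kJ_mol"], t_C),
            source="voncaemmerer",
            oxygen_ref_kPa=OXYGEN_MBAR_C4 / 10.0,
        )
        pep = PEPCKineticSet(
            species="C4-standard",
            temperature_C=t_C,
            Kp_Pa=c4["Kp_Pa_25"],  # invariant with temperature
            source="voncaemmerer",
        )
        return rub, pep
    raise KineticsError(f"unknown standard-kinetics source {source!r}")


def load_constants_table() -> pd.DataFrame:
    """The packaged species-specific constants table (verbatim transcription)."""
    with resources.files("acifit.data").joinpath("rubisco_pepc_constants.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        return pd.read_csv(fh)


def own_kinetics(
    species: str, t_C: float, mode: str = "arrhenius"
) -> RubiscoKineticSet | tuple[RubiscoKineticSet, PEPCKineticSet]:
    """Species-specific constants at ``t_C``, interpolated from the packaged
    25/38 degC assays.  For maize the PEPC set is returned alongside."""
    tab = load_constants_table()
    rows = tab[tab.species == species]
    if rows.empty:
        raise KineticsError(f"no packaged constants for species {species!r}")
    sets = {}
    peps = {}
    for _, r in rows.iterrows():
        sets[r.temperature_C] = RubiscoKineticSet.from_gamma_star(
            species=species,
            temperature_C=float(r.temperature_C),
            Kc_Pa=float(r.Kc_Pa),
            Ko_kPa=float(r.Ko_kPa),
            gamma_star_Pa=float(r.gammastar_Pa),
            source="own",
        )
        if not np.isnan(r.Kp_Pa):
            peps[r.temperature_C] = PEPCKineticSet(
                species=species, temperature_C=float(r.temperature_C), Kp_Pa=float(r.Kp_Pa)
            )
    if peps:
        return kinetics_at_temperature(
            sets[25], sets[38], t_C, mode=mode, pepc25=peps[25], pepc38=peps[38]
        )
    return kinetics_at_temperature(sets[25], sets[38], t_C, mode=mode)
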