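"""Synthetic gas-exchange + fluorescence data generator.

Emulates the study design the analysis assumes: a 3-species (rice, wheat
C3; maize C4) × 2 growth-temperature (25/38 degC) × 2 irrigation (WW/WD)
× 2 measurement-temperature (25/38 degC) factorial of A-Ci curves with
replicates, water deficit expressed as a >= 40% stomatal-conductance
reduction, and Gaussian measurement noise on the net assimilation rate.

Each curve point is a solved steady state of the supply/demand system:
stomatal supply A = (gs/1.6)(Ca - Ci), mesophyll transfer Cc = Ci - A/gm,
and the FvCB (C3) or enzyme-limited von Caemmerer (C4) demand function.
Fluorescence (Fs, Fm') is emitted consistently with the operating
electron transport, so the variable-J method is admissible by
construction at all points above the compensation point.

True-parameter magnitudes per treatment cell are scenario presets seeded
from the study's fitted treatment means, so synthetic outputs are
physiologically scaled; they are presets, not measurements.

Randomness: a single integer seed feeds a SeedSequence that spawns one
independent child stream per (cell, replicate), so cells are mutually
independent and the whole dataset is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .c3 import GM_PA_TO_BAR, ACiCurve, fvcb_finite_gm, rl_from_rdark
from .c4 import C4Constants, c4_forward
from .fluorescence import LeafOptics
from .kinetics import OXYGEN_KPA_C3, own_kinetics

__all__ = [
    "ExperimentDesign",
    "TrueParameters",
    "default_true_parameters",
    "simulate_c3_curve",
    "simulate_c4_curve",
    "simulate_experiment",
    "SyntheticDataset",
    "DEFAULT_CA_GRID",
    "WD_GS_FACTOR",
]

#: Ca sweep (µmol mol-1) spanning the measured 50-2000 range.
DEFAULT_CA_GRID = (50.0, 100.0, 150.0, 200.0, 250.0, 300.0, 400.0,
                   500.0, 700.0, 1000.0, 1500.0, 2000.0)
#: WD stomatal conductance as a fraction of the matched WW cell (>= 40% reduction).
WD_GS_FACTOR = 0.55

PPFD_MEAS = 1500.0  # saturating actinic light, µmol m-2 s-1
FM_PRIME_REF = 2000.0  # arbitrary fluorescence yield scale


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout and noise model of a synthetic experiment."""

    species: tuple[str, ...] = ("rice", "wheat", "maize")
    growth_T: tuple[float, ...] = (25.0, 38.0)
    irrigation: tuple[str, ...] = ("WW", "WD")
    meas_T: tuple[float, ...] = (25.0, 38.0)
    replicates: int = 4
    Ca_grid: tuple[float, ...] = DEFAULT_CA_GRID
    noise_sd_AN: float = 0.5
    gs_noise_cv: float = 0.0  # optional multiplicative noise on gs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 0:
            raise ValueError("replicates must be >= 0")
        if self.noise_sd_AN < 0:
            raise ValueError("noise sd must be >= 0")

    def cells(self) -> Iterable[tuple[str, float, str, float]]:
        for sp in self.species:
            for gt in self.growth_T:
                for irr in self.irrigation:
                    for mt in self.meas_T:
                        yield sp, gt, irr, mt


@dataclass(frozen=True)
class TrueParameters:
    """Generating parameter values for one treatment cell."""

    species: str
    Vcmax: float
    Jmax: float = float("nan")     # C3 only
    Vpmax: float = float("nan")    # C4 only
    gs: float = 0.3                # mol H2O m-2 s-1
    gm: float = 0.25               # mol m-2 s-1 bar-1 (C3); mole-fraction basis for C4 model is fixed
    Rdark: float = 1.0

    @property
    def is_c4(self) -> bool:
        return not np.isnan(self.Vpmax)


# Scenario presets: Vcmax/Jmax (C3) and Vcmax/Vpmax (C4) from the study's
# own-kinetics treatment means; conductances and respiration at
# field-realistic magnitudes with the WD rule applied to gs.
_C3_MEANS = {
    # (species, growth_T, irrigation, meas_T): (Vcmax, Jmax)
    ("rice", 25, "WW", 25): (102.7, 184.5),
    ("rice", 25, "WD", 25): (70.1, 146.7),
    ("rice", 25, "WW", 38): (185.1, 208.3),
    ("rice", 25, "WD", 38): (182.2, 207.3),
    ("rice", 38, "WW", 25): (70.2, 118.8),
    ("rice", 38, "WD", 25): (50.2, 90.0),
    ("rice", 38, "WW", 38): (222.1, 215.4),
    ("rice", 38, "WD", 38): (173.2, 173.4),
    ("wheat", 25, "WW", 25): (105.4, 181.5),
    ("wheat", 25, "WD", 25): (122.9, 199.8),
    ("wheat", 25, "WW", 38): (127.7, 154.7),
    ("wheat", 25, "WD", 38): (119.2, 125.3),
    ("wheat", 38, "WW", 25): (88.9, 143.8),
    ("wheat", 38, "WD", 25): (80.9, 127.2),
    ("wheat", 38, "WW", 38): (205.2, 198.7),
    ("wheat", 38, "WD", 38): (197.8, 181.1),
}
_C4_MEANS = {
    ("maize", 25, "WW", 25): (29.9, 133.8),
    ("maize", 25, "WD", 25): (22.5, 81.1),
    ("maize", 25, "WW", 38): (38.7, 141.1),
    ("maize", 25, "WD", 38): (33.6, 82.6),
    ("maize", 38, "WW", 25): (14.4, 44.9),
    ("maize", 38, "WD", 25): (22.7, 52.8),
    ("maize", 38, "WW", 38): (31.7, 219.5),
    ("maize", 38, "WD", 38): (31.1, 158.7),
}
_GS_WW = {"rice": 0.35, "wheat": 0.30, "maize": 0.25}
_GM_BASE = {"rice": 0.28, "wheat": 0.25}
_RDARK = {25.0: 0.8, 38.0: 3.2}


def default_true_parameters(
    species: str, growth_T: float, irrigation: str, meas_T: float
) -> TrueParameters:
    """Preset generating parameters for one factorial cell."""
    gs = _GS_WW[species] * (1.1 if meas_T == 38.0 else 1.0)
    if irrigation == "WD":
        gs *= WD_GS_FACTOR
    rdark = _RDARK.get(meas_T, 1.0)
    key = (species, int(growth_T), irrigation, int(meas_T))
    if species == "maize":
        vcmax, vpmax = _C4_MEANS[key]
        return TrueParameters(
            species=species, Vcmax=vcmax, Vpmax=vpmax, gs=gs, Rdark=rdark
        )
    vcmax, jmax = _C3_MEANS[key]
    gm = _GM_BASE[species] * (0.8 if meas_T == 38.0 else 1.0)
    if irrigation == "WD":
        gm *= 0.8
    return TrueParameters(
        species=species, Vcmax=vcmax, Jmax=jmax, gs=gs, gm=gm, Rdark=rdark
    )


def simulate_c3_curve(
    params: TrueParameters,
    growth_T: float,
    irrigation: str,
    meas_T: float,
    noise_sd: float = 0.5,
    ca_grid: tuple[float, ...] = DEFAULT_CA_GRID,
    rng: Optional[np.random.Generator] = None,
    optics: LeafOptics = LeafOptics(),
    patm_kpa: float = 101.325,
    curve_id: str = "",
) -> ACiCurve:
    """One C3 A-Ci curve solved from the coupled supply/demand system.

    Stomatal and mesophyll transfer act as series resistances, so the
    steady state solves A = FvCB(Ca - A(1.6/gs + 1/gm)) in closed
    (quadratic) form.  ETR is emitted consistently with the operating
    electron transport at the true (noiseless) steady state, so variable-J
    gm inversion recovers the generating gm exactly in the noiseless limit.
    Points below the CO2 compensation point are skipped (no meaningful
    fluorescence signal for the variable-J method).
    """
    rng = rng or np.random.default_rng(0)
    kin = own_kinetics(params.species, meas_T)
    if isinstance(kin, tuple):
        kin = kin[0]
    rl = rl_from_rdark(params.Rdark)
    pa = patm_kpa * 1e-3  # Pa per µmol mol-1
    gs_co2_pa = params.gs / 1.6 / pa        # µmol m-2 s-1 Pa-1
    gm_pa = params.gm / GM_PA_TO_BAR        # µmol m-2 s-1 Pa-1
    gtot_bar = GM_PA_TO_BAR / (1.0 / gs_co2_pa + 1.0 / gm_pa)

    gstar_pa = kin.gamma_star_Pa
    kapp_pa = kin.kc_app_Pa(OXYGEN_KPA_C3)

    ca_pa = np.asarray(ca_grid, dtype=float) * pa
    a_true = fvcb_finite_gm(ca_pa, params.Vcmax, params.Jmax, gtot_bar, rl, kin)
    ci_pa = ca_pa - a_true / gs_co2_pa
    cc_pa = ci_pa - a_true / gm_pa

    keep = cc_pa > gstar_pa * 1.001
    a_true, ci_pa, cc_pa = a_true[keep], ci_pa[keep], cc_pa[keep]
    ca_kept = np.asarray(ca_grid, dtype=float)[keep]

    # operating electron transport supporting carboxylation + oxygenation
    ac_gross = params.Vcmax * (cc_pa - gstar_pa) / (cc_pa + kapp_pa)
    aj_gross = params.Jmax * (cc_pa - gstar_pa) / (4 * cc_pa + 8 * gstar_pa)
    j_op = np.where(
        ac_gross <= aj_gross,
        params.Vcmax * (4 * cc_pa + 8 * gstar_pa) / (cc_pa + kapp_pa),
        params.Jmax,
    )
    phi = j_op / (optics.alpha * optics.beta * PPFD_MEAS)
    an_obs = a_true + (rng.normal(0.0, noise_sd, len(a_true)) if noise_sd > 0 else 0.0)

    return ACiCurve(
        Ca=ca_kept, Ci=ci_pa / pa, AN=an_obs,
        gs=np.full_like(a_true, params.gs), Tleaf=np.full_like(a_true, meas_T),
        ETR=j_op, PPFD=np.full_like(a_true, PPFD_MEAS),
        Fs=FM_PRIME_REF * (1.0 - phi), Fm_prime=np.full_like(a_true, FM_PRIME_REF),
        species=params.species, growth_T=growth_T, irrigation=irrigation,
        meas_T=meas_T, Rdark=params.Rdark, Patm_kPa=patm_kpa, curve_id=curve_id,
    )


def simulate_c4_curve(
    params: TrueParameters,
    growth_T: float,
    irrigation: str,
    meas_T: float,
    noise_sd: float = 0.5,
    ca_grid: tuple[float, ...] = DEFAULT_CA_GRID,
    rng: Optional[np.random.Generator] = None,
    const: C4Constants = C4Constants(),
    patm_kpa: float = 101.325,
    curve_id: str = "",
) -> ACiCurve:
    """One maize A-Ci curve from the enzyme-limited C4 forward model.

    The stomatal resistance folds into the model's mesophyll conductance
    (series combination on the mole-fraction basis), so the coupled
    stomata + C4 system solves in a single bracketed root find per point;
    Ci then follows from the supply line.
    """
    rng = rng or np.random.default_rng(0)
    rub, pepc = own_kinetics(params.species, meas_T)
    rl = rl_from_rdark(params.Rdark)
    gs_co2 = params.gs / 1.6  # mol m-2 s-1, mole-fraction basis
    g_comb = 1.0 / (1.0 / gs_co2 + 1.0 / const.gm_mol_m2_s)
    const_comb = C4Constants(
        O_mbar=const.O_mbar, gbs_mol_m2_s=const.gbs_mol_m2_s, gm_mol_m2_s=g_comb
    )

    ca = np.asarray(ca_grid, dtype=float)
    a_true, _, _ = c4_forward(
        ca, params.Vcmax, params.Vpmax, rl, rub, pepc, const_comb, patm_kpa=patm_kpa
    )
    ci = ca - a_true / gs_co2
    an_obs = a_true + (rng.normal(0.0, noise_sd, len(a_true)) if noise_sd > 0 else 0.0)
    return ACiCurve(
        Ca=ca, Ci=ci, AN=an_obs, gs=np.full_like(ca, params.gs),
        Tleaf=np.full_like(ca, meas_T), ETR=None,
        species=params.species, growth_T=growth_T, irrigation=irrigation,
        meas_T=meas_T, Rdark=params.Rdark, Patm_kPa=patm_kpa, curve_id=curve_id,
    )


@dataclass
class SyntheticDataset:
    """All simulated curves plus the generating truth for recovery scoring."""

    curves: list[ACiCurve]
    truth: dict[str, dict]
    design: ExperimentDesign

    def to_table(self) -> pd.DataFrame:
        from .io import curves_to_table

        return curves_to_table(self.curves)


def simulate_experiment(design: ExperimentDesign) -> SyntheticDataset:
    """Simulate the full factorial; one independent RNG stream per curve."""
    root = np.random.SeedSequence(design.seed)
    curves: list[ACiCurve] = []
    truth: dict[str, dict] = {}
    cells = list(design.cells())
    children = root.spawn(max(len(cells), 1))
    for cell, cell_seq in zip(cells, children):
        sp, gt, irr, mt = cell
        params = default_true_parameters(sp, gt, irr, mt)
        rep_seqs = cell_seq.spawn(max(design.replicates, 1))
        for rep in range(design.replicates):
            rng = np.random.default_rng(rep_seqs[rep])
            cid = f"{sp}_G{gt:g}_{irr}_M{mt:g}_r{rep + 1}"
            if params.is_c4:
                curve = simulate_c4_curve(
                    params, gt, irr, mt, noise_sd=design.noise_sd_AN,
                    ca_grid=design.Ca_grid, rng=rng, curve_id=cid,
                )
            else:
                curve = simulate_c3_curve(
                    params, gt, irr, mt, noise_sd=design.noise_sd_AN,
                    ca_grid=design.Ca_grid, rng=rng, curve_id=cid,
                )
            if design.gs_noise_cv > 0:
                curve.gs = curve.gs * rng.normal(1.0, design.gs_noise_cv, len(curve))
            curves.append(curve)
            truth[cid] = {k: v for k, v in asdict(params).items() if k != "species"}
            truth[cid]["species"] = sp
    return SyntheticDataset(curves=curves, truth=truth, design=design)
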