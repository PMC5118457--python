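"""FvCB C3 model: variable-J mesophyll conductance, Cc conversion, and
Vcmax/Jmax estimation from A-Cc curves.

The workflow mirrors standard leaf gas-exchange practice:

1. non-photorespiratory respiration in the light is taken as half the
   pre-dawn dark respiration, RL = Rdark/2;
2. mesophyll conductance gm is estimated per point by the variable-J
   method from combined gas exchange and fluorescence,
   gm = AN / (Ci - Gamma*(ETR + 8(AN+RL)) / (ETR - 4(AN+RL)));
3. the A-Ci curve is converted to an A-Cc curve, Cc = Ci - AN/gm;
4. Vcmax and Jmax are estimated by least squares on the A-Cc curve with
   A = min(Ac, Aj) - RL, Ac = Vcmax(Cc-Gamma*)/(Cc + Kc(1+O/Ko)),
   Aj = J(Cc-Gamma*)/(4Cc + 8Gamma*), using species- and
   temperature-specific Rubisco constants (or the tobacco standards).

An alternative single-gm estimator fits the finite-gm quadratic form of
the FvCB model directly on the Ci basis with gm as one shared parameter
across the curve.

Units: mole fractions are µmol mol-1 and convert to Pa through the
per-record atmospheric pressure; gm is reported in mol m-2 s-1 bar-1
(1 µmol m-2 s-1 Pa-1 = 0.1 mol m-2 s-1 bar-1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .fluorescence import LeafOptics
from .kinetics import OXYGEN_KPA_C3, RubiscoKineticSet, own_kinetics, standard_kinetics

logger = logging.getLogger(__name__)

__all__ = [
    "ACiCurve",
    "C3FitResult",
    "FitError",
    "rl_from_rdark",
    "gm_variable_j",
    "cc_from_ci",
    "c3_forward",
    "fit_vcmax_jmax",
    "fvcb_finite_gm",
    "gm_ethier",
    "fit_c3_curve",
    "mole_fraction_to_pa",
    "GM_PA_TO_BAR",
]

#: 1 µmol m-2 s-1 Pa-1 expressed in mol m-2 s-1 bar-1.
GM_PA_TO_BAR = 0.1

DEFAULT_PATM_KPA = 101.325


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: Optional[dict] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def mole_fraction_to_pa(x_umol_mol: np.ndarray | float, patm_kpa: float = DEFAULT_PATM_KPA):
    """Convert a µmol mol-1 mole fraction to partial pressure in Pa."""
    return np.asarray(x_umol_mol, dtype=float) * patm_kpa * 1e-3


@dataclass
class ACiCurve:
    """One CO2-response curve with its treatment metadata.

    Point arrays are ordered as measured.  ``ETR`` may be absent (e.g. for
    maize, where no fluorescence-based gm is estimated).
    """

    Ca: np.ndarray
    Ci: np.ndarray
    AN: np.ndarray
    gs: np.ndarray
    Tleaf: np.ndarray
    species: str = ""
    growth_T: float = 25.0
    irrigation: str = "WW"
    meas_T: float = 25.0
    Rdark: float = 0.0
    ETR: Optional[np.ndarray] = None
    PPFD: Optional[np.ndarray] = None
    Fs: Optional[np.ndarray] = None
    Fm_prime: Optional[np.ndarray] = None
    Patm_kPa: float = DEFAULT_PATM_KPA
    curve_id: str = ""

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in (self.Ca, self.Ci, self.AN, self.gs, self.Tleaf)]
        self.Ca, self.Ci, self.AN, self.gs, self.Tleaf = arrays
        n = len(self.Ca)
        if any(len(a) != n for a in arrays):
            raise ValueError("point arrays must share a common length")
        for name in ("ETR", "PPFD", "Fs", "Fm_prime"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if len(val) != n:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, val)
        if self.Rdark < 0:
            raise ValueError("Rdark must be non-negative")

    def __len__(self) -> int:
        return len(self.Ca)

    @property
    def Ci_Pa(self) -> np.ndarray:
        return mole_fraction_to_pa(self.Ci, self.Patm_kPa)


@dataclass
class C3FitResult:
    """FvCB parameter estimates with per-point diagnostics."""

    Vcmax: float
    Jmax: float
    RL: float
    gm: float | np.ndarray
    Cc_Pa: np.ndarray
    limitation: list[str]
    residual_sse: float
    Vcmax_SE: float = np.nan
    Jmax_SE: float = np.nan
    jmax_identifiable: bool = True
    n_points: int = 0
    excluded_points: list[int] = field(default_factory=list)

    @property
    def jmax_vcmax_ratio(self) -> float:
        return self.Jmax / self.Vcmax

    def to_dict(self) -> dict:
        gm = self.gm
        return {
            "Vcmax": self.Vcmax,
            "Jmax": self.Jmax,
            "RL": self.RL,
            "gm_bar": float(np.mean(gm)) if np.ndim(gm) else float(gm),
            "Vcmax_SE": self.Vcmax_SE,
            "Jmax_SE": self.Jmax_SE,
            "Jmax_Vcmax": self.jmax_vcmax_ratio,
            "residual_sse": self.residual_sse,
            "jmax_identifiable": self.jmax_identifiable,
            "n_points": self.n_points,
            "limitation": self.limitation,
        }


def rl_from_rdark(rdark: float) -> float:
    """Day respiration taken as half the pre-dawn dark respiration."""
    if rdark < 0:
        raise ValueError("Rdark must be non-negative")
    return 0.5 * rdark


def gm_variable_j(
    an: np.ndarray,
    ci_pa: np.ndarray,
    etr: np.ndarray,
    rl: float,
    gamma_star_pa: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point mesophyll conductance by the variable-J method.

    Returns ``(gm, admissible)`` where ``gm`` is in mol m-2 s-1 bar-1
    (NaN at inadmissible points) and ``admissible`` is a boolean mask.
    A point is inadmissible when ETR <= 4(AN+RL) (electron transport
    cannot support the observed assimilation plus photorespiration), when
    the implied Cc drawdown denominator is non-positive, or when the
    resulting conductance is non-positive.  Such points are excluded and
    logged, never fatal for the curve.
    """
    an = np.asarray(an, dtype=float)
    ci_pa = np.asarray(ci_pa, dtype=float)
    etr = np.asarray(etr, dtype=float)
    gm = np.full_like(an, np.nan)
    surplus = etr - 4.0 * (an + rl)
    admissible = surplus > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        cc_implied = gamma_star_pa * (etr + 8.0 * (an + rl)) / surplus
        denom = ci_pa - cc_implied
    admissible &= denom > 0
    ratio = np.where(admissible, an / np.where(denom > 0, denom, np.nan), np.nan)
    # zero flux gives gm = 0 (estimable limit); negative flux is inadmissible
    admissible &= np.nan_to_num(ratio, nan=-1.0) >= 0
    gm[admissible] = GM_PA_TO_BAR * ratio[admissible]
    n_bad = int((~admissible).sum())
    if n_bad:
        logger.warning(
            "variable-J gm: %d of %d points inadmissible (ETR deficit or "
            "non-positive drawdown); excluded",
            n_bad,
            len(an),
        )
    return gm, admissible


def cc_from_ci(ci, an, gm):
    """Chloroplastic CO2 from intercellular CO2: Cc = Ci - AN/gm.

    Units must pair: Ci in Pa with gm in µmol m-2 s-1 Pa-1, or Ci in
    µmol mol-1 with gm in mol m-2 s-1 (per mole fraction).  For gm in
    mol m-2 s-1 bar-1 and Ci in Pa use ``gm / GM_PA_TO_BAR``.
    """
    ci = np.asarray(ci, dtype=float)
    an = np.asarray(an, dtype=float)
    if np.any(np.asarray(gm) <= 0):
        raise ValueError("gm must be positive")
    return ci - an / gm


def c3_forward(
    cc_pa,
    vcmax: float,
    jmax: float,
    rl: float,
    kin: RubiscoKineticSet,
    o_kpa: float = OXYGEN_KPA_C3,
):
    """Net assimilation of the FvCB model on a Cc (Pa) basis.

    A = min(Ac, Aj) - RL with Ac = Vcmax(Cc-G*)/(Cc + Kc(1+O/Ko)) and
    Aj = J(Cc-G*)/(4Cc + 8G*).  At saturating light the operating
    electron transport is taken at its maximum, J = Jmax.
    Exactly -RL at Cc = Gamma*.
    """
    cc = np.asarray(cc_pa, dtype=float)
    gs_ = kin.gamma_star_Pa
    kapp = kin.kc_app_Pa(o_kpa)
    ac = vcmax * (cc - gs_) / (cc + kapp)
    aj = jmax * (cc - gs_) / (4.0 * cc + 8.0 * gs_)
    out = np.minimum(ac, aj) - rl
    return float(out) if out.ndim == 0 else out


def _limitation_labels(cc_pa, vcmax, jmax, kin, o_kpa) -> list[str]:
    cc = np.asarray(cc_pa, dtype=float)
    gs_ = kin.gamma_star_Pa
    ac = vcmax * (cc - gs_) / (cc + kin.kc_app_Pa(o_kpa))
    aj = jmax * (cc - gs_) / (4.0 * cc + 8.0 * gs_)
    return ["rubisco" if a <= b else "rubp" for a, b in zip(ac, aj)]


_VCMAX_STARTS = (30.0, 60.0, 120.0, 250.0)
_JMAX_STARTS = (60.0, 120.0, 250.0, 500.0)


def fit_vcmax_jmax(
    cc_pa: np.ndarray,
    an: np.ndarray,
    kin: RubiscoKineticSet,
    rl: float,
    o_kpa: float = OXYGEN_KPA_C3,
    gm: float | np.ndarray = np.nan,
) -> C3FitResult:
    """Least-squares FvCB fit of (Vcmax, Jmax) on an A-Cc curve.

    Multi-start nonlinear least squares over a fixed coarse grid of
    initial values (deterministic ordering, no randomness).  Reports
    per-point limitation labels and parameter standard errors from the
    residual covariance.  Jmax is flagged non-identifiable when a pure
    Rubisco-limited fit explains the curve as well as the joint fit (the
    curve never reaches the RuBP-regeneration branch).
    """
    cc = np.asarray(cc_pa, dtype=float)
    an = np.asarray(an, dtype=float)
    if len(cc) < 5:
        raise FitError(f"need >= 5 points for a fit, got {len(cc)}")

    def resid(theta):
        return c3_forward(cc, theta[0], theta[1], rl, kin, o_kpa) - an

    best = None
    for vc0 in _VCMAX_STARTS:
        for jm0 in _JMAX_STARTS:
            try:
                sol = optimize.least_squares(
                    resid, x0=[vc0, jm0], bounds=([0.1, 0.1], [2000.0, 3000.0]),
                    method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=300,
                )
            except Exception:  # pragma: no cover - solver pathologies
                continue
            if best is None or sol.cost < best.cost - 1e-12:
                best = sol
    if best is None or best.status < 0:
        raise FitError(
            "FvCB fit did not converge from any start",
            diagnostics={"n_points": len(cc)},
        )
    vcmax, jmax = best.x
    labels = _limitation_labels(cc, vcmax, jmax, kin, o_kpa)
    n_rub = labels.count("rubisco")
    n_rubp = labels.count("rubp")
    if min(n_rub, n_rubp) < 3:
        warnings.warn(
            f"only {n_rub} Rubisco-limited / {n_rubp} RuBP-limited points; "
            "degraded identifiability",
            stacklevel=2,
        )
    sse = float(2.0 * best.cost)
    dof = max(len(cc) - 2, 1)
    try:
        jac = best.jac
        cov = np.linalg.inv(jac.T @ jac) * sse / dof
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.array([np.nan, np.nan])
    # Jmax identifiability: does removing the RuBP branch cost anything?
    def resid_rubisco_only(theta):
        gs_ = kin.gamma_star_Pa
        return theta[0] * (cc - gs_) / (cc + kin.kc_app_Pa(o_kpa)) - rl - an

    sol_rub = optimize.least_squares(
        resid_rubisco_only, x0=[max(vcmax, 1.0)], bounds=([0.1], [2000.0]),
        method="trf", xtol=1e-10, ftol=1e-10, max_nfev=300,
    )
    sse_rub = float(2.0 * sol_rub.cost)
    identifiable = n_rubp > 0 and sse_rub > sse + max(1e-6 * max(sse, 1.0), 1e-8)
    return C3FitResult(
        Vcmax=float(vcmax),
        Jmax=float(jmax),
        RL=rl,
        gm=gm,
        Cc_Pa=cc,
        limitation=labels,
        residual_sse=sse,
        Vcmax_SE=float(se[0]),
        Jmax_SE=float(se[1]),
        jmax_identifiable=identifiable,
        n_points=len(cc),
    )


def _ethier_branch_roots(ci, g, vmax_like, k_lo, k_hi, rl):
    # smaller root of x^2 - b x + c = 0 for the finite-gm FvCB branch
    # written generically: (x+RL)(Ci - x/g + k_hi) = vmax_like (Ci - x/g - k_lo)
    b = g * (ci + k_hi) + vmax_like - rl
    c = g * (vmax_like * (ci - k_lo) - rl * (ci + k_hi))
    disc = np.maximum(b * b - 4.0 * c, 0.0)
    return 0.5 * (b - np.sqrt(disc))


def _ethier_model(ci_pa, vcmax, jmax, g, rl, kin, o_kpa):
    gs_ = kin.gamma_star_Pa
    kapp = kin.kc_app_Pa(o_kpa)
    ac = _ethier_branch_roots(ci_pa, g, vcmax, gs_, kapp, rl)
    # RuBP branch: (x+RL)(4Cc+8G*) = J(Cc-G*) -> divide by 4 to reuse the form
    aj = _ethier_branch_roots(ci_pa, g, jmax / 4.0, gs_, 2.0 * gs_, rl)
    return np.minimum(ac, aj)


def fvcb_finite_gm(ci_pa, vcmax, jmax, gm_bar, rl, kin, o_kpa: float = OXYGEN_KPA_C3):
    """Net assimilation on a Ci (Pa) basis with a finite mesophyll conductance.

    Closed-form (quadratic) solution of the coupled system
    A = FvCB(Ci - A/gm); ``gm_bar`` in mol m-2 s-1 bar-1.  This is both
    the forward model behind the single-gm curve fit and the steady-state
    solver used by the synthetic-data generator.
    """
    g = np.asarray(gm_bar, dtype=float) / GM_PA_TO_BAR
    return _ethier_model(np.asarray(ci_pa, dtype=float), vcmax, jmax, g, rl, kin, o_kpa)


def gm_ethier(
    ci_pa: np.ndarray,
    an: np.ndarray,
    kin: RubiscoKineticSet,
    rl: float,
    o_kpa: float = OXYGEN_KPA_C3,
) -> tuple[float, C3FitResult]:
    """Curve-level gm by the finite-gm quadratic FvCB fit on a Ci basis.

    Treats gm as a single shared parameter across the curve, fitted
    jointly with Vcmax and Jmax.  Returns ``(gm [mol m-2 s-1 bar-1],
    C3FitResult)`` where the result's Cc values derive from the fitted gm.
    """
    ci = np.asarray(ci_pa, dtype=float)
    an = np.asarray(an, dtype=float)
    if len(ci) < 5:
        raise FitError(f"need >= 5 points for a fit, got {len(ci)}")

    def resid(theta):
        return _ethier_model(ci, theta[0], theta[1], theta[2], rl, kin, o_kpa) - an

    best = None
    for vc0 in (50.0, 120.0, 250.0):
        for jm0 in (100.0, 250.0):
            for g0 in (0.5, 2.0, 8.0):  # µmol m-2 s-1 Pa-1
                try:
                    sol = optimize.least_squares(
                        resid, x0=[vc0, jm0, g0],
                        bounds=([0.1, 0.1, 1e-3], [2000.0, 3000.0, 1e3]),
                        method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=300,
                    )
                except Exception:  # pragma: no cover
                    continue
                if best is None or sol.cost < best.cost - 1e-12:
                    best = sol
    if best is None or best.status < 0:
        raise FitError("finite-gm FvCB fit did not converge from any start")
    vcmax, jmax, g = best.x
    cc = ci - _ethier_model(ci, vcmax, jmax, g, rl, kin, o_kpa) / g
    labels = _limitation_labels(cc, vcmax, jmax, kin, o_kpa)
    gm_bar = float(GM_PA_TO_BAR * g)
    res = C3FitResult(
        Vcmax=float(vcmax),
        Jmax=float(jmax),
        RL=rl,
        gm=gm_bar,
        Cc_Pa=cc,
        limitation=labels,
        residual_sse=float(2.0 * best.cost),
        jmax_identifiable=labels.count("rubp") > 0,
        n_points=len(ci),
    )
    return gm_bar, res


def fit_c3_curve(
    curve: ACiCurve,
    kinetics_source: str = "own",
    variant: str = "cc_basis",
    rl_mode: str = "half-rdark",
    gm_mode: str = "scalar",
    optics: LeafOptics = LeafOptics(),
    o_kpa: float = OXYGEN_KPA_C3,
) -> C3FitResult:
    """Full C3 pipeline for one curve: kinetics, gm, Cc conversion, fit.

    ``kinetics_source`` is "own" (species-specific constants at the curve's
    measurement temperature) or "bernacchi" (tobacco standards; ``variant``
    selects the published response set).  ``gm_mode``: "scalar" (default)
    averages the admissible per-point variable-J values into one curve-level
    gm before the Cc conversion; "per-point" uses each point's own gm.
    """
    if kinetics_source == "own":
        kin = own_kinetics(curve.species, curve.meas_T)
        if isinstance(kin, tuple):
            kin = kin[0]
    elif kinetics_source == "bernacchi":
        kin = standard_kinetics("bernacchi", curve.meas_T, variant=variant)
    else:
        raise ValueError(f"unknown kinetics source {kinetics_source!r}")

    if rl_mode not in ("half-rdark", "free"):
        raise ValueError(f"unknown rl_mode {rl_mode!r}")
    rl = rl_from_rdark(curve.Rdark)

    if curve.ETR is None:
        raise ValueError("curve has no ETR; variable-J gm needs fluorescence")
    ci_pa = curve.Ci_Pa
    gm_pts, mask = gm_variable_j(curve.AN, ci_pa, curve.ETR, rl, kin.gamma_star_Pa)
    if mask.sum() < 5:
        raise FitError(
            f"only {int(mask.sum())} admissible variable-J points; need >= 5"
        )
    if gm_mode == "scalar":
        gm_used: float | np.ndarray = float(np.nanmean(gm_pts[mask]))
        g_pa = gm_used / GM_PA_TO_BAR
        cc = cc_from_ci(ci_pa[mask], curve.AN[mask], g_pa)
    elif gm_mode == "per-point":
        gm_used = gm_pts[mask]
        cc = cc_from_ci(ci_pa[mask], curve.AN[mask], gm_used / GM_PA_TO_BAR)
    else:
        raise ValueError(f"unknown gm_mode {gm_mode!r}")

    valid = cc > 0
    if valid.sum() < 5:
        raise FitError("fewer than 5 points with positive Cc after conversion")
    if not valid.all():
        logger.warning("%d points with non-positive Cc excluded", int((~valid).sum()))
    an_fit = curve.AN[mask][valid]
    cc_fit = cc[valid]

    if rl_mode == "free":
        res = _fit_with_free_rl(cc_fit, an_fit, kin, rl, o_kpa)
    else:
        res = fit_vcmax_jmax(cc_fit, an_fit, kin, rl, o_kpa=o_kpa, gm=gm_used)
    res.gm = gm_used
    res.excluded_points = list(np.flatnonzero(~mask))
    return res


def _fit_with_free_rl(cc, an, kin, rl0, o_kpa) -> C3FitResult:
    def resid(theta):
        return c3_forward(cc, theta[0], theta[1], theta[2], kin, o_kpa) - an

    best = None
    for vc0 in _VCMAX_STARTS:
        for jm0 in _JMAX_STARTS:
            sol = optimize.least_squares(
                resid, x0=[vc0, jm0, max(rl0, 0.1)],
                bounds=([0.1, 0.1, 0.0], [2000.0, 3000.0, 20.0]),
                method="trf", xtol=1e-10, ftol=1e-10, max_nfev=300,
            )
            if best is None or sol.cost < best.cost - 1e-12:
                best = sol
    if best is None or best.status < 0:
        raise FitError("free-RL FvCB fit did not converge")
    vcmax, jmax, rl = best.x
    labels = _limitation_labels(cc, vcmax, jmax, kin, o_kpa)
    return C3FitResult(
        Vcmax=float(vcmax), Jmax=float(jmax), RL=float(rl), gm=np.nan,
        Cc_Pa=cc, limitation=labels, residual_sse=float(2.0 * best.cost),
        jmax_identifiable=labels.count("rubp") > 0, n_points=len(cc),
    )
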