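"""Own-versus-standard kinetics bias analysis.

Using "standard" tobacco Rubisco constants instead of species-specific
ones systematically biases FvCB parameter estimates, because the apparent
Michaelis constant Kc(1+O/Ko) and Gamma* differ between Rubiscos.  This
module (a) refits curves under an alternative kinetics source with the
identical pipeline (including gm re-estimation with the alternative
Gamma*), and (b) summarizes paired estimates with an OLS regression of
the own-kinetics estimate on the standard-kinetics estimate plus the mean
percent overestimation 100 (standard/own - 1).

Packaged fixtures transcribe the study's paired Vcmax/Jmax comparison for
the two C3 species and the Vcmax/Vpmax comparison for maize; a loader
verifies the transcription checksum.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .c3 import ACiCurve, fit_c3_curve
from .c4 import C4Constants, fit_c4
from .kinetics import own_kinetics, standard_kinetics

__all__ = [
    "ComparisonRecord",
    "BiasSummary",
    "load_c3_comparison",
    "load_c4_comparison",
    "refit_with_kinetics",
    "bias_summary",
]

_CHECKSUMS = {
    "c3_vcmax_jmax_comparison.csv": "sha256:cff3b0840a2005d945592e19735e4c47eb9bbca580013a10197223b97b48c68b",
    "c4_vcmax_vpmax_comparison.csv": "sha256:05a52c3e4e7ad24475299dc0f126466dd1345500d3f56d1295c030a8421f7492",
}


@dataclass(frozen=True)
class ComparisonRecord:
    """One paired parameter estimate under two kinetics sources."""

    species: str
    growth_T: float
    irrigation: str
    meas_T: float
    parameter: str  # Vcmax | Jmax | Vpmax
    estimate_own: float
    estimate_standard: float
    se_own: float = float("nan")
    se_standard: float = float("nan")

    def __post_init__(self) -> None:
        if self.estimate_own <= 0 or self.estimate_standard <= 0:
            raise ValueError("estimates must be positive")


@dataclass(frozen=True)
class BiasSummary:
    """OLS own~standard summary plus percent-overestimation statistics."""

    slope: float
    intercept: float
    r_squared: float
    mean_pct_over: float
    per_row_pct: tuple[float, ...]
    n: int


def _load_checked_csv(name: str) -> pd.DataFrame:
    raw = resources.files("acifit.data").joinpath(name).read_bytes()
    digest = "sha256:" + hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(
            f"packaged fixture {name} failed its transcription checksum "
            f"({digest} != {_CHECKSUMS[name]})"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_c3_comparison() -> pd.DataFrame:
    """Paired Vcmax/Jmax (own vs tobacco kinetics) for rice and wheat."""
    return _load_checked_csv("c3_vcmax_jmax_comparison.csv")


def load_c4_comparison() -> pd.DataFrame:
    """Paired Vcmax/Vpmax (own vs C4-standard kinetics) for maize."""
    return _load_checked_csv("c4_vcmax_vpmax_comparison.csv")


def comparison_records(df: pd.DataFrame, parameter: str) -> list[ComparisonRecord]:
    """Turn a comparison table into paired records for one parameter."""
    own_col, std_col = f"{parameter}_own", f"{parameter}_std"
    out = []
    for _, r in df.iterrows():
        out.append(
            ComparisonRecord(
                species=r.species,
                growth_T=float(r.growth_T_C),
                irrigation=r.irrigation,
                meas_T=float(r.meas_T_C),
                parameter=parameter,
                estimate_own=float(r[own_col]),
                estimate_standard=float(r[std_col]),
                se_own=float(r.get(f"{own_col}_SE", float("nan"))),
                se_standard=float(r.get(f"{std_col}_SE", float("nan"))),
            )
        )
    return out


def refit_with_kinetics(
    curves: list[ACiCurve],
    standard_source: str = "bernacchi",
    variant: str = "cc_basis",
    **fit_kwargs,
) -> list[ComparisonRecord]:
    """Refit each curve under own and standard kinetics; return paired records.

    The identical pipeline runs twice: for C3 curves the gm estimation is
    repeated with the alternative Gamma* before the Cc conversion.  Fit
    failures are propagated per curve (the pair is skipped with its error
    recorded in the returned record list's gaps), never fatal for the batch.
    """
    records: list[ComparisonRecord] = []
    for curve in curves:
        try:
            if standard_source == "voncaemmerer":
                rub_own, pep_own = own_kinetics(curve.species, curve.meas_T)
                rub_std, pep_std = standard_kinetics("voncaemmerer", curve.meas_T)
                f_own = fit_c4(curve, rub_own, pep_own, C4Constants(), **fit_kwargs)
                f_std = fit_c4(curve, rub_std, pep_std, C4Constants(), **fit_kwargs)
                pairs = [("Vcmax", f_own.Vcmax, f_std.Vcmax), ("Vpmax", f_own.Vpmax, f_std.Vpmax)]
            else:
                f_own = fit_c3_curve(curve, kinetics_source="own", **fit_kwargs)
                f_std = fit_c3_curve(
                    curve, kinetics_source=standard_source, variant=variant, **fit_kwargs
                )
                pairs = [("Vcmax", f_own.Vcmax, f_std.Vcmax), ("Jmax", f_own.Jmax, f_std.Jmax)]
        except Exception as exc:  # propagate per-row, keep the batch alive
            import logging

            logging.getLogger(__name__).warning(
                "refit failed for curve %s: %s", curve.curve_id, exc
            )
            continue
        for name, own_v, std_v in pairs:
            records.append(
                ComparisonRecord(
                    species=curve.species,
                    growth_T=curve.growth_T,
                    irrigation=curve.irrigation,
                    meas_T=curve.meas_T,
                    parameter=name,
                    estimate_own=own_v,
                    estimate_standard=std_v,
                )
            )
    return records


def bias_summary(records: list[ComparisonRecord]) -> BiasSummary:
    """OLS (with intercept) of own on standard, plus percent overestimation.

    The regression direction puts the own-kinetics estimate on the
    vertical axis; percent overestimation per row is
    100 (standard/own - 1), pooled as an unweighted mean.
    """
    if len(records) < 3:
        raise ValueError("need >= 3 paired records")
    own = np.array([r.estimate_own for r in records])
    std = np.array([r.estimate_standard for r in records])
    if np.var(std) == 0:
        raise ValueError("degenerate regression: standard estimates have no variance")
    res = sm.OLS(own, sm.add_constant(std)).fit()
    pct = 100.0 * (std / own - 1.0)
    return BiasSummary(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        mean_pct_over=float(pct.mean()),
        per_row_pct=tuple(pct),
        n=len(records),
    )
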