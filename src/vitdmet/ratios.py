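"""Model-informed metabolite ratios.

At steady state the reduced kinetic model implies three pathway-activity
ratios computable from a serum panel alone:

* ``alpha = c125 * (K + c25) / c25`` (nM) — 1a-hydroxylation activity; on a
  steady-state panel it equals a/k7, the ratio of maximal activation rate to
  active-hormone clearance.
* ``beta = cEpi25 / c25`` — epimerisation activity, equal to k3/k8.
* ``gamma = c2425 / c25`` — 24-hydroxylation activity, equal to k4/k6.

beta and gamma are invariant under common rescaling of all concentrations;
alpha needs the Michaelis constant K of the activation step, which is a
cohort-level configuration value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MetabolitePanel",
    "RatioTriple",
    "UndefinedRatioError",
    "compute_ratios",
    "ratios_for_cohort",
    "DEFAULT_C25_FLOOR",
    "METABOLITE_COLUMNS",
    "RATIO_COLUMNS",
]

#: Below this 25(OH)D3 level (nM) ratios are flagged unreliable rather than
#: computed; matches the assay's low quality-control level.
DEFAULT_C25_FLOOR = 0.5

METABOLITE_COLUMNS = ("c25_nM", "c3epi25_nM", "c125_nM", "c2425_nM")
RATIO_COLUMNS = ("alpha_nM", "beta", "gamma")


class UndefinedRatioError(ValueError):
    """Raised when ratios are requested for a panel with c25 <= 0."""


@dataclass(frozen=True)
class MetabolitePanel:
    """One subject's serum panel (nM)."""

    c25: float
    c125: float
    c2425: float
    cEpi25: float


@dataclass(frozen=True)
class RatioTriple:
    alpha: float
    beta: float
    gamma: float
    flag: str = "ok"


def compute_ratios(panel, K: float, *, c25_floor: float = DEFAULT_C25_FLOOR) -> RatioTriple:
    """Compute (alpha, beta, gamma) from a panel.

    ``panel`` is any object with attributes c25, c125, c2425, cEpi25 — a
    :class:`MetabolitePanel` or a steady-state result.  Raises
    :class:`UndefinedRatioError` for c25 <= 0; panels with 0 < c25 below
    ``c25_floor`` get NaN ratios and flag ``"below_floor"``.
    """
    if K <= 0.0:
        raise ValueError(f"K must be > 0, got {K}")
    c25 = float(panel.c25)
    if not c25 > 0.0:
        raise UndefinedRatioError(f"ratios undefined for c25 = {c25}")
    if c25 < c25_floor:
        return RatioTriple(np.nan, np.nan, np.nan, flag="below_floor")
    alpha = float(panel.c125) * (K + c25) / c25
    beta = float(panel.cEpi25) / c25
    gamma = float(panel.c2425) / c25
    return RatioTriple(alpha, beta, gamma)


def ratios_for_cohort(
    table: pd.DataFrame, K: float, *, c25_floor: float = DEFAULT_C25_FLOOR
) -> pd.DataFrame:
    """Append alpha_nM / beta / gamma / ratio_flag columns to a cohort table.

    Subjects with a missing or non-positive 25(OH)D3 value, or missing any
    required metabolite, get NaN ratios and a descriptive flag instead of
    being dropped.  The K used is recorded in ``table.attrs["ratio_K_nM"]``.
    """
    if K <= 0.0:
        raise ValueError(f"K must be > 0, got {K}")
    for col in METABOLITE_COLUMNS:
        if col not in table.columns:
            raise KeyError(f"cohort table lacks metabolite column {col!r}")
    out = table.copy()
    c25 = out["c25_nM"].to_numpy(dtype=float)
    epi = out["c3epi25_nM"].to_numpy(dtype=float)
    c125 = out["c125_nM"].to_numpy(dtype=float)
    c2425 = out["c2425_nM"].to_numpy(dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = c125 * (K + c25) / c25
        beta = epi / c25
        gamma = c2425 / c25

    flags = np.full(len(out), "ok", dtype=object)
    missing_any = np.isnan(c25) | np.isnan(epi) | np.isnan(c125) | np.isnan(c2425)
    nonpos = ~np.isnan(c25) & (c25 <= 0.0)
    low = ~np.isnan(c25) & (c25 > 0.0) & (c25 < c25_floor)
    flags[missing_any] = "missing_metabolite"
    flags[nonpos] = "nonpositive_c25"
    flags[low & ~missing_any] = "below_floor"
    bad = missing_any | nonpos | low
    alpha[bad] = np.nan
    beta[bad] = np.nan
    gamma[bad] = np.nan
    # per-ratio availability: beta/gamma only need their own numerator + c25
    beta_ok = ~np.isnan(c25) & (c25 >= c25_floor) & ~np.isnan(epi)
    gamma_ok = ~np.isnan(c25) & (c25 >= c25_floor) & ~np.isnan(c2425)
    alpha_ok = ~np.isnan(c25) & (c25 >= c25_floor) & ~np.isnan(c125)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta[beta_ok] = epi[beta_ok] / c25[beta_ok]
        gamma[gamma_ok] = c2425[gamma_ok] / c25[gamma_ok]
        alpha[alpha_ok] = c125[alpha_ok] * (K + c25[alpha_ok]) / c25[alpha_ok]

    out["alpha_nM"] = alpha
    out["beta"] = beta
    out["gamma"] = gamma
    out["ratio_flag"] = flags
    out.attrs = dict(table.attrs)
    out.attrs["ratio_K_nM"] = float(K)
    return out
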