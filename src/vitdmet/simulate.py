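"""Synthetic cohort generator.

Each synthetic subject is treated as being at quasi-steady state of the
reduced kinetic model: the generator draws subject-level rate constants
log-normally around group means (optionally trending with gestational
week), solves the closed-form steady state, applies multiplicative
log-normal measurement noise, and masks entries at random to emulate
incomplete panels.  Group differences — e.g. an upregulated epimerisation
pathway in pre-eclampsia — are therefore planted as rate-constant
fold-changes whose ground truth is exactly recoverable from the ratio
transform on noiseless data.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import DEFAULT_K_NM, MOLECULAR_WEIGHTS, surrogate_reduced_params
from .kinetic_model import ReducedParams, reduced_steady_state

__all__ = [
    "GroupSpec",
    "NoiseSpec",
    "generate_cohort",
    "planted_pet_effect",
    "write_cohort_csv",
    "read_cohort_csv",
    "unit_convert",
    "random_reduced_params",
    "west_midlands_groups",
    "scope_groups",
    "DEFAULT_PARAMS_CV",
    "COLUMN_TO_METABOLITE",
]

#: metabolite column -> analyte name in the molar-mass table
COLUMN_TO_METABOLITE = {
    "c25_nM": "25(OH)D3",
    "c3epi25_nM": "3-epi-25(OH)D3",
    "c125_nM": "1,25(OH)2D3",
    "c2425_nM": "24,25(OH)2D3",
    "c25D2_nM": "25(OH)D2",
}
_SS_TO_COLUMN = {
    "c25": "c25_nM",
    "cEpi25": "c3epi25_nM",
    "c125": "c125_nM",
    "c2425": "c2425_nM",
}
_RATE_KEYS = ("P25", "a", "k3", "k4", "k5", "k6", "k7", "k8")

#: Between-subject coefficients of variation of the rate constants.
#: Vitamin D supply (P25) varies far more across people than the enzymatic
#: rates do.
DEFAULT_PARAMS_CV = {
    "P25": 0.5,
    "a": 0.2, "k3": 0.2, "k4": 0.2, "k5": 0.2, "k6": 0.2, "k7": 0.2, "k8": 0.2,
}


@dataclass(frozen=True)
class GroupSpec:
    """Generating description of one subject group."""

    name: str
    n: int
    params_mean: ReducedParams
    week_range: tuple | None = None  # None => non-pregnant, no gestational week
    params_cv: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS_CV))
    trend: dict = field(default_factory=dict)  # param -> fractional change per week

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if any(cv < 0 for cv in self.params_cv.values()):
            raise ValueError("coefficients of variation must be >= 0")
        if self.week_range is not None:
            lo, hi = self.week_range
            if not (0 <= lo <= hi):
                raise ValueError(f"bad week_range {self.week_range}")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-layer description: assay noise, dropout, detection floor."""

    sigma_meas: float = 0.08  # log-scale SD per metabolite (assay RSD ~5-10%)
    missing_prob: float = 0.05  # independent per metabolite
    floor: float = 0.01  # nM; values below are unquantifiable -> missing

    def __post_init__(self) -> None:
        if self.sigma_meas < 0:
            raise ValueError("sigma_meas must be >= 0")
        if not 0.0 <= self.missing_prob <= 1.0:
            raise ValueError("missing_prob must be in [0, 1]")
        if self.floor < 0:
            raise ValueError("floor must be >= 0")


def _config_hash(groups, noise) -> str:
    txt = repr([repr(g) for g in groups]) + repr(noise)
    return hashlib.sha1(txt.encode()).hexdigest()[:12]


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-one multiplicative factor with the given coefficient of variation."""
    if cv == 0.0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def generate_cohort(
    groups,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    *,
    include_d2: bool = True,
    d2_mean_nM: float = 3.0,
    d2_log_sd: float = 0.5,
) -> pd.DataFrame:
    """Generate a cohort table from group specs; deterministic given seed.

    Columns: subject_id, group, gestational_week, c25_nM, c3epi25_nM,
    c125_nM, c2425_nM, [c25D2_nM], missing_mask.  ``include_d2`` adds a
    model-independent fifth analyte (25(OH)D2) so five-metabolite analyses
    can be exercised.  Provenance (seed, config hash) lives in
    ``table.attrs``.
    """
    noise = noise or NoiseSpec()
    groups = list(groups)
    for g in groups:
        if not isinstance(g, GroupSpec):
            raise TypeError(f"expected GroupSpec, got {type(g)!r}")
    rng = np.random.default_rng(seed)
    met_cols = list(_SS_TO_COLUMN.values())
    rows = []
    sid = 0
    for g in groups:
        for _ in range(g.n):
            sid += 1
            week = (
                float(rng.uniform(*g.week_range)) if g.week_range is not None else np.nan
            )
            w_eff = 0.0 if np.isnan(week) else week
            vals = {}
            for key in _RATE_KEYS:
                v = getattr(g.params_mean, key)
                v *= 1.0 + g.trend.get(key, 0.0) * w_eff
                v *= _lognormal_factor(rng, g.params_cv.get(key, 0.0))
                vals[key] = v
            params = ReducedParams(K=g.params_mean.K, **vals)
            ss = reduced_steady_state(params)
            panel = {
                col: getattr(ss, name) * math.exp(rng.normal(0.0, noise.sigma_meas))
                if noise.sigma_meas > 0
                else getattr(ss, name)
                for name, col in _SS_TO_COLUMN.items()
            }
            if include_d2:
                panel["c25D2_nM"] = d2_mean_nM * math.exp(
                    rng.normal(-0.5 * d2_log_sd**2, d2_log_sd)
                )
            missing = []
            cols = met_cols + (["c25D2_nM"] if include_d2 else [])
            for col in cols:
                if rng.uniform() < noise.missing_prob or panel[col] < noise.floor:
                    panel[col] = np.nan
                    missing.append(col)
            rows.append(
                {
                    "subject_id": f"S{sid:04d}",
                    "group": g.name,
                    "gestational_week": week,
                    **panel,
                    "missing_mask": ";".join(missing),
                }
            )
    columns = ["subject_id", "group", "gestational_week", *met_cols]
    if include_d2:
        columns.append("c25D2_nM")
    columns.append("missing_mask")
    table = pd.DataFrame(rows, columns=columns)
    table.attrs["seed"] = int(seed)
    table.attrs["config_hash"] = _config_hash(groups, noise)
    table.attrs["units"] = "nM"
    return table


def planted_pet_effect(
    base: GroupSpec,
    fold_changes: dict,
    *,
    name: str = "PET",
    n: int | None = None,
    week_range=None,
) -> GroupSpec:
    """A case group identical to ``base`` except for rate-constant fold-changes.

    E.g. ``{"k3": 2.0}`` doubles the epimerisation rate, which doubles the
    planted beta ratio; ``{"k7": m}`` scales the planted alpha by 1/m.
    """
    if any(m <= 0 for m in fold_changes.values()):
        raise ValueError("fold-change multipliers must be > 0")
    unknown = set(fold_changes) - set(_RATE_KEYS)
    if unknown:
        raise KeyError(f"unknown rate constants in fold_changes: {sorted(unknown)}")
    new_params = replace(
        base.params_mean,
        **{k: getattr(base.params_mean, k) * m for k, m in fold_changes.items()},
    )
    return GroupSpec(
        name=name,
        n=base.n if n is None else n,
        params_mean=new_params,
        week_range=base.week_range if week_range is None else week_range,
        params_cv=dict(base.params_cv),
        trend=dict(base.trend),
    )


# ---------------------------------------------------------------------------
# Cohort CSV I/O


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    """Write a cohort table with a provenance/unit header comment block."""
    with open(path, "w") as fh:
        fh.write(f"# units={table.attrs.get('units', 'nM')}\n")
        fh.write(f"# seed={table.attrs.get('seed', '')}\n")
        fh.write(f"# config_hash={table.attrs.get('config_hash', '')}\n")
        table.to_csv(fh, index=False, float_format="%.17g")


def read_cohort_csv(path, units: str | None = None) -> pd.DataFrame:
    """Read a cohort CSV, converting concentrations to nM if needed.

    The unit tag comes from the header comment unless overridden.  Duplicate
    subject ids, negative concentrations and malformed rows raise parse
    errors naming the offending row.
    """
    header = {}
    n_comments = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comments += 1
            if "=" in line:
                k, v = line[1:].strip().split("=", 1)
                header[k.strip()] = v.strip()
    try:
        table = pd.read_csv(path, comment="#", engine="python", on_bad_lines="error")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed cohort CSV {path}: {exc}") from exc

    file_units = units or header.get("units", "nM")
    if file_units not in ("nM", "ng/mL"):
        raise ValueError(f"unknown unit tag {file_units!r}")

    dup = table["subject_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate subject ids at rows {list(table.index[dup] + n_comments + 2)}"
        )
    for col in table.columns:
        if col not in COLUMN_TO_METABOLITE:
            continue
        v = table[col].to_numpy(dtype=float)
        neg = v < 0.0
        if np.any(neg):
            bad = list(table.index[neg] + n_comments + 2)
            raise ValueError(f"negative concentration in {col} at rows {bad}")
        if file_units != "nM":
            table[col] = unit_convert(v, COLUMN_TO_METABOLITE[col], file_units, "nM")
    if "missing_mask" in table.columns:
        table["missing_mask"] = table["missing_mask"].fillna("")
    table.attrs["units"] = "nM"
    for key in ("seed", "config_hash"):
        if key in header:
            table.attrs[key] = int(header[key]) if key == "seed" and header[key] else header[key]
    return table


def unit_convert(value, metabolite: str, from_unit: str, to_unit: str):
    """Convert a concentration between ng/mL and nM for a known analyte."""
    units = {"nM", "ng/mL"}
    if from_unit not in units or to_unit not in units:
        raise ValueError(f"unsupported units {from_unit!r} -> {to_unit!r}")
    if metabolite not in MOLECULAR_WEIGHTS:
        raise KeyError(f"unknown metabolite {metabolite!r}")
    if from_unit == to_unit:
        return value
    mw = MOLECULAR_WEIGHTS[metabolite]
    factor = 1000.0 / mw if from_unit == "ng/mL" else mw / 1000.0
    return value * factor


# ---------------------------------------------------------------------------
# Stock group specifications and random parameter draws


def west_midlands_groups(
    pet_fold_changes: dict | None = None,
    params: ReducedParams | None = None,
) -> list:
    """Cross-sectional pregnancy cohort: non-pregnant, 1st- and 3rd-trimester
    normal pregnancies, and 3rd-trimester pre-eclampsia (20/25/21/22).

    Normal pregnancy carries a positive weekly trend in 1a-hydroxylation
    (the active hormone roughly doubles by term) and a mild trend in supply;
    the PET group defaults to a doubled epimerisation rate.
    """
    base = params or surrogate_reduced_params()
    trend = {"a": 0.025, "P25": 0.005}
    np3 = GroupSpec("NP3", 21, base, week_range=(37.0, 41.0), trend=trend)
    return [
        GroupSpec("nonpregnant", 20, base),
        GroupSpec("NP1", 25, base, week_range=(8.0, 13.0), trend=trend),
        np3,
        planted_pet_effect(np3, pet_fold_changes or {"k3": 2.0}, n=22),
    ]


def scope_groups(
    pet_fold_changes: dict | None = None,
    params: ReducedParams | None = None,
) -> list:
    """Second-trimester (15-week) cohort of prospective PET cases and matched
    controls (25/25); the planted effect is milder than at term, reflecting
    gradual dysregulation."""
    base = params or surrogate_reduced_params()
    trend = {"a": 0.025, "P25": 0.005}
    ctrl = GroupSpec("SCOPE_control", 25, base, week_range=(14.0, 16.0), trend=trend)
    return [
        ctrl,
        planted_pet_effect(ctrl, pet_fold_changes or {"k3": 1.2}, name="SCOPE_case"),
    ]


def random_reduced_params(
    rng: np.random.Generator,
    *,
    P25=(0.5, 20.0),
    a=(0.05, 5.0),
    K=(5.0, 100.0),
    k_range=(1e-3, 5.0),
) -> ReducedParams:
    """Log-uniform random positive parameter draw for property sweeps."""

    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return ReducedParams(
        P25=lu(*P25),
        a=lu(*a),
        K=lu(*K),
        k3=lu(*k_range),
        k4=lu(*k_range),
        k5=lu(*k_range),
        k6=lu(*k_range),
        k7=lu(*k_range),
        k8=lu(*k_range),
    )
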