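"""Default parameter sets, unit tables, and parameter-file I/O.

The reduced model can be fully parametrised from literature half-lives of
the circulating metabolites together with a reference serum panel: each
first-order loss rate is ln(2)/half-life, the branch rates k3 and k4 follow
from the steady-state concentration ratios, and the production and
activation terms are then fixed by the reference 25(OH)D3 and 1,25(OH)2D3
levels.  The shipped default is a **surrogate** built this way around a
healthy third-trimester panel; any fitted parameter set can be supplied
instead via a flat YAML/JSON file.
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .kinetic_model import FullParams, ReducedParams, rate_from_halflife

__all__ = [
    "DEFAULT_K_NM",
    "HALF_LIVES_DAYS",
    "REFERENCE_NP3_PANEL_NM",
    "surrogate_reduced_params",
    "write_params_yaml",
    "read_params_yaml",
    "MOLECULAR_WEIGHTS",
]

#: Surrogate Michaelis constant of the 1a-hydroxylation step (nM).
DEFAULT_K_NM = 25.0

#: Literature-scale circulating half-lives (days).  25(OH)D3 persists for
#: about two weeks; the active hormone turns over in hours; 24,25(OH)2D3 is
#: intermediate; the C3 epimer behaves like its parent.
HALF_LIVES_DAYS = {
    "25(OH)D3": 15.0,
    "1,25(OH)2D3": 0.2,
    "24,25(OH)2D3": 7.0,
    "3-epi-25(OH)D3": 15.0,
}

#: Reference healthy third-trimester serum panel (nM) used to anchor the
#: surrogate parameter set.
REFERENCE_NP3_PANEL_NM = {"c25": 50.0, "c125": 0.15, "c2425": 4.0, "cEpi25": 2.5}

#: Molar masses (g/mol) for ng/mL <-> nM conversion.
MOLECULAR_WEIGHTS = {
    "25(OH)D3": 400.64,
    "3-epi-25(OH)D3": 400.64,
    "1,25(OH)2D3": 416.64,
    "24,25(OH)2D3": 416.64,
    "25(OH)D2": 412.65,
}

REDUCED_KEYS = ("P25", "a", "K", "k3", "k4", "k5", "k6", "k7", "k8")
FULL_KEYS = (
    "P25", "a", "K", "k3", "V4", "k5", "k6", "V7", "k8",
    "k9", "k10", "k11", "k12", "p24", "k14",
)

PARAM_UNITS = {
    "P25": "nM/d", "a": "nM/d", "K": "nM", "p24": "nM/d",
    "V4": "1/(nM d)", "V7": "1/(nM d)",
}


def surrogate_reduced_params(
    K: float = DEFAULT_K_NM,
    half_lives: dict | None = None,
    panel: dict | None = None,
) -> ReducedParams:
    """Reduced-model parameters anchored to half-lives and a reference panel.

    The steady state of the returned parameter set reproduces ``panel``
    exactly.  This is a documented surrogate, not a fitted estimate.
    """
    hl = dict(HALF_LIVES_DAYS, **(half_lives or {}))
    p = dict(REFERENCE_NP3_PANEL_NM, **(panel or {}))
    s = rate_from_halflife(hl["25(OH)D3"])  # total first-order loss of 25(OH)D3
    k6 = rate_from_halflife(hl["24,25(OH)2D3"])
    k7 = rate_from_halflife(hl["1,25(OH)2D3"])
    k8 = rate_from_halflife(hl["3-epi-25(OH)D3"])
    k4 = k6 * p["c2425"] / p["c25"]
    k3 = k8 * p["cEpi25"] / p["c25"]
    k5 = s - k3 - k4
    if k5 <= 0.0:
        raise ValueError("branch rates exceed the total 25(OH)D3 loss rate")
    a = k7 * p["c125"] * (K + p["c25"]) / p["c25"]
    P25 = s * p["c25"] + a * p["c25"] / (K + p["c25"])
    return ReducedParams(P25=P25, a=a, K=K, k3=k3, k4=k4, k5=k5, k6=k6, k7=k7, k8=k8)


def write_params_yaml(params, path) -> None:
    """Write a parameter set as a flat key-value YAML file with a units block."""
    d = asdict(params)
    units = {k: PARAM_UNITS.get(k, "1/d") for k in d}
    with open(path, "w") as fh:
        yaml.safe_dump({**d, "units": units}, fh, sort_keys=False)


def read_params_yaml(path):
    """Read a reduced or full parameter set (detected by its keys)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw.pop("units", None)
    keys = set(raw)
    if keys == set(REDUCED_KEYS):
        return ReducedParams(**raw)
    if keys == set(FULL_KEYS):
        return FullParams(**raw)
    raise ValueError(
        f"parameter keys {sorted(keys)} match neither the reduced nor the full model"
    )
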