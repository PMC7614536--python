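"""Kinetic ODE models of the vitamin D metabolic network.

Two models are provided:

* the **full** model tracks six species — the storage pro-hormone 25(OH)D3,
  the active hormone 1,25(OH)2D3, the catabolite 24,25(OH)2D3, the epimers
  3-epi-25(OH)D3 and 3-epi-1a,25(OH)2D3, and the catabolic enzyme
  24-hydroxylase — coupled through 14 reaction rate terms;
* the **reduced** model keeps only the four metabolites measurable in serum,
  treats 24-hydroxylase as constant, and lumps losses into effective
  first-order rates.  Its steady state has a closed form: the 25(OH)D3
  concentration solves a quadratic, and the three downstream metabolites are
  rational functions of it.

The activation of 25(OH)D3 by 1a-hydroxylase is modelled as Michaelis–Menten
(it saturates at physiological substrate levels); every other reaction is
mass action.  Concentrations are in nM, time in days, throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "FullState",
    "FullParams",
    "ReducedState",
    "ReducedParams",
    "SteadyStateResult",
    "Trajectory",
    "KineticModelError",
    "IntegrationError",
    "full_rate_terms",
    "full_ode_rhs",
    "reduced_rate_terms",
    "reduced_ode_rhs",
    "integrate",
    "reduced_steady_state",
    "rate_from_halflife",
    "halflife_from_rate",
    "reduce_full_params",
    "FULL_SPECIES",
    "REDUCED_SPECIES",
]

FULL_SPECIES = ("c25", "c125", "c2425", "cEpi25", "cEpi125", "cEnz")
REDUCED_SPECIES = ("c25", "c125", "c2425", "cEpi25")


class KineticModelError(ValueError):
    """Invalid state or parameters for a kinetic model operation."""


class IntegrationError(RuntimeError):
    """ODE solver failure; carries the solver's diagnostic message."""


def _check_nonneg(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0.0:
        raise KineticModelError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class FullState:
    """Concentrations (nM) of the six species tracked by the full model."""

    c25: float
    c125: float
    c2425: float
    cEpi25: float
    cEpi125: float
    cEnz: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_nonneg(f.name, getattr(self, f.name))

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in FULL_SPECIES], dtype=float)


@dataclass(frozen=True)
class FullParams:
    """Rate constants of the full model.

    Units: P25, a, p24 in nM/d; K in nM; k3..k14 in 1/d; V4, V7 in 1/(nM d).
    """

    P25: float
    a: float
    K: float
    k3: float
    V4: float
    k5: float
    k6: float
    V7: float
    k8: float
    k9: float
    k10: float
    k11: float
    k12: float
    p24: float
    k14: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_nonneg(f.name, getattr(self, f.name))
        if self.K <= 0.0:
            raise KineticModelError(f"Michaelis constant K must be > 0, got {self.K}")


@dataclass(frozen=True)
class ReducedState:
    """Concentrations (nM) of the four measured metabolites."""

    c25: float
    c125: float
    c2425: float
    cEpi25: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_nonneg(f.name, getattr(self, f.name))

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in REDUCED_SPECIES], dtype=float)


@dataclass(frozen=True)
class ReducedParams:
    """Rate constants of the reduced model.

    P25 and a in nM/d, K in nM, k3..k8 in 1/d.  k3, k4, k5 are the parallel
    first-order losses of 25(OH)D3 (epimerisation, 24-hydroxylation,
    degradation); k6, k7, k8 are the effective losses of the three
    downstream metabolites and must be positive for a steady state to exist.
    """

    P25: float
    a: float
    K: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_nonneg(f.name, getattr(self, f.name))
        if self.K <= 0.0:
            raise KineticModelError(f"Michaelis constant K must be > 0, got {self.K}")
        for name in ("k6", "k7", "k8"):
            if getattr(self, name) <= 0.0:
                raise KineticModelError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.k3 + self.k4 + self.k5 <= 0.0:
            raise KineticModelError("k3 + k4 + k5 must be > 0")


@dataclass(frozen=True)
class SteadyStateResult:
    """Steady-state concentrations of the reduced model (nM)."""

    c25: float
    c125: float
    c2425: float
    cEpi25: float
    discriminant_ok: bool = True

    def as_array(self) -> np.ndarray:
        return np.array([self.c25, self.c125, self.c2425, self.cEpi25], dtype=float)


@dataclass(frozen=True)
class Trajectory:
    """A solved time course: ``states[i]`` is the state vector at ``times[i]``."""

    times: np.ndarray
    states: np.ndarray
    model_tag: str
    species: tuple = field(default=REDUCED_SPECIES)

    def terminal(self) -> np.ndarray:
        return self.states[-1]


# ---------------------------------------------------------------------------
# Rate terms and right-hand sides


def full_rate_terms(state, params: FullParams, *, r10_from_2425: bool = False) -> dict:
    """The 14 reaction rates (nM/d) of the full model.

    R1 basal production of 25(OH)D3; R2 Michaelis–Menten activation to
    1,25(OH)2D3; R3 epimerisation of 25(OH)D3; R4 enzymatic 24-hydroxylation
    of 25(OH)D3; R5 degradation of 25(OH)D3; R6 catabolism of 24,25(OH)2D3;
    R7 enzymatic catabolism of 1,25(OH)2D3; R8 activation of the epimer;
    R9 VDR-mediated loss of 1,25(OH)2D3; R10 epimerisation of 1,25(OH)2D3;
    R11 VDR-mediated loss of the active epimer; R12 enzyme induction by
    1,25(OH)2D3; R13 basal enzyme production; R14 enzyme degradation.

    ``r10_from_2425`` switches the R10 substrate to 24,25(OH)2D3, a variant
    formulation kept for comparison; the default drives it by 1,25(OH)2D3,
    consistent with the mass balances in which R10 drains the active hormone
    and feeds its epimer, and with the network diagram.
    """
    if not isinstance(state, FullState):
        state = FullState(*np.asarray(state, dtype=float))
    r10_species = state.c2425 if r10_from_2425 else state.c125
    return {
        "R1": params.P25,
        "R2": params.a * state.c25 / (params.K + state.c25),
        "R3": params.k3 * state.c25,
        "R4": params.V4 * state.cEnz * state.c25,
        "R5": params.k5 * state.c25,
        "R6": params.k6 * state.c2425,
        "R7": params.V7 * state.cEnz * state.c125,
        "R8": params.k8 * state.cEpi25,
        "R9": params.k9 * state.c125,
        "R10": params.k10 * r10_species,
        "R11": params.k11 * state.cEpi125,
        "R12": params.k12 * state.c125,
        "R13": params.p24,
        "R14": params.k14 * state.cEnz,
    }


def full_ode_rhs(state, params: FullParams, *, r10_from_2425: bool = False) -> np.ndarray:
    """Time derivatives (nM/d) of the six full-model species."""
    r = full_rate_terms(state, params, r10_from_2425=r10_from_2425)
    return np.array(
        [
            r["R1"] - r["R2"] - r["R3"] - r["R4"] - r["R5"],
            r["R2"] - r["R7"] - r["R9"] - r["R10"],
            r["R4"] - r["R6"],
            r["R3"] - r["R8"],
            r["R8"] + r["R10"] - r["R11"],
            r["R12"] + r["R13"] - r["R14"],
        ]
    )


def reduced_rate_terms(state, params: ReducedParams) -> dict:
    """The 8 reaction rates (nM/d) of the reduced model."""
    if not isinstance(state, ReducedState):
        state = ReducedState(*np.asarray(state, dtype=float))
    return {
        "R1": params.P25,
        "R2": params.a * state.c25 / (params.K + state.c25),
        "R3": params.k3 * state.c25,
        "R4": params.k4 * state.c25,
        "R5": params.k5 * state.c25,
        "R6": params.k6 * state.c2425,
        "R7": params.k7 * state.c125,
        "R8": params.k8 * state.cEpi25,
    }


def reduced_ode_rhs(state, params: ReducedParams) -> np.ndarray:
    """Time derivatives (nM/d) of the four reduced-model species."""
    r = reduced_rate_terms(state, params)
    return np.array(
        [
            r["R1"] - r["R2"] - r["R3"] - r["R4"] - r["R5"],
            r["R2"] - r["R7"],
            r["R4"] - r["R6"],
            r["R3"] - r["R8"],
        ]
    )


# ---------------------------------------------------------------------------
# Integration


def integrate(
    model_tag: str,
    params,
    y0,
    t_grid,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    *,
    r10_from_2425: bool = False,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate either model over an ascending time grid (days).

    Uses a stiff-capable solver; small negative excursions within the solver
    tolerance are clipped to zero, larger ones raise :class:`IntegrationError`.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise KineticModelError("t_grid must be a 1-D ascending array of >= 2 times")
    y0 = np.asarray(y0, dtype=float)
    if np.any(y0 < 0) or not np.all(np.isfinite(y0)):
        raise KineticModelError("initial state must be finite and non-negative")

    if model_tag == "full":
        if y0.shape != (6,):
            raise KineticModelError("full model needs a 6-component initial state")
        species = FULL_SPECIES

        def rhs(t, y):
            return full_ode_rhs(
                FullState(*np.maximum(y, 0.0)), params, r10_from_2425=r10_from_2425
            )

    elif model_tag == "reduced":
        if y0.shape != (4,):
            raise KineticModelError("reduced model needs a 4-component initial state")
        species = REDUCED_SPECIES

        def rhs(t, y):
            return reduced_ode_rhs(ReducedState(*np.maximum(y, 0.0)), params)

    else:
        raise KineticModelError(f"unknown model_tag {model_tag!r}")

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        y0,
        t_eval=t_grid,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    states = sol.y.T
    neg_floor = -1e3 * atol
    if np.any(states < neg_floor):
        raise IntegrationError(
            f"trajectory went negative beyond tolerance (min {states.min():.3e})"
        )
    states = np.maximum(states, 0.0)
    return Trajectory(times=sol.t, states=states, model_tag=model_tag, species=species)


# ---------------------------------------------------------------------------
# Steady state


def reduced_steady_state(params: ReducedParams) -> SteadyStateResult:
    """Closed-form steady state of the reduced model.

    The 25(OH)D3 level is the unique non-negative root of

        s·x^2 + (K·s + a − P25)·x − K·P25 = 0,     s = k3 + k4 + k5,

    solved with the cancellation-safe (Citardauq) quadratic form.  The
    downstream species follow: c125 = (a/k7)·x/(K + x), c2425 = (k4/k6)·x,
    cEpi25 = (k3/k8)·x.
    """
    s = params.k3 + params.k4 + params.k5
    P, a, K = params.P25, params.a, params.K

    if s == 0.0:
        # linear balance: (a − P)·x = K·P
        if a > P:
            x = K * P / (a - P)
        else:
            raise KineticModelError(
                "no finite steady state: production exceeds saturable loss with "
                "k3 + k4 + k5 = 0"
            )
        disc_ok = True
    else:
        b = K * s + a - P
        c = -K * P
        disc = b * b - 4.0 * s * c  # c <= 0, so disc >= b^2: always real
        disc_ok = disc >= 0.0
        sqrt_disc = math.sqrt(max(disc, 0.0))
        sgn = 1.0 if b >= 0.0 else -1.0
        q = -0.5 * (b + sgn * sqrt_disc)
        # roots are q/s and c/q; their product c/s <= 0, so exactly one is >= 0
        roots = [q / s]
        if q != 0.0:
            roots.append(c / q)
        x = max(roots)
        x = max(x, 0.0)  # guard round-off at P25 = 0

    c125 = (a / params.k7) * x / (K + x)
    c2425 = (params.k4 / params.k6) * x
    cEpi25 = (params.k3 / params.k8) * x
    return SteadyStateResult(c25=x, c125=c125, c2425=c2425, cEpi25=cEpi25, discriminant_ok=disc_ok)


# ---------------------------------------------------------------------------
# Parametrisation helpers


def rate_from_halflife(t_half: float) -> float:
    """First-order rate constant (1/d) from a half-life in days: ln(2)/t_half."""
    if not (t_half > 0.0) or not math.isfinite(t_half):
        raise KineticModelError(f"half-life must be positive and finite, got {t_half!r}")
    return math.log(2.0) / t_half


def halflife_from_rate(k: float) -> float:
    """Half-life in days from a first-order rate constant (1/d)."""
    if not (k > 0.0) or not math.isfinite(k):
        raise KineticModelError(f"rate must be positive and finite, got {k!r}")
    return math.log(2.0) / k


def reduce_full_params(full: FullParams, enzyme_level: float) -> ReducedParams:
    """Map full-model parameters to the reduced model at a fixed enzyme level.

    With 24-hydroxylase held constant at ``enzyme_level`` (nM), its
    bimolecular reactions become first order: k4 = V4·E.  All first-order
    losses of 1,25(OH)2D3 — enzymatic catabolism, VDR uptake and
    epimerisation — lump into k7 = V7·E + k9 + k10.
    """
    if enzyme_level < 0.0 or not math.isfinite(enzyme_level):
        raise KineticModelError("enzyme_level must be finite and >= 0")
    return ReducedParams(
        P25=full.P25,
        a=full.a,
        K=full.K,
        k3=full.k3,
        k4=full.V4 * enzyme_level,
        k5=full.k5,
        k6=full.k6,
        k7=full.V7 * enzyme_level + full.k9 + full.k10,
        k8=full.k8,
    )
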