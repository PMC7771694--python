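"""Single-mosquito flight dynamics: Brownian steps plus threshold-gated drift.

Each simulation step a mosquito takes an isotropic Gaussian step (uncorrelated
between steps, zero mean per axis, mean three-dimensional step length 1 cm at
the default scales) plus, when the local odor concentration exceeds the
detection threshold, a deterministic drift of magnitude

    gamma * efficiency * K(c_eff),      K(c) = rho * (1 - exp(-a * c))

pointing towards the attractant release point or away from the repellent
release point.  ``K`` is the saturating response-strength function: zero at
zero concentration, approaching the response scale ``rho`` (cm per step) at
high concentration.  Concentration modulates only the drift, never the random
flight speed.

Physiologically insecticide-resistant mosquitoes tolerate a 2-fold higher
repellent concentration: by default their *effective* repellent concentration
is halved before gating and response evaluation; the alternative reading
(halving the repellency efficiency ``beta``) is available as
``Phenotype.mode = "efficiency"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Iterable, Literal, Optional

import numpy as np

from .field import SourceSpec, field_at

__all__ = [
    "FlightParams",
    "Phenotype",
    "SUSCEPTIBLE",
    "RESISTANT",
    "MosquitoState",
    "response_strength",
    "effective_concentration",
    "brownian_step",
    "drift_displacement",
    "reflect_into_cage",
    "advance_mosquito",
    "MEAN_CHI3",
]

#: E[chi_3]: mean length of a standard 3-D Gaussian vector, = 2*sqrt(2/pi).
MEAN_CHI3 = 2.0 * np.sqrt(2.0 / np.pi)


@dataclass(frozen=True)
class FlightParams:
    """Parameters governing one mosquito's per-step motion.

    ``dt`` is the step duration (0.03 s: 1000 steps per 30 s).  ``sigma``
    multiplies the Brownian step; ``step_scale`` is the per-axis standard
    deviation of the Gaussian displacement, chosen by default so the *mean*
    3-D step length is exactly 1 cm (``1/E[chi_3]``), i.e. an average flight
    speed of 10 m per 30 s.  Setting ``step_scale = 1.0`` instead recovers the
    literal per-axis-unit-variance reading (mean step ~1.6 cm).

    ``gamma1``/``gamma2`` are the response rates towards attractant / away
    from repellent, ``alpha``/``beta`` the attractance/repellency
    efficiencies, and ``a``/``rho`` the response-function parameters.  The
    attractant and repellent response functions share ``a`` and ``rho``
    unless the repellent-specific overrides ``a_repellent``/``rho_repellent``
    are set.
    """

    dt: float = 0.03
    sigma: float = 1.0
    gamma1: float = 1.0
    gamma2: float = 1.0
    alpha: float = 0.5
    beta: float = 0.5
    a: float = 1.0
    rho: float = 1.0
    step_scale: float = 1.0 / MEAN_CHI3
    a_repellent: Optional[float] = None
    rho_repellent: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        for name in ("sigma", "gamma1", "gamma2", "alpha", "beta", "a", "rho", "step_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("a_repellent", "rho_repellent"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    def response_params(self, kind: str) -> tuple[float, float]:
        """(a, rho) for the given source kind."""
        if kind == "repellent":
            return (
                self.a if self.a_repellent is None else self.a_repellent,
                self.rho if self.rho_repellent is None else self.rho_repellent,
            )
        return self.a, self.rho


ResistanceMode = Literal["concentration", "efficiency"]


@dataclass(frozen=True)
class Phenotype:
    """Insecticide-susceptibility class of a mosquito.

    ``tolerance_factor`` is 1 for susceptible mosquitoes and 2 for the
    resistant phenotype (tolerates a 2-fold higher repellent concentration).
    ``mode`` selects how tolerance acts: dividing the effective repellent
    concentration (default) or dividing the repellency efficiency ``beta``.
    """

    susceptibility: Literal["susceptible", "resistant"] = "susceptible"
    tolerance_factor: float = 1.0
    mode: ResistanceMode = "concentration"

    def __post_init__(self) -> None:
        if self.susceptibility not in ("susceptible", "resistant"):
            raise ValueError(f"unknown susceptibility: {self.susceptibility!r}")
        if self.susceptibility == "susceptible" and self.tolerance_factor != 1.0:
            raise ValueError("susceptible phenotype must have tolerance_factor = 1")
        if self.tolerance_factor < 1.0:
            raise ValueError("tolerance_factor must be >= 1")
        if self.mode not in ("concentration", "efficiency"):
            raise ValueError(f"unknown resistance mode: {self.mode!r}")


SUSCEPTIBLE = Phenotype("susceptible", 1.0)
RESISTANT = Phenotype("resistant", 2.0)


@dataclass
class MosquitoState:
    """Position and fate of one mosquito."""

    id: int
    position: np.ndarray
    status: Literal["flying", "landed", "repelled"] = "flying"
    event_time: Optional[float] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if (self.event_time is None) != (self.status == "flying"):
            raise ValueError("event_time must be set iff status != flying")


def response_strength(c_eff, a: float, rho: float):
    """Saturating response magnitude ``K = rho * (1 - exp(-a * c_eff))``, cm/step."""
    c_eff = np.asarray(c_eff, dtype=float)
    if np.any(c_eff < 0):
        raise ValueError("concentration must be >= 0")
    k = rho * (-np.expm1(-a * c_eff))
    if k.ndim == 0:
        return float(k)
    return k


def effective_concentration(c, phen: Phenotype, kind: str):
    """Concentration as perceived by the phenotype.

    Resistance never affects host attraction.  For repellent, the default
    ("concentration") mode divides by the tolerance factor; the "efficiency"
    mode leaves the concentration unchanged (the tolerance is applied to the
    repellency efficiency in the drift instead).
    """
    c = np.asarray(c, dtype=float)
    if kind == "repellent" and phen.mode == "concentration":
        c = c / phen.tolerance_factor
    if c.ndim == 0:
        return float(c)
    return c


def drift_gain(src_kind: str, params: FlightParams, phen: Phenotype) -> float:
    """Scalar drift gain ``g``: gamma1*alpha for attractant, gamma2*beta for repellent
    (beta divided by the tolerance factor in "efficiency" resistance mode)."""
    if src_kind == "attractant":
        return params.gamma1 * params.alpha
    g = params.gamma2 * params.beta
    if phen.mode == "efficiency":
        g /= phen.tolerance_factor
    return g


def brownian_step(params: FlightParams, rng: np.random.Generator) -> np.ndarray:
    """One isotropic Gaussian displacement, cm.

    Zero mean per axis, per-axis SD ``sigma * step_scale``; at defaults the
    expected Euclidean step length is 1 cm.
    """
    return params.sigma * params.step_scale * rng.standard_normal(3)


def drift_displacement(
    x, src: SourceSpec, c_eff, params: FlightParams, phen: Phenotype = SUSCEPTIBLE
) -> np.ndarray:
    """Deterministic drift for one step, cm.

    Zero when ``c_eff`` is not above the source threshold or when ``x``
    coincides with the source location.  Otherwise ``g * K(c_eff)`` along the
    unit vector towards (attractant) or away from (repellent) the release
    point.
    """
    x = np.asarray(x, dtype=float)
    if c_eff <= src.threshold:
        return np.zeros(3)
    vec = src.location - x
    dist = float(np.linalg.norm(vec))
    if dist == 0.0:
        return np.zeros(3)
    a, rho = params.response_params(src.kind)
    k = response_strength(c_eff, a, rho)
    g = drift_gain(src.kind, params, phen)
    unit = vec / dist
    if src.kind == "repellent":
        unit = -unit
    return g * k * unit


def reflect_into_cage(x, cage) -> np.ndarray:
    """Mirror-reflect a point into the box ``[0, L]^3``, repeatedly if needed."""
    x = np.asarray(x, dtype=float)
    lengths = np.asarray(cage.lengths, dtype=float)
    m = np.mod(x, 2.0 * lengths)
    return np.where(m > lengths, 2.0 * lengths - m, m)


def advance_mosquito(
    state: MosquitoState,
    sources: Iterable[SourceSpec],
    params: FlightParams,
    phen: Phenotype,
    t: float,
    rng: np.random.Generator,
    cage=None,
) -> MosquitoState:
    """Advance a flying mosquito by one step.

    New position = reflect(old + Brownian step + sum of source drifts
    evaluated at the old position and time ``t``).  Event detection is the
    engine's job; the returned state is still flying.
    """
    if state.status != "flying":
        raise ValueError("advance_mosquito requires a flying mosquito")
    disp = brownian_step(params, rng)
    for src in sources:
        c = field_at(state.position, t, src)
        c_eff = effective_concentration(c, phen, src.kind)
        disp = disp + drift_displacement(state.position, src, c_eff, params, phen)
    new_pos = state.position + disp
    if cage is not None:
        new_pos = reflect_into_cage(new_pos, cage)
    return MosquitoState(id=state.id, position=new_pos, status="flying", event_time=None)
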