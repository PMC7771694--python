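"""Scenario engine: release, step, detect landing/repelling, replicate.

Ten mosquitoes are released at the centre of a sealed 5 m x 5 m x 3 m cage.
Attractant and/or repellent start releasing at ``t = 0`` from the ground
release corner.  Every step each flying mosquito is advanced (Brownian step
plus threshold-gated drift) and then event-checked:

* **landed** -- within 1 cm of the attractant release point (proxy for
  reaching the host); checked first,
* **repelled** -- within 1 cm of the cage corner farthest from the release
  point (proxy for being expelled from the house).

A mosquito is removed on its first event; survivors at the 30-minute cap are
recorded as censored.  Replicates use seeds ``base_seed + i`` so any single
replicate can be reproduced independently of the batch.

The stepping core is vectorised across all mosquitoes of all replicates at
once; per-replicate random-number streams keep results bit-identical whether a
replicate is run alone or inside a batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import List, Literal, Optional, Sequence

import numpy as np
from scipy.special import erfc

from .field import R_MIN, SourceSpec
from .flight import SUSCEPTIBLE, FlightParams, MosquitoState, Phenotype, drift_gain

__all__ = [
    "CageGeometry",
    "ScenarioConfig",
    "EventRecord",
    "ReplicateResult",
    "detect_event",
    "run_replicate",
    "run_experiment",
    "SCENARIOS",
]

SCENARIOS = ("random_walk", "attractant_only", "repellent_only", "both")

#: Steps per RNG block.  Blocks are drawn per replicate regardless of how many
#: mosquitoes are still flying, so the consumed stream is a pure function of
#: the replicate seed.
_CHUNK = 512


@dataclass(frozen=True)
class CageGeometry:
    """Axis-aligned box cage ``[0, Lx] x [0, Ly] x [0, Lz]`` (cm)."""

    lx: float = 500.0
    ly: float = 500.0
    lz: float = 300.0
    release_corner: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if min(self.lx, self.ly, self.lz) <= 0:
            raise ValueError("cage side lengths must be > 0")
        rc = np.asarray(self.release_corner, dtype=float)
        if rc.shape != (3,):
            raise ValueError("release_corner must be a 3-vector")
        corners = self._corners()
        if not any(np.array_equal(rc, c) for c in corners):
            raise ValueError("release_corner must be a vertex of the cage")
        object.__setattr__(self, "release_corner", rc)

    def _corners(self) -> np.ndarray:
        l = np.array([self.lx, self.ly, self.lz])
        return np.array([[i * l[0], j * l[1], k * l[2]] for i in (0, 1) for j in (0, 1) for k in (0, 1)])

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz])

    @property
    def center(self) -> np.ndarray:
        return self.lengths / 2.0

    @property
    def far_corner(self) -> np.ndarray:
        """The vertex maximising Euclidean distance from the release corner."""
        corners = self._corners()
        d = np.linalg.norm(corners - self.release_corner, axis=1)
        return corners[int(np.argmax(d))]

    def contains(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.all((x >= 0) & (x <= self.lengths), axis=-1)


@dataclass(frozen=True)
class ScenarioConfig:
    """A full experiment definition."""

    scenario: str = "random_walk"
    cage: CageGeometry = dc_field(default_factory=CageGeometry)
    attractant: Optional[SourceSpec] = None
    repellent: Optional[SourceSpec] = None
    phenotype: Phenotype = SUSCEPTIBLE
    flight: FlightParams = dc_field(default_factory=FlightParams)
    n_mosquitoes: int = 10
    max_duration: float = 1800.0
    n_replicates: int = 100
    base_seed: int = 0
    landing_radius: float = 1.0
    repelled_radius: float = 1.0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario: {self.scenario!r}")
        needs_a = self.scenario in ("attractant_only", "both")
        needs_r = self.scenario in ("repellent_only", "both")
        if needs_a and self.attractant is None:
            raise ValueError(f"scenario {self.scenario!r} requires an attractant source")
        if needs_r and self.repellent is None:
            raise ValueError(f"scenario {self.scenario!r} requires a repellent source")
        for name, src, active in (
            ("attractant", self.attractant, needs_a),
            ("repellent", self.repellent, needs_r),
        ):
            if active and src.kind != name:
                raise ValueError(f"{name} source has kind {src.kind!r}")
            if active and not self.cage.contains(src.location):
                raise ValueError(f"{name} location lies outside the cage")
        if self.n_mosquitoes < 1:
            raise ValueError("n_mosquitoes must be >= 1")
        if self.max_duration <= 0:
            raise ValueError("max_duration must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.landing_radius <= 0 or self.repelled_radius <= 0:
            raise ValueError("event radii must be > 0")

    @property
    def active_sources(self) -> List[SourceSpec]:
        out = []
        if self.scenario in ("attractant_only", "both") and self.attractant is not None:
            out.append(self.attractant)
        if self.scenario in ("repellent_only", "both") and self.repellent is not None:
            out.append(self.repellent)
        return out

    @property
    def n_steps(self) -> int:
        return int(round(self.max_duration / self.flight.dt))


Fate = Literal["landed", "repelled", "censored"]


@dataclass(frozen=True)
class EventRecord:
    """Final fate of one mosquito in one replicate (censored -> time = max_duration)."""

    replicate: int
    mosquito_id: int
    fate: Fate
    time: float

    def __post_init__(self) -> None:
        if self.fate not in ("landed", "repelled", "censored"):
            raise ValueError(f"unknown fate: {self.fate!r}")
        if not (self.time > 0):
            raise ValueError("event time must be > 0")


@dataclass
class ReplicateResult:
    events: List[EventRecord]
    trajectories: Optional[np.ndarray] = None  # (n_steps+1, n_mosquitoes, 3), float32


def detect_event(state: MosquitoState, cfg: ScenarioConfig) -> Optional[str]:
    """Landing (checked first) or repelling for one flying mosquito, else None."""
    if state.status != "flying":
        raise ValueError("detect_event requires a flying mosquito")
    if cfg.scenario in ("attractant_only", "both"):
        if np.linalg.norm(state.position - cfg.attractant.location) < cfg.landing_radius:
            return "landed"
    if cfg.scenario in ("repellent_only", "both"):
        if np.linalg.norm(state.position - cfg.cage.far_corner) < cfg.repelled_radius:
            return "repelled"
    return None


def _run_batch(
    cfg: ScenarioConfig,
    seeds: Sequence[int],
    replicate_indices: Sequence[int],
    record_trajectories: bool = False,
) -> List[ReplicateResult]:
    """Vectorised stepping of ``len(seeds)`` replicates at once."""
    n_rep = len(seeds)
    n = cfg.n_mosquitoes
    p = cfg.flight
    phen = cfg.phenotype
    cage = cfg.cage
    lengths = cage.lengths
    dt = p.dt
    n_steps = cfg.n_steps
    noise_scale = p.sigma * p.step_scale

    sources = cfg.active_sources
    # Precompute per-source constants.
    src_const = []
    for src in sources:
        a_k, rho_k = p.response_params(src.kind)
        tol = phen.tolerance_factor if (src.kind == "repellent" and phen.mode == "concentration") else 1.0
        src_const.append(
            dict(
                loc=src.location,
                amp=src.amplitude,
                sqrtD=np.sqrt(src.diffusivity),
                cap=src.cap,
                thr=src.threshold,
                a=a_k,
                rho=rho_k,
                gain=drift_gain(src.kind, p, phen),
                sign=1.0 if src.kind == "attractant" else -1.0,
                tol=tol,
            )
        )

    attract_loc = cfg.attractant.location if cfg.scenario in ("attractant_only", "both") else None
    far = cage.far_corner if cfg.scenario in ("repellent_only", "both") else None

    pos = np.broadcast_to(cage.center, (n_rep, n, 3)).copy()
    active = np.ones((n_rep, n), dtype=bool)
    fate = np.full((n_rep, n), "censored", dtype=object)
    etime = np.full((n_rep, n), round(n_steps * dt, 3), dtype=float)

    gens = [np.random.default_rng(int(s)) for s in seeds]
    rep_alive = np.ones(n_rep, dtype=bool)

    traj = None
    if record_trajectories:
        traj = np.empty((n_steps + 1, n_rep, n, 3), dtype=np.float32)
        traj[0] = pos

    two_l = 2.0 * lengths
    k = 0
    while k < n_steps and active.any():
        block = min(_CHUNK, n_steps - k)
        eps = np.zeros((n_rep, block, n, 3))
        for i, g in enumerate(gens):
            if rep_alive[i]:
                eps[i] = g.standard_normal((block, n, 3))
        for j in range(block):
            t = k * dt  # field evaluated at the state time before the step
            disp = noise_scale * eps[:, j]
            for sc in src_const:
                vec = sc["loc"] - pos
                dist = np.sqrt(np.einsum("ijk,ijk->ij", vec, vec))
                r_eff = np.maximum(dist, R_MIN)
                if t > 0:
                    c = sc["amp"] / r_eff * erfc(r_eff / (2.0 * sc["sqrtD"] * np.sqrt(t)))
                    np.minimum(c, sc["cap"], out=c)
                    c /= sc["tol"]
                else:
                    c = np.zeros_like(r_eff)
                gated = (c > sc["thr"]) & (dist > 0) & active
                if gated.any():
                    kmag = sc["rho"] * (-np.expm1(-sc["a"] * c))
                    coef = np.where(gated, sc["sign"] * sc["gain"] * kmag / r_eff, 0.0)
                    disp += coef[..., None] * vec
            pos += disp
            # mirror reflection into [0, L] on each axis
            np.mod(pos, two_l, out=pos)
            flip = pos > lengths
            pos[flip] = (np.broadcast_to(two_l, pos.shape) - pos)[flip]
            k += 1
            if traj is not None:
                traj[k] = pos
            # event detection: landing first, then repelling
            if attract_loc is not None:
                d = np.linalg.norm(pos - attract_loc, axis=-1)
                hit = active & (d < cfg.landing_radius)
                if hit.any():
                    fate[hit] = "landed"
                    etime[hit] = round(k * dt, 3)
                    active &= ~hit
            if far is not None:
                d = np.linalg.norm(pos - far, axis=-1)
                hit = active & (d < cfg.repelled_radius)
                if hit.any():
                    fate[hit] = "repelled"
                    etime[hit] = round(k * dt, 3)
                    active &= ~hit
            rep_alive = active.any(axis=1)
            if not rep_alive.any():
                break

    results = []
    for i, rep in enumerate(replicate_indices):
        events = [
            EventRecord(replicate=int(rep), mosquito_id=m, fate=str(fate[i, m]), time=float(etime[i, m]))
            for m in range(n)
        ]
        results.append(ReplicateResult(events=events, trajectories=traj[:, i] if traj is not None else None))
    return results


def run_replicate(cfg: ScenarioConfig, seed: int, record_trajectories: bool = False) -> ReplicateResult:
    """Run a single replicate with an explicit seed (bit-reproducible)."""
    return _run_batch(cfg, [seed], [0], record_trajectories=record_trajectories)[0]


def run_experiment(cfg: ScenarioConfig, record_trajectories: bool = False) -> List[ReplicateResult]:
    """Run ``cfg.n_replicates`` replicates with seeds ``base_seed + i``.

    Results for replicate ``i`` are identical to
    ``run_replicate(cfg, cfg.base_seed + i)`` run on its own.
    """
    seeds = [cfg.base_seed + i for i in range(cfg.n_replicates)]
    return _run_batch(cfg, seeds, list(range(cfg.n_replicates)), record_trajectories=record_trajectories)
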