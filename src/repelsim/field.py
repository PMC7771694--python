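"""Odor / repellent concentration fields from a continuously releasing point source.

A host-odor attractant or a volatile spatial repellent is modelled as a point
source that starts releasing at ``t = 0`` with constant rate ``C0`` into still
air (no advection) and spreads by molecular/turbulent diffusion with
diffusivity ``D``.  The resulting free-space concentration is the classical
continuous-point-source solution

    C(r, t) = (mu * C0) / (4 * pi * D * r) * erfc(r / (2 * sqrt(D * t)))

which rises monotonically in time towards the steady state ``mu*C0/(4*pi*D*r)``.
Confinement by the cage is emulated by a hard concentration cap ``C_max``
rather than by reflecting boundary conditions for the chemical; the walls are
therefore invisible to the field, and the cap represents the levelling-off of
indoor concentration in a leaky house.

Distances are in cm, times in s; concentrations are in the arbitrary
"release units" the release rate is expressed in.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal

import numpy as np
from scipy.special import erfc

__all__ = ["SourceSpec", "source_concentration", "field_at", "is_above_threshold"]

#: Evaluation floor for the 1/r singularity at the source, cm.  Chosen at the
#: same scale as the landing radius; concentrations inside this radius are
#: evaluated at the floor (and are in practice clipped by the cap anyway).
R_MIN = 1.0

SourceKind = Literal["attractant", "repellent"]


@dataclass(frozen=True)
class SourceSpec:
    """A point chemical source (attractant or repellent).

    Parameters
    ----------
    location : array-like of 3 floats
        Release point, cm.
    release_rate : float
        Constant release rate ``C0`` (concentration-units per second), >= 0.
    diffusivity : float
        Diffusion coefficient ``D``, cm^2/s, > 0.
    release_scale : float
        Dimensionless scale ``mu`` measuring releasing strength, > 0.
    cap : float
        Maximum concentration ``C_max`` anywhere in the cage, > 0.
    threshold : float
        Detection threshold ``T``; below it mosquitoes do not respond, >= 0.
    kind : {"attractant", "repellent"}
    """

    location: np.ndarray
    release_rate: float = 5.0
    diffusivity: float = 1.0
    release_scale: float = 1.0
    cap: float = 5.0
    threshold: float = 0.01
    kind: SourceKind = "attractant"

    def __post_init__(self) -> None:
        loc = np.asarray(self.location, dtype=float)
        if loc.shape != (3,):
            raise ValueError("location must be a 3-vector")
        object.__setattr__(self, "location", loc)
        if self.release_rate < 0:
            raise ValueError("release_rate C0 must be >= 0")
        if self.diffusivity <= 0:
            raise ValueError("diffusivity D must be > 0")
        if self.release_scale <= 0:
            raise ValueError("release_scale mu must be > 0")
        if self.cap <= 0:
            raise ValueError("cap C_max must be > 0")
        if self.threshold < 0:
            raise ValueError("threshold T must be >= 0")
        if self.kind not in ("attractant", "repellent"):
            raise ValueError(f"unknown source kind: {self.kind!r}")

    @property
    def amplitude(self) -> float:
        """Steady-state amplitude ``mu*C0/(4*pi*D)``: C_ss(r) = amplitude / r."""
        return self.release_scale * self.release_rate / (4.0 * np.pi * self.diffusivity)


def source_concentration(r, t, src: SourceSpec):
    """Uncapped free-space concentration at radial distance ``r`` and time ``t``.

    Vectorised in ``r`` and ``t`` (broadcasting).  ``t = 0`` returns 0 (no
    release has happened yet); ``r`` below the floor radius evaluates at the
    floor.

    Raises
    ------
    ValueError
        If any ``r < 0`` or ``t < 0``.
    """
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(r < 0):
        raise ValueError("radial distance r must be >= 0")
    if np.any(t < 0):
        raise ValueError("time t must be >= 0")
    r_eff = np.maximum(r, R_MIN)
    # erfc argument; guard t=0 to avoid division by zero, then zero the result.
    with np.errstate(divide="ignore"):
        arg = np.where(t > 0, r_eff / (2.0 * np.sqrt(src.diffusivity * np.maximum(t, 1e-300))), np.inf)
    c = src.amplitude / r_eff * erfc(arg)
    c = np.where(t > 0, c, 0.0)
    if c.ndim == 0:
        return float(c)
    return c


def field_at(x, t, src: SourceSpec):
    """Capped concentration at point(s) ``x`` (cm) and time ``t`` (s).

    ``x`` may be a single 3-vector or an ``(n, 3)`` array.  Applies the cap
    ``C_max`` to the free-space solution; never negative.
    """
    x = np.asarray(x, dtype=float)
    r = np.linalg.norm(x - src.location, axis=-1)
    c = source_concentration(r, t, src)
    return np.minimum(c, src.cap)


def is_above_threshold(c, src: SourceSpec):
    """Strict threshold test ``c > T`` (at ``c == T`` the mosquito does not respond)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = c > src.threshold
    if out.ndim == 0:
        return bool(out)
    return out
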