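"""Calibrated scenario presets for the four cage experiments.

The cage experiments (random walk; attractant only; repellent only; attractant
plus repellent) share a single global calibration of the free field and
response parameters.  The model itself does not constrain the diffusion/scale
parameters, the detection thresholds or the response scales (with the nominal
``D = 1`` cm^2/s a point-source plume would never span a 5 m cage within
30 minutes), so they are treated as calibration constants, chosen once so that
the four scenarios play out on realistic cage timescales:

* the attractant fills the cage within seconds-to-tens-of-seconds and draws
  mosquitoes in at a few cm/s (host odor: fast, moderate amplitude),
* the repellent builds up more slowly but with a larger amplitude, so that it
  eventually dominates the attractant everywhere (volatile smoke: slow,
  strong),
* the repellent response saturates at lower concentration (``a_repellent = 2``)
  and its scale ``rho_repellent`` sits just above ``rho``, so that at
  saturating concentrations repellency beats attraction for every phenotype
  (no susceptible mosquito ever reaches the host), while on the rising flank
  of the plume the halved effective concentration still separates resistant
  from susceptible mosquitoes.

All presets use the standard step scheme (0.03 s per step, mean step length
1 cm) and the default response parameters ``gamma1 = gamma2 = 1``,
``alpha = 0.5``, ``a = 1``.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np

from .engine import CageGeometry, ScenarioConfig
from .field import SourceSpec
from .flight import RESISTANT, SUSCEPTIBLE, FlightParams, Phenotype

__all__ = ["CALIBRATION", "attractant_source", "repellent_source", "make_scenario"]

#: Global calibration of the free parameters (one setting for every scenario).
CALIBRATION = {
    # attractant: fast-filling host odor, steady-state amplitude mu*C0/(4*pi*D) ~ 298
    "attractant_diffusivity": 2000.0,  # cm^2/s
    "attractant_release_scale": 1.5e6,
    "attractant_threshold": 0.01,
    # repellent: slower build-up, amplitude ~ 697, sharper response (a_repellent = 2)
    "repellent_diffusivity": 800.0,  # cm^2/s
    "repellent_release_scale": 1.4e6,
    "repellent_threshold": 0.005,
    "cap": 5.0,  # C_max, both odors
    "release_rate": 5.0,  # baseline C0
    "rho": 0.7,  # attractant response scale, cm/step
    "rho_repellent": 0.78,  # slightly above rho * K(5)/K(2.5): expels susceptibles
    "a": 1.0,
    "a_repellent": 2.0,
    "alpha": 0.5,
}


def attractant_source(release_rate: Optional[float] = None, cage: Optional[CageGeometry] = None) -> SourceSpec:
    """Host-odor source at the ground release corner with calibrated transport."""
    cage = cage or CageGeometry()
    c = CALIBRATION
    return SourceSpec(
        location=cage.release_corner,
        release_rate=c["release_rate"] if release_rate is None else release_rate,
        diffusivity=c["attractant_diffusivity"],
        release_scale=c["attractant_release_scale"],
        cap=c["cap"],
        threshold=c["attractant_threshold"],
        kind="attractant",
    )


def repellent_source(release_rate: Optional[float] = None, cage: Optional[CageGeometry] = None) -> SourceSpec:
    """Spatial-repellent source co-located with the attractant at the release corner."""
    cage = cage or CageGeometry()
    c = CALIBRATION
    return SourceSpec(
        location=cage.release_corner,
        release_rate=c["release_rate"] if release_rate is None else release_rate,
        diffusivity=c["repellent_diffusivity"],
        release_scale=c["repellent_release_scale"],
        cap=c["cap"],
        threshold=c["repellent_threshold"],
        kind="repellent",
    )


def make_scenario(
    scenario: str,
    phenotype: Phenotype = SUSCEPTIBLE,
    beta_over_alpha: float = 1.0,
    attractant_release_rate: Optional[float] = None,
    n_replicates: int = 100,
    n_mosquitoes: int = 10,
    max_duration: float = 1800.0,
    base_seed: int = 0,
) -> ScenarioConfig:
    """A calibrated experiment config for one of the four cage scenarios.

    ``beta_over_alpha`` sets the relative repellency efficacy: ``alpha`` is
    held at its default and ``beta = beta_over_alpha * alpha``.
    """
    c = CALIBRATION
    cage = CageGeometry()
    flight = FlightParams(
        alpha=c["alpha"],
        beta=beta_over_alpha * c["alpha"],
        a=c["a"],
        rho=c["rho"],
        a_repellent=c["a_repellent"],
        rho_repellent=c["rho_repellent"],
    )
    attract = (
        attractant_source(attractant_release_rate, cage)
        if scenario in ("attractant_only", "both")
        else None
    )
    repel = repellent_source(None, cage) if scenario in ("repellent_only", "both") else None
    return ScenarioConfig(
        scenario=scenario,
        cage=cage,
        attractant=attract,
        repellent=repel,
        phenotype=phenotype,
        flight=flight,
        n_mosquitoes=n_mosquitoes,
        max_duration=max_duration,
        n_replicates=n_replicates,
        base_seed=base_seed,
    )
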