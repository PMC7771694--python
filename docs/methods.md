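# Methods

## The model

`repelsim` simulates host-seeking mosquitoes in a sealed cage as self-propelled
point particles.  Each mosquito updates its position once per time step
Δt = 0.03 s (1000 steps per 30 s):

    x(t + Δt) = reflect[ x(t) + σ·s·ξ + Σ_sources g · K(c_eff) · û ]

* **Random flight.**  ξ is an independent standard Gaussian 3-vector and
  s = 1/E[χ₃] ≈ 0.6267 cm, so the mean Euclidean step length is exactly 1 cm —
  an average flight speed of 10 m per 30 s, in line with video-tracking
  estimates for *Anopheles* in experimental huts.  Steps are uncorrelated:
  there is no heading persistence, and odor concentration never modulates the
  random flight speed, only the directed drift.
* **Directed drift.**  Each active odor source contributes a drift of magnitude
  g·K along the unit vector û toward the attractant release point or away from
  the repellent release point.  The response strength is the saturating
  function K(c) = ρ·(1 − e^(−a·c)), zero at zero concentration and bounded by
  the response scale ρ (cm per step).  The gain g is γ₁·α for the attractant
  and γ₂·β for the repellent, with response rates γ₁ = γ₂ = 1 and
  attractance/repellency efficiencies α = β = 0.5 by default.  Drift is
  hard-gated: below the source's detection threshold T the mosquito navigates
  randomly.
* **Confinement.**  The cage is a 5 m × 5 m × 3 m box; positions are folded
  back by mirror reflection, repeatedly if a step crosses more than one wall.
  Mosquitoes do not rest, escape, or interact with one another, and the
  repellent repels but does not knock down or kill.

**Odor fields.**  Both the host-odor attractant (a surrogate human) and the
volatile spatial repellent are point sources on the ground in one corner,
releasing continuously from t = 0 at rate C₀ into still air.  The free-space
diffusion solution

    C(r, t) = μ·C₀ / (4π·D·r) · erfc( r / (2·√(D·t)) )

is evaluated in closed form (no grid), floored at r_min = 1 cm at the
singularity and clipped at a maximum concentration C_max = 5 — the cap stands
in for the levelling-off of indoor concentration in a real, leaky house and is
the only representation of chemical confinement; the walls are transparent to
the chemicals.  Multiple sources superpose at the drift level; each field is
capped per source.

**Resistance.**  Physiologically insecticide-resistant mosquitoes tolerate a
2-fold higher repellent concentration.  By default this divides the *effective*
repellent concentration by the tolerance factor (2) before gating and response
evaluation; the alternative reading — halving the repellency efficiency β —
is available as `Phenotype.mode = "efficiency"`.  Resistance never affects
attraction to the host.

**Events.**  A mosquito *lands* when it first comes within 1 cm of the
attractant release point (it found the host) and is *repelled* when it first
comes within 1 cm of the cage vertex farthest from the release corner (it was
driven out of the house).  Landing is checked first; either event removes the
mosquito.  Survivors at the 30-minute cap are recorded as censored rather than
discarded, so landing/repelling rates are always well defined.  Event times
are quantised to the step grid and serialised with three decimals, making
write/read round trips exact.

## Scenario calibration

The four cage experiments (random walk; attractant only; repellent only;
attractant plus repellent) use one global setting of the parameters the model
leaves free.  With the nominal D = 1 cm²/s a point-source plume spreads only
a few tens of cm in 30 minutes and could never span a 5 m cage, so the
transport parameters (D, μ) and the response scales must be calibrated; they
were chosen once so that the scenario experiments play out on the reported
timescales, and are frozen in `repelsim.scenarios.CALIBRATION`:

| parameter | attractant | repellent | role |
|---|---|---|---|
| D (cm²/s) | 2000 | 800 | host odor fills the cage within seconds; the repellent plume builds up over minutes |
| μ (–) | 1.5×10⁶ | 1.4×10⁶ | steady-state amplitudes μC₀/(4πD) ≈ 298 and ≈ 697 cm·units at C₀ = 5 |
| T (units) | 0.01 | 0.005 | detection thresholds |
| a (1/units) | 1.0 | 2.0 | the repellent response saturates at lower concentration |
| ρ (cm/step) | 0.70 | 0.78 | response scales |

Shared: C₀ = 5 (10 for the doubled-release experiment), C_max = 5,
γ₁ = γ₂ = 1, α = 0.5, β = (β/α)·α with β/α ∈ {0.8, 1.0, 1.2}.

Why this shape:

* The attractant's fast transport and moderate amplitude give a landing wave
  with pooled mean ≈ 83 s at C₀ = 5 and ≈ 64 s at C₀ = 10 from the cage
  centre (384 cm from the source).
* The repellent's slower build-up makes expulsion growth-limited: the
  susceptible pooled mean is ≈ 195 s, and the 2-fold tolerance of resistant
  mosquitoes (halved effective concentration on the rising flank of the
  plume) delays theirs to ≈ 275 s.
* `a_repellent = 2` makes the repellent response saturate by mid-field
  concentrations.  During the *growth* phase (repellent-only experiment)
  the halved effective concentration still discriminates phenotypes, but at
  late times the saturated response is phenotype-independent — so in the
  combined scenario susceptible and resistant expulsion converge.
* `ρ_repellent = 0.78` is set just above ρ·K(C_max)/K(C_max/2): at saturating
  concentrations the repellency acting on a *susceptible* mosquito always
  exceeds the attraction (γ₂βρ_R K_R > γ₁αρ_A K_A), so no susceptible
  mosquito ever reaches the host in the combined scenario, while a resistant
  mosquito at β/α < 1 still experiences net attraction close to the source.

## Known structural limitations

Two features of the combined (attractant + repellent) scenario do not
reproduce what one might expect from hut experiments, and both are provable
properties of this model class rather than calibration accidents:

1. **Resistant mosquitoes rarely reach the host when both chemicals share a
   release corner.**  Because both fields decay as 1/r from the *same* point,
   any repellent strong enough to expel mosquitoes on ~200 s timescales and
   to pin them at the far corner is, from the first seconds, far stronger in
   the mid-field (r ≈ 1.5–7 m from the corner) than at the cage periphery.
   With drift entering as a vector sum, this creates a static outward barrier
   along the entire approach corridor whose removal (by weakening the
   repellent or strengthening the attractant) destroys the repellent-only
   timing by larger margins.  Under the frozen calibration the resistant
   landing fraction at β/α = 0.8 is therefore 0, not the high fraction
   semi-field studies suggest; mechanisms such as repellent-induced
   hyperactivity (orthokinesis) are outside this model.
2. **Expulsion is slower with a host present.**  The residual attractant pull
   at the far corner (≈ 0.09 cm/step) opposes the corner-pinning drift, so
   combined-scenario expulsion means come out ≈ 1.5–2× the repellent-only
   susceptible mean.  The direction of the effect (a host in the room delays
   expulsion) is expected; its size here is inflated by the 1/r tail of the
   attractant field.

## Numerical choices

* **Seeding.**  One integer base seed per experiment; replicate i uses
  `base_seed + i` and its own PCG64 generator, so a replicate re-run alone is
  bit-identical to the same replicate inside a batch.  Gaussian variates are
  drawn in fixed 512-step blocks per replicate regardless of how many
  mosquitoes are still flying, keeping the consumed stream a pure function of
  the seed.
* **Vectorisation.**  The engine steps all mosquitoes of all replicates as one
  array; event detection (landing before repulsion) runs per step.  Order
  across mosquitoes is irrelevant because the fields depend only on time.
* **Degenerate inputs.**  Strict threshold comparison (c > T); zero drift at
  the exact source location; field evaluation floored at r_min = 1 cm; the
  erfc solution returns 0 at t = 0.
* **Summary conventions.**  Time statistics pool mosquitoes across replicates
  (SD with n−1; undefined for fewer than two events); the per-replicate-mean
  alternative is exposed as `summarize(..., by_replicate=True)`.  Histogram
  bins are half-open `[k·w, (k+1)·w)` with w = 2 s by default.  Deterrence
  and excito-repellency follow the hut-trial definitions; toxicity is not
  computed because the repellent is assumed non-lethal.

## What the scenario suite does and does not show

The scenario presets are the study conditions themselves (100 replicates × 10
mosquitoes, 30 min cap); passing tests show that the implementation
reproduces the single-source time statistics and the qualitative orderings
(resistant expelled later than susceptible; faster landing at doubled release
rate; landing fraction non-increasing in β/α; susceptible never landing under
a repellent).  They do not validate the model against real mosquito flight:
real host odor is advected by convection and wind, plumes are filamentous
rather than radially smooth, flight has persistence and odor-gated upwind
anemotaxis, and repellents also irritate, knock down and kill.
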