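# repelsim

Agent-based simulation of mosquito host seeking under a host-odor attractant
and a volatile spatial repellent, with insecticide-resistant phenotypes.

Spatial repellents (mosquito coils and similar emanators) aim to keep
host-seeking *Anopheles* away from people indoors, but their efficacy against
physiologically insecticide-resistant mosquitoes is uncertain.  `repelsim`
implements a modified self-propelled-particle model to explore that question
*in silico*: point-particle mosquitoes fly inside a sealed 5 m × 5 m × 3 m
cage with uncorrelated Gaussian steps (mean step 1 cm, 1000 steps per 30 s)
plus a threshold-gated drift toward the attractant and away from the
repellent,

    x(t+Δt) = reflect[ x(t) + σ·s·ξ + γ₁α·K_A(c_A)·û_A + γ₂β·K_R(c_R)·û_R ],
    K(c)    = ρ·(1 − e^{−a·c}),

where each odor concentration is the continuously-releasing point-source
diffusion solution `C(r,t) = μC₀/(4πDr)·erfc(r/2√(Dt))`, capped at C_max.
Resistant mosquitoes tolerate a 2-fold higher repellent concentration
(effective concentration halved).  A mosquito that comes within 1 cm of the
attractant release point has *landed* (reached the host); one that reaches
within 1 cm of the opposite cage corner has been *repelled* (expelled from
the house).  Outputs are time-to-event logs, pooled summaries, histograms and
the hut-trial indicators (deterrence, excito-repellency).

The key experimental driver is the relative repellency efficacy β/α: whether
resistant mosquitoes can reach the host before being expelled depends on it.

## Worked example

Simulate host seeking toward a human-odor surrogate (no repellent), 100
replicates of 10 mosquitoes released at the cage centre:

```yaml
# host_odor.yaml
scenario: attractant_only
base_seed: 42
attractant:
  release_rate: 5.0
  diffusivity: 2000.0
  release_scale: 1.5e6
  threshold: 0.01
flight:
  rho: 0.7
```

```sh
repelsim run host_odor.yaml --out-dir demo
```

prints

```
INFO repelsim: running scenario attractant_only: 100 replicates x 10 mosquitoes, seed 42
INFO repelsim: summary: 1000 landed (100.0%), 0 repelled (0.0%), 0 censored
```

and `demo/summary.json` contains

```json
"n_landed": 1000,
"landing_rate": 1.0,
"mean_landing_time": 82.948,
"sd_landing_time": 8.225,
"min_landing_time": 62.46,
"max_landing_time": 115.14
```

Every mosquito found the host; the pooled mean landing time is ≈ 83 s, with
the first arrivals at ≈ 62 s.  The run directory also holds `events.csv`
(one row per mosquito), `histogram.csv` (2-s bins of landing times) and
`manifest.json`, from which the run can be reproduced bit-identically.

The same machinery drives the other scenarios through the library:

```python
import repelsim as rs

cfg = rs.make_scenario("repellent_only", phenotype=rs.RESISTANT,
                       n_replicates=100, base_seed=7)
summary = rs.summarize(rs.flatten_events(rs.run_experiment(cfg)))
print(summary.mean_repelling_time)   # ~275 s (susceptible: ~195 s)
```

and `repelsim sweep both.yaml --ratios 0.8,1.0,1.2` runs the combined
attractant-plus-repellent experiment over a β/α grid, one summary per point.

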