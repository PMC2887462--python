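# fuzzycell

Rule-based fuzzy-logic simulation of cellular aging networks built from
feedback-loop motifs.

Cellular aging emerges from the interplay of an amplifying positive
feedback loop — reactive oxygen species (ROS) oxidise mitochondrial
proteins, and the accumulated damage raises ROS production further (the
"vicious cycle") — with protective negative feedback closed by the
stress sensors NF-κB and mTOR, which remodel scavenging, mitochondrial
respiration, biosynthesis, glycolysis and autophagy. `fuzzycell` is a
semi-quantitative simulator for such networks aimed at systems-biology
researchers who want to study these motifs over whole simulated
lifetimes, run in-silico interventions (sensor blockade, sensitivity
knock-down) and rank reactions by their influence on lifespan.

## The model

Every node (ROS, OXPROT, MRSP, ATP, ADP, ATPconsume, ProtBiosynth, NF-κB,
mTOR, glycolysis, …) carries an activity in [0, 1]. The interval is
partitioned into six overlapping triangular fuzzy sets with centroids
C_i ∈ {0, 0.2, 0.4, 0.6, 0.8, 1.0}; a real value *R* maps to fractional
memberships *m* of at most two adjacent sets (standard additive model,
SAM). Each reaction has a rate coefficient *k* and participants with
roles — product (`pro`), substrate (`sub`), activator (`act`), inhibitor
(`inh`) — each carrying a six-integer rule vector that assigns an output
level to every input level, e.g.

```
Reaction MRSP_ATP 0.8
pro ATP 5 5 5 5 5 0
sub ADP 0 5 5 5 5 5
act MRSP 0 1 2 3 4 5
```

("mitochondrial activity determines ATP production until the scale
saturates"). The instantaneous rate is

  rate = k · Π_p ( Σ_i m_i(x_p) · rule_p[i] / 5 ),

products gain and substrates lose rate·dt per step, and the state is
advanced by 10 000 synchronous forward-Euler steps over model time
0–40, clamped to [0, 1].

Three reference models ship with the package: the vicious cycle (`vc`,
8 nodes / 18 reactions), its NF-κB extension (`nfkb`), and the full
adaptive-response model (`ar`, 10 nodes / 36 reactions / 71 rule lines).
Lifespan is defined as the first time oxidised proteins (OXPROT) reach
0.4; the sensitivity screen additionally stops at ROS ≥ 0.4 or ATP
consumption ≤ 0.4, and the Sensitivity Objective Function of a reaction
is SOF = (%Δ lifespan)/(%Δ rate), significant when |SOF| > 2.5.

## Worked example

```python
from fuzzycell import (build_vc_model, build_ar_model, simulate,
                       SimulationConfig, lifespan, accumulated_energy)
from fuzzycell.analysis import OXPROT_ONLY

vc = simulate(build_vc_model(), SimulationConfig())
ar = simulate(build_ar_model(), SimulationConfig())
for name, run in (("vicious cycle", vc), ("adaptive response", ar)):
    ls = lifespan(run, OXPROT_ONLY)
    print(f"{name}: lifespan {ls.lifespan:.2f}"
          f"{' (censored)' if ls.censored else ''}, "
          f"peak ROS {run['ROS'].max():.2f}, "
          f"energy turnover {accumulated_energy(run, until=ls.lifespan):.1f}")
```

prints

```
vicious cycle: lifespan 9.52, peak ROS 0.92, energy turnover 7.1
adaptive response: lifespan 40.00 (censored), peak ROS 0.20, energy turnover 20.1
```

— the unprotected network ages explosively (ROS runs away and oxidised
proteins cross 0.4 at t ≈ 9.5), while the sensor-protected network keeps
ROS contained near 0.2, turns over almost three times as much energy,
and its damage stays below the lifespan threshold for the whole window
(the energy criterion, ATP consumption ≤ 0.4, fires at t ≈ 29.3).

The same experiments from a shell:

```
fuzzycell run --model vc
fuzzycell run --model ar --clamp NFkB@20        # midlife sensor blockade
fuzzycell sensitivity --model ar --screen 5     # +5% rate screen
fuzzycell sensitivity --model ar --sensor mtor --deltas -20:20:5
fuzzycell lint src/fuzzycell/models/ar.model
```

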