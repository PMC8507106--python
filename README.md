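# rhono — bistability in the RhoA / nitric-oxide mutual-antagonism network

RhoA (via ROCK) drives cytoskeletal contraction; nitric oxide (via
cGMP/PKG) drives relaxation, and the two pathways antagonise each other:
ROCK suppresses Akt-mediated eNOS activation and RhoA destabilises eNOS
mRNA, while PKG inactivates RhoA by Ser188 phosphorylation. A mutual
(double-negative) antagonism is a positive feedback loop, and with enough
ultrasensitivity such loops can be *bistable* — the network settles into
either a contractile RhoA-high/NO-low state or a relaxed NO-high/RhoA-low
state depending on history.

This package implements the computational side of that question as a
reusable, tested toolkit plus a scripted analysis:

* a reaction-network representation with typed rate laws (mass action,
  Michaelis–Menten, Hill) compiled to fast ODE right-hand sides
  (`rhono.network_core`);
* three concrete models (`rhono.models`): the minimal two-node mass-action
  motif, an 11-equation / 31-reaction biochemical RhoA–NO network, and a
  12-equation extension that treats cytoskeletal tension as a network
  species with ROCK-driven generation, cGMP-driven dissipation and
  positive feedback onto RhoA activation (36 perturbable rate constants);
* stiff integration with steady-state detection, Newton refinement and
  eigenvalue stability classification (`rhono.simulation`);
* multistart attractor censuses, an extreme-initialization probe and a
  bistability screen that requires both (`rhono.multistability`);
* pseudo-arclength equilibrium continuation with saddle-node (fold)
  detection, refined fold positions, bistable-interval extraction and an
  independent quasi-static hysteresis cross-check (`rhono.bifurcation`);
* single-parameter robustness grids — does bistability survive ±p%
  perturbation of each rate constant? (`rhono.robustness`);
* seeded generators for every synthetic input: random initial-condition
  ensembles, percentage perturbations, log-uniform parameter samples
  (`rhono.synthetic_inputs`);
* a CLI (`rhono simulate|classify|bifurcate|robustness|search|run`)
  writing CSV/JSON results, figures and a reproducibility manifest
  (`rhono.cli_io`).

The supplementary kinetics of the original study are not bundled here, so
the two network models are calibrated reconstructions; see
`docs/methods.md` for exactly what they reproduce and what they do not.

## Worked example

```python
import numpy as np
from rhono import build_initial_model, build_extended_model
from rhono.multistability import classify_attractors
from rhono.bifurcation import continue_branch, no_range_across_regime

model, params = build_initial_model()
res = classify_attractors(model, params, n_starts=100, seed=1, horizon=1e5)
j = model.state_species().index("NO")
print(res.n_attractors, res.basin_counts)
print([round(float(a.state[j]), 2) for a in res.attractors])

d = continue_branch(model, params, "ki1", (0.001, 0.03), horizon=1e5)
print([round(p, 5) for p, _ in d.folds])
print(no_range_across_regime(d))
```

prints

```
2 [73, 27]
[5.82, 0.65]
[0.00951, 0.0185]
(0.3997450638988719, 5.633806224695859)
```

— 100 random initializations split between exactly two attractors, a
NO-high state at 5.8 nM and a NO-low (RhoA-high) state at 0.65 nM; the
sweep over ki1 (the ROCK→Akt antagonism constant) is the S-shaped curve of
bistability with two folds at ki1 ≈ 0.0095 and 0.0185, and across that
bistable regime the stable-branch NO concentration spans ≈ 0.4–5.6 nM.
Running the same sweep on the tension-extended model widens the interval
to ≈ [0.0052, 0.0180]: mechanical feedback lets the contractile state
survive weaker biochemical antagonism.

The scripted analyses under `analysis/` run the full workflow in order —
`01_two_node_monostability.py` (the minimal motif is never bistable),
`02_multistart_census.py`, `03_bifurcation_diagrams.py`,
`04_robustness.py` (the biochemical switch is brittle; the
tension-coupled switch is robust) — writing tables and figures under
`results/`.

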