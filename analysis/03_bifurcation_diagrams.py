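"""Bifurcation structure of the antagonism parameters ki1 and ki2.

Pseudo-arclength continuation over each antagonism constant for both
models, with a quasi-static hysteresis sweep as an independent cross-check.
All four diagrams are S-shaped (two saddle-node folds bracketing a bistable
interval).  The tension-extended model's bistable interval is wider than
the initial model's for both parameters, and its stable-branch NO levels
span a wider range.

Writes results/diagram_<model>_<param>.csv/.json, figures, and
results/bifurcation_summary.csv.
"""

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from rhono import assemble, build_extended_model, build_initial_model
from rhono.bifurcation import (
    continue_branch,
    hysteresis_sweep,
    no_range_across_regime,
)
from rhono.multistability import extreme_initial_states
from rhono.plotting import plot_bifurcation
from rhono.simulation import find_steady_state

OUT = Path(__file__).resolve().parents[1] / "results"
FIG = OUT / "figures"
FIG.mkdir(parents=True, exist_ok=True)

HORIZON = 1e5
RANGES = {"ki1": (0.001, 0.03), "ki2": (0.0005, 0.008)}
N_HYST = 60

rows = []
for name, build in [("initial", build_initial_model),
                    ("extended", build_extended_model)]:
    model, params = build()
    field = assemble(model, params)
    no_hi, rhoa_hi = extreme_initial_states(model)
    anchor_lo = find_steady_state(field, rhoa_hi, horizon=HORIZON).state
    anchor_hi = find_steady_state(field, no_hi, horizon=HORIZON).state
    for pname, rng in RANGES.items():
        t0 = time.time()
        d = continue_branch(model, params, pname, rng,
                            anchor_states=(anchor_lo, anchor_hi),
                            horizon=HORIZON)
        h = hysteresis_sweep(model, params, pname, rng, n_steps=N_HYST,
                             horizon=HORIZON)
        step = (rng[1] - rng[0]) / (N_HYST - 1)
        agree = (d.bistable_interval is not None
                 and h.bistable_interval is not None
                 and abs(d.bistable_interval[0] - h.bistable_interval[0]) <= step
                 and abs(d.bistable_interval[1] - h.bistable_interval[1]) <= step)
        nr = no_range_across_regime(d)
        d.to_csv(OUT / f"diagram_{name}_{pname}.csv")
        (OUT / f"diagram_{name}_{pname}.json").write_text(d.summary_json())
        ax = plot_bifurcation(d)
        ax.set_title(f"{name} model, {pname}")
        ax.figure.savefig(FIG / f"diagram_{name}_{pname}.png", dpi=150,
                          bbox_inches="tight")
        rows.append({
            "model": name, "parameter": pname,
            "fold_lo": d.bistable_interval[0],
            "fold_hi": d.bistable_interval[1],
            "interval_width": d.bistable_interval[1] - d.bistable_interval[0],
            "interval_ratio": d.bistable_interval[1] / d.bistable_interval[0],
            "NO_min_nM": nr[0], "NO_max_nM": nr[1],
            "hysteresis_agrees": agree,
            "elapsed_s": round(time.time() - t0, 1),
        })
        print(f"{name} {pname}: interval "
              f"[{d.bistable_interval[0]:.5f}, {d.bistable_interval[1]:.5f}] "
              f"NO {nr[0]:.2f}-{nr[1]:.2f} nM, hysteresis agrees: {agree}")

df = pd.DataFrame(rows)
df.to_csv(OUT / "bifurcation_summary.csv", index=False)

wide = {}
for pname in RANGES:
    wi = df[(df.model == "initial") & (df.parameter == pname)].iloc[0]
    we = df[(df.model == "extended") & (df.parameter == pname)].iloc[0]
    wide[pname] = {
        "widening_absolute": we.interval_width / wi.interval_width,
        "widening_ratio_scale": np.log(we.interval_ratio) / np.log(wi.interval_ratio),
        "NO_span_fold_initial": wi.NO_max_nM / wi.NO_min_nM,
        "NO_span_fold_extended": we.NO_max_nM / we.NO_min_nM,
    }
(OUT / "bifurcation_widening.json").write_text(json.dumps(wide, indent=1))
print(json.dumps(wide, indent=1))
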