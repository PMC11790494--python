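"""Hard-rectangle ordering: squares vs in-place transformed rods.

Equilibrates near-square rafts at coverage 0.23, transforms them in place to
aspect-ratio-9.5 rods, and compares the near-contact ordered fraction against
(a) the square state and (b) rods inserted directly at the same coverage with
limited relaxation.  Writes the per-seed table.
"""

import numpy as np
import pandas as pd

from guvshape import ordering as od

OUT = "results/ordering.csv"
SEEDS = (1, 2, 3, 4, 5)

rows = []
for seed in SEEDS:
    squares = od.init_config(200, od.SDR_DIMS_NM, coverage=0.23, seed=seed)
    eq = od.run_mc(squares, od.MoveSettings(sweeps=10_000, seed=seed + 100)).final
    report = od.transform_shapes(
        eq, od.EDR_DIMS_NM, n_substeps=20,
        relax=od.MoveSettings(sweeps=50, seed=seed + 200), max_retries=300,
    )
    rods = od.run_mc(report.config, od.MoveSettings(sweeps=2000, seed=seed + 300)).final
    direct = od.run_mc(
        od.init_config(200, od.EDR_DIMS_NM, coverage=0.224, seed=seed + 400),
        od.MoveSettings(sweeps=100, seed=seed + 500),
    ).final
    rows.append(
        {
            "seed": seed,
            "squares": od.order_metrics(eq).ordered_fraction,
            "transformed": od.order_metrics(rods).ordered_fraction,
            "direct": od.order_metrics(direct).ordered_fraction,
            "transform_retries": report.total_retries,
            "phi_final": rods.coverage,
        }
    )

table = pd.DataFrame(rows)
table.to_csv(OUT, index=False)
print(table.to_string(index=False))
means = table[["squares", "transformed", "direct"]].mean()
print(
    f"\nmean ordered fraction: squares {means['squares']:.3f}, "
    f"transformed rods {means['transformed']:.3f}, direct rods {means['direct']:.3f}"
)
print(
    "transformed rods order >= 2x squares:",
    means["transformed"] >= 2 * means["squares"],
)
print(
    "note: the transformed-vs-direct contrast is weak in a pure hard-core model; "
    "see docs/methods.md."
)
print(f"wrote {OUT}")
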