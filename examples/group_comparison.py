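"""Control vs rotenone: simulate small cell populations and compare groups.

Rotenone blocks mitochondrial complex I, raising the free/bound NAD(P)H
ratio and shrinking the flavin contribution.  This script simulates 40
cell-integrated decays per group, fits each cell, and runs Mann-Whitney
comparisons on the fitted descriptors.
"""

import pandas as pd

from specflim import (
    ComponentBasis,
    InstrumentModel,
    compare_groups,
    fit_global,
    make_group_scene,
    simulate_cell_decays,
)

instrument = InstrumentModel()
basis = ComponentBasis.default(instrument.spectral)

rows = []
for i, group in enumerate(("control", "rotenone")):
    phantom = make_group_scene(group, 40, seed=100 + i)
    decays = simulate_cell_decays(phantom, instrument, 2e5, seed=200 + i)
    for cell in range(decays.shape[0]):
        fit = fit_global(decays[cell], instrument, basis)
        rows.append(
            {"group": group, "ratio_free_bound": fit.ratio_free_bound,
             "tau_bound_ns": fit.tau_bound_ns, "a_flavins": fit.a_flavins}
        )
table = pd.DataFrame(rows)

for parameter in ("ratio_free_bound", "tau_bound_ns", "a_flavins"):
    out = compare_groups(table, parameter, reference_group="control")
    ctrl = out[out.group == "control"].iloc[0]
    rot = out[out.group == "rotenone"].iloc[0]
    print(f"{parameter:<18} control {ctrl['median']:6.3f}  "
          f"rotenone {rot['median']:6.3f}  p = {rot.p_value:.2e}")
print()
print("Expected directions: ratio up, tau_bound down, a_flavins down")
print("under rotenone; p-values are two-sided Mann-Whitney U vs control.")
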