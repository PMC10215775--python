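"""Four-pool carbon bookkeeping on the embedded study tables.

Computes the 2000 and 2020 carbon totals from the transfer-matrix margins
and the per-class density table, and decomposes the 20-year net change over
the individual land-use transitions.  Writes results/carbon/.
"""

import os

import pandas as pd

from landcarbon import datasets
from landcarbon.carbon_accounting import carbon_change, carbon_from_areas, load_density_table

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "carbon")


def main():
    os.makedirs(OUT, exist_ok=True)
    tm = datasets.transfer_matrix_2000_2020()
    density = load_density_table(datasets.carbon_density_table())

    rows = {}
    for label, areas in (("2000", tm.row_totals()), ("2020", tm.col_totals())):
        out = carbon_from_areas(areas, density)
        rows[label] = {**out["per_pool_t"], "total_t": out["total_t"]}
        print(f"carbon storage {label}: {out['total_t']:.4e} t")
    pd.DataFrame(rows).T.to_csv(os.path.join(OUT, "carbon_totals_by_pool.csv"))

    delta, net = carbon_change(tm, density)
    delta.round(1).to_csv(os.path.join(OUT, "carbon_change_by_transition.csv"))
    print(f"net change 2000→2020: {net:.4e} t")
    worst = delta.stack().idxmin()
    print(f"largest single loss: {worst[0]} → {worst[1]} ({delta.loc[worst]:.3e} t)")


if __name__ == "__main__":
    main()
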