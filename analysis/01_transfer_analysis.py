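"""Land-use change analysis from the embedded 2000→2020 transfer matrix.

Reports per-class area change, shares of the mapped total, and the Markov
transition probabilities that drive the demand projection.  Writes
results/transfer/.
"""

import os

from landcarbon import datasets
from landcarbon.transitions import markov_project, transition_probabilities

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "transfer")


def main():
    os.makedirs(OUT, exist_ok=True)
    tm = datasets.transfer_matrix_2000_2020()
    tm.to_csv(os.path.join(OUT, "transfer_matrix_2000_2020.csv"))

    deltas = tm.deltas()
    shares = tm.shares("to").round(1)
    print(f"mapped total: {tm.total():.2f} km²")
    print("net change 2000→2020 (km²):")
    for cls, d in deltas.items():
        print(f"  {cls:<13}{d:+10.2f}   share 2020: {shares[cls]:4.1f}%")

    tp = transition_probabilities(tm)
    tp.P.round(6).to_csv(os.path.join(OUT, "transition_probabilities.csv"))
    demand = markov_project(tm.col_totals(), tp, n_steps=1)
    demand.round(2).to_csv(os.path.join(OUT, "markov_demand_one_step.csv"))
    print("\none-step Markov projection from the 2020 margins (km²):")
    print(demand.round(2).to_string())
    print(f"\nforest persistence probability: {tp.P.loc['forest','forest']:.4f}")


if __name__ == "__main__":
    main()
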