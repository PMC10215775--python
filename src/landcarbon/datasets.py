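"""Published study tables shipped with the package.

Three small tables from the Kunming-type plateau-city study design are
embedded as CSV package data: the 2000→2020 land-use transfer matrix (km²),
the per-class four-pool carbon density table (t/ha) and the per-scenario
neighborhood weights.  They are inputs of the analysis, not fixtures.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .transitions import TransferMatrix

_DATA = resources.files(__package__) / "data"


def transfer_matrix_2000_2020() -> TransferMatrix:
    """Observed 2000→2020 transfer matrix of the study area (km²)."""
    with resources.as_file(_DATA / "transfer_matrix_2000_2020.csv") as path:
        return TransferMatrix.from_csv(path, date_from="2000", date_to="2020")


def carbon_density_table() -> pd.DataFrame:
    """Per-class carbon densities (t/ha) for the four pools."""
    with resources.as_file(_DATA / "carbon_density_t_ha.csv") as path:
        return pd.read_csv(path, index_col=0)


def neighborhood_weights() -> pd.DataFrame:
    """Per-scenario, per-class neighborhood weights (0–1)."""
    with resources.as_file(_DATA / "neighborhood_weights.csv") as path:
        return pd.read_csv(path, index_col=0)
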