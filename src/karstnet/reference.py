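"""Bundled reference data.

Treatment-mean soil physico-chemical properties (mean +/- SE, n = 5 blocks)
from a 2x2x2 water x nitrogen x phosphorus addition experiment in a
subtropical karst shrubland. Used as the baseline for the environmental-table
simulator and as the input for marginal-effect (percent change) computations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_soil_reference"]


def load_soil_reference() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load the bundled soil-property treatment table.

    Returns
    -------
    means, ses
        Two DataFrames indexed by variable name with one column per treatment
        (C, W, N, P, WN, WP, NP, WNP): the treatment means and their standard
        errors (n = 5 blocks each).
    """
    with resources.files("karstnet.data").joinpath("soil_treatment_means.csv").open() as fh:
        df = pd.read_csv(fh, comment="#", index_col=0)
    means = df[[c for c in df.columns if c.endswith("_mean")]].copy()
    means.columns = [c[: -len("_mean")] for c in means.columns]
    ses = df[[c for c in df.columns if c.endswith("_se")]].copy()
    ses.columns = [c[: -len("_se")] for c in ses.columns]
    return means, ses
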