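"""Bundled reference tables."""

from importlib import resources

import pandas as pd

__all__ = ["load_transect_summary"]


def load_transect_summary() -> pd.DataFrame:
    """Published per-taxon summary for the Hewatt–Sagarin transect.

    Era-averaged densities (individuals m^-2, with SD where the era had more
    than one survey year), the mean log response ratio vs the pooled 1931-1933
    baseline with its printed 95% CI bounds, and the geographic range class
    (C coastwide / S southern / U uncertain) for the 48 common taxa that pass
    the inclusion filter.  Values are as printed (one decimal), which is why
    the evidence counters carry a rounding-aware convention.
    """
    path = resources.files("rockyshore.data").joinpath("hewatt_sagarin_taxa.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    df["range_class"] = df["range_class"].map(
        {"C": "coastwide", "S": "southern", "U": "uncertain", "N": "northern"}
    )
    return df
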