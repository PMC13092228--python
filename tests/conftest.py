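import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def toy_records() -> pd.DataFrame:
    """A tiny well-formed survey record set spanning two eras."""
    rows = [
        ("1931-1933", 1931, "q27", "Alia carinata", 5, None),
        ("1931-1933", 1932, "q28", "Tegula funebralis", 3, None),
        ("1993-1996", 1993, "q27", "Acanthina punctulata", 2, None),
        ("1993-1996", 1993, "q28", "Tegula funebralis", 4, None),
        ("1993-1996", 1996, "q27", "Pagurus spp.", None, "rare"),
    ]
    df = pd.DataFrame(
        rows, columns=["era", "year", "quadrat_id", "taxon", "count", "qualitative_code"]
    )
    df["date"] = None
    return df


@pytest.fixture
def toy_crosswalk() -> pd.DataFrame:
    names = [
        ("Alia carinata", "Alia carinata", "species", "mobile", False, True),
        ("Tegula funebralis", "Tegula funebralis", "species", "mobile", False, True),
        ("Acanthina punctulata", "Acanthinucella punctulata", "species", "mobile", False, True),
        ("Acanthinucella punctulata", "Acanthinucella punctulata", "species", "mobile", False, True),
        ("Pagurus spp.", "Pagurus spp.", "genus", "mobile", False, True),
    ]
    return pd.DataFrame(
        names,
        columns=["taxon_recorded", "analysis_taxon", "rank", "mobility", "epibiont", "on_baseline_list"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231)
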