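"""rockyshore: biodiversity change on a century-scale rocky intertidal transect.

Coverage-standardized Hill diversity, Bayesian trend detection across
investigator eras, causal attribution of diversity change to extreme sea
surface temperature, and per-taxon log response ratios by geographic range
class — with a synthetic-data generator reproducing the statistical structure
of the survey so the whole pipeline is testable end to end.
"""

from . import (
    datasets,
    diversity,
    evidence,
    inference,
    population_change,
    survey_data,
    synthetic_data,
    temperature,
)

__all__ = [
    "datasets",
    "diversity",
    "evidence",
    "inference",
    "population_change",
    "survey_data",
    "synthetic_data",
    "temperature",
]

__version__ = "0.1.0"
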