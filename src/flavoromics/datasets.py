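"""Packaged reference tables.

``load_published_vip_table`` returns the printed VIP/p-value table from a
published seven-year strawberry consumer-panel study (148 samples, three
technical periods, 3-component PLS models for sweetness and liking; slope
p-values Bonferroni-adjusted, sugars untested).  It is the desk-scale input
for exercising the consensus-selection and thresholding rules exactly as
printed: empty VIP cells mean the compound was not detected in that period
(or not reported for that response) and cast no consensus vote.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_PERIODS = ("2011_2012", "2013_2015", "2016_2017")


def load_published_vip_table() -> pd.DataFrame:
    """The printed per-period VIP table, indexed by compound name."""
    ref = resources.files("flavoromics.data") / "published_vip_table.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, index_col="compound")
    return df


def published_vips(response: str) -> pd.DataFrame:
    """Volatile x period VIP matrix for one response ('sweetness'/'liking'),
    sugars excluded."""
    df = load_published_vip_table()
    df = df[df["class"] != "sugar"]
    cols = [f"vip_{response}_{p}" for p in _PERIODS]
    out = df[cols]
    out.columns = list(_PERIODS)
    return out


def published_adjusted_p(response: str) -> pd.Series:
    """Bonferroni-adjusted slope p-values for one response, volatiles only."""
    df = load_published_vip_table()
    df = df[df["class"] != "sugar"]
    return df[f"p_adj_{response}"]
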