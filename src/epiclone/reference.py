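"""Published summary tables from the Cardamine leucantha field survey.

These small tables ship with the package as worked-example inputs: the
per-locus positional / seasonal stability concordances and the per-locus
global methylation probabilities with deviating-genet counts, for the 24
polymorphic MS-AFLP loci of the original study population.  They let users
exercise the summary arithmetic (column means, ranges, deviation tallies)
without access to the undeposited raw field data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("epiclone.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="locus")


def stability_table() -> pd.DataFrame:
    """Per-locus stability concordances (%): positional and seasonal, CG / CHG."""
    return _load("stability_reference.tsv")


def global_probability_table() -> pd.DataFrame:
    """Per-locus global probabilities (%) and deviating-genet counts per class."""
    return _load("global_probability_reference.tsv")


def stability_summary() -> dict[str, float]:
    """Means and extremes of the stability table (all cells per column group)."""
    t = stability_table()
    pos = t[["positional_CG", "positional_CHG"]].to_numpy()
    sea = t[["seasonal_CG", "seasonal_CHG"]].to_numpy()
    return {
        "positional_mean": float(pos.mean()),
        "positional_min": float(pos.min()),
        "positional_max": float(pos.max()),
        "seasonal_mean": float(sea.mean()),
        "seasonal_min": float(sea.min()),
        "seasonal_max": float(sea.max()),
    }


def global_probability_summary() -> dict[str, float]:
    """Column means and ranges of the three global-probability columns."""
    t = global_probability_table()
    out: dict[str, float] = {}
    for klass in ("n", "m", "h"):
        col = t[f"{klass}_global"]
        out[f"{klass}_mean"] = float(col.mean())
        out[f"{klass}_min"] = float(col.min())
        out[f"{klass}_max"] = float(col.max())
    return out
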