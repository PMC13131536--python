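"""Delimited-text I/O for tip trait tables.

A tip table is a TSV with a ``taxon`` column and any subset of ``value``
(continuous), ``state`` (discrete level), and ``censored`` (``low``/``high``).
Rows with neither value nor state are fully ambiguous (missing data).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .likelihood import TipObservation

__all__ = ["read_tip_table", "write_tip_table", "observations_from_frame"]


def observations_from_frame(df: pd.DataFrame) -> list:
    obs = []
    for _, row in df.iterrows():
        taxon = str(row["taxon"])
        value = row.get("value", np.nan)
        state = row.get("state", np.nan)
        cens = row.get("censored", np.nan)
        has_v = pd.notna(value)
        has_s = pd.notna(state)
        if pd.notna(cens):
            obs.append(TipObservation(taxon, "censored", value=float(value),
                                      side=str(cens)))
        elif has_v and has_s:
            obs.append(TipObservation(taxon, "joint", value=float(value),
                                      level=int(state)))
        elif has_v:
            obs.append(TipObservation(taxon, "point", value=float(value)))
        elif has_s:
            obs.append(TipObservation(taxon, "discrete", level=int(state)))
        else:
            obs.append(TipObservation(taxon, "missing"))
    return obs


def read_tip_table(path) -> list:
    return observations_from_frame(pd.read_csv(path, sep="\t"))


def write_tip_table(observations, path) -> None:
    rows = []
    for o in observations:
        rows.append({"taxon": o.taxon,
                     "value": o.value if o.value is not None else "",
                     "state": o.level if o.level is not None else "",
                     "censored": o.side if o.side is not None else ""})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
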