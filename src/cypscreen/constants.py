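"""Packaged compound constants for the five proton pump inhibitors.

Molecular weights are standard free-base values (g/mol).  Total Cmax values
(µg/mL) are peak plasma concentrations at the highest labelled dose; the
ilaprazole entry has no labelled source and is back-derived from its
published unbound Cmax at fu = 0.01, flagged ``back_derived`` in the CSV.
Ticlopidine is the positive-inhibitor control and carries no Cmax.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .plate import CompoundProfile

MOLECULAR_WEIGHTS = {
    "Omeprazole": 345.42,
    "Lansoprazole": 369.36,
    "Pantoprazole": 383.37,
    "Rabeprazole": 359.44,
    "Ilaprazole": 366.44,
    "Ticlopidine": 263.78,
}

PPI_NAMES = ("Omeprazole", "Lansoprazole", "Pantoprazole", "Rabeprazole", "Ilaprazole")


def constants_table() -> pd.DataFrame:
    """The packaged constants table as a DataFrame (includes cmax_source)."""
    with resources.files("cypscreen.data").joinpath("ppi_constants.csv").open() as fh:
        return pd.read_csv(fh)


def builtin_profiles() -> dict[str, CompoundProfile]:
    """CompoundProfile for every packaged compound, keyed by name."""
    df = constants_table()
    return {
        row["name"]: CompoundProfile(
            name=row["name"],
            molecular_weight=float(row["molecular_weight"]),
            cmax_total_ug_per_ml=float(row["cmax_ug_per_ml"]),
            fu_plasma=float(row["fu_plasma"]),
            fu_incubation=float(row["fu_incubation"]),
        )
        for _, row in df.iterrows()
    }
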