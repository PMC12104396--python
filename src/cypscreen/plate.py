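"""Plate-level domain types and assay arithmetic.

This module holds the vocabulary of a 96-well endpoint fluorometric
inhibition assay: individual well readings with their role on the plate,
serial-dilution arithmetic, compound constants, and the percent-inhibition
statistic computed against the solvent (uninhibited) and positive-inhibitor
(fully inhibited) controls,

    %I = (1 - (X - B) / (A - B)) * 100

where X is the test-well fluorescence, A the solvent-control mean and B the
positive-control mean.  Percent inhibition is deliberately NOT clipped to
[0, 100]: dose-response fitting needs the unclipped values, and clipping is
offered only as a reporting option.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ROLES = ("test", "solvent_control", "positive_control", "standard", "blank")

#: Units accepted for well concentrations.
CONC_UNITS = ("uM", "nM", "ug/mL")

_WELL_RE = re.compile(r"^([A-Ha-h])(\d{1,2})$")

PLATE_ROWS = "ABCDEFGH"
PLATE_COLUMNS = tuple(range(1, 13))


class DegenerateControlsError(ValueError):
    """Raised when the solvent and positive controls coincide (zero assay window)."""


class MissingControlError(ValueError):
    """Raised when a required control role is absent from a plate."""


def parse_well(label: str) -> str:
    """Validate and canonicalise a 96-well coordinate (rows A-H, columns 1-12).

    Parsing is case-insensitive; the canonical form is uppercase without
    zero-padding, e.g. ``'a01'`` -> ``'A1'``.
    """
    m = _WELL_RE.match(label.strip())
    if not m:
        raise ValueError(f"not a well coordinate: {label!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if not 1 <= col <= 12:
        raise ValueError(f"column out of range 1-12 in well {label!r}")
    return f"{row}{col}"


def well_sort_key(well: str) -> tuple[int, int]:
    """Row-major ordering key (A1, A2, ..., A12, B1, ...)."""
    w = parse_well(well)
    return (PLATE_ROWS.index(w[0]), int(w[1:]))


@dataclass(frozen=True)
class WellMeasurement:
    """One well's endpoint read: role, compound, concentration and RFU.

    Invariants: blanks carry concentration 0; test wells carry a compound
    name and a positive concentration; RFU is finite and non-negative.
    """

    plate_id: str
    well: str
    role: str
    compound: str
    conc_value: float
    conc_unit: str
    rfu: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "well", parse_well(self.well))
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.conc_unit not in CONC_UNITS:
            raise ValueError(f"unknown unit {self.conc_unit!r}; expected one of {CONC_UNITS}")
        if not math.isfinite(self.rfu) or self.rfu < 0:
            raise ValueError(f"rfu must be finite and >= 0, got {self.rfu}")
        if self.conc_value < 0 or not math.isfinite(self.conc_value):
            raise ValueError(f"concentration must be finite and >= 0, got {self.conc_value}")
        if self.role == "blank" and self.conc_value != 0:
            raise ValueError("blank wells must have concentration 0")
        if self.role == "test":
            if not self.compound:
                raise ValueError("test wells must name a compound")
            if self.conc_value <= 0:
                raise ValueError("test wells must have concentration > 0")


@dataclass(frozen=True)
class DilutionSeries:
    """Descending geometric dilution series: c_i = top / fold**i."""

    top_concentration: float
    fold: float
    n_points: int
    unit: str = "uM"

    def __post_init__(self) -> None:
        if self.top_concentration <= 0:
            raise ValueError("top concentration must be > 0")
        if self.fold <= 1:
            raise ValueError("dilution fold must be > 1")
        if self.n_points < 2:
            raise ValueError("a dilution series needs at least 2 points")
        if self.unit not in CONC_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")

    @property
    def concentrations(self) -> list[float]:
        return [self.top_concentration / self.fold**i for i in range(self.n_points)]


def build_dilution_series(top: float, fold: float, n: int, unit: str = "uM") -> DilutionSeries:
    """Two-fold (or any-fold) serial dilution from a top concentration."""
    return DilutionSeries(top_concentration=top, fold=fold, n_points=n, unit=unit)


#: 4-point preset honouring the published 0.8-6.4 µg/mL test range.
PAPER_RANGE_PRESET = DilutionSeries(top_concentration=6.4, fold=2.0, n_points=4, unit="ug/mL")


@dataclass(frozen=True)
class CompoundProfile:
    """Per-drug constants for in-vitro-to-in-vivo extrapolation.

    fu_plasma is the fraction unbound in plasma (regulatory default 0.01 for
    highly protein-bound drugs); fu_incubation the fraction unbound in the
    incubation system (default 0.02).
    """

    name: str
    molecular_weight: float
    cmax_total_ug_per_ml: float = 0.0
    fu_plasma: float = 0.01
    fu_incubation: float = 0.02

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be > 0")
        if not 0 < self.fu_plasma <= 1:
            raise ValueError("fu_plasma must be in (0, 1]")
        if not 0 < self.fu_incubation <= 1:
            raise ValueError("fu_incubation must be in (0, 1]")
        if self.cmax_total_ug_per_ml < 0:
            raise ValueError("cmax_total must be >= 0")


@dataclass(frozen=True)
class AssayConditions:
    """Metadata describing the endpoint assay setup; carried, not simulated.

    Both the 20-min preincubation and the 10-min reaction are stored
    separately (their sum is the plate's total incubation time).
    """

    premix_volume_ul: float = 50.0
    substrate_mix_volume_ul: float = 10.0
    preincubation_minutes: float = 20.0
    reaction_minutes: float = 10.0
    stop_reagent: str = "0.5 M Tris buffer"
    excitation_nm: float = 415.0
    emission_nm: float = 460.0
    mode: str = "endpoint"

    def __post_init__(self) -> None:
        for name in ("premix_volume_ul", "substrate_mix_volume_ul",
                     "preincubation_minutes", "reaction_minutes",
                     "excitation_nm", "emission_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.mode != "endpoint":
            raise ValueError("only endpoint assay mode is supported")


# ---------------------------------------------------------------------------
# core arithmetic
# ---------------------------------------------------------------------------

def percent_inhibition(x_rfu: float, a_rfu: float, b_rfu: float) -> float:
    """Percent inhibition of a test well against the plate controls.

    Parameters
    ----------
    x_rfu : test-well fluorescence.
    a_rfu : solvent-control (uninhibited reaction) fluorescence.
    b_rfu : positive-inhibitor (full inhibition) fluorescence.

    Returns ``(1 - (x - b)/(a - b)) * 100``, unclipped.
    """
    for v in (x_rfu, a_rfu, b_rfu):
        if not math.isfinite(v):
            raise ValueError("RFU inputs must be finite")
    if a_rfu == b_rfu:
        raise DegenerateControlsError(
            "solvent and positive controls are equal: assay window is zero"
        )
    return (1.0 - (x_rfu - b_rfu) / (a_rfu - b_rfu)) * 100.0


def clip_inhibition(values: Iterable[float]) -> np.ndarray:
    """Reporting helper: clip percent inhibition to [0, 100]."""
    return np.clip(np.asarray(list(values), dtype=float), 0.0, 100.0)


def mass_conc_to_molar(conc_ug_per_ml: float, molecular_weight: float) -> float:
    """Convert µg/mL to µM given a molecular weight in g/mol."""
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be > 0")
    return conc_ug_per_ml * 1000.0 / molecular_weight


def molar_to_mass_conc(conc_um: float, molecular_weight: float) -> float:
    """Convert µM to µg/mL given a molecular weight in g/mol."""
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be > 0")
    return conc_um * molecular_weight / 1000.0


@dataclass(frozen=True)
class ControlSummary:
    """Replicate-averaged plate controls: A (solvent) and B (positive) RFU.

    SDs are NaN when only a single replicate exists for a role (flagged
    rather than reported as 0).
    """

    a_rfu: float
    b_rfu: float
    a_sd: float
    b_sd: float
    n_solvent: int
    n_positive: int


def aggregate_controls(wells: Sequence[WellMeasurement]) -> ControlSummary:
    """Average replicate control wells at the RFU level.

    Averaging happens before the percent-inhibition formula is applied (the
    formula takes a single A and B), matching plate-reader convention.
    """
    solvent = [w.rfu for w in wells if w.role == "solvent_control"]
    positive = [w.rfu for w in wells if w.role == "positive_control"]
    if not solvent:
        raise MissingControlError("no solvent_control wells on plate")
    if not positive:
        raise MissingControlError("no positive_control wells on plate")

    def _sd(vals: list[float]) -> float:
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")

    return ControlSummary(
        a_rfu=float(np.mean(solvent)),
        b_rfu=float(np.mean(positive)),
        a_sd=_sd(solvent),
        b_sd=_sd(positive),
        n_solvent=len(solvent),
        n_positive=len(positive),
    )


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

PLATE_CSV_COLUMNS = ["plate_id", "well", "role", "compound", "conc_value", "conc_unit", "rfu"]
COMPOUND_CSV_COLUMNS = ["name", "molecular_weight", "cmax_ug_per_ml", "fu_plasma", "fu_incubation"]


def wells_to_frame(wells: Sequence[WellMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plate_id": w.plate_id,
                "well": w.well,
                "role": w.role,
                "compound": w.compound,
                "conc_value": w.conc_value,
                "conc_unit": w.conc_unit,
                "rfu": w.rfu,
            }
            for w in wells
        ],
        columns=PLATE_CSV_COLUMNS,
    )


def frame_to_wells(df: pd.DataFrame) -> list[WellMeasurement]:
    missing = set(PLATE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        compound = "" if pd.isna(row.compound) else str(row.compound)
        out.append(
            WellMeasurement(
                plate_id=str(row.plate_id),
                well=str(row.well),
                role=str(row.role),
                compound=compound,
                conc_value=float(row.conc_value),
                conc_unit=str(row.conc_unit),
                rfu=float(row.rfu),
            )
        )
    return out


def write_plate_csv(wells: Sequence[WellMeasurement], path) -> None:
    wells_to_frame(wells).to_csv(path, index=False)


def read_plate_csv(path) -> list[WellMeasurement]:
    # round_trip float parsing keeps read(write(x)) lossless to the bit
    df = pd.read_csv(path, keep_default_na=False, na_values=[],
                     float_precision="round_trip")
    return frame_to_wells(df)


def write_compounds_csv(profiles: Sequence[CompoundProfile], path) -> None:
    pd.DataFrame(
        [
            {
                "name": p.name,
                "molecular_weight": p.molecular_weight,
                "cmax_ug_per_ml": p.cmax_total_ug_per_ml,
                "fu_plasma": p.fu_plasma,
                "fu_incubation": p.fu_incubation,
            }
            for p in profiles
        ],
        columns=COMPOUND_CSV_COLUMNS,
    ).to_csv(path, index=False)


def read_compounds_csv(path) -> dict[str, CompoundProfile]:
    df = pd.read_csv(path)
    missing = set(COMPOUND_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"compound table missing columns: {sorted(missing)}")
    return {
        str(r.name_): CompoundProfile(
            name=str(r.name_),
            molecular_weight=float(r.molecular_weight),
            cmax_total_ug_per_ml=float(r.cmax_ug_per_ml),
            fu_plasma=float(r.fu_plasma),
            fu_incubation=float(r.fu_incubation),
        )
        for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
    }
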