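"""Kinetic simulator for endpoint fluorometric inhibition plates.

Stands in for the wet assay: a recombinant CYP isozyme converts a
fluorogenic substrate to a fluorescent product under competitive
inhibition,

    v(I) = Vmax * S / (Km * (1 + I/Ki) + S),

with product accumulating linearly over the reaction window (no substrate
depletion) and read out as RFU = background + gain * product.  Measurement
noise is multiplicative Gaussian with a CV parameter, drawn per well in
row-major plate order so a seed fully determines the plate.

Under this kinetics the noiseless percent-inhibition curve is exactly the
Hill-slope-1 logistic %I(I) = 100 * I / (I + IC50) with
IC50 = Ki * (1 + S/Km) — the closed form the dose-response fitter is
checked against.

Default plate layout (96 wells):

* column 1: fluorescent standard, two-fold from 500 nM in A1 down to G1,
  buffer blank in H1;
* column 2: solvent controls A2-D2, ticlopidine-style positive controls
  E2-G2, blank H2;
* columns 3-12: test compounds, one dilution series per column pair
  (duplicates), highest concentration in row A.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .plate import (
    DilutionSeries,
    PLATE_ROWS,
    WellMeasurement,
    well_sort_key,
    wells_to_frame,
    write_plate_csv,
)

STANDARD_TOP_NM = 500.0
STANDARD_POINTS = 7


@dataclass(frozen=True)
class KineticParams:
    """Ground-truth kinetics and readout parameters for the simulator.

    Defaults keep the substrate well below Km (S = 1 µM vs Km = 10 µM, the
    regime in which the /2 Ki shortcut is conservative) and give ~1 kRFU of
    uninhibited signal over the 10-min reaction.
    """

    vmax_nm_per_min: float = 550.0
    km_um: float = 10.0
    s_um: float = 1.0
    reaction_minutes: float = 10.0
    fluorescence_gain: float = 2.0   # RFU per nM product
    background_rfu: float = 50.0
    noise_cv: float = 0.05
    residual_activity_at_full_inhibition: float = 0.0
    paper_mode: bool = True          # enforce S <= Km

    def __post_init__(self) -> None:
        for name in ("vmax_nm_per_min", "km_um", "s_um", "reaction_minutes",
                     "fluorescence_gain", "background_rfu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 <= self.residual_activity_at_full_inhibition < 1:
            raise ValueError("residual activity must be in [0, 1)")
        if self.paper_mode and self.s_um > self.km_um:
            raise ValueError("substrate must not exceed Km when paper_mode is set")

    def to_dict(self) -> dict:
        return {
            "vmax_nm_per_min": self.vmax_nm_per_min,
            "km_um": self.km_um,
            "s_um": self.s_um,
            "reaction_minutes": self.reaction_minutes,
            "fluorescence_gain": self.fluorescence_gain,
            "background_rfu": self.background_rfu,
            "noise_cv": self.noise_cv,
            "residual_activity_at_full_inhibition": self.residual_activity_at_full_inhibition,
        }


def simulate_rate(i_um: float, ki_um: float, params: KineticParams) -> float:
    """Product formed (nM) at inhibitor concentration ``i_um``.

    Competitive inhibition; linear accumulation over the reaction window.
    """
    if i_um < 0:
        raise ValueError("inhibitor concentration must be >= 0")
    if ki_um <= 0:
        raise ValueError("Ki must be > 0")
    v = params.vmax_nm_per_min * params.s_um / (
        params.km_um * (1.0 + i_um / ki_um) + params.s_um
    )
    return v * params.reaction_minutes


def ic50_from_ki(ki_um: float, params: KineticParams) -> float:
    """The IC50 implied by the kinetics: Ki * (1 + S/Km)."""
    return ki_um * (1.0 + params.s_um / params.km_um)


@dataclass(frozen=True)
class SimulatedPlate:
    """A generated plate plus its ground truth."""

    wells: tuple[WellMeasurement, ...]
    truth: dict
    seed: int
    params: KineticParams

    def write(self, plate_path, truth_path) -> None:
        write_plate_csv(list(self.wells), plate_path)
        payload = {
            "truth": self.truth,
            "params": self.params.to_dict(),
            "seed": self.seed,
        }
        Path(truth_path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    def frame(self):
        return wells_to_frame(list(self.wells))


def simulate_plate(
    compounds: list[tuple[str, float]],
    dilution: DilutionSeries | None = None,
    replicates: int = 2,
    params: KineticParams | None = None,
    seed: int = 0,
    plate_id: str = "SIM1",
) -> SimulatedPlate:
    """Simulate a complete plate for ``(name, ki_true_um)`` compounds.

    Each compound occupies ``replicates`` adjacent columns, with the
    dilution series (default 8-point two-fold from 12.8 µM) running down
    the rows.  Deterministic given ``seed``.
    """
    params = params or KineticParams()
    dilution = dilution or DilutionSeries(top_concentration=12.8, fold=2.0, n_points=8, unit="uM")
    if dilution.n_points > len(PLATE_ROWS):
        raise ValueError("dilution series longer than plate column")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    n_compound_cols = len(compounds) * replicates
    if n_compound_cols > 10:
        raise ValueError(
            f"layout collision: {len(compounds)} compounds x {replicates} replicates "
            "need more than the 10 available columns"
        )
    for name, ki in compounds:
        if ki <= 0:
            raise ValueError(f"ki_true must be > 0 for {name}")

    product0 = simulate_rate(0.0, 1.0, params)  # Ki irrelevant at I=0

    assignments: dict[str, tuple[str, str, float]] = {}  # well -> (role, compound, conc_uM)

    def assign(well: str, role: str, compound: str, conc: float) -> None:
        if well in assignments:
            raise ValueError(f"layout collision at well {well}")
        assignments[well] = (role, compound, conc)

    # column 1: fluorescent standard series + blank
    std = DilutionSeries(top_concentration=STANDARD_TOP_NM, fold=2.0,
                         n_points=STANDARD_POINTS, unit="nM")
    for i, conc in enumerate(std.concentrations):
        assign(f"{PLATE_ROWS[i]}1", "standard", "", conc)
    assign("H1", "blank", "", 0.0)

    # column 2: solvent + positive controls + blank
    for row in "ABCD":
        assign(f"{row}2", "solvent_control", "", 0.0)
    for row in "EFG":
        assign(f"{row}2", "positive_control", "", 0.0)
    assign("H2", "blank", "", 0.0)

    # columns 3+: compounds in duplicate columns
    col = 3
    for name, _ in compounds:
        for _rep in range(replicates):
            for i, conc in enumerate(dilution.concentrations):
                assign(f"{PLATE_ROWS[i]}{col}", "test", name, conc)
            col += 1

    ki_by_name = dict(compounds)

    def mean_rfu(role: str, compound: str, conc: float) -> float:
        if role == "standard":
            return params.background_rfu + params.fluorescence_gain * conc  # conc in nM
        if role == "blank":
            return params.background_rfu
        if role == "solvent_control":
            return params.background_rfu + params.fluorescence_gain * product0
        if role == "positive_control":
            residual = params.residual_activity_at_full_inhibition
            return params.background_rfu + params.fluorescence_gain * residual * product0
        product = simulate_rate(conc, ki_by_name[compound], params)
        return params.background_rfu + params.fluorescence_gain * product

    rng = np.random.default_rng(seed)
    wells: list[WellMeasurement] = []
    for well in sorted(assignments, key=well_sort_key):
        role, compound, conc = assignments[well]
        mu = mean_rfu(role, compound, conc)
        eps = rng.normal(0.0, params.noise_cv) if params.noise_cv > 0 else 0.0
        rfu = max(mu * (1.0 + eps), 0.0)
        unit = "nM" if role == "standard" else "uM"
        wells.append(
            WellMeasurement(
                plate_id=plate_id, well=well, role=role, compound=compound,
                conc_value=conc, conc_unit=unit, rfu=rfu,
            )
        )

    truth = {
        name: {"ki_true_um": ki, "ic50_true_um": ic50_from_ki(ki, params)}
        for name, ki in compounds
    }
    return SimulatedPlate(wells=tuple(wells), truth=truth, seed=seed, params=params)


def make_fixture_suite(out_dir, seed: int = 11) -> dict[str, Path]:
    """Write three small canonical plate fixtures for testing.

    ``clean`` is noiseless, ``noisy`` uses the default 5% CV, and
    ``degenerate`` lacks positive-control wells so control aggregation must
    fail on it.  Byte-identical across reruns with the same seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    compounds = [("DrugA", 2.0), ("DrugB", 6.0)]

    clean = simulate_plate(compounds, params=KineticParams(noise_cv=0.0),
                           seed=seed, plate_id="CLEAN")
    noisy = simulate_plate(compounds, params=KineticParams(), seed=seed, plate_id="NOISY")

    paths = {
        "clean": out / "plate_clean.csv",
        "clean_truth": out / "plate_clean_truth.json",
        "noisy": out / "plate_noisy.csv",
        "noisy_truth": out / "plate_noisy_truth.json",
        "degenerate": out / "plate_degenerate.csv",
    }
    clean.write(paths["clean"], paths["clean_truth"])
    noisy.write(paths["noisy"], paths["noisy_truth"])
    degenerate = [w for w in noisy.wells if w.role != "positive_control"]
    write_plate_csv(degenerate, paths["degenerate"])
    return paths
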