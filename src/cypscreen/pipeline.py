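"""End-to-end orchestration: plate table in, fits and risk assessments out.

Two entry modes exist because raw plate data is not always available:

* :func:`analyze_plate` — the full chain: control aggregation, per-well
  percent inhibition, 4PL IC50 fits with bootstrap SDs, then the
  extrapolation chain to a DDI risk flag.
* :func:`replay_ic50s` — published IC50s supplied directly, fitting
  skipped; the extrapolation arithmetic runs unchanged.  This is the mode
  for auditing printed summary tables.

Every run carries a provenance block (config hash, seed, package version)
sufficient to reproduce deterministic outputs bit-for-bit, and the
assumption constants in force (fu values, Ki convention, threshold) are
logged at INFO.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dose_response import (
    BootstrapResult,
    DoseResponsePoint,
    FitOptions,
    fit_ic50,
)
from .ivive import DDIAssessment, assess_compound, rank_by_potency
from .plate import (
    CompoundProfile,
    MissingControlError,
    WellMeasurement,
    aggregate_controls,
    mass_conc_to_molar,
    percent_inhibition,
)

log = logging.getLogger("cypscreen")

ASSESSMENT_COLUMNS = [
    "compound", "ic50_uM", "ic50_u_uM", "ki_u_uM",
    "cmax_u_ug_per_ml", "cmax_u_uM", "ratio", "threshold", "risk_flag",
]
FIT_COLUMNS = ["compound", "bottom", "top", "hill", "ic50_uM", "ic50_sd_uM",
               "sse", "converged"]

_CONFIG_KEYS = {
    "fu_incubation", "fu_plasma", "ki_convention", "s_um", "km_um",
    "ddi_threshold", "fix_bottom", "fix_top", "n_boot", "seed",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Assumption constants and fit options for one analysis run.

    Fractions unbound here override whatever the compound table carries, so
    a single config line changes the regulatory assumption for every drug.
    """

    fu_incubation: float = 0.02
    fu_plasma: float = 0.01
    ki_convention: str = "regulatory_half"   # or "cheng_prusoff"
    s_um: float | None = None
    km_um: float | None = None
    ddi_threshold: float = 0.02
    fix_bottom: float | None = 0.0
    fix_top: float | None = 100.0
    n_boot: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fu_incubation <= 1:
            raise ValueError("fu_incubation must be in (0, 1]")
        if not 0 < self.fu_plasma <= 1:
            raise ValueError("fu_plasma must be in (0, 1]")
        if self.ddi_threshold <= 0:
            raise ValueError("ddi_threshold must be > 0")
        if self.ki_convention not in ("regulatory_half", "cheng_prusoff"):
            raise ValueError(f"unknown ki_convention {self.ki_convention!r}")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def fit_options(self) -> FitOptions:
        return FitOptions(fix_bottom=self.fix_bottom, fix_top=self.fix_top)

    def provenance(self) -> dict:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return {
            "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
            "seed": self.seed,
            "version": __version__,
        }


def inhibition_points(
    wells: Sequence[WellMeasurement],
    profiles: dict[str, CompoundProfile] | None = None,
) -> dict[str, list[DoseResponsePoint]]:
    """Per-compound dose-response points from a plate's raw wells.

    Controls are replicate-averaged at the RFU level, each test well is
    normalised to percent inhibition, and µg/mL concentrations are
    converted to µM through the compound's molecular weight.
    """
    controls = aggregate_controls(wells)
    log.debug("controls: A=%.2f (n=%d) B=%.2f (n=%d)", controls.a_rfu,
              controls.n_solvent, controls.b_rfu, controls.n_positive)
    out: dict[str, list[DoseResponsePoint]] = {}
    rep_counter: dict[tuple[str, float], int] = {}
    for w in sorted((w for w in wells if w.role == "test"),
                    key=lambda w: (w.compound, -w.conc_value, w.well)):
        conc = w.conc_value
        if w.conc_unit == "nM":
            conc = conc / 1000.0
        elif w.conc_unit == "ug/mL":
            if profiles is None or w.compound not in profiles:
                raise ValueError(
                    f"µg/mL well for {w.compound!r} needs a molecular weight"
                )
            conc = mass_conc_to_molar(conc, profiles[w.compound].molecular_weight)
        key = (w.compound, conc)
        rep = rep_counter.get(key, 0)
        rep_counter[key] = rep + 1
        pi = percent_inhibition(w.rfu, controls.a_rfu, controls.b_rfu)
        log.debug("well %s %s %.4g µM -> %%I %.2f", w.well, w.compound, conc, pi)
        out.setdefault(w.compound, []).append(
            DoseResponsePoint(concentration=conc, inhibition=pi, replicate_id=rep)
        )
    return out


def bootstrap_plate_ic50(
    wells: Sequence[WellMeasurement],
    compound: str,
    n_boot: int = 300,
    seed: int = 0,
    options: FitOptions | None = None,
    profiles: dict[str, CompoundProfile] | None = None,
) -> BootstrapResult:
    """Plate-level case bootstrap of one compound's IC50.

    Unlike the point-level bootstrap in :mod:`cypscreen.dose_response`,
    control wells are resampled too, so the uncertainty of the shared A and
    B references — which shifts every point on the curve coherently —
    propagates into the IC50 SD.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for a stable SD")
    solvent = [w.rfu for w in wells if w.role == "solvent_control"]
    positive = [w.rfu for w in wells if w.role == "positive_control"]
    if not solvent or not positive:
        raise MissingControlError("plate bootstrap needs both control roles")
    base_points = inhibition_points(wells, profiles)
    if compound not in base_points:
        raise ValueError(f"no test wells for {compound!r}")
    tests = [w for w in wells if w.role == "test" and w.compound == compound]
    concs = []
    by_idx = []
    for w, p in zip(sorted(tests, key=lambda w: (-w.conc_value, w.well)),
                    base_points[compound]):
        concs.append(p.concentration)
        by_idx.append(w.rfu)
    rng = np.random.default_rng(seed)
    samples: list[float] = []
    failed = 0
    n = len(tests)
    for _ in range(n_boot):
        a = float(np.mean(rng.choice(solvent, size=len(solvent))))
        b = float(np.mean(rng.choice(positive, size=len(positive))))
        idx = rng.integers(0, n, size=n)
        try:
            pts = [
                DoseResponsePoint(concs[i], percent_inhibition(by_idx[i], a, b))
                for i in idx
            ]
            fit = fit_ic50(pts, options)
        except ValueError:
            failed += 1
            continue
        if fit.converged:
            samples.append(fit.ic50)
        else:
            failed += 1
    sd = float(np.std(samples, ddof=1)) if len(samples) > 1 else float("nan")
    return BootstrapResult(sd=sd, n_boot=n_boot, failed_fraction=failed / n_boot,
                           ic50_samples=tuple(samples))


@dataclass(frozen=True)
class AnalysisResult:
    fits: pd.DataFrame
    assessments: pd.DataFrame
    assessment_records: tuple[DDIAssessment, ...]
    provenance: dict

    def write(self, fits_csv=None, assessments_csv=None, json_path=None) -> None:
        if fits_csv is not None:
            self.fits.to_csv(fits_csv, index=False)
        if assessments_csv is not None:
            self.assessments.to_csv(assessments_csv, index=False)
        if json_path is not None:
            payload = {
                "provenance": self.provenance,
                "fits": self.fits.to_dict(orient="records"),
                "assessments": self.assessments.to_dict(orient="records"),
            }
            Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")


def _apply_config_fu(profile: CompoundProfile, config: PipelineConfig) -> CompoundProfile:
    return replace(profile, fu_plasma=config.fu_plasma,
                   fu_incubation=config.fu_incubation)


def _log_assumptions(config: PipelineConfig) -> None:
    log.info(
        "assumptions: fu_inc=%.3g fu_plasma=%.3g ki_convention=%s threshold=%.3g",
        config.fu_incubation, config.fu_plasma, config.ki_convention,
        config.ddi_threshold,
    )


def _assess(ic50_um: float, profile: CompoundProfile,
            config: PipelineConfig) -> DDIAssessment:
    return assess_compound(
        ic50_um, _apply_config_fu(profile, config),
        ki_convention=config.ki_convention,
        s_um=config.s_um, km_um=config.km_um,
        threshold=config.ddi_threshold,
    )


def _assessment_frame(records: Sequence[DDIAssessment]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(a, c) for c in ASSESSMENT_COLUMNS} for a in records],
        columns=ASSESSMENT_COLUMNS,
    )


def analyze_plate(
    wells: Sequence[WellMeasurement],
    profiles: dict[str, CompoundProfile],
    config: PipelineConfig | None = None,
) -> AnalysisResult:
    """Full analysis of one plate: fits and DDI assessments per compound.

    Compounds without a profile are fitted but not extrapolated; compounds
    whose fit does not converge appear in the fit table flagged and are
    excluded from the assessment table.
    """
    config = config or PipelineConfig()
    _log_assumptions(config)
    points = inhibition_points(wells, profiles)
    opts = config.fit_options()

    fit_rows = []
    records: list[DDIAssessment] = []
    for name in sorted(points):
        pts = points[name]
        fit = fit_ic50(pts, opts)
        sd = float("nan")
        if fit.converged and config.n_boot >= 100:
            sd = bootstrap_plate_ic50(
                wells, name, n_boot=config.n_boot, seed=config.seed,
                options=opts, profiles=profiles,
            ).sd
        fit_rows.append({
            "compound": name, "bottom": fit.bottom, "top": fit.top,
            "hill": fit.hill, "ic50_uM": fit.ic50, "ic50_sd_uM": sd,
            "sse": fit.residual_sse, "converged": fit.converged,
        })
        if not fit.converged:
            log.warning("fit for %s did not converge; excluded from assessment", name)
            continue
        if name in profiles:
            records.append(_assess(fit.ic50, profiles[name], config))
        else:
            log.warning("no profile for %s; IC50 fitted but not extrapolated", name)

    return AnalysisResult(
        fits=pd.DataFrame(fit_rows, columns=FIT_COLUMNS),
        assessments=_assessment_frame(records),
        assessment_records=tuple(records),
        provenance=config.provenance(),
    )


def replay_ic50s(
    ic50s_um: dict[str, float],
    profiles: dict[str, CompoundProfile],
    config: PipelineConfig | None = None,
) -> AnalysisResult:
    """Extrapolation chain on supplied IC50s (µM); no fitting.

    The mode for auditing published tables: IC50,u, Ki,u, Cmax,u and the
    static-model ratio are recomputed from the inputs and the configured
    assumptions.
    """
    config = config or PipelineConfig()
    _log_assumptions(config)
    records = [
        _assess(ic50, profiles[name], config)
        for name, ic50 in sorted(ic50s_um.items())
    ]
    fits = pd.DataFrame(
        [{"compound": a.compound, "bottom": float("nan"), "top": float("nan"),
          "hill": float("nan"), "ic50_uM": a.ic50_uM, "ic50_sd_uM": float("nan"),
          "sse": float("nan"), "converged": False} for a in records],
        columns=FIT_COLUMNS,
    )
    return AnalysisResult(
        fits=fits,
        assessments=_assessment_frame(records),
        assessment_records=tuple(records),
        provenance=config.provenance(),
    )


def flag_printed_ratios(
    ratios: dict[str, float], threshold: float = 0.02
) -> dict[str, str]:
    """Threshold calls on externally supplied (e.g. published) ratios."""
    from .ivive import RISK_EXCLUDED, RISK_POTENTIAL

    return {
        name: (RISK_POTENTIAL if r >= threshold else RISK_EXCLUDED)
        for name, r in ratios.items()
    }


def render_report(
    assessments: pd.DataFrame,
    printed_ratios: dict[str, float] | None = None,
    provenance: dict | None = None,
) -> str:
    """Human-readable markdown report: potency ranking, flags, discrepancies."""
    if assessments.empty:
        raise ValueError("assessment table is empty")
    records = [
        DDIAssessment(**{c: row[c] for c in ASSESSMENT_COLUMNS})
        for _, row in assessments.iterrows()
    ]
    ordered, had_ties = rank_by_potency(records)

    lines = ["# CYP2C19 inhibition assessment", ""]
    if provenance:
        lines += [
            f"config sha256: `{provenance['config_sha256']}` | "
            f"seed: {provenance['seed']} | cypscreen {provenance['version']}",
            "",
        ]
    lines += [
        "| rank | compound | IC50 (µM) | IC50,u (µM) | Ki,u (µM) | "
        "Cmax,u (µM) | Cmax,u/Ki,u | flag |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for i, a in enumerate(ordered, start=1):
        lines.append(
            f"| {i} | {a.compound} | {a.ic50_uM:.3g} | {a.ic50_u_uM:.4g} | "
            f"{a.ki_u_uM:.4g} | {a.cmax_u_uM:.3g} | {a.ratio:.3g} | {a.risk_flag} |"
        )
    lines.append("")
    lines.append(
        "Potency ranking (most potent first): "
        + " > ".join(a.compound for a in ordered)
        + ("  (ties broken alphabetically)" if had_ties else "")
    )
    flagged = [a.compound for a in ordered if a.risk_flag == "potential_inhibitor"]
    lines.append("")
    lines.append(
        "Potential in vivo inhibitors (ratio >= threshold): "
        + (", ".join(flagged) if flagged else "none")
    )

    if printed_ratios:
        lines += ["", "## Printed vs computed ratios", ""]
        lines.append("| compound | computed | printed | relative difference |")
        lines.append("|---|---|---|---|")
        for a in ordered:
            if a.compound in printed_ratios:
                p = printed_ratios[a.compound]
                rel = abs(a.ratio - p) / p if p else float("nan")
                lines.append(
                    f"| {a.compound} | {a.ratio:.3g} | {p:.3g} | {rel:.1%} |"
                )
        lines.append("")
        lines.append(
            "Note: where printed ratios disagree with Cmax,u/Ki,u computed "
            "from the same table's own columns, the computed value follows "
            "the stated formula; the source of the printed value is unknown."
        )
    return "\n".join(lines) + "\n"
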