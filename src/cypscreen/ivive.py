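"""In-vitro-to-in-vivo extrapolation and static-model DDI risk calls.

The chain implemented here takes an assay IC50 (µM, total) to a regulatory
risk flag:

* unbound IC50:        IC50,u = IC50 / fu_inc           (fu_inc default 0.02)
* inhibition constant: Ki,u = IC50,u / (1 + S/Km)       (Cheng-Prusoff)
  or the regulatory shortcut Ki,u = IC50,u / 2, the default convention
  (equivalent to Cheng-Prusoff at S = Km)
* unbound plasma peak: Cmax,u = Cmax * fu               (fu default 0.01)
* basic static model:  R = Cmax,u / Ki,u, compared (inclusively) against a
  configurable cutoff, 0.02 by default; at or above the cutoff in vivo
  inhibition cannot be excluded.

The ratio is always formed in µM/µM; µg/mL inputs are converted through the
compound's molecular weight first, never divided raw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .plate import CompoundProfile, mass_conc_to_molar

DEFAULT_DDI_THRESHOLD = 0.02

RISK_POTENTIAL = "potential_inhibitor"
RISK_EXCLUDED = "risk_excluded"


def unbound_ic50(ic50_um: float, fu_inc: float = 0.02) -> float:
    """Correct a total IC50 (µM) for nonspecific binding in the incubation."""
    if not 0 < fu_inc <= 1:
        raise ValueError("fu_inc must be in (0, 1]")
    if ic50_um <= 0:
        raise ValueError("ic50 must be > 0")
    return ic50_um / fu_inc


def ki_u_cheng_prusoff(ic50_u_um: float, s_um: float, km_um: float) -> float:
    """Cheng-Prusoff: Ki,u = IC50,u / (1 + S/Km) for competitive inhibition."""
    if km_um <= 0:
        raise ValueError("Km must be > 0")
    if s_um < 0:
        raise ValueError("substrate concentration must be >= 0")
    if ic50_u_um <= 0:
        raise ValueError("ic50_u must be > 0")
    return ic50_u_um / (1.0 + s_um / km_um)


def ki_u_regulatory(ic50_u_um: float) -> float:
    """Regulatory shortcut Ki,u = IC50,u / 2 (Cheng-Prusoff at S = Km)."""
    if ic50_u_um <= 0:
        raise ValueError("ic50_u must be > 0")
    return ic50_u_um / 2.0


def unbound_cmax(profile: CompoundProfile) -> tuple[float, float]:
    """Unbound peak plasma concentration as (µg/mL, µM)."""
    cmax_u_ug = profile.cmax_total_ug_per_ml * profile.fu_plasma
    return cmax_u_ug, mass_conc_to_molar(cmax_u_ug, profile.molecular_weight)


@dataclass(frozen=True)
class DDIAssessment:
    """Per-compound extrapolation record and static-model risk flag."""

    compound: str
    ic50_uM: float
    ic50_u_uM: float
    ki_u_uM: float
    cmax_u_ug_per_ml: float
    cmax_u_uM: float
    ratio: float
    threshold: float
    risk_flag: str

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError("ratio must be >= 0")
        expected = RISK_POTENTIAL if self.ratio >= self.threshold else RISK_EXCLUDED
        if self.risk_flag != expected:
            raise ValueError("risk_flag inconsistent with ratio and threshold")


def ddi_ratio_and_flag(
    cmax_u_um: float,
    ki_u_um: float,
    threshold: float = DEFAULT_DDI_THRESHOLD,
) -> tuple[float, str]:
    """Static-model ratio Cmax,u/Ki,u and its inclusive threshold call."""
    if ki_u_um <= 0:
        raise ValueError("ki_u must be > 0")
    if cmax_u_um < 0:
        raise ValueError("cmax_u must be >= 0")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    ratio = cmax_u_um / ki_u_um
    flag = RISK_POTENTIAL if ratio >= threshold else RISK_EXCLUDED
    return ratio, flag


def assess_compound(
    ic50_um: float,
    profile: CompoundProfile,
    ki_convention: str = "regulatory_half",
    s_um: float | None = None,
    km_um: float | None = None,
    threshold: float = DEFAULT_DDI_THRESHOLD,
) -> DDIAssessment:
    """Full extrapolation chain from a total IC50 (µM) to the risk flag.

    ``ki_convention`` selects the regulatory /2 shortcut (default) or exact
    Cheng-Prusoff, which then requires ``s_um`` and ``km_um``.
    """
    ic50_u = unbound_ic50(ic50_um, profile.fu_incubation)
    if ki_convention == "regulatory_half":
        ki_u = ki_u_regulatory(ic50_u)
    elif ki_convention == "cheng_prusoff":
        if s_um is None or km_um is None:
            raise ValueError("cheng_prusoff convention requires s_um and km_um")
        ki_u = ki_u_cheng_prusoff(ic50_u, s_um, km_um)
    else:
        raise ValueError(f"unknown ki convention {ki_convention!r}")
    cmax_u_ug, cmax_u_um = unbound_cmax(profile)
    ratio, flag = ddi_ratio_and_flag(cmax_u_um, ki_u, threshold)
    return DDIAssessment(
        compound=profile.name,
        ic50_uM=ic50_um,
        ic50_u_uM=ic50_u,
        ki_u_uM=ki_u,
        cmax_u_ug_per_ml=cmax_u_ug,
        cmax_u_uM=cmax_u_um,
        ratio=ratio,
        threshold=threshold,
        risk_flag=flag,
    )


def rank_by_potency(
    assessments: Sequence[DDIAssessment],
) -> tuple[list[DDIAssessment], bool]:
    """Order by ascending IC50 (most potent first).

    Ties break alphabetically by compound name; returns ``(ordered,
    had_ties)`` so reports can flag ambiguous rankings.
    """
    for a in assessments:
        if not a.ic50_uM > 0:
            raise ValueError(f"missing or non-positive IC50 for {a.compound}")
    ordered = sorted(assessments, key=lambda a: (a.ic50_uM, a.compound))
    ic50s = [a.ic50_uM for a in ordered]
    had_ties = len(set(ic50s)) < len(ic50s)
    return list(ordered), had_ties
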