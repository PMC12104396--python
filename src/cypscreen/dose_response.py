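"""Concentration-response modelling: four-parameter logistic IC50 fits.

The model is the standard 4PL on inhibitor concentration c,

    %I(c) = bottom + (top - bottom) / (1 + (ic50 / c)**hill),

fitted by least squares against log10(concentration) for conditioning.  By
default bottom and top are fixed at 0 and 100 because responses are already
normalised to the plate controls ("log(inhibitor) vs normalised response");
an unconstrained mode frees them for QC.  The optimiser is multistarted
over five initial IC50 values spanning the tested concentration range;
ties resolve to the lowest SSE, then the lowest Hill slope.
Non-convergence is flagged, never papered over by interpolation.

IC50 uncertainty comes from a case bootstrap: wells are resampled with
replacement and refitted; the SD of the refitted IC50s is reported along
with the fraction of resamples whose refit failed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

HILL_BOUNDS = (0.1, 10.0)


@dataclass(frozen=True)
class DoseResponsePoint:
    """One (concentration, percent inhibition) observation from one well.

    Concentrations must be strictly positive; zero-concentration control
    wells are consumed upstream by the percent-inhibition normalisation and
    never enter the fit.
    """

    concentration: float
    inhibition: float
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.concentration <= 0 or not np.isfinite(self.concentration):
            raise ValueError("concentration must be finite and > 0")
        if not np.isfinite(self.inhibition):
            raise ValueError("inhibition must be finite")


@dataclass(frozen=True)
class FitOptions:
    """Fit constraints: fix bottom/top (None = free), Hill bounds, multistart."""

    fix_bottom: float | None = 0.0
    fix_top: float | None = 100.0
    hill_bounds: tuple[float, float] = HILL_BOUNDS
    n_starts: int = 5


@dataclass(frozen=True)
class DoseResponseFit:
    bottom: float
    top: float
    hill: float
    ic50: float
    ic50_sd: float
    n_points: int
    converged: bool
    residual_sse: float

    def __post_init__(self) -> None:
        if self.converged:
            if self.ic50 <= 0:
                raise ValueError("converged fit requires ic50 > 0")
            if not self.bottom < self.top:
                raise ValueError("converged fit requires bottom < top")
            if self.hill <= 0:
                raise ValueError("converged fit requires hill > 0")


def four_pl(conc, bottom: float, top: float, hill: float, ic50: float):
    """Evaluate the 4PL at concentration(s) > 0."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ic50 / conc) ** hill)


def predict_inhibition(fit: DoseResponseFit, concentration: float) -> float:
    """Evaluate a converged fit at a positive concentration."""
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    return float(four_pl(concentration, fit.bottom, fit.top, fit.hill, fit.ic50))


def _pack_residual(logc, y, opts: FitOptions):
    """Residual function over free parameters [log10_ic50, hill, (bottom), (top)]."""

    def resid(theta):
        log_ic50, hill = theta[0], theta[1]
        k = 2
        if opts.fix_bottom is None:
            bottom = theta[k]; k += 1
        else:
            bottom = opts.fix_bottom
        top = theta[k] if opts.fix_top is None else opts.fix_top
        # (ic50/c)^hill in log space avoids overflow at extreme ratios
        frac = 1.0 / (1.0 + 10.0 ** (hill * (log_ic50 - logc)))
        return bottom + (top - bottom) * frac - y

    return resid


def fit_ic50(
    points: Sequence[DoseResponsePoint],
    options: FitOptions | None = None,
    ic50_sd: float = float("nan"),
) -> DoseResponseFit:
    """Fit the 4PL to dose-response points and return the IC50.

    Requires >= 4 distinct concentrations.  The IC50 is returned in the
    unit the concentrations were supplied in; rescaling every concentration
    by a factor rescales the IC50 by the same factor and changes nothing
    else about the fit.
    """
    opts = options or FitOptions()
    if len({p.concentration for p in points}) < 4:
        raise ValueError("IC50 fitting needs >= 4 distinct concentrations")
    conc = np.array([p.concentration for p in points], dtype=float)
    y = np.array([p.inhibition for p in points], dtype=float)
    order = np.argsort(conc, kind="stable")
    conc, y = conc[order], y[order]
    logc = np.log10(conc)

    lo, hi = logc.min(), logc.max()
    # log10(ic50) allowed two decades beyond the tested range; starts span it
    bounds_lo = [lo - 2.0, opts.hill_bounds[0]]
    bounds_hi = [hi + 2.0, opts.hill_bounds[1]]
    if opts.fix_bottom is None:
        bounds_lo.append(-100.0); bounds_hi.append(100.0)
    if opts.fix_top is None:
        bounds_lo.append(0.0); bounds_hi.append(200.0)

    starts = np.linspace(lo, hi, opts.n_starts)
    best = None
    for s in starts:
        theta0 = [s, 1.0]
        if opts.fix_bottom is None:
            theta0.append(0.0)
        if opts.fix_top is None:
            theta0.append(100.0)
        try:
            sol = least_squares(
                _pack_residual(logc, y, opts), theta0,
                bounds=(bounds_lo, bounds_hi), method="trf",
            )
        except Exception:
            continue
        if not sol.success:
            continue
        sse = float(np.sum(sol.fun**2))
        key = (round(sse, 10), sol.x[1])  # lowest SSE, then lowest hill
        if best is None or key < best[0]:
            best = (key, sol, sse)

    n = len(points)
    if best is None:
        return DoseResponseFit(
            bottom=float("nan"), top=float("nan"), hill=float("nan"),
            ic50=float("nan"), ic50_sd=ic50_sd, n_points=n,
            converged=False, residual_sse=float("nan"),
        )

    _, sol, sse = best
    log_ic50, hill = sol.x[0], sol.x[1]
    k = 2
    if opts.fix_bottom is None:
        bottom = float(sol.x[k]); k += 1
    else:
        bottom = opts.fix_bottom
    top = float(sol.x[k]) if opts.fix_top is None else opts.fix_top

    # the midpoint is only identified when it falls within a decade of the
    # tested range; flat or saturated responses push it beyond -> flagged,
    # never interpolated
    identifiable = lo - 1.0 <= log_ic50 <= hi + 1.0
    converged = identifiable and bottom < top
    return DoseResponseFit(
        bottom=bottom, top=top, hill=float(hill),
        ic50=float(10.0**log_ic50) if converged else float("nan"),
        ic50_sd=ic50_sd, n_points=n, converged=converged,
        residual_sse=sse,
    )


@dataclass(frozen=True)
class BootstrapResult:
    sd: float
    n_boot: int
    failed_fraction: float
    ic50_samples: tuple[float, ...] = field(repr=False, default=())


def bootstrap_ic50(
    points: Sequence[DoseResponsePoint],
    n_boot: int = 500,
    seed: int = 0,
    options: FitOptions | None = None,
) -> BootstrapResult:
    """Case bootstrap of the IC50: resample wells with replacement, refit.

    Deterministic given ``seed``.  Resamples that end up with fewer than 4
    distinct concentrations, or whose refit does not converge, are counted
    as failures and excluded from the SD.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for a stable SD")
    base = fit_ic50(points, options)
    if not base.converged:
        raise ValueError("bootstrap requires a converged base fit")
    rng = np.random.default_rng(seed)
    pts = list(points)
    n = len(pts)
    samples: list[float] = []
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resample = [pts[i] for i in idx]
        if len({p.concentration for p in resample}) < 4:
            failed += 1
            continue
        fit = fit_ic50(resample, options)
        if fit.converged:
            samples.append(fit.ic50)
        else:
            failed += 1
    sd = float(np.std(samples, ddof=1)) if len(samples) > 1 else float("nan")
    return BootstrapResult(
        sd=sd, n_boot=n_boot, failed_fraction=failed / n_boot,
        ic50_samples=tuple(samples),
    )


def bootstrap_ic50_sd(
    points: Sequence[DoseResponsePoint],
    n_boot: int = 500,
    seed: int = 0,
    options: FitOptions | None = None,
) -> float:
    """SD of the case-bootstrapped IC50 (see :func:`bootstrap_ic50`)."""
    return bootstrap_ic50(points, n_boot=n_boot, seed=seed, options=options).sd
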