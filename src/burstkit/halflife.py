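"""mRNA half-life estimation from transcription-shutoff time courses.

After transcription is blocked (actinomycin D), each transcript's
concentration relaxes exponentially toward an asymptote:

    y(t) = Asym + (R0 - Asym) * exp(-k_decay * t)

Concentrations are obtained from raw counts via ERCC spike-in scaling (the
spike-ins are added at known amounts, so the observed spike-in total in
each sample yields that sample's scale factor).  The decay constant is
fitted per gene by nonlinear least squares with a self-starting
initialization (asymptote from the late timepoints, rate from a log-linear
regression of the decaying component), and the half-life is ``ln 2 /
k_decay`` hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DecayTimeCourse",
    "HalfLifeFit",
    "spikein_normalize",
    "fit_decay",
    "fit_decay_table",
]

LN2 = math.log(2.0)


@dataclass
class DecayTimeCourse:
    """Spike-in normalized concentrations over timepoints (hours).

    ``timepoints`` gives the harvest time of every sample column; repeated
    values denote replicate samples of the same timepoint (all points are
    fitted jointly).  The distinct timepoints must increase strictly from 0.
    """

    timepoints: np.ndarray
    concentrations: pd.DataFrame  # genes x samples
    scale_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        t = np.unique(self.timepoints)
        if t[0] != 0 or t.size < 2 or np.any(np.diff(self.timepoints) < 0):
            raise ValueError(
                "timepoints must start at 0 and increase (repeats = replicates)"
            )
        if self.concentrations.shape[1] != self.timepoints.size:
            raise ValueError("concentration columns must match timepoints")
        if (self.concentrations.to_numpy() < 0).any():
            raise ValueError("concentrations must be nonnegative")


@dataclass(frozen=True)
class HalfLifeFit:
    """One gene's fitted exponential decay."""

    gene: str
    asym: float
    r0: float
    k_decay: float  # per hour
    rss: float
    converged: bool

    @property
    def half_life(self) -> float:
        """Half-life in hours, ln 2 / k_decay; NaN when not converged."""
        if not self.converged or self.k_decay <= 0:
            return float("nan")
        return LN2 / self.k_decay


def spikein_normalize(
    raw: pd.DataFrame,
    timepoints_hours,
    *,
    spikein_prefix: str = "ERCC-",
    spikein_total_amount: float = 1.0,
) -> DecayTimeCourse:
    """Convert raw per-sample counts to concentrations via spike-in totals.

    Each sample's scale factor is ``spikein_total_amount`` (the known total
    spiked input, arbitrary concentration units) divided by that sample's
    observed total spike-in counts; gene rows are multiplied by it.
    Spike-in rows are identified by name prefix and dropped from the
    returned course.
    """
    is_spike = raw.index.astype(str).str.startswith(spikein_prefix)
    if not is_spike.any():
        raise ValueError(f"no spike-in rows with prefix {spikein_prefix!r}")
    spike_totals = raw.loc[is_spike].sum(axis=0)
    if (spike_totals <= 0).any():
        bad = spike_totals.index[spike_totals <= 0].tolist()
        raise ValueError(f"zero spike-in counts in sample(s) {bad}")
    scale = spikein_total_amount / spike_totals
    conc = raw.loc[~is_spike].mul(scale, axis=1)
    return DecayTimeCourse(
        timepoints=np.asarray(timepoints_hours, dtype=float),
        concentrations=conc,
        scale_factors=scale,
    )


def _self_start(t: np.ndarray, y: np.ndarray, fix_asym_zero: bool) -> tuple[float, float, float]:
    """SSasymp-style initial values (Asym from late points, k from log-linear fit)."""
    asym0 = 0.0 if fix_asym_zero else float(min(y[-1], y.min()))
    r00 = float(y[0])
    z = y - asym0
    pos = z > max(1e-12, 1e-9 * max(abs(r00), 1.0))
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(z[pos]), 1)[0]
        k0 = max(-slope, 1e-6)
    else:
        k0 = 0.1
    return asym0, r00, k0


def fit_decay(
    concentrations,
    timepoints_hours,
    *,
    gene: str = "",
    fix_asym_zero: bool = False,
    weighting: str = "relative",
    max_iter: int = 2000,
) -> HalfLifeFit:
    """Least-squares exponential-decay fit of one gene's time course.

    Replicate measurements may be supplied by repeating timepoints; all
    points are fitted jointly.  ``weighting="relative"`` (default) scales
    residuals by the observed value, the efficient choice under the
    multiplicative (log-normal) noise of sequencing-derived concentrations;
    ``"absolute"`` is plain unweighted least squares.  A fit is flagged not
    converged when the optimizer fails or returns a nonpositive decay
    constant, in which case the half-life is NaN.
    """
    t = np.asarray(timepoints_hours, dtype=float)
    y = np.asarray(concentrations, dtype=float)
    finite = np.isfinite(y)
    t, y = t[finite], y[finite]
    if t.size < 4:
        raise ValueError("need at least 4 finite timepoints")
    if weighting not in ("relative", "absolute"):
        raise ValueError("weighting must be 'relative' or 'absolute'")
    sigma = np.maximum(y, 1e-9 * max(float(y.max()), 1.0)) if weighting == "relative" else None
    asym0, r00, k0 = _self_start(t, y, fix_asym_zero)

    try:
        if fix_asym_zero:
            popt, _ = curve_fit(
                lambda tt, r0, k: r0 * np.exp(-k * tt),
                t, y, p0=[r00, k0], sigma=sigma, maxfev=max_iter,
            )
            asym, r0, k = 0.0, float(popt[0]), float(popt[1])
        else:
            popt, _ = curve_fit(
                lambda tt, a, r0, k: a + (r0 - a) * np.exp(-k * tt),
                t, y, p0=[asym0, r00, k0], sigma=sigma, maxfev=max_iter,
            )
            asym, r0, k = (float(v) for v in popt)
        converged = k > 0 and math.isfinite(k)
    except RuntimeError:
        asym, r0, k, converged = asym0, r00, float("nan"), False

    if converged:
        resid = y - (asym + (r0 - asym) * np.exp(-k * t))
        rss = float(resid @ resid)
    else:
        rss = float("nan")
    return HalfLifeFit(gene=gene, asym=asym, r0=r0, k_decay=k, rss=rss, converged=converged)


def fit_decay_table(course: DecayTimeCourse, **kwargs) -> pd.DataFrame:
    """Fit every gene in a time course; returns the half-life output table."""
    rows = []
    for gene, y in course.concentrations.iterrows():
        fit = fit_decay(y.to_numpy(), course.timepoints, gene=str(gene), **kwargs)
        rows.append(
            {
                "gene": fit.gene,
                "k_decay_per_hour": fit.k_decay,
                "half_life_hours": fit.half_life,
                "Asym": fit.asym,
                "R0": fit.r0,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows).set_index("gene")
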