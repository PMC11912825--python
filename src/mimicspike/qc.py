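"""Standard-curve and dose-response quality control for spike-in experiments.

A staggered spike-in pool (members added at different known copy numbers)
turns every sample into its own standard curve: regressing the log10
within-pool read percentage on log10 copies should give a slope near one
when amplification and counting are consistent across members and
concentrations.  Dilution series of a pool against a fixed background
follow a rectangular hyperbola when reads at fixed depth are plotted
against spike copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .quantify import AssignmentResult, QuantError, SpikeConfig


@dataclass(frozen=True)
class StandardCurveFit:
    sample: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    excluded: tuple[str, ...] = ()
    flagged: bool = False
    message: str = ""


@dataclass(frozen=True)
class HyperbolaFit:
    """y = a*x / (b + x): asymptote a (max reads), half-saturation b (copies)."""
    asymptote: float
    half_saturation: float
    residual_rmse: float
    n_points: int
    flagged: bool = False
    message: str = ""

    def predict(self, x):
        return self.asymptote * np.asarray(x, float) / (self.half_saturation + np.asarray(x, float))


def staggered_curve(mimic_counts, copies, sample: str = "",
                    exclude=()) -> StandardCurveFit:
    """OLS of log10(within-pool read percentage) on log10(spike copies).

    ``mimic_counts`` and ``copies`` map mimic id → reads / copies added.
    Percentages are taken within the subcomposition of all detected pool
    members; ``exclude`` lists members left out of the regression (e.g.
    members with known primer-site differences) — they still contribute to
    the subcomposition total.  Members with zero reads are excluded from the
    fit.  Fewer than 3 usable points yields a flagged, empty fit.
    """
    counts = {m: float(c) for m, c in dict(mimic_counts).items()}
    copies = {m: float(c) for m, c in dict(copies).items()}
    total = sum(counts.values())
    if total <= 0:
        return StandardCurveFit(sample, np.nan, np.nan, np.nan, 0,
                                tuple(exclude), True, "no spike-in reads")
    usable = [m for m in copies
              if m in counts and counts[m] > 0 and m not in set(exclude)]
    if len(usable) < 3:
        return StandardCurveFit(sample, np.nan, np.nan, np.nan, len(usable),
                                tuple(exclude), True,
                                f"only {len(usable)} usable points (<3)")
    x = np.log10([copies[m] for m in usable])
    y = np.log10([counts[m] / total * 100.0 for m in usable])
    res = stats.linregress(x, y)
    return StandardCurveFit(sample, float(res.slope), float(res.intercept),
                            float(res.rvalue ** 2), len(usable), tuple(exclude))


def hyperbola_fit(spike_levels, reads) -> HyperbolaFit:
    """Least-squares rectangular hyperbola through (spike copies, reads) points."""
    x = np.asarray(spike_levels, dtype=float)
    y = np.asarray(reads, dtype=float)
    if x.shape != y.shape or len(np.unique(x)) < 3:
        return HyperbolaFit(np.nan, np.nan, np.nan, x.size, True,
                            "need >=3 distinct spike levels")
    if np.allclose(y, y[0]):
        return HyperbolaFit(np.nan, np.nan, np.nan, x.size, True,
                            "degenerate: constant response")
    # sort for reproducibility; the fit itself is order-invariant
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    p0 = (max(y.max(), 1.0), max(np.median(x), 1.0))
    try:
        popt, _ = optimize.curve_fit(lambda t, a, b: a * t / (b + t), x, y,
                                     p0=p0, bounds=(1e-12, np.inf), maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        return HyperbolaFit(np.nan, np.nan, np.nan, x.size, True,
                            f"fit failed: {exc}")
    resid = y - popt[0] * x / (popt[1] + x)
    return HyperbolaFit(float(popt[0]), float(popt[1]),
                        float(np.sqrt(np.mean(resid ** 2))), x.size)


def qc_report(assign: AssignmentResult, spike: SpikeConfig,
              fits: dict[str, StandardCurveFit] | None = None,
              min_mimic_reads: int = 50, saturation_fraction: float = 0.95,
              slope_band: tuple[float, float] = (0.8, 1.2),
              r2_min: float = 0.9) -> pd.DataFrame:
    """Boolean per-sample QC flag matrix.

    Flags: ``low_spike_reads`` (total mimic reads below threshold),
    ``spike_saturation`` (mimic read fraction above the saturation warning,
    mirroring exclusion of samples where nearly all reads are spike-in),
    ``poor_curve_slope`` / ``poor_curve_r2`` (standard-curve fit outside the
    configured bands).  Pure function of its inputs.
    """
    samples = list(assign.env_counts.index)
    flags = pd.DataFrame(False, index=samples,
                         columns=["low_spike_reads", "spike_saturation",
                                  "poor_curve_slope", "poor_curve_r2"])
    for sample in samples:
        mimic_reads = int(assign.mimic_counts[sample].sum())
        total = int(assign.total_counts[sample])
        if mimic_reads < min_mimic_reads:
            flags.at[sample, "low_spike_reads"] = True
        if total > 0 and mimic_reads / total > saturation_fraction:
            flags.at[sample, "spike_saturation"] = True
        fit = (fits or {}).get(sample)
        if fit is not None and not fit.flagged:
            if not slope_band[0] <= fit.slope <= slope_band[1]:
                flags.at[sample, "poor_curve_slope"] = True
            if fit.r_squared < r2_min:
                flags.at[sample, "poor_curve_r2"] = True
    return flags


def plot_standard_curve(mimic_counts, copies, fit: StandardCurveFit, path):
    """Optional per-sample curve plot (PNG/SVG by file extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = {m: float(c) for m, c in dict(mimic_counts).items()}
    total = sum(counts.values())
    xs, ys = [], []
    for m, c in dict(copies).items():
        if counts.get(m, 0) > 0:
            xs.append(float(c))
            ys.append(counts[m] / total * 100.0)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.loglog(xs, ys, "o")
    if not fit.flagged:
        grid = np.logspace(np.log10(min(xs)), np.log10(max(xs)), 50)
        ax.loglog(grid, 10 ** (fit.intercept + fit.slope * np.log10(grid)), "-",
                  label=f"s={fit.slope:.2f}, R²={fit.r_squared:.3f}")
        ax.legend(frameon=False)
    ax.set_xlabel("spike-in copies")
    ax.set_ylabel("% of pool reads")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
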