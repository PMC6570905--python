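"""Population-level expression statistics: Fano factor, CV, inhibition curves.

The Fano factor F = sigma^2 / mu equals 1 for Poisson molecule counts; values
far above 1 flag super-Poissonian spread, e.g. a two-peaked mixture of low and
high expressors.  Because fluorescence is only proportional to molecule number,
F computed on fluorescence units is scale-dependent (F(a*x) = a*F(x)) and only
its trend across conditions is meaningful; the CV = sigma/mu is scale-free.
The inhibition probability at a threshold is the fraction of cells dimmer than
the threshold — evaluated on a grid it is the empirical CDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from autorep.stochastic_model import StationaryDistribution, detect_modes

#: samples below this make the snapshot reader warn (population statistics get noisy)
MIN_RECOMMENDED_CELLS = 1000


@dataclass
class PopulationSnapshot:
    """Per-cell mean fluorescence (linear scale) at one inducer concentration."""

    values: np.ndarray
    atc_ng_per_ml: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValueError("snapshot needs at least one cell")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("fluorescence values must be positive and finite")

    @property
    def n_cells(self) -> int:
        return int(self.values.size)


@dataclass
class SummaryStats:
    """Moments, noise measures and mode structure of one population."""

    mean: float
    var: float
    fano: float
    cv: float
    inhibition_p: float
    threshold: float
    n_modes: int
    mode_locations: np.ndarray = field(default_factory=lambda: np.array([]))
    mode_weights: np.ndarray = field(default_factory=lambda: np.array([]))
    n_cells: int = 0


def fano_factor(values) -> float:
    """Variance over mean (population variance, denominator n)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("Fano factor needs at least two values")
    mu = x.mean()
    if mu <= 0:
        raise ValueError("Fano factor undefined for non-positive mean")
    return float(x.var() / mu)


def coefficient_of_variation(values) -> float:
    x = np.asarray(values, dtype=float)
    mu = x.mean()
    if mu <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(x.std() / mu)


def inhibition_probability(values, threshold: float) -> float:
    """Fraction of cells with fluorescence strictly below the threshold."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return float(np.mean(x < threshold))

def inhibition_curve(values, thresholds) -> np.ndarray:
    """Empirical CDF of the population on a threshold grid."""
    return np.array([inhibition_probability(values, t) for t in np.atleast_1d(thresholds)])


def _fd_bins(logx: np.ndarray, min_bins: int = 30) -> np.ndarray:
    """Freedman-Diaconis bin edges on log10 intensity, at least ``min_bins`` bins."""
    lo, hi = logx.min(), logx.max()
    if hi - lo <= 0:
        return np.linspace(lo - 0.5, lo + 0.5, min_bins + 1)
    iqr = np.subtract(*np.percentile(logx, [75, 25]))
    width = 2 * iqr / logx.size ** (1 / 3) if iqr > 0 else 0.0
    nbins = int(np.ceil((hi - lo) / width)) if width > 0 else min_bins
    return np.linspace(lo, hi, max(nbins, min_bins) + 1)


def snapshot_summary(
    snap: PopulationSnapshot,
    threshold: float | None = None,
    smoothing_window: int = 3,
) -> SummaryStats:
    """Full summary of a snapshot; mode statistics come from the log10 histogram.

    If no inhibition threshold is given, the minimum-density valley between the
    two largest modes is used (or the mean if the population is unimodal); the
    threshold actually used is always reported back.
    """
    x = snap.values
    mu = float(x.mean())
    var = float(x.var())
    logx = np.log10(x)
    edges = _fd_bins(logx)
    hist, _ = np.histogram(logx, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if hist.sum() == 0:
        raise ValueError("degenerate histogram")
    modes = detect_modes(hist.astype(float), smoothing_window=smoothing_window, centers=centers)
    if threshold is None:
        if modes.n_modes >= 2:
            i0, i1 = int(modes.indices[0]), int(modes.indices[-1])
            valley = i0 + int(np.argmin(hist[i0 : i1 + 1]))
            threshold = float(10 ** centers[valley])
        else:
            threshold = mu
    return SummaryStats(
        mean=mu,
        var=var,
        fano=fano_factor(x) if x.size >= 2 else 0.0,
        cv=coefficient_of_variation(x),
        inhibition_p=inhibition_probability(x, threshold),
        threshold=float(threshold),
        n_modes=modes.n_modes,
        mode_locations=10.0 ** modes.locations,
        mode_weights=modes.weights,
        n_cells=snap.n_cells,
    )


def summarize_distribution(
    dist: StationaryDistribution,
    threshold: float,
    smoothing_window: int = 3,
) -> SummaryStats:
    """SummaryStats of a discrete count distribution (model-side analogue).

    Mode structure is assessed on the log10-rebinned mass, as for snapshots.
    """
    from autorep.stochastic_model import detect_modes_log

    n = dist.support
    mu, var = dist.mean, dist.var
    fano = var / mu if mu > 0 else 0.0
    cv = np.sqrt(var) / mu if mu > 0 else 0.0
    inh = float(dist.pmf[n < threshold].sum())
    modes = detect_modes_log(dist, smoothing_window=smoothing_window)
    return SummaryStats(
        mean=mu,
        var=var,
        fano=float(fano),
        cv=float(cv),
        inhibition_p=inh,
        threshold=float(threshold),
        n_modes=modes.n_modes,
        mode_locations=modes.locations,
        mode_weights=modes.weights,
    )


def read_snapshots_tsv(path, min_cells: int = MIN_RECOMMENDED_CELLS) -> list[PopulationSnapshot]:
    """Read a snapshot table (columns: cell_id, fluorescence, aTc_ng_per_ml).

    Emits a UserWarning for any concentration with fewer than ``min_cells``
    cells.
    """
    import warnings

    df = pd.read_csv(path, sep="\t")
    required = {"fluorescence", "aTc_ng_per_ml"}
    if not required.issubset(df.columns):
        raise ValueError(f"snapshot table must have columns {sorted(required)}")
    out = []
    for atc, grp in df.groupby("aTc_ng_per_ml", sort=True):
        if len(grp) < min_cells:
            warnings.warn(
                f"snapshot at {atc} ng/mL has only {len(grp)} cells "
                f"(< {min_cells}); statistics may be unreliable"
            )
        out.append(PopulationSnapshot(grp["fluorescence"].to_numpy(), float(atc)))
    return out


def stats_table(snapshots, threshold: float | None = None) -> pd.DataFrame:
    """One row of summary statistics per snapshot (per inducer concentration)."""
    rows = []
    for snap in snapshots:
        s = snapshot_summary(snap, threshold=threshold)
        w_low = s.mode_weights[0] if s.n_modes >= 1 else np.nan
        w_high = s.mode_weights[-1] if s.n_modes >= 2 else np.nan
        rows.append(
            (
                snap.atc_ng_per_ml,
                s.n_cells,
                s.mean,
                s.var,
                s.fano,
                s.cv,
                s.inhibition_p,
                s.threshold,
                s.n_modes,
                w_low,
                w_high,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "aTc_ng_per_ml",
            "n_cells",
            "mean",
            "var",
            "fano",
            "cv",
            "inhibition_p",
            "threshold_used",
            "n_modes",
            "w_low",
            "w_high",
        ],
    )
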