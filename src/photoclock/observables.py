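"""Comparison quantities computed from trajectories and data tables.

All published expression data the model is compared against are *relative*
(rescaled so a reference series peaks at 1), so every statistic here operates
on peak-normalised series: AUC over a cycle, peak phase with sub-grid
refinement, circular phase differences, counts of prominent local maxima
(diurnal bimodality), fold-changes, and the weighted least-squares cost used
for fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks


@dataclass(frozen=True)
class Timeseries:
    """A single diurnal series: ZT grid + relative expression values."""

    zt: np.ndarray
    value: np.ndarray
    label: str = ""
    scale_factor: float = 1.0  # recorded by normalise_to_peak

    def __post_init__(self) -> None:
        zt = np.asarray(self.zt, dtype=float)
        value = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "zt", zt)
        object.__setattr__(self, "value", value)
        if zt.shape != value.shape or zt.ndim != 1:
            raise ValueError("zt and value must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(zt)) and np.all(np.isfinite(value))):
            raise ValueError("timeseries contains NaN/Inf")


class NoPeakError(ValueError):
    """Raised for constant series where a peak phase is undefined."""


def normalise_to_peak(s: Timeseries, ref: Timeseries | None = None) -> Timeseries:
    """Divide by the peak of ``ref`` (default: the series' own peak).

    The scaling factor is recorded on the result, so the operation can be
    inverted exactly.  Normalising a mutant series by the wild-type peak is
    the convention used for all cross-genotype comparisons.
    """
    ref = s if ref is None else ref
    peak = float(np.max(ref.value))
    if peak <= 0:
        raise ValueError("reference peak must be > 0 (all-zero reference?)")
    return replace(s, value=s.value / peak, scale_factor=s.scale_factor * peak)


def denormalise(s: Timeseries) -> Timeseries:
    return replace(s, value=s.value * s.scale_factor, scale_factor=1.0)


def auc(s: Timeseries, window: tuple[float, float] | None = None) -> float:
    """Trapezoidal area under the series over ``window`` (default: full span,
    typically one 24-h cycle)."""
    if window is None:
        t0, t1 = float(s.zt[0]), float(s.zt[-1])
    else:
        t0, t1 = map(float, window)
    if not (t1 > t0):
        raise ValueError("degenerate window")
    if t0 < s.zt[0] - 1e-9 or t1 > s.zt[-1] + 1e-9:
        raise ValueError("window outside series span")
    mask = (s.zt >= t0 - 1e-12) & (s.zt <= t1 + 1e-12)
    if mask.sum() < 2:
        raise ValueError("need at least 2 points inside the window")
    return float(np.trapezoid(s.value[mask], s.zt[mask]))


def peak_time(s: Timeseries) -> float:
    """ZT of the global maximum, refined by a 3-point quadratic fit.

    Ties are broken to the earliest sample.  Raises :class:`NoPeakError` for a
    constant series.
    """
    y = s.value
    if np.ptp(y) == 0:
        raise NoPeakError("constant series has no peak")
    i = int(np.argmax(y))  # argmax already takes the earliest maximum
    if 0 < i < len(y) - 1:
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:  # proper local max; refine on a locally uniform grid
            delta = 0.5 * (y0 - y2) / denom
            h = 0.5 * (s.zt[i + 1] - s.zt[i - 1])
            return float(s.zt[i] + np.clip(delta, -1, 1) * h)
    return float(s.zt[i])


def phase_advance(a: Timeseries, b: Timeseries) -> float:
    """Circular peak-phase difference ``peak(b) - peak(a)`` mapped to
    (-12, +12]; positive means ``a`` peaks earlier (is advanced) vs ``b``."""
    d = peak_time(b) - peak_time(a)
    d = d % 24.0
    if d > 12.0:
        d -= 24.0
    return float(d)


def count_local_maxima(s: Timeseries, prominence_frac: float = 0.1) -> int:
    """Number of local maxima with prominence >= ``prominence_frac`` x range,
    on one 24-h cycle treated circularly."""
    if not 0.0 < prominence_frac < 1.0:
        raise ValueError("prominence_frac must be in (0, 1)")
    y = s.value
    rng = float(np.ptp(y))
    if rng == 0:
        return 0
    # drop a duplicated wrap-around endpoint before tiling
    yy = y[:-1] if abs(y[0] - y[-1]) < 1e-12 * max(1.0, rng) else y
    tiled = np.concatenate([yy, yy, yy])
    pk, _ = find_peaks(tiled, prominence=prominence_frac * rng)
    n = len(yy)
    return int(np.sum((pk >= n) & (pk < 2 * n)))


def fold_change(a: Timeseries, b: Timeseries, mode: str = "auc",
                zt: float | None = None) -> float:
    """Ratio statistic(a)/statistic(b); mode in {auc, at_zt, peak}."""
    if mode == "auc":
        num, den = auc(a), auc(b)
    elif mode == "peak":
        num, den = float(np.max(a.value)), float(np.max(b.value))
    elif mode == "at_zt":
        if zt is None:
            raise ValueError("mode='at_zt' requires zt")
        num = float(np.interp(zt % 24.0, a.zt, a.value))
        den = float(np.interp(zt % 24.0, b.zt, b.value))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if den <= 0:
        raise ZeroDivisionError("denominator statistic must be > 0")
    return num / den


def cost(model: dict[str, Timeseries], data: dict[str, Timeseries],
         weights: dict[str, float] | None = None,
         normalise: bool = True) -> tuple[float, dict[str, float]]:
    """Weighted sum of squared residuals between matched model/data series.

    Each dataset is compared on its own normalised scale (both series divided
    by their own peaks when ``normalise``), so heterogeneous experiments
    combine; the model is linearly interpolated onto the data's ZT grid.
    Returns (total, per-dataset costs).
    """
    if set(model) != set(data):
        raise KeyError(
            f"label mismatch: model={sorted(model)} data={sorted(data)}")
    weights = weights or {}
    per: dict[str, float] = {}
    for key in sorted(data):
        m, d = model[key], data[key]
        if normalise:
            m = normalise_to_peak(m)
            d = normalise_to_peak(d)
        mv = np.interp(d.zt, m.zt, m.value)
        per[key] = float(weights.get(key, 1.0) * np.sum((mv - d.value) ** 2))
    return float(sum(per.values())), per


def from_simulation(r, species: str, label: str | None = None) -> Timeseries:
    """Last-cycle series of one species from a :class:`SimulationResult`."""
    from .simulate import last_cycle

    zt, X = last_cycle(r)
    from .registry import SPECIES_INDEX

    return Timeseries(zt, X[:, SPECIES_INDEX[species]],
                      label=label or f"{species}|{r.genotype.label}")
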