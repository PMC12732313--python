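"""Thermal-shift (DSF) melt-curve analysis.

Dye fluorescence rises as a protein unfolds, so each unfolding event
shows up as a trough in the negative first derivative of fluorescence
against temperature.  Biphasic curves yield two melting temperatures,
Tm1 < Tm2 (one per domain of a two-domain protein).  Shoulder
transitions too weak to produce a first-derivative trough can be picked
up from the second derivative.  A temperature exclusion window lets a
known contaminant transition (e.g. a co-purified chaperone melting near
68 degC) be ignored.  Ligand-induced stabilization is quantified as the
mean and standard deviation of per-replicate paired Tm differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

log = logging.getLogger(__name__)

__all__ = [
    "DerivativeSeries",
    "MeltResult",
    "smooth_and_differentiate",
    "find_tms",
    "analyze_curve",
    "delta_tm",
    "summarize_replicates",
]


@dataclass(frozen=True)
class DerivativeSeries:
    """Negated smoothed derivative of fluorescence vs temperature."""

    temp_C: np.ndarray
    values: np.ndarray  # -(d^order F / dT^order)
    order: int


@dataclass
class MeltResult:
    """Melting temperatures extracted from one curve.

    ``tms`` are ascending; ``orders`` records the derivative order that
    produced each Tm; ``excluded_region`` flags whether an exclusion
    window was applied.
    """

    tms: list[float] = field(default_factory=list)
    orders: list[int] = field(default_factory=list)
    excluded_region: bool = False

    @property
    def tm1(self) -> Optional[float]:
        return self.tms[0] if self.tms else None

    @property
    def tm2(self) -> Optional[float]:
        return self.tms[1] if len(self.tms) > 1 else None


def _grid_step(temp: np.ndarray) -> float:
    steps = np.diff(temp)
    if (steps <= 0).any():
        raise ValueError("temperature grid must be strictly increasing")
    if not np.allclose(steps, steps[0]):
        raise ValueError("temperature grid must be uniform")
    return float(steps[0])


def smooth_and_differentiate(
    temp_C, fluorescence, order: int = 1, window: int = 7, polyorder: int = 3
) -> DerivativeSeries:
    """Savitzky-Golay smoothed derivative of the melt curve, negated.

    ``window`` must be odd and >= 5; endpoints are handled by polynomial
    extrapolation within the terminal window.
    """
    if order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    if window % 2 == 0 or window < 5:
        raise ValueError("window must be odd and >= 5")
    T = np.asarray(temp_C, dtype=float)
    F = np.asarray(fluorescence, dtype=float)
    if T.size < window:
        raise ValueError("curve shorter than the smoothing window")
    step = _grid_step(T)
    deriv = savgol_filter(F, window, polyorder, deriv=order, delta=step, mode="interp")
    return DerivativeSeries(temp_C=T, values=-deriv, order=order)


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-grid vertex of the parabola through (x,y) at i-1, i, i+1."""
    if i == 0 or i == x.size - 1:
        return float(x[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(x[i])
    shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(x[i] + shift * (x[1] - x[0]))


def find_tms(
    deriv: DerivativeSeries,
    max_peaks: int = 2,
    exclusion_window: Optional[tuple[float, float]] = None,
    min_prominence: Optional[float] = None,
) -> MeltResult:
    """Extract up to ``max_peaks`` melting temperatures from a derivative.

    Troughs of the (negated) derivative mark maximal rates of fluorescence
    change.  Troughs inside the exclusion window are dropped, the
    ``max_peaks`` most prominent survivors are kept and sorted ascending,
    and each is refined by parabolic interpolation of the trough and its
    two neighbours.  ``min_prominence`` defaults to 5% of the series
    peak-to-peak range.
    """
    y = -deriv.values  # trough of -dF/dT == peak of dF/dT
    span = float(np.ptp(y))
    if span == 0:
        log.warning("flat derivative series: no melting transition found")
        return MeltResult(excluded_region=exclusion_window is not None)
    prom = min_prominence if min_prominence is not None else 0.05 * span
    idx, props = find_peaks(y, prominence=prom)
    if idx.size == 0:
        log.warning("no trough above prominence %.3g", prom)
        return MeltResult(excluded_region=exclusion_window is not None)
    temps = np.array([_parabolic_refine(deriv.temp_C, y, i) for i in idx])
    prominences = props["prominences"]
    if exclusion_window is not None:
        lo, hi = exclusion_window
        keep = (temps < lo) | (temps > hi)
        temps, prominences = temps[keep], prominences[keep]
    order = np.argsort(-prominences)[:max_peaks]
    chosen = np.sort(temps[order])
    return MeltResult(
        tms=[float(t) for t in chosen],
        orders=[deriv.order] * chosen.size,
        excluded_region=exclusion_window is not None,
    )


def analyze_curve(
    curve: pd.DataFrame,
    max_peaks: int = 2,
    exclusion_window: Optional[tuple[float, float]] = None,
    window: int = 7,
    min_prominence: Optional[float] = None,
) -> MeltResult:
    """First-derivative trough analysis with a second-derivative fallback.

    Runs :func:`find_tms` on the negative first derivative; if fewer than
    ``max_peaks`` transitions emerge, shoulder transitions are sought as
    downward zero-crossings of the second derivative — local maxima of
    dF/dT too weak to clear the prominence threshold — and merged in,
    each recorded with the derivative order that produced it.  A clean
    monophasic curve gains nothing from the fallback: its only
    zero-crossing is the Tm already found.
    """
    T = curve["temp_C"].to_numpy(dtype=float)
    F = curve["fluorescence"].to_numpy(dtype=float)
    d1 = smooth_and_differentiate(T, F, order=1, window=window)
    result = find_tms(d1, max_peaks, exclusion_window, min_prominence)
    if len(result.tms) < max_peaks:
        d2 = smooth_and_differentiate(T, F, order=2, window=window)
        slope = -d1.values  # dF/dT
        floor = 0.1 * float(slope.max()) if slope.max() > 0 else 0.0
        dd = -d2.values  # d2F/dT2
        for i in range(dd.size - 1):
            if dd[i] > 0 >= dd[i + 1] and slope[i] >= floor:
                frac = dd[i] / (dd[i] - dd[i + 1])
                t = float(T[i] + frac * (T[i + 1] - T[i]))
                if exclusion_window and exclusion_window[0] <= t <= exclusion_window[1]:
                    continue
                if all(abs(t - t0) > 1.0 for t0 in result.tms):
                    result.tms.append(t)
                    result.orders.append(2)
        pairs = sorted(zip(result.tms, result.orders))
        result.tms = [t for t, _ in pairs][:max_peaks]
        result.orders = [o for _, o in pairs][:max_peaks]
    return result


def summarize_replicates(results: Sequence[MeltResult]) -> pd.DataFrame:
    """Mean +/- sd of Tm1/Tm2 across replicate MeltResults."""
    rows = []
    for k, name in enumerate(("Tm1", "Tm2")):
        vals = [r.tms[k] for r in results if len(r.tms) > k]
        if not vals:
            continue
        arr = np.asarray(vals)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        rows.append({"tm": name, "mean_C": float(arr.mean()), "sd_C": sd, "n": arr.size})
    return pd.DataFrame(rows)


def delta_tm(
    apo: Sequence[MeltResult], ligand: Sequence[MeltResult]
) -> pd.DataFrame:
    """Paired ligand-minus-apo melting-temperature shifts.

    Replicates are paired in order.  For each Tm index present in every
    paired result, reports the mean and standard deviation of the
    per-pair differences (not the difference of means with pooled sd).
    """
    if len(apo) != len(ligand):
        raise ValueError("unpaired replicates: apo and ligand counts differ")
    if not apo:
        raise ValueError("no replicate pairs")
    rows = []
    for k, name in enumerate(("dTm1", "dTm2")):
        if any(len(r.tms) <= k for r in apo) or any(len(r.tms) <= k for r in ligand):
            continue
        diffs = np.array([l.tms[k] - a.tms[k] for a, l in zip(apo, ligand)])
        sd = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
        rows.append(
            {"tm": name, "mean_C": float(diffs.mean()), "sd_C": sd, "n": diffs.size}
        )
    return pd.DataFrame(rows)
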