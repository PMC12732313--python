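"""Enzyme-kinetics fitting for coupled fucokinase/pyrophosphorylase assays.

The kinase reaction is followed as an absorbance decrease at 340 nm
(NADH oxidation via a pyruvate kinase / lactate dehydrogenase couple,
one NADH per ADP, hence per phosphorylated sugar); the pyrophosphorylase
reaction as an absorbance increase at 635 nm (malachite-green detection
of the phosphate released when an inorganic pyrophosphatase splits the
PPi product).  Raw slopes are converted to concentration rates through
linear standard curves, then fitted to the Michaelis-Menten law

    v = kcat * E0 * S / (KM + S)

or, where high substrate suppresses the rate, to the uncompetitive
substrate-inhibition form

    v = kcat * E0 * S / (KM + S + S^2/Ki),

whose rate peaks at S* = sqrt(KM * Ki).  Fits run in log-parameter space
(positivity without bounds); parameter uncertainties come from the
residual-scaled Gauss-Newton covariance, and the catalytic efficiency
kcat/KM carries first-order (quadrature) error propagation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import mm_rate, substrate_inhibition_rate

log = logging.getLogger(__name__)

__all__ = [
    "StandardCurve",
    "KineticFit",
    "FitError",
    "fit_standard_curve",
    "initial_rate",
    "fit_mm",
    "fit_substrate_inhibition",
    "efficiency",
    "normalize_mutant",
    "pi_to_ppi_rate",
    "round_sig",
]


class FitError(RuntimeError):
    """Fit failure; carries the best iterate when available."""

    def __init__(self, message: str, best: Optional[dict] = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class StandardCurve:
    """Linear analyte-vs-absorbance calibration."""

    slope: float  # AU per uM
    intercept: float  # AU
    r_squared: float
    incubation_tag: str = ""

    def predict(self, conc_uM: float) -> float:
        return self.slope * conc_uM + self.intercept

    def inverse(self, absorbance: float) -> float:
        return (absorbance - self.intercept) / self.slope


@dataclass
class KineticFit:
    """Fitted kinetic parameters with 1-sigma uncertainties.

    KM and Ki in uM, kcat in 1/s, efficiency in 1/(M s).
    """

    model: str
    KM: float
    KM_sd: float
    kcat: float
    kcat_sd: float
    E0: float
    Ki: Optional[float] = None
    Ki_sd: Optional[float] = None
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    aicc: float = float("nan")

    @property
    def efficiency(self) -> tuple[float, float]:
        return efficiency(self.kcat, self.kcat_sd, self.KM, self.KM_sd)

    @property
    def peak_substrate(self) -> Optional[float]:
        """Substrate concentration of maximal rate (substrate inhibition only)."""
        if self.Ki is None:
            return None
        return math.sqrt(self.KM * self.Ki)


def fit_standard_curve(
    concentrations, absorbances, incubation_tag: str = ""
) -> StandardCurve:
    """Ordinary least-squares line absorbance = slope * conc + intercept."""
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.size < 2 or np.unique(c).size < 2:
        raise ValueError("standard curve needs >= 2 distinct concentration levels")
    res = stats.linregress(c, a)
    if res.slope == 0:
        raise ValueError("degenerate standard curve (zero slope)")
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        incubation_tag=incubation_tag,
    )


def initial_rate(
    time_s,
    absorbance,
    curve: StandardCurve,
    window: Optional[tuple[float, float]] = None,
    wavelength_nm: int = 340,
    r2_floor: float = 0.9,
) -> float:
    """Initial rate (uM/s) from the linear phase of an absorbance trace.

    ``window`` is a (start, stop) time range in seconds (default: first
    60 s).  Sign convention: a falling 340 nm trace (substrate-coupled
    NADH consumption) gives a positive rate, a rising 635 nm trace
    (product formation) gives a positive rate.  A window fitting worse
    than ``r2_floor`` logs a warning but still returns the rate.
    """
    t = np.asarray(time_s, dtype=float)
    A = np.asarray(absorbance, dtype=float)
    if t.size != A.size:
        raise ValueError("time and absorbance must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    lo, hi = window if window is not None else (t[0], t[0] + 60.0)
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 3:
        raise ValueError("rate window must contain >= 3 points")
    res = stats.linregress(t[mask], A[mask])
    if res.rvalue**2 < r2_floor and np.ptp(A[mask]) > 0:
        log.warning(
            "nonlinear rate window (R^2 = %.3f < %.2f)", res.rvalue**2, r2_floor
        )
    conc_rate = res.slope / curve.slope  # uM/s, signed
    return -conc_rate if wavelength_nm == 340 else conc_rate


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _aicc(ssr: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return float("inf")
    return n * math.log(max(ssr, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _nls_log(residual_fn, p0: np.ndarray, n_obs: int):
    """Least squares in log-parameter space; returns (params, sds, result)."""
    res = optimize.least_squares(
        residual_fn, np.log(p0), method="lm", xtol=1e-14, ftol=1e-14, max_nfev=20000
    )
    theta = res.x
    params = np.exp(theta)
    k = theta.size
    dof = max(n_obs - k, 1)
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * s2
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj) * s2
    var = np.clip(np.diag(cov), 0.0, None)
    # delta method: sd(p) = p * sd(log p)
    sds = params * np.sqrt(var)
    if not res.success:
        raise FitError(
            "nonlinear fit did not converge",
            best={"params": params, "sds": sds, "cost": res.cost},
        )
    return params, sds, res


def _prepare(data: pd.DataFrame, E0_uM: float):
    S = data["substrate_conc_uM"].to_numpy(dtype=float)
    v = data["rate_uM_per_s"].to_numpy(dtype=float)
    if (S <= 0).any():
        raise ValueError("substrate concentrations must be positive")
    if np.unique(S).size < 3:
        raise ValueError("need >= 3 distinct substrate levels")
    if E0_uM <= 0:
        raise ValueError("enzyme concentration must be positive")
    return S, v


def fit_mm(
    data: pd.DataFrame, E0_uM: float, weights: Optional[str] = None
) -> KineticFit:
    """Fit v = kcat*E0*S/(KM+S) by nonlinear least squares.

    ``data`` has columns substrate_conc_uM and rate_uM_per_s (replicates
    as extra rows).  ``weights="1/v2"`` applies relative weighting.
    Initialization: KM = median(S), kcat = max(v)/E0.
    """
    S, v = _prepare(data, E0_uM)
    w = 1.0 / np.maximum(v, 1e-12) if weights == "1/v2" else np.ones_like(v)

    def resid(theta):
        km, kcat = np.exp(theta)
        return (mm_rate(S, km, kcat, E0_uM) - v) * w

    p0 = np.array([np.median(S), max(v.max(), 1e-9) / E0_uM])
    params, sds, res = _nls_log(resid, p0, v.size)
    fitted = mm_rate(S, *params, E0_uM)
    return KineticFit(
        model="mm",
        KM=float(params[0]),
        KM_sd=float(sds[0]),
        kcat=float(params[1]),
        kcat_sd=float(sds[1]),
        E0=E0_uM,
        residuals=v - fitted,
        aicc=_aicc(float(np.sum((v - fitted) ** 2)), v.size, 2),
    )


def fit_substrate_inhibition(
    data: pd.DataFrame, E0_uM: float, weights: Optional[str] = None
) -> KineticFit:
    """Fit v = kcat*E0*S/(KM + S + S^2/Ki) and compare against plain MM.

    Requires >= 5 substrate levels.  The corrected-AIC comparison with the
    two-parameter MM fit is recorded; data with no rate decline drive Ki
    toward infinity and the MM model is preferred (``fit.aicc`` of the
    returned fit is still the substrate-inhibition value, with
    ``mm_preferred`` flagged via the model tag).
    """
    S, v = _prepare(data, E0_uM)
    if np.unique(S).size < 5:
        raise ValueError("substrate inhibition fit needs >= 5 substrate levels")
    w = 1.0 / np.maximum(v, 1e-12) if weights == "1/v2" else np.ones_like(v)

    def resid(theta):
        km, kcat, ki = np.exp(theta)
        return (substrate_inhibition_rate(S, km, kcat, ki, E0_uM) - v) * w

    km0 = float(np.median(S))
    ki0 = float(S.max())
    kcat0 = max(v.max(), 1e-9) / E0_uM * (1.0 + 2.0 * math.sqrt(km0 / ki0))
    params, sds, res = _nls_log(resid, np.array([km0, kcat0, ki0]), v.size)
    fitted = substrate_inhibition_rate(S, *params, E0_uM)
    ssr = float(np.sum((v - fitted) ** 2))
    aicc_si = _aicc(ssr, v.size, 3)
    mm_fit = fit_mm(data, E0_uM, weights=weights)
    tag = "substrate_inhibition" if aicc_si < mm_fit.aicc else "substrate_inhibition(mm_preferred)"
    return KineticFit(
        model=tag,
        KM=float(params[0]),
        KM_sd=float(sds[0]),
        kcat=float(params[1]),
        kcat_sd=float(sds[1]),
        E0=E0_uM,
        Ki=float(params[2]),
        Ki_sd=float(sds[2]),
        residuals=v - fitted,
        aicc=aicc_si,
    )


def efficiency(
    kcat: float, kcat_sd: float, KM_uM: float, KM_sd_uM: float
) -> tuple[float, float]:
    """kcat/KM in 1/(M s) with first-order error propagation.

    (sd_eff/eff)^2 = (sd_kcat/kcat)^2 + (sd_KM/KM)^2.
    """
    if KM_uM <= 0 or kcat <= 0:
        raise ValueError("central values must be positive")
    if kcat_sd < 0 or KM_sd_uM < 0:
        raise ValueError("uncertainties must be >= 0")
    eff = kcat / (KM_uM * 1e-6)
    rel = math.hypot(kcat_sd / kcat, KM_sd_uM / KM_uM)
    return eff, eff * rel


def normalize_mutant(
    wt_reps, mut_reps, detection_floor: float = 0.0
) -> tuple[Optional[float], Optional[float], bool]:
    """Mutant activity as percent of wild-type mean.

    Returns (percent, sd, not_detected).  percent = 100*mean(mut)/mean(wt);
    the replicate standard deviation is scaled by the same factor.  A
    mutant mean below ``detection_floor`` is flagged N.D. (None values).
    """
    wt = np.asarray(list(wt_reps), dtype=float)
    mut = np.asarray(list(mut_reps), dtype=float)
    if wt.size < 3 or mut.size < 3:
        raise ValueError("need >= 3 replicates for each protein")
    if wt.mean() <= 0:
        raise ValueError("wild-type mean activity must be positive")
    if mut.mean() < detection_floor:
        return None, None, True
    scale = 100.0 / wt.mean()
    return float(mut.mean() * scale), float(mut.std(ddof=1) * scale), False


def pi_to_ppi_rate(pi_rate: float, stoichiometry_factor: float = 2.0) -> float:
    """Convert a phosphate-appearance rate to a pyrophosphorylase rate.

    Each PPi released by the pyrophosphorylase is hydrolyzed to two Pi by
    the coupling pyrophosphatase, hence the default factor of 2.
    """
    if stoichiometry_factor <= 0:
        raise ValueError("stoichiometry factor must be positive")
    if pi_rate < 0:
        raise ValueError("rate must be >= 0")
    return pi_rate / stoichiometry_factor


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (report-style output)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{sig}g}")
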