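"""Native-state proteolysis energetics.

A folded protein is cleaved by a nonspecific protease only through
transiently open (partially unfolded) conformations.  Under the EX2-like
condition the observed first-order proteolysis rate is

    k_obs = K_op * (kcat/KM) * [protease],

so the slope of k_obs versus protease concentration gives K_op * (kcat/KM),
and referencing it to the protease's specificity constant for fully
unfolded chains (thermolysin: 99,000 M^-1 s^-1) yields the opening free
energy

    dG_proteolysis = -RT ln( slope / 99,000 ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .constants import (
    DEFAULT_TEMPERATURE_K,
    R_KCAL,
    THERMOLYSIN_KCAT_KM,
    THERMOLYSIN_MW,
)

__all__ = [
    "ProteolysisDataset",
    "ProteolysisResult",
    "fit_kobs",
    "fit_slope",
    "delta_g_proteolysis",
    "run_proteolysis_pipeline",
    "mg_per_ml_to_molar",
]


class ProteolysisFitError(RuntimeError):
    pass


def mg_per_ml_to_molar(mg_per_ml, mw: float = THERMOLYSIN_MW):
    """Convert a protease concentration from mg/mL to mol/L."""
    return np.asarray(mg_per_ml, dtype=float) / mw


@dataclass
class ProteolysisDataset:
    """Band-intensity time courses at several protease concentrations.

    ``intensities`` has shape (n_concentrations, n_times), normalized to the
    no-protease control lane.
    """

    concentrations: np.ndarray  # M
    times: np.ndarray  # s
    intensities: np.ndarray
    control: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(self.concentrations <= 0):
            raise ValueError("protease concentrations must be positive")
        if self.concentrations.size < 3:
            raise ValueError("need at least 3 protease concentrations")
        if self.times.size < 4:
            raise ValueError("need at least 4 time points")
        if self.intensities.shape != (self.concentrations.size, self.times.size):
            raise ValueError("intensities must be (n_concentrations, n_times)")
        if self.control is not None:
            self.control = np.asarray(self.control, dtype=float)


@dataclass
class ProteolysisResult:
    kobs: np.ndarray  # s^-1, per concentration
    kobs_se: np.ndarray
    m_proteolysis: float  # M^-1 s^-1
    m_se: float
    intercept: float
    kop: float
    dg_proteolysis: float  # kcal/mol
    dg_se: float
    temperature_k: float


def fit_kobs(times, intensities) -> tuple[float, float]:
    """First-order decay fit I(t) = A exp(-k t); returns (k_obs, se).

    The amplitude is co-fitted but bounded near the control intensity
    ([0.8, 1.2]) to stabilize sparse time courses.  A time course whose
    intensity rises with time has no proteolytic interpretation and raises.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    slope = stats.linregress(t, y).slope
    if slope > 1e-12 and y[-1] > y[0]:
        raise ProteolysisFitError("intensities increase with time")
    k0 = 1.0 / max(t[-1], 1e-12)
    if np.all(y > 0):
        lr = stats.linregress(t, np.log(np.clip(y, 1e-12, None)))
        if lr.slope < 0:
            k0 = -lr.slope
    popt, pcov = optimize.curve_fit(
        lambda tt, a, k: a * np.exp(-k * tt), t, y,
        p0=[1.0, k0], bounds=([0.8, 0.0], [1.2, np.inf]), maxfev=10000,
    )
    k = float(popt[1])
    se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
    return k, se


def fit_slope(kobs_list, concentrations, kobs_se=None) -> tuple[float, float, float]:
    """Weighted linear regression of k_obs on protease concentration.

    Returns (slope, slope_se, intercept).  The intercept absorbs background
    proteolysis and is not used in the free-energy conversion.
    """
    c = np.asarray(concentrations, dtype=float)
    k = np.asarray(kobs_list, dtype=float)
    if c.size < 3:
        raise ValueError("need at least 3 concentrations for the linear fit")
    if kobs_se is not None and np.all(np.asarray(kobs_se) > 0):
        w = 1.0 / np.asarray(kobs_se, dtype=float) ** 2
    else:
        w = np.ones_like(c)
    W = np.sum(w)
    xbar = np.sum(w * c) / W
    ybar = np.sum(w * k) / W
    sxx = np.sum(w * (c - xbar) ** 2)
    slope = np.sum(w * (c - xbar) * (k - ybar)) / sxx
    intercept = ybar - slope * xbar
    resid = k - (intercept + slope * c)
    dof = max(c.size - 2, 1)
    s2 = np.sum(w * resid**2) / dof
    slope_se = float(np.sqrt(s2 / sxx))
    return float(slope), slope_se, float(intercept)


def delta_g_proteolysis(slope: float, temperature_k: float = DEFAULT_TEMPERATURE_K,
                        kcat_km_ref: float = THERMOLYSIN_KCAT_KM,
                        slope_se: float = 0.0) -> tuple[float, float]:
    """dG = -RT ln(slope / kcat_km_ref), with error propagated from the slope."""
    if slope <= 0:
        raise ValueError("slope must be positive to define an opening free energy")
    rt = R_KCAL * temperature_k
    dg = -rt * np.log(slope / kcat_km_ref)
    dg_se = rt * slope_se / slope if slope_se else 0.0
    return float(dg), float(dg_se)


def run_proteolysis_pipeline(dataset: ProteolysisDataset,
                             temperature_k: float = DEFAULT_TEMPERATURE_K,
                             kcat_km_ref: float = THERMOLYSIN_KCAT_KM,
                             ) -> ProteolysisResult:
    """Compose k_obs fits, the concentration slope, and the free energy."""
    kobs, kse = [], []
    for row in dataset.intensities:
        k, se = fit_kobs(dataset.times, row)
        kobs.append(k)
        kse.append(se)
    kobs = np.array(kobs)
    kse = np.array(kse)
    slope, slope_se, intercept = fit_slope(kobs, dataset.concentrations, kobs_se=None)
    dg, dg_se = delta_g_proteolysis(slope, temperature_k, kcat_km_ref, slope_se)
    return ProteolysisResult(
        kobs=kobs, kobs_se=kse,
        m_proteolysis=slope, m_se=slope_se, intercept=intercept,
        kop=slope / kcat_km_ref,
        dg_proteolysis=dg, dg_se=dg_se,
        temperature_k=temperature_k,
    )
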