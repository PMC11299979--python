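"""Two-state equilibrium unfolding fits.

Chemical denaturation follows the linear extrapolation model

    dG([D]) = dG0 - m [D]

with the unfolded fraction given by the Boltzmann population

    f_u([D]) = 1 / (1 + exp(dG([D]) / RT)),

so the midpoint Cm = dG0 / m and the observable at Cm is halfway between the
folded and unfolded baselines.  Thermal melts are fitted with an empirical
four-parameter logistic (midpoint Tm, width), without assuming a van't Hoff
enthalpy.

Un-normalized optical signals (ellipticity, fluorescence) carry linear
folded/unfolded baselines that are co-fitted; curves flagged as normalized
are fitted with the bare two-parameter model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

from .constants import DEFAULT_TEMPERATURE_K, R_KCAL

__all__ = [
    "DenaturationCurve",
    "TwoStateFit",
    "ThermalFit",
    "FitError",
    "normalize_curve",
    "fit_chemical_two_state",
    "fit_thermal_melt",
    "delta_delta_g",
]


class FitError(RuntimeError):
    """Raised when a denaturation fit cannot converge or the input is degenerate."""


@dataclass
class DenaturationCurve:
    """A denaturant- or temperature-axis melt.

    axis: denaturant concentration (M) for chemical mode, temperature (degC)
    for thermal mode.  signal: the optical observable, or the apparent
    unfolded fraction when ``normalized`` is set.
    """

    axis: np.ndarray
    signal: np.ndarray
    mode: str = "chemical"
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.axis.shape != self.signal.shape:
            raise ValueError("axis and signal must have equal length")
        if self.axis.size < 8:
            raise ValueError("need at least 8 points spanning the transition")
        if self.mode not in ("chemical", "thermal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        order = np.argsort(self.axis)
        self.axis = self.axis[order]
        self.signal = self.signal[order]
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("axis values must be distinct (strictly increasing)")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")


@dataclass
class TwoStateFit:
    """Result of a chemical two-state fit (energies in kcal/mol)."""

    dg0: float
    m_value: float
    baselines: dict
    se: dict
    rss: float
    temperature_k: float
    in_range: bool = True

    @property
    def cm(self) -> float:
        """Midpoint denaturant concentration, dG0/m (exact identity)."""
        return self.dg0 / self.m_value


@dataclass
class ThermalFit:
    tm: float
    width: float
    baselines: dict
    se: dict
    rss: float


def fraction_unfolded(axis: np.ndarray, dg0: float, m_value: float,
                      temperature_k: float = DEFAULT_TEMPERATURE_K) -> np.ndarray:
    """Unfolded population from the linear extrapolation model."""
    rt = R_KCAL * temperature_k
    dg = dg0 - m_value * np.asarray(axis, dtype=float)
    return 1.0 / (1.0 + np.exp(dg / rt))


def _two_state_signal(params, axis, rt):
    fu = 1.0 / (1.0 + np.exp((params["dg0"] - params["m"] * axis) / rt))
    folded = params["af"] + params["bf"] * axis
    unfolded = params["au"] + params["bu"] * axis
    return folded * (1.0 - fu) + unfolded * fu


def _initial_midpoint(axis: np.ndarray, signal: np.ndarray) -> float:
    """Axis value where the signal crosses halfway between its extremes."""
    lo, hi = signal[:3].mean(), signal[-3:].mean()
    half = 0.5 * (lo + hi)
    crossing = np.where(np.diff(np.sign(signal - half)))[0]
    if crossing.size:
        i = crossing[0]
        x0, x1 = axis[i], axis[i + 1]
        y0, y1 = signal[i], signal[i + 1]
        if y1 != y0:
            return x0 + (half - y0) * (x1 - x0) / (y1 - y0)
        return 0.5 * (x0 + x1)
    return float(np.median(axis))


def normalize_curve(curve: DenaturationCurve,
                    baseline_strategy: str = "fit") -> DenaturationCurve:
    """Map an optical melt onto apparent fraction-unfolded in [0, 1].

    ``fit`` co-fits linear baselines with the two-state transition and
    divides them out; ``endpoint`` estimates baselines from the outer 20% of
    points on each side.  Raises :class:`FitError` when the signal has no
    discernible transition.
    """
    if curve.normalized:
        return curve
    sig = curve.signal
    if np.ptp(sig) < 1e-12 or np.std(sig) == 0:
        raise FitError("signal is constant: no transition to normalize")
    if curve.mode == "chemical":
        if baseline_strategy == "fit":
            fit = fit_chemical_two_state(curve)
            b = fit.baselines
            folded = b["af"] + b["bf"] * curve.axis
            unfolded = b["au"] + b["bu"] * curve.axis
        elif baseline_strategy == "endpoint":
            k = max(2, curve.axis.size // 5)
            pf = np.polyfit(curve.axis[:k], sig[:k], 1)
            pu = np.polyfit(curve.axis[-k:], sig[-k:], 1)
            folded = np.polyval(pf, curve.axis)
            unfolded = np.polyval(pu, curve.axis)
        else:
            raise ValueError(f"unknown baseline strategy {baseline_strategy!r}")
    else:
        fit = fit_thermal_melt(curve)
        b = fit.baselines
        folded = np.full_like(curve.axis, b["af"])
        unfolded = np.full_like(curve.axis, b["au"])
    span = unfolded - folded
    if np.any(np.abs(span) < 1e-12):
        raise FitError("degenerate baselines: folded and unfolded signals coincide")
    frac = (sig - folded) / span
    meta = dict(curve.meta)
    meta["baseline_strategy"] = baseline_strategy
    return DenaturationCurve(curve.axis.copy(), frac, mode=curve.mode,
                             normalized=True, meta=meta)


def fit_chemical_two_state(curve: DenaturationCurve,
                           temperature_k: float = DEFAULT_TEMPERATURE_K) -> TwoStateFit:
    """Fit dG0 and the m-value to a chemical melt.

    Normalized curves use the bare two-parameter model; raw curves co-fit
    linear folded/unfolded baselines.  Levenberg-Marquardt from several
    endpoint-derived starting points; the best solution by residual sum of
    squares wins.
    """
    if curve.mode != "chemical":
        raise ValueError("fit_chemical_two_state requires a chemical-mode curve")
    rt = R_KCAL * temperature_k
    axis, sig = curve.axis, curve.signal
    if np.ptp(sig) < 1e-12:
        raise FitError("signal is constant: no transition to fit")

    cm0 = _initial_midpoint(axis, sig)
    cm0 = float(np.clip(cm0, axis[0] + 1e-6, axis[-1] - 1e-6))
    span = max(axis[-1] - axis[0], 1e-6)
    m_guesses = (0.5, 1.5, 3.0, 8.0 * rt / span)

    best = None
    for m0 in m_guesses:
        params = Parameters()
        params.add("m", value=m0, min=1e-4)
        params.add("dg0", value=m0 * max(cm0, 1e-3), min=1e-6)
        if curve.normalized:
            params.add("af", value=0.0, vary=False)
            params.add("bf", value=0.0, vary=False)
            params.add("au", value=1.0, vary=False)
            params.add("bu", value=0.0, vary=False)
        else:
            params.add("af", value=float(sig[:3].mean()))
            params.add("bf", value=0.0)
            params.add("au", value=float(sig[-3:].mean()))
            params.add("bu", value=0.0)
        try:
            out = minimize(
                lambda p: _two_state_signal(p, axis, rt) - sig,
                params, method="leastsq", xtol=1e-10, ftol=1e-10,
            )
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None or not best.success:
        raise FitError("two-state chemical fit did not converge")

    p = best.params
    cm = p["dg0"].value / p["m"].value
    in_range = bool(axis[0] <= cm <= axis[-1])
    if not in_range:
        warnings.warn("fitted transition midpoint lies outside the sampled range",
                      stacklevel=2)
    se = {k: (p[k].stderr if p[k].stderr is not None else np.nan)
          for k in ("dg0", "m")}
    return TwoStateFit(
        dg0=float(p["dg0"].value),
        m_value=float(p["m"].value),
        baselines={k: float(p[k].value) for k in ("af", "bf", "au", "bu")},
        se={"dg0": se["dg0"], "m_value": se["m"]},
        rss=float(best.chisqr),
        temperature_k=temperature_k,
        in_range=in_range,
    )


def _logistic_signal(params, t):
    fu = 1.0 / (1.0 + np.exp((params["tm"] - t) / params["width"]))
    return params["af"] + (params["au"] - params["af"]) * fu


def fit_thermal_melt(curve: DenaturationCurve) -> ThermalFit:
    """Fit an empirical sigmoid to a thermal melt and return Tm and width."""
    if curve.mode != "thermal":
        raise ValueError("fit_thermal_melt requires a thermal-mode curve")
    t, sig = curve.axis, curve.signal
    if np.ptp(sig) < 1e-12:
        raise FitError("signal is constant: no transition to fit")
    tm0 = _initial_midpoint(t, sig)
    span = t[-1] - t[0]
    best = None
    for w0 in (0.5, 2.0, 5.0, span / 10.0):
        params = Parameters()
        params.add("tm", value=tm0, min=t[0], max=t[-1])
        params.add("width", value=w0, min=1e-3, max=span)
        params.add("af", value=float(sig[:3].mean()))
        params.add("au", value=float(sig[-3:].mean()))
        try:
            out = minimize(lambda p: _logistic_signal(p, t) - sig, params,
                           method="leastsq", xtol=1e-10, ftol=1e-10)
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None or not best.success:
        raise FitError("thermal sigmoid fit did not converge")
    p = best.params
    return ThermalFit(
        tm=float(p["tm"].value),
        width=float(p["width"].value),
        baselines={"af": float(p["af"].value), "au": float(p["au"].value)},
        se={k: (p[k].stderr if p[k].stderr is not None else np.nan)
            for k in ("tm", "width")},
        rss=float(best.chisqr),
    )


def delta_delta_g(fit_a: TwoStateFit, fit_b: TwoStateFit) -> tuple[float, float]:
    """ddG = dG0(a) - dG0(b), with quadrature-propagated standard error."""
    if abs(fit_a.temperature_k - fit_b.temperature_k) > 1e-9:
        raise ValueError("fits were performed at different temperatures")
    ddg = fit_a.dg0 - fit_b.dg0
    sa = fit_a.se.get("dg0", np.nan)
    sb = fit_b.se.get("dg0", np.nan)
    return ddg, float(np.hypot(sa, sb))
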