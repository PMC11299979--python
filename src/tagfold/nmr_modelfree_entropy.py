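"""Lipari-Szabo model-free analysis and conformational entropy.

Backbone 15N R1, R2 and the steady-state {1H}-15N NOE are interpreted with
the model-free spectral density

    J(w) = (2/5) [ S^2 tau_m / (1 + (w tau_m)^2)
                 + (1 - S^2) tau' / (1 + (w tau')^2) ],
    1/tau' = 1/tau_m + 1/tau_e,

under isotropic tumbling, with the standard dipolar (r_NH = 1.02 A) plus
CSA (-160 ppm) relaxation expressions and an optional exchange term Rex
added to R2.  The global tumbling time tau_m is estimated from the trimmed
R2/R1 ratio of rigid residues (NOE > 0.65) and refined on a grid by the
global chi-square.  Per residue, four nested models are fitted

    M1: {S^2}   M2: {S^2, tau_e}   M3: {S^2, Rex}   M4: {S^2, tau_e, Rex}

and the winner selected by the Akaike information criterion.  (With three
observables per residue at a single field the small-sample AICc correction
is degenerate, so the plain AIC penalty 2k is used.)

Order parameters map onto backbone conformational entropy via a linear
"entropy meter", S_conf = s_slope * (1 - S^2) + s_0.  The default slope,
0.0109 kcal mol^-1 K^-1 per unit (1 - S^2), comes from linearizing the
diffusion-in-a-cone closed form around S^2 ~ 0.8; only entropy differences
are ever reported, so the additive constant cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .constants import CSA_N, GAMMA_H, GAMMA_N, HBAR, MU0, R_NH
from .segments import SegmentMap

__all__ = [
    "RelaxationDataset",
    "ModelFreeResult",
    "spectral_density",
    "relaxation_rates",
    "fit_rate",
    "compute_hetnoe",
    "estimate_tau_m",
    "fit_model_free",
    "order_param_entropy",
    "segment_entropy_compare",
]

# Linearized diffusion-in-a-cone slope, kcal mol^-1 K^-1 per unit (1 - S^2)
ENTROPY_METER_SLOPE = 0.0109


@dataclass
class RelaxationDataset:
    """Per-residue R1/R2/NOE with errors at a stated 1H field (MHz)."""

    residues: np.ndarray
    r1: np.ndarray
    r1_err: np.ndarray
    r2: np.ndarray
    r2_err: np.ndarray
    noe: np.ndarray
    noe_err: np.ndarray
    field_mhz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("residues", "r1", "r1_err", "r2", "r2_err", "noe", "noe_err"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float)
                    if name != "residues" else np.asarray(getattr(self, name)))
        n = self.residues.size
        for name in ("r1", "r1_err", "r2", "r2_err", "noe", "noe_err"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length mismatch")
        if np.any(self.r1 <= 0) or np.any(self.r2 <= 0):
            raise ValueError("relaxation rates must be positive")
        if np.any(self.r1_err <= 0) or np.any(self.r2_err <= 0) or np.any(self.noe_err <= 0):
            raise ValueError("errors must be positive")
        if np.any(self.noe > 1.05):
            raise ValueError("15N backbone NOE cannot exceed ~1.05")


@dataclass
class ModelFreeResult:
    per_residue: pd.DataFrame  # s2, s2_err, tau_e (s), rex, model_id, chi2
    tau_m: float  # s
    field_mhz: float


def _frequencies(field_mhz: float):
    """Angular frequencies (rad/s) of 1H and 15N at the given 1H field."""
    omega_h = 2.0 * np.pi * field_mhz * 1e6
    omega_n = omega_h * GAMMA_N / GAMMA_H  # negative
    return omega_h, omega_n


def spectral_density(omega, s2: float, tau_m: float, tau_e: float = 0.0):
    """Model-free J(w); omega in rad/s, times in seconds."""
    omega = np.asarray(omega, dtype=float)
    jm = s2 * tau_m / (1.0 + (omega * tau_m) ** 2)
    if tau_e > 0.0 and s2 < 1.0:
        tau_p = tau_m * tau_e / (tau_m + tau_e)
        jm = jm + (1.0 - s2) * tau_p / (1.0 + (omega * tau_p) ** 2)
    return 0.4 * jm


def relaxation_rates(s2: float, tau_m: float, tau_e: float = 0.0,
                     rex: float = 0.0, field_mhz: float = 600.0):
    """(R1, R2, NOE) from the dipolar + CSA expressions; times in seconds."""
    omega_h, omega_n = _frequencies(field_mhz)
    d = MU0 * HBAR * GAMMA_H * GAMMA_N / (4.0 * np.pi * R_NH**3)
    d2 = d * d
    c2 = (omega_n * CSA_N) ** 2 / 3.0

    j = lambda w: spectral_density(w, s2, tau_m, tau_e)
    j0 = j(0.0)
    jn = j(abs(omega_n))
    jh = j(omega_h)
    jhmn = j(omega_h - omega_n)  # omega_n < 0: this is the sum-frequency magnitude
    jhpn = j(omega_h + omega_n)

    # with signed omega_n, |omega_h - omega_n| > omega_h > |omega_h + omega_n|
    r1 = (d2 / 4.0) * (jhpn + 3.0 * jn + 6.0 * jhmn) + c2 * jn
    r2 = (d2 / 8.0) * (4.0 * j0 + jhpn + 3.0 * jn + 6.0 * jh + 6.0 * jhmn) \
        + (c2 / 6.0) * (4.0 * j0 + 3.0 * jn) + rex
    noe = 1.0 + (d2 / 4.0) * (GAMMA_H / GAMMA_N) * (6.0 * jhmn - jhpn) / r1
    return float(r1), float(r2), float(noe)


def fit_rate(delays, intensities) -> tuple[float, float]:
    """Single-exponential fit I(tau) = I0 exp(-R tau) for R1/R2 series."""
    t = np.asarray(delays, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 relaxation delays")
    if stats.linregress(t, y).slope > 0 and y[-1] >= y[0]:
        raise RuntimeError("intensity series does not decay")
    r0 = 1.0
    if np.all(y > 0):
        lr = stats.linregress(t, np.log(y))
        if lr.slope < 0:
            r0 = -lr.slope
    popt, pcov = optimize.curve_fit(
        lambda tt, i0, r: i0 * np.exp(-r * tt), t, y,
        p0=[float(y[0]), r0], maxfev=10000,
    )
    return float(popt[1]), float(np.sqrt(pcov[1, 1]))


def compute_hetnoe(i_sat: float, i_sat_err: float,
                   i_ref: float, i_ref_err: float) -> tuple[float, float]:
    """NOE = I_sat / I_ref with relative-error quadrature propagation."""
    if i_ref == 0:
        raise ValueError("reference intensity is zero")
    noe = i_sat / i_ref
    rel = np.sqrt((i_ref_err / i_ref) ** 2 + (i_sat_err / i_sat) ** 2) \
        if i_sat != 0 else np.inf
    return float(noe), float(abs(noe) * rel)


def _rigid_ratio(tau_m: float, field_mhz: float) -> float:
    r1, r2, _ = relaxation_rates(1.0, tau_m, 0.0, 0.0, field_mhz)
    return r2 / r1


def _rigid_subset(dataset: RelaxationDataset, noe_cutoff: float = 0.65):
    """Residues usable for tau_m estimation: high NOE, no R2/R1 outliers.

    Exchange broadening inflates R2/R1, so residues whose ratio deviates
    from the median by more than 1.5x the median absolute deviation are
    dropped (in addition to the NOE cutoff for fast internal motion).
    """
    rigid = dataset.noe > noe_cutoff
    if rigid.sum() < 3:
        rigid = np.ones(dataset.residues.size, dtype=bool)
    ratio = dataset.r2 / dataset.r1
    med = np.median(ratio[rigid])
    mad = np.median(np.abs(ratio[rigid] - med))
    if mad > 0:
        rigid = rigid & (np.abs(ratio - med) <= 1.5 * mad + 1e-9)
    if rigid.sum() < 3:
        rigid = dataset.noe > noe_cutoff
    return rigid


def estimate_tau_m(dataset: RelaxationDataset, noe_cutoff: float = 0.65,
                   trim: float = 0.10) -> float:
    """Global tumbling time from the trimmed R2/R1 ratio of rigid residues."""
    rigid = _rigid_subset(dataset, noe_cutoff)
    ratio = dataset.r2[rigid] / dataset.r1[rigid]
    ratio = float(stats.trim_mean(ratio, trim)) if ratio.size >= 5 \
        else float(np.median(ratio))
    f = lambda tm: _rigid_ratio(tm, dataset.field_mhz) - ratio
    lo, hi = 0.5e-9, 50e-9
    if f(lo) > 0:
        return lo
    if f(hi) < 0:
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-13))


_MODELS = {
    "M1": ("s2",),
    "M2": ("s2", "tau_e"),
    "M3": ("s2", "rex"),
    "M4": ("s2", "tau_e", "rex"),
}
# tau_e is carried in picoseconds inside the optimizer so all parameters
# are O(1)-O(100); converted to seconds in the forward model
_BOUNDS = {"s2": (0.0, 1.0), "tau_e": (0.0, 2000.0), "rex": (0.0, 50.0)}
_STARTS = {"s2": (0.85,), "tau_e": (20.0, 100.0), "rex": (1.0,)}


def _fit_one_model(obs, err, tau_m, field_mhz, names):
    def resid(x):
        p = {"s2": x[0], "tau_e": 0.0, "rex": 0.0}
        for i, nm in enumerate(names[1:], start=1):
            p[nm] = x[i]
        r1, r2, noe = relaxation_rates(p["s2"], tau_m, p["tau_e"] * 1e-12,
                                       p["rex"], field_mhz)
        return (np.array([r1, r2, noe]) - obs) / err

    lo = [_BOUNDS[nm][0] for nm in names]
    hi = [_BOUNDS[nm][1] for nm in names]
    best = None
    starts = [[s2] for s2 in _STARTS["s2"]]
    for nm in names[1:]:
        starts = [s + [v] for s in starts for v in _STARTS[nm]]
    for x0 in starts:
        try:
            sol = optimize.least_squares(resid, x0, bounds=(lo, hi),
                                         xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return None
    chi2 = float(2.0 * best.cost)
    # covariance from the jacobian at the optimum
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.pinv(jtj)
        perr = np.sqrt(np.clip(np.diag(cov), 0, None))
    except Exception:
        perr = np.full(len(names), np.nan)
    params = dict(zip(names, best.x))
    errs = dict(zip(names, perr))
    return params, errs, chi2


def fit_model_free(dataset: RelaxationDataset, tau_m: float | None = None,
                   refine_tau_m: bool = True) -> ModelFreeResult:
    """Per-residue model-free fit with AIC model selection.

    tau_m is taken from :func:`estimate_tau_m` when not supplied and, by
    default, refined on a +/-15% grid by the summed chi-square of the
    selected models.
    """
    if tau_m is None:
        tau_m = estimate_tau_m(dataset)
        if refine_tau_m:
            # refine against exchange-free residues only, with the
            # exchange-free model M2, so spurious Rex cannot absorb a
            # tau_m error
            rigid = np.where(_rigid_subset(dataset))[0]

            def cost(tm):
                total = 0.0
                for i in rigid:
                    obs = np.array([dataset.r1[i], dataset.r2[i],
                                    dataset.noe[i]])
                    err = np.array([dataset.r1_err[i], dataset.r2_err[i],
                                    dataset.noe_err[i]])
                    fit = _fit_one_model(obs, err, tm, dataset.field_mhz,
                                         ("s2", "tau_e"))
                    total += fit[2] if fit is not None else 1e6
                return total

            sol = optimize.minimize_scalar(
                cost, bounds=(0.8 * tau_m, 1.25 * tau_m), method="bounded",
                options={"xatol": tau_m * 1e-4})
            tau_m = float(sol.x)

    rows = []
    for i in range(dataset.residues.size):
        res = _fit_residue(dataset, i, tau_m)
        if res is None:
            warnings.warn(f"residue {dataset.residues[i]}: model-free fit failed",
                          stacklevel=2)
            continue
        res["residue"] = dataset.residues[i]
        rows.append(res)
    df = pd.DataFrame(rows).set_index("residue")
    return ModelFreeResult(per_residue=df, tau_m=tau_m,
                           field_mhz=dataset.field_mhz)


def _fit_residue(dataset: RelaxationDataset, i: int, tau_m: float):
    obs = np.array([dataset.r1[i], dataset.r2[i], dataset.noe[i]])
    err = np.array([dataset.r1_err[i], dataset.r2_err[i], dataset.noe_err[i]])
    best = None
    for model_id, names in _MODELS.items():
        fit = _fit_one_model(obs, err, tau_m, dataset.field_mhz, names)
        if fit is None:
            continue
        params, errs, chi2 = fit
        aic = chi2 + 2.0 * len(names)
        if best is None or aic < best["aic"]:
            best = {
                "s2": params["s2"], "s2_err": errs.get("s2", np.nan),
                "tau_e": params.get("tau_e", 0.0) * 1e-12,
                "tau_e_err": errs.get("tau_e", np.nan) * 1e-12,
                "rex": params.get("rex", 0.0),
                "rex_err": errs.get("rex", np.nan),
                "model_id": model_id, "chi2": chi2, "aic": aic,
            }
    return best


def order_param_entropy(s2, slope: float = ENTROPY_METER_SLOPE,
                        offset: float = 0.0, mode: str = "linear"):
    """Backbone conformational entropy (kcal mol^-1 K^-1) from S^2.

    ``linear`` applies the entropy meter S_conf = slope*(1 - S^2) + offset;
    ``cone`` evaluates the diffusion-in-a-cone closed form
    S_conf = R ln(pi * (3 - sqrt(1 + 8 S))) with S = sqrt(S^2), which
    diverges at S^2 = 1 and is clamped just below it.  Both maps are
    monotone decreasing in S^2; only differences are physically meaningful.
    """
    s2 = np.asarray(s2, dtype=float)
    if np.any(s2 < 0) or np.any(s2 > 1):
        raise ValueError("order parameters must lie in [0, 1]")
    if mode == "linear":
        return slope * (1.0 - s2) + offset
    if mode == "cone":
        from .constants import R_KCAL
        s = np.sqrt(np.clip(s2, 0.0, 1.0 - 1e-9))
        return R_KCAL * np.log(np.pi * (3.0 - np.sqrt(1.0 + 8.0 * s)))
    raise ValueError(f"unknown entropy map {mode!r}")


def segment_entropy_compare(res_a: pd.DataFrame, res_b: pd.DataFrame,
                            seg_map: SegmentMap, temperature_k: float = 298.0,
                            slope: float = ENTROPY_METER_SLOPE,
                            mode: str = "linear") -> pd.DataFrame:
    """Segment-averaged -T dS, with dS = S_conf(a) - S_conf(b).

    ``a`` is the reference protein; a large positive -T dS means the query
    ``b`` is more flexible in that segment.  Inputs are the ``per_residue``
    frames from :func:`fit_model_free` (column ``s2``).  Flagging uses a
    single (mean + mean error) threshold line, as in the temperature
    coefficient comparison.
    """
    rows = []
    for name in seg_map.names:
        mem_a = [r for r in seg_map.residues_in(name) if r in res_a.index]
        mem_b = [r for r in seg_map.residues_in(name) if r in res_b.index]
        if not mem_a or not mem_b:
            warnings.warn(f"segment {name!r} empty in one protein; excluded",
                          stacklevel=2)
            continue
        sa = order_param_entropy(res_a.loc[mem_a, "s2"].to_numpy(), slope=slope,
                                 mode=mode)
        sb = order_param_entropy(res_b.loc[mem_b, "s2"].to_numpy(), slope=slope,
                                 mode=mode)
        val = -temperature_k * (sa.mean() - sb.mean())
        sem_a = sa.std(ddof=1) / np.sqrt(sa.size) if sa.size > 1 else 0.0
        sem_b = sb.std(ddof=1) / np.sqrt(sb.size) if sb.size > 1 else 0.0
        err = temperature_k * float(np.hypot(sem_a, sem_b))
        rows.append({"segment": name, "minus_t_ds": val, "err": err})
    if not rows:
        raise ValueError("no shared segments with data")
    df = pd.DataFrame(rows).set_index("segment")
    threshold = df["minus_t_ds"].mean() + df["err"].mean()
    df["flag"] = df["minus_t_ds"] > threshold
    df.attrs["threshold"] = float(threshold)
    return df
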