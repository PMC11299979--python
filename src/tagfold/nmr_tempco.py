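"""Amide-proton temperature coefficients.

The backbone amide 1H chemical shift drifts linearly with temperature; the
slope Tc = d(deltaNH)/dT (in ppb/K) reports hydrogen-bond strength.
Strongly negative coefficients (more negative than about -4.6 ppb/K) mark
amides with weak or absent hydrogen bonds and hence local disorder
propensity.  Because low-identity homologues cannot be compared residue by
residue, coefficients are averaged over named secondary-structure segments
and the per-segment difference dTc_avg = mean(reference) - mean(query) is
examined against a (mean + error) threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segments import SegmentMap

__all__ = [
    "ShiftTable",
    "TcResult",
    "fit_temp_coefficients",
    "flag_disordered",
    "segment_average",
    "compare_proteins",
]


@dataclass
class ShiftTable:
    """Per-residue amide 1H shifts (ppm) across temperatures (K).

    ``shifts`` has shape (n_residues, n_temperatures); NaN marks a missing
    peak at one temperature.  Shifts are assumed referenced to water /
    calibrated against DSS upstream.
    """

    residues: np.ndarray
    temperatures: np.ndarray
    shifts: np.ndarray
    reference_note: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.temperatures.size < 3:
            raise ValueError("need at least 3 temperatures")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.shifts.shape != (self.residues.size, self.temperatures.size):
            raise ValueError("shifts must be (n_residues, n_temperatures)")


@dataclass
class TcResult:
    residue: int
    tc: float  # ppb/K
    intercept: float  # ppm at the first (reference) temperature
    se_tc: float  # ppb/K
    rss: float  # ppm^2


def fit_temp_coefficients(table: ShiftTable) -> pd.DataFrame:
    """Per-residue OLS of shift (ppm) on temperature (K).

    Returns a DataFrame indexed by residue with columns ``tc`` (ppb/K),
    ``intercept`` (ppm at the lowest temperature), ``se_tc`` and ``rss``.
    Residues with fewer than 3 observed temperatures are skipped with a
    warning.
    """
    rows = []
    t_ref = table.temperatures[0]
    for res, series in zip(table.residues, table.shifts):
        ok = np.isfinite(series)
        if ok.sum() < 3:
            warnings.warn(f"residue {res}: fewer than 3 points, skipped",
                          stacklevel=2)
            continue
        t = table.temperatures[ok] - t_ref
        y = series[ok]
        # closed-form OLS; slope in ppm/K -> ppb/K
        A = np.vstack([t, np.ones_like(t)]).T
        coef, rss_arr, _, _ = np.linalg.lstsq(A, y, rcond=None)
        slope, intercept = coef
        fitted = A @ coef
        rss = float(np.sum((y - fitted) ** 2))
        n = t.size
        if n > 2 and np.ptp(t) > 0:
            sxx = np.sum((t - t.mean()) ** 2)
            se = np.sqrt(rss / (n - 2) / sxx)
        else:
            se = np.nan
        rows.append({"residue": res, "tc": slope * 1e3,
                     "intercept": float(intercept),
                     "se_tc": se * 1e3 if np.isfinite(se) else np.nan,
                     "rss": rss})
    if not rows:
        raise ValueError("no residue had enough temperatures to fit")
    return pd.DataFrame(rows).set_index("residue")


def flag_disordered(results: pd.DataFrame, n_sd: float = 1.0) -> list:
    """Residues whose Tc falls below (mean - n_sd * SD).

    The mean Tc must be negative (the physical convention for amide
    proton coefficients); positive-mean input indicates a sign-flipped
    table and raises.  With zero spread no residue is flagged.
    """
    if len(results) < 5:
        raise ValueError("need at least 5 residues for a mean - SD threshold")
    tc = results["tc"].to_numpy(dtype=float)
    mean = tc.mean()
    if mean >= 0:
        raise ValueError("mean Tc is non-negative; check the sign convention")
    sd = tc.std(ddof=1)
    threshold = mean - n_sd * sd
    return [int(r) for r, v in zip(results.index, tc) if v < threshold]


def segment_average(results: pd.DataFrame, seg_map: SegmentMap) -> pd.DataFrame:
    """Arithmetic mean and SEM of Tc per named segment.

    Singleton segments carry an undefined SEM (NaN) and are flagged;
    empty segments are excluded with a warning.  Residues not covered by
    the map are listed in ``df.attrs['unassigned']``.
    """
    rows = []
    assigned = set()
    for name in seg_map.names:
        members = [r for r in seg_map.residues_in(name) if r in results.index]
        assigned.update(members)
        if not members:
            warnings.warn(f"segment {name!r} has no residues with data; excluded",
                          stacklevel=2)
            continue
        vals = results.loc[members, "tc"].to_numpy(dtype=float)
        sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
        rows.append({"segment": name, "mean": vals.mean(), "sem": sem,
                     "n": vals.size, "singleton": vals.size == 1})
    out = pd.DataFrame(rows).set_index("segment")
    out.attrs["unassigned"] = sorted(set(map(int, results.index)) - assigned)
    return out


def compare_proteins(seg_a: pd.DataFrame, seg_b: pd.DataFrame) -> pd.DataFrame:
    """Per-segment dTc_avg = mean(a) - mean(b), with quadrature error.

    ``a`` is the reference protein, ``b`` the query; a large positive
    dTc_avg marks a segment whose hydrogen bonds are weaker in the query.
    The highlight rule follows a single threshold line at
    (mean over segments of dTc_avg) + (mean propagated error).
    """
    shared = [s for s in seg_a.index if s in seg_b.index]
    if not shared:
        raise ValueError("proteins share no segment names")
    delta = seg_a.loc[shared, "mean"].to_numpy() - seg_b.loc[shared, "mean"].to_numpy()
    err = np.hypot(
        np.nan_to_num(seg_a.loc[shared, "sem"].to_numpy(dtype=float)),
        np.nan_to_num(seg_b.loc[shared, "sem"].to_numpy(dtype=float)),
    )
    threshold = delta.mean() + np.nanmean(err)
    out = pd.DataFrame({
        "mean_a": seg_a.loc[shared, "mean"].to_numpy(),
        "mean_b": seg_b.loc[shared, "mean"].to_numpy(),
        "delta": delta,
        "err": err,
        "flag": delta > threshold,
    }, index=pd.Index(shared, name="segment"))
    out.attrs["threshold"] = float(threshold)
    return out
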