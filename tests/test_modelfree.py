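"""Relaxation-rate fitting, model-free analysis, and conformational entropy."""

import numpy as np
import pytest

from tagfold import synthetic_data as sd
from tagfold.constants import CSA_N, GAMMA_H, GAMMA_N, HBAR, MU0, R_NH
from tagfold.nmr_modelfree_entropy import (
    compute_hetnoe,
    fit_model_free,
    fit_rate,
    order_param_entropy,
    relaxation_rates,
    segment_entropy_compare,
    spectral_density,
)

T1_DELAYS = np.array([0.004, 0.03, 0.06, 0.1, 0.15, 0.2, 0.4, 0.8])


def test_fit_rate_forward_inverse_and_scale_invariance():
    y = np.exp(-1.5 * T1_DELAYS)
    r, _ = fit_rate(T1_DELAYS, y)
    assert r == pytest.approx(1.5, rel=1e-8)
    r10, _ = fit_rate(T1_DELAYS, 10.0 * y)
    assert r10 == pytest.approx(r, rel=1e-8)
    with pytest.raises(RuntimeError):
        fit_rate(T1_DELAYS, 1.0 + T1_DELAYS)


def test_fit_rate_noise_bias():
    """Rate bias under 5% intensity noise stays below 2% over 50 replicates."""
    fits = []
    for seed in range(50):
        rng = np.random.default_rng(seed)
        y = np.exp(-1.5 * T1_DELAYS) + rng.normal(0, 0.05, T1_DELAYS.size)
        r, _ = fit_rate(T1_DELAYS, y)
        fits.append(r)
    assert abs(np.mean(fits) - 1.5) / 1.5 < 0.02


def test_hetnoe_error_propagation():
    noe, err = compute_hetnoe(0.8, 0.04, 1.0, 0.05)
    assert noe == pytest.approx(0.8)
    expected = 0.8 * np.sqrt((0.04 / 0.8) ** 2 + (0.05 / 1.0) ** 2)
    assert err == pytest.approx(expected, rel=1e-12)
    assert err == pytest.approx(0.0566, abs=5e-4)
    assert compute_hetnoe(1.0, 0.0, 1.0, 0.0) == (1.0, 0.0)
    with pytest.raises(ValueError):
        compute_hetnoe(0.5, 0.01, 0.0, 0.01)


def test_rigid_rotor_spectral_density():
    """S2 = 1, tau_e = 0 collapses J(w) to the single-Lorentzian form."""
    tau_m = 5e-9
    w = np.array([0.0, 1e8, 5e8, 4e9])
    j = spectral_density(w, 1.0, tau_m, 0.0)
    assert np.allclose(j, 0.4 * tau_m / (1 + (w * tau_m) ** 2), rtol=1e-14)
    # tau_e = 0: the internal-motion branch vanishes regardless of S2
    j_a = spectral_density(w, 0.7, tau_m, 0.0)
    assert np.allclose(j_a, 0.7 * 0.4 * tau_m / (1 + (w * tau_m) ** 2), rtol=1e-14)


def test_rates_match_textbook_formula_oracle():
    """Rates agree with an independent hand-coded dipolar+CSA evaluation."""
    s2, tau_m, tau_e, field = 0.85, 5e-9, 50e-12, 600.0

    # independent oracle written directly from the relaxation equations
    wh = 2 * np.pi * field * 1e6
    wn = wh * GAMMA_N / GAMMA_H
    d = MU0 * HBAR * GAMMA_H * GAMMA_N / (4 * np.pi * R_NH**3)
    c2 = (wn * CSA_N) ** 2 / 3.0
    tau_p = tau_m * tau_e / (tau_m + tau_e)

    def J(w):
        return 0.4 * (s2 * tau_m / (1 + (w * tau_m) ** 2)
                      + (1 - s2) * tau_p / (1 + (w * tau_p) ** 2))

    r1_o = (d * d / 4) * (J(wh + wn) + 3 * J(abs(wn)) + 6 * J(wh - wn)) \
        + c2 * J(abs(wn))
    r2_o = (d * d / 8) * (4 * J(0) + J(wh + wn) + 3 * J(abs(wn)) + 6 * J(wh)
                          + 6 * J(wh - wn)) + (c2 / 6) * (4 * J(0) + 3 * J(abs(wn)))
    noe_o = 1 + (d * d / 4) * (GAMMA_H / GAMMA_N) * (6 * J(wh - wn) - J(wh + wn)) / r1_o

    r1, r2, noe = relaxation_rates(s2, tau_m, tau_e, 0.0, field)
    assert r1 == pytest.approx(r1_o, rel=1e-12)
    assert r2 == pytest.approx(r2_o, rel=1e-12)
    assert noe == pytest.approx(noe_o, rel=1e-12)


def test_rigid_limit_recovery():
    """Rigid-generated data returns S2 = 1 and the simplest model."""
    ds = sd.gen_relaxation(sd.RelaxSpec(
        s2_true=np.ones(6), tau_m=5.0, tau_e=0.0, rex=0.0, noise_frac=0.0))
    res = fit_model_free(ds)
    assert np.allclose(res.per_residue["s2"], 1.0, atol=1e-3)
    assert res.tau_m == pytest.approx(5e-9, rel=5e-3)
    assert (res.per_residue["model_id"] == "M1").all()


def test_recovery_with_internal_motion():
    """S2 = 0.85, tau_e = 50 ps recovered within 0.02 over 10 seeds."""
    errs = []
    for seed in range(1, 11):
        ds = sd.gen_relaxation(sd.RelaxSpec(
            s2_true=np.full(8, 0.85), tau_m=5.0, tau_e=50.0, rex=0.0,
            noise_frac=0.02, seed=seed))
        res = fit_model_free(ds)
        errs.append(np.abs(res.per_residue["s2"].to_numpy() - 0.85).mean())
    assert np.mean(errs) < 0.02


def test_exchange_detected_and_recovered():
    """Rex = 3 /s on one residue selects an exchange model, within 20%."""
    rex = np.zeros(8)
    rex[4] = 3.0
    rex_fit = []
    for seed in range(1, 11):
        ds = sd.gen_relaxation(sd.RelaxSpec(
            s2_true=np.full(8, 0.87), tau_m=5.0, tau_e=30.0, rex=rex,
            noise_frac=0.02, seed=seed))
        res = fit_model_free(ds)
        row = res.per_residue.iloc[4]
        assert row["model_id"] in ("M3", "M4")
        rex_fit.append(row["rex"])
    assert abs(np.mean(rex_fit) - 3.0) / 3.0 < 0.20


def test_chi2_optimum_not_above_truth():
    """Fitted chi2 never exceeds chi2 evaluated at the true parameters."""
    s2, te = np.full(5, 0.8), 40.0
    ds = sd.gen_relaxation(sd.RelaxSpec(
        s2_true=s2, tau_m=5.0, tau_e=te, rex=0.0, noise_frac=0.02, seed=3))
    res = fit_model_free(ds, tau_m=5e-9, refine_tau_m=False)
    for i in range(5):
        r1, r2, noe = relaxation_rates(s2[i], 5e-9, te * 1e-12, 0.0, 600.0)
        obs = np.array([ds.r1[i], ds.r2[i], ds.noe[i]])
        err = np.array([ds.r1_err[i], ds.r2_err[i], ds.noe_err[i]])
        chi2_truth = np.sum(((np.array([r1, r2, noe]) - obs) / err) ** 2)
        assert res.per_residue["chi2"].iloc[i] <= chi2_truth + 1e-6


def test_entropy_map_monotone_and_boundary():
    s_lo = order_param_entropy(0.7)
    s_hi = order_param_entropy(0.9)
    assert s_lo > s_hi
    grid = np.linspace(0.0, 1.0, 21)
    for mode in ("linear", "cone"):
        vals = order_param_entropy(grid, mode=mode)
        assert np.all(np.diff(vals) < 1e-15)
        assert vals[-1] == min(vals)
    with pytest.raises(ValueError):
        order_param_entropy(1.2)


def test_segment_entropy_compare(toy_segments):
    import pandas as pd

    idx = pd.Index(range(1, 11), name="residue")
    ref = pd.DataFrame({"s2": np.full(10, 0.85)}, index=idx)
    same = segment_entropy_compare(ref, ref, toy_segments)
    assert np.allclose(same["minus_t_ds"], 0.0)

    query = pd.DataFrame({"s2": np.full(10, 0.75)}, index=idx)
    shifted = segment_entropy_compare(ref, query, toy_segments, temperature_k=298.0)
    assert np.allclose(shifted["minus_t_ds"], shifted["minus_t_ds"].iloc[0])
    assert np.all(shifted["minus_t_ds"] > 0)  # query more flexible

    # antisymmetry under swapping proteins
    swapped = segment_entropy_compare(query, ref, toy_segments, temperature_k=298.0)
    assert np.allclose(swapped["minus_t_ds"].to_numpy(),
                       -shifted["minus_t_ds"].to_numpy())


def test_localized_flexibility_flagged(toy_segments):
    """Lower S2 only in a1 flags a1 and no other segment."""
    import pandas as pd

    idx = pd.Index(range(1, 11), name="residue")
    ref = pd.DataFrame({"s2": np.full(10, 0.87)}, index=idx)
    q = np.full(10, 0.87)
    q[3:7] = 0.70  # residues 4-7 = segment a1
    query = pd.DataFrame({"s2": q}, index=idx)
    out = segment_entropy_compare(ref, query, toy_segments)
    assert bool(out.loc["a1", "flag"])
    assert not out.loc[["b1", "b2"], "flag"].any()
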