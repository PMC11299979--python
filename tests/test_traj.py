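"""Trajectory plasticity metrics against brute-force oracles."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from tagfold import synthetic_data as sd
from tagfold.constants import KB_KCAL
from tagfold.traj_plasticity import (
    Trajectory,
    contact_disruption,
    contact_fraction,
    define_native_contacts,
    fel_2d,
    gyration,
    hbond_fraction,
    pca,
    rmsf_rmsd,
    superpose,
)


def _rotate(coords, seed=0):
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=rng)
    shift = rng.normal(0, 20, 3)
    return rot.apply(coords) + shift


# ---------------------------------------------------------------- contacts

def test_contact_rules_minimal():
    """Separation rule and cutoff on a hand-built two-residue system."""
    coords = np.array([[0.0, 0, 0], [5.0, 0, 0], [4.0, 0, 0], [0.0, 1, 0]])
    # residues 1 and 11 are 5 A apart; residues 1 and 2 are 4 A apart
    traj = Trajectory(coords[None], coords, np.array(["CA"] * 4),
                      np.array([1, 11, 2, 1]))
    cs = define_native_contacts(traj, cutoff_a=7.0, min_separation=4)
    pairs = {tuple(p) for p in cs.pairs}
    assert (1, 11) in pairs
    assert (1, 2) not in pairs


def test_contacts_match_brute_force(static_toy):
    """Contact list equals an exhaustive O(n^2) min-distance scan."""
    traj = static_toy
    cs = define_native_contacts(traj, cutoff_a=7.0, min_separation=4)
    expected = set()
    residues = traj.residues
    for a in range(residues.size):
        for b in range(a + 1, residues.size):
            ri, rj = int(residues[a]), int(residues[b])
            if abs(ri - rj) < 4:
                continue
            ai = np.where(traj.residue_index == ri)[0]
            aj = np.where(traj.residue_index == rj)[0]
            d = np.linalg.norm(traj.reference[ai][:, None] - traj.reference[aj][None],
                               axis=-1)
            if d.min() <= 7.0:
                expected.add((ri, rj))
    assert {tuple(p) for p in cs.pairs} == expected


def test_alpha_native_frames_and_schedule(static_toy):
    cs = define_native_contacts(static_toy)
    assert np.allclose(contact_fraction(static_toy, cs), 1.0)

    sched = np.array([1.0, 0.85, 0.7, 0.6, 0.5, 0.5])
    traj = sd.gen_toy_trajectory(sd.ToyTrajectorySpec(
        n_residues=20, n_frames=6, unfold_schedule=sched, seed=2))
    alpha = contact_fraction(traj, traj.meta["contacts"])
    assert np.all(np.diff(alpha) <= 1e-12)  # monotone under the schedule
    assert alpha[-1] == pytest.approx(0.5, abs=0.1)


def test_eta_counting_and_monotone():
    traj = sd.gen_toy_trajectory(sd.ToyTrajectorySpec(
        n_residues=16, n_frames=5,
        unfold_schedule=np.array([1.0, 0.8, 0.6, 0.4, 0.2]), seed=1))
    m = 8
    eta = hbond_fraction(traj, {"sheet": ((1, m), (m + 1, 2 * m))})["sheet"]
    assert eta[0] == pytest.approx(1.0)
    assert np.all(np.diff(eta) <= 1e-12)
    # brute-force recount on the final frame
    pairs = []
    for i in range(traj.n_atoms):
        for j in range(traj.n_atoms):
            if traj.atom_names[i] == "N" and traj.atom_names[j] == "O" \
                    and traj.residue_index[i] <= m < traj.residue_index[j] \
                    and np.linalg.norm(traj.reference[i] - traj.reference[j]) <= 3.5:
                pairs.append((i, j))
    kept = sum(np.linalg.norm(traj.coords[-1, i] - traj.coords[-1, j]) <= 3.5
               for i, j in pairs)
    assert eta[-1] == pytest.approx(kept / len(pairs))


# ---------------------------------------------------------------- rmsf/rmsd

def test_static_trajectory_zero_metrics(static_toy):
    _, rmsf, rmsd = rmsf_rmsd(static_toy)
    assert np.allclose(rmsf, 0.0, atol=1e-12)
    assert np.allclose(rmsd, 0.0, atol=1e-12)


def test_superposition_removes_rigid_body_motion(static_toy):
    ref = static_toy.reference
    frames = np.array([_rotate(ref, seed=s) for s in range(4)])
    traj = Trajectory(frames, ref, static_toy.atom_names,
                      static_toy.residue_index)
    _, rmsf, rmsd = rmsf_rmsd(traj)
    assert np.allclose(rmsd, 0.0, atol=1e-8)
    assert np.allclose(rmsf, 0.0, atol=1e-8)


def test_rmsf_gaussian_limit():
    """Isotropic sigma = 0.5 A displacements give RMSF -> sigma sqrt(3)."""
    traj = sd.gen_toy_trajectory(sd.ToyTrajectorySpec(
        n_residues=16, fluct_amplitudes=0.5, n_frames=600, seed=4))
    # do not superpose: fluctuations are measured about the reference frame
    ca = traj.ca_indices()
    x = traj.coords[:, ca]
    rmsf = np.sqrt(((x - x.mean(0)) ** 2).sum(-1).mean(0))
    assert rmsf.mean() == pytest.approx(0.5 * np.sqrt(3), rel=0.05)


# ---------------------------------------------------------------- gyration

def test_gyration_closed_forms():
    coords = np.array([[0.0, 0, 0]])
    t1 = Trajectory(coords[None], coords, np.array(["CA"]), np.array([1]))
    rgyr, rog = gyration(t1)
    assert rog[0] == pytest.approx(0.0)

    coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    t2 = Trajectory(coords[None], coords, np.array(["CA", "CA"]),
                    np.array([1, 2]))
    _, rog = gyration(t2)
    assert rog[0] == pytest.approx(1.0, rel=1e-12)


def test_gyration_matches_direct_formula():
    rng = np.random.default_rng(9)
    coords = rng.normal(0, 5, (100, 3))
    masses = rng.uniform(1, 16, 100)
    traj = Trajectory(coords[None], coords, np.array(["CA"] * 100),
                      np.arange(100), masses=masses)
    _, rog = gyration(traj)
    com = (coords * masses[:, None]).sum(0) / masses.sum()
    expected = np.sqrt((masses * ((coords - com) ** 2).sum(1)).sum() / masses.sum())
    assert rog[0] == pytest.approx(expected, rel=1e-12)
    # loop exclusion changes rgyr, not rog
    mask = np.zeros(100, dtype=bool)
    mask[:30] = True
    rgyr, rog2 = gyration(traj, loop_mask=mask)
    assert rog2[0] == pytest.approx(expected, rel=1e-12)
    assert rgyr[0] != pytest.approx(expected, rel=1e-6)


# ---------------------------------------------------------------- FEL

def test_fel_minimum_and_kbt_ratio():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, 4000)
    y = rng.normal(0, 1, 4000)
    grid = fel_2d(x, y, temperature_k=300.0, bins=20)
    assert np.nanmin(grid.dg) == 0.0
    # constructed 9:1 bin populations sit kB T ln 9 apart
    series_x = np.concatenate([np.zeros(900), np.ones(100)])
    series_y = np.zeros(1000)
    g2 = fel_2d(series_x, series_y, temperature_k=300.0, bins=2)
    finite = np.sort(g2.dg[np.isfinite(g2.dg)])
    assert finite[0] == 0.0
    assert finite[-1] == pytest.approx(KB_KCAL * 300.0 * np.log(9.0), rel=1e-9)


def test_fel_empty_bins_masked():
    x = np.array([0.0, 0.0, 1.0])
    y = np.array([0.0, 1.0, 0.0])
    grid = fel_2d(x, y, bins=2)
    assert np.isnan(grid.dg).sum() == 1


# ---------------------------------------------------------------- PCA

def test_pca_static_and_forced_oscillation(static_toy):
    _, variances, _ = pca(static_toy)
    assert np.allclose(variances, 0.0, atol=1e-20)

    ref = static_toy.reference.copy()
    frames = np.tile(ref, (40, 1, 1))
    ca = static_toy.ca_indices()
    amp = np.sin(np.linspace(0, 6 * np.pi, 40)) * 3.0
    # oscillate one interior atom along x
    frames[:, ca[5], 0] += amp
    traj = Trajectory(frames, ref, static_toy.atom_names,
                      static_toy.residue_index)
    comps, variances, proj = pca(traj)
    assert variances[0] / variances.sum() > 0.99
    assert np.all(np.diff(variances) <= 1e-12)
    # total variance is preserved by the eigendecomposition
    fitted = superpose(traj)[:, ca].reshape(40, -1)
    total = ((fitted - fitted.mean(0)) ** 2).sum() / 39
    assert variances.sum() == pytest.approx(total, rel=1e-8)


# ---------------------------------------------------------------- rotation invariance

def test_metrics_rotation_invariant():
    sched = np.array([1.0, 0.9, 0.8, 0.7])
    traj = sd.gen_toy_trajectory(sd.ToyTrajectorySpec(
        n_residues=16, n_frames=4, fluct_amplitudes=0.1,
        unfold_schedule=sched, seed=5))
    rotated = Trajectory(
        np.array([_rotate(f, seed=i) for i, f in enumerate(traj.coords)]),
        traj.reference, traj.atom_names, traj.residue_index)
    cs = traj.meta["contacts"]
    assert np.allclose(contact_fraction(traj, cs),
                       contact_fraction(rotated, cs), atol=1e-9)
    _, rmsf_a, rmsd_a = rmsf_rmsd(traj)
    _, rmsf_b, rmsd_b = rmsf_rmsd(rotated)
    assert np.allclose(rmsf_a, rmsf_b, atol=1e-8)
    assert np.allclose(rmsd_a, rmsd_b, atol=1e-8)
    _, rog_a = gyration(traj)
    _, rog_b = gyration(rotated)
    assert np.allclose(rog_a, rog_b, atol=1e-9)


def test_unfolding_signature():
    """Scheduled unfolding: alpha and eta fall while RMSD and Rog rise."""
    sched = np.linspace(1.0, 0.3, 10)
    traj = sd.gen_toy_trajectory(sd.ToyTrajectorySpec(
        n_residues=20, n_frames=10, unfold_schedule=sched, seed=6))
    alpha = contact_fraction(traj, traj.meta["contacts"])
    eta = hbond_fraction(traj, {"sheet": ((1, 10), (11, 20))})["sheet"]
    _, _, rmsd = rmsf_rmsd(traj)
    _, rog = gyration(traj)
    assert alpha[-1] < alpha[0] and eta[-1] < eta[0]
    assert rmsd[-1] > rmsd[0] and rog[-1] > rog[0]


# ---------------------------------------------------------------- disruption

def test_disruption_identical_and_tag_free():
    conj, free = sd.gen_conjugate_toy(broken_frame_fraction=0.0, n_frames=10,
                                      fluct=0.0, seed=1)
    out = contact_disruption(conj, conj)
    assert np.allclose(out["disruption"], 0.0)
    out2 = contact_disruption(free, free)
    assert np.allclose(out2["occupancy"], 0.0)  # no tag chain present


def test_disruption_occupancy_colocalize():
    """Generator-forced overlap: disruption and occupancy rank-correlate > 0.8."""
    conj, free = sd.gen_conjugate_toy(target_columns=(3, 4, 5),
                                      broken_frame_fraction=0.7,
                                      n_frames=40, fluct=0.05, seed=2)
    out = contact_disruption(conj, free)
    rho = spearmanr(out["disruption"], out["occupancy"]).statistic
    assert rho > 0.8
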