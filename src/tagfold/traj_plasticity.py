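"""Trajectory-level plasticity metrics.

Given a reference (native) structure and Cartesian frames, this module
computes the observables used to characterize how labile a beta-grasp fold
is: the fraction of native residue contacts alpha (minimum heavy-atom
distance, 7 A cutoff, |i-j| >= 4), the fraction of native beta-sheet
backbone hydrogen bonds eta per strand pair (N...O <= 3.5 A), RMSF/RMSD
after least-squares superposition, loop-excluded (Rgyr) and whole-protein
(Rog) radii of gyration, Boltzmann-inverted 2D free-energy landscapes

    dG_i = -kB T ln(N_i / N_0),

Cartesian PCA of the Calpha covariance, and tag-substrate contact
disruption/occupancy maps for conjugate trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import KB_KCAL

__all__ = [
    "Trajectory",
    "ContactSet",
    "FELGrid",
    "define_native_contacts",
    "contact_fraction",
    "hbond_fraction",
    "rmsf_rmsd",
    "gyration",
    "fel_2d",
    "pca",
    "contact_disruption",
]


@dataclass
class Trajectory:
    """Topology + coordinate frames in angstrom.

    coords: (n_frames, n_atoms, 3); reference: (n_atoms, 3) native frame.
    residue_index gives the residue number of each atom; chain_id is a
    per-atom label separating, e.g., tag ('T') from substrate ('S').
    """

    coords: np.ndarray
    reference: np.ndarray
    atom_names: np.ndarray
    residue_index: np.ndarray
    chain_id: np.ndarray | None = None
    masses: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        self.atom_names = np.asarray(self.atom_names)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        n_atoms = self.coords.shape[1]
        if self.reference.shape != (n_atoms, 3):
            raise ValueError("reference atom set must match frames")
        if self.atom_names.size != n_atoms or self.residue_index.size != n_atoms:
            raise ValueError("topology arrays must match atom count")
        if self.chain_id is None:
            self.chain_id = np.full(n_atoms, "A")
        else:
            self.chain_id = np.asarray(self.chain_id)
        if self.masses is None:
            self.masses = np.ones(n_atoms)
        else:
            self.masses = np.asarray(self.masses, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def residues(self) -> np.ndarray:
        return np.unique(self.residue_index)

    def atom_indices(self, name: str | None = None,
                     chain: str | None = None) -> np.ndarray:
        mask = np.ones(self.n_atoms, dtype=bool)
        if name is not None:
            mask &= self.atom_names == name
        if chain is not None:
            mask &= self.chain_id == chain
        return np.where(mask)[0]

    def ca_indices(self) -> np.ndarray:
        idx = self.atom_indices(name="CA")
        return idx if idx.size else np.arange(self.n_atoms)


@dataclass
class ContactSet:
    """Unique residue pairs in contact in the reference structure."""

    pairs: np.ndarray  # (n_pairs, 2) residue numbers
    classes: np.ndarray  # 'native-intra' | 'tag-substrate'
    cutoff: float
    min_separation: int
    definition: str = "min-heavy-atom"

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.classes = np.asarray(self.classes)

    def __len__(self) -> int:
        return self.pairs.shape[0]


@dataclass
class FELGrid:
    x_edges: np.ndarray
    y_edges: np.ndarray
    dg: np.ndarray  # kcal/mol; NaN marks empty (masked) bins
    temperature_k: float


def _residue_atom_lists(traj: Trajectory):
    out = {}
    for r in traj.residues:
        out[int(r)] = np.where(traj.residue_index == r)[0]
    return out


def _min_residue_distance(coords, atoms_i, atoms_j) -> float:
    d = coords[atoms_i][:, None, :] - coords[atoms_j][None, :, :]
    return float(np.sqrt((d**2).sum(-1)).min())


def define_native_contacts(traj: Trajectory, cutoff_a: float = 7.0,
                           min_separation: int = 4) -> ContactSet:
    """Residue pairs with minimum heavy-atom distance <= cutoff in the reference.

    Pairs on the same chain closer in sequence than ``min_separation`` are
    excluded; pairs across chains are classed 'tag-substrate'.
    """
    if traj.n_atoms == 0:
        raise ValueError("no atoms in the reference")
    atoms = _residue_atom_lists(traj)
    res = traj.residues
    chain_of = {int(r): traj.chain_id[atoms[int(r)][0]] for r in res}
    pairs, classes = [], []
    for a in range(res.size):
        for b in range(a + 1, res.size):
            ri, rj = int(res[a]), int(res[b])
            same_chain = chain_of[ri] == chain_of[rj]
            if same_chain and abs(ri - rj) < min_separation:
                continue
            if _min_residue_distance(traj.reference, atoms[ri], atoms[rj]) <= cutoff_a:
                pairs.append((ri, rj))
                classes.append("native-intra" if same_chain else "tag-substrate")
    return ContactSet(np.array(pairs, dtype=int).reshape(-1, 2),
                      np.array(classes), cutoff_a, min_separation)


def contact_fraction(traj: Trajectory, contacts: ContactSet) -> np.ndarray:
    """Per-frame fraction of native pairs still within the cutoff (alpha)."""
    atoms = _residue_atom_lists(traj)
    for ri, rj in contacts.pairs:
        if int(ri) not in atoms or int(rj) not in atoms:
            raise ValueError(f"contact residue pair ({ri}, {rj}) absent from topology")
    if len(contacts) == 0:
        raise ValueError("empty contact set")
    alpha = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        kept = sum(
            _min_residue_distance(traj.coords[f], atoms[int(ri)], atoms[int(rj)])
            <= contacts.cutoff
            for ri, rj in contacts.pairs
        )
        alpha[f] = kept / len(contacts)
    return alpha


def native_hbond_pairs(traj: Trajectory, strand_a, strand_b,
                       cutoff_a: float = 3.5) -> list[tuple[int, int]]:
    """Native backbone N...O atom pairs between two strands in the reference."""
    def backbone(res_range, name):
        lo, hi = res_range
        return [i for i in range(traj.n_atoms)
                if lo <= traj.residue_index[i] <= hi and traj.atom_names[i] == name]

    n_a, o_a = backbone(strand_a, "N"), backbone(strand_a, "O")
    n_b, o_b = backbone(strand_b, "N"), backbone(strand_b, "O")
    if not (n_a or o_a) or not (n_b or o_b):
        raise ValueError("strands lack backbone N/O atoms")
    pairs = []
    for donors, acceptors in ((n_a, o_b), (n_b, o_a)):
        for i in donors:
            for j in acceptors:
                d = np.linalg.norm(traj.reference[i] - traj.reference[j])
                if d <= cutoff_a:
                    pairs.append((i, j))
    return pairs


def hbond_fraction(traj: Trajectory, strand_pairs: dict,
                   cutoff_a: float = 3.5) -> dict[str, np.ndarray]:
    """Per-frame retained fraction of native backbone hydrogen bonds (eta).

    ``strand_pairs`` maps a pair name (e.g. 'b1-b2') to a tuple of two
    inclusive residue ranges ((lo1, hi1), (lo2, hi2)).
    """
    out = {}
    for name, (range_a, range_b) in strand_pairs.items():
        pairs = native_hbond_pairs(traj, range_a, range_b, cutoff_a)
        if not pairs:
            raise ValueError(f"strand pair {name!r} has no native hydrogen bonds")
        eta = np.empty(traj.n_frames)
        idx_i = np.array([p[0] for p in pairs])
        idx_j = np.array([p[1] for p in pairs])
        for f in range(traj.n_frames):
            d = np.linalg.norm(traj.coords[f, idx_i] - traj.coords[f, idx_j],
                               axis=1)
            eta[f] = np.mean(d <= cutoff_a)
        out[name] = eta
    return out


def superpose(traj: Trajectory, fit_indices: np.ndarray | None = None) -> np.ndarray:
    """Least-squares (Kabsch) superposition of each frame onto the reference.

    Returns transformed coordinates (n_frames, n_atoms, 3); the input
    trajectory is not modified.
    """
    if fit_indices is None:
        fit_indices = traj.ca_indices()
    fit_indices = np.asarray(fit_indices)
    if fit_indices.size < 3:
        raise ValueError("need at least 3 atoms for superposition")
    ref = traj.reference[fit_indices]
    ref_c = ref - ref.mean(axis=0)
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        mob = traj.coords[f, fit_indices]
        mob_mean = mob.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_c, mob - mob_mean)
        out[f] = rot.apply(traj.coords[f] - mob_mean) + ref.mean(axis=0)
    return out


def rmsf_rmsd(traj: Trajectory, selection: np.ndarray | None = None,
              fit_selection: np.ndarray | None = None):
    """Per-residue RMSF about the mean structure and per-frame RMSD vs reference.

    Frames are first superposed onto the reference over ``fit_selection``
    (default: Calpha atoms).  RMSF is reported per residue over
    ``selection`` (default: Calpha).
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if selection is None:
        selection = traj.ca_indices()
    fitted = superpose(traj, fit_selection)
    sel = np.asarray(selection)
    x = fitted[:, sel]  # (F, S, 3)
    rmsd = np.sqrt(((x - traj.reference[sel]) ** 2).sum(-1).mean(-1))
    mean_structure = x.mean(axis=0)
    per_atom = np.sqrt(((x - mean_structure) ** 2).sum(-1).mean(0))
    res_of = traj.residue_index[sel]
    residues = np.unique(res_of)
    rmsf = np.array([per_atom[res_of == r].mean() for r in residues])
    return residues, rmsf, rmsd


def gyration(traj: Trajectory, loop_mask: np.ndarray | None = None):
    """Mass-weighted radii of gyration per frame.

    Returns (rgyr, rog): rgyr over the loop-excluded selection (atoms where
    ``loop_mask`` is False), rog over all atoms.  With no mask the two are
    identical.
    """
    def rg(coords, masses):
        com = (coords * masses[:, None]).sum(0) / masses.sum()
        return np.sqrt((masses * ((coords - com) ** 2).sum(-1)).sum() / masses.sum())

    m = traj.masses
    rog = np.array([rg(traj.coords[f], m) for f in range(traj.n_frames)])
    if loop_mask is None:
        return rog.copy(), rog
    keep = ~np.asarray(loop_mask, dtype=bool)
    if not keep.any():
        raise ValueError("loop mask excludes every atom")
    rgyr = np.array([rg(traj.coords[f, keep], m[keep])
                     for f in range(traj.n_frames)])
    return rgyr, rog


def fel_2d(x_series, y_series, temperature_k: float = 300.0,
           bins: int | tuple = 50) -> FELGrid:
    """Boltzmann inversion of the 2D histogram of two structural coordinates.

    dG_i = -kB T ln(N_i / N_0) with N_0 the most populated bin, so the
    global minimum is exactly zero; empty bins are NaN (masked).
    """
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if x.size == 0 or x.size != y.size:
        raise ValueError("series must be equal-length and non-empty")
    counts, xe, ye = np.histogram2d(x, y, bins=bins)
    n0 = counts.max()
    with np.errstate(divide="ignore"):
        dg = -KB_KCAL * temperature_k * np.log(counts / n0)
    dg[counts == 0] = np.nan
    return FELGrid(xe, ye, dg, temperature_k)


def pca(traj: Trajectory, selection: np.ndarray | None = None):
    """Cartesian PCA of the (superposed) Calpha covariance.

    Returns (components, variances, projections): components are rows of
    shape (k, 3*n_sel) sorted by non-increasing variance; projections are
    per-frame scores (n_frames, k).
    """
    if selection is None:
        selection = traj.ca_indices()
    sel = np.asarray(selection)
    fitted = superpose(traj, sel)
    X = fitted[:, sel].reshape(traj.n_frames, -1)
    Xc = X - X.mean(axis=0)
    if traj.n_frames < Xc.shape[1]:
        import warnings
        warnings.warn("fewer frames than coordinates: covariance is rank-deficient",
                      stacklevel=2)
    cov = Xc.T @ Xc / max(traj.n_frames - 1, 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    variances = np.clip(w[order], 0.0, None)
    components = v[:, order].T
    projections = Xc @ components.T
    return components, variances, projections


def pc1_extremes(traj: Trajectory, selection: np.ndarray | None = None,
                 n_interp: int = 5) -> np.ndarray:
    """Interpolated structures between the PC1 extremes (n_interp, n_sel, 3)."""
    if selection is None:
        selection = traj.ca_indices()
    sel = np.asarray(selection)
    comps, _, proj = pca(traj, sel)
    fitted = superpose(traj, sel)[:, sel]
    mean = fitted.mean(axis=0).reshape(-1)
    lo, hi = proj[:, 0].min(), proj[:, 0].max()
    ts = np.linspace(lo, hi, n_interp)
    return np.array([(mean + t * comps[0]).reshape(-1, 3) for t in ts])


def contact_disruption(traj_conjugate: Trajectory, traj_free: Trajectory,
                       cutoff_a: float = 7.0, min_separation: int = 4,
                       substrate_chain: str = "S", tag_chain: str = "T"):
    """Per-substrate-residue disruption and tag-occupancy maps.

    Disruption: mean long-range intra-substrate native-contact count per
    residue in the free run minus the conjugated run, normalized to [0, 1].
    Occupancy: fraction of conjugate frames in which any tag atom lies
    within the cutoff of the residue, normalized.  Returns a dict with
    'residues', 'disruption', 'occupancy'.
    """
    sub_free = traj_free.residue_index[traj_free.chain_id == substrate_chain]
    sub_conj = traj_conjugate.residue_index[
        traj_conjugate.chain_id == substrate_chain]
    residues = np.unique(sub_free)
    if not np.array_equal(residues, np.unique(sub_conj)):
        raise ValueError("substrate residue indexing differs between trajectories")

    def per_residue_counts(traj):
        atoms = _residue_atom_lists(traj)
        chain_of = {int(r): traj.chain_id[atoms[int(r)][0]] for r in traj.residues}
        sub = [r for r in traj.residues if chain_of[int(r)] == substrate_chain]
        ref_contacts = []
        for a in range(len(sub)):
            for b in range(a + 1, len(sub)):
                ri, rj = int(sub[a]), int(sub[b])
                if abs(ri - rj) < min_separation:
                    continue
                if _min_residue_distance(traj.reference, atoms[ri], atoms[rj]) <= cutoff_a:
                    ref_contacts.append((ri, rj))
        counts = {int(r): 0.0 for r in sub}
        for f in range(traj.n_frames):
            for ri, rj in ref_contacts:
                if _min_residue_distance(traj.coords[f], atoms[ri], atoms[rj]) <= cutoff_a:
                    counts[ri] += 1.0
                    counts[rj] += 1.0
        for r in counts:
            counts[r] /= traj.n_frames
        return counts

    free_counts = per_residue_counts(traj_free)
    conj_counts = per_residue_counts(traj_conjugate)
    disruption = np.array([free_counts[int(r)] - conj_counts.get(int(r), 0.0)
                           for r in residues])
    disruption = np.clip(disruption, 0.0, None)
    if disruption.max() > 0:
        disruption = disruption / disruption.max()

    tag_atoms = np.where(traj_conjugate.chain_id == tag_chain)[0]
    atoms_conj = _residue_atom_lists(traj_conjugate)
    occupancy = np.zeros(residues.size)
    if tag_atoms.size:
        for k, r in enumerate(residues):
            hits = 0
            a_idx = atoms_conj[int(r)]
            for f in range(traj_conjugate.n_frames):
                d = traj_conjugate.coords[f, a_idx][:, None, :] \
                    - traj_conjugate.coords[f, tag_atoms][None, :, :]
                if np.sqrt((d**2).sum(-1)).min() <= cutoff_a:
                    hits += 1
            occupancy[k] = hits / traj_conjugate.n_frames
    if occupancy.max() > 0:
        occupancy = occupancy / occupancy.max()
    return {"residues": residues, "disruption": disruption, "occupancy": occupancy}
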