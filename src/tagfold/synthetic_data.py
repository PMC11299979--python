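"""Synthetic datasets with known ground truth for every analysis stage.

Each generator is the exact forward model of the corresponding fitter, so
parameter recovery closes the loop: at zero noise the fitted parameters
must reproduce the ground truth to high precision, and at realistic noise
the recovery tolerances characterize the pipeline, not the data.

Randomness: each spec carries one integer seed.  Generators draw through
per-series child streams (``numpy`` SeedSequence spawning, one stream per
residue / concentration / frame series), so enlarging a spec never
reshuffles the draws of earlier series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .equilibrium_unfolding import DenaturationCurve, fraction_unfolded
from .nmr_modelfree_entropy import RelaxationDataset, relaxation_rates
from .nmr_tempco import ShiftTable
from .proteolysis_energetics import ProteolysisDataset
from .traj_plasticity import Trajectory, define_native_contacts

__all__ = [
    "MeltSpec",
    "ProteolysisSpec",
    "TempcoSpec",
    "RelaxSpec",
    "ToyTrajectorySpec",
    "gen_chemical_melt",
    "gen_thermal_melt",
    "gen_proteolysis",
    "gen_shift_table",
    "gen_relaxation",
    "gen_toy_trajectory",
    "gen_conjugate_toy",
]

REFERENCE_TEMPERATURE_K = 283.0  # lowest shift-acquisition temperature


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class MeltSpec:
    """Ground truth for a chemical or thermal two-state melt."""

    dg0: float = 5.0  # kcal/mol, chemical mode
    m_value: float = 2.0  # kcal/mol/M
    axis: np.ndarray | None = None  # M or degC
    tm: float = 55.0  # degC, thermal mode
    slope_t: float = 3.0  # degC transition width
    noise_sd: float = 0.0
    baselines: tuple = (0.0, 0.0, 1.0, 0.0)  # af, bf, au, bu
    temperature_k: float = 298.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dg0 <= 0 or self.m_value <= 0:
            raise ValueError("dG0 and m must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.axis is not None:
            self.axis = np.asarray(self.axis, dtype=float)
            if np.any(np.diff(self.axis) <= 0):
                raise ValueError("axis must be strictly increasing")


@dataclass
class ProteolysisSpec:
    """Ground truth for native-state proteolysis time courses."""

    kop: float = 1e-6
    kcat_km: float = 99_000.0  # M^-1 s^-1
    concentrations: np.ndarray = field(
        default_factory=lambda: np.array([0.72e-6, 1.44e-6, 2.89e-6, 5.78e-6]))
    times: np.ndarray | None = None  # default: 8 points to ~3/k at the mid conc
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kop <= 0 or self.kcat_km <= 0:
            raise ValueError("Kop and kcat/KM must be positive")
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)


@dataclass
class TempcoSpec:
    """Ground truth per-residue amide temperature coefficients."""

    residues: np.ndarray = field(default_factory=lambda: np.arange(1, 11))
    tc_true: np.ndarray = field(default_factory=lambda: np.full(10, -5.0))  # ppb/K
    intercepts: np.ndarray | None = None  # ppm at the reference temperature
    temperatures: np.ndarray = field(
        default_factory=lambda: np.arange(283.0, 314.0, 5.0))
    noise_sd: float = 0.0  # ppm
    seed: int = 0

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues)
        self.tc_true = np.asarray(self.tc_true, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.temperatures.size < 3:
            raise ValueError("need at least 3 temperatures")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.intercepts is None:
            self.intercepts = np.full(self.residues.size, 8.3)
        self.intercepts = np.asarray(self.intercepts, dtype=float)


@dataclass
class RelaxSpec:
    """Ground truth for a 15N relaxation dataset."""

    s2_true: np.ndarray = field(default_factory=lambda: np.full(10, 0.85))
    tau_m: float = 5.0  # ns, global
    tau_e: np.ndarray | float = 50.0  # ps, per residue
    rex: np.ndarray | float = 0.0  # s^-1, per residue
    field_mhz: float = 600.0
    noise_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.s2_true = np.asarray(self.s2_true, dtype=float)
        if np.any(self.s2_true < 0) or np.any(self.s2_true > 1):
            raise ValueError("order parameters must lie in [0, 1]")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        n = self.s2_true.size
        self.tau_e = np.broadcast_to(np.asarray(self.tau_e, dtype=float), (n,)).copy()
        self.rex = np.broadcast_to(np.asarray(self.rex, dtype=float), (n,)).copy()
        if np.any(self.tau_e < 0) or np.any(self.rex < 0):
            raise ValueError("tau_e and Rex must be non-negative")


@dataclass
class ToyTrajectorySpec:
    """An idealized two-strand (hairpin) chain with programmed dynamics.

    The toy places three pseudo-atoms (N, CA, O) per residue on two paired
    antiparallel strands, giving a native contact set and one backbone
    hydrogen bond per strand column.  ``fluct_amplitudes`` are per-residue
    isotropic Gaussian displacement sigmas (A, rigid per residue);
    ``unfold_schedule`` maps each frame to the fraction of native contacts
    to retain (monotone non-increasing).
    """

    n_residues: int = 20
    fluct_amplitudes: np.ndarray | float = 0.0
    unfold_schedule: np.ndarray | None = None
    n_frames: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 8 or self.n_residues % 2:
            raise ValueError("n_residues must be even and >= 8")
        self.fluct_amplitudes = np.broadcast_to(
            np.asarray(self.fluct_amplitudes, dtype=float),
            (self.n_residues,)).copy()
        if np.any(self.fluct_amplitudes < 0):
            raise ValueError("fluctuation amplitudes must be non-negative")
        if self.unfold_schedule is not None:
            sched = np.asarray(self.unfold_schedule, dtype=float)
            if sched.size != self.n_frames:
                raise ValueError("schedule must give one retained fraction per frame")
            if np.any(np.diff(sched) > 1e-12):
                raise ValueError("retained-contact schedule must be non-increasing")
            if np.any(sched < 0) or np.any(sched > 1):
                raise ValueError("schedule fractions must lie in [0, 1]")
            self.unfold_schedule = sched


def gen_chemical_melt(spec: MeltSpec) -> DenaturationCurve:
    """Two-state chemical melt from dG([D]) = dG0 - m [D] at the spec temperature."""
    axis = spec.axis if spec.axis is not None else np.arange(0.0, 6.25, 0.25)
    fu = fraction_unfolded(axis, spec.dg0, spec.m_value, spec.temperature_k)
    af, bf, au, bu = spec.baselines
    signal = (af + bf * axis) * (1 - fu) + (au + bu * axis) * fu
    rng = np.random.default_rng(spec.seed)
    signal = signal + rng.normal(0.0, spec.noise_sd, axis.size)
    normalized = spec.baselines == (0.0, 0.0, 1.0, 0.0)
    return DenaturationCurve(axis, signal, mode="chemical", normalized=normalized,
                             meta={"truth": spec})


def gen_thermal_melt(spec: MeltSpec) -> DenaturationCurve:
    """Normalized sigmoid melt with midpoint tm and width slope_t.

    Default axis 20-95 degC at 1 degC steps.  A vanishing width yields a
    step function with the midpoint still at tm.
    """
    axis = spec.axis if spec.axis is not None else np.arange(20.0, 96.0, 1.0)
    if not (axis[0] <= spec.tm <= axis[-1]):
        raise ValueError("tm must lie within the temperature axis")
    width = max(spec.slope_t, 1e-9)
    fu = 1.0 / (1.0 + np.exp((spec.tm - axis) / width))
    rng = np.random.default_rng(spec.seed)
    signal = fu + rng.normal(0.0, spec.noise_sd, axis.size)
    return DenaturationCurve(axis, signal, mode="thermal", normalized=True,
                             meta={"truth": spec})


def gen_proteolysis(spec: ProteolysisSpec) -> ProteolysisDataset:
    """First-order decays I(t) = exp(-k_obs t), k_obs = Kop (kcat/KM) [protease].

    Times default to 8 points reaching ~3/k_obs at the median concentration.
    A no-protease control lane of unit intensity is attached.
    """
    rate = spec.kop * spec.kcat_km * spec.concentrations
    if spec.times is None:
        k_mid = spec.kop * spec.kcat_km * np.median(spec.concentrations)
        times = np.linspace(0.0, 3.0 / k_mid, 8)
    else:
        times = spec.times
    rngs = _rngs(spec.seed, spec.concentrations.size)
    rows = []
    for k, rng in zip(rate, rngs):
        decay = np.exp(-k * times)
        rows.append(decay + rng.normal(0.0, spec.noise_sd, times.size))
    control = np.ones(times.size)
    return ProteolysisDataset(spec.concentrations, times, np.array(rows),
                              control=control, meta={"truth": spec})


def gen_shift_table(spec: TempcoSpec) -> ShiftTable:
    """Linear shift drifts delta(T) = intercept + Tc (T - Tref) 1e-3 ppm."""
    t = spec.temperatures
    t_ref = t[0]
    rngs = _rngs(spec.seed, spec.residues.size)
    shifts = np.empty((spec.residues.size, t.size))
    for i, rng in enumerate(rngs):
        line = spec.intercepts[i] + spec.tc_true[i] * 1e-3 * (t - t_ref)
        shifts[i] = line + rng.normal(0.0, spec.noise_sd, t.size)
    return ShiftTable(spec.residues, t, shifts,
                      reference_note="synthetic", meta={"truth": spec})


def gen_relaxation(spec: RelaxSpec) -> RelaxationDataset:
    """R1/R2/NOE from the model-free forward equations, with relative noise.

    Reported errors are ``max(noise_frac, 0.005)`` of each rate, so a
    noiseless dataset still carries usable fitting weights.
    """
    n = spec.s2_true.size
    rngs = _rngs(spec.seed, n)
    r1 = np.empty(n)
    r2 = np.empty(n)
    noe = np.empty(n)
    for i, rng in enumerate(rngs):
        v1, v2, vn = relaxation_rates(spec.s2_true[i], spec.tau_m * 1e-9,
                                      spec.tau_e[i] * 1e-12, spec.rex[i],
                                      spec.field_mhz)
        noise = rng.normal(0.0, 1.0, 3) * spec.noise_frac
        r1[i] = v1 * (1.0 + noise[0])
        r2[i] = v2 * (1.0 + noise[1])
        noe[i] = vn * (1.0 + noise[2])
    err_frac = max(spec.noise_frac, 0.005)
    residues = np.arange(1, n + 1)
    return RelaxationDataset(
        residues, r1, np.abs(r1) * err_frac, r2, np.abs(r2) * err_frac,
        np.clip(noe, None, 1.05), np.maximum(np.abs(noe) * err_frac, 1e-3),
        field_mhz=spec.field_mhz, meta={"truth": spec})


# toy hairpin geometry (angstrom)
_CA_SPACING = 3.8
_STRAND_SEP = 4.8
_NO_Y_OFFSET = 1.2
_NO_Z_OFFSET = 0.6


def _hairpin_reference(n_residues: int):
    """Two paired antiparallel strands; returns (coords, names, res_idx)."""
    m = n_residues // 2
    coords, names, res_idx = [], [], []

    def add_residue(res, x, y, facing):
        # N and O point toward the partner strand (facing = +1/-1 along y)
        coords.append((x, y + facing * _NO_Y_OFFSET, _NO_Z_OFFSET))
        names.append("N")
        res_idx.append(res)
        coords.append((x, y, 0.0))
        names.append("CA")
        res_idx.append(res)
        coords.append((x, y + facing * _NO_Y_OFFSET, -_NO_Z_OFFSET))
        names.append("O")
        res_idx.append(res)

    for i in range(m):  # strand A: residues 1..m, left to right
        add_residue(i + 1, i * _CA_SPACING, 0.0, +1)
    for k in range(m):  # strand B: residues m+1..n, right to left (hairpin)
        add_residue(m + 1 + k, (m - 1 - k) * _CA_SPACING, _STRAND_SEP, -1)
    return (np.array(coords, dtype=float), np.array(names),
            np.array(res_idx, dtype=int))


def _partner_column(n_residues: int):
    """Residue pairs sharing an x column: A residue m-k <-> B residue m+1+k."""
    m = n_residues // 2
    return {m - k: m + 1 + k for k in range(m)}


def gen_toy_trajectory(spec: ToyTrajectorySpec) -> Trajectory:
    """Reference + frames with Gaussian fluctuations and scheduled contact loss.

    Contacts are broken by displacing strand-B residues away from the sheet
    in a fixed seeded order; for each frame the number of displaced
    residues is the smallest that brings the retained-contact fraction at
    or below the schedule value (granularity: one residue breaks its 2-3
    contacts at once).
    """
    ref, names, res_idx = _hairpin_reference(spec.n_residues)
    n_atoms = ref.shape[0]
    traj0 = Trajectory(ref[None, :, :], ref, names, res_idx)
    contacts = define_native_contacts(traj0, cutoff_a=7.0, min_separation=4)
    n_contacts = len(contacts)

    # fixed seeded order of strand-B residues to displace
    m = spec.n_residues // 2
    order_rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    b_residues = np.arange(m + 1, spec.n_residues + 1)
    order = order_rng.permutation(b_residues)
    # cumulative broken-contact count as residues are displaced
    broken_after = [0]
    broken_set: set[tuple[int, int]] = set()
    for r in order:
        for ri, rj in contacts.pairs:
            if r in (ri, rj):
                broken_set.add((int(ri), int(rj)))
        broken_after.append(len(broken_set))
    broken_after = np.array(broken_after)

    rngs = _rngs(spec.seed, spec.n_residues + 1)  # stream 0 reserved (order)
    frames = np.empty((spec.n_frames, n_atoms, 3))
    atom_of_res = {r: np.where(res_idx == r)[0] for r in np.unique(res_idx)}
    # pre-draw per-residue displacement series so schedule handling cannot
    # perturb the stream order
    disp = np.zeros((spec.n_residues, spec.n_frames, 3))
    for i in range(spec.n_residues):
        sigma = spec.fluct_amplitudes[i]
        if sigma > 0:
            disp[i] = rngs[i + 1].normal(0.0, sigma, (spec.n_frames, 3))

    for f in range(spec.n_frames):
        frame = ref.copy()
        for i, r in enumerate(np.unique(res_idx)):
            frame[atom_of_res[r]] += disp[i, f]
        if spec.unfold_schedule is not None:
            target_broken = (1.0 - spec.unfold_schedule[f]) * n_contacts
            n_disp = int(np.argmin(np.abs(broken_after - target_broken)))
            for r in order[:n_disp]:
                frame[atom_of_res[r]] += np.array([0.0, 3.0 * _STRAND_SEP, 0.0])
        frames[f] = frame
    return Trajectory(frames, ref, names, res_idx,
                      meta={"truth": spec, "contacts": contacts})


def gen_conjugate_toy(n_residues: int = 20, target_columns=(3, 4, 5),
                      broken_frame_fraction: float = 0.7, n_frames: int = 40,
                      fluct: float = 0.05, seed: int = 0):
    """A (conjugate, free-substrate) trajectory pair with forced overlap
    between tag contacts and intra-substrate contact disruption.

    The substrate is the toy hairpin (chain 'S').  A pseudo-tag (chain 'T',
    one CA bead hovering 6 A above each targeted residue and its strand
    partner) contacts exactly the targeted region, and in
    ``broken_frame_fraction`` of the conjugate frames the targeted strand-A
    residues are lifted out of the sheet, breaking their native contacts.
    Disruption and tag-occupancy maps computed from this pair must
    co-localize by construction.
    """
    ref, names, res_idx = _hairpin_reference(n_residues)
    m = n_residues // 2
    partner = _partner_column(n_residues)
    targets_a = [c for c in target_columns if 1 <= c <= m]
    targets_b = [partner[c] for c in targets_a]
    targeted = targets_a + targets_b

    # tag beads above each targeted residue (out of the sheet plane, just
    # inside the 7 A contact cutoff for the targeted residue and outside it
    # for the neighbouring columns)
    tag_coords, tag_names, tag_res = [], [], []
    for j, r in enumerate(targeted):
        ca = ref[(res_idx == r) & (names == "CA")][0]
        tag_coords.append(ca + np.array([0.0, 0.0, 6.5]))
        tag_names.append("CA")
        tag_res.append(500 + j)

    full_ref = np.vstack([ref, np.array(tag_coords)])
    full_names = np.concatenate([names, np.array(tag_names)])
    full_res = np.concatenate([res_idx, np.array(tag_res, dtype=int)])
    chains = np.array(["S"] * len(names) + ["T"] * len(tag_names))

    rng = np.random.default_rng(seed)
    broken = rng.random(n_frames) < broken_frame_fraction

    conj_frames = np.empty((n_frames, full_ref.shape[0], 3))
    free_frames = np.empty((n_frames, ref.shape[0], 3))
    for f in range(n_frames):
        jitter = rng.normal(0.0, fluct, ref.shape)
        free_frames[f] = ref + jitter
        frame = full_ref.copy()
        frame[: ref.shape[0]] += jitter
        if broken[f]:
            # lift clears the 7 A contact cutoff even against partner
            # backbone atoms offset toward the lifted residue, while
            # staying within reach of the tag bead at z = 6.5
            for r in targets_a:
                frame[(full_res == r)] += np.array([0.0, 0.0, 9.0])
        conj_frames[f] = frame

    conj = Trajectory(conj_frames, full_ref, full_names, full_res, chain_id=chains)
    free = Trajectory(free_frames, ref, names, res_idx,
                      chain_id=np.array(["S"] * len(names)))
    return conj, free
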