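"""Plain-text I/O for the tabular datasets and trajectory files.

Tables are TSV with ``# key: value`` metadata header lines followed by a
pandas-readable header row.  Trajectories are written as a reference PDB
plus either a multi-model PDB or a DCD of frames (via mdtraj).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .equilibrium_unfolding import DenaturationCurve
from .nmr_modelfree_entropy import RelaxationDataset
from .nmr_tempco import ShiftTable
from .proteolysis_energetics import ProteolysisDataset
from .traj_plasticity import Trajectory


def _write_tsv(path, df: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    lines = Path(path).read_text().splitlines(keepends=True)
    body = 0
    for line in lines:
        if line.startswith("#"):
            body += 1
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
        else:
            break
    df = pd.read_csv(_io.StringIO("".join(lines[body:])), sep="\t")
    return df, meta


def save_curve(path, curve: DenaturationCurve) -> None:
    _write_tsv(path, pd.DataFrame({"axis": curve.axis, "signal": curve.signal}),
               {"mode": curve.mode, "normalized": curve.normalized})


def load_curve(path) -> DenaturationCurve:
    df, meta = _read_tsv(path)
    return DenaturationCurve(df["axis"].to_numpy(), df["signal"].to_numpy(),
                             mode=meta.get("mode", "chemical"),
                             normalized=meta.get("normalized", "False") == "True")


def save_proteolysis(path, ds: ProteolysisDataset) -> None:
    rows = []
    for c, row in zip(ds.concentrations, ds.intensities):
        for t, i in zip(ds.times, row):
            rows.append({"concentration_M": c, "time_s": t, "intensity": i})
    _write_tsv(path, pd.DataFrame(rows), {"control": "normalized-to-1"})


def load_proteolysis(path) -> ProteolysisDataset:
    df, _ = _read_tsv(path)
    conc = np.sort(df["concentration_M"].unique())
    times = np.sort(df["time_s"].unique())
    mat = np.empty((conc.size, times.size))
    for i, c in enumerate(conc):
        sub = df[df["concentration_M"] == c].sort_values("time_s")
        mat[i] = sub["intensity"].to_numpy()
    return ProteolysisDataset(conc, times, mat, control=np.ones(times.size))


def save_shift_table(path, table: ShiftTable) -> None:
    rows = []
    for r, series in zip(table.residues, table.shifts):
        for t, s in zip(table.temperatures, series):
            rows.append({"residue": r, "temperature_K": t, "shift_ppm": s})
    _write_tsv(path, pd.DataFrame(rows), {"reference": table.reference_note})


def load_shift_table(path) -> ShiftTable:
    df, meta = _read_tsv(path)
    residues = np.sort(df["residue"].unique())
    temps = np.sort(df["temperature_K"].unique())
    shifts = np.full((residues.size, temps.size), np.nan)
    t_pos = {t: j for j, t in enumerate(temps)}
    r_pos = {r: i for i, r in enumerate(residues)}
    for _, row in df.iterrows():
        shifts[r_pos[row["residue"]], t_pos[row["temperature_K"]]] = row["shift_ppm"]
    return ShiftTable(residues, temps, shifts,
                      reference_note=meta.get("reference", ""))


def save_relaxation(path, ds: RelaxationDataset) -> None:
    df = pd.DataFrame({
        "residue": ds.residues, "R1": ds.r1, "R1_err": ds.r1_err,
        "R2": ds.r2, "R2_err": ds.r2_err, "NOE": ds.noe, "NOE_err": ds.noe_err,
    })
    _write_tsv(path, df, {"field_mhz": ds.field_mhz})


def load_relaxation(path) -> RelaxationDataset:
    df, meta = _read_tsv(path)
    return RelaxationDataset(
        df["residue"].to_numpy(), df["R1"].to_numpy(), df["R1_err"].to_numpy(),
        df["R2"].to_numpy(), df["R2_err"].to_numpy(),
        df["NOE"].to_numpy(), df["NOE_err"].to_numpy(),
        field_mhz=float(meta["field_mhz"]))


def _mdtraj_topology(traj: Trajectory):
    import mdtraj as md

    top = md.Topology()
    chains = {}
    residues = {}
    for i in range(traj.n_atoms):
        cid = str(traj.chain_id[i])
        if cid not in chains:
            chains[cid] = top.add_chain()
        key = (cid, int(traj.residue_index[i]))
        if key not in residues:
            residues[key] = top.add_residue("GLY", chains[cid],
                                            resSeq=int(traj.residue_index[i]))
        name = str(traj.atom_names[i])
        element = md.element.carbon if name == "CA" else (
            md.element.nitrogen if name == "N" else md.element.oxygen)
        top.add_atom(name, element, residues[key])
    return top


def save_trajectory(prefix, traj: Trajectory, frame_format: str = "pdb") -> None:
    """Write ``<prefix>_ref.pdb`` plus frames as multi-model PDB or DCD."""
    import mdtraj as md

    top = _mdtraj_topology(traj)
    ref = md.Trajectory(traj.reference[None] / 10.0, top)  # A -> nm
    ref.save_pdb(f"{prefix}_ref.pdb")
    frames = md.Trajectory(traj.coords / 10.0, top)
    if frame_format == "pdb":
        frames.save_pdb(f"{prefix}_frames.pdb")
    elif frame_format == "dcd":
        frames.save_dcd(f"{prefix}_frames.dcd")
    else:
        raise ValueError(f"unknown frame format {frame_format!r}")


def load_trajectory(reference_pdb, frames_file) -> Trajectory:
    """Read a reference PDB and a frames file (multi-model PDB or DCD)."""
    import mdtraj as md

    ref = md.load(str(reference_pdb))
    if str(frames_file).endswith(".dcd"):
        frames = md.load_dcd(str(frames_file), top=ref.topology)
    else:
        frames = md.load(str(frames_file))
    names = np.array([a.name for a in ref.topology.atoms])
    res_idx = np.array([a.residue.resSeq for a in ref.topology.atoms])
    chain_ids = np.array([chr(ord("A") + a.residue.chain.index)
                          for a in ref.topology.atoms])
    masses = np.array([a.element.mass for a in ref.topology.atoms])
    return Trajectory(frames.xyz * 10.0, ref.xyz[0] * 10.0, names, res_idx,
                      chain_id=chain_ids, masses=masses)
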