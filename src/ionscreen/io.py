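"""File formats: TSV profiles/windows/scans and extended-XYZ trajectories.

All formats are plain text.  Profile and scan files carry ``# key=value``
metadata lines before a tab-separated header row.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .decompose import CoulombProfile
from .lj import EnergyScan
from .profiles import FreeEnergyProfile
from .windows import MeanForceWindow

__all__ = [
    "write_profile",
    "read_profile",
    "write_coulomb_profile",
    "read_coulomb_profile",
    "write_window",
    "read_window",
    "write_scan",
    "read_scan",
    "Frame",
    "write_xyz_trajectory",
    "read_xyz_trajectory",
]


def _parse_metadata(lines: List[str], path) -> Tuple[Dict[str, str], int]:
    meta: Dict[str, str] = {}
    k = 0
    for k, line in enumerate(lines):
        if not line.startswith("#"):
            break
        body = line[1:].strip()
        if body and "=" not in body:
            raise ValueError(f"{path}: malformed metadata at line {k + 1}: {line!r}")
        if body:
            key, _, val = body.partition("=")
            meta[key.strip()] = val.strip()
    return meta, k


def _read_table(path) -> Tuple[Dict[str, str], List[str], np.ndarray]:
    lines = Path(path).read_text().splitlines()
    meta, k = _parse_metadata(lines, path)
    if k >= len(lines):
        raise ValueError(f"{path}: no column header found")
    header = lines[k].split("\t")
    rows = [ln.split("\t") for ln in lines[k + 1 :] if ln.strip()]
    try:
        data = np.array(rows, dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric table entry ({exc})") from exc
    if data.ndim != 2 or data.shape[1] != len(header):
        raise ValueError(f"{path}: table width does not match header")
    return meta, header, data


# -- free-energy / Coulomb profiles -----------------------------------------

def _write_profile_like(path, meta: Dict[str, str], r, values, sigma) -> None:
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        if sigma is None:
            fh.write("r_A\tF_kJ_mol\n")
            for ri, fi in zip(r, values):
                fh.write(f"{ri:.6f}\t{fi:.8f}\n")
        else:
            fh.write("r_A\tF_kJ_mol\tsigma_kJ_mol\n")
            for ri, fi, si in zip(r, values, sigma):
                fh.write(f"{ri:.6f}\t{fi:.8f}\t{si:.8f}\n")


def write_profile(profile: FreeEnergyProfile, path) -> None:
    meta = {
        "kind": "free_energy",
        "reference": profile.reference,
        "corrected": str(profile.corrected).lower(),
    }
    if profile.temperature is not None:
        meta["temperature_K"] = f"{profile.temperature:g}"
    _write_profile_like(path, meta, profile.distances, profile.free_energy, profile.sigma)


def read_profile(path) -> FreeEnergyProfile:
    meta, header, data = _read_table(path)
    if header[:2] != ["r_A", "F_kJ_mol"]:
        raise ValueError(f"{path}: unexpected profile columns {header}")
    sigma = data[:, 2] if len(header) > 2 else None
    temp = float(meta["temperature_K"]) if "temperature_K" in meta else None
    return FreeEnergyProfile(
        distances=data[:, 0],
        free_energy=data[:, 1],
        sigma=sigma,
        reference=meta.get("reference", "rmax"),
        temperature=temp,
        corrected=meta.get("corrected", "false") == "true",
    )


def write_coulomb_profile(profile: CoulombProfile, path) -> None:
    _write_profile_like(
        path, {"kind": "coulomb"}, profile.distances, profile.coulomb_energy, profile.sigma
    )


def read_coulomb_profile(path) -> CoulombProfile:
    meta, header, data = _read_table(path)
    if meta.get("kind") != "coulomb":
        raise ValueError(f"{path}: not a Coulomb profile (kind={meta.get('kind')!r})")
    sigma = data[:, 2] if len(header) > 2 else None
    return CoulombProfile(distances=data[:, 0], coulomb_energy=data[:, 1], sigma=sigma)


# -- mean-force windows ------------------------------------------------------

def write_window(window: MeanForceWindow, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# target_distance_A={window.target_distance:g}\n")
        fh.write(f"# timestep_fs={window.timestep:g}\n")
        fh.write(f"# equilibration_steps={window.equilibration_steps}\n")
        fh.write(f"# mode={window.mode}\n")
        fh.write(f"# seed={window.seed}\n")
        fh.write("step\ttime_fs\tr_A\tprojected_force_kJ_mol_A\n")
        r = window.target_distance
        for k, f in enumerate(window.projected_forces):
            fh.write(f"{k}\t{k * window.timestep:.3f}\t{r:.6f}\t{f:.8f}\n")


def read_window(path) -> MeanForceWindow:
    meta, header, data = _read_table(path)
    if header != ["step", "time_fs", "r_A", "projected_force_kJ_mol_A"]:
        raise ValueError(f"{path}: unexpected window columns {header}")
    return MeanForceWindow(
        target_distance=float(meta["target_distance_A"]),
        projected_forces=data[:, 3],
        timestep=float(meta["timestep_fs"]),
        production_steps=data.shape[0],
        equilibration_steps=int(meta.get("equilibration_steps", 0)),
        mode=meta.get("mode", "polarizable_charged"),
        seed=int(meta.get("seed", 0)),
    )


# -- energy scans ------------------------------------------------------------

def write_scan(scan: EnergyScan, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# q1={scan.charges[0]:g}\n")
        fh.write(f"# q2={scan.charges[1]:g}\n")
        fh.write(f"# pair={scan.species_pair[0]}-{scan.species_pair[1]}\n")
        fh.write("r_A\tE_kJ_mol\n")
        for r, e in zip(scan.distances, scan.energies):
            fh.write(f"{r:.6f}\t{e:.8f}\n")


def read_scan(path) -> EnergyScan:
    meta, header, data = _read_table(path)
    if header != ["r_A", "E_kJ_mol"]:
        raise ValueError(f"{path}: unexpected scan columns {header}")
    pair = tuple(meta.get("pair", "A-B").split("-"))[:2]
    return EnergyScan(
        distances=data[:, 0],
        energies=data[:, 1],
        species_pair=pair,  # type: ignore[arg-type]
        charges=(float(meta.get("q1", 0.0)), float(meta.get("q2", 0.0))),
    )


# -- extended XYZ ------------------------------------------------------------

@dataclass
class Frame:
    """One trajectory frame: symbols, positions (Å), cubic box side, step."""

    symbols: Sequence[str]
    positions: np.ndarray
    side_length: float
    step: int = 0


def write_xyz_trajectory(frames: Sequence[Frame], path, stride: int = 1) -> None:
    """Extended-XYZ with the cubic Lattice in the comment line."""
    if stride < 1:
        raise ValueError("stride must be positive")
    with open(path, "w") as fh:
        for frame in frames[::stride]:
            L = frame.side_length
            fh.write(f"{len(frame.symbols)}\n")
            fh.write(
                f'Lattice="{L:.8f} 0.0 0.0 0.0 {L:.8f} 0.0 0.0 0.0 {L:.8f}" '
                f"Properties=species:S:1:pos:R:3 step={frame.step}\n"
            )
            for sym, p in zip(frame.symbols, frame.positions):
                fh.write(f"{sym} {p[0]:.8f} {p[1]:.8f} {p[2]:.8f}\n")


def read_xyz_trajectory(path) -> List[Frame]:
    lines = Path(path).read_text().splitlines()
    frames: List[Frame] = []
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].strip())
        except ValueError as exc:
            raise ValueError(f"{path}: expected atom count at line {k + 1}") from exc
        comment = lines[k + 1]
        if "Lattice=" not in comment:
            raise ValueError(f"{path}: frame at line {k + 1} lacks Lattice metadata")
        lattice = comment.split('Lattice="', 1)[1].split('"', 1)[0].split()
        vals = [float(v) for v in lattice]
        if len(vals) != 9 or vals[0] != vals[4] or vals[4] != vals[8]:
            raise ValueError(f"{path}: only cubic lattices are supported")
        step = 0
        for tok in comment.split():
            if tok.startswith("step="):
                step = int(tok[5:])
        symbols = []
        positions = np.empty((n, 3))
        for i in range(n):
            parts = lines[k + 2 + i].split()
            symbols.append(parts[0])
            positions[i] = [float(x) for x in parts[1:4]]
        frames.append(Frame(symbols, positions, vals[0], step))
        k += 2 + n
    return frames
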