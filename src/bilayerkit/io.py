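"""Readers and writers for GRO and PDB structures and multi-frame trajectories.

Both formats are parsed from their fixed-column dialects. Coordinates are
stored in nm internally; PDB angstroms are converted at this boundary and
nowhere else. Only orthorhombic cells are supported — triclinic box lines
are rejected with an explicit message rather than silently mangled.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .core import (
    AtomRecord,
    Frame,
    ResidueClass,
    Topology,
    Trajectory,
    UnitCell,
    guess_mass,
)

__all__ = [
    "ParseError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "classify_residue",
]


class ParseError(ValueError):
    """Raised when a structure/trajectory file violates its format."""


# residue-name -> coarse chemical class; extended by callers as needed
_RESIDUE_CLASS_TABLE = {
    "SOL": ResidueClass.SOLVENT,
    "HOH": ResidueClass.SOLVENT,
    "WAT": ResidueClass.SOLVENT,
    "TIP3": ResidueClass.SOLVENT,
    "LYS": ResidueClass.CATIONIC,
    "ARG": ResidueClass.CATIONIC,
    "HIS": ResidueClass.CATIONIC,
    "GLU": ResidueClass.ANIONIC,
    "ASP": ResidueClass.ANIONIC,
    "GLUH": ResidueClass.POLAR,
    "SER": ResidueClass.POLAR,
    "THR": ResidueClass.POLAR,
    "ASN": ResidueClass.POLAR,
    "GLN": ResidueClass.POLAR,
    "TYR": ResidueClass.POLAR,
    "GLY": ResidueClass.POLAR,
    "ALA": ResidueClass.HYDROPHOBIC,
    "VAL": ResidueClass.HYDROPHOBIC,
    "LEU": ResidueClass.HYDROPHOBIC,
    "ILE": ResidueClass.HYDROPHOBIC,
    "PHE": ResidueClass.HYDROPHOBIC,
    "TRP": ResidueClass.HYDROPHOBIC,
    "MET": ResidueClass.HYDROPHOBIC,
    "PRO": ResidueClass.HYDROPHOBIC,
    "POPG": ResidueClass.LIPID,
    "POPC": ResidueClass.LIPID,
    "DPPG": ResidueClass.LIPID,
    "LIP": ResidueClass.LIPID,
    "NA": ResidueClass.CATIONIC,
    "CL": ResidueClass.ANIONIC,
}


def classify_residue(residue_name: str) -> ResidueClass:
    """Map a residue name onto its coarse chemical class (OTHER if unknown)."""
    return _RESIDUE_CLASS_TABLE.get(residue_name.strip().upper(), ResidueClass.OTHER)


def _detect_format(path: str | Path, format: str | None) -> str:
    if format is not None:
        fmt = format.upper()
    else:
        fmt = Path(path).suffix.lstrip(".").upper()
    if fmt not in ("GRO", "PDB"):
        raise ValueError(f"unsupported structure format {fmt!r} (expected GRO or PDB)")
    return fmt


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

_TIME_RE = re.compile(r"\bt\s*=\s*([-+0-9.eE]+)")


def _parse_gro_box(line: str, lineno: int) -> UnitCell:
    parts = line.split()
    if len(parts) < 3:
        raise ParseError(f"line {lineno}: GRO box line needs >= 3 numbers, got {line!r}")
    try:
        vals = [float(p) for p in parts]
    except ValueError as exc:
        raise ParseError(f"line {lineno}: unreadable GRO box line {line!r}") from exc
    if len(vals) > 3 and any(abs(v) > 1e-9 for v in vals[3:]):
        raise ParseError(f"line {lineno}: triclinic cells are not supported")
    return UnitCell(vals[0], vals[1], vals[2])


def _parse_gro_frame(lines: list[str], start: int):
    """Parse one GRO frame starting at ``lines[start]`` (the title line).

    Returns (records, coords, cell, time, next_line_index); records is None
    when the parsed frame should reuse a previously built topology.
    """
    title = lines[start]
    m = _TIME_RE.search(title)
    time = float(m.group(1)) if m else None
    try:
        natoms = int(lines[start + 1].split()[0])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"line {start + 2}: expected atom count, got {lines[start + 1]!r}") from exc
    if natoms <= 0:
        raise ParseError(f"line {start + 2}: non-positive atom count {natoms}")
    if len(lines) < start + 3 + natoms:
        raise ParseError(
            f"line {len(lines)}: file truncated, expected {natoms} atom lines plus a box line"
        )
    records: list[AtomRecord] = []
    coords = np.empty((natoms, 3))
    for i in range(natoms):
        lineno = start + 3 + i  # 1-based line number for messages
        line = lines[start + 2 + i]
        if len(line.rstrip("\n")) < 44:
            raise ParseError(f"line {lineno}: truncated GRO atom line {line!r}")
        try:
            resid = int(line[0:5])
            resname = line[5:10].strip()
            name = line[10:15].strip()
            serial = int(line[15:20])
            coords[i, 0] = float(line[20:28])
            coords[i, 1] = float(line[28:36])
            coords[i, 2] = float(line[36:44])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: malformed GRO atom line {line!r}") from exc
        records.append(
            AtomRecord(
                atom_index=serial if serial > 0 else i + 1,
                atom_name=name,
                residue_name=resname,
                residue_index=resid,
                mass=guess_mass(name),
                residue_class=classify_residue(resname),
            )
        )
    cell = _parse_gro_box(lines[start + 2 + natoms], start + 3 + natoms)
    return records, coords, cell, time, start + 3 + natoms


def _read_gro_frames(path: str | Path):
    text = Path(path).read_text()
    lines = text.splitlines()
    frames = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        frames.append(_parse_gro_frame(lines, pos))
        pos = frames[-1][4]
    return frames


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _parse_pdb(path: str | Path):
    """Parse a PDB file into (records, list of (coords_nm, time)) and a cell."""
    cell = None
    records: list[AtomRecord] = []
    model_coords: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] = []
    in_model = False
    first_model_done = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        rec = line[:6]
        if rec == "CRYST1":
            try:
                a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
                alpha, beta, gamma = float(line[33:40]), float(line[40:47]), float(line[47:54])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed CRYST1 record") from exc
            if any(abs(ang - 90.0) > 1e-3 for ang in (alpha, beta, gamma)):
                raise ParseError(f"line {lineno}: triclinic cells are not supported")
            cell = UnitCell(a / 10.0, b / 10.0, c / 10.0)
        elif rec == "MODEL ":
            in_model = True
            current = []
        elif rec == "ENDMDL":
            model_coords.append(current)
            first_model_done = True
            in_model = False
        elif rec in ("ATOM  ", "HETATM"):
            if len(line) < 54:
                raise ParseError(f"line {lineno}: truncated {rec.strip()} record")
            try:
                serial = int(line[6:11])
                x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed {rec.strip()} record") from exc
            name = line[12:16].strip()
            resname = line[17:21].strip()
            chain = line[21].strip() or None
            try:
                resid = int(line[22:26])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed residue number") from exc
            current.append((x / 10.0, y / 10.0, z / 10.0))
            if not first_model_done:
                records.append(
                    AtomRecord(
                        atom_index=serial,
                        atom_name=name,
                        residue_name=resname,
                        residue_index=resid,
                        protomer_id=chain,
                        mass=guess_mass(name),
                        residue_class=classify_residue(resname),
                    )
                )
    if current and (not model_coords or not in_model):
        if not first_model_done:
            model_coords.append(current)
    if not model_coords or not model_coords[0]:
        raise ParseError(f"{path}: no frames (no ATOM/HETATM records found)")
    return records, [np.asarray(c) for c in model_coords], cell


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_structure(
    path: str | Path,
    format: str | None = None,
    cell: UnitCell | None = None,
) -> tuple[Topology, Frame]:
    """Read a single-frame structure file into a (Topology, Frame) pair.

    Coordinates are returned in nm (PDB input is converted from angstrom).
    ``cell`` supplies the unit cell when the file lacks one; a file that
    has neither raises :class:`ParseError`.
    """
    fmt = _detect_format(path, format)
    if fmt == "GRO":
        records, coords, file_cell, time, _ = _parse_gro_frame(
            Path(path).read_text().splitlines(), 0
        )
    else:
        records, models, file_cell = _parse_pdb(path)
        coords, time = models[0], None
    use_cell = file_cell or cell
    if use_cell is None:
        raise ParseError(f"{path}: no unit cell in file and none supplied")
    topo = Topology(records)
    return topo, Frame(time=time or 0.0, coordinates=coords, cell=use_cell)


def read_trajectory(
    path: str | Path,
    topology: Topology | None = None,
    format: str | None = None,
    dt: float = 1.0,
) -> Trajectory:
    """Read a multi-frame GRO or PDB file as a trajectory.

    Frame times come from ``t=`` stamps in GRO title lines when present;
    otherwise frames are stamped ``i * dt`` ps in file order. When
    ``topology`` is given, every frame must match its atom count.
    """
    fmt = _detect_format(path, format)
    if fmt == "GRO":
        parsed = _read_gro_frames(path)
        if not parsed:
            raise ParseError(f"{path}: no frames")
        topo = topology or Topology(parsed[0][0])
        frames = []
        for i, (_, coords, cell, time, _) in enumerate(parsed):
            if coords.shape[0] != len(topo):
                raise ParseError(
                    f"frame {i}: {coords.shape[0]} atoms, topology has {len(topo)}"
                )
            t = time if time is not None else i * dt
            frames.append(Frame(time=t, coordinates=coords, cell=cell))
    else:
        records, models, cell = _parse_pdb(path)
        if cell is None:
            raise ParseError(f"{path}: no CRYST1 cell in PDB trajectory")
        topo = topology or Topology(records)
        frames = []
        for i, coords in enumerate(models):
            if coords.shape[0] != len(topo):
                raise ParseError(
                    f"frame {i}: {coords.shape[0]} atoms, topology has {len(topo)}"
                )
            frames.append(Frame(time=i * dt, coordinates=coords, cell=cell))
    times = [f.time for f in frames]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        # identical stamps (common in concatenated GRO) fall back to file order
        frames = [
            Frame(time=i * dt, coordinates=f.coordinates, cell=f.cell)
            for i, f in enumerate(frames)
        ]
    return Trajectory(topo, frames)


def _format_gro_frame(topo: Topology, frame: Frame, title: str) -> str:
    lines = [f"{title} t= {frame.time:.3f}", f"{len(topo):5d}"]
    for atom, (x, y, z) in zip(topo.atoms, frame.coordinates):
        lines.append(
            f"{atom.residue_index % 100000:5d}{atom.residue_name:<5.5s}"
            f"{atom.atom_name:>5.5s}{atom.atom_index % 100000:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    c = frame.cell
    lines.append(f"{c.lx:10.5f}{c.ly:10.5f}{c.lz:10.5f}")
    return "\n".join(lines) + "\n"


def _format_pdb_frame(topo: Topology, frame: Frame, model: int | None) -> str:
    lines = []
    if model is not None:
        lines.append(f"MODEL     {model:4d}")
    for atom, (x, y, z) in zip(topo.atoms, frame.coordinates):
        name = atom.atom_name if len(atom.atom_name) >= 4 else f" {atom.atom_name:<3.3s}"
        lines.append(
            f"ATOM  {atom.atom_index % 100000:5d} {name:<4.4s} "
            f"{atom.residue_name:<4.4s}{(atom.protomer_id or ' ')[:1]}"
            f"{atom.residue_index % 10000:4d}    "
            f"{x * 10:8.3f}{y * 10:8.3f}{z * 10:8.3f}{1.0:6.2f}{0.0:6.2f}"
        )
    if model is not None:
        lines.append("ENDMDL")
    return "\n".join(lines) + "\n"


def write_structure(path: str | Path, topology: Topology, frame: Frame,
                    format: str | None = None, title: str = "bilayerkit") -> None:
    """Write one frame as GRO or PDB (format from extension if not given)."""
    fmt = _detect_format(path, format)
    if fmt == "GRO":
        Path(path).write_text(_format_gro_frame(topology, frame, title))
    else:
        c = frame.cell
        head = (
            f"CRYST1{c.lx * 10:9.3f}{c.ly * 10:9.3f}{c.lz * 10:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
        )
        Path(path).write_text(head + _format_pdb_frame(topology, frame, None) + "END\n")


def write_trajectory(path: str | Path, traj: Trajectory,
                     format: str | None = None, title: str = "bilayerkit") -> None:
    """Write a trajectory as concatenated GRO frames or a MODEL/ENDMDL PDB."""
    fmt = _detect_format(path, format)
    if fmt == "GRO":
        chunks = [_format_gro_frame(traj.topology, fr, title) for fr in traj]
        Path(path).write_text("".join(chunks))
    else:
        c = traj[0].cell
        head = (
            f"CRYST1{c.lx * 10:9.3f}{c.ly * 10:9.3f}{c.lz * 10:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
        )
        chunks = [head] + [
            _format_pdb_frame(traj.topology, fr, i + 1) for i, fr in enumerate(traj)
        ]
        Path(path).write_text("".join(chunks) + "END\n")
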