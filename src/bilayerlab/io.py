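"""Readers and writers: GRO coordinate files (single- and multi-frame),
the columnar TRJTXT v1 trajectory dialect, and the site-table TSV.

GRO files carry no masses, charges or polarity metadata, so the site
table returned by :func:`read_gro` fills those columns with neutral
defaults (mass 1 u, charge 0, 0 electrons, polarity ``other``); merge a
real site table when those quantities matter.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Tuple, Union

import numpy as np
import pandas as pd

from .core import BilayerError, Frame, SiteTable, Trajectory, SITE_TABLE_COLUMNS


class GroParseError(BilayerError):
    def __init__(self, message: str, line_no: int):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


class UnsupportedBoxError(BilayerError):
    pass


_TIME_RE = re.compile(r"\bt\s*=\s*([0-9.eE+\-]+)")


def _parse_box_line(line: str, line_no: int) -> np.ndarray:
    try:
        vals = [float(x) for x in line.split()]
    except ValueError:
        raise GroParseError(f"cannot parse box line {line.strip()!r}", line_no) from None
    if len(vals) == 3:
        box = np.array(vals)
    elif len(vals) == 9:
        if any(abs(v) > 1e-12 for v in vals[3:]):
            raise UnsupportedBoxError(
                f"line {line_no}: triclinic box (nonzero off-diagonal elements) "
                "is not supported; only orthorhombic boxes are accepted"
            )
        box = np.array(vals[:3])
    else:
        raise GroParseError(
            f"box line must have 3 or 9 numbers, found {len(vals)}", line_no
        )
    if np.any(box <= 0):
        raise GroParseError("box edges must be strictly positive", line_no)
    return box


def _parse_atom_line(line: str, line_no: int):
    if len(line.rstrip("\n")) < 44:
        raise GroParseError("atom line shorter than fixed-column GRO layout", line_no)
    try:
        resid = int(line[0:5])
        resname = line[5:10].strip()
        name = line[10:15].strip()
        x = float(line[20:28])
        y = float(line[28:36])
        z = float(line[36:44])
    except ValueError:
        raise GroParseError(f"malformed atom line {line.rstrip()!r}", line_no) from None
    return resid, resname, name, (x, y, z)


def read_gro(path: Union[str, Path]) -> Tuple[SiteTable, Union[Frame, Trajectory]]:
    """Read a GRO file; concatenated blocks are returned as a Trajectory.

    Coordinates are in nm; velocities, if present, are ignored.  The
    first block's title line is preserved in ``table.df.attrs['title']``.
    Frame times are taken from a ``t=<ps>`` tag in each title when
    present, otherwise frames are numbered 0, 1, 2, ... ps.
    """
    lines = Path(path).read_text().splitlines()
    frames = []
    table = None
    title0 = ""
    i = 0
    block = 0
    while i < len(lines):
        if not lines[i].strip() and i + 1 >= len(lines):
            break
        title = lines[i]
        if i + 1 >= len(lines):
            raise GroParseError("missing atom count line", i + 2)
        try:
            n_atoms = int(lines[i + 1].strip())
        except ValueError:
            raise GroParseError(
                f"malformed atom count line {lines[i + 1].strip()!r}", i + 2
            ) from None
        if n_atoms <= 0:
            raise GroParseError(f"atom count must be positive, got {n_atoms}", i + 2)
        first_atom = i + 2
        if first_atom + n_atoms >= len(lines) + 1 and first_atom + n_atoms > len(lines):
            raise GroParseError(
                f"declared {n_atoms} atoms but file ends after "
                f"{len(lines) - first_atom} atom lines", len(lines)
            )
        records = []
        coords = np.empty((n_atoms, 3))
        for j in range(n_atoms):
            ln = first_atom + j
            resid, resname, name, xyz = _parse_atom_line(lines[ln], ln + 1)
            coords[j] = xyz
            if block == 0:
                records.append(
                    {
                        "site_id": j,
                        "site_name": name,
                        "residue_name": resname,
                        "molecule_id": resid,
                    }
                )
        box_ln = first_atom + n_atoms
        if box_ln >= len(lines):
            raise GroParseError("missing box line", box_ln + 1)
        box = _parse_box_line(lines[box_ln], box_ln + 1)
        m = _TIME_RE.search(title)
        time = float(m.group(1)) if m else float(block)
        frames.append(Frame(time=time, box=box, coords=coords))
        if block == 0:
            table = SiteTable.from_records(records)
            title0 = title
        elif frames[-1].n_sites != table.df.shape[0]:
            raise GroParseError("frame blocks disagree on atom count", i + 2)
        i = box_ln + 1
        block += 1
        while i < len(lines) and not lines[i].strip():
            i += 1
    if table is None:
        raise GroParseError("empty GRO file", 1)
    table.df.attrs["title"] = title0
    if len(frames) == 1:
        return table, frames[0]
    return table, Trajectory(frames)


def write_gro(
    table: SiteTable,
    frame: Union[Frame, Trajectory],
    path: Union[str, Path],
    title: str = "written by bilayerlab",
) -> None:
    """Write a frame (or every frame of a trajectory) in fixed-column GRO."""
    frames = frame.frames if isinstance(frame, Trajectory) else [frame]
    if len(table) == 0:
        raise BilayerError("cannot write a GRO file for an empty site table")
    if len(table) > 99999:
        raise BilayerError("GRO fixed-width fields support at most 99,999 sites")
    names = table.column("site_name")
    resnames = table.column("residue_name")
    molids = table.molecule_ids
    out = []
    for fr in frames:
        if fr.n_sites != len(table):
            raise BilayerError("frame size does not match site table")
        out.append(f"{title} t= {fr.time:.5f}")
        out.append(f"{fr.n_sites:5d}")
        for j in range(fr.n_sites):
            x, y, z = fr.coords[j]
            out.append(
                f"{int(molids[j]) % 100000:5d}{str(resnames[j])[:5]:<5s}"
                f"{str(names[j])[:5]:>5s}{(j + 1) % 100000:5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}"
            )
        out.append(f"{fr.box[0]:10.5f}{fr.box[1]:10.5f}{fr.box[2]:10.5f}")
    Path(path).write_text("\n".join(out) + "\n")


# --- TRJTXT v1 -------------------------------------------------------------

def write_trjtxt(traj: Trajectory, path: Union[str, Path]) -> None:
    """Write the native columnar trajectory dialect (TRJTXT v1)."""
    out = [f"#TRJTXT n_sites={traj.n_sites} dt_ps={traj.dt:g}"]
    for fr in traj.frames:
        out.append(
            f"#FRAME t={fr.time:g} box={fr.box[0]:.6f} {fr.box[1]:.6f} {fr.box[2]:.6f}"
        )
        for x, y, z in fr.coords:
            out.append(f"{x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(out) + "\n")


def read_trjtxt(path: Union[str, Path]) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#TRJTXT"):
        raise BilayerError(f"{path}: not a TRJTXT v1 file")
    header = dict(kv.split("=") for kv in lines[0].split()[1:])
    n_sites = int(header["n_sites"])
    dt = float(header.get("dt_ps", 0))
    frames = []
    i = 1
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith("#FRAME"):
            raise BilayerError(f"{path}: expected #FRAME at line {i + 1}")
        m = re.match(
            r"#FRAME t=([0-9.eE+\-]+) box=([0-9.eE+\-]+) ([0-9.eE+\-]+) ([0-9.eE+\-]+)",
            lines[i],
        )
        if not m:
            raise BilayerError(f"{path}: malformed #FRAME header at line {i + 1}")
        t = float(m.group(1))
        box = np.array([float(m.group(k)) for k in (2, 3, 4)])
        block = lines[i + 1 : i + 1 + n_sites]
        if len(block) < n_sites:
            raise BilayerError(f"{path}: truncated frame at line {i + 1}")
        coords = np.loadtxt(block, ndmin=2)
        if coords.shape != (n_sites, 3):
            raise BilayerError(f"{path}: bad coordinate block at line {i + 2}")
        frames.append(Frame(time=t, box=box, coords=coords))
        i += 1 + n_sites
    return Trajectory(frames, dt=dt)


# --- SiteTable TSV ---------------------------------------------------------

def write_site_table(table: SiteTable, path: Union[str, Path]) -> None:
    df = table.df.copy()
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_site_table(path: Union[str, Path]) -> SiteTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in SITE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise BilayerError(f"{path}: site table TSV missing columns {missing}")
    df["chain_label"] = df["chain_label"].where(df["chain_label"].notna(), None)
    return SiteTable(df)
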