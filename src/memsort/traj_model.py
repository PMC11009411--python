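"""Coarse-grained bilayer trajectory containers, I/O and periodic geometry.

A trajectory here is a stack of frames of typed beads (phosphate headgroup
beads such as ``PO4``, cholesterol ``ROH``, protein backbone ``BB``) living
in a laterally periodic box.  Internal units are Å for length, ns for time
and K for temperature; the GRO-series reader converts nm → Å on read.

Two on-disk dialects are supported:

* a CSV dialect with header ``frame,time_ns,bead_id,bead_name,resid,resname,
  x,y,z`` plus a JSON sidecar carrying the box, temperature, protein resids
  and head-bead names;
* a concatenated GRO-snapshot dialect (one standard GRO block per frame,
  coordinates in nm) with the same sidecar.

The z axis (the bilayer normal) is never wrapped: trajectories are assumed
pre-imaged in z, since leaflet analyses break under z-wrapping.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Box",
    "Bead",
    "Frame",
    "Trajectory",
    "LeafletLabel",
    "TrajectoryFormatError",
    "RosterMismatchError",
    "read_trajectory",
    "write_trajectory",
    "assign_leaflets",
    "lateral_displacement",
    "minimum_image",
    "lateral_com",
    "sidecar_path",
]

CSV_COLUMNS = ["frame", "time_ns", "bead_id", "bead_name", "resid", "resname", "x", "y", "z"]


class TrajectoryFormatError(ValueError):
    """A trajectory file does not conform to its dialect."""


class RosterMismatchError(ValueError):
    """Frames of one trajectory disagree on the bead roster."""


@dataclass(frozen=True)
class Box:
    """Orthorhombic simulation box, lengths in Å.

    x and y are treated as periodic for all lateral analyses; z (the bilayer
    normal) is not wrapped.
    """

    Lx: float
    Ly: float
    Lz: float
    lateral_periodic: bool = True

    def __post_init__(self) -> None:
        if not (self.Lx > 0 and self.Ly > 0 and self.Lz > 0):
            raise ValueError(f"box lengths must be positive, got {(self.Lx, self.Ly, self.Lz)}")


@dataclass(frozen=True)
class Bead:
    """One coarse-grained bead; ``resid`` groups beads into a molecule."""

    bead_id: int
    bead_name: str
    resid: int
    resname: str
    x: float
    y: float
    z: float


class Frame:
    """One time point: a box plus parallel bead arrays.

    Parameters
    ----------
    time_ns : float
    box : Box
    bead_id, bead_name, resid, resname : array-like
        Per-bead identity columns.  ``bead_id`` must be unique within the
        frame.
    xyz : (n, 3) array of float
        Positions in Å.
    """

    def __init__(self, time_ns, box, bead_id, bead_name, resid, resname, xyz):
        self.time_ns = float(time_ns)
        self.box = box
        self.bead_id = np.asarray(bead_id, dtype=np.int64)
        self.bead_name = np.asarray(bead_name, dtype=object)
        self.resid = np.asarray(resid, dtype=np.int64)
        self.resname = np.asarray(resname, dtype=object)
        self.xyz = np.asarray(xyz, dtype=float)
        n = self.bead_id.shape[0]
        if self.xyz.shape != (n, 3):
            raise ValueError(f"xyz must have shape ({n}, 3), got {self.xyz.shape}")
        for name, arr in (("bead_name", self.bead_name), ("resid", self.resid), ("resname", self.resname)):
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != {n}")
        if np.unique(self.bead_id).size != n:
            raise TrajectoryFormatError("bead_id values must be unique within a frame")

    @property
    def n_beads(self) -> int:
        return self.bead_id.shape[0]

    @property
    def beads(self) -> Iterator[Bead]:
        for i in range(self.n_beads):
            yield Bead(
                int(self.bead_id[i]), str(self.bead_name[i]), int(self.resid[i]),
                str(self.resname[i]), *map(float, self.xyz[i]),
            )

    def roster(self) -> tuple:
        """Hashable identity of the bead roster (ids, names, resids, resnames)."""
        return (
            tuple(self.bead_id.tolist()),
            tuple(self.bead_name.tolist()),
            tuple(self.resid.tolist()),
            tuple(self.resname.tolist()),
        )

    def select(self, mask: np.ndarray) -> "Frame":
        return Frame(self.time_ns, self.box, self.bead_id[mask], self.bead_name[mask],
                     self.resid[mask], self.resname[mask], self.xyz[mask])


@dataclass
class Trajectory:
    """An ordered stack of frames sharing one bead roster."""

    frames: list
    temperature_K: float = 295.0
    protein_resids: tuple = ()
    lipid_head_beads: tuple = ("PO4",)
    composition: object = None  # optional MembraneRecipe

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("a trajectory needs at least one frame")
        self.protein_resids = tuple(int(r) for r in self.protein_resids)
        if isinstance(self.lipid_head_beads, str):
            self.lipid_head_beads = (self.lipid_head_beads,)
        self.lipid_head_beads = tuple(self.lipid_head_beads)
        ref = self.frames[0].roster()
        for i, fr in enumerate(self.frames[1:], start=1):
            if fr.roster() != ref:
                raise RosterMismatchError(f"frame {i} bead roster differs from frame 0")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def box(self) -> Box:
        return self.frames[0].box

    def lipid_resids(self) -> np.ndarray:
        fr = self.frames[0]
        mask = ~np.isin(fr.resid, list(self.protein_resids))
        return np.unique(fr.resid[mask])


@dataclass(frozen=True)
class LeafletLabel:
    """Exhaustive, exclusive upper/lower assignment of lipid resids."""

    upper: frozenset
    lower: frozenset

    def side(self, resid: int) -> str:
        if resid in self.upper:
            return "upper"
        if resid in self.lower:
            return "lower"
        raise KeyError(f"resid {resid} is not labeled")

    def as_dict(self) -> dict:
        d = {r: "upper" for r in self.upper}
        d.update({r: "lower" for r in self.lower})
        return d


# ---------------------------------------------------------------------------
# periodic geometry

def minimum_image(d: np.ndarray, box: Box) -> np.ndarray:
    """Wrap lateral displacement components into [-L/2, L/2]."""
    d = np.array(d, dtype=float, copy=True)
    L = np.array([box.Lx, box.Ly])
    d[..., 0] -= L[0] * np.round(d[..., 0] / L[0])
    d[..., 1] -= L[1] * np.round(d[..., 1] / L[1])
    return d


def lateral_displacement(a, b, box: Box) -> tuple:
    """Minimum-image lateral displacement from point ``a`` to point ``b``.

    ``a`` and ``b`` are (x, y[, z]) sequences; z is ignored.  Components
    satisfy |dx| <= Lx/2 and |dy| <= Ly/2.
    """
    d = np.array([b[0] - a[0], b[1] - a[1]], dtype=float)
    d = minimum_image(d, box)
    return float(d[0]), float(d[1])


def lateral_com(xy: np.ndarray, box: Box) -> np.ndarray:
    """Periodic-aware lateral center of mass of a point cloud.

    Uses the circular mean per axis so molecules split across a periodic
    boundary get a sensible center.
    """
    xy = np.asarray(xy, dtype=float)
    out = np.empty(2)
    for k, L in enumerate((box.Lx, box.Ly)):
        theta = xy[:, k] * (2.0 * np.pi / L)
        ang = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
        out[k] = (ang % (2.0 * np.pi)) * L / (2.0 * np.pi)
    return out


# ---------------------------------------------------------------------------
# leaflet assignment

def assign_leaflets(frame: Frame, lipid_head_bead) -> LeafletLabel:
    """Assign every lipid to the upper or lower leaflet.

    The instantaneous midplane is the mean z of all head beads; lipids whose
    head bead sits above it go to the upper leaflet, the rest to the lower.
    If all head beads are exactly coplanar the frame is degenerate: every
    lipid is assigned to the upper leaflet and a warning is emitted.
    """
    heads = (lipid_head_bead,) if isinstance(lipid_head_bead, str) else tuple(lipid_head_bead)
    mask = np.isin(frame.bead_name, heads)
    if not mask.any():
        raise ValueError(f"no head beads named {heads!r} in frame")
    z = frame.xyz[mask, 2]
    resids = frame.resid[mask]
    if resids.size < 2:
        raise ValueError("need at least two lipids with head beads to assign leaflets")
    if np.ptp(z) == 0.0:
        warnings.warn("all head beads coplanar; assigning every lipid to the upper leaflet",
                      RuntimeWarning, stacklevel=2)
        return LeafletLabel(upper=frozenset(int(r) for r in resids), lower=frozenset())
    mid = z.mean()
    up = z > mid
    return LeafletLabel(
        upper=frozenset(int(r) for r in resids[up]),
        lower=frozenset(int(r) for r in resids[~up]),
    )


# ---------------------------------------------------------------------------
# I/O

def sidecar_path(path) -> Path:
    """Path of the JSON sidecar accompanying a trajectory file."""
    p = Path(path)
    return p.with_suffix(p.suffix + ".json") if p.suffix != ".json" else p


def _read_sidecar(path) -> dict:
    sp = sidecar_path(path)
    if not sp.exists():
        raise TrajectoryFormatError(f"missing JSON sidecar {sp}")
    with open(sp, "r", encoding="utf-8") as fh:
        return json.load(fh)


def _write_sidecar(path, traj: Trajectory) -> None:
    meta = {
        "Lx": traj.box.Lx,
        "Ly": traj.box.Ly,
        "Lz": traj.box.Lz,
        "temperature_K": traj.temperature_K,
        "protein_resids": list(traj.protein_resids),
        "lipid_head_bead": list(traj.lipid_head_beads),
    }
    if traj.composition is not None:
        meta["composition"] = traj.composition.to_dict()
    with open(sidecar_path(path), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")


def read_trajectory(path, dialect: Literal["csv", "gro-series"] = "csv") -> Trajectory:
    """Read a trajectory in the CSV or concatenated-GRO dialect.

    Raises
    ------
    TrajectoryFormatError
        On malformed rows (the message names the offending line).
    RosterMismatchError
        If the bead roster differs between frames.
    """
    meta = _read_sidecar(path)
    box = Box(float(meta["Lx"]), float(meta["Ly"]), float(meta["Lz"]))
    heads = meta.get("lipid_head_bead", "PO4")
    composition = meta.get("composition")
    if composition is not None:
        from .membrane_builder import MembraneRecipe

        composition = MembraneRecipe.from_dict(composition)
    if dialect == "csv":
        frames = _read_csv_frames(path, box)
    elif dialect == "gro-series":
        frames = _read_gro_frames(path, box)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return Trajectory(
        frames=frames,
        temperature_K=float(meta.get("temperature_K", 295.0)),
        protein_resids=tuple(meta.get("protein_resids", ())),
        lipid_head_beads=heads,
        composition=composition,
    )


def _read_csv_frames(path, box: Box) -> list:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TrajectoryFormatError(f"cannot parse {path}: {exc}") from exc
    if list(df.columns) != CSV_COLUMNS:
        raise TrajectoryFormatError(
            f"{path}: header must be {','.join(CSV_COLUMNS)}, got {','.join(map(str, df.columns))}"
        )
    for col in ("frame", "bead_id", "resid"):
        if not np.issubdtype(df[col].dtype, np.integer):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise TrajectoryFormatError(f"{path}: non-integer value in column {col!r} near line {line}")
    for col in ("time_ns", "x", "y", "z"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise TrajectoryFormatError(f"{path}: non-numeric value in column {col!r} near line {line}")
    frames = []
    for fidx, g in df.groupby("frame", sort=True):
        frames.append(Frame(
            time_ns=float(g["time_ns"].iloc[0]),
            box=box,
            bead_id=g["bead_id"].to_numpy(),
            bead_name=g["bead_name"].to_numpy(dtype=object),
            resid=g["resid"].to_numpy(),
            resname=g["resname"].to_numpy(dtype=object),
            xyz=g[["x", "y", "z"]].to_numpy(dtype=float),
        ))
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames found")
    return frames


def _read_gro_frames(path, box: Box) -> list:
    frames = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    i = 0
    nline = len(lines)
    while i < nline:
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        time_ns = 0.0
        if "t=" in title:
            try:
                time_ns = float(title.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                raise TrajectoryFormatError(f"{path}: bad time in title line {i + 1}")
        try:
            natoms = int(lines[i + 1].strip())
        except (ValueError, IndexError):
            raise TrajectoryFormatError(f"{path}: bad atom count at line {i + 2}")
        rows = lines[i + 2:i + 2 + natoms]
        if len(rows) < natoms:
            raise TrajectoryFormatError(f"{path}: truncated snapshot starting at line {i + 1}")
        bead_id, bead_name, resid, resname, xyz = [], [], [], [], []
        for j, row in enumerate(rows):
            try:
                resid.append(int(row[0:5]))
                resname.append(row[5:10].strip())
                bead_name.append(row[10:15].strip())
                bead_id.append(int(row[15:20]))
                # GRO stores nm; internal unit is Å
                xyz.append([float(row[20:28]) * 10.0, float(row[28:36]) * 10.0, float(row[36:44]) * 10.0])
            except ValueError as exc:
                raise TrajectoryFormatError(f"{path}: malformed atom record at line {i + 3 + j}") from exc
        frames.append(Frame(time_ns, box, bead_id, bead_name, resid, resname, xyz))
        i += 2 + natoms + 1  # skip box line
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames found")
    return frames


def write_trajectory(traj: Trajectory, path, dialect: Literal["csv", "gro-series"] = "csv") -> None:
    """Write a trajectory plus its JSON sidecar; re-readable to equality."""
    if dialect == "csv":
        recs = []
        for fidx, fr in enumerate(traj.frames):
            recs.append(pd.DataFrame({
                "frame": fidx,
                "time_ns": fr.time_ns,
                "bead_id": fr.bead_id,
                "bead_name": fr.bead_name,
                "resid": fr.resid,
                "resname": fr.resname,
                "x": fr.xyz[:, 0],
                "y": fr.xyz[:, 1],
                "z": fr.xyz[:, 2],
            }))
        # %.17g guarantees exact float round-trip on re-read
        pd.concat(recs, ignore_index=True).to_csv(path, index=False, lineterminator="\n",
                                                  float_format="%.17g")
    elif dialect == "gro-series":
        with open(path, "w", encoding="utf-8") as fh:
            box_nm = (traj.box.Lx / 10.0, traj.box.Ly / 10.0, traj.box.Lz / 10.0)
            for fr in traj.frames:
                fh.write(f"memsort frame t= {fr.time_ns:.6f}\n{fr.n_beads}\n")
                for i in range(fr.n_beads):
                    fh.write("%5d%-5s%5s%5d%8.3f%8.3f%8.3f\n" % (
                        int(fr.resid[i]) % 100000, str(fr.resname[i])[:5], str(fr.bead_name[i])[:5],
                        int(fr.bead_id[i]) % 100000,
                        fr.xyz[i, 0] / 10.0, fr.xyz[i, 1] / 10.0, fr.xyz[i, 2] / 10.0,
                    ))
                fh.write("%10.5f%10.5f%10.5f\n" % box_nm)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    _write_sidecar(path, traj)
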