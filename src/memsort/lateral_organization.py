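"""First-shell lipid composition and protein-protein distance statistics.

Quantifies radially biased lipid sorting around a transmembrane inclusion
(the time-averaged mole fraction of each lipid type in the first shell of
surrounding lipids) and the lateral centre-of-mass distance distribution of
two inclusions in a periodic box.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .traj_model import Box, Frame, Trajectory, lateral_com, minimum_image

__all__ = [
    "ShellComposition",
    "DistanceDistribution",
    "first_shell_members",
    "first_shell_members_knn",
    "shell_fraction",
    "shell_fraction_vs_temperature",
    "pair_distances",
    "pair_distance_distribution",
]


@dataclass
class ShellComposition:
    """Time-averaged first-shell mole fractions per lipid type."""

    fractions: dict          # lipid type -> fraction; sums to 1
    shell_radius: float
    n_frames_used: int
    n_frames_empty: int
    mean_shell_size: float

    def fraction_of(self, lipid_type: str) -> float:
        return self.fractions.get(lipid_type, 0.0)


@dataclass
class DistanceDistribution:
    """Normalised histogram of per-frame inclusion-pair COM distances."""

    bin_edges: np.ndarray
    mass: np.ndarray
    n_samples: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers, "mass": self.mass})


def _protein_center(frame: Frame, protein_resid: int) -> np.ndarray:
    mask = frame.resid == protein_resid
    if not mask.any():
        raise ValueError(f"protein resid {protein_resid} absent from frame")
    return lateral_com(frame.xyz[mask, 0:2], frame.box)


def _lipid_heads(frame: Frame, head_beads, protein_resids) -> tuple:
    mask = np.isin(frame.bead_name, tuple(head_beads)) & ~np.isin(frame.resid, tuple(protein_resids))
    return frame.resid[mask], frame.resname[mask], frame.xyz[mask, 0:2]


def first_shell_members(frame: Frame, protein_resid: int, shell_radius: float,
                        head_beads=("PO4", "ROH"), protein_resids=(),
                        r_min: float = 0.0) -> set:
    """Lipid resids whose head bead lies in the annulus (r_min, shell_radius].

    Membership is binary (a lipid is in the shell or not).  ``r_min`` is the
    inclusion radius; the default 0 keeps every lipid out to the shell edge.
    """
    if shell_radius <= 0:
        raise ValueError("shell_radius must be positive")
    protein_resids = tuple(protein_resids) or (protein_resid,)
    center = _protein_center(frame, protein_resid)
    resids, _, xy = _lipid_heads(frame, head_beads, protein_resids)
    d = minimum_image(xy - center, frame.box)
    r = np.hypot(d[:, 0], d[:, 1])
    members = {int(rr) for rr, ri in zip(resids, r) if r_min < ri <= shell_radius}
    if shell_radius <= r_min:
        warnings.warn("shell_radius does not exceed the inclusion radius; shell is empty",
                      RuntimeWarning, stacklevel=2)
    return members


def first_shell_members_knn(frame: Frame, protein_resid: int, k: int,
                            head_beads=("PO4", "ROH"), protein_resids=()) -> set:
    """k-nearest-neighbour alternative shell, for sensitivity checks."""
    if k < 1:
        raise ValueError("k must be >= 1")
    protein_resids = tuple(protein_resids) or (protein_resid,)
    center = _protein_center(frame, protein_resid)
    resids, _, xy = _lipid_heads(frame, head_beads, protein_resids)
    d = minimum_image(xy - center, frame.box)
    r = np.hypot(d[:, 0], d[:, 1])
    order = np.argsort(r, kind="stable")[:k]
    return {int(rr) for rr in resids[order]}


def shell_fraction(traj: Trajectory, protein_resid: int, lipid_type: Optional[str] = None,
                   shell_radius: float = 17.0, r_min: float = 0.0) -> ShellComposition:
    """Time-averaged shell composition around one inclusion.

    The fraction of a type is the total number of its in-shell occurrences
    over all frames divided by the total shell occupancy; frames with empty
    shells are skipped and counted.
    """
    counts: dict = {}
    total = 0
    n_used = 0
    n_empty = 0
    head_beads = traj.lipid_head_beads
    for frame in traj.frames:
        members = first_shell_members(frame, protein_resid, shell_radius,
                                      head_beads=head_beads,
                                      protein_resids=traj.protein_resids, r_min=r_min)
        if not members:
            n_empty += 1
            continue
        n_used += 1
        resname_of = dict(zip(frame.resid.tolist(), frame.resname.tolist()))
        for m in members:
            t = resname_of[m]
            counts[t] = counts.get(t, 0) + 1
            total += 1
    if total == 0:
        raise ValueError("shell was empty in every frame")
    fractions = {t: c / total for t, c in counts.items()}
    comp = ShellComposition(fractions=fractions, shell_radius=shell_radius,
                            n_frames_used=n_used, n_frames_empty=n_empty,
                            mean_shell_size=total / n_used)
    return comp


def _per_frame_shell_counts(traj: Trajectory, protein_resid: int, lipid_type: str,
                            shell_radius: float, r_min: float) -> np.ndarray:
    """(n_frames, 2) array of (count of lipid_type in shell, shell size)."""
    out = []
    for frame in traj.frames:
        members = first_shell_members(frame, protein_resid, shell_radius,
                                      head_beads=traj.lipid_head_beads,
                                      protein_resids=traj.protein_resids, r_min=r_min)
        resname_of = dict(zip(frame.resid.tolist(), frame.resname.tolist()))
        k = sum(1 for m in members if resname_of[m] == lipid_type)
        out.append((k, len(members)))
    return np.array(out, dtype=float)


def shell_fraction_vs_temperature(trajs: Mapping, lipid_type: str, protein_resid: int,
                                  shell_radius: float = 17.0, r_min: float = 0.0,
                                  n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-temperature shell fraction of one lipid type with bootstrap CIs.

    ``trajs`` maps temperature (K or °C, caller's convention) to Trajectory.
    The CI is a percentile bootstrap over frames (1000 resamples, seeded);
    with lipid types frozen in time it reflects head-position noise only,
    not sorting variability between realisations.
    """
    temps = list(trajs.keys())
    if len(temps) != len(set(temps)):
        raise ValueError("duplicate temperature keys")
    if len(temps) < 2:
        raise ValueError("need at least two temperatures")
    rng = np.random.default_rng(seed)
    rows = []
    for T in sorted(temps):
        counts = _per_frame_shell_counts(trajs[T], protein_resid, lipid_type,
                                         shell_radius, r_min)
        nonempty = counts[counts[:, 1] > 0]
        if nonempty.shape[0] == 0:
            raise ValueError(f"shell empty in every frame at T={T}")
        frac = nonempty[:, 0].sum() / nonempty[:, 1].sum()
        nf = nonempty.shape[0]
        boots = np.empty(n_boot)
        for b in range(n_boot):
            pick = rng.integers(0, nf, size=nf)
            sub = nonempty[pick]
            boots[b] = sub[:, 0].sum() / sub[:, 1].sum()
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append({"temperature": T, "fraction": frac, "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)


def pair_distances(traj: Trajectory, protein_a: int, protein_b: int) -> np.ndarray:
    """Per-frame lateral minimum-image COM distance between two inclusions (Å)."""
    if traj.protein_resids:
        for p in (protein_a, protein_b):
            if p not in traj.protein_resids:
                raise ValueError(f"protein resid {p} absent from trajectory "
                                 f"(inclusions: {traj.protein_resids})")
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        ca = _protein_center(frame, protein_a)
        cb = _protein_center(frame, protein_b)
        d = minimum_image(cb - ca, frame.box)
        out[i] = np.hypot(d[0], d[1])
    return out


def pair_distance_distribution(traj: Trajectory, protein_a: int, protein_b: int,
                               bin_width: float = 5.0) -> DistanceDistribution:
    """Histogram of inclusion-pair COM distances, normalised to unit mass.

    Support runs to half the lateral box diagonal, the largest realisable
    minimum-image distance.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    box = traj.box
    r_max = np.hypot(box.Lx / 2.0, box.Ly / 2.0)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    dists = pair_distances(traj, protein_a, protein_b)
    hist, _ = np.histogram(dists, bins=edges)
    mass = hist / hist.sum()
    return DistanceDistribution(bin_edges=edges, mass=mass, n_samples=int(hist.sum()))
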