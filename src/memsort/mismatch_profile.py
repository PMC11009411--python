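"""Radial membrane-thickness profiling and hydrophobic-mismatch bookkeeping.

The central statistic: phosphate head-bead positions are binned by lateral
minimum-image distance from the protein centre (1 nm bins by default); per
bin, the mean upper-leaflet head z minus the mean lower-leaflet head z is
the local leaflet-to-leaflet thickness, averaged over frames.  Membrane
compression is the difference between the thickness read from the bin
containing 70 Å and the bin containing 10 Å; both published sign
conventions are provided:

* ``eq1``:   compression = Thickness(70 Å) - Thickness(10 Å)
* ``prose``: compression = Thickness(10 Å) - Thickness(70 Å)

Hydrophobic mismatch is membrane hydrophobic thickness minus protein
hydrophobic thickness (positive = membrane thicker than the protein span).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .traj_model import Box, Frame, Trajectory, assign_leaflets, lateral_com, minimum_image

__all__ = [
    "ThicknessProfile",
    "CompressionResult",
    "MismatchRecord",
    "InsufficientSamplingError",
    "radial_thickness_profile",
    "membrane_compression",
    "hydrophobic_mismatch",
    "compression_mismatch_table",
]


class InsufficientSamplingError(ValueError):
    """A required radial bin holds no samples."""


@dataclass
class ThicknessProfile:
    """Trajectory-averaged leaflet-to-leaflet thickness per radial bin (Å).

    ``mean_thickness`` is NaN in bins that were never occupied by both
    leaflets simultaneously; such bins are flagged, never interpolated.
    """

    bin_edges: np.ndarray
    mean_thickness: np.ndarray
    n_samples: np.ndarray        # head beads contributing, summed over frames
    n_frames_occupied: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def occupied(self) -> np.ndarray:
        return ~np.isnan(self.mean_thickness)

    def bin_index_for(self, x: float) -> int:
        """Index of the bin whose half-open interval [lo, hi) contains x."""
        idx = int(np.searchsorted(self.bin_edges, x, side="right")) - 1
        if idx < 0 or idx >= self.bin_edges.size - 1:
            raise ValueError(f"x = {x} Å is outside the profiled range")
        return idx

    def thickness_at(self, x: float) -> float:
        idx = self.bin_index_for(x)
        val = self.mean_thickness[idx]
        if np.isnan(val):
            raise InsufficientSamplingError(
                f"bin [{self.bin_edges[idx]:g}, {self.bin_edges[idx + 1]:g}) Å holds no samples")
        return float(val)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center": self.bin_centers,
            "mean_thickness": self.mean_thickness,
            "n": self.n_samples,
        })


@dataclass(frozen=True)
class CompressionResult:
    thickness_at_10: float
    thickness_at_70: float
    compression: float
    convention: str

    def to_dict(self) -> dict:
        return {"thickness_at_10": self.thickness_at_10,
                "thickness_at_70": self.thickness_at_70,
                "compression": self.compression,
                "convention": self.convention}


@dataclass(frozen=True)
class MismatchRecord:
    membrane_thickness: float
    protein_thickness: float
    mismatch: float


def _default_center(frame: Frame, protein_resid: int) -> np.ndarray:
    """Lateral COM of all protein beads (periodic-aware), recomputed per frame."""
    mask = frame.resid == protein_resid
    if not mask.any():
        raise ValueError(f"protein resid {protein_resid} absent from frame")
    return lateral_com(frame.xyz[mask, 0:2], frame.box)


def radial_thickness_profile(traj: Trajectory, protein_resid: int,
                             head_bead=None, bin_width: float = 10.0,
                             r_max: Optional[float] = None,
                             center_fn: Callable = _default_center) -> ThicknessProfile:
    """Radial leaflet-to-leaflet thickness profile around one inclusion.

    Per frame and per radial bin, thickness = mean upper-leaflet head z minus
    mean lower-leaflet head z; a bin contributes that frame only when both
    leaflets sample it.  Frames are weighted equally in the average.

    Parameters
    ----------
    head_bead : str or sequence of str, optional
        Head bead name(s); defaults to the trajectory's sidecar value.
    bin_width : float
        Radial bin width in Å (10 Å = the 1 nm convention).
    r_max : float, optional
        Outer edge of the last bin; defaults to half the larger lateral box
        dimension times sqrt(2) rounded down to a whole bin (the largest
        realisable minimum-image distance).
    center_fn : callable
        Hook mapping (frame, protein_resid) -> lateral centre; default is the
        per-frame lateral COM of all protein beads.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    heads = head_bead if head_bead is not None else traj.lipid_head_beads
    if isinstance(heads, str):
        heads = (heads,)
    if protein_resid not in traj.protein_resids and not (traj.frames[0].resid == protein_resid).any():
        raise ValueError(f"protein resid {protein_resid} not present in trajectory")
    box = traj.box
    if r_max is None:
        r_diag = np.hypot(box.Lx / 2.0, box.Ly / 2.0)
        r_max = np.floor(r_diag / bin_width) * bin_width
    if r_max < bin_width:
        raise ValueError("r_max must be at least one bin wide")
    edges = np.arange(0.0, r_max + bin_width / 2.0, bin_width)
    nbins = edges.size - 1

    sum_thick = np.zeros(nbins)
    n_frames_occ = np.zeros(nbins, dtype=int)
    n_samples = np.zeros(nbins, dtype=int)

    for frame in traj.frames:
        center = np.asarray(center_fn(frame, protein_resid), dtype=float)
        label = assign_leaflets(frame, heads)
        mask = np.isin(frame.bead_name, heads)
        resids = frame.resid[mask]
        xy = frame.xyz[mask, 0:2]
        z = frame.xyz[mask, 2]
        d = minimum_image(xy - center, box)
        r = np.hypot(d[:, 0], d[:, 1])
        bins = np.searchsorted(edges, r, side="right") - 1
        in_range = (bins >= 0) & (bins < nbins)
        upper = np.array([rr in label.upper for rr in resids])
        for b in range(nbins):
            sel = in_range & (bins == b)
            up = sel & upper
            lo = sel & ~upper
            if up.any() and lo.any():
                sum_thick[b] += z[up].mean() - z[lo].mean()
                n_frames_occ[b] += 1
                n_samples[b] += int(up.sum() + lo.sum())

    mean = np.full(nbins, np.nan)
    occ = n_frames_occ > 0
    mean[occ] = sum_thick[occ] / n_frames_occ[occ]
    return ThicknessProfile(bin_edges=edges, mean_thickness=mean,
                            n_samples=n_samples, n_frames_occupied=n_frames_occ)


def membrane_compression(profile: ThicknessProfile, convention: str = "eq1",
                         x_near: float = 10.0, x_far: float = 70.0) -> CompressionResult:
    """Compression between the bins containing ``x_far`` and ``x_near`` Å.

    ``eq1`` returns Thickness(x_far) - Thickness(x_near); ``prose`` the
    negation.  Raises :class:`InsufficientSamplingError` if either bin is
    unoccupied.
    """
    if convention not in ("eq1", "prose"):
        raise ValueError(f"convention must be 'eq1' or 'prose', got {convention!r}")
    t_near = profile.thickness_at(x_near)
    t_far = profile.thickness_at(x_far)
    comp = t_far - t_near
    if convention == "prose":
        comp = -comp
    return CompressionResult(thickness_at_10=t_near, thickness_at_70=t_far,
                             compression=comp, convention=convention)


def hydrophobic_mismatch(membrane_thickness: float, protein_thickness: float) -> MismatchRecord:
    """Membrane hydrophobic thickness minus protein hydrophobic thickness (Å)."""
    if membrane_thickness <= 0 or protein_thickness <= 0:
        raise ValueError("thicknesses must be positive")
    return MismatchRecord(membrane_thickness=float(membrane_thickness),
                          protein_thickness=float(protein_thickness),
                          mismatch=float(membrane_thickness - protein_thickness))


def compression_mismatch_table(profiles: Mapping, protein_thicknesses: Mapping,
                               convention: str = "eq1") -> tuple:
    """Join per-(protein, membrane) profiles into a (mismatch, compression) table.

    Parameters
    ----------
    profiles : mapping of (protein_key, membrane_key) -> ThicknessProfile
    protein_thicknesses : mapping of protein_key -> hydrophobic thickness (Å)

    Returns
    -------
    (DataFrame, float)
        Table with columns protein, membrane, membrane_thickness (far-field,
        read from the 70 Å bin), mismatch and compression, plus the Pearson r
        between mismatch and compression.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two (protein, membrane) entries")
    rows = []
    for key, prof in profiles.items():
        try:
            protein_key, membrane_key = key
        except (TypeError, ValueError):
            raise ValueError(f"profile key {key!r} is not a (protein, membrane) pair")
        if protein_key not in protein_thicknesses:
            raise KeyError(f"no protein thickness for key {protein_key!r}")
        comp = membrane_compression(prof, convention=convention)
        mem_th = comp.thickness_at_70
        mis = hydrophobic_mismatch(mem_th, protein_thicknesses[protein_key])
        rows.append({"protein": protein_key, "membrane": membrane_key,
                     "membrane_thickness": mem_th, "mismatch": mis.mismatch,
                     "compression": comp.compression})
    df = pd.DataFrame(rows)
    if df["mismatch"].nunique() < 2 or df["compression"].nunique() < 2:
        r = np.nan
    else:
        r = float(stats.pearsonr(df["mismatch"], df["compression"]).statistic)
    return df, r
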