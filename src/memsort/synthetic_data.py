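"""Seeded synthetic trajectories and assay fixtures with known ground truth.

The membrane generator emulates the phenomenology of a coarse-grained
bilayer hosting one or two transmembrane inclusions:

* the leaflet-to-leaflet thickness decays from a contact value at the
  protein surface to a far-field value with radial distance,
  ``h(r) = h_far + (h_contact - h_far) * exp(-(r - R_protein) / lambda_decay)``
  for ``r >= R_protein`` (and ``h_contact`` inside the inclusion footprint);
* lipid-type sorting around inclusions is radially biased: inside a first
  shell the "thin" lipid type is drawn with relative weight ``sort_weight``;
* inclusions perform a 2-D Gaussian random walk (variance ``2 * D_lat * dt``
  per axis), minimum-image wrapped, with hard-core rejection below a minimum
  separation.

Everything is reproducible from (parameters, seed), and the generator keeps
its own bookkeeping (leaflet tags, per-lipid types, shell membership,
inclusion tracks, the closed-form field) so analyses can be tested against
injected truth rather than a physical claim.

Assay fixtures produce plate-reader kinetics, calcein endpoint intensities,
flow-cytometry event tables, donor-quenching FRET pairs and split-luciferase
luminescence tables whose noiseless statistics equal the stated truths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .membrane_builder import MembraneRecipe
from .traj_model import Box, Frame, Trajectory, minimum_image

__all__ = [
    "GroundTruth",
    "AssayGroundTruth",
    "SimulationRecord",
    "AssayFixture",
    "CapacityError",
    "generate_membrane_trajectory",
    "generate_assay_fixture",
    "sort_weight_from_temperature",
]


class CapacityError(ValueError):
    """The requested recipe does not fit in the box at the configured area per lipid."""


@dataclass(frozen=True)
class GroundTruth:
    """Generator parameters; the recovery target for every trajectory analysis.

    Lengths in Å, diffusion in Å²/ns.  ``sort_weight`` is the relative
    sampling weight of the thin lipid type inside ``shell_radius`` of an
    inclusion (1 = no sorting).  ``sigma_z`` is Gaussian head-bead z noise;
    ``sigma_xy`` is per-frame lateral jitter of each lipid around its fixed
    grid site.  ``min_separation`` of ``None`` means the hard-core default
    ``2 * R_protein``; 0 disables pair exclusion entirely.
    """

    h_far: float = 29.0
    h_contact: float = 28.0
    lambda_decay: float = 15.0
    R_protein: float = 10.0
    sort_weight: float = 1.0
    shell_radius: float = 17.0
    D_lat: float = 1.0
    sigma_z: float = 1.0
    sigma_xy: float = 1.0
    min_separation: Optional[float] = None
    area_per_lipid: float = 65.0
    thin_lipid: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        if not (self.h_far > 0 and self.h_contact > 0):
            raise ValueError("thicknesses must be positive")
        if self.lambda_decay <= 0:
            raise ValueError("lambda_decay must be positive")
        if self.sort_weight <= 0:
            raise ValueError("sort_weight must be positive")

    def thickness_field(self, r) -> np.ndarray:
        """Closed-form leaflet-to-leaflet thickness at lateral distance r (Å)."""
        r = np.asarray(r, dtype=float)
        reff = np.maximum(r, self.R_protein)
        return self.h_far + (self.h_contact - self.h_far) * np.exp(
            -(reff - self.R_protein) / self.lambda_decay
        )


def sort_weight_from_temperature(T: float, w0: float = 6.0, T0: float = 290.0,
                                 T_scale: float = 15.0) -> float:
    """Synthetic temperature -> sort_weight map: sorting decays toward 1 as T rises.

    ``w(T) = 1 + (w0 - 1) * exp(-(T - T0) / T_scale)``.  This emulates shell
    composition relaxing toward the bulk membrane composition with heating;
    the mapping is explicitly synthetic, not a thermodynamic model.
    """
    return 1.0 + (w0 - 1.0) * float(np.exp(-(T - T0) / T_scale))


@dataclass
class SimulationRecord:
    """Generator bookkeeping returned alongside the trajectory."""

    truth: GroundTruth
    recipe: MembraneRecipe
    box: Box
    protein_resids: tuple
    protein_centers: np.ndarray  # (n_frames, n_proteins, 2) Å
    lipids: pd.DataFrame  # resid, leaflet, lipid_type, site_x, site_y, in_shell
    head_index: dict  # resid -> row index of the head bead within each frame

    def leaflet_of(self, resid: int) -> str:
        return self.lipids.set_index("resid").loc[resid, "leaflet"]

    def shell_resids(self) -> set:
        return set(self.lipids.loc[self.lipids["in_shell"], "resid"])


_HEAD_BEAD_FOR_TYPE = {"CHOL": "ROH"}
_PROTEIN_RING_BEADS = 12


def _protein_bead_offsets(R: float) -> np.ndarray:
    """Lateral offsets of one inclusion's beads: a centre bead plus a ring."""
    ang = 2.0 * np.pi * np.arange(_PROTEIN_RING_BEADS) / _PROTEIN_RING_BEADS
    ring = np.column_stack([R * np.cos(ang), R * np.sin(ang)])
    return np.vstack([[0.0, 0.0], ring])


def _assign_types(rng: np.random.Generator, recipe: MembraneRecipe, in_shell: np.ndarray,
                  thin_idx: int, sort_weight: float) -> np.ndarray:
    """Weighted sequential draw honouring recipe counts exactly.

    Sites are visited in random order; each draws a type with probability
    proportional to remaining count, the thin type up-weighted by
    ``sort_weight`` on in-shell sites.  For shells small relative to the
    leaflet the expected in-shell thin fraction is
    ``w f / (w f + (1 - f))`` with f the bulk thin fraction.
    """
    n = in_shell.size
    remaining = np.array(recipe.counts, dtype=float)
    out = np.empty(n, dtype=int)
    ntypes = len(recipe.counts)
    for i in rng.permutation(n):
        w = remaining.copy()
        if in_shell[i]:
            w[thin_idx] *= sort_weight
        p = w / w.sum()
        t = rng.choice(ntypes, p=p)
        out[i] = t
        remaining[t] -= 1.0
    return out


def generate_membrane_trajectory(recipe: MembraneRecipe, truth: GroundTruth,
                                 n_frames: int, box: Box, n_proteins: int = 1,
                                 dt_ns: float = 1.0, temperature_K: float = 295.0):
    """Generate a seeded bilayer trajectory with one or two inclusions.

    Returns ``(Trajectory, SimulationRecord)``; the record carries the
    injected :class:`GroundTruth` plus all generator bookkeeping.

    Raises
    ------
    CapacityError
        If the per-leaflet lipid count times ``area_per_lipid`` exceeds the
        lateral box area (minus the inclusion footprints).
    """
    if n_proteins not in (1, 2):
        raise ValueError("n_proteins must be 1 or 2")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(truth.seed)
    n_lip = recipe.n_per_leaflet
    area = box.Lx * box.Ly
    prot_area = n_proteins * np.pi * truth.R_protein ** 2
    if n_lip * truth.area_per_lipid > area - prot_area:
        raise CapacityError(
            f"{n_lip} lipids x {truth.area_per_lipid} A^2 do not fit a "
            f"{box.Lx:.0f} x {box.Ly:.0f} A box with {n_proteins} inclusion(s)"
        )

    min_sep = 2.0 * truth.R_protein if truth.min_separation is None else truth.min_separation

    # --- initial inclusion centres
    if n_proteins == 1:
        centers0 = np.array([[box.Lx / 2.0, box.Ly / 2.0]])
    else:
        centers0 = np.array([[box.Lx / 4.0, box.Ly / 2.0], [3.0 * box.Lx / 4.0, box.Ly / 2.0]])

    # --- inclusion random walk (shared by both leaflets; protein spans the bilayer)
    step_sd = np.sqrt(2.0 * truth.D_lat * dt_ns)
    centers = np.empty((n_frames, n_proteins, 2))
    centers[0] = centers0
    for f in range(1, n_frames):
        prev = centers[f - 1]
        for _ in range(1000):
            prop = (prev + rng.normal(0.0, step_sd, size=prev.shape)) % [box.Lx, box.Ly]
            if n_proteins == 1 or min_sep <= 0:
                break
            d = minimum_image(prop[0] - prop[1], box)
            if np.hypot(*d) >= min_sep:
                break
        else:  # pragma: no cover - pathological parameter choice
            prop = prev
        centers[f] = prop

    # --- lipid grid sites per leaflet, avoiding the frame-0 inclusion disks
    margin = 2.0
    sites = {}
    for leaflet in ("upper", "lower"):
        nx = int(np.ceil(np.sqrt(n_lip * box.Lx / box.Ly)))
        free = np.empty((0, 2))
        # refine the grid until enough sites clear the inclusion footprints
        for _ in range(8):
            ny = int(np.ceil(n_lip / nx))
            cx = (np.arange(nx) + 0.5) * box.Lx / nx
            cy = (np.arange(ny) + 0.5) * box.Ly / ny
            grid = np.array(np.meshgrid(cx, cy)).reshape(2, -1).T
            dmin = _dist_to_nearest(grid, centers0, box)
            free = grid[dmin > truth.R_protein + margin]
            if free.shape[0] >= n_lip:
                break
            nx += 1
        if free.shape[0] < n_lip:
            raise CapacityError("not enough grid sites clear of the inclusions")
        pick = rng.choice(free.shape[0], size=n_lip, replace=False)
        sites[leaflet] = free[pick]

    # --- frame-0 shell membership and lipid types (fixed for the whole run)
    thin = truth.thin_lipid or recipe.lipids[0]
    if thin not in recipe.lipids:
        raise ValueError(f"thin lipid {thin!r} not in recipe {recipe.lipids}")
    thin_idx = recipe.lipids.index(thin)
    lip_rows = []
    types = {}
    for leaflet in ("upper", "lower"):
        dmin = _dist_to_nearest(sites[leaflet], centers0, box)
        in_shell = (dmin > truth.R_protein) & (dmin <= truth.shell_radius)
        t = _assign_types(rng, recipe, in_shell, thin_idx, truth.sort_weight)
        types[leaflet] = t
        for i in range(n_lip):
            lip_rows.append({
                "leaflet": leaflet, "lipid_type": recipe.lipids[t[i]],
                "site_x": sites[leaflet][i, 0], "site_y": sites[leaflet][i, 1],
                "in_shell": bool(in_shell[i]),
            })

    # --- bead roster: proteins first, then upper leaflet, then lower
    offsets = _protein_bead_offsets(truth.R_protein)
    n_pb = offsets.shape[0]
    protein_resids = tuple(range(1, n_proteins + 1))
    bead_id, bead_name, resid, resname = [], [], [], []
    for p in range(n_proteins):
        for b in range(n_pb):
            bead_id.append(p * n_pb + b + 1)
            bead_name.append("BB")
            resid.append(protein_resids[p])
            resname.append("PROT")
    next_id = n_proteins * n_pb + 1
    next_resid = n_proteins + 1
    lipid_resid_order = []
    for k, row in enumerate(lip_rows):
        row["resid"] = next_resid
        lipid_resid_order.append(next_resid)
        bead_id.append(next_id)
        bead_name.append(_HEAD_BEAD_FOR_TYPE.get(row["lipid_type"], "PO4"))
        resid.append(next_resid)
        resname.append(row["lipid_type"])
        next_id += 1
        next_resid += 1
    bead_id = np.array(bead_id)
    bead_name = np.array(bead_name, dtype=object)
    resid_arr = np.array(resid)
    resname = np.array(resname, dtype=object)
    head_index = {row["resid"]: n_proteins * n_pb + k for k, row in enumerate(lip_rows)}

    site_xy = np.array([[r["site_x"], r["site_y"]] for r in lip_rows])
    leaf_sign = np.array([1.0 if r["leaflet"] == "upper" else -1.0 for r in lip_rows])

    # --- frames
    frames = []
    for f in range(n_frames):
        xyz = np.empty((bead_id.size, 3))
        # proteins: centre bead + ring at the bilayer midplane (z = 0)
        for p in range(n_proteins):
            rows = slice(p * n_pb, (p + 1) * n_pb)
            lateral = (centers[f, p] + offsets) % [box.Lx, box.Ly]
            xyz[rows, 0:2] = lateral
            xyz[rows, 2] = 0.0
        # lipids: jittered sites, pushed to the inclusion rim if they land inside.
        # Noise is always drawn and scaled so runs differing only in sigma_z /
        # sigma_xy share the remaining random stream (noiseless twins line up).
        jitter = rng.normal(0.0, 1.0, size=site_xy.shape) * truth.sigma_xy
        pos = (site_xy + jitter) % [box.Lx, box.Ly]
        pos = _push_out_of_disks(pos, centers[f], truth.R_protein, box)
        r = _dist_to_nearest(pos, centers[f], box)
        h = truth.thickness_field(r)
        z = leaf_sign * h / 2.0 + rng.normal(0.0, 1.0, size=leaf_sign.shape) * truth.sigma_z
        lip_rows_slice = slice(n_proteins * n_pb, None)
        xyz[lip_rows_slice, 0:2] = pos
        xyz[lip_rows_slice, 2] = z
        frames.append(Frame(f * dt_ns, box, bead_id, bead_name, resid_arr, resname, xyz))

    head_beads = tuple(sorted({_HEAD_BEAD_FOR_TYPE.get(t, "PO4") for t in recipe.lipids}))
    traj = Trajectory(frames=frames, temperature_K=temperature_K,
                      protein_resids=protein_resids, lipid_head_beads=head_beads,
                      composition=recipe)
    record = SimulationRecord(
        truth=truth, recipe=recipe, box=box, protein_resids=protein_resids,
        protein_centers=centers, lipids=pd.DataFrame(lip_rows), head_index=head_index,
    )
    return traj, record


def _dist_to_nearest(points: np.ndarray, centers: np.ndarray, box: Box) -> np.ndarray:
    """Minimum-image lateral distance of each point to its nearest centre."""
    points = np.atleast_2d(points)
    d = points[:, None, :] - centers[None, :, :]
    d = minimum_image(d, box)
    return np.sqrt((d ** 2).sum(axis=-1)).min(axis=1)


def _push_out_of_disks(pos: np.ndarray, centers: np.ndarray, R: float, box: Box,
                       rim: float = 0.5) -> np.ndarray:
    """Move any point inside an inclusion disk radially to just outside its rim."""
    pos = pos.copy()
    for c in centers:
        d = minimum_image(pos - c, box)
        r = np.hypot(d[:, 0], d[:, 1])
        inside = r < R
        if inside.any():
            safe_r = np.where(r[inside] > 1e-9, r[inside], 1e-9)
            scale = (R + rim) / safe_r
            pos[inside] = (c + d[inside] * scale[:, None]) % [box.Lx, box.Ly]
    return pos


# ---------------------------------------------------------------------------
# assay fixtures

@dataclass(frozen=True)
class AssayGroundTruth:
    """True assay quantities plus noise scales; the recovery target for Eqs. 2-6 analogues."""

    # calcein leakage
    release_fraction: float = 0.5
    calcein_baseline: float = 100.0
    calcein_span: float = 300.0
    calcein_noise_cv: float = 0.02
    # flow cytometry (MFI-ratio sorting between thick/thin vesicles)
    mfi_rhodamine_thick: float = 300.0
    mfi_cy55_thin: float = 500.0
    flow_cv: float = 0.35
    n_events: int = 100_000
    dim_channel_mfi: float = 20.0
    # biocytin delivery (percent-positive enrichment)
    pos_frac_thick: float = 0.30
    pos_frac_thin: float = 0.10
    background_pos_frac: float = 0.02
    af488_mfi_positive: float = 1000.0
    af488_mfi_negative: float = 50.0
    # FRET temperature ramp (donor quenching ratios per condition)
    fret_temperatures: tuple = (20.0, 25.0, 30.0, 35.0, 40.0, 45.0)
    cdch_start: float = 1.3    # C_D/C_H at the first temperature
    cdch_end: float = 1.0      # ... and at the last; linear in between
    ff0_homogeneous: float = 0.8
    fret_f0: float = 1000.0
    fret_noise_cv: float = 0.0
    # split-luciferase
    rapamycin_ratio: float = 2.0
    lum_minus_rap: float = 250.0
    nanobit_temperatures: tuple = (22.0, 30.0, 38.0, 45.0)
    relative_assembly_start: float = 1.0
    relative_assembly_end: float = 1.5
    lum_homo_20: float = 100.0
    lum_homo_50: float = 300.0
    lum_noise_cv: float = 0.0
    # GFP folding kinetics: (construct, membrane) -> true 0->3 h increase
    gfp_deltas: tuple = (
        ("P20", "thin", 250.0), ("P20", "thick", 80.0),
        ("P50", "thin", 60.0), ("P50", "thick", 300.0),
    )
    gfp_baseline: float = 100.0
    gfp_noise_sd: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        for name, v in (("release_fraction", self.release_fraction),
                        ("pos_frac_thick", self.pos_frac_thick),
                        ("pos_frac_thin", self.pos_frac_thin),
                        ("background_pos_frac", self.background_pos_frac)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_events < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")

    def cdch_curve(self) -> dict:
        T = np.asarray(self.fret_temperatures, dtype=float)
        vals = np.interp(T, [T[0], T[-1]], [self.cdch_start, self.cdch_end])
        return dict(zip(T.tolist(), vals.tolist()))

    def relative_assembly_curve(self) -> dict:
        T = np.asarray(self.nanobit_temperatures, dtype=float)
        vals = np.interp(T, [T[0], T[-1]],
                         [self.relative_assembly_start, self.relative_assembly_end])
        return dict(zip(T.tolist(), vals.tolist()))


@dataclass
class AssayFixture:
    kind: str
    tables: dict          # name -> DataFrame, in the assay CSV dialects
    truth: AssayGroundTruth

    def write(self, outdir) -> None:
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False, lineterminator="\n")
        truth = {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in self.truth.__dict__.items()}
        with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump({"kind": self.kind, "truth": truth}, fh, indent=1)
            fh.write("\n")


ASSAY_KINDS = ("gfp_kinetics", "calcein", "flow_enrichment", "biocytin_flow",
               "fret_ramp", "nanobit_ramp")


def _lognormal(rng, mean, cv, size):
    """Log-normal draws with the requested arithmetic mean and CV."""
    if cv <= 0:
        return np.full(size, float(mean))
    s2 = np.log1p(cv ** 2)
    mu = np.log(mean) - s2 / 2.0
    return rng.lognormal(mu, np.sqrt(s2), size=size)


def generate_assay_fixture(kind: str, truth: AssayGroundTruth) -> AssayFixture:
    """Build one synthetic assay table set whose noiseless statistics equal the truth."""
    rng = np.random.default_rng(truth.seed)
    if kind == "gfp_kinetics":
        tables = {"kinetics": _gen_gfp(rng, truth)}
    elif kind == "calcein":
        tables = {"calcein": _gen_calcein(rng, truth)}
    elif kind == "flow_enrichment":
        tables = {"events": _gen_flow(rng, truth, with_af488=False)}
    elif kind == "biocytin_flow":
        tables = {
            "events": _gen_flow(rng, truth, with_af488=True),
            "background": _gen_flow(rng, truth, with_af488=True, background=True),
        }
    elif kind == "fret_ramp":
        tables = {"fret": _gen_fret(rng, truth)}
    elif kind == "nanobit_ramp":
        tables = {"luminescence": _gen_nanobit(rng, truth)}
    else:
        raise ValueError(f"unknown assay kind {kind!r}; expected one of {ASSAY_KINDS}")
    return AssayFixture(kind=kind, tables=tables, truth=truth)


def _gen_gfp(rng, truth: AssayGroundTruth) -> pd.DataFrame:
    times = np.arange(0.0, 3.0 + 1e-9, 0.25)
    tau = 1.0
    shape = (1.0 - np.exp(-times / tau)) / (1.0 - np.exp(-3.0 / tau))  # 0 at t=0, 1 at t=3
    rows = []
    well = 0
    for construct, membrane, delta in truth.gfp_deltas:
        for rep in range(truth.n_replicates):
            sig = truth.gfp_baseline + delta * shape
            if truth.gfp_noise_sd > 0:
                noise = rng.normal(0.0, truth.gfp_noise_sd, size=times.size)
                noise[0] = 0.0
                noise[-1] = 0.0
                sig = sig + noise
            for t, s in zip(times, sig):
                rows.append({"well": f"W{well:03d}", "construct": construct,
                             "membrane": membrane, "time_h": t, "signal": s})
            well += 1
    return pd.DataFrame(rows)


def _gen_calcein(rng, truth: AssayGroundTruth) -> pd.DataFrame:
    rows = []
    for rep in range(truth.n_replicates):
        noise = _lognormal(rng, 1.0, truth.calcein_noise_cv, 3)
        i0 = truth.calcein_baseline * noise[0]
        itr = i0 + truth.calcein_span * noise[1]
        # Invert the release equation so the noiseless statistic is exact.
        i3 = i0 + truth.release_fraction * (itr - i0)
        rows.append({"sample": f"S{rep}", "I_t0": i0, "I_t3": i3, "I_triton": itr,
                     "band_intensity": 1.0})
    return pd.DataFrame(rows)


def _gen_flow(rng, truth: AssayGroundTruth, with_af488: bool, background: bool = False) -> pd.DataFrame:
    n = truth.n_events
    n_thick = n // 2
    n_thin = n - n_thick
    rhod = np.concatenate([
        _lognormal(rng, truth.mfi_rhodamine_thick, truth.flow_cv, n_thick),
        _lognormal(rng, truth.dim_channel_mfi, truth.flow_cv, n_thin),
    ])
    cy55 = np.concatenate([
        _lognormal(rng, truth.dim_channel_mfi, truth.flow_cv, n_thick),
        _lognormal(rng, truth.mfi_cy55_thin, truth.flow_cv, n_thin),
    ])
    df = pd.DataFrame({"event_id": np.arange(n), "rhodamine": rhod, "cy55": cy55})
    df["true_population"] = np.array(["thick"] * n_thick + ["thin"] * n_thin, dtype=object)
    if with_af488:
        p_thick = truth.background_pos_frac if background else min(
            1.0, truth.pos_frac_thick + truth.background_pos_frac)
        p_thin = truth.background_pos_frac if background else min(
            1.0, truth.pos_frac_thin + truth.background_pos_frac)
        pos = np.concatenate([
            rng.random(n_thick) < p_thick,
            rng.random(n_thin) < p_thin,
        ])
        af = np.where(pos,
                      _lognormal(rng, truth.af488_mfi_positive, truth.flow_cv, n),
                      _lognormal(rng, truth.af488_mfi_negative, truth.flow_cv, n))
        df["af488"] = af
        df["true_af488_positive"] = pos
    return df


def _gen_fret(rng, truth: AssayGroundTruth) -> pd.DataFrame:
    rows = []
    curve = truth.cdch_curve()
    for T, cdch in curve.items():
        ff0_h = truth.ff0_homogeneous
        ff0_d = float(np.exp(cdch * np.log(ff0_h)))  # so ln(F/F0)_D / ln(F/F0)_H == cdch
        for cond, ff0 in (("D", ff0_d), ("H", ff0_h)):
            for rep in range(truth.n_replicates):
                f0 = truth.fret_f0 * _lognormal(rng, 1.0, truth.fret_noise_cv, 1)[0]
                f = f0 * ff0 * _lognormal(rng, 1.0, truth.fret_noise_cv, 1)[0]
                rows.append({"condition": cond, "temperature_C": T, "F": f, "F_o": f0,
                             "replicate": rep})
    return pd.DataFrame(rows)


def _gen_nanobit(rng, truth: AssayGroundTruth) -> pd.DataFrame:
    rows = []
    curve = truth.relative_assembly_curve()
    room_T = truth.nanobit_temperatures[0]
    for T, rel in curve.items():
        homo20 = truth.lum_homo_20
        homo50 = truth.lum_homo_50
        hetero = rel * 0.5 * (homo20 + homo50)
        for pairing, lum in (("20-50", hetero), ("20-20", homo20), ("50-50", homo50)):
            for rep in range(truth.n_replicates):
                noisy = lum * _lognormal(rng, 1.0, truth.lum_noise_cv, 1)[0]
                rows.append({"pairing": pairing, "condition": "ramp",
                             "temperature_C": T, "lum": noisy, "replicate": rep})
    # rapamycin induction measured at room temperature on the hetero pair
    base = truth.lum_minus_rap
    for rep in range(truth.n_replicates):
        minus = base * _lognormal(rng, 1.0, truth.lum_noise_cv, 1)[0]
        plus = truth.rapamycin_ratio * base * _lognormal(rng, 1.0, truth.lum_noise_cv, 1)[0]
        rows.append({"pairing": "20-50", "condition": "minus_rap",
                     "temperature_C": room_T, "lum": minus, "replicate": rep})
        rows.append({"pairing": "20-50", "condition": "plus_rap",
                     "temperature_C": room_T, "lum": plus, "replicate": rep})
    return pd.DataFrame(rows)
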