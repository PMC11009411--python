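"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: minimum-image distances
are found by brute force over the 9 lateral periodic images, leaflet sides
come from the generator's own bookkeeping, and the thickness oracle
evaluates the injected closed-form field directly at the sampled head
positions.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_min_image(a, b, Lx, Ly):
    """Lateral displacement a -> b minimised over the 9 periodic images."""
    best = None
    for ix, iy in itertools.product((-1, 0, 1), repeat=2):
        dx = b[0] + ix * Lx - a[0]
        dy = b[1] + iy * Ly - a[1]
        if best is None or dx * dx + dy * dy < best[0]:
            best = (dx * dx + dy * dy, dx, dy)
    return best[1], best[2]


def _min_image_r(xy, center, Lx, Ly):
    d = xy - center
    d[:, 0] -= Lx * np.round(d[:, 0] / Lx)
    d[:, 1] -= Ly * np.round(d[:, 1] / Ly)
    return np.hypot(d[:, 0], d[:, 1])


def field_profile_oracle(traj, record, bin_edges):
    """Closed-form-field thickness profile at the trajectory's sampled radii.

    For each frame and radial bin, averages h(r)/2 over the upper-leaflet
    heads in the bin plus h(r)/2 over the lower-leaflet heads (leaflet sides
    taken from generator bookkeeping, not from the analysis code), then
    averages over frames.  With sigma_z = 0 the measured profile must equal
    this to float precision.
    """
    truth = record.truth
    box = traj.box
    edges = np.asarray(bin_edges)
    nb = edges.size - 1
    leaf = dict(zip(record.lipids["resid"], record.lipids["leaflet"]))
    acc = np.zeros(nb)
    cnt = np.zeros(nb)
    head_rows = np.array(sorted(record.head_index.values()))
    resids = traj.frames[0].resid[head_rows]
    upper = np.array([leaf[int(r)] == "upper" for r in resids])
    for f, frame in enumerate(traj.frames):
        center = record.protein_centers[f, 0]
        xy = frame.xyz[head_rows, 0:2].copy()
        r = _min_image_r(xy, center, box.Lx, box.Ly)
        h = truth.thickness_field(r)
        b = np.searchsorted(edges, r, side="right") - 1
        for k in range(nb):
            sel = b == k
            up, lo = sel & upper, sel & ~upper
            if up.any() and lo.any():
                acc[k] += h[up].mean() / 2.0 + h[lo].mean() / 2.0
                cnt[k] += 1
    out = np.full(nb, np.nan)
    occ = cnt > 0
    out[occ] = acc[occ] / cnt[occ]
    return out


def uniform_pair_distances(n, Lx, Ly, seed):
    """Brute-force Monte-Carlo of the min-image distance of two uniform points."""
    rng = np.random.default_rng(seed)
    a = rng.random((n, 2)) * [Lx, Ly]
    b = rng.random((n, 2)) * [Lx, Ly]
    d = a - b
    d[:, 0] -= Lx * np.round(d[:, 0] / Lx)
    d[:, 1] -= Ly * np.round(d[:, 1] / Ly)
    return np.hypot(d[:, 0], d[:, 1])


def shell_fraction_expectation(sort_weight, bulk_fraction):
    """Closed-form expected in-shell thin-lipid fraction under weighted sampling."""
    wf = sort_weight * bulk_fraction
    return wf / (wf + (1.0 - bulk_fraction))
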