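# Methods

## Scope and units

`memsort` analyses coarse-grained bilayer trajectories (typed beads in an
orthorhombic, laterally periodic box) and liposome/cell-free assay tables.
Internal units are Å (length), ns (time) and K (temperature); the GRO-series
reader converts nm → Å on read. The z axis is the bilayer normal and is
never wrapped — trajectories are assumed pre-imaged in z, because leaflet
assignment and thickness are meaningless across a z-wrap.

## Thickness profile and compression

Leaflets are assigned per frame from head-bead z relative to the
instantaneous midplane (the mean head-bead z). A fitted surface is not
used: the bilayers in scope are planar, and a per-frame scalar midplane
matches the per-leaflet binning the profile uses. If all heads are exactly
coplanar (a degenerate fixture) every lipid is assigned to the upper
leaflet and a warning is emitted, rather than failing, so property tests
run on pathological inputs.

The radial profile bins head beads by lateral minimum-image distance to
the protein centre. The protein centre is the lateral centre of mass of
all protein beads, recomputed per frame with a circular mean per axis
(so inclusions straddling a periodic boundary keep a sensible centre);
the definition is exposed as a `center_fn` hook. Per frame and bin,
thickness = mean upper head z − mean lower head z, and a bin contributes
only in frames where both leaflets sample it. Frames are weighted equally;
bins empty in a frame contribute nothing, and never-occupied bins are NaN
and flagged, never interpolated.

"Thickness at x Å" is the mean of the bin whose half-open interval
contains x — with the default 10 Å (1 nm) bins, x = 10 falls in [10, 20)
and x = 70 in [70, 80). No interpolation is done: interpolating would
invent data between bin centres. Compression is reported under two
labelled sign conventions, `eq1` (T₇₀ − T₁₀, the default) and `prose`
(T₁₀ − T₇₀); the magnitudes are identical and both appear in the result
object, because both conventions are in circulation for this statistic.

A consequence worth stating: the binned estimator recovers the
*bin-averaged* deformation field, not its point values. For a field that
drops from 29 Å to 20 Å with a 20 Å decay length around a 10 Å inclusion,
the [10, 20) bin averages ≈ 22 Å even though the field is exactly 20 Å at
r = 10. All recovery tests therefore compare the estimator against the
closed-form field processed identically (evaluated at the sampled head
radii and binned the same way), which is the quantity the estimator is
defined to measure.

## First shell and pair distances

The first shell is the annulus (R_protein, R_protein + 7 Å] around the
protein's lateral COM — 7 Å being one coarse-grained lipid diameter — with
the cutoff configurable and a k-nearest-neighbour alternative provided for
sensitivity checks, since no canonical cutoff exists. A lipid's position is
its head bead (PO4; ROH for cholesterol); membership is binary. Shell
fractions are ratios of summed counts over frames (frames with empty
shells are skipped and counted), and the per-temperature CIs are a
percentile bootstrap over frames (1000 resamples, seeded). Because the
synthetic generator freezes lipid types at frame 0, frame-bootstrap CIs on
generator data reflect head-position noise only, not sorting variability;
tests that check sorting recovery therefore average over independent
generator seeds and use a one-shot multinomial standard error
`sqrt(p(1−p)/n_shell)` rather than the bootstrap.

Inclusion-pair distances are per-frame lateral minimum-image COM
distances, histogrammed and normalised to unit mass; the support ends at
half the lateral box diagonal, the largest realisable minimum-image
distance.

## Membrane recipes

Mole fractions are turned into integer per-leaflet counts by
largest-remainder (Hamilton) apportionment with ties to the first-listed
lipid. Hamilton is the standard minimal-|error| rule and maps
42/28/30 mol% at 329 lipids per leaflet to 138/92/99; the per-type error
is bounded by one lipid (|count/N − f| ≤ 1/N), which is property-tested.

## Assay statistics

The assay formulas are implemented exactly as defined in the README, with
these numerical choices:

- endpoint matching (t = 0 and 3 h for kinetics, 20 and 45 °C for FRET
  ramps) uses the nearest sample within a stated tolerance (5 min / 2 °C)
  rather than interpolation;
- flow gating is rectangular thresholding on the rhodamine and Cy5.5
  channels into single-dye populations ("curly" quadrant boundaries that
  bend to absorb photon-counting error at high laser gain are not
  reproducible from a formula; explicit rectangular thresholds are
  deterministic and sufficient for synthetic fixtures, and the deviation
  is surfaced here);
- MFI is the arithmetic mean of channel intensities in a gated population
  (geometric mean by flag); background statistics from a protein-free
  sample are subtracted and floored at zero, with a flag when flooring
  occurred;
- the expression-vs-compression relation is an ordinary least-squares fit
  (slope, intercept, Pearson r, R²).

## The synthetic generator

The generator emulates the phenomenology the analyses target, not the
physics that produces it:

- **Thickness field.** Leaflet head height is ±h(r)/2 with
  `h(r) = h_far + (h_contact − h_far)·exp(−(r − R_protein)/λ)` for
  r ≥ R_protein (h_contact inside the footprint), plus Gaussian z-noise
  σ_z. Exponential decay is the simplest monotone radial relaxation
  consistent with elastic deformation around an inclusion; the generator
  records the field so analyses are tested against injected truth, not a
  physical claim.
- **Placement.** Per leaflet, lipids occupy distinct grid sites chosen
  clear of the inclusion footprints, with per-frame Gaussian lateral
  jitter (σ_xy, default 1 Å) around the site; a jittered position landing
  inside an inclusion is pushed to its rim. Composition counts equal the
  recipe exactly in every frame.
- **Sorting.** Lipid types are assigned once at frame 0 by a sequential
  weighted draw that honours the recipe counts exactly: sites inside
  `shell_radius` of an inclusion up-weight the thin lipid type by
  `sort_weight`. For shells small against the leaflet the expected
  in-shell thin fraction is `w·f/(w·f + 1 − f)` (f = bulk thin fraction),
  which is the closed form the recovery tests use. Types do not exchange
  between frames, so time-averaging averages noise, not sorting dynamics —
  this keeps the estimator's expectation analytically computable.
  Temperature enters only through a synthetic map
  `w(T) = 1 + (w₀ − 1)·exp(−(T − T₀)/T_s)` that relaxes sorting toward the
  bulk composition on heating.
- **Inclusions.** One or two bead-ring inclusions (radius R_protein)
  perform a 2-D Gaussian random walk (per-axis step variance 2·D_lat·Δt,
  minimum-image wrapped) with hard-core rejection below `min_separation`
  (default 2·R_protein; 0 disables the core, giving the free-diffusion
  limit whose long-run pair-distance distribution matches two uniform
  points in the box). There is no attractive interaction; the "segregated"
  two-protein scenario is emulated by raising `min_separation`.
- Everything is reproducible from (parameters, seed), and noise draws are
  always consumed and scaled, so runs differing only in σ_z or σ_xy share
  the rest of the random stream (noiseless twins line up sample for
  sample).

What the generator does **not** emulate: force fields, lipid exchange and
flip-flop, curvature, membrane undulations, protein tilt, or thermodynamic
realism of any kind. Passing recovery tests therefore demonstrates that
the estimators measure what they claim on data with known truth — not that
real membranes behave like the generator.

Assay fixtures are built by inverting each statistic: noiseless tables
reproduce the injected truths exactly (e.g. the calcein table is
constructed so the release equation returns the injected fraction), and
noisy tables use log-normal intensities with configurable CV, a background
population with its own MFI for the subtraction path, and per-population
positive fractions for the gating path.

## Default parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `h_far`, `h_contact` | 29, 28 Å | far-field / contact leaflet-to-leaflet thickness |
| `lambda_decay` | 15 Å | radial decay length of the deformation |
| `R_protein` | 10 Å | inclusion radius (bead-ring radius) |
| `shell_radius` | 17 Å | first-shell cutoff = R_protein + one lipid diameter |
| `sort_weight` | 1 | thin-lipid weight inside the shell (1 = no sorting) |
| `D_lat` | 1 Å²/ns | inclusion lateral diffusion coefficient |
| `sigma_z`, `sigma_xy` | 1, 1 Å | head-bead z-noise / lateral jitter |
| `area_per_lipid` | 65 Å² | capacity check for recipe-in-box |
| bin width | 10 Å | radial profile binning (1 nm convention) |

## Problem sizes used in tests and the acceptance script

Recovery runs use 216 single-type lipids per leaflet in a 120 × 120 Å box
(200 frames for noisy compression recovery, 20 for the exact noiseless
check) and the 138/92/99 ternary leaflet in a 160 × 160 Å box for shell
statistics; sorting statistics average 24–60 independent single-frame
realisations because types are frozen per run. The free-diffusion KS check
uses 2001 frames strided by 10 (D_lat = 500 Å²/ns, so consecutive kept
samples decorrelate) against 10⁵ uniform pairs. Flow fixtures use 10⁵
events. These sizes give standard errors comfortably inside the 3·SE
acceptance bands while keeping the whole suite in seconds.

## Known limitations

- The thickness estimator reports bin averages; comparing it to point
  values of a steep field is a category error (see above).
- Shell statistics on generator data with lateral jitter carry a small
  dilution toward the bulk composition from boundary churn (lipids
  assigned just outside the shell jittering in); jitter-free fixtures are
  used where the closed-form comparison needs to be sharp.
- The membrane area–matching rule between different lipid systems (e.g.
  326 vs 329 lipids per leaflet) is not modelled; recipes are taken as
  given.
- Flow gating is rectangular; spectral compensation and densitometry are
  out of scope.
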