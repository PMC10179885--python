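# Methods

This note documents the models behind `argentms`: what is simulated, how
annotation inverts it, which parameters matter, and what the defaults do
and do not claim about real chromatograms.

## Species model and mass arithmetic

A hydrocarbon is identified by carbon number CN and double-bond count DB,
with formula CnH(2n+2−2d); geometry (cis/trans per bond) and double-bond
positions are labels only and never affect mass.  Two mass scales are
carried:

* **nominal** (C=12, H=1) — the scale on which unit-resolution ion traps
  report and on which reference m/z values are printed (e.g. [M+H]+ of
  C39:2 at 545);
* **monoisotopic** (C=12, H=1.00783) — the scale on which centroids are
  simulated and matched.

Spectral matching is done on the monoisotopic scale with a ±0.3 Da
window.  Matching on the nominal scale, although superficially closer to
a unit-resolution instrument's display, would be wrong for long chains:
the accumulated hydrogen mass defect puts C63H127+ at m/z 884.0 while its
nominal value is 883, i.e. real centroids drift up to ~1 Da away from
their nominal positions across the C25–C63 range.

Electron mass is neglected throughout (±0.0005 Da, far below the matching
window).  Adduct offsets are kept unrounded so that mass additivity and
the alkane/alkene ion degeneracy ([M−H]+ of CN:0 ≡ [M+H]+ of CN:1, the
ion CnH2n+1+) hold exactly on both scales.

Isotope envelopes are exact binomial convolutions over ¹³C (0.0107) and
²H (0.000115), with peaks placed at multiples of 1.00336 Da (the ²H
spacing difference of 0.0029 Da is ignored — two orders of magnitude
below the matching window).

## Retention model

Argentation chromatography is modeled as

    Rt = apex(system, T, DB)
       + cn_slope[DB] · (CN − ref_cn[DB])
       + (isomer_index − isomer_anchor) · isomer_spacing
       − trans_offset[DB]  (all-trans species)

* `apex` — measured apex time of the most abundant peak per class; the
  packaged calibration covers three solvent systems (hexane- and
  isooctane-based with acetonitrile/2-propanol, and hexane/toluene) at
  15/25/35 °C.  The default condition is hexane/toluene at 15 °C with a
  0.5 %/min toluene ramp (apexes 6.5 / 22.9 / 74.1 / 130.1 min for 0–3
  double bonds), the condition under which class separation is best.
* `cn_slope` < 0 (−0.005 / −0.08 / −0.15 / −0.30 min/CN for DB 0–3):
  heavier chains elute slightly earlier within a class (residual
  normal-phase behaviour).  The saturated slope reproduces a saturated
  cluster only a few seconds wide; the unsaturated slopes reproduce the
  printed within-class Rt spans of the packaged profiles.
* `ref_cn` = {0: 30, 1: 39, 2: 41, 3: 43} pins each class apex to its
  dominant species so fixture-derived compositions apex at the calibrated
  times.
* `isomer_spacing` (0.4 min): species sharing CN:DB but chromatographically
  resolved are treated as positional-isomer sub-peaks at this spacing,
  centered so the most abundant isomer sits at the family's base Rt.
  Isomer identity is an elution-order index; no locants are assigned.
* `trans_offset` per class (3 / 12 / 16 min for 1–3 double bonds):
  all-trans species elute ahead of their cis counterparts because their
  Ag+ complexes are weaker.  The per-class values are chosen once so the
  trans cluster clears the cis cluster's carbon-number spread, matching
  the qualitative trans/cis cluster separation seen with synthetic
  standards.  A single scalar offset cannot do this: the monoene cis
  cluster alone spans ~1.6 min in CN.
* `peak_sigma` per class (0.02 / 0.08 / 0.20 / 0.35 min): Gaussian peak
  widths, from the seconds-wide saturated cluster to broadened
  late-eluting trienes under the shallow gradient.

Reference tables measured under different gradient slopes disagree on
absolute within-class times (e.g. monoene apex 22.9 min in the
calibration table vs 30.3–31.9 min in the fly profile).  The model
resolves this by regenerating all retention times from the calibrated
apexes, using printed profile Rt only for isomer elution *order*.

Run-to-run retention variability is a per-species multiplicative jitter
(default sd 0.5 %, inside reported same-day reproducibility).

One calibration row (hexane/acetonitrile system at 15 °C) has equal
di- and tri-unsaturated apex times; class windows cannot be built for
that condition and `calibrate_class_windows` rejects it.

## APCI response model

Per scan, a species' ion current splits over adducts according to the
local mobile phase.  For hexane/toluene the fractions are piecewise
linear in %toluene, honouring the qualitative behaviour of hydrocarbon
APCI spectra: in pure hexane [M+C3H3]+ dominates; [M+H]+ rises to a
plateau at 40–60 % toluene and declines beyond; DB ≥ 2 species gain
[M]+• and [M+C7H9]+ at high toluene; saturated chains are always
dominated by [M−H]+.  For the two weakly modified systems the fractions
are fixed per class ([M+C4H9]+ dominating in the isooctane system,
[M+C3H3]+/[M+C6H13]+ in the hexane one).  The knot values themselves are
free configuration; no validation target depends on them.

Relative response factors are 1 : 3 : 5 : 7 for 0–3 double bonds — the
direction (response grows with unsaturation) is established, the
magnitudes are a documented package default.  A fragment floor emits 8 %
of the base channel as low-mass alkyl fragments below m/z 350.  Noise is
multiplicative log-normal per centroid (default sd 5 %) plus a sparse
Poisson baseline (~2 random centroids per scan, exponential intensities);
`noise_sd = 0` yields a noiseless, baseline-free run.  Intensity units
are arbitrary — the instrument's absolute sensitivity is not modeled —
so only ratios of areas are meaningful.

A species' total assigned-channel area is abundance × class share ×
response factor.  Because printed class shares are themselves
area-derived, simulated *measured* class shares differ from the printed
ones by the response factors; within-class relative areas, the quantity
the method actually reports, are unaffected.

The simulator reproduces one instructive real-world artifact: the M+2
isotopologue of [M+C3H3]+ of species CN falls within ~0.01 Da of [M−H]+
of species CN+3, and several adducts are literally the same ion formula
across species (e.g. [M+C4H9]+ of CN:0 ≡ [M+H]+ of (CN+4):0).

## Annotation pipeline

1. **Class windows** — centered on the configured class apexes with
   boundaries at midpoints between adjacent apexes (first window starts
   at 0, last ends at the run end).  The window, not the mass, fixes DB:
   this is what breaks the alkane/alkene degeneracy, so a
   saturated-window peak is never called DB = 1.
2. **EICs** — per candidate (CN, DB), the summed trace of all centroids
   within ±0.3 Da of the [M−H]+, [M]+•, [M+H]+ targets *and their first
   two isotopologue positions* (overlapping windows merged).  Extending
   to the full envelope keeps the captured share independent of CN; with
   monoisotopic-only windows the captured share would fall from ~0.75 at
   C25 to ~0.53 at C63 and skew within-class areas toward short chains.
3. **Peak detection** — local maxima above 1 % of the window maximum on
   a Gaussian-smoothed trace (kernel = half the class peak sigma;
   multiplicative noise otherwise fragments one peak into many maxima),
   boundaries at flanking minima taken closest to the peak, a
   3-scans-above-half-height width requirement, and a raw-trace support
   requirement that removes isolated baseline spikes.  Areas are always
   trapezoidal integrals of the *raw* trace over the detected bounds.
4. **Assignment** — DB from the window; CN from reverse lookup on the
   averaged-spectrum ions within the EIC's own targets (so co-eluting
   species cannot hijack a call).  A call must show at least two of the
   three quantification channels; single-channel matches are rejected as
   isotope interference (this is exactly what defuses the +39/M+2 →
   [M−H]+ collision described above, which otherwise fabricates phantom
   CN+3 species).
5. **Geometry** — trans if the apex precedes the per-class cis/trans
   boundary, cis otherwise; the default boundary is the class apex minus
   half the trans offset.  Geometry is undefined for alkanes.  A second,
   locally scaled detection pass over the pre-boundary segment (enabled
   with `detect_trans_traces`) recovers all-trans trace species that are
   three orders of magnitude below the cis peaks sharing their EIC.
   An independent NMR-side helper classifies a disubstituted double bond
   from the allylic ¹³C shift (cis ≈ 27 ppm, trans ≈ 32.6 ppm; threshold
   at the 30 ppm midpoint).
6. **Quantification** — within each DB class, area / class total × 100;
   never across classes.  Rows below 0.1 % within-class relative area
   move to a traces section and the main report renormalizes to 100.

## Validation design

Because the underlying instrument data are not distributable, validation
is a round trip against the simulator: compositions built from the two
packaged profiles (136-species fly, 44-species cockroach — stored
verbatim with digests, including the printed tables' duplicated peak
numbers, recorded in a `printed_id` column) are simulated, annotated,
and compared to their own ground truth.  The standard checks, all in the
test-suite, are: exact recovery (species, class, geometry) of the
44-species profile at zero noise with within-class areas within 1 pp;
≥95 % recall and geometry accuracy at default noise over 10 seeds with
within-class RMSE ≤ 2 pp; and recovery of a configured 1000:1 cis:trans
trace ratio within a factor of 1.5 over 5 seeds.

What passing these does **not** show: the simulator's Gaussian peaks,
piecewise-linear adduct fractions and per-centroid noise are idealized —
real runs add tailing, co-eluting matrix, gradient disturbances,
detector saturation and drifting calibration, and branched
(methyl-alkane) species isobaric with straight chains are not modeled as
distinct entities.  Recovery rates here bound what the algorithms can do
under the stated model, not instrument performance.

Problem sizes in routine runs: ~16 000 scans (2 Hz over ~135 min of
gradient), 44–248 species, m/z 200–900.  mzML output is plain
uncompressed XML (64-bit float arrays) readable by standard tooling;
the suite cross-checks it against Bioconductor's mzR.

## Known limitations

* DB classes 0–3 only (extendable through the retention/response maps).
* Isomer identity is an elution-order index; no double-bond locants or
  branch points (these require MS/MS, out of scope).
* The matching tolerance (±0.3 Da) and the vendor peak-detection
  parameters of the original workflow are not published; both are
  explicit configuration here.
* Mixed cis/trans multi-ene species are representable but the geometry
  caller only distinguishes all-trans-like (early) from cis-like (late)
  retention.
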