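"""Annotation of silver-ion HPLC / APCI-MS hydrocarbon runs.

The inference mirrors how such runs are interpreted at the instrument:

1. reconstruct, per candidate species, the summed-ion chromatogram of the
   three quantification channels [M-H]+, [M]+., [M+H]+;
2. detect and integrate chromatographic peaks;
3. assign carbon number and double-bond count — the double-bond class
   comes from the retention window (argentation chromatography separates
   classes into disjoint elution windows), the carbon number from the
   averaged mass spectrum across the peak.  The retention window is what
   breaks the alkane/alkene mass degeneracy: CnH2n+2 - H+ and
   CnH2n + H+ are the same ion (CnH2n+1+), so a saturated-window peak is
   always called DB=0 and never DB=1;
4. call cis/trans geometry from the retention time relative to a
   per-class reference boundary (trans isomers elute ahead of cis);
5. report relative peak areas normalized to 100 within each double-bond
   class (never across classes: APCI response grows with unsaturation).

Two numerical details matter for unbiased within-class areas:

* EICs integrate the full isotope envelope of the three channels, not
  just the monoisotopic peaks.  The monoisotopic share of the envelope
  falls from ~0.75 at C25 to ~0.53 at C63, so monoisotopic-only windows
  would skew within-class percentages toward shorter chains.
* An assignment must show at least two of the three quantification
  channels in the averaged spectrum.  A single-channel match is treated
  as isotope interference — e.g. the M+2 isotopologue of [M+C3H3]+ of
  species CN falls within ~0.01 Da of [M-H]+ of species CN+3 and would
  otherwise fabricate a phantom CN+3 peak at the CN retention time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

from .chem import (
    ADDUCT_REGISTRY,
    QUANT_ADDUCTS,
    HydrocarbonSpecies,
    candidates_for_mz,
    ion_mz,
)
from .fixtures import ReportRow, load_class_apexes
from .simulate import GroundTruthComposition, SyntheticRun

__all__ = [
    "EIC",
    "ChromPeak",
    "Annotation",
    "ClassWindows",
    "AnnotationResult",
    "RecoveryMetrics",
    "extract_eic",
    "detect_peaks",
    "average_spectrum",
    "calibrate_class_windows",
    "assign_species",
    "call_geometry",
    "quantify_within_class",
    "geometry_from_allylic_shift",
    "annotate_run",
    "cis_trans_area_ratio",
    "evaluate_recovery",
]

DEFAULT_TOLERANCE = 0.3  # Da; unit-resolution ion-trap matching window
DEFAULT_CN_RANGE = (24, 70)
DEFAULT_THRESHOLD_PCT = 0.1  # within-class % below which a row is a trace


@dataclass
class EIC:
    """Summed-ion chromatogram for a set of target ions."""

    target_mzs: tuple[float, ...]
    tolerance: float
    rt: np.ndarray
    intensity: np.ndarray

    def restricted(self, start: float, end: float) -> "EIC":
        """Same trace with intensity zeroed outside [start, end)."""
        inten = np.where((self.rt >= start) & (self.rt < end), self.intensity, 0.0)
        return EIC(self.target_mzs, self.tolerance, self.rt, inten)


@dataclass(frozen=True)
class ChromPeak:
    """An integrated chromatographic peak (trapezoidal area)."""

    apex_rt: float
    left_rt: float
    right_rt: float
    area: float
    height: float
    apex_index: int = -1

    def __post_init__(self) -> None:
        if not (self.left_rt < self.apex_rt < self.right_rt):
            raise ValueError("require left_rt < apex_rt < right_rt")
        if self.area <= 0:
            raise ValueError("peak area must be > 0")


@dataclass
class Annotation:
    """A species/class/geometry call for one chromatographic peak."""

    peak: ChromPeak
    species: HydrocarbonSpecies | None
    db_class: int
    matched_adducts: tuple[str, ...] = ()
    geometry_call: str | None = None  # cis | trans | mixed | unknown | None
    relative_area_pct: float | None = None
    corrected_area: float | None = None
    quant_share: float | None = None
    isomer_index: int = 0
    is_trace: bool = False

    @property
    def assigned(self) -> bool:
        return self.species is not None

    def to_report_row(self, peak_number: int) -> ReportRow:
        if not self.assigned or self.relative_area_pct is None:
            raise ValueError("cannot report an unassigned/unquantified annotation")
        return ReportRow(
            peak_number=peak_number,
            rt=self.peak.apex_rt,
            cn=self.species.carbon_number,
            db=self.species.double_bonds,
            relative_area_pct=self.relative_area_pct,
            geometry=self.geometry_call,
        )


@dataclass(frozen=True)
class ClassWindows:
    """Disjoint retention windows, one per double-bond class."""

    windows: dict[int, tuple[float, float]]

    def __post_init__(self) -> None:
        items = sorted(self.windows.items())
        for (d1, (s1, e1)), (d2, (s2, e2)) in zip(items, items[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise ValueError(
                    f"class windows must be ordered and non-overlapping: "
                    f"DB{d1}={s1, e1}, DB{d2}={s2, e2}"
                )

    def class_of(self, rt: float) -> int | None:
        for db, (start, end) in self.windows.items():
            if start <= rt < end:
                return db
        return None


def extract_eic(
    run: SyntheticRun,
    species: HydrocarbonSpecies,
    adducts: Iterable[str] = QUANT_ADDUCTS,
    tolerance: float = DEFAULT_TOLERANCE,
    include_isotopes: int = 3,
) -> EIC:
    """Reconstructed chromatogram for the summed target ions of a species.

    Sums, per scan, all centroids within ``tolerance`` of each adduct's
    monoisotopic m/z and of its first ``include_isotopes - 1``
    isotopologue positions (so the captured share of the isotope envelope
    does not depend on carbon number).  Overlapping m/z windows are merged
    before summation so no centroid is counted twice.
    """
    adducts = tuple(adducts)
    if not adducts:
        raise ValueError("adduct set must not be empty")
    if not run.scans:
        raise ValueError("run has no scans")
    from .chem import MASS_C13_DELTA

    targets = tuple(
        ion_mz(species, a, "monoisotopic") + k * MASS_C13_DELTA
        for a in adducts
        for k in range(max(1, include_isotopes))
    )
    mz, inten, scan_idx = run.flat_by_mz()
    trace = np.zeros(len(run.scans))
    intervals = sorted((t - tolerance, t + tolerance) for t in targets)
    merged: list[list[float]] = []
    for lo_t, hi_t in intervals:
        if merged and lo_t <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi_t)
        else:
            merged.append([lo_t, hi_t])
    for lo_t, hi_t in merged:
        lo = np.searchsorted(mz, lo_t)
        hi = np.searchsorted(mz, hi_t)
        if hi > lo:
            np.add.at(trace, scan_idx[lo:hi], inten[lo:hi])
    return EIC(targets, tolerance, run.scan_times, trace)


def detect_peaks(
    eic: EIC,
    min_height_frac: float = 0.01,
    min_width_scans: int = 3,
    min_height_abs: float = 0.0,
    smooth_sigma_scans: float = 0.0,
) -> list[ChromPeak]:
    """Local-maximum peak picking with boundaries at flanking minima.

    When ``smooth_sigma_scans`` > 0 the trace is Gaussian-smoothed for
    apex/boundary *detection* only (multiplicative detector noise turns a
    single chromatographic peak into many local maxima otherwise); areas
    are always trapezoidal integrals of the raw trace over
    [left, right].  Apexes must exceed ``min_height_frac`` of the trace
    maximum (and ``min_height_abs``); each peak must hold at least
    ``min_width_scans`` scans above half its apex height, which
    suppresses single-scan noise spikes.  Boundaries are placed at the
    lowest point between adjacent apexes, taking the crossing nearest the
    peak when the trace bottoms out at a flat baseline.
    """
    raw = eic.intensity
    if len(raw) < 3:
        raise ValueError("trace must hold at least 3 points")
    if smooth_sigma_scans > 0:
        from scipy.ndimage import gaussian_filter1d

        y = gaussian_filter1d(raw, smooth_sigma_scans)
    else:
        y = raw
    top = float(y.max(initial=0.0))
    if top <= 0:
        return []
    thr = max(min_height_frac * top, min_height_abs)
    apexes, _ = find_peaks(y, height=thr)
    peaks: list[ChromPeak] = []
    for j, apex in enumerate(apexes):
        left_lim = apexes[j - 1] if j > 0 else 0
        right_lim = apexes[j + 1] if j + 1 < len(apexes) else len(y) - 1
        seg = y[left_lim : apex + 1]
        lo = seg.min()
        eps = 1e-9 * y[apex]
        left = left_lim + int(np.nonzero(seg <= lo + eps)[0][-1])
        seg = y[apex : right_lim + 1]
        lo = seg.min()
        right = apex + int(np.nonzero(seg <= lo + eps)[0][0])
        if right - left < 2:
            continue
        half = y[apex] / 2.0
        if int(np.sum(y[left : right + 1] >= half)) < min_width_scans:
            continue
        # an isolated detector spike smeared by the smoothing kernel still
        # has almost no support in the raw trace
        if int(np.sum(raw[left : right + 1] > 0)) < min_width_scans:
            continue
        area = float(np.trapezoid(raw[left : right + 1], eic.rt[left : right + 1]))
        if area <= 0:
            continue
        peaks.append(
            ChromPeak(
                apex_rt=float(eic.rt[apex]),
                left_rt=float(eic.rt[left]),
                right_rt=float(eic.rt[right]),
                area=area,
                height=float(y[apex]),
                apex_index=int(apex),
            )
        )
    return peaks


def average_spectrum(
    run: SyntheticRun,
    rt_window: tuple[float, float],
    bin_width: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean centroid spectrum across the scans in ``rt_window``.

    Centroids are pooled into ``bin_width``-wide m/z bins (unit resolution
    by default); each bin reports its intensity-weighted mean m/z and the
    summed intensity divided by the number of scans averaged.
    """
    start, end = rt_window
    times = run.scan_times
    sel = np.nonzero((times >= start) & (times <= end))[0]
    if len(sel) == 0:
        raise ValueError(f"no scans inside window {rt_window}")
    mzs, intens = [], []
    for i in sel:
        mzs.append(run.scans[i].mz)
        intens.append(run.scans[i].intensity)
    mz = np.concatenate(mzs)
    inten = np.concatenate(intens)
    if len(mz) == 0:
        return np.empty(0), np.empty(0)
    keys = np.round(mz / bin_width).astype(np.int64)
    order = np.argsort(keys, kind="stable")
    keys, mz, inten = keys[order], mz[order], inten[order]
    bounds = np.nonzero(np.diff(keys))[0] + 1
    groups = np.split(np.arange(len(keys)), bounds)
    out_mz = np.array([np.average(mz[g], weights=inten[g]) if inten[g].sum() > 0 else mz[g].mean() for g in groups])
    out_int = np.array([inten[g].sum() / len(sel) for g in groups])
    return out_mz, out_int


def calibrate_class_windows(
    run: SyntheticRun | float,
    class_apexes: dict[int, float] | None = None,
) -> ClassWindows:
    """Windows centered on configured class apexes, boundaries at the
    midpoints between adjacent apexes; the first window starts at 0 and
    the last ends at the run end."""
    if class_apexes is None:
        if isinstance(run, SyntheticRun):
            class_apexes = load_class_apexes(
                run.metadata.get("system", "III"),
                run.metadata.get("temperature", 15),
            )
        else:
            raise ValueError("class_apexes required when no run metadata available")
    end = run.duration if isinstance(run, SyntheticRun) else float(run)
    dbs = sorted(class_apexes)
    apexes = [class_apexes[d] for d in dbs]
    if any(b <= a for a, b in zip(apexes, apexes[1:])):
        raise ValueError(f"class apexes must strictly increase: {apexes}")
    windows: dict[int, tuple[float, float]] = {}
    for i, db in enumerate(dbs):
        start = 0.0 if i == 0 else (apexes[i - 1] + apexes[i]) / 2.0
        stop = (
            max(end, apexes[-1] + 1.0)
            if i == len(dbs) - 1
            else (apexes[i] + apexes[i + 1]) / 2.0
        )
        windows[db] = (start, stop)
    return ClassWindows(windows)


def _channel_intensities(
    spectrum: tuple[np.ndarray, np.ndarray],
    species: HydrocarbonSpecies,
    tolerance: float,
) -> dict[str, float]:
    """Intensity in each registry adduct's monoisotopic window."""
    mz, inten = spectrum
    out: dict[str, float] = {}
    for name in ADDUCT_REGISTRY:
        t = ion_mz(species, name, "monoisotopic")
        sel = np.abs(mz - t) <= tolerance
        out[name] = float(inten[sel].sum())
    return out


def assign_species(
    peak: ChromPeak,
    run: SyntheticRun,
    windows: ClassWindows,
    tolerance: float = DEFAULT_TOLERANCE,
    cn_range: tuple[int, int] = DEFAULT_CN_RANGE,
    target_mzs: Sequence[float] | None = None,
    min_quant_channels: int = 2,
    channel_floor: float = 0.02,
) -> Annotation:
    """Call CN:DB for a peak: DB from the window holding the apex, CN from
    the averaged-spectrum base ions via reverse mass lookup restricted to
    that DB.  ``target_mzs`` optionally restricts the base-ion search to
    the EIC's own targets (used by the pipeline so co-eluting species in
    the same window do not hijack the call).

    A call must be supported by at least ``min_quant_channels`` of the
    three quantification channels, each holding at least ``channel_floor``
    of the strongest one; single-channel matches are isotope interference
    from another species' adduct envelope and come back unassigned.
    Returns an unassigned annotation when no candidate matches within
    tolerance."""
    db = windows.class_of(peak.apex_rt)
    if db is None:
        raise ValueError(f"peak at {peak.apex_rt:.2f} min lies in no class window")
    mz, inten = average_spectrum(run, (peak.left_rt, peak.right_rt))
    if len(mz) == 0:
        return Annotation(peak=peak, species=None, db_class=db)
    if target_mzs is not None:
        keep = np.zeros(len(mz), dtype=bool)
        for t in target_mzs:
            keep |= np.abs(mz - t) <= tolerance
        cand_mz, cand_int = mz[keep], inten[keep]
    else:
        cand_mz, cand_int = mz, inten
    order = np.argsort(cand_int)[::-1]
    species = None
    for i in order[:8]:
        hits = candidates_for_mz(
            float(cand_mz[i]),
            tolerance,
            QUANT_ADDUCTS,
            cn_range=cn_range,
            db_range=(db, db),
            scale="monoisotopic",
        )
        if hits:
            species = hits[0][0]
            break
    if species is None:
        return Annotation(peak=peak, species=None, db_class=db)
    channels = _channel_intensities((mz, inten), species, tolerance)
    quant_int = [channels[n] for n in QUANT_ADDUCTS]
    strongest = max(quant_int)
    n_present = sum(1 for v in quant_int if v >= channel_floor * strongest and v > 0)
    if n_present < min_quant_channels:
        return Annotation(peak=peak, species=None, db_class=db)
    floor = channel_floor * max(channels.values())
    matched = tuple(n for n, v in channels.items() if v >= floor and v > 0)
    return Annotation(
        peak=peak,
        species=species,
        db_class=db,
        matched_adducts=matched,
        corrected_area=peak.area,
    )


def call_geometry(
    annotation: Annotation,
    geometry_reference: dict[int, float],
) -> str:
    """cis/trans call from the apex Rt against the per-class boundary:
    trans elutes ahead of (earlier than) the boundary, cis after.
    Geometry is undefined for alkanes (DB=0) and ``unknown`` when the
    class has no reference boundary."""
    if annotation.db_class == 0:
        raise ValueError("geometry is undefined for saturated hydrocarbons")
    boundary = geometry_reference.get(annotation.db_class)
    if boundary is None:
        return "unknown"
    return "trans" if annotation.peak.apex_rt < boundary else "cis"


def quantify_within_class(
    annotations: list[Annotation],
    use_corrected: bool = True,
) -> list[Annotation]:
    """Fill ``relative_area_pct``: 100 * area / class total, per DB class.

    Areas are never compared across classes.  Uses the response-corrected
    areas when available."""
    if any(not a.assigned for a in annotations):
        raise ValueError("all annotations must be assigned before quantification")

    def area_of(a: Annotation) -> float:
        if use_corrected and a.corrected_area is not None:
            return a.corrected_area
        return a.peak.area

    by_class: dict[int, list[Annotation]] = {}
    for a in annotations:
        by_class.setdefault(a.db_class, []).append(a)
    for db, group in by_class.items():
        total = sum(area_of(a) for a in group)
        if total <= 0:
            raise ValueError(f"class DB={db} has zero total area")
        for a in group:
            a.relative_area_pct = 100.0 * area_of(a) / total
    return annotations


def geometry_from_allylic_shift(delta_c: float) -> str:
    """Double-bond geometry from the allylic 13C chemical shift.

    Disubstituted cis alkenes place the allylic carbon near 27 ppm (a
    steric ~-5.4 ppm upfield shift between the flanking methylenes); in
    trans alkenes the effect is absent and the carbon sits near 32.6 ppm.
    The decision threshold is the midpoint, 30 ppm.
    """
    if not (20.0 <= delta_c <= 40.0):
        raise ValueError(
            f"allylic shift {delta_c} ppm outside the plausible 20-40 ppm range"
        )
    return "cis" if delta_c < 30.0 else "trans"


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------


@dataclass
class AnnotationResult:
    """Everything the pipeline inferred from one run."""

    annotations: list[Annotation]  # main report, above threshold
    traces: list[Annotation]  # below-threshold rows (e.g. trans traces)
    unassigned: list[Annotation]
    windows: ClassWindows

    def report_rows(self, include_traces: bool = False) -> list[ReportRow]:
        anns = sorted(
            self.annotations + (self.traces if include_traces else []),
            key=lambda a: (a.db_class, a.peak.apex_rt),
        )
        return [a.to_report_row(i + 1) for i, a in enumerate(anns)]

    def class_share_estimates(self) -> dict[int, float]:
        """Share of the total corrected area per class — area shares, not
        molar shares, since APCI response differs across classes."""
        totals: dict[int, float] = {}
        for a in self.annotations + self.traces:
            totals[a.db_class] = totals.get(a.db_class, 0.0) + (
                a.corrected_area or a.peak.area
            )
        grand = sum(totals.values())
        return {db: 100.0 * v / grand for db, v in totals.items()}


def annotate_run(
    run: SyntheticRun,
    windows: ClassWindows | None = None,
    *,
    tolerance: float = DEFAULT_TOLERANCE,
    adducts: Iterable[str] = QUANT_ADDUCTS,
    cn_range: tuple[int, int] = DEFAULT_CN_RANGE,
    db_classes: Iterable[int] = (0, 1, 2, 3),
    min_height_frac: float = 0.01,
    min_width_scans: int = 3,
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
    geometry_reference: dict[int, float] | None = None,
    detect_trans_traces: bool = False,
) -> AnnotationResult:
    """Full inference pass over a run.

    For every double-bond class window and candidate carbon number, the
    quantification-channel EIC is reconstructed and peak-picked inside the
    window; each peak is assigned from its averaged spectrum, geometry is
    called against ``geometry_reference`` (per-class boundary Rt), areas
    are response-corrected and normalized within class, and rows below
    ``threshold_pct`` within-class percent move to the traces section.

    ``detect_trans_traces`` adds a second, locally scaled detection pass
    over the early (pre-boundary) segment of each unsaturated window so
    that trace-level all-trans counterparts — orders of magnitude below
    the cis peaks sharing the same EIC — are still picked up.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if windows is None:
        windows = calibrate_class_windows(run)
    from .simulate import RetentionModel

    model = RetentionModel.default()
    times = run.scan_times
    scans_per_min = 1.0 / float(np.median(np.diff(times))) if len(times) > 1 else 120.0
    if geometry_reference is None:
        try:
            geometry_reference = model.geometry_boundaries(
                run.metadata.get("system", "III"),
                run.metadata.get("temperature", 15),
            )
        except KeyError:
            geometry_reference = {}
    adducts = tuple(adducts)
    annotations: list[Annotation] = []
    unassigned: list[Annotation] = []
    for db in db_classes:
        if db not in windows.windows:
            continue
        start, end = windows.windows[db]
        boundary = geometry_reference.get(db) if db >= 1 else None
        smooth = model.peak_sigma.get(db, 0.1) * scans_per_min / 2.0
        for cn in range(cn_range[0], cn_range[1] + 1):
            if db > (cn - 1) // 2:
                continue
            sp = HydrocarbonSpecies(cn, db)
            eic = extract_eic(run, sp, adducts, tolerance)
            win_eic = eic.restricted(start, end)
            if win_eic.intensity.max(initial=0.0) <= 0:
                continue
            peaks = detect_peaks(
                win_eic, min_height_frac, min_width_scans, smooth_sigma_scans=smooth
            )
            if detect_trans_traces and boundary is not None and boundary > start:
                sub = win_eic.restricted(start, boundary)
                if sub.intensity.max(initial=0.0) > 0:
                    seen = {p.apex_index for p in peaks}
                    for p in detect_peaks(
                        sub, min_height_frac, min_width_scans, smooth_sigma_scans=smooth
                    ):
                        if p.apex_index not in seen:
                            peaks.append(p)
            for peak in sorted(peaks, key=lambda p: p.apex_rt):
                ann = assign_species(
                    peak, run, windows, tolerance, cn_range,
                    target_mzs=eic.target_mzs,
                )
                if not ann.assigned:
                    unassigned.append(ann)
                    continue
                if ann.db_class >= 1:
                    ann.geometry_call = call_geometry(ann, geometry_reference)
                annotations.append(ann)

    # positional isomer index: elution order within each CN:DB family
    fams: dict[tuple[int, int], list[Annotation]] = {}
    for a in annotations:
        fams.setdefault(
            (a.species.carbon_number, a.species.double_bonds), []
        ).append(a)
    for fam in fams.values():
        for i, a in enumerate(sorted(fam, key=lambda x: x.peak.apex_rt)):
            a.isomer_index = i

    if annotations:
        quantify_within_class(annotations)
    main = [a for a in annotations if (a.relative_area_pct or 0) >= threshold_pct]
    traces = [a for a in annotations if (a.relative_area_pct or 0) < threshold_pct]
    for a in traces:
        a.is_trace = True
    if main:
        quantify_within_class(main)  # renormalize the reported rows to 100
    return AnnotationResult(
        annotations=main, traces=traces, unassigned=unassigned, windows=windows
    )


def cis_trans_area_ratio(result: AnnotationResult) -> float:
    """Summed cis-called to trans-called area ratio over unsaturated rows
    (main report and traces pooled; response-corrected areas)."""
    cis = trans = 0.0
    for a in result.annotations + result.traces:
        if a.db_class == 0:
            continue
        area = a.corrected_area or a.peak.area
        if a.geometry_call == "cis":
            cis += area
        elif a.geometry_call == "trans":
            trans += area
    if trans <= 0:
        raise ValueError("no trans-called peaks; ratio undefined")
    return cis / trans


# --------------------------------------------------------------------------
# Evaluation against ground truth
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryMetrics:
    species_precision: float
    species_recall: float
    per_class_area_rmse: dict[int, float]  # percentage points, matched rows
    geometry_accuracy: float  # over matched unsaturated rows

    @property
    def overall_area_rmse(self) -> float:
        errs = [v**2 for v in self.per_class_area_rmse.values()]
        return float(np.sqrt(np.mean(errs))) if errs else 0.0


def evaluate_recovery(
    result: AnnotationResult | list[Annotation],
    truth: GroundTruthComposition,
    include_traces: bool = False,
) -> RecoveryMetrics:
    """Match annotations to ground truth on (CN, DB, isomer rank by Rt).

    Recall counts recovered truth entries; precision counts annotations
    that correspond to a truth entry; the per-class area RMSE compares
    within-class relative areas (percentage points) over matched non-trace
    rows; geometry accuracy is the fraction of matched unsaturated rows
    whose cis/trans call equals the truth geometry.
    """
    if isinstance(result, AnnotationResult):
        anns = list(result.annotations) + (list(result.traces) if include_traces else [])
    else:
        anns = list(result)
    truth_entries = list(truth.entries if include_traces else truth.main_entries)

    def keyed(items, key_rt, key_fam):
        fams: dict[tuple, list] = {}
        for it in items:
            fams.setdefault(key_fam(it), []).append(it)
        out = {}
        for famkey, fam in fams.items():
            for i, it in enumerate(sorted(fam, key=key_rt)):
                out[famkey + (i,)] = it
        return out

    t_keyed = keyed(
        truth_entries,
        key_rt=lambda e: e.rt,
        key_fam=lambda e: (e.species.carbon_number, e.species.double_bonds),
    )
    a_keyed = keyed(
        anns,
        key_rt=lambda a: a.peak.apex_rt,
        key_fam=lambda a: (a.species.carbon_number, a.species.double_bonds),
    )
    matched = [(k, t_keyed[k], a_keyed[k]) for k in t_keyed if k in a_keyed]
    recall = len(matched) / len(t_keyed) if t_keyed else 1.0
    precision = len(matched) / len(a_keyed) if a_keyed else 1.0

    # within-class % over the same (non-trace) row sets on both sides
    errs_by_class: dict[int, list[float]] = {}
    main_matches = [(k, t, a) for k, t, a in matched if not t.is_trace]
    cls_truth_tot: dict[int, float] = {}
    for e in truth_entries:
        if not e.is_trace:
            db = e.species.double_bonds
            cls_truth_tot[db] = cls_truth_tot.get(db, 0.0) + e.abundance_pct
    for _, t, a in main_matches:
        db = t.species.double_bonds
        t_pct = 100.0 * t.abundance_pct / cls_truth_tot[db]
        a_pct = a.relative_area_pct
        if a_pct is None:
            continue
        errs_by_class.setdefault(db, []).append(a_pct - t_pct)
    rmse = {
        db: float(np.sqrt(np.mean(np.square(v)))) for db, v in errs_by_class.items()
    }

    unsat = [(t, a) for _, t, a in matched if t.species.double_bonds >= 1]
    if unsat:
        good = sum(
            1 for t, a in unsat if a.geometry_call == t.geometry_label
        )
        geometry_accuracy = good / len(unsat)
    else:
        geometry_accuracy = 1.0
    return RecoveryMetrics(
        species_precision=precision,
        species_recall=recall,
        per_class_area_rmse=rmse,
        geometry_accuracy=geometry_accuracy,
    )
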