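"""Seeded simulator of silver-ion HPLC / APCI-MS hydrocarbon runs.

Silver-ion (argentation) chromatography retains hydrocarbons through
complexation of C=C pi electrons with Ag+: species elute in well-separated
groups by double-bond count, trans isomers ahead of cis (weaker Ag+
complexes), and, within a group, later with *fewer* carbons (a residual
normal-phase contribution).  APCI then ionizes each analyte into a
mobile-phase-dependent mixture of [M-H]+, [M+H]+, [M]+., and solvent
adducts, with response rising with unsaturation.

This module encodes those regularities as an explicit generative model —
a retention model anchored on measured class apex times, a piecewise
response/adduct model, Gaussian chromatographic peaks, isotope envelopes,
and multiplicative log-normal noise — and renders a time-ordered list of
centroid spectra plus its ground truth, so the annotation pipeline can be
exercised end-to-end without instrument data.

Intensity units are arbitrary; only ratios are meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import fixtures
from .chem import (
    HydrocarbonSpecies,
    get_adduct,
    ion_formula,
    ion_mz,
    isotope_pattern,
)
from .fixtures import ReportRow
from .mzml import read_mzml, write_mzml  # noqa: F401  (re-exported)

__all__ = [
    "GradientProgram",
    "RetentionModel",
    "ResponseModel",
    "GroundTruthEntry",
    "GroundTruthComposition",
    "Scan",
    "SyntheticRun",
    "gradient_percent_B",
    "predict_rt",
    "adduct_profile",
    "composition_from_report",
    "simulate_run",
    "write_mzml",
    "read_mzml",
]

DB_CLASSES = (0, 1, 2, 3)


# --------------------------------------------------------------------------
# Gradient
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GradientProgram:
    """Linear binary gradient: %B ramps from ``percent_b_start`` at
    ``slope`` %/min, clipped at 100.  For the hexane/toluene system (III),
    %B equals %toluene."""

    solvent_system: str = "III"
    percent_b_start: float = 0.0
    slope: float = 0.5
    duration: float = 140.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_b_start <= 100.0):
            raise ValueError("percent_b_start must be in [0, 100]")
        if self.slope < 0:
            raise ValueError("slope must be >= 0")

    def percent_b(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be >= 0")
        return np.minimum(self.percent_b_start + self.slope * t, 100.0)


def gradient_percent_B(t, program: GradientProgram):
    """%B of the mobile phase at time ``t`` (minutes); scalar or array."""
    out = program.percent_b(t)
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


# --------------------------------------------------------------------------
# Retention
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RetentionModel:
    """Class-anchored retention model.

    Rt(species) = apex(system, T, DB)
                  + cn_slope[DB] * (CN - ref_cn[DB])
                  + (isomer_index - isomer_anchor) * isomer_spacing
                  - trans_offset[DB]   (all-trans species only)

    ``class_apex`` holds measured apex times of the most abundant peak per
    double-bond class, keyed by (solvent system, column temperature).
    ``cn_slope`` is negative: heavier chains elute earlier within a class.
    ``ref_cn`` pins the class apex to the carbon number of the dominant
    species so a fixture-derived composition reproduces the measured apex.
    ``isomer_spacing`` separates positional-isomer sub-peaks; the anchor
    (most abundant isomer) sits at offset zero.  ``trans_offset`` (> 0,
    per class) moves all-trans species ahead of their cis counterparts.
    ``peak_sigma`` is the Gaussian chromatographic sigma per class: the
    saturated cluster is a few seconds wide while late-eluting polyenes
    broaden under the shallow gradient.
    """

    class_apex: dict[tuple[str, float], dict[int, float]]
    cn_slope: dict[int, float] = field(
        default_factory=lambda: {0: -0.005, 1: -0.08, 2: -0.15, 3: -0.30}
    )
    ref_cn: dict[int, int] = field(
        default_factory=lambda: {0: 30, 1: 39, 2: 41, 3: 43}
    )
    isomer_spacing: float = 0.4
    trans_offset: dict[int, float] = field(
        default_factory=lambda: {1: 3.0, 2: 12.0, 3: 16.0}
    )
    peak_sigma: dict[int, float] = field(
        default_factory=lambda: {0: 0.02, 1: 0.08, 2: 0.20, 3: 0.35}
    )

    def __post_init__(self) -> None:
        if any(v >= 0 for v in self.cn_slope.values()):
            raise ValueError("cn_slope must be < 0 for every class")
        if any(v <= 0 for v in self.trans_offset.values()):
            raise ValueError("trans_offset must be > 0 for every class")
        for key, apexes in self.class_apex.items():
            vals = [apexes[d] for d in sorted(apexes)]
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"class apexes out of DB order for {key}: {vals}")

    @classmethod
    def default(cls) -> "RetentionModel":
        """Model anchored on the packaged class-apex table (all nine
        system/temperature combinations)."""
        df = fixtures._read_tsv("table2.tsv")
        apex: dict[tuple[str, float], dict[int, float]] = {}
        for r in df.itertuples():
            apex.setdefault((str(r.system), float(r.temp_c)), {})[int(r.db)] = float(
                r.rt_min
            )
        return cls(class_apex=apex)

    def apexes(self, system: str, temperature: float) -> dict[int, float]:
        try:
            return self.class_apex[(system, float(temperature))]
        except KeyError:
            known = sorted(self.class_apex)
            raise KeyError(
                f"no retention calibration for system {system!r} at "
                f"{temperature} degC; known: {known}"
            ) from None

    def geometry_boundaries(self, system: str, temperature: float) -> dict[int, float]:
        """Default per-class cis/trans boundary: halfway between the class
        apex and the all-trans cluster (apex - trans_offset/2)."""
        apexes = self.apexes(system, temperature)
        return {
            db: apexes[db] - self.trans_offset[db] / 2.0
            for db in apexes
            if db in self.trans_offset
        }


def predict_rt(
    species: HydrocarbonSpecies,
    model: RetentionModel,
    system: str = "III",
    temperature: float = 15,
    isomer_index: int = 0,
    isomer_anchor: int = 0,
) -> float:
    """Deterministic retention time (minutes) of a species."""
    db = species.double_bonds
    apexes = model.apexes(system, temperature)
    if db not in apexes:
        raise KeyError(f"no class apex for DB={db}")
    rt = apexes[db]
    rt += model.cn_slope[db] * (species.carbon_number - model.ref_cn[db])
    rt += (isomer_index - isomer_anchor) * model.isomer_spacing
    if species.all_trans:
        rt -= model.trans_offset[db]
    if rt <= 0:
        raise ValueError(f"predicted Rt {rt:.2f} min <= 0 for {species.label}")
    return rt


# --------------------------------------------------------------------------
# APCI response / adduct model
# --------------------------------------------------------------------------

# Piecewise-linear adduct-fraction knots vs %toluene for the hexane/toluene
# system: (percent, weight) pairs, linearly interpolated then normalized.
# Chosen to honour the qualitative behaviour of hydrocarbon APCI spectra:
# pure hexane gives mostly [M+C3H3]+; [M+H]+ peaks at 40-60% toluene and
# declines beyond; polyunsaturated species at high %toluene additionally
# give [M]+. and protonated-toluene adducts; saturated chains always give
# predominantly [M-H]+.
_KNOTS_III_SAT = {
    "[M-H]+": [(0, 0.65), (100, 0.65)],
    "[M+H]+": [(0, 0.08), (100, 0.08)],
    "[M]+.": [(0, 0.07), (100, 0.07)],
    "[M+C3H3]+": [(0, 0.20), (40, 0.06), (100, 0.02)],
}
_KNOTS_III_UNSAT = {
    "[M+H]+": [(0, 0.15), (40, 0.55), (60, 0.55), (80, 0.45), (100, 0.35)],
    "[M+C3H3]+": [(0, 0.60), (40, 0.10), (100, 0.00)],
    "[M-H]+": [(0, 0.10), (100, 0.10)],
}
_KNOTS_III_M = {1: [(0, 0.05), (100, 0.10)], 2: [(0, 0.05), (60, 0.15), (100, 0.25)]}
_KNOTS_III_TOL_ADDUCT = [(0, 0.00), (60, 0.05), (100, 0.20)]

# Fixed adduct fractions for the weakly modified isocratic-like systems:
# hexane/MeCN/iPrOH (I) and isooctane/MeCN/iPrOH (II).
_FIXED_PROFILES = {
    ("I", 0): {"[M-H]+": 0.40, "[M+H]+": 0.10, "[M]+.": 0.05,
               "[M+C3H3]+": 0.30, "[M+C6H13]+": 0.15},
    ("I", 1): {"[M+C3H3]+": 0.40, "[M+C6H13]+": 0.20, "[M-H]+": 0.16,
               "[M+H]+": 0.10, "[M]+.": 0.14},
    ("II", 0): {"[M-H]+": 0.45, "[M+H]+": 0.10, "[M]+.": 0.05, "[M+C4H9]+": 0.40},
    ("II", 1): {"[M+C4H9]+": 0.44, "[M-H]+": 0.22, "[M+H]+": 0.22, "[M]+.": 0.12},
}


def adduct_profile(
    db_class: int,
    percent_toluene,
    system: str = "III",
) -> dict[str, np.ndarray | float]:
    """Fraction of ion current per adduct at the local mobile-phase mix.

    For system III the fractions interpolate the knot tables above as a
    function of %toluene; for systems I and II they are fixed per class.
    Fractions always sum to 1.  ``percent_toluene`` may be scalar or array.
    """
    scalar = np.ndim(percent_toluene) == 0
    pct = np.atleast_1d(np.asarray(percent_toluene, dtype=float))
    if np.any((pct < 0) | (pct > 100)):
        raise ValueError("percent_toluene must be within [0, 100]")
    if system in ("I", "II"):
        prof = _FIXED_PROFILES[(system, 0 if db_class == 0 else 1)]
        out = {k: np.full_like(pct, v) for k, v in prof.items()}
    elif system == "III":
        weights: dict[str, np.ndarray] = {}
        if db_class == 0:
            table = _KNOTS_III_SAT
        else:
            table = dict(_KNOTS_III_UNSAT)
            table["[M]+."] = _KNOTS_III_M[1 if db_class < 2 else 2]
            if db_class >= 2:
                table["[M+C7H9]+"] = _KNOTS_III_TOL_ADDUCT
        for name, knots in table.items():
            xs, ys = zip(*knots)
            weights[name] = np.interp(pct, xs, ys)
        total = sum(weights.values())
        out = {k: v / total for k, v in weights.items()}
    else:
        raise KeyError(f"unknown solvent system {system!r}")
    if scalar:
        return {k: float(v[0]) for k, v in out.items()}
    return out


@dataclass(frozen=True)
class ResponseModel:
    """Detector response: per-class relative response factors (APCI response
    grows with the number of double bonds) and the chain-fragment floor
    (low-mass fragment current as a fraction of the base channel)."""

    db_response: dict[int, float] = field(
        default_factory=lambda: {0: 1.0, 1: 3.0, 2: 5.0, 3: 7.0}
    )
    fragment_floor: float = 0.08

    def __post_init__(self) -> None:
        vals = [self.db_response[d] for d in sorted(self.db_response)]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("db_response must be non-decreasing in DB class")


# Fixed low-mass alkyl fragment channels (CnH2n+1+, all below m/z 350).
_FRAGMENT_MZ = (211.2427, 253.2897, 281.3210)


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroundTruthEntry:
    species: HydrocarbonSpecies
    rt: float
    abundance_pct: float  # relative area within its DB class
    class_share_pct: float
    isomer_index: int = 0
    is_trace: bool = False

    @property
    def geometry_label(self) -> str | None:
        if self.species.double_bonds == 0:
            return None
        if self.species.all_trans:
            return "trans"
        if self.species.all_cis:
            return "cis"
        return "unknown"


@dataclass(frozen=True)
class GroundTruthComposition:
    """The species content of a simulated sample.

    Within each double-bond class the non-trace abundances sum to 100;
    trace entries (e.g. all-trans counterparts) ride on top and are
    excluded from that normalization.
    """

    entries: tuple[GroundTruthEntry, ...]
    class_shares: dict[int, float]

    def __post_init__(self) -> None:
        for db in sorted({e.species.double_bonds for e in self.entries}):
            if db not in self.class_shares:
                raise ValueError(f"class share missing for DB={db}")
            s = sum(
                e.abundance_pct
                for e in self.entries
                if e.species.double_bonds == db and not e.is_trace
            )
            if abs(s - 100.0) > 0.5:
                raise ValueError(f"DB={db} abundances sum to {s:.2f}, not 100")
        total = sum(self.class_shares.values())
        if abs(total - 100.0) > 0.1:
            raise ValueError(f"class shares sum to {total}, not 100")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def main_entries(self) -> tuple[GroundTruthEntry, ...]:
        return tuple(e for e in self.entries if not e.is_trace)

    @property
    def trace_entries(self) -> tuple[GroundTruthEntry, ...]:
        return tuple(e for e in self.entries if e.is_trace)

    def to_tsv(self, path: str | Path) -> Path:
        rows = [
            {
                "cn": e.species.carbon_number,
                "db": e.species.double_bonds,
                "geometry": e.geometry_label or "",
                "isomer_index": e.isomer_index,
                "rt_min": e.rt,
                "abundance_pct": e.abundance_pct,
                "class_share_pct": e.class_share_pct,
                "is_trace": int(e.is_trace),
            }
            for e in self.entries
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return Path(path)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroundTruthComposition":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        entries = []
        shares: dict[int, float] = {}
        for r in df.itertuples():
            db = int(r.db)
            geom = tuple([str(r.geometry)] * db) if r.geometry else None
            entries.append(
                GroundTruthEntry(
                    species=HydrocarbonSpecies(int(r.cn), db, geometry=geom),
                    rt=float(r.rt_min),
                    abundance_pct=float(r.abundance_pct),
                    class_share_pct=float(r.class_share_pct),
                    isomer_index=int(r.isomer_index),
                    is_trace=bool(int(r.is_trace)),
                )
            )
            shares[db] = float(r.class_share_pct)
        return cls(entries=tuple(entries), class_shares=shares)


def composition_from_report(
    report: Sequence[ReportRow],
    class_shares: dict[int, float],
    cis_trans_ratio: float | None = None,
    retention: RetentionModel | None = None,
    system: str = "III",
    temperature: float = 15,
) -> GroundTruthComposition:
    """Turn a profile table into a simulatable ground-truth composition.

    Within-class abundances equal the report's relative areas.  Unsaturated
    rows become all-cis species (the geometry inferred in the source
    profiles); retention times are regenerated from the retention model,
    using the report's within-family elution order to assign positional
    isomer indices, with each family's most abundant isomer anchored at
    offset zero.

    ``cis_trans_ratio`` (e.g. 1000 for a 1000:1 cis:trans area ratio) adds
    a trace all-trans counterpart for every unsaturated species at
    1/ratio of its abundance, eluting ahead of it by the model's per-class
    trans offset.  ``None`` or 0 adds no traces.
    """
    if retention is None:
        retention = RetentionModel.default()
    for db in sorted({r.db for r in report}):
        if db not in class_shares:
            raise ValueError(f"class share missing for DB={db}")
    families: dict[tuple[int, int], list[ReportRow]] = {}
    for r in report:
        if r.relative_area_pct <= 0:
            raise ValueError("report rows must have positive areas")
        families.setdefault(r.cn_db, []).append(r)
    entries: list[GroundTruthEntry] = []
    for (cn, db), fam in sorted(families.items()):
        fam = sorted(fam, key=lambda x: x.rt)
        anchor = int(np.argmax([x.relative_area_pct for x in fam]))
        for i, row in enumerate(fam):
            geom = ("cis",) * db if db >= 1 else None
            sp = HydrocarbonSpecies(cn, db, geometry=geom)
            rt = predict_rt(
                sp, retention, system, temperature, isomer_index=i, isomer_anchor=anchor
            )
            entries.append(
                GroundTruthEntry(
                    species=sp,
                    rt=rt,
                    abundance_pct=row.relative_area_pct,
                    class_share_pct=class_shares[db],
                    isomer_index=i,
                )
            )
            if cis_trans_ratio and db >= 1:
                sp_t = HydrocarbonSpecies(cn, db, geometry=("trans",) * db)
                rt_t = predict_rt(
                    sp_t,
                    retention,
                    system,
                    temperature,
                    isomer_index=i,
                    isomer_anchor=anchor,
                )
                entries.append(
                    GroundTruthEntry(
                        species=sp_t,
                        rt=rt_t,
                        abundance_pct=row.relative_area_pct / cis_trans_ratio,
                        class_share_pct=class_shares[db],
                        isomer_index=i,
                        is_trace=True,
                    )
                )
    return GroundTruthComposition(entries=tuple(entries), class_shares=dict(class_shares))


# --------------------------------------------------------------------------
# Run container
# --------------------------------------------------------------------------


@dataclass
class Scan:
    """One centroided spectrum: retention time (minutes) and peak lists."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray


@dataclass
class SyntheticRun:
    """Time-ordered centroid spectra plus acquisition metadata.

    ``metadata`` records the gradient program, solvent system, column
    temperature, scan rate, m/z range, seed, and any truncated species.
    """

    scans: list[Scan]
    metadata: dict

    _flat_cache: tuple | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.scans)

    @property
    def scan_times(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans])

    @property
    def duration(self) -> float:
        if "duration" in self.metadata:
            return float(self.metadata["duration"])
        return float(self.scans[-1].rt) if self.scans else 0.0

    def flat_by_mz(self):
        """All centroids flattened and sorted by m/z:
        (mz, intensity, scan_index) — the fast path for EIC extraction."""
        if self._flat_cache is None:
            if self.scans:
                mz = np.concatenate([s.mz for s in self.scans])
                inten = np.concatenate([s.intensity for s in self.scans])
                idx = np.concatenate(
                    [np.full(len(s.mz), i, dtype=np.int64) for i, s in enumerate(self.scans)]
                )
            else:
                mz = inten = np.empty(0)
                idx = np.empty(0, dtype=np.int64)
            order = np.argsort(mz, kind="stable")
            self._flat_cache = (mz[order], inten[order], idx[order])
        return self._flat_cache


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------


def simulate_run(
    composition: GroundTruthComposition,
    retention: RetentionModel | None = None,
    response: ResponseModel | None = None,
    noise_sd: float = 0.05,
    scan_rate: float = 2.0,
    seed: int = 0,
    *,
    system: str = "III",
    temperature: float = 15,
    gradient: GradientProgram | None = None,
    mz_range: tuple[float, float] = (200.0, 900.0),
    duration: float | None = None,
    rt_jitter: float = 0.005,
    baseline_rate: float = 2.0,
    baseline_scale: float = 1.0,
    n_isotopes: int = 3,
) -> SyntheticRun:
    """Render a composition into a synthetic centroided run.

    Each ground-truth species contributes a Gaussian chromatographic
    profile at its (jittered) retention time with the class peak sigma;
    its total assigned-channel area is ``abundance * class_share *
    db_response``.  At every scan the ion current splits over the adducts
    of :func:`adduct_profile` evaluated at the local %toluene (system III)
    or the fixed solvent mix (systems I/II), each adduct carrying its
    isotope envelope; a chain-fragment floor is emitted below m/z 350.
    ``noise_sd`` applies multiplicative log-normal noise per centroid and
    enables a sparse Poisson baseline; ``noise_sd=0`` yields a noiseless,
    baseline-free run.  Identical arguments and seed give identical runs.
    """
    if scan_rate <= 0:
        raise ValueError("scan_rate must be > 0")
    retention = retention or RetentionModel.default()
    response = response or ResponseModel()
    rng = np.random.default_rng(seed)

    sigma = retention.peak_sigma
    if duration is None:
        duration = max(e.rt for e in composition.entries) + 5.0
    if gradient is None:
        gradient = GradientProgram(solvent_system=system, duration=duration)
    dt = 1.0 / (60.0 * scan_rate)
    times = np.arange(0.0, duration, dt)
    n_scans = len(times)
    pct_b = gradient.percent_b(times)

    chunks_idx: list[np.ndarray] = []
    chunks_mz: list[np.ndarray] = []
    chunks_int: list[np.ndarray] = []
    truncated: list[str] = []

    for entry in composition.entries:
        sp = entry.species
        db = sp.double_bonds
        rt = entry.rt
        if rt_jitter > 0:
            rt = rt * (1.0 + rng.normal(0.0, rt_jitter))
        sig = sigma[db]
        if rt < 0 or rt > duration:
            warnings.warn(
                f"{sp.label} Rt {rt:.2f} min outside run duration; truncated",
                stacklevel=2,
            )
            truncated.append(sp.label)
            continue
        i0 = int(np.searchsorted(times, rt - 4 * sig))
        i1 = int(np.searchsorted(times, rt + 4 * sig))
        if i1 <= i0:
            continue
        t = times[i0:i1]
        area = entry.abundance_pct * entry.class_share_pct * response.db_response[db]
        g = area * np.exp(-0.5 * ((t - rt) / sig) ** 2) / (sig * np.sqrt(2 * np.pi))
        fractions = adduct_profile(db, pct_b[i0:i1], system=system)
        idx = np.arange(i0, i1, dtype=np.int64)
        base_channel = np.zeros_like(g)
        for name, frac in fractions.items():
            if np.max(frac) < 1e-6:
                continue
            pat = isotope_pattern(ion_formula(sp, name), n_peaks=n_isotopes)
            iso_int = pat.intensity
            iso_int = iso_int / iso_int.sum()
            channel = g * frac
            base_channel = np.maximum(base_channel, channel)
            for k, (mz_k, _) in enumerate(pat.entries):
                if not (mz_range[0] <= mz_k <= mz_range[1]):
                    continue
                chunks_idx.append(idx)
                chunks_mz.append(np.full(len(idx), mz_k))
                chunks_int.append(channel * iso_int[k])
        if response.fragment_floor > 0:
            frag_each = response.fragment_floor * base_channel / len(_FRAGMENT_MZ)
            for fmz in _FRAGMENT_MZ:
                if mz_range[0] <= fmz <= mz_range[1]:
                    chunks_idx.append(idx)
                    chunks_mz.append(np.full(len(idx), fmz))
                    chunks_int.append(frag_each.copy())

    if chunks_idx:
        scan_idx = np.concatenate(chunks_idx)
        mz = np.concatenate(chunks_mz)
        inten = np.concatenate(chunks_int)
    else:
        scan_idx = np.empty(0, dtype=np.int64)
        mz = inten = np.empty(0)

    if noise_sd > 0 and len(inten):
        inten = inten * rng.lognormal(0.0, noise_sd, size=len(inten))
    if noise_sd > 0 and baseline_rate > 0:
        counts = rng.poisson(baseline_rate, size=n_scans)
        nb = int(counts.sum())
        if nb:
            b_idx = np.repeat(np.arange(n_scans, dtype=np.int64), counts)
            b_mz = rng.uniform(mz_range[0], mz_range[1], size=nb)
            b_int = rng.exponential(baseline_scale, size=nb)
            scan_idx = np.concatenate([scan_idx, b_idx])
            mz = np.concatenate([mz, b_mz])
            inten = np.concatenate([inten, b_int])

    order = np.lexsort((mz, scan_idx))
    scan_idx, mz, inten = scan_idx[order], mz[order], inten[order]
    bounds = np.searchsorted(scan_idx, np.arange(n_scans + 1))
    scans = [
        Scan(rt=float(times[i]), mz=mz[bounds[i] : bounds[i + 1]],
             intensity=inten[bounds[i] : bounds[i + 1]])
        for i in range(n_scans)
    ]
    metadata = {
        "system": system,
        "temperature": float(temperature),
        "gradient": {
            "solvent_system": gradient.solvent_system,
            "percent_b_start": gradient.percent_b_start,
            "slope": gradient.slope,
            "duration": duration,
        },
        "scan_rate_hz": scan_rate,
        "mz_range": tuple(mz_range),
        "seed": seed,
        "noise_sd": noise_sd,
        "duration": duration,
        "truncated": truncated,
        "run_id": f"argentms_sim_seed{seed}",
    }
    return SyntheticRun(scans=scans, metadata=metadata)
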