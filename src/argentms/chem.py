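"""Hydrocarbon mass chemistry for APCI ionization.

Aliphatic hydrocarbons CnH(2n+2-2d) (carbon number *n*, double-bond count
*d*) ionize in positive-mode APCI as deprotonated molecules [M-H]+,
protonated molecules [M+H]+, radical cations [M]+., and solvent-derived
adducts such as [M+C3H3]+ (+39 Da, from hexane plasma), [M+C4H9]+
(+57 Da, from isooctane), [M+C6H13]+ (+85 Da, hexane minus H), and
[M+C7H9]+ (+93 Da, protonated toluene).  This module provides formula and
mass arithmetic for these species, the adduct registry, isotope envelope
computation, and the reverse lookup from an observed m/z to candidate
(species, adduct) assignments.

Masses are available on two scales: *nominal* (integer masses C=12, H=1,
the scale at which unit-resolution ion traps report m/z)
and *monoisotopic* (C=12 exactly, H=1.00783).  Electron mass is neglected
throughout; cation m/z equals the sum of atomic masses of the ion formula.

Double-bond geometry (cis/trans) and position never affect mass; they are
carried as labels only and are resolved chromatographically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "MASS_H_MONO",
    "MASS_C13_DELTA",
    "HydrocarbonSpecies",
    "AdductDef",
    "IsotopePattern",
    "ADDUCT_REGISTRY",
    "QUANT_ADDUCTS",
    "get_adduct",
    "adduct_offset",
    "neutral_formula",
    "neutral_mass",
    "ion_mz",
    "isotope_pattern",
    "monoisotopic_fraction",
    "candidates_for_mz",
]

MASS_H_MONO = 1.00783
MASS_C13_DELTA = 1.00336  # 13C - 12C, the dominant isotope spacing
ABUNDANCE_13C = 0.0107
ABUNDANCE_2H = 0.000115

MassScale = Literal["nominal", "monoisotopic"]

GeometryLabel = Literal["cis", "trans", "unknown"]


class ChemValidationError(ValueError):
    """A species or adduct violates its structural constraints."""


@dataclass(frozen=True)
class HydrocarbonSpecies:
    """A neutral aliphatic hydrocarbon identified by CN:DB.

    Parameters
    ----------
    carbon_number : int
        Number of carbons (CN), >= 1.
    double_bonds : int
        Number of C=C (DB), 0 <= DB <= (CN - 1) // 2.
    geometry : tuple of {"cis", "trans", "unknown"}, optional
        Per-double-bond geometry labels; length must equal ``double_bonds``.
    positions : tuple of int, optional
        Double-bond locants; informational only, never used in mass
        arithmetic.
    """

    carbon_number: int
    double_bonds: int = 0
    geometry: tuple[GeometryLabel, ...] | None = None
    positions: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        cn, db = self.carbon_number, self.double_bonds
        if cn < 1:
            raise ChemValidationError(f"carbon_number must be >= 1, got {cn}")
        if db < 0:
            raise ChemValidationError(f"double_bonds must be >= 0, got {db}")
        if db > (cn - 1) // 2:
            raise ChemValidationError(
                f"C{cn}:{db} invalid: double_bonds must be <= (CN - 1) // 2 "
                f"= {(cn - 1) // 2}"
            )
        if self.geometry is not None:
            object.__setattr__(self, "geometry", tuple(self.geometry))
            if len(self.geometry) != db:
                raise ChemValidationError(
                    f"geometry length {len(self.geometry)} != double_bonds {db}"
                )
            for g in self.geometry:
                if g not in ("cis", "trans", "unknown"):
                    raise ChemValidationError(f"unknown geometry label {g!r}")
        if self.positions is not None:
            object.__setattr__(self, "positions", tuple(self.positions))

    @property
    def hydrogen_count(self) -> int:
        return 2 * self.carbon_number + 2 - 2 * self.double_bonds

    @property
    def all_trans(self) -> bool:
        return (
            self.double_bonds >= 1
            and self.geometry is not None
            and all(g == "trans" for g in self.geometry)
        )

    @property
    def all_cis(self) -> bool:
        return (
            self.double_bonds >= 1
            and self.geometry is not None
            and all(g == "cis" for g in self.geometry)
        )

    @property
    def label(self) -> str:
        """Field shorthand, e.g. ``C32:1`` or ``c-C32:1`` for all-cis."""
        prefix = ""
        if self.all_trans:
            prefix = "t-"
        elif self.all_cis:
            prefix = "c-"
        return f"{prefix}C{self.carbon_number}:{self.double_bonds}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class AdductDef:
    """One APCI ionization channel: a signed elemental offset on the neutral.

    ``delta_formula`` maps element symbol to a signed atom count added to
    the neutral molecule (e.g. ``{"H": -1}`` for [M-H]+).  All registry
    adducts are singly charged cations.
    """

    name: str
    delta_formula: Mapping[str, int]
    charge: int = 1
    source_solvent: str = ""

    def __post_init__(self) -> None:
        if self.charge != 1:
            raise ChemValidationError("only singly charged adducts are supported")
        object.__setattr__(self, "delta_formula", dict(self.delta_formula))

    @property
    def nominal_offset(self) -> int:
        return sum(
            n * (12 if el == "C" else 1) for el, n in self.delta_formula.items()
        )

    @property
    def monoisotopic_offset(self) -> float:
        # unrounded, so mass additivity and the alkane/alkene ion
        # degeneracy hold exactly
        return sum(
            n * (12.0 if el == "C" else MASS_H_MONO)
            for el, n in self.delta_formula.items()
        )


#: The seven adducts observed for hydrocarbons in positive-mode APCI with
#: hexane / isooctane / toluene mobile phases.
ADDUCT_REGISTRY: dict[str, AdductDef] = {
    a.name: a
    for a in [
        AdductDef("[M-H]+", {"H": -1}, source_solvent="any"),
        AdductDef("[M+H]+", {"H": 1}, source_solvent="any"),
        AdductDef("[M]+.", {}, source_solvent="toluene"),
        AdductDef("[M+C3H3]+", {"C": 3, "H": 3}, source_solvent="hexane"),
        AdductDef("[M+C4H9]+", {"C": 4, "H": 9}, source_solvent="isooctane"),
        AdductDef("[M+C6H13]+", {"C": 6, "H": 13}, source_solvent="hexane"),
        AdductDef("[M+C7H9]+", {"C": 7, "H": 9}, source_solvent="toluene"),
    ]
}

#: Aliases in the +N Da notation used in spectra prints.
_ADDUCT_ALIASES = {
    "[M-39]+": None,  # guard against typos; no negative solvent adducts
    "[M+39]+": "[M+C3H3]+",
    "[M+57]+": "[M+C4H9]+",
    "[M+85]+": "[M+C6H13]+",
    "[M+93]+": "[M+C7H9]+",
    "[M−H]+": "[M-H]+",
}

#: Channels summed for quantification: the reconstructed-ion chromatograms
#: are built from [M-H]+, [M]+., and [M+H]+ only.
QUANT_ADDUCTS: tuple[str, ...] = ("[M-H]+", "[M]+.", "[M+H]+")


def get_adduct(name: str) -> AdductDef:
    """Resolve an adduct by registry name or +N Da alias."""
    key = _ADDUCT_ALIASES.get(name) or name
    try:
        return ADDUCT_REGISTRY[key]
    except KeyError:
        raise KeyError(
            f"unknown adduct {name!r}; registered: {sorted(ADDUCT_REGISTRY)}"
        ) from None


def adduct_offset(name: str) -> tuple[int, float]:
    """Return (nominal Da, monoisotopic Da) mass offsets of an adduct."""
    a = get_adduct(name)
    return a.nominal_offset, a.monoisotopic_offset


def neutral_formula(species: HydrocarbonSpecies) -> dict[str, int]:
    """Elemental composition of the neutral: CN carbons, 2*CN+2-2*DB hydrogens."""
    return {"C": species.carbon_number, "H": species.hydrogen_count}


def _formula_mass(formula: Mapping[str, int], scale: MassScale) -> float:
    if scale == "nominal":
        return float(
            sum(n * (12 if el == "C" else 1) for el, n in formula.items())
        )
    if scale == "monoisotopic":
        return sum(
            n * (12.0 if el == "C" else MASS_H_MONO) for el, n in formula.items()
        )
    raise ValueError(f"unknown mass scale {scale!r}")


def neutral_mass(species: HydrocarbonSpecies, scale: MassScale = "nominal") -> float:
    """Mass of the neutral hydrocarbon in Da on the requested scale."""
    return _formula_mass(neutral_formula(species), scale)


def ion_mz(
    species: HydrocarbonSpecies,
    adduct: AdductDef | str,
    scale: MassScale = "nominal",
) -> float:
    """m/z of the singly charged (species, adduct) ion."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    if scale == "nominal":
        return neutral_mass(species, "nominal") + adduct.nominal_offset
    if scale == "monoisotopic":
        return neutral_mass(species, "monoisotopic") + adduct.monoisotopic_offset
    raise ValueError(f"unknown mass scale {scale!r}")


def ion_formula(species: HydrocarbonSpecies, adduct: AdductDef | str) -> dict[str, int]:
    """Elemental composition of the cation (charge carrier atoms included)."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    f = neutral_formula(species)
    for el, n in adduct.delta_formula.items():
        f[el] = f.get(el, 0) + n
        if f[el] < 0:
            raise ChemValidationError(
                f"adduct {adduct.name} removes more {el} than present"
            )
    return {el: n for el, n in f.items() if n}


@dataclass(frozen=True)
class IsotopePattern:
    """Isotopologue envelope: (m/z, relative intensity), base peak = 1."""

    entries: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        mzs = [mz for mz, _ in self.entries]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ChemValidationError("isotope m/z values must strictly increase")

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.entries])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([i for _, i in self.entries])


def isotope_pattern(
    formula: Mapping[str, int],
    n_peaks: int = 3,
    base_mz: float | None = None,
) -> IsotopePattern:
    """Isotope envelope of a CxHy formula by exhaustive binomial convolution.

    The abundance of the k-th isotopologue peak is the coefficient of the
    convolution of Binomial(nC, 0.0107) (one extra neutron per 13C) with
    Binomial(nH, 0.000115) (per 2H).  Intensities are normalized so the
    base (most intense) peak is 1.  Peaks are placed at
    ``base_mz + k * 1.00336``; the tiny 2H spacing difference (0.0029 Da)
    is far below the matching tolerance and is ignored.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    formula = {el: n for el, n in formula.items() if n}
    if not formula:
        raise ChemValidationError("empty formula")
    unknown = set(formula) - {"C", "H"}
    if unknown:
        raise ChemValidationError(f"unsupported elements: {sorted(unknown)}")
    nC = formula.get("C", 0)
    nH = formula.get("H", 0)

    dist = np.array([1.0])
    for n, p in ((nC, ABUNDANCE_13C), (nH, ABUNDANCE_2H)):
        if n:
            # binomial pmf over 0..n extra neutrons
            k = np.arange(n + 1)
            logpmf = (
                _log_binom(n, k) + k * np.log(p) + (n - k) * np.log1p(-p)
            )
            dist = np.convolve(dist, np.exp(logpmf))
    dist = dist[:n_peaks]
    dist = dist / dist.max()
    if base_mz is None:
        base_mz = _formula_mass(formula, "monoisotopic")
    entries = tuple(
        (base_mz + k * MASS_C13_DELTA, float(v)) for k, v in enumerate(dist)
    )
    return IsotopePattern(entries)


def _log_binom(n: int, k: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def monoisotopic_fraction(formula: Mapping[str, int], n_peaks: int = 3) -> float:
    """Share of the first ``n_peaks`` isotopologue intensities carried by M."""
    pat = isotope_pattern(formula, n_peaks=n_peaks)
    inten = pat.intensity
    return float(inten[0] / inten.sum())


def candidates_for_mz(
    mz: float,
    tolerance: float,
    adducts: Iterable[AdductDef | str],
    cn_range: tuple[int, int] = (20, 70),
    db_range: tuple[int, int] = (0, 3),
    scale: MassScale = "nominal",
) -> list[tuple[HydrocarbonSpecies, AdductDef, float]]:
    """Reverse lookup: all (species, adduct) whose ion m/z matches ``mz``.

    Rather than enumerating the full CN x DB grid, the carbon number is
    solved from the mass arithmetic for each (adduct, DB) pair and only
    neighbouring integers are checked; the result is identical to brute
    force.  Matches are sorted by absolute mass error, then fewer double
    bonds, then lower CN (deterministic ranking).

    Returns
    -------
    list of (species, adduct, mass_error)
        ``mass_error = ion_mz - mz`` in Da; every entry satisfies
        ``|mass_error| <= tolerance``.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    cn_lo, cn_hi = cn_range
    db_lo, db_hi = db_range
    if cn_lo > cn_hi or db_lo > db_hi:
        raise ValueError("empty CN or DB range")
    c_mass = 12.0
    h_mass = 1.0 if scale == "nominal" else MASS_H_MONO
    out: list[tuple[HydrocarbonSpecies, AdductDef, float]] = []
    for adduct in adducts:
        if isinstance(adduct, str):
            adduct = get_adduct(adduct)
        offset = (
            adduct.nominal_offset if scale == "nominal" else adduct.monoisotopic_offset
        )
        for db in range(db_lo, db_hi + 1):
            # neutral mass = CN*(12 + 2 h) + (2 - 2 db) h
            target = mz - offset - (2 - 2 * db) * h_mass
            cn_est = target / (c_mass + 2 * h_mass)
            for cn in {int(np.floor(cn_est)), int(np.ceil(cn_est))}:
                if not (cn_lo <= cn <= cn_hi) or db > (cn - 1) // 2:
                    continue
                sp = HydrocarbonSpecies(cn, db)
                err = ion_mz(sp, adduct, scale) - mz
                if abs(err) <= tolerance:
                    out.append((sp, adduct, err))
    out.sort(
        key=lambda t: (abs(t[2]), t[0].double_bonds, t[0].carbon_number, t[1].name)
    )
    return out
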