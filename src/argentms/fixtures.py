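"""Packaged reference tables, loaders, and report comparison utilities.

Three tables ship with the package as TSV under ``argentms/data``:

* ``table2`` — class apex retention times (minutes) of the most abundant
  peak per unsaturation class, for three solvent systems at 15/25/35 °C.
* ``table3`` — the 136-species cuticular hydrocarbon profile of the flesh
  fly *Neobellieria bullata* (peak number, Rt, CN:DB, relative peak area
  % within its double-bond class).
* ``table4`` — the 44-species profile of the cockroach *Periplaneta
  americana*, same schema.

Relative areas are *within-class* percentages: comparable only among
species with the same double-bond count, because APCI response rises
steeply with unsaturation.  Class shares (percent of total summed area
per double-bond class) are stored separately in ``class_shares.tsv``.

Loaders verify a stored SHA-256 digest of every file, validate every
CN:DB against the chemistry module, and check class-share and
within-class sums.  ``table4`` as printed carries duplicated and
disordered peak numbers; those printed identifiers are preserved in the
``printed_id`` column while loaders assign clean sequential ``row_id``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .chem import HydrocarbonSpecies

__all__ = [
    "ReportRow",
    "FixtureTable",
    "FixtureError",
    "load_fixture",
    "load_class_apexes",
    "class_counts",
    "compare_reports",
    "render_report",
]

_EXPECTED_ROWS = {"table3": 136, "table4": 44}
_SHARE_TOL = 0.1  # class shares must sum to 100 within this
_WITHIN_CLASS_TOL = 0.5  # printed within-class areas carry rounding error


class FixtureError(ValueError):
    """A packaged fixture failed its integrity or schema checks."""


@dataclass(frozen=True)
class ReportRow:
    """One line of a profile report: peak number, Rt, CN:DB, relative area."""

    peak_number: int
    rt: float
    cn: int
    db: int
    relative_area_pct: float
    printed_id: int | None = None
    geometry: str | None = None

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise FixtureError(f"rt must be > 0, got {self.rt}")
        if self.relative_area_pct <= 0:
            raise FixtureError(
                f"relative_area_pct must be > 0, got {self.relative_area_pct}"
            )
        HydrocarbonSpecies(self.cn, self.db)  # raises if CN:DB invalid

    @property
    def cn_db(self) -> tuple[int, int]:
        return (self.cn, self.db)

    @property
    def species(self) -> HydrocarbonSpecies:
        return HydrocarbonSpecies(self.cn, self.db)


@dataclass(frozen=True)
class FixtureTable:
    """A validated profile table plus its per-class area shares."""

    source: str
    rows: tuple[ReportRow, ...]
    class_shares: dict[int, float]

    def rows_in_class(self, db: int) -> list[ReportRow]:
        return [r for r in self.rows if r.db == db]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peak_number": [r.peak_number for r in self.rows],
                "printed_id": [r.printed_id for r in self.rows],
                "rt_min": [r.rt for r in self.rows],
                "cn": [r.cn for r in self.rows],
                "db": [r.db for r in self.rows],
                "rel_area_pct": [r.relative_area_pct for r in self.rows],
            }
        )


def _data_path(name: str):
    return resources.files("argentms").joinpath("data", name)


def _read_verified(name: str) -> bytes:
    raw = _data_path(name).read_bytes()
    digests = {}
    for line in _data_path("digests.sha256").read_text().splitlines():
        h, fn = line.split()
        digests[fn] = h
    got = hashlib.sha256(raw).hexdigest()
    if digests.get(name) != got:
        raise FixtureError(f"fixture {name} digest mismatch: {got}")
    return raw


def _read_tsv(name: str) -> pd.DataFrame:
    from io import BytesIO

    return pd.read_csv(BytesIO(_read_verified(name)), sep="\t")


def load_class_apexes(system: str = "III", temperature: float = 15) -> dict[int, float]:
    """Class apex retention times {DB class -> minutes} for one condition."""
    df = _read_tsv("table2.tsv")
    sel = df[(df.system == system) & (df.temp_c == temperature)]
    if sel.empty:
        known = sorted(set(zip(df.system, df.temp_c)))
        raise KeyError(f"no apexes for system {system!r} at {temperature} degC; known: {known}")
    return dict(zip(sel.db.astype(int), sel.rt_min.astype(float)))


def load_fixture(source: str) -> FixtureTable:
    """Load and validate a packaged profile table (``table3`` or ``table4``).

    For the class-apex table use :func:`load_class_apexes`.
    """
    if source not in _EXPECTED_ROWS:
        raise FixtureError(f"unknown fixture {source!r}; known: {sorted(_EXPECTED_ROWS)}")
    df = _read_tsv(f"{source}.tsv")
    if len(df) != _EXPECTED_ROWS[source]:
        raise FixtureError(
            f"{source}: expected {_EXPECTED_ROWS[source]} rows, found {len(df)}"
        )
    shares_df = _read_tsv("class_shares.tsv")
    shares = {
        int(r.db): float(r.share_pct)
        for r in shares_df[shares_df.source == source].itertuples()
    }
    total = sum(shares.values())
    if abs(total - 100.0) > _SHARE_TOL:
        raise FixtureError(f"{source}: class shares sum to {total}, not 100")
    rows = tuple(
        ReportRow(
            peak_number=i + 1,
            printed_id=int(r.printed_id),
            rt=float(r.rt_min),
            cn=int(r.cn),
            db=int(r.db),
            relative_area_pct=float(r.rel_area_pct),
            geometry="cis" if int(r.db) >= 1 else None,
        )
        for i, r in enumerate(df.itertuples())
    )
    for db in sorted({r.db for r in rows}):
        if db not in shares:
            raise FixtureError(f"{source}: class share missing for DB={db}")
        s = sum(r.relative_area_pct for r in rows if r.db == db)
        if abs(s - 100.0) > _WITHIN_CLASS_TOL:
            raise FixtureError(
                f"{source}: DB={db} areas sum to {s:.2f}, outside 100 +/- {_WITHIN_CLASS_TOL}"
            )
    return FixtureTable(source=source, rows=rows, class_shares=shares)


def class_counts(table: FixtureTable) -> dict[int, int]:
    """Row count per double-bond class (exhaustive partition of the rows)."""
    out: dict[int, int] = {}
    for r in table.rows:
        out[r.db] = out.get(r.db, 0) + 1
    return out


@dataclass
class ReportDiff:
    """Row-level diff between a produced report and a reference table."""

    matches: list[tuple[ReportRow, ReportRow, float]] = field(default_factory=list)
    missing: list[ReportRow] = field(default_factory=list)
    spurious: list[ReportRow] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.matches)

    def max_abs_area_delta(self) -> float:
        return max((abs(d) for *_, d in self.matches), default=0.0)


def _isomer_keyed(rows) -> dict[tuple[int, int, int], ReportRow]:
    """Key rows by (CN, DB, isomer rank), rank = elution order within CN:DB."""
    out: dict[tuple[int, int, int], ReportRow] = {}
    by_fam: dict[tuple[int, int], list[ReportRow]] = {}
    for r in rows:
        by_fam.setdefault(r.cn_db, []).append(r)
    for (cn, db), fam in by_fam.items():
        for i, r in enumerate(sorted(fam, key=lambda x: x.rt)):
            out[(cn, db, i)] = r
    return out


def compare_reports(
    produced: list[ReportRow],
    fixture: FixtureTable | list[ReportRow],
    rt_tol: float = float("inf"),
    area_tol: float = 2.0,
) -> ReportDiff:
    """Match produced rows to a reference by (CN:DB, within-family Rt order).

    ``rt_tol`` additionally requires matched retention times to agree within
    the given minutes (default: no Rt constraint, since simulated and
    printed time axes may use different gradient programs); ``area_tol``
    only labels which matches exceed the tolerance, it never unmatches.
    """
    ref_rows = fixture.rows if isinstance(fixture, FixtureTable) else fixture
    prod = _isomer_keyed(produced)
    ref = _isomer_keyed(ref_rows)
    diff = ReportDiff()
    for key, r_ref in ref.items():
        r_prod = prod.get(key)
        if r_prod is None or abs(r_prod.rt - r_ref.rt) > rt_tol:
            diff.missing.append(r_ref)
        else:
            delta = r_prod.relative_area_pct - r_ref.relative_area_pct
            diff.matches.append((r_prod, r_ref, delta))
    matched_prod = {id(p) for p, *_ in diff.matches}
    diff.spurious = [r for r in produced if id(r) not in matched_prod]
    return diff


def render_report(
    rows: list[ReportRow],
    class_shares: dict[int, float] | None = None,
) -> str:
    """Render rows in the printed table layout, grouped by double-bond class."""
    lines = ["Peak No.\tRt (min)\tCN:DB\tRelative Peak Area (%)"]
    for db in sorted({r.db for r in rows}):
        share = (
            f"\t{class_shares[db]:.1f}" if class_shares and db in class_shares else ""
        )
        lines.append(f"{db} double bond(s){share}")
        for r in sorted((r for r in rows if r.db == db), key=lambda x: x.rt):
            geo = f"{r.geometry[0]}-" if r.geometry in ("cis", "trans") else ""
            lines.append(
                f"{r.peak_number}\t{r.rt:.2f}\t{geo}{r.cn}:{r.db}\t"
                f"{r.relative_area_pct:.1f}"
            )
    return "\n".join(lines) + "\n"
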