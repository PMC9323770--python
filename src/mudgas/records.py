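"""Sample data model and detection-limit-aware table I/O.

Field gas samples carry two kinds of measurements: molecular composition
(mole percent of CH4, CO2 and the C2-C4 alkanes) and stable-isotope ratios
on the delta scale (per mil vs VPDB for carbon, VSMOW for hydrogen).
Both kinds are tri-state: a cell is either a measured number, *below
detection limit* (bdl — measured, but unquantifiable), or missing
(not measured at all).  "Below detection limit" is scientifically
informative — e.g. the absence of n-butane where propane is clearly being
consumed — so it is never coerced to zero or NaN.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "BDL",
    "Bdl",
    "GasComposition",
    "IsotopeValue",
    "SampleRecord",
    "TableDialect",
    "ColumnSummary",
    "read_sample_table",
    "write_sample_table",
    "merge_records",
    "summarize",
]


class Bdl:
    """Singleton marker for a below-detection-limit measurement."""

    _instance = None

    def __new__(cls) -> "Bdl":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "BDL"

    def __bool__(self) -> bool:
        return False


BDL = Bdl()

#: tri-state measurement: number | below-detection-limit | not measured
Measurement = float | Bdl | None

COMPOSITION_SPECIES = ("ch4", "co2", "c2h6", "c3h8", "i_c4h10", "n_c4h10")

# isotope column -> delta scale ("C" = d13C vs VPDB, "H" = dD vs VSMOW)
DEFAULT_ISOTOPE_SCALES: dict[str, str] = {
    "d13c_ch4": "C",
    "dd_ch4": "H",
    "d13c_co2": "C",
    "d13c_c2h6": "C",
    "d13c_c3h8": "C",
    "d13c_i_c4h10": "C",
    "d13c_n_c4h10": "C",
    "delta13c_central": "C",
    "d13c_central": "C",
    "d13c_terminal": "C",
}


def is_value(x: Measurement) -> bool:
    return isinstance(x, (int, float)) and not isinstance(x, bool)


@dataclass(frozen=True)
class GasComposition:
    """Molecular composition in mole percent (0-100), tri-state per species."""

    ch4: Measurement = None
    co2: Measurement = None
    c2h6: Measurement = None
    c3h8: Measurement = None
    i_c4h10: Measurement = None
    n_c4h10: Measurement = None

    def __post_init__(self) -> None:
        total = 0.0
        for name in COMPOSITION_SPECIES:
            v = getattr(self, name)
            if v is None or isinstance(v, Bdl):
                continue
            if not is_value(v) or not math.isfinite(v):
                raise ValueError(f"{name}: composition must be a finite number, got {v!r}")
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}: mole percent outside [0, 100]: {v}")
            total += v
        # bdl counts as 0 only here, in the closure check
        if total > 100.5:
            raise ValueError(f"composition sums to {total:.2f}% > 100.5% (rounding slack)")

    def get(self, species: str) -> Measurement:
        if species not in COMPOSITION_SPECIES:
            raise KeyError(species)
        return getattr(self, species)


@dataclass(frozen=True)
class IsotopeValue:
    """A delta-scale isotope ratio in per mil, with optional 1-sigma."""

    value: float
    sigma: float | None = None
    scale: str = "C"

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value <= -1000.0:
            raise ValueError(f"delta value must be finite and > -1000 permil, got {self.value}")
        if self.sigma is not None and self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.scale not in ("C", "H"):
            raise ValueError(f"scale must be 'C' or 'H', got {self.scale!r}")


@dataclass
class SampleRecord:
    """One field sample: id, site, optional temperature, composition, isotopes."""

    id: str
    site: str
    composition: GasComposition = field(default_factory=GasComposition)
    isotopes: dict[str, IsotopeValue | Bdl | None] = field(default_factory=dict)
    temperature: float | None = None

    def isotope_value(self, label: str) -> Measurement:
        """Return the delta value for a label, preserving bdl/missing state."""
        iv = self.isotopes.get(label)
        if iv is None or isinstance(iv, Bdl):
            return iv
        return iv.value


@dataclass(frozen=True)
class TableDialect:
    """How to parse/emit a delimited sample table."""

    delimiter: str = ","
    id_column: str = "sample"
    bdl_token: str = "bdl"
    missing_tokens: tuple[str, ...] = ("", "-", "na", "NA")
    site_prefixes: Mapping[str, str] = field(
        default_factory=lambda: {"G": "Gamou", "M": "Murono"}
    )
    isotope_scales: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ISOTOPE_SCALES)
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TableDialect":
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("delimiter", "id_column", "bdl_token"):
            if key in cfg:
                kwargs[key] = cfg[key]
        if "missing_tokens" in cfg:
            kwargs["missing_tokens"] = tuple(cfg["missing_tokens"])
        if "site_prefixes" in cfg:
            kwargs["site_prefixes"] = dict(cfg["site_prefixes"])
        if "isotope_scales" in cfg:
            kwargs["isotope_scales"] = dict(cfg["isotope_scales"])
        return cls(**kwargs)

    def site_for(self, sample_id: str) -> str:
        for prefix, site in self.site_prefixes.items():
            if sample_id.upper().startswith(prefix.upper()):
                return site
        return "unknown"


def _parse_cell(raw: str, dialect: TableDialect, row: str, col: str) -> Measurement:
    token = raw.strip()
    if token.lower() == dialect.bdl_token.lower():
        return BDL
    if token in dialect.missing_tokens:
        return None
    try:
        return float(token)
    except ValueError:
        raise ValueError(
            f"unparseable numeric cell {raw!r} at row {row!r}, column {col!r}"
        ) from None


def read_sample_table(
    path: str | Path, dialect: TableDialect | None = None
) -> list[SampleRecord]:
    """Read a delimited sample table into records.

    The header must name the id column; composition columns (mole %) and
    isotope columns (per mil) are recognised by name, unknown columns are
    ignored.  ``bdl`` cells become the below-detection-limit state, empty
    cells become missing.  Duplicate ids and unparseable numbers are errors.
    """
    dialect = dialect or TableDialect()
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        if reader.fieldnames is None or dialect.id_column not in reader.fieldnames:
            raise ValueError(f"{path}: header must name the id column {dialect.id_column!r}")
        known = set(COMPOSITION_SPECIES) | set(dialect.isotope_scales)
        measured = [c for c in reader.fieldnames if c in known]
        if not measured:
            raise ValueError(f"{path}: no recognised measurement columns in header")
        records: list[SampleRecord] = []
        seen: set[str] = set()
        for row in reader:
            sid = (row.get(dialect.id_column) or "").strip()
            if not sid:
                raise ValueError(f"{path}: empty sample id")
            if sid in seen:
                raise ValueError(f"{path}: duplicate sample id {sid!r}")
            seen.add(sid)
            comp_kwargs: dict[str, Measurement] = {}
            isotopes: dict[str, IsotopeValue | Bdl | None] = {}
            for col in measured:
                cell = _parse_cell(row.get(col, ""), dialect, sid, col)
                if col in COMPOSITION_SPECIES:
                    comp_kwargs[col] = cell
                else:
                    if is_value(cell):
                        isotopes[col] = IsotopeValue(
                            float(cell), scale=dialect.isotope_scales[col]
                        )
                    else:
                        isotopes[col] = cell
            temp = None
            if "temperature" in (reader.fieldnames or []):
                t = _parse_cell(row.get("temperature", ""), dialect, sid, "temperature")
                temp = t if is_value(t) else None
            records.append(
                SampleRecord(
                    id=sid,
                    site=dialect.site_for(sid),
                    composition=GasComposition(**comp_kwargs),
                    isotopes=isotopes,
                    temperature=temp,
                )
            )
    return records


def _format_cell(x: Measurement, dialect: TableDialect) -> str:
    if isinstance(x, Bdl):
        return dialect.bdl_token
    if x is None:
        return ""
    return repr(float(x))


def write_sample_table(
    records: Sequence[SampleRecord],
    path: str | Path,
    dialect: TableDialect | None = None,
) -> None:
    """Write records to CSV; round trips bit-for-bit, preserving bdl/missing."""
    dialect = dialect or TableDialect()
    comp_cols = [
        c
        for c in COMPOSITION_SPECIES
        if any(getattr(r.composition, c) is not None for r in records)
    ]
    iso_cols: list[str] = []
    for r in records:
        for k in r.isotopes:
            if k not in iso_cols:
                iso_cols.append(k)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow([dialect.id_column, *comp_cols, *iso_cols])
        for r in records:
            row = [r.id]
            row += [_format_cell(getattr(r.composition, c), dialect) for c in comp_cols]
            for k in iso_cols:
                row.append(_format_cell(r.isotope_value(k) if k in r.isotopes else None, dialect))
            writer.writerow(row)


def merge_records(
    a: Sequence[SampleRecord], b: Sequence[SampleRecord]
) -> list[SampleRecord]:
    """Merge two record collections by sample id (e.g. composition + isotopes)."""
    by_id = {r.id: r for r in a}
    out: list[SampleRecord] = []
    for r in a:
        out.append(r)
    for r in b:
        if r.id in by_id:
            tgt = by_id[r.id]
            comp_kwargs = {}
            for c in COMPOSITION_SPECIES:
                v = getattr(tgt.composition, c)
                w = getattr(r.composition, c)
                comp_kwargs[c] = v if v is not None else w
            tgt.composition = GasComposition(**comp_kwargs)
            merged = dict(tgt.isotopes)
            merged.update(r.isotopes)
            tgt.isotopes = merged
            if tgt.temperature is None:
                tgt.temperature = r.temperature
        else:
            out.append(r)
    return out


@dataclass(frozen=True)
class ColumnSummary:
    column: str
    n: int
    n_bdl: int
    n_missing: int
    min: float | None
    max: float | None
    mean: float | None

    @property
    def available(self) -> bool:
        return self.n > 0


def _iter_columns(records: Sequence[SampleRecord]) -> list[str]:
    cols = [
        c
        for c in COMPOSITION_SPECIES
        if any(getattr(r.composition, c) is not None for r in records)
    ]
    for r in records:
        for k in r.isotopes:
            if k not in cols:
                cols.append(k)
    return cols


def summarize(records: Sequence[SampleRecord]) -> dict[str, ColumnSummary]:
    """Per-column min/max/mean over *present* values.

    Below-detection-limit cells are excluded from the statistics but
    counted; a column that is entirely bdl/missing is marked unavailable
    (``min``/``max``/``mean`` = None), never reported as zero.
    """
    if not records:
        raise ValueError("summarize requires at least one record")
    out: dict[str, ColumnSummary] = {}
    for col in _iter_columns(records):
        values: list[float] = []
        n_bdl = n_missing = 0
        for r in records:
            if col in COMPOSITION_SPECIES:
                cell = r.composition.get(col)
            else:
                cell = r.isotope_value(col) if col in r.isotopes else None
            if isinstance(cell, Bdl):
                n_bdl += 1
            elif cell is None:
                n_missing += 1
            else:
                values.append(float(cell))
        if values:
            out[col] = ColumnSummary(
                col, len(values), n_bdl, n_missing,
                min(values), max(values), sum(values) / len(values),
            )
        else:
            out[col] = ColumnSummary(col, 0, n_bdl, n_missing, None, None, None)
    return out
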