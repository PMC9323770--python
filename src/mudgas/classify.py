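"""Conventional gas-source diagnostics and two-end-member mixing.

Two classic diagrams place a methane sample among genetic fields:
the Schoell diagram (dD vs d13C of methane) and the Bernard plot
(C1/(C2+C3) vs d13C).  Thermogenic methane is relatively 13C- and
D-enriched with abundant C2+ (low Bernard ratio); microbial methane is
13C-depleted with very high Bernard ratios.  A thermogenic gas whose C2+
has been stripped — e.g. by preferential anaerobic biodegradation — keeps
a thermogenic methane isotope signature but drifts to high Bernard
ratios; such samples are flagged "altered".

Field boundaries are configuration, not code (see data/source_fields.yaml);
classification is deterministic point-in-polygon with the first listed
field winning on boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml
from shapely.geometry import Point, Polygon

from .records import BDL, Bdl, GasComposition, Measurement, is_value

__all__ = [
    "SourceField",
    "SourceFieldSet",
    "EndMember",
    "load_source_fields",
    "bernard_ratio",
    "classify_schoell",
    "classify_bernard",
    "BernardCall",
    "mix",
]

UNCLASSIFIED = "mixed/unclassified"


@dataclass(frozen=True)
class SourceField:
    """A named genetic field: a simple polygon in diagram coordinates."""

    name: str
    polygon: Polygon

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError(f"field {self.name!r}: polygon must be simple with area > 0")

    def contains(self, x: float, y: float) -> bool:
        # covers() includes the boundary, so ties go to the first field listed
        return bool(self.polygon.covers(Point(x, y)))

    @property
    def x_span(self) -> tuple[float, float]:
        xs = [v[0] for v in self.polygon.exterior.coords]
        return min(xs), max(xs)


@dataclass(frozen=True)
class SourceFieldSet:
    schoell: tuple[SourceField, ...]
    bernard: tuple[SourceField, ...]


def _parse_fields(entries: Sequence[Mapping]) -> tuple[SourceField, ...]:
    return tuple(
        SourceField(e["name"], Polygon([tuple(v) for v in e["polygon"]])) for e in entries
    )


def load_source_fields(path: str | Path | None = None) -> SourceFieldSet:
    """Load genetic-field polygons from YAML (packaged defaults if no path)."""
    if path is None:
        path = Path(str(resources.files("mudgas").joinpath("data", "source_fields.yaml")))
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return SourceFieldSet(
        schoell=_parse_fields(cfg.get("schoell", [])),
        bernard=_parse_fields(cfg.get("bernard", [])),
    )


def bernard_ratio(comp: GasComposition) -> float | None:
    """C1/(C2+C3); None (undefined) when both C2 and C3 are bdl or the sum is 0."""
    c1 = comp.ch4
    if not is_value(c1):
        raise ValueError("bernard_ratio requires a measured CH4 fraction")
    c2, c3 = comp.c2h6, comp.c3h8
    if not is_value(c2) and not is_value(c3):
        return None
    denom = (float(c2) if is_value(c2) else 0.0) + (float(c3) if is_value(c3) else 0.0)
    if denom == 0.0:
        return None
    return float(c1) / denom


def classify_schoell(
    d13c_ch4: float, dd_ch4: float, fields: SourceFieldSet | None = None
) -> str:
    """Name of the Schoell genetic field containing the sample."""
    fields = fields or load_source_fields()
    for f in fields.schoell:
        if f.contains(d13c_ch4, dd_ch4):
            return f.name
    return UNCLASSIFIED


@dataclass(frozen=True)
class BernardCall:
    name: str
    altered: bool
    ratio: float | None


def classify_bernard(
    d13c_ch4: float,
    ratio: float | None,
    fields: SourceFieldSet | None = None,
    altered_threshold: float = 100.0,
) -> BernardCall:
    """Bernard-plot field label plus a C2+-depletion ("altered") flag.

    A sample whose methane d13C sits in the thermogenic band but whose
    C1/(C2+C3) ratio exceeds the threshold is thermogenic gas that lost
    C2+ hydrocarbons after generation — flagged altered.
    """
    fields = fields or load_source_fields()
    if ratio is None or ratio <= 0:
        return BernardCall(UNCLASSIFIED, False, ratio)
    y = math.log10(ratio)
    for f in fields.bernard:
        if f.contains(d13c_ch4, y):
            altered = f.name == "thermogenic" and ratio > altered_threshold
            return BernardCall(f.name, altered, ratio)
    # off-field in ratio only: fall back to the d13C band
    for f in fields.bernard:
        lo, hi = f.x_span
        if lo <= d13c_ch4 <= hi:
            altered = f.name == "thermogenic" and ratio > altered_threshold
            return BernardCall(f.name, altered, ratio)
    return BernardCall(UNCLASSIFIED, False, ratio)


@dataclass(frozen=True)
class EndMember:
    """A gas end member: composition (mole %) and per-species d13C (permil)."""

    name: str
    composition: GasComposition
    isotopes: Mapping[str, float] = field(default_factory=dict)


def mix(e1: EndMember, e2: EndMember, x: float) -> EndMember:
    """Concentration-weighted blend of two end members; x = fraction of e1.

    Species concentration: C = x*C1 + (1-x)*C2 (absent treated as 0);
    species delta: isotope-mass balance (x*C1*d1 + (1-x)*C2*d2)/C,
    undefined (omitted) when C = 0 or a contributing delta is unknown.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"mixing fraction must be in [0, 1], got {x}")
    comp_kwargs: dict[str, Measurement] = {}
    isotopes: dict[str, float] = {}
    from .records import COMPOSITION_SPECIES

    for sp in COMPOSITION_SPECIES:
        c1 = e1.composition.get(sp)
        c2 = e2.composition.get(sp)
        if not is_value(c1) and not is_value(c2):
            comp_kwargs[sp] = None  # absent in both -> absent in mix
            continue
        v1 = float(c1) if is_value(c1) else 0.0
        v2 = float(c2) if is_value(c2) else 0.0
        c = x * v1 + (1.0 - x) * v2
        comp_kwargs[sp] = c
        if c > 0.0:
            d1 = e1.isotopes.get(sp)
            d2 = e2.isotopes.get(sp)
            w1, w2 = x * v1, (1.0 - x) * v2
            if (w1 > 0 and d1 is None) or (w2 > 0 and d2 is None):
                continue  # contributing delta unknown -> mixture delta undefined
            isotopes[sp] = ((w1 * (d1 or 0.0)) + (w2 * (d2 or 0.0))) / c
    return EndMember(
        name=f"mix({e1.name}:{x:g}, {e2.name}:{1 - x:g})",
        composition=GasComposition(**comp_kwargs),
        isotopes=isotopes,
    )
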