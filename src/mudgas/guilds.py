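"""Metabolic-guild annotation of genus-level abundance tables.

Downstream of any 16S pipeline: this module consumes a finished
taxon-by-sample relative-abundance table (wide CSV/TSV in either
orientation, or long three-column format) and sums abundances into the
metabolic guilds relevant to seep hydrocarbon cycling — methanogens
(hydrogenotrophic / acetoclastic), anaerobic methanotrophs (ANME),
sulfate reducers, nitrate-reducing alkane oxidisers and iron reducers.
A small rule engine matches taxon names (bare genera or SILVA-style
lineage strings) against an editable YAML lookup.

`consistency_report` confronts the guild summary with the isotope-based
inferences: secondary methanogenesis needs methanogens to actually be
there, biodegradation needs a plausible C2+ oxidiser, and near-absent
ANME argues against anaerobic methane oxidation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .biodeg import SecondaryMethaneReport

__all__ = [
    "GuildRule",
    "GuildLookup",
    "GuildTable",
    "GuildSummary",
    "load_guild_lookup",
    "read_abundance_table",
    "annotate",
    "consistency_report",
]

GUILDS = (
    "hydrogenotrophic_methanogen",
    "acetoclastic_methanogen",
    "ANME",
    "sulfate_reducer",
    "nitrate_reducing_alkane_oxidizer",
    "iron_reducer",
    "other",
)

_RANK_PREFIX = {
    "d": "domain", "k": "domain", "p": "phylum", "c": "class",
    "o": "order", "f": "family", "g": "genus", "s": "species",
}
_RANK_SPECIFICITY = {
    "domain": 0, "phylum": 1, "class": 2, "order": 3,
    "family": 4, "genus": 5, "species": 6, "any": 3.5,
}


@dataclass(frozen=True)
class GuildRule:
    pattern: str
    rank: str  # genus | family | order | ... | any
    guild: str

    @property
    def specificity(self) -> float:
        return _RANK_SPECIFICITY.get(self.rank, 3.5)


@dataclass(frozen=True)
class GuildLookup:
    rules: tuple[GuildRule, ...]


def load_guild_lookup(path: str | Path | None = None) -> GuildLookup:
    """Load guild rules from YAML (packaged defaults when no path given)."""
    if path is None:
        path = Path(str(resources.files("mudgas").joinpath("data", "guild_lookup.yaml")))
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    rules = []
    for guild, entries in (cfg.get("guilds") or {}).items():
        for e in entries:
            rules.append(GuildRule(e["pattern"], e.get("rank", "any"), guild))
    return GuildLookup(tuple(rules))


def _lineage_tokens(taxon: str) -> dict[str, str]:
    """Split a taxon label into rank -> name tokens.

    SILVA-style prefixes (g__Geobacter) land at their rank; unprefixed
    tokens (bare genus names, plain lineages) land under 'any'.
    """
    tokens: dict[str, str] = {}
    free: list[str] = []
    for part in re.split(r"[;|]", taxon):
        part = part.strip()
        if not part:
            continue
        m = re.match(r"^([a-zA-Z])__(.*)$", part)
        if m and m.group(1).lower() in _RANK_PREFIX:
            tokens[_RANK_PREFIX[m.group(1).lower()]] = m.group(2).strip()
        else:
            free.append(part)
    if free:
        tokens["any"] = ";".join(free)
    return tokens


def _rule_matches(rule: GuildRule, tokens: Mapping[str, str]) -> bool:
    pat = rule.pattern.lower()
    if rule.rank == "any":
        return any(pat in tok.lower() for tok in tokens.values())
    tok = tokens.get(rule.rank)
    if tok is not None:
        return pat in tok.lower()
    # no token at the declared rank: fall back to unranked text
    free = tokens.get("any")
    return free is not None and pat in free.lower()


def assign_guild(taxon: str, lookup: GuildLookup) -> str:
    """Guild for one taxon; most specific matching rank wins.

    Two matching rules of equal specificity mapping to different guilds
    raise, demanding lookup disambiguation.
    """
    tokens = _lineage_tokens(taxon)
    hits = [r for r in lookup.rules if _rule_matches(r, tokens)]
    if not hits:
        return "other"
    best = max(r.specificity for r in hits)
    top = {r.guild for r in hits if r.specificity == best}
    if len(top) > 1:
        raise ValueError(
            f"taxon {taxon!r} matches rules of equal rank in different guilds "
            f"({sorted(top)}); disambiguate the lookup"
        )
    return next(iter(top))


@dataclass
class GuildTable:
    """Taxon x sample relative abundances plus the unit convention."""

    abundance: pd.DataFrame  # rows = taxa, columns = samples
    percent: bool

    def __post_init__(self) -> None:
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("abundances must be >= 0")
        limit = 100.5 if self.percent else 1.005
        sums = self.abundance.sum(axis=0)
        bad = sums[sums > limit]
        if len(bad):
            raise ValueError(f"per-sample abundance sums exceed {limit}: {dict(bad)}")


_LONG_COLUMNS = {"taxon", "sample", "abundance"}


def read_abundance_table(
    path: str | Path, lookup: GuildLookup | None = None
) -> GuildTable:
    """Read a CSV/TSV abundance table, auto-detecting layout and units.

    Wide tables may have taxa as rows or as columns (detected by matching
    the lookup patterns and lineage punctuation against both axes); long
    tables need columns named taxon/sample/abundance.
    """
    path = Path(path)
    lookup = lookup or load_guild_lookup()
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    cols_lower = {str(c).strip().lower() for c in df.columns}
    if _LONG_COLUMNS <= cols_lower:
        df.columns = [str(c).strip().lower() for c in df.columns]
        wide = df.pivot_table(
            index="taxon", columns="sample", values="abundance", aggfunc="sum", fill_value=0.0
        )
        wide.columns = [str(c) for c in wide.columns]
    else:
        wide = df.set_index(df.columns[0])
        wide.index = [str(i) for i in wide.index]
        wide.columns = [str(c) for c in wide.columns]
        if _looks_like_taxa(wide.columns, lookup) and not _looks_like_taxa(wide.index, lookup):
            wide = wide.T
    wide = wide.astype(float)
    percent = bool(wide.sum(axis=0).max() > 1.5)
    return GuildTable(wide, percent)


def _looks_like_taxa(labels: Sequence[str], lookup: GuildLookup | None) -> bool:
    score = 0
    for lab in labels:
        if "__" in lab or ";" in lab:
            score += 1
        elif lookup is not None and assign_guild_safe(lab, lookup) != "other":
            score += 1
    return score > 0


def assign_guild_safe(taxon: str, lookup: GuildLookup) -> str:
    try:
        return assign_guild(taxon, lookup)
    except ValueError:
        return "other"


@dataclass
class GuildSummary:
    """Per-sample summed abundance per guild, plus which taxa matched."""

    abundance: pd.DataFrame  # rows = guilds, columns = samples
    matched: dict[str, list[str]]
    percent: bool

    def present(self, guild: str, floor: float = 0.0) -> pd.Series:
        return self.abundance.loc[guild] > floor


def annotate(table: GuildTable, lookup: GuildLookup | None = None) -> GuildSummary:
    """Sum taxon abundances into guilds; unmatched taxa go to 'other'."""
    if table.abundance.empty:
        raise ValueError("abundance table is empty")
    lookup = lookup or load_guild_lookup()
    assignments = {taxon: assign_guild(taxon, lookup) for taxon in table.abundance.index}
    rows = pd.DataFrame(
        0.0, index=list(GUILDS), columns=table.abundance.columns, dtype=float
    )
    matched: dict[str, list[str]] = {g: [] for g in GUILDS}
    for taxon, guild in assignments.items():
        rows.loc[guild] += table.abundance.loc[taxon]
        matched[guild].append(taxon)
    for g in matched:
        matched[g].sort()
    return GuildSummary(rows, matched, table.percent)


@dataclass(frozen=True)
class ConsistencyReport:
    secondary_methanogenesis_support: str
    c2plus_oxidizer_candidates: tuple[str, ...]
    aom_note: str
    overlapping_samples: tuple[str, ...]
    warnings: tuple[str, ...] = ()


def consistency_report(
    summary: GuildSummary,
    indicator: SecondaryMethaneReport,
    biodegradation_detected: bool = True,
    biodeg_sample_ids: Sequence[str] | None = None,
    anme_minor_threshold: float = 0.9,
) -> ConsistencyReport:
    """Confront guild membership with the isotope-based inferences."""
    cols = list(summary.abundance.columns)
    if biodeg_sample_ids is not None:
        overlap = [c for c in cols if c in set(biodeg_sample_ids)]
        if not overlap:
            return ConsistencyReport(
                "indeterminate", (), "indeterminate", (),
                ("no overlapping samples between guild table and gas samples",),
            )
    else:
        overlap = cols

    ab = summary.abundance[overlap]
    methanogens = (
        ab.loc["hydrogenotrophic_methanogen"] + ab.loc["acetoclastic_methanogen"]
    )
    isotopes_ok = indicator.verdict.startswith("consistent")
    if isotopes_ok and (methanogens > 0).all():
        support = "yes"
    elif isotopes_ok:
        support = "isotope-only support"
    else:
        support = "no/indeterminate"

    oxidizer_guilds = (
        "sulfate_reducer", "nitrate_reducing_alkane_oxidizer", "iron_reducer"
    )
    candidates = tuple(
        g for g in oxidizer_guilds if biodegradation_detected and (ab.loc[g] > 0).any()
    )

    anme = ab.loc["ANME"]
    anme_pct = anme if summary.percent else anme * 100.0
    if (anme_pct < anme_minor_threshold).all():
        aom_note = (
            f"ANME below {anme_minor_threshold}% everywhere: anaerobic methane "
            "oxidation likely minor; oxidation limited to C2+ chains"
        )
    else:
        aom_note = "ANME present above the minor threshold in at least one sample"

    return ConsistencyReport(support, candidates, aom_note, tuple(overlap))
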