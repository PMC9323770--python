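"""Packaged Tokamachi mud-volcano fixtures (gas composition + isotope tables).

Seven samples from the Tokamachi area, Niigata, Japan: two from the Gamou
mud volcano (G-1, G-2) and five from Murono (one crater, four seeps;
M-1 ... M-5).  Values are transcribed from the published tables; ``bdl``
marks below-detection-limit cells, a dash/empty cell marks quantities that
could not be derived (M-3's position-specific values, where the central
offset itself is bdl).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .records import SampleRecord, TableDialect, merge_records, read_sample_table

__all__ = [
    "composition_table_path",
    "isotope_table_path",
    "load_composition",
    "load_isotopes",
    "load_tokamachi",
]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("mudgas").joinpath("data", name)))


def composition_table_path() -> Path:
    return _data_path("table1_composition.csv")


def isotope_table_path() -> Path:
    return _data_path("table2_isotopes.csv")


def load_composition(dialect: TableDialect | None = None) -> list[SampleRecord]:
    """The packaged chemical-composition table (mole %)."""
    return read_sample_table(composition_table_path(), dialect)


def load_isotopes(dialect: TableDialect | None = None) -> list[SampleRecord]:
    """The packaged bulk + position-specific isotope table (per mil)."""
    return read_sample_table(isotope_table_path(), dialect)


def load_tokamachi(dialect: TableDialect | None = None) -> list[SampleRecord]:
    """Both packaged tables merged into one record per sample."""
    return merge_records(load_composition(dialect), load_isotopes(dialect))
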