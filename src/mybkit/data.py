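"""Packaged fixture tables transcribed from the published family survey."""

from importlib import resources
from pathlib import Path

from .catalog import CatalogEntry, load_catalog
from .expression import ExpressionMatrix, load_fpkm_tsv


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged data table."""
    return Path(resources.files("mybkit").joinpath("data", name))


def load_table1_catalog() -> list[CatalogEntry]:
    """The 294-gene family catalog (gene id, position, strand, bHLH
    flag, coding exons, peptide length, MYB type, functional label)."""
    return load_catalog(fixture_path("table1_catalog.tsv"))


def load_table2_expression() -> ExpressionMatrix:
    """The 293-gene x 17-sample FPKM table (integer-rounded as printed)."""
    return load_fpkm_tsv(fixture_path("table2_expression.tsv"))
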