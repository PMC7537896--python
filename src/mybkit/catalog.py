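"""Gene-model parsing, structure statistics and the family catalog.

The catalog is the per-gene summary table of a MYB family survey: one
row per retained gene with its chromosomal position, strand,
bHLH-interaction flag, coding-exon count, peptide length, repeat-domain
type and functional (clade) assignment.  Helper statistics reproduce
the standard survey numbers: the exon-count histogram, the
chromosome distribution with placed/unplaced totals, and the share of
the family among background gene sets.

Pseudochromosomes are named ``Ma01``..``Ma11``; ``Ma00`` collects genes
on sequences without chromosomal assignment and sorts last.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import gffutils

from .errors import GFFParseError, MybkitError, ReconciliationError

CATALOG_COLUMNS = [
    "gene_id",
    "synonym",
    "start",
    "end",
    "strand",
    "bhlh_motif",
    "coding_exons",
    "peptide_length",
    "myb_type",
    "functional_assignment",
    "paralog_cluster",
]

#: Assignment-text patterns of the five flavonoid-related, potentially
#: bHLH-interacting clades (matched as substrings, in this order).
FLAVONOID_CLADE_PATTERNS = [
    ("repressors PP", "22"),
    ("proanthocyanidins", "25"),
    ("general flavonoid", "23"),
    ("flavonoid repressor", "27"),
    ("anthocyanins", "24"),
]


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Half-up rounded percentage, matching printed table precision."""
    if total <= 0:
        raise MybkitError("zero background for percentage")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )


def family_share(n_family: int, n_background: int, decimals: int = 2) -> float:
    """Share of the family among a background gene set, in percent."""
    return percent(n_family, n_background, decimals)


# ---------------------------------------------------------------------------
# gene models


@dataclass
class GeneModel:
    """One gene with its exon structure (1-based inclusive coordinates)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    peptide_length: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GFFParseError(f"{self.gene_id}: start > end")
        self.exons = sorted(self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


def parse_gff(source: str | Path, count_cds: bool = False) -> list[GeneModel]:
    """Parse gene models from GFF3 (gene/mRNA/exon/CDS hierarchy).

    One :class:`GeneModel` per gene; the exon count comes from the exon
    features of the primary (longest) transcript, or from its CDS
    features with ``count_cds``.  ``source`` may be a path or GFF text.
    """
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and "\t" not in source):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted internals
        raise GFFParseError(str(exc)) from exc

    feat_type = "CDS" if count_cds else "exon"
    models = []
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, featuretype="mRNA", level=1))
        if not transcripts:
            raise GFFParseError(f"gene {gene.id} has no mRNA child")
        best = None
        for t in transcripts:
            parts = [
                (f.start, f.end) for f in db.children(t, featuretype=feat_type)
            ]
            if not parts:
                raise GFFParseError(
                    f"transcript {t.id} has no {feat_type} features"
                )
            length = sum(e - s + 1 for s, e in parts)
            if best is None or length > best[0]:
                best = (length, parts)
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                exons=best[1],
            )
        )
    return models


# ---------------------------------------------------------------------------
# catalog entries


@dataclass
class CatalogEntry:
    """One row of the family catalog."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    bhlh_flag: bool
    n_exons: int
    peptide_length: int
    myb_type: str
    functional_assignment: str = ""
    synonym: str = ""
    paralog_cluster: bool = False

    @property
    def is_cdc5(self) -> bool:
        return self.myb_type == "2R" or self.functional_assignment == "CDC5"

    @property
    def placed(self) -> bool:
        return self.chrom != "Ma00"


def _chrom_rank(chrom: str) -> tuple[int, str]:
    # Ma01..Ma11 in order, the unplaced Ma00 bin last, anything else after
    if chrom == "Ma00":
        return (1, "")
    return (0, chrom)


def sort_catalog(entries: list[CatalogEntry]) -> list[CatalogEntry]:
    return sorted(entries, key=lambda e: (_chrom_rank(e.chrom), e.start))


def load_catalog(path: str | Path) -> list[CatalogEntry]:
    """Read a catalog TSV (columns as in :data:`CATALOG_COLUMNS`)."""
    lines = Path(path).read_text().rstrip("\n").split("\n")
    header = lines[0].split("\t")
    if header != CATALOG_COLUMNS:
        raise MybkitError(f"unexpected catalog columns: {header}")
    out = []
    for ln in lines[1:]:
        f = ln.split("\t")
        out.append(
            CatalogEntry(
                gene_id=f[0],
                synonym=f[1],
                chrom=f[0][:4],
                start=int(f[2]),
                end=int(f[3]),
                strand=f[4],
                bhlh_flag=f[5] == "+",
                n_exons=int(f[6]),
                peptide_length=int(f[7]),
                myb_type=f[8],
                functional_assignment=f[9],
                paralog_cluster=f[10] == "1",
            )
        )
    return out


def save_catalog(entries: list[CatalogEntry], path: str | Path | None = None) -> str:
    """Serialise a catalog in canonical order; returns the TSV text."""
    buf = io.StringIO()
    buf.write("\t".join(CATALOG_COLUMNS) + "\n")
    for e in sort_catalog(entries):
        buf.write(
            "\t".join(
                [
                    e.gene_id,
                    e.synonym,
                    str(e.start),
                    str(e.end),
                    e.strand,
                    "+" if e.bhlh_flag else "",
                    str(e.n_exons),
                    str(e.peptide_length),
                    e.myb_type,
                    e.functional_assignment,
                    "1" if e.paralog_cluster else "0",
                ]
            )
            + "\n"
        )
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# statistics


def exon_histogram(
    entries: list[CatalogEntry], type_filter: str | None = None
) -> dict[int, tuple[int, float]]:
    """Exon-count histogram ``count -> (n, percent)`` over the filtered set.

    Percentages use half-up rounding to one decimal, the precision of
    the printed survey numbers.
    """
    sel = [e for e in entries if type_filter is None or e.myb_type == type_filter]
    if not sel:
        return {}
    counts = Counter(e.n_exons for e in sel)
    total = len(sel)
    return {
        k: (v, percent(v, total)) for k, v in sorted(counts.items())
    }


def chromosome_distribution(entries: list[CatalogEntry]):
    """Per-chromosome counts plus placed/unplaced totals."""
    counts = Counter(e.chrom for e in entries)
    ordered = dict(sorted(counts.items(), key=lambda kv: _chrom_rank(kv[0])))
    unplaced = counts.get("Ma00", 0)
    return ordered, len(entries) - unplaced, unplaced


def bhlh_crosstab(entries: list[CatalogEntry]) -> dict[str, int]:
    """Cross-tabulate bHLH-flagged genes against the flavonoid-related
    clade labels; genes without an assignment count as ``unassigned``."""
    out: Counter = Counter()
    for e in entries:
        if not e.bhlh_flag:
            continue
        for pattern, clade in FLAVONOID_CLADE_PATTERNS:
            if pattern in e.functional_assignment:
                out[clade] += 1
                break
        else:
            out["unassigned" if not e.functional_assignment else "other"] += 1
    return dict(out)


def catalog_summary(entries: list[CatalogEntry]) -> dict:
    """All survey statistics of a catalog in one JSON-ready dict."""
    type_counts = Counter(
        "CDC5" if e.is_cdc5 else e.myb_type for e in entries
    )
    chrom_counts, placed, unplaced = chromosome_distribution(entries)
    hist = exon_histogram(entries, type_filter="R2R3")
    return {
        "n_total": len(entries),
        "type_counts": dict(type_counts),
        "chromosome_counts": chrom_counts,
        "n_placed": placed,
        "n_unplaced": unplaced,
        "r2r3_exon_histogram": {
            str(k): {"count": c, "percent": p} for k, (c, p) in hist.items()
        },
        "n_bhlh": sum(1 for e in entries if e.bhlh_flag),
        "bhlh_crosstab": bhlh_crosstab(entries),
    }


# ---------------------------------------------------------------------------
# assembly


def build_catalog(
    architectures: dict,
    motif_hits: dict,
    models: dict[str, GeneModel],
    clade_assignments: dict[str, str] | None = None,
    cdc5_ids: set[str] | frozenset = frozenset(),
) -> list[CatalogEntry]:
    """Assemble catalog entries from the per-stage results.

    Retained genes are those whose architecture has two or more repeats,
    plus any ids supplied as CDC5-like by external annotation (CDC5
    cannot be told from R2R3 by repeat count alone).  Missing gene
    models for retained ids raise a reconciliation error naming them.
    """
    clade_assignments = clade_assignments or {}
    retained = [
        pid
        for pid, arch in architectures.items()
        if arch.n_repeats >= 2 or pid in cdc5_ids
    ]
    missing = sorted(p for p in retained if p not in models)
    if missing:
        raise ReconciliationError(f"retained ids without gene model: {missing}")
    entries = []
    for pid in retained:
        arch = architectures[pid]
        model = models[pid]
        myb_type = "2R" if pid in cdc5_ids else arch.myb_type
        assignment = "CDC5" if pid in cdc5_ids else clade_assignments.get(pid, "")
        entries.append(
            CatalogEntry(
                gene_id=pid,
                chrom=model.chrom,
                start=model.start,
                end=model.end,
                strand=model.strand,
                bhlh_flag=bool(motif_hits.get(pid)),
                n_exons=model.n_exons,
                peptide_length=model.peptide_length,
                myb_type=myb_type,
                functional_assignment=assignment,
            )
        )
    return sort_catalog(entries)
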