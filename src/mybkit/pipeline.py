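"""End-to-end orchestration: scan -> motif -> tree/clades -> catalog -> express.

``run_all`` drives the stages over file inputs and writes per-stage TSVs
plus a versioned JSON summary with the survey statistics (per-type
counts, exon histogram, chromosome distribution, bHLH count and clade
cross-tab, expression breadth).  ``run_bundle`` is the in-memory
equivalent used on synthetic bundles, and ``summarize_fixtures``
computes the same summary from ready-made catalog/FPKM tables.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from . import __version__
from .catalog import (
    build_catalog,
    catalog_summary,
    load_catalog,
    parse_gff,
    save_catalog,
)
from .domain_scan import DEFAULT_MIN_SCORE_FRAC, scan_proteins
from .errors import StageError
from .expression import (
    DEFAULT_ORGAN_MAP,
    ExpressionMatrix,
    breadth_counts,
    classify_breadth,
    load_fpkm_tsv,
    organ_expressed_counts,
)
from .motif_scan import scan_motifs
from .phylo import (
    DEFAULT_BOOTSTRAP,
    DomainAlignmentSet,
    assign_clades,
    bootstrap_consensus,
    build_master_alignment,
    distances_from_alignment,
    nj_build,
)
from .profiles import RepeatProfile
from .synthetic import SyntheticBundle

SUMMARY_SCHEMA_VERSION = 1

log = logging.getLogger("mybkit")


@dataclass
class RunConfig:
    """Configuration surface of a full pipeline run."""

    proteins: Path | None = None
    gff: Path | None = None
    domains: Path | None = None
    labels: Path | None = None
    fpkm: Path | None = None
    from_catalog: Path | None = None
    outdir: Path = Path("mybkit_out")
    min_score_frac: float = DEFAULT_MIN_SCORE_FRAC
    bootstrap: int = DEFAULT_BOOTSTRAP
    seed: int = 0
    fpkm_threshold: float = 0.0
    organ_map: dict = field(default_factory=lambda: dict(DEFAULT_ORGAN_MAP))
    profile: RepeatProfile = field(default_factory=RepeatProfile)

    def __post_init__(self) -> None:
        if self.bootstrap < 1:
            raise StageError("config", "bootstrap B must be >= 1")
        for p in (
            self.proteins,
            self.gff,
            self.domains,
            self.labels,
            self.fpkm,
            self.from_catalog,
        ):
            if p is not None and not Path(p).exists():
                raise StageError("config", f"input path does not exist: {p}")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def read_labels(path: str | Path) -> dict[str, str]:
    out = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        sid, lab = ln.split("\t")
        out[sid] = lab
    return out


def _expression_summary(matrix: ExpressionMatrix, threshold: float) -> dict:
    classes = classify_breadth(matrix, threshold)
    organ = organ_expressed_counts(classes)
    return {
        "n_genes": len(classes),
        "breadth_counts": breadth_counts(classes),
        "organ_expressed": {
            k: {"count": c, "percent": p} for k, (c, p) in organ.items()
        },
        "leaf_exclusive": sorted(
            c.gene_id for c in classes if c.exclusive_organ == "leaf"
        ),
    }


def run_all(config: RunConfig) -> dict:
    """Run every configured stage; returns the summary dict.

    A stage failure aborts with the failing stage named; outputs of the
    completed stages are retained in ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "mybkit_version": __version__,
        "seed": config.seed,
        "parameters": {
            "min_score_frac": config.min_score_frac,
            "bootstrap": config.bootstrap,
            "fpkm_threshold": config.fpkm_threshold,
        },
    }

    architectures = motifs = models = None
    clade_map: dict[str, str] = {}

    if config.proteins is not None:
        try:
            log.info("stage scan: %s", config.proteins)
            prots = read_fasta(config.proteins)
            architectures = scan_proteins(
                prots, config.profile, config.min_score_frac
            )
            with open(out / "scan.tsv", "w") as fh:
                fh.write(
                    "protein_id\tn_repeats\tmyb_type\thit_start\thit_end\t"
                    "score\tanchor_matches\n"
                )
                for pid, arch in architectures.items():
                    fh.write(
                        f"{pid}\t{arch.n_repeats}\t{arch.myb_type}\t.\t.\t.\t.\n"
                    )
                    for h in arch.hits:
                        fh.write(
                            f"{pid}\t.\t.\t{h.start}\t{h.end}\t{h.score:g}\t"
                            f"{h.anchor_matches}\n"
                        )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("scan", str(exc)) from exc

        try:
            log.info("stage motif")
            motifs = scan_motifs(prots)
            with open(out / "motifs.tsv", "w") as fh:
                fh.write("protein_id\tstart\tend\tmatched\n")
                for pid, hits in motifs.items():
                    for h in hits:
                        fh.write(f"{pid}\t{h.start}\t{h.end}\t{h.matched}\n")
        except Exception as exc:
            raise StageError("motif", str(exc)) from exc

    if config.domains is not None and config.labels is not None:
        try:
            log.info("stage tree (B=%d, seed=%d)", config.bootstrap, config.seed)
            domains = read_fasta(config.domains)
            labels = read_labels(config.labels)
            roles = {
                sid: "reference" if sid in labels else "query" for sid in domains
            }
            aln_set = DomainAlignmentSet(domains, roles, labels)
            aligned = build_master_alignment(domains)
            tree = bootstrap_consensus(aligned, config.bootstrap, config.seed)
            (out / "tree.nwk").write_text(tree.newick() + "\n")
            assignments = assign_clades(tree, labels, aln_set.queries)
            with open(out / "clades.tsv", "w") as fh:
                fh.write("query_id\tclade\tsupport\n")
                for a in assignments:
                    fh.write(f"{a.query_id}\t{a.clade}\t{a.support:g}\n")
            clade_map = {a.query_id: a.clade for a in assignments}
            summary["n_tree_leaves"] = len(tree.leaves)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("tree", str(exc)) from exc

    entries = None
    if config.from_catalog is not None:
        entries = load_catalog(config.from_catalog)
    elif architectures is not None and config.gff is not None:
        try:
            log.info("stage catalog: %s", config.gff)
            models = {m.gene_id: m for m in parse_gff(Path(config.gff))}
            prots = read_fasta(config.proteins)
            for m in models.values():
                if m.gene_id in prots:
                    m.peptide_length = len(prots[m.gene_id])
            entries = build_catalog(
                architectures, motifs or {}, models, clade_map
            )
            save_catalog(entries, out / "catalog.tsv")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("catalog", str(exc)) from exc

    if entries is not None:
        summary["catalog"] = catalog_summary(entries)

    if config.fpkm is not None:
        try:
            log.info("stage express: %s", config.fpkm)
            matrix = load_fpkm_tsv(config.fpkm, config.organ_map)
            summary["expression"] = _expression_summary(
                matrix, config.fpkm_threshold
            )
        except Exception as exc:
            raise StageError("express", str(exc)) from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def run_bundle(bundle: SyntheticBundle, outdir: str | Path, seed: int = 0,
               bootstrap: int = 100) -> dict:
    """Run the full pipeline on an in-memory synthetic bundle."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.write(out / "inputs")
    from .expression import fpkm as fpkm_compute

    matrix = fpkm_compute(bundle.counts, bundle.lengths, bundle.totals)
    fpkm_path = out / "inputs" / "fpkm.tsv"
    matrix.values.to_csv(fpkm_path, sep="\t", index_label="gene")
    cfg = RunConfig(
        proteins=out / "inputs" / "proteins.fasta",
        gff=out / "inputs" / "genes.gff3",
        domains=out / "inputs" / "domains.fasta",
        labels=out / "inputs" / "labels.tsv",
        fpkm=fpkm_path,
        outdir=out,
        seed=seed,
        bootstrap=bootstrap,
        profile=bundle.spec.profile,
    )
    return run_all(cfg)


def summarize_fixtures(catalog_path: Path, fpkm_path: Path,
                       fpkm_threshold: float = 0.0) -> dict:
    """Survey summary straight from ready catalog and FPKM tables."""
    entries = load_catalog(catalog_path)
    matrix = load_fpkm_tsv(fpkm_path)
    return {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "catalog": catalog_summary(entries),
        "expression": _expression_summary(matrix, fpkm_threshold),
    }
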