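"""Synthetic family generator with a planted-truth manifest.

Every pipeline stage is testable without any external download: the
generator emits proteins with 0-4 planted MYB repeats (copies of the
profile consensus, optionally mutated), planted bHLH-interaction
motifs, GFF3 gene models with 1-12 exons over the eleven
pseudochromosomes plus the unplaced ``Ma00`` bin, organ-structured
count matrices, and clade-structured domain sequences with labelled
references — together with a manifest recording exactly what was
planted, which serves as the oracle in round-trip tests.

Defaults mirror the observed family marginals: the exon-count
distribution has its mode at three exons, roughly 1% of genes land in
``Ma00``, about 10% of retained genes carry the bHLH motif, and the
per-organ expression probabilities follow the survey's organ-level
expression shares.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GenerationError
from .motif_scan import MOTIF_LEN
from .profiles import AMINO_ACIDS, RepeatProfile

CHROMOSOMES = tuple(f"Ma{i:02d}" for i in range(1, 12))

#: Exon-count distribution of the family survey (mode at 3 exons).
DEFAULT_EXON_DIST = {1: 7, 2: 23, 3: 155, 4: 67, 5: 21, 6: 8, 7: 2, 12: 2}

#: Per-organ expression probabilities for "some"-breadth genes, following
#: the survey's organ-level expressed-gene shares.
DEFAULT_ORGAN_PROBS = {
    "embryogenic": 0.44,
    "seedling": 0.334,
    "root": 0.754,
    "leaf": 0.693,
    "pulp": 0.713,
    "peel": 0.669,
}

DEFAULT_SAMPLES = (
    "embryogenic",
    "seedling",
    "root",
    "leaf",
    "young_leaf",
    "adult_leaf",
    "old_leaf",
    "pulp",
    "pulpS1",
    "pulpS2",
    "pulpS3",
    "pulpS4",
    "peel",
    "peelS1",
    "peelS2",
    "peelS3",
    "peelS4",
)

SAMPLE_ORGAN = {
    s: ("leaf" if "leaf" in s else "pulp" if "pulp" in s else "peel" if "peel" in s else s)
    for s in DEFAULT_SAMPLES
}

_REPEATS_PER_TYPE = {"none": 0, "1R": 1, "R2R3": 2, "3R": 3, "4R": 4}


@dataclass
class FamilySpec:
    """Tunable description of one synthetic MYB family."""

    n_genes: dict = field(
        default_factory=lambda: {"none": 5, "1R": 5, "R2R3": 30, "3R": 3, "4R": 2}
    )
    profile: RepeatProfile = field(default_factory=RepeatProfile)
    mutation_rate: float = 0.0  # per-residue mutation of planted repeats
    motif_fraction: float = 0.1  # P(retained gene carries a bHLH motif)
    exon_count_dist: dict = field(default_factory=lambda: dict(DEFAULT_EXON_DIST))
    unplaced_fraction: float = 3 / 294
    linker_range: tuple[int, int] = (20, 45)
    # clade structure of the domain set
    n_clades: int = 6
    refs_per_clade: int = 3
    n_lineage_clades: int = 1
    within_clade_divergence: float = 0.05
    between_clade_divergence: float = 0.3
    # expression
    p_none: float = 0.044
    p_all: float = 0.137
    organ_probs: dict = field(default_factory=lambda: dict(DEFAULT_ORGAN_PROBS))
    fpkm_log_mean: float = 1.5
    fpkm_log_sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for k, v in self.n_genes.items():
            if k not in _REPEATS_PER_TYPE:
                raise GenerationError(f"unknown myb_type {k!r}")
            if v < 0:
                raise GenerationError("n_genes must be >= 0")
        for p in (
            self.mutation_rate,
            self.motif_fraction,
            self.unplaced_fraction,
            self.p_none,
            self.p_all,
            *self.organ_probs.values(),
        ):
            if not 0 <= p <= 1:
                raise GenerationError(f"probability {p} outside [0, 1]")
        if self.p_none + self.p_all > 1:
            raise GenerationError("p_none + p_all must not exceed 1")
        if self.linker_range[0] < MOTIF_LEN:
            raise GenerationError(
                "linkers must be able to hold a motif "
                f"(min linker {self.linker_range[0]} < motif length {MOTIF_LEN})"
            )
        if not self.exon_count_dist or min(self.exon_count_dist) < 1:
            raise GenerationError("exon counts must be >= 1")


@dataclass
class SyntheticBundle:
    """Generated inputs plus the planted-truth manifest."""

    proteins: dict[str, str]
    gff3: str
    counts: pd.DataFrame
    lengths: pd.Series
    totals: pd.Series
    domains: dict[str, str]
    roles: dict[str, str]
    clade_labels: dict[str, str]
    manifest: dict
    spec: FamilySpec

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "proteins.fasta", "w") as fh:
            for pid, seq in self.proteins.items():
                fh.write(f">{pid}\n{seq}\n")
        (out / "genes.gff3").write_text(self.gff3)
        self.counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene")
        self.lengths.to_frame("length").to_csv(
            out / "lengths.tsv", sep="\t", index_label="gene"
        )
        self.totals.to_frame("total").to_csv(
            out / "totals.tsv", sep="\t", index_label="sample"
        )
        with open(out / "domains.fasta", "w") as fh:
            for sid, seq in self.domains.items():
                fh.write(f">{sid}\n{seq}\n")
        with open(out / "labels.tsv", "w") as fh:
            for sid, lab in self.clade_labels.items():
                fh.write(f"{sid}\t{lab}\n")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1))


def _rng(seed: int, stream: int) -> np.random.Generator:
    # named substreams: one master seed, fixed per-module stream indices
    return np.random.default_rng(np.random.SeedSequence((seed, stream)))


def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != out[i]]
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _make_motif(rng) -> str:
    """A 20-mer satisfying [D/E]Lx2[R/K]x3Lx6Lx3R."""
    x = lambda n: _random_seq(rng, n)
    return (
        ("D", "E")[rng.integers(0, 2)]
        + "L"
        + x(2)
        + ("R", "K")[rng.integers(0, 2)]
        + x(3)
        + "L"
        + x(6)
        + "L"
        + x(3)
        + "R"
    )


def generate(spec: FamilySpec) -> SyntheticBundle:
    """Generate a full synthetic bundle; deterministic for a fixed seed."""
    spec.validate()
    rng_seq = _rng(spec.seed, 0)
    rng_struct = _rng(spec.seed, 1)
    rng_expr = _rng(spec.seed, 2)
    rng_clade = _rng(spec.seed, 3)

    # ---- gene list with chromosome placement ------------------------------
    gene_types: list[str] = []
    for t in ("R2R3", "3R", "4R", "1R", "none"):
        gene_types += [t] * spec.n_genes.get(t, 0)
    n_total = len(gene_types)
    if n_total == 0:
        raise GenerationError("empty family specification")
    order = rng_struct.permutation(n_total)
    gene_types = [gene_types[i] for i in order]

    chrom_of: list[str] = []
    for _ in range(n_total):
        if rng_struct.random() < spec.unplaced_fraction:
            chrom_of.append("Ma00")
        else:
            chrom_of.append(CHROMOSOMES[rng_struct.integers(0, len(CHROMOSOMES))])
    per_chrom_counter: dict[str, int] = {}
    gene_ids = []
    for chrom in chrom_of:
        per_chrom_counter[chrom] = per_chrom_counter.get(chrom, 0) + 10
        gene_ids.append(f"{chrom}_g{per_chrom_counter[chrom]:05d}")

    exon_keys = sorted(spec.exon_count_dist)
    exon_p = np.array([spec.exon_count_dist[k] for k in exon_keys], dtype=float)
    exon_p /= exon_p.sum()

    manifest_genes: dict[str, dict] = {}
    proteins: dict[str, str] = {}

    # ---- proteins with planted repeats and motifs -------------------------
    lo, hi = spec.linker_range
    for gid, gtype in zip(gene_ids, gene_types):
        n_rep = _REPEATS_PER_TYPE[gtype]
        parts = []
        intervals = []
        pos = 0
        for r in range(n_rep):
            linker = _random_seq(rng_seq, int(rng_seq.integers(lo, hi + 1)))
            parts.append(linker)
            pos += len(linker)
            rep = _mutate(rng_seq, spec.profile.consensus, spec.mutation_rate)
            parts.append(rep)
            intervals.append([pos + 1, pos + len(rep)])  # 1-based inclusive
            pos += len(rep)
        tail = _random_seq(rng_seq, int(rng_seq.integers(lo, hi + 1)))
        parts.append(tail)
        pos += len(tail)
        if n_rep == 0:  # background protein long enough to scan
            extra = _random_seq(rng_seq, 120)
            parts.append(extra)
            pos += len(extra)

        motif_positions = []
        retained = n_rep >= 2
        seq = "".join(parts)
        if retained and rng_seq.random() < spec.motif_fraction:
            motif = _make_motif(rng_seq)
            # plant inside the C-terminal tail, never overlapping a repeat
            offset = int(rng_seq.integers(0, len(tail) - MOTIF_LEN + 1))
            abs0 = len(seq) - len(tail) + offset
            seq = seq[:abs0] + motif + seq[abs0 + MOTIF_LEN :]
            motif_positions.append(abs0 + 1)
        proteins[gid] = seq

        manifest_genes[gid] = {
            "myb_type": gtype,
            "n_repeats": n_rep,
            "repeats": intervals,
            "motif_positions": motif_positions,
            "retained": retained,
        }

    # ---- gene models ------------------------------------------------------
    gff_lines = ["##gff-version 3"]
    chrom_cursor: dict[str, int] = {}
    lengths = {}
    by_chrom: dict[str, list[str]] = {}
    for gid, chrom in zip(gene_ids, chrom_of):
        by_chrom.setdefault(chrom, []).append(gid)
    for chrom in sorted(by_chrom):
        for gid in by_chrom[chrom]:
            n_exons = int(exon_keys[rng_struct.choice(len(exon_keys), p=exon_p)])
            pep_len = len(proteins[gid])
            cds_total = 3 * (pep_len + 1)
            min_exon = 3
            if cds_total < n_exons * min_exon:
                n_exons = max(1, cds_total // min_exon)
            # split cds_total into n_exons parts of >= min_exon nt
            rem = cds_total - n_exons * min_exon
            extra_nt = rng_struct.multinomial(rem, [1 / n_exons] * n_exons)
            exon_lens = [min_exon + int(x) for x in extra_nt]
            start = chrom_cursor.get(chrom, 0) + int(
                rng_struct.integers(5_000, 50_000)
            )
            strand = "+-"[rng_struct.integers(0, 2)]
            exons = []
            cur = start
            for i, el in enumerate(exon_lens):
                exons.append((cur, cur + el - 1))
                cur += el + (
                    int(rng_struct.integers(80, 800)) if i < n_exons - 1 else 0
                )
            end = exons[-1][1]
            chrom_cursor[chrom] = end
            gff_lines.append(
                f"{chrom}\tmybkit\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}"
            )
            mid = f"{gid}.t1"
            gff_lines.append(
                f"{chrom}\tmybkit\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={mid};Parent={gid}"
            )
            for k, (s, e) in enumerate(exons, 1):
                gff_lines.append(
                    f"{chrom}\tmybkit\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                    f"ID={mid}.exon{k};Parent={mid}"
                )
                gff_lines.append(
                    f"{chrom}\tmybkit\tCDS\t{s}\t{e}\t.\t{strand}\t0\t"
                    f"ID={mid}.cds{k};Parent={mid}"
                )
            lengths[gid] = cds_total
            manifest_genes[gid].update(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "n_exons": len(exons),
                    "peptide_length": pep_len,
                }
            )
    gff3 = "\n".join(gff_lines) + "\n"

    # ---- expression -------------------------------------------------------
    samples = list(DEFAULT_SAMPLES)
    totals = pd.Series(
        rng_expr.integers(15_000_000, 30_000_000, size=len(samples)).astype(float),
        index=samples,
    )
    organ_samples: dict[str, list[str]] = {}
    for s in samples:
        organ_samples.setdefault(SAMPLE_ORGAN[s], []).append(s)

    counts = pd.DataFrame(0, index=gene_ids, columns=samples, dtype=int)
    for gid in gene_ids:
        u = rng_expr.random()
        if u < spec.p_none:
            breadth = "none"
            on = {s: False for s in samples}
        elif u < spec.p_none + spec.p_all:
            breadth = "all_samples"
            on = {s: True for s in samples}
        else:
            breadth = "some"
            on = {s: False for s in samples}
            for organ, members in organ_samples.items():
                if rng_expr.random() < spec.organ_probs[organ]:
                    k = int(rng_expr.integers(1, len(members) + 1))
                    idx = rng_expr.choice(len(members), size=k, replace=False)
                    for i in idx:
                        on[members[int(i)]] = True
            if not any(on.values()):  # force >= 1 expressed sample
                on[samples[int(rng_expr.integers(0, len(samples)))]] = True
            if all(on.values()):  # keep it strictly below all-sample breadth
                on[samples[int(rng_expr.integers(0, len(samples)))]] = False
        for s in samples:
            if on[s]:
                target_fpkm = float(
                    rng_expr.lognormal(spec.fpkm_log_mean, spec.fpkm_log_sigma)
                )
                c = round(target_fpkm * lengths[gid] * totals[s] / 1e9)
                counts.loc[gid, s] = max(1, int(c))
        organs = frozenset(
            org
            for org, members in organ_samples.items()
            if any(on[s] for s in members)
        )
        manifest_genes[gid].update(
            {"breadth": breadth, "organs_expressed": sorted(organs)}
        )

    # ---- clade-structured domains -----------------------------------------
    domains: dict[str, str] = {}
    roles: dict[str, str] = {}
    clade_labels: dict[str, str] = {}
    # clade ancestors diverge moderately from the shared repeat consensus,
    # members diverge slightly from their ancestor: clean clade separation
    n_all_clades = spec.n_clades + spec.n_lineage_clades
    ancestors = [
        _mutate(rng_clade, spec.profile.consensus, spec.between_clade_divergence)
        for _ in range(n_all_clades)
    ]
    for c in range(spec.n_clades):
        for r in range(spec.refs_per_clade):
            sid = f"REF{c + 1:02d}_{r + 1}"
            domains[sid] = _mutate(
                rng_clade, ancestors[c], spec.within_clade_divergence
            )
            roles[sid] = "reference"
            clade_labels[sid] = f"clade{c + 1}"
    retained_ids = [g for g in gene_ids if manifest_genes[g]["retained"]]
    for gid in retained_ids:
        c = int(rng_clade.integers(0, n_all_clades))
        domains[gid] = _mutate(rng_clade, ancestors[c], spec.within_clade_divergence)
        roles[gid] = "query"
        manifest_genes[gid]["clade"] = (
            f"clade{c + 1}" if c < spec.n_clades else "lineage-specific"
        )

    manifest = {
        "seed": spec.seed,
        "n_genes": dict(spec.n_genes),
        "samples": samples,
        "genes": manifest_genes,
    }
    return SyntheticBundle(
        proteins=proteins,
        gff3=gff3,
        counts=counts,
        lengths=pd.Series(lengths),
        totals=totals,
        domains=domains,
        roles=roles,
        clade_labels=clade_labels,
        manifest=manifest,
        spec=spec,
    )
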