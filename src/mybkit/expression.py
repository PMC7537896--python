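"""FPKM computation and expression-breadth classification.

Expression breadth summarises where in the plant a gene is detectably
transcribed.  Samples (17 in the survey design) are grouped into six
organ groups — embryogenic cell suspension, seedling, root, leaf, pulp
and peel — and a gene counts as expressed in an organ if any member
sample exceeds the FPKM threshold (default: strictly above 0).  Breadth
classes: ``all_samples`` (every sample expressed), ``none`` (no sample),
otherwise ``some``; a gene expressed in exactly one organ group is
additionally organ-exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, LookupError_, MybkitError

ORGAN_GROUPS = ("embryogenic", "seedling", "root", "leaf", "pulp", "peel")

#: Sample -> organ-group map of the 17-sample survey design.
DEFAULT_ORGAN_MAP = {
    "embryogenic": "embryogenic",
    "seedling": "seedling",
    "root": "root",
    "leaf": "leaf",
    "young_leaf": "leaf",
    "adult_leaf": "leaf",
    "old_leaf": "leaf",
    "pulp": "pulp",
    "pulpS1": "pulp",
    "pulpS2": "pulp",
    "pulpS3": "pulp",
    "pulpS4": "pulp",
    "peel": "peel",
    "peelS1": "peel",
    "peelS2": "peel",
    "peelS3": "peel",
    "peelS4": "peel",
}


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM values with a sample -> organ-group map."""

    values: pd.DataFrame  # index gene_id, columns sample_id
    organ_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ORGAN_MAP))

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise MybkitError("negative expression values")
        unmapped = [s for s in self.values.columns if s not in self.organ_map]
        if unmapped:
            raise ConfigurationError(f"samples without organ group: {unmapped}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def organ_samples(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.values.columns:
            out.setdefault(self.organ_map[s], []).append(s)
        return out


def fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    totals: pd.Series,
    organ_map: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped fragments.

    ``FPKM[g, s] = counts[g, s] * 1e9 / (lengths[g] * totals[s])`` with
    transcript lengths in nucleotides and per-sample mapped-fragment
    totals.  Invariant to scaling a sample's counts and total together.
    """
    lengths = lengths.reindex(counts.index)
    totals = totals.reindex(counts.columns)
    if lengths.isna().any() or (lengths <= 0).any():
        raise MybkitError("every gene needs a positive transcript length")
    bad = totals.index[totals.isna() | (totals <= 0)].tolist()
    if bad:
        raise MybkitError(f"samples with non-positive mapped totals: {bad}")
    vals = counts.astype(float) * 1e9
    vals = vals.div(lengths, axis=0).div(totals, axis=1)
    return ExpressionMatrix(vals, organ_map or dict(DEFAULT_ORGAN_MAP))


@dataclass(frozen=True)
class BreadthClass:
    """Expression-breadth call for one gene."""

    gene_id: str
    breadth: str  # all_samples | none | some
    organs_expressed: frozenset
    exclusive_organ: str = ""


def classify_breadth(
    m: ExpressionMatrix, threshold: float = 0.0
) -> list[BreadthClass]:
    """Classify every gene's expression breadth at an FPKM threshold.

    A sample is expressed iff its value is strictly greater than the
    threshold; an organ is expressed iff any member sample is.
    """
    if threshold < 0:
        raise ConfigurationError("threshold must be >= 0")
    organ_samples = m.organ_samples()
    expressed = m.values > threshold
    out = []
    for gid, row in expressed.iterrows():
        organs = frozenset(
            org for org, samples in organ_samples.items() if row[samples].any()
        )
        if row.all():
            breadth = "all_samples"
        elif not organs:
            breadth = "none"
        else:
            breadth = "some"
        exclusive = next(iter(organs)) if len(organs) == 1 else ""
        out.append(BreadthClass(gid, breadth, organs, exclusive))
    return out


def organ_expressed_counts(
    classes: list[BreadthClass],
) -> dict[str, tuple[int, float]]:
    """Per-organ expressed-gene counts with percent of total genes
    (half-up, one decimal)."""
    if not classes:
        raise MybkitError("no breadth classes given")
    total = len(classes)
    out = {}
    for organ in ORGAN_GROUPS:
        n = sum(1 for c in classes if organ in c.organs_expressed)
        pct = float(
            (Decimal(100) * Decimal(n) / Decimal(total)).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP
            )
        )
        out[organ] = (n, pct)
    return out


def organ_representative_counts(
    m: ExpressionMatrix, threshold: float = 0.0
) -> dict[str, tuple[int, float]]:
    """Per-organ expressed-gene counts using each organ's representative
    aggregate column (the sample named exactly like the organ group).

    The survey design carries both an aggregate column per organ
    ("pulp") and per-stage columns ("pulpS1".."pulpS4"); organ-level
    expressed-gene totals are computed on the aggregate column, while
    breadth/exclusivity pooling uses every member sample.
    """
    total = len(m.values.index)
    out = {}
    for organ in ORGAN_GROUPS:
        if organ not in m.values.columns:
            continue
        n = int((m.values[organ] > threshold).sum())
        pct = float(
            (Decimal(100) * Decimal(n) / Decimal(total)).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP
            )
        )
        out[organ] = (n, pct)
    return out


def breadth_counts(classes: list[BreadthClass]) -> dict[str, int]:
    """Counts of the breadth classes plus the >=1-sample total."""
    n_all = sum(1 for c in classes if c.breadth == "all_samples")
    n_none = sum(1 for c in classes if c.breadth == "none")
    return {
        "all_samples": n_all,
        "none": n_none,
        "some": len(classes) - n_all - n_none,
        "at_least_one": len(classes) - n_none,
    }


def compare_paralogs(
    m: ExpressionMatrix,
    pair: tuple[str, str],
    threshold: float = 0.0,
) -> dict[str, float]:
    """Profile similarity of a paralog pair.

    Reports the Pearson correlation of the log2(FPKM + 1) profiles and
    the Jaccard overlap of the expressed-organ sets.
    """
    a, b = pair
    for g in pair:
        if g not in m.values.index:
            raise LookupError_(f"gene {g!r} not in matrix")
    va = np.log2(m.values.loc[a].to_numpy(dtype=float) + 1)
    vb = np.log2(m.values.loc[b].to_numpy(dtype=float) + 1)
    if va.std() == 0 or vb.std() == 0:
        corr = float("nan")
    else:
        corr = float(np.corrcoef(va, vb)[0, 1])
    sub = ExpressionMatrix(m.values.loc[[a, b]], m.organ_map)
    ca, cb = classify_breadth(sub, threshold)
    union = ca.organs_expressed | cb.organs_expressed
    inter = ca.organs_expressed & cb.organs_expressed
    jaccard = len(inter) / len(union) if union else 1.0
    return {"pearson_log2": corr, "jaccard_organs": jaccard}


def load_fpkm_tsv(
    path: str | Path, organ_map: dict[str, str] | None = None
) -> ExpressionMatrix:
    """Read a ready FPKM table (genes x samples, first column gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, organ_map or dict(DEFAULT_ORGAN_MAP))
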