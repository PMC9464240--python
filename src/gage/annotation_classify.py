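"""Partition target counts by genomic annotation class.

Reproduces the classification-table view of a targets library: how many
candidate target windows (total and deduplicated) fall in unannotated vs
annotated regions, in coding-gene bodies, in CDS intervals, and in ncRNAs
(miRNA/rRNA/snRNA/tRNA), plus the fraction of coding genes whose CDS
contains at least one target.

Membership is by *containment*: an occurrence belongs to a class only if its
full window ``[start0, start0 + k)`` lies inside a single feature of that
class.  "Annotated" means contained in the merged union of coding-gene and
ncRNA intervals, so overlapping features are counted once; "unannotated" is
its complement.  Class rows other than that partition are not mutually
exclusive (a window can be in a CDS, its gene, and the annotated union at
once).
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .genome_io import Feature, NCRNA_TYPES
from .target_library import TargetLibrary

__all__ = [
    "ClassCounts",
    "ClassificationTable",
    "GeneCoverage",
    "CLASSES",
    "classify_targets",
    "gene_cds_coverage",
    "write_classification_tsv",
]

CLASSES = ("genome", "unannotated", "annotated", "coding_genes", "CDS", "ncRNA")


@dataclass
class ClassCounts:
    total: int = 0
    dedup: int = 0


@dataclass
class ClassificationTable:
    """Per-class occurrence totals, dedup counts and percentages of genome."""

    rows: dict[str, ClassCounts]

    @property
    def percentage(self) -> dict[str, float]:
        genome_total = self.rows["genome"].total
        if genome_total == 0:
            return {c: 0.0 for c in self.rows}
        return {c: self.rows[c].total / genome_total for c in self.rows}


@dataclass
class GeneCoverage:
    """Fraction of coding genes containing >=1 CDS-contained target window."""

    n_genes: int
    n_genes_with_cds_target: int

    @property
    def fraction(self) -> float | None:
        if self.n_genes == 0:
            return None
        return self.n_genes_with_cds_target / self.n_genes


def _merged_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _contained_in_merged(
    merged: list[tuple[int, int]], start: int, end: int
) -> bool:
    i = bisect.bisect_right(merged, (start, float("inf"))) - 1
    return i >= 0 and merged[i][1] >= end


def _contained_in_tree(tree: IntervalTree | None, start: int, end: int) -> bool:
    if tree is None:
        return False
    return any(iv.begin <= start and iv.end >= end for iv in tree.overlap(start, end))


def classify_targets(
    lib: TargetLibrary, features: Sequence[Feature]
) -> ClassificationTable:
    """Count target occurrences per annotation class.

    Per-class totals count occurrences; a deduplicated record counts toward a
    class if at least one of its occurrences lies in that class (so one
    record can contribute to several dedup columns).  Features on sequence
    ids absent from the library are ignored with a warning.
    """
    known = set(lib.seq_lengths) if lib.seq_lengths else None
    coding: dict[str, IntervalTree] = {}
    cds: dict[str, IntervalTree] = {}
    ncrna: dict[str, IntervalTree] = {}
    union_iv: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        if known is not None and f.seqid not in known:
            warnings.warn(
                f"feature on unknown sequence {f.seqid!r} ignored", stacklevel=2
            )
            continue
        if f.category == "coding_gene":
            coding.setdefault(f.seqid, IntervalTree()).addi(f.start0, f.end0)
            union_iv.setdefault(f.seqid, []).append((f.start0, f.end0))
        elif f.category == "CDS":
            cds.setdefault(f.seqid, IntervalTree()).addi(f.start0, f.end0)
        elif f.category in NCRNA_TYPES:
            ncrna.setdefault(f.seqid, IntervalTree()).addi(f.start0, f.end0)
            union_iv.setdefault(f.seqid, []).append((f.start0, f.end0))
    annotated = {s: _merged_intervals(ivs) for s, ivs in union_iv.items()}

    rows = {c: ClassCounts() for c in CLASSES}
    for rec in lib.records.values():
        member_of: set[str] = set()
        for occ in rec.occurrences:
            s, e = occ.start0, occ.start0 + lib.k
            classes = {"genome"}
            if _contained_in_merged(annotated.get(occ.seqid, []), s, e):
                classes.add("annotated")
            else:
                classes.add("unannotated")
            if _contained_in_tree(coding.get(occ.seqid), s, e):
                classes.add("coding_genes")
            if _contained_in_tree(cds.get(occ.seqid), s, e):
                classes.add("CDS")
            if _contained_in_tree(ncrna.get(occ.seqid), s, e):
                classes.add("ncRNA")
            for c in classes:
                rows[c].total += 1
            member_of |= classes
        for c in member_of:
            rows[c].dedup += 1
    return ClassificationTable(rows=rows)


def gene_cds_coverage(
    lib: TargetLibrary, features: Sequence[Feature]
) -> GeneCoverage:
    """A coding gene is covered iff some target window lies inside one of its CDSs."""
    genes = {
        f.gene_id for f in features if f.category == "coding_gene" and f.gene_id
    }
    cds_trees: dict[str, IntervalTree] = {}
    for f in features:
        if f.category == "CDS" and f.gene_id:
            cds_trees.setdefault(f.seqid, IntervalTree()).addi(
                f.start0, f.end0, f.gene_id
            )
    covered: set[str] = set()
    for rec in lib.records.values():
        for occ in rec.occurrences:
            tree = cds_trees.get(occ.seqid)
            if tree is None:
                continue
            s, e = occ.start0, occ.start0 + lib.k
            for iv in tree.overlap(s, e):
                if iv.begin <= s and iv.end >= e:
                    covered.add(iv.data)
    covered &= genes
    return GeneCoverage(n_genes=len(genes), n_genes_with_cds_target=len(covered))


def write_classification_tsv(table: ClassificationTable, path) -> None:
    pct = table.percentage
    with open(path, "wt") as fh:
        fh.write("#class\ttotal\tpercentage\tdeduplicated\n")
        for c in CLASSES:
            row = table.rows[c]
            fh.write(f"{c}\t{row.total}\t{pct[c]:.4f}\t{row.dedup}\n")
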