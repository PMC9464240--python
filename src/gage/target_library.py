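"""Genome-wide enumeration of candidate Cas12a target sequences.

A candidate *target* is a 25-mer genome window consisting of a 4-nt PAM and
a 21-nt protospacer.  Sliding a width-k window over each contig's forward
strand yields ``len - k + 1`` windows per contig; a window qualifies if its
first 4 nt match the forward PAM pattern (``TTTV`` for LbCas12a) or its last
4 nt match the reverse pattern.  Identical 25-mer strings are aggregated into
one deduplicated record with a copy number, exactly like a plain k-mer
counter restricted to PAM-bearing words.

Two PAM conventions are supported:

* ``paper`` (default): forward ``TTTV``, reverse ``VAAA`` — the published
  rule, matched literally on the forward-strand string.
* ``strict``: reverse pattern is the reverse complement of the forward one
  (``BAAA`` for ``TTTV``), i.e. a true opposite-strand TTTV site.

Note the published rule is *not* strand-symmetric: ``VAAA`` is not the reverse
complement of ``TTTV``.  Strand-mirror properties hold only in strict mode.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .genome_io import (
    ACGT,
    GenomeSet,
    Region,
    iupac_regex,
    matches_iupac,
    reverse_complement,
)

__all__ = [
    "PamPattern",
    "TargetOccurrence",
    "TargetRecord",
    "TargetLibrary",
    "NoTargetsError",
    "scan_targets",
    "density",
    "extract_region_targets",
    "build_region_library",
    "write_library_tsv",
    "read_library_tsv",
]

DEFAULT_K = 25


class NoTargetsError(ValueError):
    """Signals an operation that is undefined on an empty target library."""


@dataclass(frozen=True)
class PamPattern:
    """PAM matching rule: IUPAC forward pattern + reverse-end pattern.

    If ``reverse`` is not given it defaults to ``VAAA`` in ``paper`` mode
    (with the default ``TTTV`` forward pattern) and to
    ``reverse_complement(forward)`` in ``strict`` mode.
    """

    forward: str = "TTTV"
    reverse: str | None = None
    mode: str = "paper"

    def __post_init__(self) -> None:
        if self.mode not in ("paper", "strict"):
            raise ValueError(f"unknown PAM mode {self.mode!r}")
        fwd = self.forward.upper()
        object.__setattr__(self, "forward", fwd)
        rev = self.reverse
        if rev is None:
            if self.mode == "paper" and fwd == "TTTV":
                rev = "VAAA"
            else:
                rev = reverse_complement(fwd)
        rev = rev.upper()
        if self.mode == "strict" and rev != reverse_complement(fwd):
            raise ValueError(
                "strict mode requires reverse == reverse_complement(forward)"
            )
        if len(rev) != len(fwd):
            raise ValueError("forward and reverse PAM patterns differ in length")
        object.__setattr__(self, "reverse", rev)

    def __len__(self) -> int:
        return len(self.forward)


@dataclass
class TargetOccurrence:
    """One genomic placement of a target window (0-based window start)."""

    seqid: str
    start0: int
    orientation: str  # fwd | rev | both


@dataclass
class TargetRecord:
    """A deduplicated candidate target (one distinct 25-mer string).

    ``kmer`` is read on the scanned (forward) strand.  For ``fwd`` (and
    ``both``) orientation the PAM is the first 4 nt and the protospacer the
    remaining 21; for ``rev`` orientation both are read on the opposite
    strand: ``pam = revcomp(kmer[-4:])``, ``protospacer = revcomp(kmer[:21])``.
    """

    kmer: str
    pam: str
    protospacer: str
    orientation: str
    occurrences: list[TargetOccurrence] = field(default_factory=list)

    @property
    def copy_number(self) -> int:
        return len(self.occurrences)


@dataclass
class TargetLibrary:
    """All candidate targets of one genome, keyed by 25-mer string."""

    records: dict[str, TargetRecord]
    genome_length: int
    k: int
    pam: PamPattern
    seq_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(r.copy_number for r in self.records.values())

    @property
    def dedup_count(self) -> int:
        return len(self.records)

    @property
    def density_bp(self) -> float | None:
        """bp of genome per candidate target, or None for an empty library."""
        total = self.total_count
        return self.genome_length / total if total else None


def _pam_fields(kmer: str, orientation: str, pam: PamPattern) -> tuple[str, str]:
    plen = len(pam)
    if orientation in ("fwd", "both"):
        return kmer[:plen], kmer[plen:]
    return reverse_complement(kmer[-plen:]), reverse_complement(kmer[:-plen])


def scan_targets(
    genome: GenomeSet, k: int = DEFAULT_K, pam: PamPattern | None = None
) -> TargetLibrary:
    """Enumerate all PAM-bearing k-mers of a genome with copy numbers.

    Windows slide over each contig's forward strand independently (never
    spanning contig boundaries).  Windows containing any non-ACGT letter are
    skipped.  A window matching both the forward and reverse PAM rules is
    counted once, with orientation ``both``.  The genome length used for the
    density statistic is the raw assembly length, including skipped bases.
    """
    pam = pam if pam is not None else PamPattern()
    plen = len(pam)
    if k <= plen:
        raise ValueError(f"k ({k}) must exceed the PAM length ({plen})")
    for rec in genome:
        if len(rec) < k:
            raise ValueError(
                f"record {rec.id!r} is shorter ({len(rec)}) than k ({k})"
            )

    fwd_re = re.compile("(?=" + iupac_regex(pam.forward) + ")")
    rev_re = re.compile("(?=" + iupac_regex(pam.reverse) + ")")
    tail = k - plen

    records: dict[str, TargetRecord] = {}
    for rec in genome:
        seq = rec.seq
        n = len(seq)
        fwd_starts = {
            m.start() for m in fwd_re.finditer(seq) if m.start() + k <= n
        }
        rev_starts = {
            m.start() - tail
            for m in rev_re.finditer(seq)
            if m.start() - tail >= 0
        }
        for s in sorted(fwd_starts | rev_starts):
            kmer = seq[s : s + k]
            if set(kmer) - ACGT:
                continue
            if s in fwd_starts and s in rev_starts:
                orientation = "both"
            elif s in fwd_starts:
                orientation = "fwd"
            else:
                orientation = "rev"
            entry = records.get(kmer)
            if entry is None:
                pam_seq, proto = _pam_fields(kmer, orientation, pam)
                entry = records[kmer] = TargetRecord(
                    kmer=kmer,
                    pam=pam_seq,
                    protospacer=proto,
                    orientation=orientation,
                )
            entry.occurrences.append(TargetOccurrence(rec.id, s, orientation))

    return TargetLibrary(
        records=records,
        genome_length=genome.total_length,
        k=k,
        pam=pam,
        seq_lengths=genome.lengths,
    )


def density(lib: TargetLibrary) -> float:
    """Genome bp per candidate target (``L / total_count``)."""
    total = lib.total_count
    if total == 0:
        raise NoTargetsError("library contains no targets; density is undefined")
    return lib.genome_length / total


def extract_region_targets(
    lib: TargetLibrary, region: Region
) -> list[TargetRecord]:
    """Deduplicated records with >=1 occurrence window fully inside ``region``.

    Returned records keep their genome-wide copy number — a multi-copy
    barcode target (e.g. the ITS2 target) reports all its genomic copies even
    though only one lies in the region.  Records are ordered by their first
    in-region window position, then kmer.
    """
    if lib.seq_lengths:
        seq_len = lib.seq_lengths.get(region.seqid)
        if seq_len is None:
            raise ValueError(f"unknown sequence id {region.seqid!r}")
        if region.end0 > seq_len:
            raise ValueError(
                f"region [{region.start0}, {region.end0}) exceeds "
                f"{region.seqid!r} length {seq_len}"
            )
    hits: list[tuple[int, str, TargetRecord]] = []
    for rec in lib.records.values():
        pos = [
            o.start0
            for o in rec.occurrences
            if o.seqid == region.seqid
            and o.start0 >= region.start0
            and o.start0 + lib.k <= region.end0
        ]
        if pos:
            hits.append((min(pos), rec.kmer, rec))
    hits.sort(key=lambda t: (t[0], t[1]))
    return [rec for _, _, rec in hits]


def build_region_library(
    region_fasta: GenomeSet, k: int = DEFAULT_K, pam: PamPattern | None = None
) -> TargetLibrary:
    """Build a targets library directly from a region-only FASTA.

    Used when a whole-genome scan is impractical (e.g. the ITS2-only library
    for very large assemblies); identical to :func:`scan_targets` applied to
    the extracted sequence.
    """
    return scan_targets(region_fasta, k=k, pam=pam)


# --- TSV serialisation -------------------------------------------------------

_LIB_COLUMNS = (
    "kmer",
    "pam",
    "protospacer",
    "orientation",
    "copy_number",
    "occurrences",
)


def write_library_tsv(lib: TargetLibrary, path) -> None:
    """Write a library as TSV with a commented header and metadata lines."""
    path = Path(path)
    with open(path, "wt") as fh:
        fh.write("## gage target library\n")
        fh.write(f"## genome_length={lib.genome_length}\n")
        fh.write(f"## k={lib.k}\n")
        fh.write(f"## pam_forward={lib.pam.forward}\n")
        fh.write(f"## pam_reverse={lib.pam.reverse}\n")
        fh.write(f"## pam_mode={lib.pam.mode}\n")
        seq_lens = ",".join(f"{s}:{n}" for s, n in lib.seq_lengths.items())
        fh.write(f"## seq_lengths={seq_lens}\n")
        fh.write("#" + "\t".join(_LIB_COLUMNS) + "\n")
        for kmer in sorted(lib.records):
            rec = lib.records[kmer]
            occ = ";".join(
                f"{o.seqid}:{o.start0}:{o.orientation}" for o in rec.occurrences
            )
            fh.write(
                "\t".join(
                    (
                        rec.kmer,
                        rec.pam,
                        rec.protospacer,
                        rec.orientation,
                        str(rec.copy_number),
                        occ,
                    )
                )
                + "\n"
            )


def read_library_tsv(path) -> TargetLibrary:
    path = Path(path)
    meta: dict[str, str] = {}
    records: dict[str, TargetRecord] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                if "=" in line:
                    key, _, val = line[2:].strip().partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if line.startswith("#") or not line:
                continue
            kmer, pam_seq, proto, orientation, _copies, occ_str = line.split("\t")
            occurrences = []
            if occ_str:
                for part in occ_str.split(";"):
                    seqid, start0, orient = part.rsplit(":", 2)
                    occurrences.append(
                        TargetOccurrence(seqid, int(start0), orient)
                    )
            records[kmer] = TargetRecord(
                kmer=kmer,
                pam=pam_seq,
                protospacer=proto,
                orientation=orientation,
                occurrences=occurrences,
            )
    pam = PamPattern(
        forward=meta.get("pam_forward", "TTTV"),
        reverse=meta.get("pam_reverse"),
        mode=meta.get("pam_mode", "paper"),
    )
    seq_lengths: dict[str, int] = {}
    if meta.get("seq_lengths"):
        for part in meta["seq_lengths"].split(","):
            seqid, _, n = part.rpartition(":")
            seq_lengths[seqid] = int(n)
    return TargetLibrary(
        records=records,
        genome_length=int(meta.get("genome_length", 0)),
        k=int(meta.get("k", DEFAULT_K)),
        pam=pam,
        seq_lengths=seq_lengths,
    )
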