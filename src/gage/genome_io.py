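"""Input/output for genome-scale sequence data and fixed coordinate conventions.

Reads FASTA (optionally gzip-compressed), GFF3 annotation and BED regions,
and provides the sequence utilities the rest of the package builds on.

Coordinate convention
---------------------
Everything in memory is 0-based, half-open ``[start0, end0)``.  GFF3 files
(1-based, inclusive) are converted at the boundary; BED is native.  A feature
or region of length ``n`` therefore always satisfies ``end0 - start0 == n``.

Sequences are normalised to uppercase on input; soft-masked (lowercase)
regions are treated as ordinary sequence.  IUPAC ambiguity letters are kept
in the sequence but downstream scanners skip any window containing a
non-ACGT letter.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "GenomeSet",
    "Feature",
    "Region",
    "FastaFormatError",
    "Gff3FormatError",
    "BedFormatError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "read_bed",
    "reverse_complement",
    "iupac_set",
    "matches_iupac",
    "iupac_regex",
]

# Watson-Crick complement over the full IUPAC alphabet.
_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMPLEMENT_TABLE = str.maketrans(_COMPLEMENT)

#: IUPAC degenerate letter -> set of concrete bases it stands for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

ACGT = frozenset("ACGT")

#: ncRNA feature types tabulated by the annotation classifier.
NCRNA_TYPES = frozenset({"miRNA", "rRNA", "snRNA", "tRNA"})


class FastaFormatError(ValueError):
    """Raised for empty FASTA files or duplicate sequence identifiers."""


class Gff3FormatError(ValueError):
    """Raised for malformed GFF3 lines; the message carries the line number."""


class BedFormatError(ValueError):
    """Raised for malformed BED lines."""


@dataclass
class SequenceRecord:
    """One FASTA record: ``id`` is the first whitespace-delimited header token."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenomeSet:
    """An ordered collection of sequences that together form one assembly."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise FastaFormatError("a GenomeSet must contain at least one record")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise FastaFormatError("duplicate sequence ids in GenomeSet")
        self._by_id = {r.id: r for r in self.records}

    @property
    def total_length(self) -> int:
        """Total assembly length L in bp, including N/ambiguity bases."""
        return sum(len(r) for r in self.records)

    @property
    def lengths(self) -> dict[str, int]:
        return {r.id: len(r) for r in self.records}

    def __getitem__(self, seqid: str) -> SequenceRecord:
        return self._by_id[seqid]

    def __contains__(self, seqid: str) -> bool:
        return seqid in self._by_id

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class Feature:
    """A genome annotation interval (0-based half-open).

    ``category`` is the classification bucket derived deterministically from
    the GFF3 feature type and attributes: ``coding_gene`` for protein-coding
    gene bodies, ``CDS`` for coding intervals, one of miRNA/rRNA/snRNA/tRNA
    for the tabulated ncRNA classes, and ``other`` for everything else.
    """

    seqid: str
    start0: int
    end0: int
    strand: str
    ftype: str
    gene_id: str = ""
    category: str = "other"

    def __post_init__(self) -> None:
        if not (0 <= self.start0 < self.end0):
            raise ValueError(
                f"invalid feature interval [{self.start0}, {self.end0})"
            )

    def __len__(self) -> int:
        return self.end0 - self.start0


@dataclass
class Region:
    """A named genomic interval, e.g. the ITS2 barcode region."""

    seqid: str
    start0: int
    end0: int
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start0 < self.end0):
            raise ValueError(f"invalid region [{self.start0}, {self.end0})")

    def __len__(self) -> int:
        return self.end0 - self.start0


def reverse_complement(seq: str) -> str:
    """Reverse complement over the IUPAC alphabet (e.g. ``TTTV`` -> ``BAAA``)."""
    s = seq.upper()
    bad = set(s) - set(_COMPLEMENT)
    if bad:
        raise ValueError(f"illegal nucleotide character(s): {sorted(bad)}")
    return s.translate(_COMPLEMENT_TABLE)[::-1]


def iupac_set(letter: str) -> frozenset[str]:
    try:
        return IUPAC_SETS[letter.upper()]
    except KeyError:
        raise ValueError(f"unknown IUPAC letter {letter!r}") from None


def matches_iupac(pattern: str, s: str) -> bool:
    """True iff concrete string ``s`` matches the IUPAC ``pattern`` base-wise."""
    if len(pattern) != len(s):
        return False
    return all(c in iupac_set(p) for p, c in zip(pattern, s))


def iupac_regex(pattern: str) -> str:
    """Regex source matching the concrete (ACGT) expansions of ``pattern``."""
    parts = []
    for p in pattern.upper():
        bases = sorted(iupac_set(p))
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return "".join(parts)


def _open_text(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> GenomeSet:
    """Read a (possibly gzipped) FASTA file into a :class:`GenomeSet`.

    Sequences are uppercased; record ids are the first header token and the
    full header is preserved as ``description`` for output.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FastaFormatError(f"duplicate FASTA id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append(
                SequenceRecord(rec.id, str(rec.seq).upper(), rec.description)
            )
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return GenomeSet(records)


def write_fasta(genome: GenomeSet, path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "wt") as fh:
        for rec in genome:
            header = rec.description if rec.description else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _validate_gff3_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            if stripped.startswith("##FASTA"):
                break
            continue
        fields = stripped.split("\t")
        if len(fields) != 9:
            raise Gff3FormatError(
                f"GFF3 line {lineno}: expected 9 tab-separated fields, "
                f"got {len(fields)}"
            )
        try:
            start1, end1 = int(fields[3]), int(fields[4])
        except ValueError:
            raise Gff3FormatError(
                f"GFF3 line {lineno}: non-integer coordinates"
            ) from None
        if start1 < 1:
            raise Gff3FormatError(f"GFF3 line {lineno}: start < 1")
        if end1 < start1:
            raise Gff3FormatError(f"GFF3 line {lineno}: end < start")


def _gffutils_db(text: str):
    import gffutils

    return gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )


def _feature_id(f) -> str:
    vals = f.attributes.get("ID")
    return vals[0] if vals else (f.id or "")


def _gene_biotype(f) -> str:
    for key in ("gene_biotype", "biotype", "gene_type"):
        vals = f.attributes.get(key)
        if vals:
            return vals[0]
    return ""


def read_gff3(path) -> list[Feature]:
    """Parse GFF3 into :class:`Feature` objects with derived categories.

    1-based inclusive file coordinates are converted to 0-based half-open.
    A ``gene`` is ``coding_gene`` if its biotype is protein_coding or it has
    a CDS descendant; a ``CDS`` carries the ID of its ancestral gene (via any
    number of mRNA levels); miRNA/rRNA/snRNA/tRNA features (by type or gene
    biotype) take that category; everything else is ``other``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    _validate_gff3_lines(text)
    db = _gffutils_db(text)

    feats: list[Feature] = []
    for f in db.all_features():
        ftype = f.featuretype
        gid = ""
        if ftype == "CDS":
            category = "CDS"
            parents = list(db.parents(f, featuretype="gene"))
            if parents:
                gid = _feature_id(parents[0])
            else:
                vals = f.attributes.get("Parent")
                gid = vals[0] if vals else ""
        elif ftype in NCRNA_TYPES:
            category = ftype
            gid = _feature_id(f)
        elif ftype == "gene":
            gid = _feature_id(f)
            biotype = _gene_biotype(f)
            if biotype in NCRNA_TYPES:
                category = biotype
            elif biotype == "protein_coding" or next(
                db.children(f, featuretype="CDS"), None
            ) is not None:
                category = "coding_gene"
            else:
                category = "other"
        else:
            category = "other"
        feats.append(
            Feature(
                seqid=f.seqid,
                start0=f.start - 1,
                end0=f.end,
                strand=f.strand or ".",
                ftype=ftype,
                gene_id=gid,
                category=category,
            )
        )
    return feats


def read_bed(path) -> list[Region]:
    """Read 3- or 4-column BED into :class:`Region` objects (native 0-based)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    regions: list[Region] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            fields = stripped.split("\t")
            if len(fields) < 3:
                raise BedFormatError(
                    f"BED line {lineno}: expected at least 3 columns"
                )
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedFormatError(
                    f"BED line {lineno}: non-integer coordinates"
                ) from None
            name = fields[3] if len(fields) > 3 else f"region{len(regions) + 1}"
            if end0 <= start0:
                raise BedFormatError(f"BED line {lineno}: end <= start")
            regions.append(Region(fields[0], start0, end0, name))
    if not regions:
        raise BedFormatError(f"no regions found in {path}")
    return regions
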