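"""Seeded synthetic genomes, annotations and assay data with known ground truth.

Every other module of the package is exercised against data from this
generator: random background genomes with configurable base composition,
planted multi-copy targets and near-miss sites at controlled Hamming
distances, toy GFF3 annotations, divergent "adulterant" genomes, and
replicate fluorescence dilution ladders with a planted detection threshold.

Determinism: all randomness flows from the integer seed of each spec through
a named ``numpy.random.Generator``; identical spec + seed yields identical
sequences (and, via :func:`gage.genome_io.write_fasta`, identical files).

Collision checking: after assembly the finished genome is re-scanned with
the strict-mode off-target search; if the background accidentally contains
an exact or near-miss (<= max(3, planted mismatches)) copy of any planted
protospacer beyond the planted sites themselves, the background is
regenerated.  Truth tables are therefore exact, not merely probable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assay_detection import DEFAULT_TIMEPOINTS_MIN, FluorescenceSeries
from .genome_io import (
    ACGT,
    Feature,
    GenomeSet,
    SequenceRecord,
    matches_iupac,
    reverse_complement,
)
from .specificity import QueryTarget, find_offtargets
from .target_library import PamPattern

__all__ = [
    "GenerationError",
    "PlantedSite",
    "SyntheticGenomeSpec",
    "PlacedCopy",
    "GenomeTruth",
    "AnnotationTruth",
    "AssaySignalModel",
    "AssayTruth",
    "AT_RICH_BASE_FREQS",
    "DEFAULT_CONCENTRATIONS",
    "generate_genome",
    "generate_annotation",
    "generate_adulterant",
    "generate_assay_series",
    "write_assay_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: AT-rich composition preset (A, C, G, T) emulating plant nuclear genomes,
#: which pushes TTTV/VAAA PAM density toward the 18-30 bp range seen in
#: real assemblies.
AT_RICH_BASE_FREQS = (0.30, 0.185, 0.185, 0.33)

#: Ten-fold dilution ladder (ng/uL) of the reference sensitivity experiment.
DEFAULT_CONCENTRATIONS = (10.0, 1.0, 0.1, 0.01, 0.001, 0.0001)


class GenerationError(RuntimeError):
    """Raised when sites/features cannot be placed within bounded retries."""


@dataclass
class PlantedSite:
    """A target to embed in a synthetic genome.

    ``kmer`` must be a 25-mer whose *prefix* matches the forward PAM pattern
    (TTTV-type).  Reverse-strand sites are requested with orientation
    ``rev``, which embeds the reverse complement.  ``mutations_per_copy``
    Hamming edits are applied to protospacer positions only (never the PAM),
    so a planted copy lands in exactly that mismatch stratum of the
    off-target search.  Scalars broadcast over all copies; sequences give
    per-copy control.
    """

    kmer: str
    copies: int = 1
    mutations_per_copy: int | Sequence[int] = 0
    orientation: str | Sequence[str] = "fwd"

    def per_copy(self) -> list[tuple[int, str]]:
        muts = self.mutations_per_copy
        if isinstance(muts, int):
            muts = [muts] * self.copies
        orients = self.orientation
        if isinstance(orients, str):
            orients = [orients] * self.copies
        if len(muts) != self.copies or len(orients) != self.copies:
            raise ValueError("per-copy lists must match the copy count")
        for m in muts:
            if not 0 <= m <= 4:
                raise ValueError("mutations_per_copy must be in 0..4")
        for o in orients:
            if o not in ("fwd", "rev"):
                raise ValueError(f"unknown orientation {o!r}")
        return list(zip(muts, orients))


@dataclass
class SyntheticGenomeSpec:
    """Parameters of one synthetic genome draw."""

    length: int
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    n_contigs: int = 1
    planted: Sequence[PlantedSite] = ()

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.base_freqs)
        if len(freqs) != 4 or any(f < 0 for f in freqs) or not np.isclose(
            sum(freqs), 1.0
        ):
            raise ValueError("base_freqs must be 4 probabilities summing to 1")
        self.base_freqs = freqs
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if self.length < self.n_contigs * 25:
            raise ValueError("each contig must be at least one window long")


@dataclass
class PlacedCopy:
    """Ground truth for one embedded copy of a planted site.

    ``site_seq`` is the embedded 25-mer as it reads on the forward strand;
    for ``strand == '-'`` the biological site is its reverse complement.
    """

    kmer: str
    seqid: str
    start0: int
    strand: str  # + | -
    mismatches: int
    site_seq: str


@dataclass
class GenomeTruth:
    copies: list[PlacedCopy]
    contig_lengths: dict[str, int]

    def copies_of(self, kmer: str) -> list[PlacedCopy]:
        return [c for c in self.copies if c.kmer == kmer]


def _mutate_protospacer(
    kmer: str, n_mut: int, rng: np.random.Generator, pam_length: int = 4
) -> str:
    """Apply ``n_mut`` substitutions at distinct protospacer positions."""
    if n_mut == 0:
        return kmer
    positions = rng.choice(
        np.arange(pam_length, len(kmer)), size=n_mut, replace=False
    )
    chars = list(kmer)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def _proto_distance(site_seq: str, strand: str, proto: str, pam_length: int = 4) -> int:
    """Hamming distance between a placed site's protospacer reading and ``proto``."""
    reading = site_seq if strand == "+" else reverse_complement(site_seq)
    return sum(a != b for a, b in zip(reading[pam_length:], proto))


def _build_genome(
    spec: SyntheticGenomeSpec, rng: np.random.Generator, pam: PamPattern
) -> tuple[GenomeSet, GenomeTruth]:
    k = 25
    base = spec.length // spec.n_contigs
    lengths = [base] * spec.n_contigs
    lengths[0] += spec.length - base * spec.n_contigs
    names = [f"contig{i + 1}" for i in range(spec.n_contigs)]
    arrays = [
        _BASES[rng.choice(4, size=n, p=spec.base_freqs)] for n in lengths
    ]

    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(spec.n_contigs)}
    copies: list[PlacedCopy] = []
    weights = np.asarray(lengths, dtype=float) / sum(lengths)
    for site in spec.planted:
        kmer = site.kmer.upper()
        if len(kmer) != k or set(kmer) - ACGT:
            raise ValueError(f"planted kmer must be a concrete {k}-mer: {kmer!r}")
        if not matches_iupac(pam.forward, kmer[: len(pam)]):
            raise ValueError(
                f"planted kmer {kmer!r} must start with a {pam.forward} PAM"
            )
        for n_mut, orient in site.per_copy():
            mutated = _mutate_protospacer(kmer, n_mut, rng, len(pam))
            embedded = mutated if orient == "fwd" else reverse_complement(mutated)
            for _attempt in range(200):
                ci = int(rng.choice(spec.n_contigs, p=weights))
                if lengths[ci] < k:
                    continue
                pos = int(rng.integers(0, lengths[ci] - k + 1))
                if all(
                    pos + k <= s or pos >= e for s, e in occupied[ci]
                ):
                    break
            else:
                raise GenerationError(
                    "could not place planted sites without overlap"
                )
            occupied[ci].append((pos, pos + k))
            arrays[ci][pos : pos + k] = np.frombuffer(
                embedded.encode("ascii"), dtype=np.uint8
            )
            copies.append(
                PlacedCopy(
                    kmer=kmer,
                    seqid=names[ci],
                    start0=pos,
                    strand="+" if orient == "fwd" else "-",
                    mismatches=n_mut,
                    site_seq=embedded,
                )
            )

    records = [
        SequenceRecord(name, arr.tobytes().decode("ascii"))
        for name, arr in zip(names, arrays)
    ]
    return GenomeSet(records), GenomeTruth(
        copies=copies, contig_lengths=dict(zip(names, lengths))
    )


def _no_collisions(
    genome: GenomeSet, truth: GenomeTruth, pam: PamPattern
) -> bool:
    """True iff the off-target search finds exactly the planted copies."""
    if not truth.copies:
        return True
    max_mut = max(c.mismatches for c in truth.copies)
    mm_cap = max(3, max_mut)
    strict = PamPattern(forward=pam.forward, mode="strict")
    for kmer in sorted({c.kmer for c in truth.copies}):
        proto = kmer[len(pam) :]
        hits = find_offtargets(QueryTarget(proto, strict), genome, mm_cap)
        actual = {(h.seqid, h.start0, h.strand, h.mismatches) for h in hits}
        expected = set()
        for c in truth.copies:
            d = _proto_distance(c.site_seq, c.strand, proto, len(pam))
            if d <= mm_cap:
                expected.add((c.seqid, c.start0, c.strand, d))
        if actual != expected:
            return False
    return True


def generate_genome(
    spec: SyntheticGenomeSpec,
    pam: PamPattern | None = None,
    max_tries: int = 20,
) -> tuple[GenomeSet, GenomeTruth]:
    """Draw a background genome and embed the planted sites.

    Deterministic given ``spec`` (including its seed).  The returned truth
    table is verified against the genome: every planted copy is recoverable
    at its exact position, strand and mismatch stratum, and the background
    contains no accidental near-copies (see module docstring).
    """
    pam = pam if pam is not None else PamPattern()
    for attempt in range(max_tries):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(attempt,))
        )
        genome, truth = _build_genome(spec, rng, pam)
        if _no_collisions(genome, truth, pam):
            return genome, truth
    raise GenerationError(
        f"no collision-free genome found in {max_tries} attempts"
    )


# --- annotation --------------------------------------------------------------


@dataclass
class AnnotationTruth:
    features: list[Feature]
    gff3_text: str


def _place_interval(
    rng: np.random.Generator,
    contig_lengths: dict[str, int],
    occupied: dict[str, list[tuple[int, int]]],
    length: int,
    max_tries: int = 200,
) -> tuple[str, int]:
    names = list(contig_lengths)
    weights = np.asarray([contig_lengths[n] for n in names], dtype=float)
    weights /= weights.sum()
    for _ in range(max_tries):
        seqid = names[int(rng.choice(len(names), p=weights))]
        n = contig_lengths[seqid]
        if n < length:
            continue
        start = int(rng.integers(0, n - length + 1))
        if all(start + length <= s or start >= e for s, e in occupied[seqid]):
            occupied[seqid].append((start, start + length))
            return seqid, start
    raise GenerationError("could not place annotation features without overlap")


def generate_annotation(
    genome: GenomeSet,
    n_genes: int = 3,
    n_ncrna: int = 2,
    seed: int = 0,
) -> AnnotationTruth:
    """Toy GFF3: protein-coding genes (gene > mRNA > 1-3 CDS) and ncRNAs.

    Features never overlap.  The returned ``features`` list matches what
    :func:`gage.genome_io.read_gff3` yields on the emitted text (same
    coordinates and categories), so tests can use either interchangeably.
    """
    rng = np.random.default_rng(seed)
    contig_lengths = genome.lengths
    occupied: dict[str, list[tuple[int, int]]] = {s: [] for s in contig_lengths}

    features: list[Feature] = []
    lines = ["##gff-version 3"]
    for i in range(1, n_genes + 1):
        glen = int(rng.integers(600, 1501))
        seqid, gstart = _place_interval(rng, contig_lengths, occupied, glen)
        strand = "+" if rng.random() < 0.5 else "-"
        gid, mid = f"gene{i}", f"mrna{i}"
        lines.append(
            f"{seqid}\tgage_sim\tgene\t{gstart + 1}\t{gstart + glen}\t.\t"
            f"{strand}\t.\tID={gid};gene_biotype=protein_coding"
        )
        lines.append(
            f"{seqid}\tgage_sim\tmRNA\t{gstart + 1}\t{gstart + glen}\t.\t"
            f"{strand}\t.\tID={mid};Parent={gid}"
        )
        features.append(
            Feature(seqid, gstart, gstart + glen, strand, "gene", gid, "coding_gene")
        )
        features.append(
            Feature(seqid, gstart, gstart + glen, strand, "mRNA", "", "other")
        )
        n_cds = int(rng.integers(1, 4))
        chunk = glen // n_cds
        for j in range(n_cds):
            lo = gstart + j * chunk
            span = chunk if j < n_cds - 1 else glen - (n_cds - 1) * chunk
            clen = int(rng.integers(60, max(61, span - 20)))
            clen = min(clen, span)
            cstart = lo + int(rng.integers(0, span - clen + 1))
            lines.append(
                f"{seqid}\tgage_sim\tCDS\t{cstart + 1}\t{cstart + clen}\t.\t"
                f"{strand}\t{j % 3}\tID=cds{i}.{j + 1};Parent={mid}"
            )
            features.append(
                Feature(seqid, cstart, cstart + clen, strand, "CDS", gid, "CDS")
            )
    nc_types = ("miRNA", "rRNA", "snRNA", "tRNA")
    for i in range(1, n_ncrna + 1):
        ftype = nc_types[int(rng.integers(0, 4))]
        flen = int(rng.integers(60, 201))
        seqid, fstart = _place_interval(rng, contig_lengths, occupied, flen)
        strand = "+" if rng.random() < 0.5 else "-"
        nid = f"ncrna{i}"
        lines.append(
            f"{seqid}\tgage_sim\t{ftype}\t{fstart + 1}\t{fstart + flen}\t.\t"
            f"{strand}\t.\tID={nid}"
        )
        features.append(
            Feature(seqid, fstart, fstart + flen, strand, ftype, nid, ftype)
        )
    return AnnotationTruth(features=features, gff3_text="\n".join(lines) + "\n")


# --- adulterant genomes ------------------------------------------------------


def generate_adulterant(
    subject: GenomeSet, divergence: float, seed: int = 0
) -> GenomeSet:
    """Mutate the subject genome by i.i.d. per-base substitution.

    Each ACGT base is replaced, with probability ``divergence``, by one of
    the three other bases chosen uniformly.  Non-ACGT letters are left
    untouched.  This emulates an unrelated/related adulterant genome at a
    controlled nucleotide distance; no indels or rearrangements.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    code = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    records = []
    for rec in subject:
        arr = np.frombuffer(rec.seq.encode("ascii"), dtype=np.uint8).copy()
        idx = code[arr]
        is_acgt = idx != 255
        hit = is_acgt & (rng.random(arr.size) < divergence)
        shift = rng.integers(1, 4, size=arr.size)
        arr[hit] = _BASES[(idx[hit] + shift[hit]) % 4]
        records.append(SequenceRecord(rec.id, arr.tobytes().decode("ascii")))
    return GenomeSet(records)


# --- fluorescence assay ------------------------------------------------------


@dataclass
class AssaySignalModel:
    """Saturating-kinetics signal model for the dilution ladder.

    Plateau gap over background follows a Hill curve in substrate
    concentration c (ng/uL): ``gap(c) = f_max * c^h / (c^h + c_half^h)``;
    the time course rises as ``1 - exp(-t / tau_min)`` toward the plateau.
    Readings are the mean curve plus i.i.d. Gaussian noise (sd ``noise_sd``),
    clipped at zero.  Units are arbitrary fluorescence units (AU).
    """

    f_max: float = 3000.0
    c_half: float = 0.005
    hill: float = 2.0
    baseline: float = 300.0
    tau_min: float = 8.0
    noise_sd: float = 150.0

    def gap(self, concentration: float) -> float:
        if concentration <= 0:
            return 0.0
        ch = concentration**self.hill
        return self.f_max * ch / (ch + self.c_half**self.hill)

    def mean_curve(self, concentration: float, t_min: np.ndarray) -> np.ndarray:
        rise = 1.0 - np.exp(-np.asarray(t_min, dtype=float) / self.tau_min)
        return self.baseline + self.gap(concentration) * rise


@dataclass
class AssayTruth:
    planted_lod: float | None
    model: AssaySignalModel
    detect_at_min: float


def generate_assay_series(
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    model: AssaySignalModel | None = None,
    noise_sd: float | None = None,
    n_replicates: int = 3,
    seed: int = 0,
    timepoints_min: Sequence[float] = DEFAULT_TIMEPOINTS_MIN,
    detect_at_min: float = 25.0,
) -> tuple[list[FluorescenceSeries], FluorescenceSeries, AssayTruth]:
    """Simulate the dilution ladder plus negative control (CK).

    The planted detection threshold is the smallest ladder concentration
    whose expected gap over background at ``detect_at_min`` is at least six
    noise standard deviations (comfortably detectable with triplicates at
    alpha 0.01); concentrations below the threshold are required to sit
    within one noise sd of background, so the truth is unambiguous.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    model = model if model is not None else AssaySignalModel()
    if noise_sd is not None:
        model = AssaySignalModel(
            f_max=model.f_max,
            c_half=model.c_half,
            hill=model.hill,
            baseline=model.baseline,
            tau_min=model.tau_min,
            noise_sd=noise_sd,
        )
    concs = sorted((float(c) for c in concentrations), reverse=True)
    if any(c <= 0 for c in concs) or len(set(concs)) != len(concs):
        raise ValueError("concentrations must be positive and distinct")
    rng = np.random.default_rng(seed)
    t = np.asarray(timepoints_min, dtype=float)
    rise_at = 1.0 - np.exp(-detect_at_min / model.tau_min)

    def draw(label: str, conc: float) -> FluorescenceSeries:
        mean = model.mean_curve(conc, t)
        readings = np.clip(
            mean + rng.normal(0.0, model.noise_sd, size=(n_replicates, t.size)),
            0.0,
            None,
        )
        return FluorescenceSeries(
            group_label=label,
            timepoints_min=tuple(t),
            readings=readings,
            concentration=conc if conc > 0 else None,
        )

    groups = [draw(f"{c:g} ng/uL", c) for c in concs]
    control = draw("CK", 0.0)

    detectable = [
        c for c in concs if model.gap(c) * rise_at >= 6.0 * model.noise_sd
    ]
    planted_lod = min(detectable) if detectable else None
    if planted_lod is not None:
        below = [c for c in concs if c < planted_lod]
        if any(model.gap(c) * rise_at > model.noise_sd for c in below):
            raise GenerationError(
                "signal model does not separate the planted threshold: some "
                "sub-threshold concentration exceeds one noise sd"
            )
    truth = AssayTruth(
        planted_lod=planted_lod, model=model, detect_at_min=detect_at_min
    )
    return groups, control, truth


def write_assay_tsv(
    groups: Sequence[FluorescenceSeries], control: FluorescenceSeries, path
) -> None:
    """Write ladder + control in the long plate-TSV format."""
    with open(path, "wt") as fh:
        fh.write("#group\treplicate\ttimepoint_min\treading\n")
        for series in [*groups, control]:
            for r in range(series.n_replicates):
                for j, t in enumerate(series.timepoints_min):
                    fh.write(
                        f"{series.group_label}\t{r + 1}\t{t:g}\t"
                        f"{series.readings[r, j]:.3f}\n"
                    )
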