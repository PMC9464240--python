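"""crRNA assembly: direct repeat + spacer for a chosen target.

The Cas12a crRNA is the constant direct repeat (5') followed by the variable
spacer (3').  The spacer is the RNA transcript of the protospacer (same
sense, T -> U), so hybridisation to the target's non-protospacer strand is
implicit.  The default repeat is the 21-nt mature LbCas12a direct repeat;
it is configurable and recorded in all outputs, since vendor crRNA formats
differ (some ship longer precursor repeats).
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import reverse_complement
from .target_library import TargetRecord

__all__ = ["CrRNA", "DEFAULT_REPEAT_RNA", "extract_protospacer", "design_crrna"]

#: Mature LbCas12a direct repeat (21 nt).
DEFAULT_REPEAT_RNA = "UAAUUUCUACUAAGUGUAGAU"

_RNA_ALPHABET = frozenset("ACGU")


@dataclass(frozen=True)
class CrRNA:
    """An assembled CRISPR RNA: ``full = repeat_rna + spacer_rna``."""

    repeat_rna: str
    spacer_rna: str
    target_kmer: str = ""

    @property
    def full(self) -> str:
        return self.repeat_rna + self.spacer_rna


def extract_protospacer(t: TargetRecord, pam_length: int = 4) -> str:
    """Protospacer DNA of a target record.

    Forward-orientation targets are ``kmer[pam_length:]``; reverse ones read
    the opposite strand (``revcomp(kmer[:-pam_length])``); ``both`` defaults
    to the forward reading.
    """
    if len(t.kmer) <= pam_length:
        raise ValueError(f"kmer {t.kmer!r} is too short for PAM length {pam_length}")
    if t.orientation in ("fwd", "both"):
        return t.kmer[pam_length:]
    if t.orientation == "rev":
        return reverse_complement(t.kmer[:-pam_length])
    raise ValueError(f"unknown orientation {t.orientation!r}")


def design_crrna(
    t: TargetRecord, repeat_rna: str = DEFAULT_REPEAT_RNA, pam_length: int = 4
) -> CrRNA:
    """Assemble the crRNA for a target: repeat upstream of the transcribed spacer."""
    repeat = repeat_rna.upper()
    if not repeat or set(repeat) - _RNA_ALPHABET:
        raise ValueError("repeat must be a non-empty RNA string over {A,C,G,U}")
    spacer = extract_protospacer(t, pam_length).replace("T", "U")
    return CrRNA(repeat_rna=repeat, spacer_rna=spacer, target_kmer=t.kmer)
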