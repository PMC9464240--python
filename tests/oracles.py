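"""Independent brute-force oracles used to validate the package's scanners.

These deliberately share no code with the implementation: the target scan is
a per-window loop with explicit IUPAC set membership, the off-target search
is a position-by-position double-strand Hamming scan, and the permutation
test enumerates all label reassignments.  Keep them simple and slow.
"""

from __future__ import annotations

from itertools import combinations

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def _matches(pattern: str, s: str) -> bool:
    return len(pattern) == len(s) and all(
        c in _IUPAC[p] for p, c in zip(pattern, s)
    )


def scan_oracle(
    sequences: dict[str, str],
    k: int = 25,
    fwd_pattern: str = "TTTV",
    rev_pattern: str = "VAAA",
) -> list[tuple[str, int, str, str]]:
    """Every qualifying window as (seqid, start0, orientation, kmer)."""
    plen = len(fwd_pattern)
    out = []
    for seqid, seq in sequences.items():
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if any(c not in "ACGT" for c in w):
                continue
            f = _matches(fwd_pattern, w[:plen])
            r = _matches(rev_pattern, w[-plen:])
            if f and r:
                out.append((seqid, i, "both", w))
            elif f:
                out.append((seqid, i, "fwd", w))
            elif r:
                out.append((seqid, i, "rev", w))
    return out


def offtarget_oracle(
    protospacer: str,
    sequences: dict[str, str],
    max_mm: int,
    fwd_pattern: str = "TTTV",
    rev_pattern: str = "VAAA",
) -> list[tuple[str, int, str, int]]:
    """Brute-force hits as (seqid, start0, strand, mismatches).

    Forward sites: window prefix matches the forward PAM pattern, Hamming
    distance of the remaining positions to the protospacer <= max_mm.
    Reverse sites: window suffix matches the reverse-end pattern, distance
    measured on the reverse-complement reading.
    """
    plen = len(fwd_pattern)
    w = plen + len(protospacer)
    rc_proto = revcomp(protospacer)
    out = []
    for seqid, seq in sequences.items():
        for i in range(len(seq) - w + 1):
            site = seq[i : i + w]
            if _matches(fwd_pattern, site[:plen]):
                mm = sum(a != b for a, b in zip(site[plen:], protospacer))
                if mm <= max_mm:
                    out.append((seqid, i, "+", mm))
            if _matches(rev_pattern, site[-plen:]):
                mm = sum(a != b for a, b in zip(site[: w - plen], rc_proto))
                if mm <= max_mm:
                    out.append((seqid, i, "-", mm))
    return out


def permutation_pvalue(group: list[float], control: list[float]) -> float:
    """Exact two-sided permutation p-value on the difference of means."""
    pooled = list(group) + list(control)
    n_g = len(group)
    observed = abs(
        sum(group) / n_g - sum(control) / len(control)
    )
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n_g):
        g = [pooled[i] for i in idx]
        c = [pooled[i] for i in range(len(pooled)) if i not in idx]
        diff = abs(sum(g) / len(g) - sum(c) / len(c))
        if diff >= observed - 1e-12:
            count += 1
        total += 1
    return count / total
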