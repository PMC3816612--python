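"""Standard-genetic-code codon utilities and Nei-Gojobori (1986) counting.

The NG86 method classifies each of the three positions of a codon by the
fraction of its possible single-base changes that are synonymous, giving
per-codon synonymous (s) and nonsynonymous (n) site counts with s + n = 3.
Differences between a pair of codons are decomposed along all minimal
mutational pathways (orderings of the differing positions); pathways that
pass through a stop codon are excluded, and the synonymous/nonsynonymous
step counts are averaged over the remaining pathways.

Changes that create a stop codon are counted as nonsynonymous in the site
computation; this convention is shared by the simulator, which only ever
applies synonymous (sense-preserving) changes.
"""

from __future__ import annotations

import math
from functools import lru_cache
from itertools import permutations

from Bio.Data import CodonTable

BASES = "ACGT"

_table = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))


def translate_codon(codon: str) -> str:
    """Amino acid for a codon; ``*`` for a stop."""
    if codon in STOP_CODONS:
        return "*"
    try:
        return GENETIC_CODE[codon]
    except KeyError:
        raise ValueError(f"not an unambiguous codon: {codon!r}") from None


def translate_cds(cds: str) -> str:
    """Translate a CDS (length divisible by 3) to protein, ``*`` for stops."""
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    return "".join(translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3))


@lru_cache(maxsize=None)
def synonymous_changes(codon: str) -> tuple[tuple[int, str], ...]:
    """All (position, alternative base) single-base changes that preserve
    the encoded amino acid and do not create a stop codon."""
    aa = translate_codon(codon)
    out = []
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if mut not in STOP_CODONS and translate_codon(mut) == aa:
                out.append((pos, alt))
    return tuple(out)


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """NG86 synonymous and nonsynonymous site counts (s, n); s + n = 3."""
    s = len(synonymous_changes(codon)) / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """NG86 synonymous/nonsynonymous difference counts (sd, nd) for a codon
    pair, averaged over all minimal mutational pathways.

    Pathways with a stop-codon intermediate are discarded; if every pathway
    is discarded (possible only for 2-3 differences between particular
    codons) all pathways are used, counting steps into/out of stops as
    nonsynonymous.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        cur = codon_a
        sd = nd = 0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if (
                cur not in STOP_CODONS
                and nxt not in STOP_CODONS
                and translate_codon(cur) == translate_codon(nxt)
            ):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return float(sd), float(nd)

    paths = [p for o in permutations(diff) if (p := walk(o, False)) is not None]
    if not paths:
        paths = [walk(o, True) for o in permutations(diff)]
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def ng86_counts(cds_a: str, cds_b: str) -> tuple[float, float, float, float]:
    """Aggregate NG86 counts (S, N, Sd, Nd) over a gap-free codon alignment.

    S and N are the per-sequence site sums averaged over both sequences, so
    S + N = 3 x (number of codons).
    """
    if len(cds_a) != len(cds_b) or len(cds_a) % 3:
        raise ValueError("sequences must be equal length and divisible by 3")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = pair_differences(ca, cb)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; ``None`` when p >= 3/4 (undefined)."""
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]
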