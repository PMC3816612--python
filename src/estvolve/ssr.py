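"""Microsatellite (SSR) mining in the MISA tradition.

Scans sequences for maximal perfect tandem repeats of 2-6 bp units, with
per-unit-length minimum repeat counts (default: six repeats for
dinucleotides, five for tri- through hexa-nucleotides), merges nearby
motifs into compound SSRs, classifies units into strand-equivalence
(unit / reverse-complement) classes, and summarizes counts by nucleotide
type, repeat number and motif class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .codon import reverse_complement

#: minimum repeat count per unit length
DEFAULT_THRESHOLDS: dict[int, int] = {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

NT_TYPE = {2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass(frozen=True)
class SSRMotif:
    """A perfect tandem repeat (or a compound of several).

    Coordinates are 1-based inclusive on the given strand.
    """

    unigene_id: str
    start: int
    end: int
    unit: str
    repeats: int
    nt_type: str
    canonical_class: str
    in_compound: bool = False
    constituents: tuple["SSRMotif", ...] = field(default_factory=tuple)

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end

    @property
    def is_compound(self) -> bool:
        return self.nt_type == "compound"


def is_primitive(unit: str) -> bool:
    """True iff the unit is not itself a tandem repetition of a shorter unit."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def canonical_class(unit: str) -> str:
    """Strand-equivalence class label ``X/Y`` pairing a unit with its reverse
    complement, lexicographically smaller member first.

    Rotations are *not* collapsed: AG/CT and TC/GA are distinct classes.
    """
    if not (2 <= len(unit) <= 6) or any(b not in "ACGT" for b in unit):
        raise ValueError(f"invalid SSR unit: {unit!r}")
    rc = reverse_complement(unit)
    a, b = sorted((unit, rc))
    return f"{a}/{b}"


def scan_ssrs(
    sequence: str,
    unigene_id: str = "",
    thresholds: dict[int, int] | None = None,
) -> list[SSRMotif]:
    """Find every maximal perfect tandem repeat meeting its threshold.

    Runs are broken at any non-ACGT character (N included).  A reported run
    cannot be extended by one more full unit on either side, its unit is
    primitive, and no reported motif lies inside another reported motif with
    a shorter-or-equal unit.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    seq = sequence.upper()
    if any(c not in "ACGTN-" for c in seq):
        bad = sorted({c for c in seq if c not in "ACGTN-"})
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")

    motifs: list[SSRMotif] = []
    # split into pure-ACGT chunks, remembering offsets
    offset = 0
    for chunk in _chunks(seq):
        start, text = chunk
        motifs.extend(_scan_chunk(text, start, unigene_id, thresholds))
        offset = start + len(text)
    motifs.sort(key=lambda m: (m.start, m.end, len(m.unit)))
    return _suppress_contained(motifs)


def _chunks(seq: str) -> list[tuple[int, str]]:
    out = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] in "ACGT":
            j = i
            while j < n and seq[j] in "ACGT":
                j += 1
            out.append((i, seq[i:j]))
            i = j
        else:
            i += 1
    return out


def _scan_chunk(
    text: str, chunk_offset: int, unigene_id: str, thresholds: dict[int, int]
) -> list[SSRMotif]:
    found: list[SSRMotif] = []
    L = len(text)
    for k, min_rep in sorted(thresholds.items()):
        if L < k * min_rep:
            continue
        i = 0
        # maximal blocks of text[i] == text[i+k]
        while i + k < L:
            if text[i] != text[i + k]:
                i += 1
                continue
            a = i
            while i + k < L and text[i] == text[i + k]:
                i += 1
            run_len = (i - a) + k  # tandem region incl. first unit
            repeats = run_len // k
            unit = text[a : a + k]
            if repeats >= min_rep and is_primitive(unit):
                s = chunk_offset + a
                e = s + repeats * k  # half-open
                found.append(
                    SSRMotif(
                        unigene_id=unigene_id,
                        start=s + 1,
                        end=e,
                        unit=unit,
                        repeats=repeats,
                        nt_type=NT_TYPE[k],
                        canonical_class=canonical_class(unit),
                    )
                )
    return found


def _suppress_contained(motifs: list[SSRMotif]) -> list[SSRMotif]:
    keep = []
    for m in motifs:
        contained = any(
            o is not m
            and len(o.unit) <= len(m.unit)
            and o.start <= m.start
            and m.end <= o.end
            and (o.start, o.end, o.unit) != (m.start, m.end, m.unit)
            for o in motifs
        )
        if not contained:
            keep.append(m)
    return keep


def merge_compound(motifs: list[SSRMotif], max_gap: int = 100) -> list[SSRMotif]:
    """Merge runs of nearby motifs on the same sequence into compound SSRs.

    Consecutive motifs separated by at most ``max_gap`` intervening bases
    merge into a single compound record spanning all constituents; the
    constituents are retained, flagged ``in_compound``.  Use
    ``max_gap=float('inf')`` for the no-limit behavior.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out: list[SSRMotif] = []
    by_seq: dict[str, list[SSRMotif]] = {}
    for m in sorted(motifs, key=lambda m: (m.unigene_id, m.start, m.end)):
        by_seq.setdefault(m.unigene_id, []).append(m)
    for uid, ms in by_seq.items():
        group = [ms[0]]
        for m in ms[1:]:
            gap = m.start - group[-1].end - 1
            if gap <= max_gap:
                group.append(m)
            else:
                out.extend(_emit_group(group))
                group = [m]
        out.extend(_emit_group(group))
    out.sort(key=lambda m: (m.unigene_id, m.start, m.end))
    return out


def _emit_group(group: list[SSRMotif]) -> list[SSRMotif]:
    if len(group) == 1:
        return list(group)
    members = tuple(replace(m, in_compound=True) for m in group)
    compound = SSRMotif(
        unigene_id=group[0].unigene_id,
        start=group[0].start,
        end=max(m.end for m in group),
        unit="+".join(m.unit for m in group),
        repeats=0,
        nt_type="compound",
        canonical_class="+".join(m.canonical_class for m in group),
        constituents=members,
    )
    return [*members, compound]


def check_flanks(motif: SSRMotif, sequence: str, min_flank: int = 50) -> bool:
    """True iff at least ``min_flank`` non-N bases flank the motif on both
    sides (sufficiency for primer design)."""
    if min_flank < 0:
        raise ValueError("min_flank must be >= 0")
    if motif.start < 1 or motif.end > len(sequence):
        raise ValueError("motif span outside sequence")
    left = sequence[: motif.start - 1].upper()
    right = sequence[motif.end :].upper()
    count = lambda s: sum(1 for c in s if c in "ACGT")
    return count(left) >= min_flank and count(right) >= min_flank


@dataclass
class SSRSummary:
    by_nt_type: dict[str, int]
    by_repeat_count: dict[int, int]
    by_canonical_class: dict[str, int]
    n_total: int
    n_unigenes_with_ssr: int

    def share_pct(self, nt_type: str) -> float:
        """Percentage of all SSRs with the given nucleotide type."""
        return 100.0 * self.by_nt_type.get(nt_type, 0) / self.n_total

    def class_share_pct(self, cls: str) -> float:
        key = canonical_class(cls.split("/")[0]) if "/" in cls else canonical_class(cls)
        return 100.0 * self.by_canonical_class.get(key, 0) / self.n_total

    def repeat_share_pct(self, repeats: int) -> float:
        return 100.0 * self.by_repeat_count.get(repeats, 0) / self.n_total

    @classmethod
    def from_counts(
        cls,
        by_nt_type: dict[str, int],
        by_repeat_count: dict[int, int] | None = None,
        by_canonical_class: dict[str, int] | None = None,
        n_unigenes_with_ssr: int = 0,
    ) -> "SSRSummary":
        """Build a summary from already-tallied marginal counts (e.g. a
        published statistics table); the total is recomputed from the
        nucleotide-type margin."""
        return cls(
            by_nt_type=dict(by_nt_type),
            by_repeat_count=dict(by_repeat_count or {}),
            by_canonical_class=dict(by_canonical_class or {}),
            n_total=sum(by_nt_type.values()),
            n_unigenes_with_ssr=n_unigenes_with_ssr,
        )


def summarize_ssrs(motifs: list[SSRMotif]) -> SSRSummary:
    """Marginal counts in the style of an SSR statistics table.

    Compound SSRs replace their constituents in the totals: a motif flagged
    ``in_compound`` is not counted on its own.
    """
    counted = [m for m in motifs if not m.in_compound]
    by_type: dict[str, int] = {}
    by_rep: dict[int, int] = {}
    by_cls: dict[str, int] = {}
    for m in counted:
        by_type[m.nt_type] = by_type.get(m.nt_type, 0) + 1
        if not m.is_compound:
            by_rep[m.repeats] = by_rep.get(m.repeats, 0) + 1
            by_cls[m.canonical_class] = by_cls.get(m.canonical_class, 0) + 1
    return SSRSummary(
        by_nt_type=by_type,
        by_repeat_count=by_rep,
        by_canonical_class=by_cls,
        n_total=len(counted),
        n_unigenes_with_ssr=len({m.unigene_id for m in counted}),
    )
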