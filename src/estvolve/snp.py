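"""SNP discovery from multi-accession EST alignments.

A column of a per-unigene alignment yields a SNP for a pair of accessions
when each accession has at least 2x (non-N) coverage at the column, each is
internally monomorphic there, and the two accessions carry different
symbols.  A base/gap contrast is a single-base indel; gap columns that are
part of a longer gap run in the carrying accession are skipped.  Calls are
classified as transition (A<->G, C<->T), transversion (any other base pair)
or indel, and assembled into an accession x site genotype matrix, optionally
restricted to sites informative in every accession.

Leading and trailing gaps of an aligned read are alignment padding (the read
simply does not cover those columns) and are treated as missing data, unlike
internal gaps, which are real single-base deletions.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

logger = logging.getLogger(__name__)

MISSING = "?"

TRANSITIONS = (frozenset("AG"), frozenset("CT"))


def classify_snp(allele_pair: tuple[str, str]) -> str:
    """Classify an unordered allele pair as transition/transversion/indel."""
    a, b = allele_pair
    if a == b:
        raise ValueError(f"identical symbols in allele pair: {allele_pair}")
    valid = set("ACGT-")
    if a not in valid or b not in valid:
        raise ValueError(f"invalid allele symbols: {allele_pair}")
    if "-" in (a, b):
        return "indel"
    if frozenset((a, b)) in TRANSITIONS:
        return "transition"
    return "transversion"


@dataclass(frozen=True)
class AlignmentColumn:
    unigene_id: str
    column: int  # 1-based
    observations: dict[str, tuple[str, ...]]  # accession -> symbols (N excluded)


@dataclass(frozen=True)
class SNPSite:
    unigene_id: str
    column: int
    accession_alleles: dict[str, str]
    allele_pair: frozenset[str]
    snp_class: str

    @property
    def site_id(self) -> tuple[str, int]:
        return (self.unigene_id, self.column)


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    accession: str
    aligned: str  # gapped sequence over unigene coordinates


def columns_from_alignment(
    unigene_id: str, reads: list[ReadAlignment]
) -> list[AlignmentColumn]:
    """Build per-column accession observations from gap-padded reads.

    Terminal gap runs of each read are masked as missing; N observations are
    dropped.  Columns with no observation at all are still emitted (empty
    observation map) so that column indices stay aligned for indel-run
    checks.
    """
    if not reads:
        return []
    width = len(reads[0].aligned)
    if any(len(r.aligned) != width for r in reads):
        raise ValueError(f"ragged alignment for unigene {unigene_id}")
    masked = []
    for r in reads:
        s = r.aligned.upper()
        lead = len(s) - len(s.lstrip("-"))
        tail = len(s) - len(s.rstrip("-"))
        core = s[lead : width - tail] if width - tail > lead else ""
        masked.append((r.accession, lead, width - tail, core))
    columns = []
    for col in range(width):
        obs: dict[str, list[str]] = {}
        for acc, lead, stop, core in masked:
            if lead <= col < stop:
                sym = core[col - lead]
                if sym != "N":
                    obs.setdefault(acc, []).append(sym)
        columns.append(
            AlignmentColumn(
                unigene_id, col + 1, {a: tuple(v) for a, v in obs.items()}
            )
        )
    return columns


def call_snps(
    columns: list[AlignmentColumn],
    accession_pairs: list[tuple[str, str]] | None = None,
    min_coverage: int = 2,
) -> list[SNPSite]:
    """Call fixed inter-accession differences from alignment columns.

    Columns must belong to a single unigene and be consecutive (used for the
    longer-than-1-bp indel check).  One site is emitted per (column, allele
    pair), carrying the majority symbol of every accession with sufficient
    monomorphic coverage at the column.
    """
    if not columns:
        return []
    uid = columns[0].unigene_id
    by_col = {c.column: c for c in columns}
    sites: list[SNPSite] = []
    warned_empty = False
    for col_obj in columns:
        if not col_obj.observations:
            if not warned_empty:
                logger.warning(
                    "%s:%d has no usable (non-N) observations; skipping such columns",
                    uid, col_obj.column,
                )
                warned_empty = True
            continue
        alleles = _accession_alleles(col_obj, min_coverage)
        if not alleles:
            logger.debug("%s:%d no accession with usable coverage", uid, col_obj.column)
            continue
        pairs = accession_pairs or list(combinations(sorted(alleles), 2))
        emitted: set[frozenset[str]] = set()
        for p, q in pairs:
            if p not in alleles or q not in alleles:
                continue
            ap, aq = alleles[p], alleles[q]
            if ap == aq:
                continue
            pair = frozenset((ap, aq))
            if pair in emitted:
                continue
            if "-" in pair and _in_longer_gap_run(
                by_col, col_obj.column, p if ap == "-" else q, min_coverage
            ):
                continue
            emitted.add(pair)
            sites.append(
                SNPSite(
                    unigene_id=uid,
                    column=col_obj.column,
                    accession_alleles=dict(alleles),
                    allele_pair=pair,
                    snp_class=classify_snp(tuple(sorted(pair))),
                )
            )
    return sites


def _accession_alleles(
    col: AlignmentColumn, min_coverage: int
) -> dict[str, str]:
    """Majority symbol per accession, restricted to accessions with
    >= min_coverage observations that are internally monomorphic."""
    out = {}
    for acc, obs in col.observations.items():
        if len(obs) < min_coverage:
            continue
        counts = Counter(obs)
        if len(counts) > 1:
            logger.debug(
                "ambiguous accession %s at %s:%d (%s)",
                acc, col.unigene_id, col.column, dict(counts),
            )
            continue
        out[acc] = next(iter(counts))
    return out


def _in_longer_gap_run(
    by_col: dict[int, AlignmentColumn], column: int, gap_acc: str, min_coverage: int
) -> bool:
    """True if the gap-carrying accession is also fixed for a gap in an
    adjacent column (i.e. the deletion is longer than one base)."""
    for adj in (column - 1, column + 1):
        c = by_col.get(adj)
        if c is None:
            continue
        alleles = _accession_alleles(c, min_coverage)
        if alleles.get(gap_acc) == "-":
            return True
    return False


@dataclass
class GenotypeMatrix:
    accessions: list[str]
    sites: list[SNPSite]
    alleles: list[list[str]] = field(default_factory=list)  # site x accession

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def row(self, accession: str) -> list[str]:
        i = self.accessions.index(accession)
        return [r[i] for r in self.alleles]

    @property
    def is_complete(self) -> bool:
        return all(MISSING not in r for r in self.alleles)


def build_genotype_matrix(
    snps: list[SNPSite],
    accessions: list[str],
    require_complete: bool = True,
) -> GenotypeMatrix:
    """Assemble SNP calls into an accession x site allele matrix.

    With ``require_complete`` only sites whose column was informative in
    every listed accession are retained (the published phylogeny used such
    complete-information markers).  Site order is (unigene_id, column).
    """
    if not accessions:
        raise ValueError("accession list is empty")
    ordered = sorted(snps, key=lambda s: (s.unigene_id, s.column, sorted(s.allele_pair)))
    kept, rows = [], []
    for s in ordered:
        row = [s.accession_alleles.get(a, MISSING) for a in accessions]
        if require_complete and MISSING in row:
            continue
        kept.append(s)
        rows.append(row)
    return GenotypeMatrix(accessions=list(accessions), sites=kept, alleles=rows)
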