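"""EST quality filtering and unigene summary statistics.

An EST set is cleaned by discarding reads whose fraction of N (undetermined)
bases exceeds a threshold (default 3%, strict inequality).  Unigene cluster
memberships are summarized as a distribution of member counts over exact and
range bins, and basic length statistics are computed over unigene consensus
sequences, split into contigs (>=2 members) and singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

IUPAC_NT = set("ACGTURYSWKMBDHVN")


@dataclass(frozen=True)
class ESTRecord:
    est_id: str
    accession: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for EST {self.est_id}")
        bad = set(self.sequence.upper()) - IUPAC_NT
        if bad:
            raise ValueError(f"non-IUPAC characters in {self.est_id}: {sorted(bad)}")

    @property
    def n_fraction(self) -> float:
        s = self.sequence.upper()
        return s.count("N") / len(s)


@dataclass(frozen=True)
class UnigeneCluster:
    unigene_id: str
    consensus: str
    member_est_ids: tuple[str, ...]

    def __post_init__(self):
        if not self.member_est_ids:
            raise ValueError(f"unigene {self.unigene_id} has no members")

    @property
    def is_singleton(self) -> bool:
        return len(self.member_est_ids) == 1


def filter_low_quality(
    ests: list[ESTRecord], max_n_fraction: float = 0.03
) -> tuple[list[ESTRecord], list[ESTRecord]]:
    """Partition ESTs into (kept, rejected) by N content.

    A read is rejected iff its N fraction strictly exceeds ``max_n_fraction``
    (a 100 bp read with exactly 3 Ns passes the default 3% threshold).
    """
    if not 0.0 <= max_n_fraction <= 1.0:
        raise ValueError("max_n_fraction must be in [0, 1]")
    kept, rejected = [], []
    for est in ests:
        (rejected if est.n_fraction > max_n_fraction else kept).append(est)
    return kept, rejected


# Bin layout of the published member-count distribution: exact bins 1..10,
# then 11-30, 31-50, 51-70, 71-90, 91-110, >110.
DEFAULT_BINS: tuple[tuple[int, int | None], ...] = tuple(
    [(i, i) for i in range(1, 11)]
    + [(11, 30), (31, 50), (51, 70), (71, 90), (91, 110), (111, None)]
)


@dataclass(frozen=True)
class DistributionRow:
    label: str
    lo: int
    hi: int | None  # None = open-ended
    n_unigenes: int
    n_ests: int


@dataclass
class MembershipDistribution:
    """Distribution of EST member counts over unigenes."""

    rows: list[DistributionRow] = field(default_factory=list)

    @property
    def total_ests(self) -> int:
        return sum(r.n_ests for r in self.rows)

    @property
    def total_unigenes(self) -> int:
        return sum(r.n_unigenes for r in self.rows)

    def unigenes_with_at_least(self, k: int) -> int:
        """Number of unigenes whose member count is >= k (k must fall on a
        bin boundary)."""
        self._check_boundary(k)
        return sum(r.n_unigenes for r in self.rows if r.lo >= k)

    def est_share_at_least(self, k: int) -> float:
        """Percentage of all member ESTs held by unigenes with >= k members."""
        self._check_boundary(k)
        return 100.0 * sum(r.n_ests for r in self.rows if r.lo >= k) / self.total_ests

    def _check_boundary(self, k: int) -> None:
        if not any(r.lo == k for r in self.rows):
            raise ValueError(f"{k} is not a bin lower boundary")

    @classmethod
    def from_counts(
        cls,
        rows: list[tuple[int | str, int, int]],
        bins: tuple[tuple[int, int | None], ...] = DEFAULT_BINS,
    ) -> "MembershipDistribution":
        """Build from already-tallied (bin, n_unigenes, n_ests) rows, e.g. a
        published distribution table; bins given in the same order."""
        if len(rows) != len(bins):
            raise ValueError("row count does not match bin count")
        out = []
        for (label, n_uni, n_est), (lo, hi) in zip(rows, bins):
            if lo == hi and n_est != lo * n_uni:
                raise ValueError(
                    f"exact bin {lo}: n_ests {n_est} != {lo} x {n_uni} unigenes"
                )
            out.append(DistributionRow(str(label), lo, hi, n_uni, n_est))
        return cls(out)


def membership_distribution(
    clusters: list[UnigeneCluster],
    bins: tuple[tuple[int, int | None], ...] = DEFAULT_BINS,
) -> MembershipDistribution:
    """Tally unigenes and their member ESTs into member-count bins.

    Bins must be disjoint and cover every observed member count.
    """
    _validate_bins(bins)
    tallies = {b: [0, 0] for b in bins}
    for c in clusters:
        n = len(c.member_est_ids)
        for lo, hi in bins:
            if n >= lo and (hi is None or n <= hi):
                tallies[(lo, hi)][0] += 1
                tallies[(lo, hi)][1] += n
                break
        else:
            raise ValueError(f"member count {n} not covered by bins")
    rows = []
    for lo, hi in bins:
        label = str(lo) if lo == hi else (f">{lo - 1}" if hi is None else f"{lo}-{hi}")
        n_uni, n_est = tallies[(lo, hi)]
        rows.append(DistributionRow(label, lo, hi, n_uni, n_est))
    return MembershipDistribution(rows)


def _validate_bins(bins) -> None:
    prev_hi = 0
    for lo, hi in bins:
        if lo <= prev_hi:
            raise ValueError("bins overlap or are out of order")
        if hi is not None:
            if hi < lo:
                raise ValueError(f"bad bin ({lo}, {hi})")
            prev_hi = hi
        else:
            prev_hi = float("inf")  # open bin must be last


@dataclass(frozen=True)
class UnigeneStats:
    n_total: int
    n_contigs: int
    n_singletons: int
    mean_length: float
    mean_contig_length: float
    mean_singleton_length: float


def unigene_stats(clusters: list[UnigeneCluster]) -> UnigeneStats:
    """Counts and mean consensus lengths for all unigenes, contigs and
    singletons."""
    singles = [c for c in clusters if c.is_singleton]
    contigs = [c for c in clusters if not c.is_singleton]

    def mean_len(cs):
        return sum(len(c.consensus) for c in cs) / len(cs) if cs else 0.0

    return UnigeneStats(
        n_total=len(clusters),
        n_contigs=len(contigs),
        n_singletons=len(singles),
        mean_length=mean_len(clusters),
        mean_contig_length=mean_len(contigs),
        mean_singleton_length=mean_len(singles),
    )
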