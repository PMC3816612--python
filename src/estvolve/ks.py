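"""Paralog pairing, synonymous distances (Ks) and WGD dating.

Whole-genome duplications leave a burst of paralog pairs of similar age; on
a Ks (synonymous substitutions per synonymous site) distribution of
reciprocal-best paralog pairs such a burst appears as a density peak.  The
workflow here: translate unigenes via their longest open reading frame
(6-frame, standard code, minimum 100 aa), drop redundant CDS caused by
alternative transcripts of the same locus, pair the remainder by reciprocal
best alignment score, estimate Ks per pair with the Nei-Gojobori (1986)
counting method under a Jukes-Cantor correction, keep 0 < Ks < 3, locate
kernel-density peaks, and convert peak Ks to an age interval with a
fossil-calibrated substitution-rate interval via T = Ks / r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .codon import (
    STOP_CODONS,
    jukes_cantor,
    ng86_counts,
    reverse_complement,
    translate_cds,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- translation

@dataclass(frozen=True)
class TranslatedGene:
    gene_id: str
    cds: str
    protein: str
    species: str = ""

    def __post_init__(self):
        if len(self.cds) % 3:
            raise ValueError("CDS length not divisible by 3")
        if translate_cds(self.cds) != self.protein:
            raise ValueError(f"protein is not the translation of cds for {self.gene_id}")
        if "*" in self.protein:
            raise ValueError(f"internal stop in {self.gene_id}")


def translate_longest_orf(
    sequence: str, gene_id: str = "", species: str = "", min_aa: int = 100
) -> TranslatedGene | None:
    """Longest open reading frame over all six frames.

    An ORF is a maximal run of sense codons (stop-to-stop; a start codon is
    not required, as EST fragments routinely truncate the 5' end).  Returns
    ``None`` when the best ORF encodes fewer than ``min_aa`` residues.
    Ties keep the first ORF in frame order (+1,+2,+3,-1,-2,-3), leftmost.
    """
    seq = sequence.upper().replace("U", "T")
    best: tuple[int, str] | None = None  # (aa length, cds)
    for s in (seq, reverse_complement(seq)):
        for off in range(3):
            run: list[str] = []
            for i in range(off, len(s) - 2, 3):
                codon = s[i : i + 3]
                if any(c not in "ACGT" for c in codon) or codon in STOP_CODONS:
                    if best is None or len(run) > best[0]:
                        best = (len(run), "".join(run))
                    run = []
                else:
                    run.append(codon)
            if best is None or len(run) > best[0]:
                best = (len(run), "".join(run))
    if best is None or best[0] < min_aa:
        return None
    cds = best[1]
    return TranslatedGene(gene_id, cds, translate_cds(cds), species)


# ----------------------------------------------------------------- alignment

@dataclass(frozen=True)
class ProteinAlignment:
    """Global pairwise protein alignment with derived statistics."""

    a_id: str
    b_id: str
    a_aligned: str
    b_aligned: str
    score: float

    @property
    def n_aligned_residues(self) -> int:
        """Columns where both sequences have a residue."""
        return sum(
            1 for x, y in zip(self.a_aligned, self.b_aligned) if x != "-" and y != "-"
        )

    @property
    def aligned_length_nt(self) -> int:
        """Aligned length in CDS base pairs (3 x residue columns)."""
        return 3 * self.n_aligned_residues

    @property
    def identity_pct(self) -> float:
        """Percent identity over residue-residue columns."""
        n = self.n_aligned_residues
        if n == 0:
            return 0.0
        m = sum(
            1
            for x, y in zip(self.a_aligned, self.b_aligned)
            if x == y and x != "-"
        )
        return 100.0 * m / n

    def coverage_of(self, which: str) -> float:
        """Fraction of the given member covered by residue-residue columns."""
        seq = self.a_aligned if which == "a" else self.b_aligned
        ungapped = len(seq) - seq.count("-")
        return self.n_aligned_residues / ungapped if ungapped else 0.0


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def align_protein_pair(
    protein_a: str, protein_b: str, a_id: str = "a", b_id: str = "b"
) -> ProteinAlignment:
    """Deterministic global alignment (BLOSUM62, affine gaps 10/0.5)."""
    if not protein_a or not protein_b:
        raise ValueError("empty protein sequence")
    aln = _aligner().align(protein_a, protein_b)
    first = aln[0]  # PairwiseAligner iteration order is deterministic
    return ProteinAlignment(a_id, b_id, str(first[0]), str(first[1]), float(first.score))


# --------------------------------------------------------- redundancy removal

@dataclass(frozen=True)
class PairStats:
    """Alignment statistics for one CDS pair, as used by the redundancy rules."""

    a_id: str
    b_id: str
    aligned_length_nt: int
    identity_pct: float
    coverage_a: float
    coverage_b: float


def remove_redundant_cds(
    genes: list[TranslatedGene], pair_stats: list[PairStats]
) -> list[TranslatedGene]:
    """Drop the shorter member of highly similar CDS pairs.

    Rules (any one triggers removal of the shorter CDS):
      1. aligned length > 600 bp and identity > 95%;
      2. both CDS < 600 bp, aligned length > 300 bp, identity > 95%;
      3. the aligned region covers >= 95% of either member with
         identity >= 95%.
    Pairs are processed sorted by (identity desc, aligned length desc, ids)
    and removals applied greedily, making cascades order-independent.
    """
    by_id = {g.gene_id: g for g in genes}
    removed: set[str] = set()
    for ps in sorted(
        pair_stats,
        key=lambda p: (-p.identity_pct, -p.aligned_length_nt, p.a_id, p.b_id),
    ):
        if ps.a_id in removed or ps.b_id in removed:
            continue
        if ps.a_id not in by_id or ps.b_id not in by_id:
            continue  # stale pair from an earlier pass
        ga, gb = by_id[ps.a_id], by_id[ps.b_id]
        la, lb = len(ga.cds), len(gb.cds)
        rule1 = ps.aligned_length_nt > 600 and ps.identity_pct > 95.0
        rule2 = (
            la < 600 and lb < 600
            and ps.aligned_length_nt > 300
            and ps.identity_pct > 95.0
        )
        rule3 = (
            max(ps.coverage_a, ps.coverage_b) >= 0.95 and ps.identity_pct >= 95.0
        )
        if rule1 or rule2 or rule3:
            # remove the shorter member; ties resolved by gene_id so the
            # outcome is deterministic
            if (la, ps.b_id) < (lb, ps.a_id):
                removed.add(ps.a_id)
            else:
                removed.add(ps.b_id)
    return [g for g in genes if g.gene_id not in removed]


# ----------------------------------------------------- reciprocal best pairing

def candidate_pairs(
    genes: list[TranslatedGene], k: int = 6, min_shared: int = 10
) -> list[tuple[str, str]]:
    """Cheap shared-k-mer prescreen before all-vs-all alignment.

    Stands in for a BLAST similarity search at desk scale: only pairs whose
    proteins share at least ``min_shared`` distinct k-mers are aligned.
    """
    kmers: dict[str, set[str]] = {}
    for g in genes:
        kmers[g.gene_id] = {
            g.protein[i : i + k] for i in range(len(g.protein) - k + 1)
        }
    ids = sorted(kmers)
    index: dict[str, list[str]] = {}
    for gid in ids:
        for km in kmers[gid]:
            index.setdefault(km, []).append(gid)
    shared: dict[tuple[str, str], int] = {}
    for members in index.values():
        if len(members) < 2:
            continue
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                key = (a, b) if a < b else (b, a)
                shared[key] = shared.get(key, 0) + 1
    return sorted(p for p, n in shared.items() if n >= min_shared)


def reciprocal_best_pairs(
    gene_ids: list[str], scores: dict[tuple[str, str], float]
) -> list[tuple[str, str]]:
    """Mutual-best-hit pairs under a symmetric score.

    ``scores`` holds one entry per unordered pair (sorted-id key).  Ties in
    a gene's best partner are broken toward the lexicographically smallest
    id; each gene appears in at most one pair.
    """
    partners: dict[str, list[tuple[float, str]]] = {g: [] for g in gene_ids}
    for (a, b), sc in scores.items():
        if a == b:
            continue
        partners[a].append((sc, b))
        partners[b].append((sc, a))
    best: dict[str, str] = {}
    for g, cand in partners.items():
        if cand:
            best[g] = min(cand, key=lambda t: (-t[0], t[1]))[1]
    pairs = set()
    for g, b in best.items():
        if best.get(b) == g:
            pairs.add((g, b) if g < b else (b, g))
    return sorted(pairs)


# ------------------------------------------------------------- codon alignment

def codon_align(
    alignment: ProteinAlignment, cds_a: str, cds_b: str
) -> tuple[str, str]:
    """Back-translate a protein alignment to paired codon columns.

    Columns where either side is a gap are dropped, so both returned
    sequences have equal length divisible by 3.  The proteins must be exact
    translations of their CDS.
    """
    if translate_cds(cds_a) != alignment.a_aligned.replace("-", ""):
        raise ValueError("cds_a does not translate to the aligned protein")
    if translate_cds(cds_b) != alignment.b_aligned.replace("-", ""):
        raise ValueError("cds_b does not translate to the aligned protein")
    ia = ib = 0
    out_a: list[str] = []
    out_b: list[str] = []
    for x, y in zip(alignment.a_aligned, alignment.b_aligned):
        if x != "-" and y != "-":
            out_a.append(cds_a[3 * ia : 3 * ia + 3])
            out_b.append(cds_b[3 * ib : 3 * ib + 3])
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    return "".join(out_a), "".join(out_b)


# ------------------------------------------------------------------------- Ks

@dataclass(frozen=True)
class KsResult:
    ks: float | None  # None when the JC correction is undefined
    S: float
    N: float
    sd: float
    nd: float

    @property
    def ps(self) -> float:
        return self.sd / self.S if self.S else 0.0


def compute_ks(cds_a: str, cds_b: str, min_codons: int = 30) -> KsResult:
    """NG86 synonymous distance for a gap-free codon alignment.

    ``ks`` is the Jukes-Cantor-corrected proportion of synonymous
    differences per synonymous site; it is ``None`` (flagged, excluded
    downstream) when ps >= 3/4 and the correction is undefined.
    """
    n_codons = len(cds_a) // 3
    if n_codons < min_codons:
        raise ValueError(f"alignment has {n_codons} codons; need >= {min_codons}")
    S, N, sd, nd = ng86_counts(cds_a, cds_b)
    ks = jukes_cantor(sd / S) if S > 0 else None
    return KsResult(ks=ks, S=S, N=N, sd=sd, nd=nd)


@dataclass(frozen=True)
class HomologPair:
    gene_a: str
    gene_b: str
    kind: str  # "paralog" (within-species RBH) or "ortholog"
    ks: float | None
    S: float
    N: float


def paralog_ks_pairs(
    genes: list[TranslatedGene],
    min_codons: int = 30,
    min_score: float = 0.0,
    prescreen_min_shared: int = 10,
) -> list[HomologPair]:
    """Within-species reciprocal-best homolog pairs with their Ks.

    Candidate pairs come from the shared-k-mer prescreen, are globally
    aligned, ranked by alignment score for reciprocal-best pairing, then
    codon-aligned for the NG86 Ks estimate.
    """
    genes = sorted(genes, key=lambda g: g.gene_id)
    by_id = {g.gene_id: g for g in genes}
    scores: dict[tuple[str, str], float] = {}
    alignments: dict[tuple[str, str], ProteinAlignment] = {}
    for a, b in candidate_pairs(genes, min_shared=prescreen_min_shared):
        aln = align_protein_pair(by_id[a].protein, by_id[b].protein, a, b)
        if aln.score >= min_score:
            scores[(a, b)] = aln.score
            alignments[(a, b)] = aln
    out = []
    for a, b in reciprocal_best_pairs([g.gene_id for g in genes], scores):
        aln = alignments[(a, b)]
        ca, cb = codon_align(aln, by_id[a].cds, by_id[b].cds)
        if len(ca) // 3 < min_codons:
            continue
        res = compute_ks(ca, cb, min_codons=min_codons)
        out.append(HomologPair(a, b, "paralog", res.ks, res.S, res.N))
    return out


# ------------------------------------------------------------ density & peaks

@dataclass
class KsDistribution:
    values: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    peaks: list[tuple[float, float]]  # (ks location, density height)


def filter_ks(values, ks_min: float = 0.0, ks_max: float = 3.0) -> np.ndarray:
    """Keep defined Ks values strictly inside (ks_min, ks_max)."""
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    return arr[(arr > ks_min) & (arr < ks_max)]


def ks_density_peaks(
    values,
    bandwidth: float = 0.03,
    grid_points: int = 600,
    ks_range: tuple[float, float] = (0.0, 3.0),
    min_height_frac: float = 0.10,
) -> KsDistribution:
    """Gaussian kernel density of a Ks sample and its strict local maxima.

    Peaks below ``min_height_frac`` of the global density maximum are
    discarded; peaks are reported sorted by Ks location.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("empty Ks sample")
    lo, hi = ks_range
    if np.any(vals <= lo) or np.any(vals >= hi):
        raise ValueError(f"Ks values must lie strictly inside ({lo}, {hi})")
    if vals.size < 30:
        logger.warning("only %d Ks values; density peaks may be unreliable", vals.size)
    grid = np.linspace(lo, hi, grid_points)
    z = (grid[:, None] - vals[None, :]) / bandwidth
    density = np.exp(-0.5 * z**2).sum(axis=1) / (vals.size * bandwidth * np.sqrt(2 * np.pi))
    interior = np.arange(1, grid_points - 1)
    is_peak = (density[interior] > density[interior - 1]) & (
        density[interior] > density[interior + 1]
    )
    floor = min_height_frac * density.max()
    peaks = [
        (float(grid[i]), float(density[i]))
        for i in interior[is_peak]
        if density[i] >= floor
    ]
    return KsDistribution(values=vals, grid=grid, density=density, peaks=peaks)


# ---------------------------------------------------------------- calibration

@dataclass(frozen=True)
class CalibratedRate:
    """Substitution-rate interval from a fossil-dated split.

    A split of known Ks and fossil age window (t_min, t_max) MYA brackets
    the synonymous rate: r in (ks / t_max, ks / t_min), Ks per million years.
    """

    ks_calibration: float
    t_interval: tuple[float, float]

    def __post_init__(self):
        t_min, t_max = self.t_interval
        if self.ks_calibration <= 0 or t_min <= 0 or t_max <= t_min:
            raise ValueError("need ks_calibration > 0 and 0 < t_min < t_max")

    @property
    def r_interval(self) -> tuple[float, float]:
        t_min, t_max = self.t_interval
        return (self.ks_calibration / t_max, self.ks_calibration / t_min)


def calibrate_rate(ks_calibration: float, t_min: float, t_max: float) -> CalibratedRate:
    return CalibratedRate(ks_calibration, (t_min, t_max))


@dataclass(frozen=True)
class DatedEvent:
    label: str
    ks_peak: float
    t_interval: tuple[float, float]  # MYA, (young, old)


def date_event(ks_peak: float, rate: CalibratedRate, label: str = "") -> DatedEvent:
    """Age interval of a Ks peak under T = Ks / r."""
    if ks_peak <= 0:
        raise ValueError("ks_peak must be positive")
    r_min, r_max = rate.r_interval
    return DatedEvent(label, ks_peak, (ks_peak / r_max, ks_peak / r_min))
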