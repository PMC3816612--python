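"""Synthetic EST datasets with known ground truth.

Generates the structures the analysis stages consume, with a truth record
for every planted feature:

* gene families duplicated at controlled synonymous divergence — the
  duplicate differs from its ancestor only at synonymous positions, mutated
  by a Poisson process whose expectation is (target Ks) x (NG86 synonymous
  sites), with multiple hits allowed, so the realized mutation count is an
  unbiased draw around the target and the multiple-hit correction is
  exercised realistically;
* per-unigene multi-accession EST alignments whose SNP columns are fixed
  differences placed by a single mutation on one branch of a known
  accession tree (sites are perfectly tree-compatible);
* planted SSR motifs verified at insertion time to be recoverable exactly
  once by the scanner.

All randomness flows from ``SimulationConfig.seed`` through per-purpose
child streams; identical (seed, config) yields identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .codon import SENSE_CODONS, codon_sites, synonymous_changes
from .snp import ReadAlignment
from .ssr import DEFAULT_THRESHOLDS, is_primitive, scan_ssrs

#: Eight accessions with a cultivated (Rs*) / wild (Rr*) bipartition,
#: branch lengths in expected substitutions per site.
DEFAULT_ACCESSION_TREE = (
    "(((Rs_RatTail3870:0.02,Rs_GSK3_1:0.02):0.015,"
    "(Rs_EarlyScarletGlobe:0.02,Rs_oleiformis:0.02):0.015):0.05,"
    "((Rr_raphanistrum_MS:0.02,Rr_raphanistrum_NY:0.02):0.015,"
    "(Rr_maritimus:0.02,Rr_landra:0.02):0.015):0.05);"
)

#: planted per sequence: (unit, repeats, insertions); kept sparse so the
#: non-overlap windows fit a typical unigene
DEFAULT_SSR_SPEC = (("AG", 6, 1), ("TC", 7, 1), ("AAG", 5, 1), ("ATCG", 5, 1))


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_families: int = 300  # families per duplication Ks target
    duplication_ks_targets: tuple[float, ...] = (0.13, 0.35)
    family_codons: int = 300
    n_accessions: int = 8
    accession_tree: str = DEFAULT_ACCESSION_TREE
    snp_rate: float = 0.01
    indel_snp_fraction: float = 0.1
    ssr_spec: tuple[tuple[str, int, int], ...] = DEFAULT_SSR_SPEC
    est_length_mean: float = 500.0
    est_length_sd: float = 50.0
    n_fraction: float = 0.01
    coverage_per_accession: int = 4
    unigene_length_mean: float = 800.0
    unigene_length_sd: float = 100.0

    def __post_init__(self):
        for name in ("snp_rate", "indel_snp_fraction", "n_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_families", "family_codons", "n_accessions",
                     "coverage_per_accession"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if any(t < 0 for t in self.duplication_ks_targets):
            raise ValueError("duplication Ks targets must be >= 0")


@dataclass(frozen=True)
class SnpTruth:
    unigene_id: str
    column: int  # 1-based
    alleles: dict[str, str]  # accession -> symbol


@dataclass(frozen=True)
class PlantedSSR:
    seq_id: str
    start: int  # 1-based inclusive
    end: int
    unit: str
    repeats: int


@dataclass
class TruthSet:
    planted_ssrs: list[PlantedSSR] = field(default_factory=list)
    true_snp_sites: list[SnpTruth] = field(default_factory=list)
    pair_ks_expected: dict[tuple[str, str], float] = field(default_factory=dict)
    true_tree_bipartitions: set[frozenset[str]] = field(default_factory=set)


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stream])


# -------------------------------------------------------- duplicated families

def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Uniform sense codons (no internal stop, hence a valid CDS)."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def synonymous_site_count(cds: str) -> float:
    return sum(codon_sites(cds[i : i + 3])[0] for i in range(0, len(cds), 3))


@dataclass(frozen=True)
class FamilySim:
    family_id: str
    ancestor_cds: str
    duplicate_cds: str
    target_ks: float
    n_mutations: int
    synonymous_sites: float


def simulate_duplicated_family(
    config: SimulationConfig, family_index: int
) -> FamilySim:
    """One ancestor CDS and its duplicate at a target synonymous divergence.

    The Ks target for family ``i`` is ``duplication_ks_targets[i //
    n_families]``.  The number of mutation events is Poisson with mean
    target x S (S = NG86 synonymous site count of the ancestor); each event
    picks uniformly among the synonymous single-base changes available in
    the current duplicate, so repeat hits of one site are possible.
    """
    n_targets = len(config.duplication_ks_targets)
    if not 0 <= family_index < n_targets * config.n_families:
        raise ValueError("family_index out of range")
    target = config.duplication_ks_targets[family_index // config.n_families]
    rng = _rng(config, 1, family_index)
    ancestor = random_cds(rng, config.family_codons)
    S = synonymous_site_count(ancestor)
    if S < 1.0 / 3.0:
        raise ValueError("CDS too short to host a synonymous site")
    n_mut = int(rng.poisson(target * S))
    duplicate = apply_synonymous_mutations(ancestor, n_mut, rng)
    return FamilySim(
        family_id=f"fam{family_index:05d}",
        ancestor_cds=ancestor,
        duplicate_cds=duplicate,
        target_ks=target,
        n_mutations=n_mut,
        synonymous_sites=S,
    )


def apply_synonymous_mutations(
    cds: str, n_mutations: int, rng: np.random.Generator
) -> str:
    """Apply mutation events drawn uniformly over the synonymous single-base
    changes available in the evolving sequence."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    weights = np.array([len(synonymous_changes(c)) for c in codons], dtype=float)
    for _ in range(n_mutations):
        total = weights.sum()
        if total == 0:
            raise ValueError("no synonymous change available")
        ci = rng.choice(len(codons), p=weights / total)
        changes = synonymous_changes(codons[ci])
        pos, alt = changes[rng.integers(0, len(changes))]
        c = codons[ci]
        codons[ci] = c[:pos] + alt + c[pos + 1 :]
        weights[ci] = len(synonymous_changes(codons[ci]))
    return "".join(codons)


def simulate_families(config: SimulationConfig) -> tuple[list[FamilySim], TruthSet]:
    """All duplicated families plus the expected-Ks truth map."""
    fams = [
        simulate_duplicated_family(config, i)
        for i in range(len(config.duplication_ks_targets) * config.n_families)
    ]
    truth = TruthSet(
        pair_ks_expected={
            (f"{f.family_id}_a", f"{f.family_id}_b"): f.target_ks for f in fams
        }
    )
    return fams, truth


# --------------------------------------------------- accession-tree alignments

def parse_accession_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


def _tree_edges(tree: dendropy.Tree) -> tuple[list[str], list[tuple[frozenset[str], float]]]:
    """Leaf labels and (leafset-below, branch length) per non-root edge."""
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    edges = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(
            l.taxon.label for l in node.leaf_iter()
        )
        length = node.edge.length or 0.0
        if 0 < len(below) < len(leaves) and length > 0:
            edges.append((below, float(length)))
    return leaves, edges


def tree_bipartitions(newick: str) -> set[frozenset[str]]:
    """Non-trivial splits of the accession tree, each as the side not
    containing the alphabetically first leaf."""
    tree = parse_accession_tree(newick)
    leaves, edges = _tree_edges(tree)
    anchor = min(leaves)
    all_set = frozenset(leaves)
    out = set()
    for below, _ in edges:
        if 1 < len(below) < len(leaves) - 1:
            out.add(below if anchor not in below else all_set - below)
    return out


@dataclass
class UnigeneAlignment:
    unigene_id: str
    consensus: str
    reads: list[ReadAlignment]


def simulate_accession_alignments(
    config: SimulationConfig,
) -> tuple[list[UnigeneAlignment], TruthSet]:
    """Per-unigene gap-padded EST alignments across accessions, plus truth.

    Every SNP column is a fixed difference created by one mutation on one
    branch of the accession tree (branch chosen with probability
    proportional to its length); accessions below the branch carry the
    derived allele (a gap for a planted single-base indel).  Reads are
    substrings of the accession haplotype with independent per-base N
    noise; planted SNP positions are kept non-adjacent so indel columns are
    genuine single-base events.
    """
    if config.coverage_per_accession < 1:
        raise ValueError("coverage_per_accession must be >= 1")
    tree = parse_accession_tree(config.accession_tree)
    leaves, edges = _tree_edges(tree)
    if len(leaves) != config.n_accessions:
        raise ValueError(
            f"accession_tree has {len(leaves)} leaves, config says "
            f"{config.n_accessions}"
        )
    edge_w = np.array([w for _, w in edges])
    edge_p = edge_w / edge_w.sum()

    truth = TruthSet(true_tree_bipartitions=tree_bipartitions(config.accession_tree))
    alignments = []
    for u in range(config.n_families):
        rng = _rng(config, 2, u)
        uid = f"unigene{u:05d}"
        length = max(200, int(rng.normal(config.unigene_length_mean,
                                         config.unigene_length_sd)))
        consensus = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))

        # Plant tree-consistent SNP columns at non-adjacent interior
        # positions (a gap at a terminal column would be indistinguishable
        # from alignment padding).
        positions = np.flatnonzero(rng.random(length) < config.snp_rate)
        kept: list[int] = []
        for p in positions:
            if p < 1 or p > length - 2:
                continue
            if not kept or p - kept[-1] > 1:
                kept.append(int(p))
        site_alleles: dict[int, dict[str, str]] = {}
        for p in kept:
            below, _ = edges[rng.choice(len(edges), p=edge_p)]
            ref = consensus[p]
            if rng.random() < config.indel_snp_fraction:
                derived = "-"
            else:
                derived = rng.choice([b for b in "ACGT" if b != ref])
            alleles = {a: (derived if a in below else ref) for a in leaves}
            site_alleles[p] = alleles
            truth.true_snp_sites.append(SnpTruth(uid, p + 1, alleles))

        haplotypes = {}
        for acc in leaves:
            h = list(consensus)
            for p, alleles in site_alleles.items():
                h[p] = alleles[acc]
            haplotypes[acc] = h

        reads = []
        for acc in leaves:
            for c in range(config.coverage_per_accession):
                rl = int(rng.normal(config.est_length_mean, config.est_length_sd))
                rl = min(max(rl, 50), length)
                start = int(rng.integers(0, length - rl + 1))
                body = []
                for i in range(start, start + rl):
                    sym = haplotypes[acc][i]
                    if sym != "-" and rng.random() < config.n_fraction:
                        sym = "N"
                    body.append(sym)
                aligned = "-" * start + "".join(body) + "-" * (length - start - rl)
                reads.append(
                    ReadAlignment(f"{uid}_{acc}_r{c}", acc, aligned)
                )
        alignments.append(UnigeneAlignment(uid, consensus, reads))
    return alignments, truth


# ------------------------------------------------------------------ SSR seeds

def plant_ssrs(
    sequence: str,
    ssr_spec: tuple[tuple[str, int, int], ...],
    seed: int,
    max_tries: int = 500,
) -> tuple[str, list[PlantedSSR]]:
    """Insert perfect SSR runs into a sequence at random positions.

    ``ssr_spec`` lists (unit, repeat count, number of insertions).  Each
    insertion is verified in place: scanning a window around the planted
    run must report exactly the planted span and nothing new, otherwise the
    position is re-drawn.  Raises if a unit contains non-ACGT characters or
    is a repetition of a shorter unit.
    """
    rng = np.random.default_rng([seed, 3])
    seq = sequence.upper()
    for unit, repeats, count in ssr_spec:
        if any(c not in "ACGT" for c in unit):
            raise ValueError(f"SSR unit must be ACGT only: {unit!r}")
        if not is_primitive(unit):
            raise ValueError(f"SSR unit is a repetition of a shorter unit: {unit!r}")
    planted: list[PlantedSSR] = []
    spans: list[tuple[int, int]] = []  # 0-based half-open, in current coords
    for unit, repeats, count in ssr_spec:
        run = unit * repeats
        for _ in range(count):
            for attempt in range(max_tries):
                pos = int(rng.integers(0, len(seq) + 1))
                if any(pos > s - 30 and pos < e + 30 for s, e in spans):
                    continue
                cand = seq[:pos] + run + seq[pos:]
                if _clean_insertion(cand, pos, pos + len(run), unit, repeats):
                    # shift earlier spans at/after the insertion point
                    spans = [
                        (s, e) if e <= pos else (s + len(run), e + len(run))
                        for s, e in spans
                    ]
                    planted = [
                        p if p.end <= pos else replace(
                            p, start=p.start + len(run), end=p.end + len(run)
                        )
                        for p in planted
                    ]
                    seq = cand
                    spans.append((pos, pos + len(run)))
                    planted.append(
                        PlantedSSR("", pos + 1, pos + len(run), unit, repeats)
                    )
                    break
            else:
                raise RuntimeError(
                    f"could not place ({unit} x {repeats}) after {max_tries} tries"
                )
    planted.sort(key=lambda p: p.start)
    return seq, planted


def _clean_insertion(seq: str, start: int, end: int, unit: str, repeats: int) -> bool:
    """The planted run, scanned in a local window, is reported exactly as
    planted (or, below threshold, not at all) and introduces no other motif
    near the junctions."""
    k = len(unit)
    lo = max(0, start - 7 * k * repeats)
    hi = min(len(seq), end + 7 * k * repeats)
    window = seq[lo:hi]
    before = {
        (m.start, m.end, m.unit)
        for m in scan_ssrs(seq[lo:start] + seq[end:hi])
    }
    found = scan_ssrs(window)
    target = [(m.start + lo, m.end + lo, m.unit) for m in found]
    if repeats < DEFAULT_THRESHOLDS[k]:
        return len(target) == len(before)
    want = (start + 1, end, unit)
    return target.count(want) == 1 and len(target) == len(before) + 1


def screened_background(
    length: int,
    seed: int,
    thresholds: dict[int, int] | None = None,
    max_rounds: int = 50,
) -> str:
    """Random ACGT background free of spontaneous SSRs above threshold.

    Spontaneous motifs are disrupted by redrawing their span until the
    scanner finds nothing; used as a clean canvas for planting.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    rng = np.random.default_rng([seed, 4])
    seq = list("ACGT"[i] for i in rng.integers(0, 4, size=length))
    for _ in range(max_rounds):
        motifs = scan_ssrs("".join(seq), thresholds=thresholds)
        if not motifs:
            return "".join(seq)
        for m in motifs:
            for i in range(m.start - 1, m.end):
                seq[i] = "ACGT"[rng.integers(0, 4)]
    raise RuntimeError("could not screen background of spontaneous SSRs")
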