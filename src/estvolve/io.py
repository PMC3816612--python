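"""File formats: FASTA via Biopython, tab-separated tables via csv.

All tables are UTF-8 TSV with a header row; coordinates are 1-based
inclusive.
"""

from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ks import DatedEvent, HomologPair, KsDistribution
from .phylo import PhyloTree, write_newick
from .preprocess import ESTRecord, MembershipDistribution, UnigeneCluster
from .snp import GenotypeMatrix, ReadAlignment, SNPSite
from .ssr import SSRMotif
from .synthetic import PlantedSSR, SnpTruth, UnigeneAlignment


def write_fasta(path: Path, records: list[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path),
        "fasta",
    )


def read_fasta(path: Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def _write_tsv(path: Path, header: list[str], rows) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def _read_tsv(path: Path) -> list[dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


# ------------------------------------------------------------------ EST data

def write_membership(path: Path, rows: list[tuple[str, str, str]]) -> None:
    _write_tsv(path, ["unigene_id", "est_id", "accession"], rows)


def read_membership(path: Path) -> list[tuple[str, str, str]]:
    return [
        (r["unigene_id"], r["est_id"], r["accession"]) for r in _read_tsv(path)
    ]


def read_ests(path: Path, accession: str) -> list[ESTRecord]:
    return [ESTRecord(rid, accession, seq) for rid, seq in read_fasta(path)]


def clusters_from_membership(
    consensus: dict[str, str], membership: list[tuple[str, str, str]]
) -> list[UnigeneCluster]:
    members: dict[str, list[str]] = {}
    for uid, est_id, _acc in membership:
        members.setdefault(uid, []).append(est_id)
    return [
        UnigeneCluster(uid, consensus[uid], tuple(ids))
        for uid, ids in sorted(members.items())
    ]


def write_distribution(path: Path, dist: MembershipDistribution) -> None:
    _write_tsv(
        path,
        ["member_bin", "n_unigenes", "n_ests"],
        [(r.label, r.n_unigenes, r.n_ests) for r in dist.rows],
    )


# ----------------------------------------------------------------- alignments

def write_alignment(path: Path, aln: UnigeneAlignment) -> None:
    write_fasta(
        path, [(f"{r.read_id} {r.accession}", r.aligned) for r in aln.reads]
    )


def read_alignment(
    path: Path, unigene_id: str, accession_of: dict[str, str]
) -> list[ReadAlignment]:
    out = []
    for r in SeqIO.parse(str(path), "fasta"):
        out.append(ReadAlignment(r.id, accession_of[r.id], str(r.seq).upper()))
    return out


# ----------------------------------------------------------------- SSR tables

def write_ssrs(path: Path, motifs: list[SSRMotif]) -> None:
    _write_tsv(
        path,
        ["unigene_id", "start", "end", "unit", "repeats", "type", "class",
         "in_compound"],
        [
            (m.unigene_id, m.start, m.end, m.unit, m.repeats, m.nt_type,
             m.canonical_class, int(m.in_compound))
            for m in motifs
        ],
    )


def write_ssr_summary(path: Path, summary) -> None:
    rows = [("total", "", summary.n_total),
            ("unigenes_with_ssr", "", summary.n_unigenes_with_ssr)]
    rows += [("nt_type", k, v) for k, v in sorted(summary.by_nt_type.items())]
    rows += [("repeats", k, v) for k, v in sorted(summary.by_repeat_count.items())]
    rows += [("class", k, v) for k, v in sorted(summary.by_canonical_class.items())]
    _write_tsv(path, ["margin", "key", "count"], rows)


def write_planted_ssrs(path: Path, planted: list[PlantedSSR]) -> None:
    _write_tsv(
        path,
        ["seq_id", "start", "end", "unit", "repeats"],
        [(p.seq_id, p.start, p.end, p.unit, p.repeats) for p in planted],
    )


# ----------------------------------------------------------------- SNP tables

def write_snps(path: Path, snps: list[SNPSite]) -> None:
    _write_tsv(
        path,
        ["unigene_id", "column", "alleles", "class"],
        [
            (s.unigene_id, s.column, "/".join(sorted(s.allele_pair)), s.snp_class)
            for s in snps
        ],
    )


def write_genotype_matrix(path: Path, gm: GenotypeMatrix) -> None:
    header = ["site"] + gm.accessions
    rows = [
        [f"{s.unigene_id}:{s.column}", *alleles]
        for s, alleles in zip(gm.sites, gm.alleles)
    ]
    _write_tsv(path, header, rows)


def read_genotype_matrix(path: Path) -> GenotypeMatrix:
    from .snp import SNPSite as _S

    recs = _read_tsv(path)
    if not recs:
        return GenotypeMatrix([], [], [])
    accessions = [k for k in recs[0] if k != "site"]
    sites, alleles = [], []
    for r in recs:
        uid, col = r["site"].rsplit(":", 1)
        row = [r[a] for a in accessions]
        present = sorted(set(row) - {"?"})
        pair = frozenset(present[:2]) if len(present) >= 2 else frozenset(present)
        sites.append(
            _S(uid, int(col), dict(zip(accessions, row)), pair, "unknown")
        )
        alleles.append(row)
    return GenotypeMatrix(accessions, sites, alleles)


def write_snp_truth(path: Path, sites: list[SnpTruth], accessions: list[str]) -> None:
    _write_tsv(
        path,
        ["unigene_id", "column", *accessions],
        [
            (t.unigene_id, t.column, *[t.alleles[a] for a in accessions])
            for t in sites
        ],
    )


# ------------------------------------------------------------------ Ks tables

def write_pairs(path: Path, pairs: list[HomologPair]) -> None:
    _write_tsv(
        path,
        ["gene_a", "gene_b", "kind", "ks", "S", "N"],
        [
            (p.gene_a, p.gene_b, p.kind,
             "" if p.ks is None else f"{p.ks:.6f}", f"{p.S:.3f}", f"{p.N:.3f}")
            for p in pairs
        ],
    )


def write_density(path: Path, dist: KsDistribution) -> None:
    _write_tsv(
        path,
        ["ks", "density"],
        [(f"{x:.5f}", f"{y:.6f}") for x, y in zip(dist.grid, dist.density)],
    )


def write_events(path: Path, events: list[DatedEvent]) -> None:
    _write_tsv(
        path,
        ["label", "ks_peak", "t_young_mya", "t_old_mya"],
        [
            (e.label, f"{e.ks_peak:.4f}", f"{e.t_interval[0]:.2f}",
             f"{e.t_interval[1]:.2f}")
            for e in events
        ],
    )


def write_pair_truth(path: Path, truth: dict[tuple[str, str], float]) -> None:
    _write_tsv(
        path,
        ["gene_a", "gene_b", "target_ks"],
        [(a, b, t) for (a, b), t in sorted(truth.items())],
    )


# ---------------------------------------------------------------------- trees

def write_tree(path: Path, tree: PhyloTree) -> None:
    Path(path).write_text(write_newick(tree) + "\n", encoding="utf-8")


def write_splits(path: Path, tree: PhyloTree) -> None:
    rows = []
    for node in tree.internal_nodes():
        if node.support is None:
            continue
        side = ",".join(sorted(l.name for l in node.leaves()))
        rows.append((side, node.support))
    _write_tsv(path, ["split", "support_pct"], rows)
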