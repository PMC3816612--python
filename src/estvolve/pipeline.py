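"""Pipeline orchestration: demo data generation, staged runs, manifest.

A single flat YAML config drives every stage; all randomness derives from
one top-level seed via per-stage child streams.  Each run writes a JSON
manifest echoing the config and recording a SHA-256 checksum per output
file, so deterministic stages can be verified checksum-stable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as eio
from .ks import (
    calibrate_rate,
    date_event,
    filter_ks,
    ks_density_peaks,
    paralog_ks_pairs,
    translate_longest_orf,
)
from .phylo import bootstrap_support, p_distance, neighbor_joining
from .preprocess import filter_low_quality, membership_distribution, unigene_stats
from .snp import build_genotype_matrix, call_snps, columns_from_alignment
from .ssr import merge_compound, scan_ssrs, summarize_ssrs
from .synthetic import (
    SimulationConfig,
    plant_ssrs,
    simulate_accession_alignments,
    simulate_families,
)

logger = logging.getLogger("estvolve")

STAGES = ("preprocess", "ssr", "snp", "ks", "phylo")


@dataclass
class PipelineConfig:
    seed: int = 0
    data_dir: str = "demo_data"
    out_dir: str = "results"
    stages: tuple[str, ...] = STAGES
    # preprocess
    max_n_fraction: float = 0.03
    # ssr
    min_di: int = 6
    min_tri: int = 5
    min_tetra: int = 5
    min_penta: int = 5
    min_hexa: int = 5
    max_compound_gap: float = 100
    min_flank: int = 50
    # snp
    min_coverage: int = 2
    # ks
    min_protein_aa: int = 100
    min_codons: int = 30
    ks_min: float = 0.0
    ks_max: float = 3.0
    bandwidth: float = 0.03
    calibration_ks: float = 1.475
    calibration_t_min: float = 54.0
    calibration_t_max: float = 90.0
    # phylo
    bootstrap_replicates: int = 1000
    # demo generator scale
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            bad = set(sim_raw) - sim_known
            if bad:
                raise ValueError(f"unknown sim config keys: {sorted(bad)}")
            if isinstance(sim_raw.get("duplication_ks_targets"), list):
                sim_raw["duplication_ks_targets"] = tuple(
                    sim_raw["duplication_ks_targets"]
                )
            if isinstance(sim_raw.get("ssr_spec"), list):
                sim_raw["ssr_spec"] = tuple(tuple(x) for x in sim_raw["ssr_spec"])
            cfg.sim = SimulationConfig(**sim_raw)
        if sim_raw is None or "seed" not in sim_raw:
            # the top-level seed drives the simulator unless one was given
            cfg.sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    stages_run: list[str] = field(default_factory=list)
    started: str = ""
    platform: str = ""

    def record(self, *paths: Path) -> None:
        for p in paths:
            self.outputs[str(p)] = _sha256(p)

    def write(self, path: Path) -> None:
        payload = {
            "config": self.config,
            "stages_run": self.stages_run,
            "outputs": self.outputs,
            "started": self.started,
            "platform": self.platform,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


# ----------------------------------------------------------------- demo data

def generate_demo(config: PipelineConfig) -> Path:
    """Write a desk-scale synthetic dataset exercising every stage."""
    data = Path(config.data_dir)
    data.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    logger.info("demo: simulating %d duplicated families x %d targets",
                sim.n_families, len(sim.duplication_ks_targets))
    fams, fam_truth = simulate_families(sim)
    cds_records = []
    for f in fams:
        cds_records.append((f"{f.family_id}_a", f.ancestor_cds))
        cds_records.append((f"{f.family_id}_b", f.duplicate_cds))
    eio.write_fasta(data / "cds.fasta", cds_records)
    eio.write_pair_truth(data / "truth_pairs.tsv", fam_truth.pair_ks_expected)

    logger.info("demo: simulating accession alignments")
    alignments, truth = simulate_accession_alignments(sim)
    aln_dir = data / "alignments"
    aln_dir.mkdir(exist_ok=True)
    membership: list[tuple[str, str, str]] = []
    by_acc: dict[str, list[tuple[str, str]]] = {}
    consensus_records = []
    planted_all = []
    for i, aln in enumerate(alignments):
        eio.write_alignment(aln_dir / f"{aln.unigene_id}.afa", aln)
        for r in aln.reads:
            membership.append((aln.unigene_id, r.read_id, r.accession))
            by_acc.setdefault(r.accession, []).append(
                (r.read_id, r.aligned.replace("-", ""))
            )
        mutated, planted = plant_ssrs(
            aln.consensus, sim.ssr_spec, seed=sim.seed + 10_000 + i
        )
        planted_all.extend(
            dataclasses.replace(p, seq_id=aln.unigene_id) for p in planted
        )
        consensus_records.append((aln.unigene_id, mutated))
    eio.write_fasta(data / "unigenes.fasta", consensus_records)
    eio.write_membership(data / "membership.tsv", membership)
    for acc, recs in sorted(by_acc.items()):
        eio.write_fasta(data / f"ests_{acc}.fasta", recs)
    eio.write_planted_ssrs(data / "truth_ssrs.tsv", planted_all)
    accs = sorted({a for _, _, a in membership})
    eio.write_snp_truth(data / "truth_snps.tsv", truth.true_snp_sites, accs)
    return data


# --------------------------------------------------------------------- stages

def _stage_preprocess(config: PipelineConfig, out: Path, manifest: RunManifest):
    data = Path(config.data_dir)
    ests = []
    for f in sorted(data.glob("ests_*.fasta")):
        acc = f.stem[len("ests_"):]
        ests.extend(eio.read_ests(f, acc))
    kept, rejected = filter_low_quality(ests, config.max_n_fraction)
    kept_ids = {e.est_id for e in kept}
    membership = [
        m for m in eio.read_membership(data / "membership.tsv") if m[1] in kept_ids
    ]
    consensus = dict(eio.read_fasta(data / "unigenes.fasta"))
    clusters = eio.clusters_from_membership(consensus, membership)
    dist = membership_distribution(clusters)
    stats = unigene_stats(clusters)
    eio.write_distribution(out / "membership_distribution.tsv", dist)
    (out / "unigene_stats.json").write_text(
        json.dumps(dataclasses.asdict(stats), indent=2) + "\n"
    )
    logger.info(
        "preprocess: %d/%d ESTs kept; %d unigenes, mean length %.0f bp",
        len(kept), len(ests), stats.n_total, stats.mean_length,
    )
    manifest.record(out / "membership_distribution.tsv", out / "unigene_stats.json")


def _stage_ssr(config: PipelineConfig, out: Path, manifest: RunManifest):
    thresholds = {2: config.min_di, 3: config.min_tri, 4: config.min_tetra,
                  5: config.min_penta, 6: config.min_hexa}
    motifs = []
    for uid, seq in eio.read_fasta(Path(config.data_dir) / "unigenes.fasta"):
        motifs.extend(scan_ssrs(seq, uid, thresholds))
    merged = merge_compound(motifs, max_gap=config.max_compound_gap)
    summary = summarize_ssrs(merged)
    eio.write_ssrs(out / "ssrs.tsv", merged)
    eio.write_ssr_summary(out / "ssr_summary.tsv", summary)
    logger.info("ssr: %d motifs (%d compound) in %d unigenes",
                summary.n_total, summary.by_nt_type.get("compound", 0),
                summary.n_unigenes_with_ssr)
    manifest.record(out / "ssrs.tsv", out / "ssr_summary.tsv")


def _stage_snp(config: PipelineConfig, out: Path, manifest: RunManifest):
    data = Path(config.data_dir)
    membership = eio.read_membership(data / "membership.tsv")
    accession_of = {est: acc for _, est, acc in membership}
    accessions = sorted(set(accession_of.values()))
    snps = []
    for f in sorted((data / "alignments").glob("*.afa")):
        reads = eio.read_alignment(f, f.stem, accession_of)
        cols = columns_from_alignment(f.stem, reads)
        snps.extend(call_snps(cols, min_coverage=config.min_coverage))
    gm = build_genotype_matrix(snps, accessions, require_complete=True)
    eio.write_snps(out / "snps.tsv", snps)
    eio.write_genotype_matrix(out / "genotype_matrix.tsv", gm)
    by_class = {}
    for s in snps:
        by_class[s.snp_class] = by_class.get(s.snp_class, 0) + 1
    logger.info("snp: %d calls (%s); %d complete-information sites",
                len(snps), by_class, gm.n_sites)
    manifest.record(out / "snps.tsv", out / "genotype_matrix.tsv")


def _stage_ks(config: PipelineConfig, out: Path, manifest: RunManifest):
    genes = []
    for gid, seq in eio.read_fasta(Path(config.data_dir) / "cds.fasta"):
        g = translate_longest_orf(seq, gid, min_aa=config.min_protein_aa)
        if g is not None:
            genes.append(g)
    pairs = paralog_ks_pairs(genes, min_codons=config.min_codons)
    values = filter_ks([p.ks for p in pairs], config.ks_min, config.ks_max)
    dist = ks_density_peaks(values, bandwidth=config.bandwidth,
                            ks_range=(config.ks_min, config.ks_max))
    rate = calibrate_rate(config.calibration_ks, config.calibration_t_min,
                          config.calibration_t_max)
    events = [
        date_event(ks, rate, label=f"peak{i + 1}")
        for i, (ks, _h) in enumerate(dist.peaks)
    ]
    eio.write_pairs(out / "ks_pairs.tsv", pairs)
    eio.write_density(out / "ks_density.tsv", dist)
    eio.write_events(out / "dated_events.tsv", events)
    logger.info("ks: %d pairs, %d in (%g,%g); peaks at %s",
                len(pairs), values.size, config.ks_min, config.ks_max,
                [round(k, 3) for k, _ in dist.peaks])
    manifest.record(out / "ks_pairs.tsv", out / "ks_density.tsv",
                    out / "dated_events.tsv")


def _stage_phylo(config: PipelineConfig, out: Path, manifest: RunManifest):
    gm = eio.read_genotype_matrix(out / "genotype_matrix.tsv")
    tree = bootstrap_support(gm, replicates=config.bootstrap_replicates,
                             seed=config.seed)
    eio.write_tree(out / "nj_tree.nwk", tree)
    eio.write_splits(out / "nj_splits.tsv", tree)
    logger.info("phylo: %d sites, %d bootstrap replicates",
                gm.n_sites, config.bootstrap_replicates)
    manifest.record(out / "nj_tree.nwk", out / "nj_splits.tsv")


_STAGE_FN = {
    "preprocess": _stage_preprocess,
    "ssr": _stage_ssr,
    "snp": _stage_snp,
    "ks": _stage_ks,
    "phylo": _stage_phylo,
}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the configured stages in dependency order and write a manifest."""
    bad = set(config.stages) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
        platform=platform.platform(),
    )
    order = [s for s in STAGES if s in config.stages]
    if "phylo" in order and "snp" not in order:
        if not (out / "genotype_matrix.tsv").exists():
            raise ValueError("phylo stage needs the snp stage (or its output)")
    for stage in order:
        logger.info("== stage %s ==", stage)
        try:
            _STAGE_FN[stage](config, out, manifest)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest.stages_run.append(stage)
    manifest.write(out / "manifest.json")
    return manifest
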