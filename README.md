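# estvolve

EST comparative genomics for crop plants: quality filtering and unigene
statistics, microsatellite (SSR) and SNP marker mining, Ks-based dating of
whole-genome duplications (WGD), and SNP-based neighbor-joining
phylogenetics — with a synthetic-data generator that plants every feature
with known ground truth, so the whole chain is testable without any
external downloads.

The package is aimed at researchers working with transcript collections of
non-model plants (the motivating system is radish, *Raphanus*, with its
cultivated *R. sativus* and wild *R. raphanistrum* accessions), where ESTs
are the primary genomic resource and markers, paleopolyploidy and
germplasm relationships all have to be extracted from the same dataset.

## What it computes

* **Preprocessing** — reads with > 3% Ns are discarded; unigene clusters
  are summarized as a member-count distribution (exact bins 1..10 and
  ranges up to >110) with the identity `n_ests = bin x n_unigenes` on
  exact bins, plus consensus-length statistics for contigs and singletons.
* **SSR mining** — maximal perfect tandem repeats of primitive 2-6 bp
  units (>= 6 repeats for di-, >= 5 for tri- through hexanucleotides),
  compound merging within a configurable gap, unit/reverse-complement
  classes (AG/CT distinct from TC/GA), flank-sufficiency checks, and
  marginal summaries.
* **SNP calling** — per alignment column and accession pair: >= 2x non-N
  coverage on both sides, internal monomorphism, disjoint symbols;
  single-base gap contrasts are indels; calls are classified
  transition / transversion / indel and assembled into a
  complete-information genotype matrix.
* **Ks / WGD** — six-frame longest-ORF translation (>= 100 aa), redundancy
  removal, shared-k-mer prescreen + global protein alignment (BLOSUM62),
  reciprocal-best pairing, codon back-translation, Nei–Gojobori (1986)
  Ks with Jukes–Cantor correction, kernel-density peaks on 0 < Ks < 3,
  and fossil-calibrated dating via T = Ks/r with r bracketed by an age
  window (default 54–90 MYA).
* **Phylogenetics** — p-distances over SNP alleles, Saitou–Nei neighbor
  joining with deterministic tie-breaking, column bootstrap, Newick I/O
  that round-trips byte-identically.

See `docs/methods.md` for models, assumptions, defaults and limitations.

## Worked example: recovering two WGD peaks

Simulate 300 duplicate gene pairs at each of two synonymous-divergence
targets (Ks 0.13 and 0.35, the two recent duplication signals reported
for radish), estimate Ks for every pair, and date the detected density
peaks with a rate window calibrated on a 54–90 MYA fossil interval:

```python
from estvolve import (SimulationConfig, simulate_duplicated_family, compute_ks,
                      filter_ks, ks_density_peaks, calibrate_rate, date_event)

cfg = SimulationConfig(seed=1, n_families=300,
                       duplication_ks_targets=(0.13, 0.35), family_codons=300)
ks = [compute_ks(f.ancestor_cds, f.duplicate_cds).ks
      for f in (simulate_duplicated_family(cfg, i) for i in range(600))]
dist = ks_density_peaks(filter_ks(ks), bandwidth=0.03)
rate = calibrate_rate(1.475, 54, 90)
for loc, height in dist.peaks:
    ev = date_event(loc, rate)
    print(f"Ks peak {loc:.3f} (density {height:.2f}) -> "
          f"{ev.t_interval[0]:.1f}-{ev.t_interval[1]:.1f} MYA")
```

Output:

```
Ks peak 0.130 (density 4.84) -> 4.8-7.9 MYA
Ks peak 0.361 (density 3.46) -> 13.2-22.0 MYA
```

Both planted peaks are recovered (the second with the expected slight
upward estimation noise), and each peak Ks maps to an age interval whose
width reflects the fossil calibration uncertainty: the younger burst dates
to ~5–8 MYA and the older one to ~13–22 MYA.

## Command line

A demo dataset and the full staged pipeline are available from the shell:

```
estvolve demo --seed 4 --data demo_data
estvolve all  --seed 4 --data demo_data --out results
```

Stages (`preprocess`, `ssr`, `snp`, `ks`, `phylo`) can be run
individually; every run writes a `manifest.json` with a SHA-256 checksum
per output, and identical seeds reproduce identical checksums. A YAML
config (`--config`) exposes every threshold; unknown keys are rejected.

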