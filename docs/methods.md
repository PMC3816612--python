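# Methods

`estvolve` reimplements, as a tested library, the analysis chain used in
EST-based comparative studies of crop plants such as radish (*Raphanus*):
clean an EST collection, summarize its unigene assembly, mine SSR and SNP
markers, date whole-genome duplications (WGD) from the paralog Ks
distribution, and infer accession relationships with a neighbor-joining
tree. Because a ~300k-read dbEST corpus is not reproducible at desk scale,
every stage is validated against a synthetic-data generator that plants
features with known truth.

## EST preprocessing

A read is discarded when its fraction of N bases strictly exceeds
`max_n_fraction` (default 0.03, i.e. the ">3% Ns" convention; a 100 bp read
with exactly 3 Ns passes). Only N counts; other IUPAC ambiguity codes are
left alone. Unigene statistics use consensus lengths, with contigs (>= 2
members) and singletons reported separately. The member-count distribution
uses exact bins 1..10 and ranges 11-30, 31-50, 51-70, 71-90, 91-110, >110;
for exact bins the identity `n_ests = bin x n_unigenes` is enforced, and
the grand total must equal the number of clustered ESTs. Vector/adapter
screening and the assembly itself are out of scope: cluster membership is
an input.

## SSR mining

The scanner reports every maximal perfect tandem repeat of a primitive
2-6 bp unit meeting its minimum repeat count (six for dinucleotides, five
for tri- through hexanucleotides — the MISA defaults used across the EST
literature). Runs are broken at Ns; a truncated final unit is not counted;
when the same interval is describable by units of several lengths only the
shortest-unit description is kept (e.g. (AG)6, never (AGAG)3). Motif
classes pair a unit with its reverse complement only — rotations are *not*
collapsed, so AG/CT and TC/GA are distinct classes, as in the standard
reporting convention.

Nearby motifs merge into a compound SSR when separated by at most
`max_gap` bases. Published definitions of "compound" often allow any
spacer length; an unbounded gap would merge motifs across a whole unigene,
so the default is 100 bp (the screening-tool convention), configurable up
to `float('inf')` for the literal behavior. Compound records replace their
constituents in summary totals. A flank-sufficiency predicate (>= 50 non-N
bases on both sides by default) stands in for primer design, which is out
of scope.

## SNP calling

ESTs are pooled per accession; there is no base-quality model and no
heterozygote calling. At each alignment column a pair of accessions yields
a SNP iff both have at least 2x non-N coverage, both are internally
monomorphic (a mixed accession is logged and treated as unresolved), and
their symbols differ. A base/gap contrast is a single-base indel; a gap
that is also fixed in an adjacent column of the same accession is taken as
part of a longer deletion and skipped. Leading/trailing gaps of a read are
alignment padding (missing data), not deletions. Calls are classified
transition (A<->G, C<->T) / transversion / indel — a strict partition.
Each (column, allele pair) is emitted once, carrying the majority symbol of
every accession with usable coverage, and the complete-information genotype
matrix keeps only sites informative in all accessions, mirroring the
marker selection used for published EST phylogenies.

## Ks distributions and WGD dating

Unigenes are translated by a six-frame longest-ORF scan (stop-to-stop, no
start-codon requirement, standard code); translations under 100 aa are
dropped. This replaces HMM-based EST translation, which needs an external
training matrix; for CDS-derived synthetic input the longest ORF is the
planted frame. Redundant CDS (alternative transcripts of one locus) are
removed pairwise: (1) aligned length > 600 bp and identity > 95%; (2) both
CDS < 600 bp, aligned length > 300 bp, identity > 95%; (3) aligned region
covering >= 95% of either member at >= 95% identity — in each case the
shorter member is dropped, pairs processed by descending identity then
length so cascades are order-independent. Rule 3's inclusive ">= 95%" vs
rules 1-2's strict "> 95%" is deliberate, matching the distinct wording of
the published rules.

Candidate pairs pass a shared-k-mer prescreen (a desk-scale stand-in for a
BLAST similarity search), are aligned globally (BLOSUM62, gap open 10,
extend 0.5, via Biopython's PairwiseAligner), and paired by reciprocal
best score with lexicographic tie-breaking. Protein alignments are
back-translated to codon alignments with gap columns dropped.

Ks uses the Nei-Gojobori (1986) counting method with Jukes-Cantor
correction: per-codon synonymous site fractions (stop-creating changes
count as nonsynonymous), difference counts averaged over all minimal
mutational pathways (pathways through stops excluded, with an all-paths
fallback), ps = Sd/S, and Ks = -3/4 ln(1 - 4ps/3), undefined (flagged and
excluded) when ps >= 3/4. ML codon-model estimators (yn00/F3x4) would need
a re-implementation of PAML; NG86 is closed-form, testable against an
independent path-enumeration oracle to 1e-9, and at the divergences of
interest (Ks < 0.5) the peak locations — the quantity used downstream —
are insensitive to the estimator choice. The estimator sits behind a
single function and is replaceable.

Only 0 < Ks < 3 enters the distribution. The density is a Gaussian KDE
with absolute bandwidth 0.03 on a 600-point grid over (0, 3); peaks are
strict local maxima at or above 10% of the global maximum. The source
studies state no smoothing parameters, so these are package defaults,
all configurable; 0.03 resolves peaks 0.1 apart without fragmenting a
600-sample unimodal peak.

Dating uses T = Ks/r with r bracketed by a fossil window: r in
(ks_cal/t_max, ks_cal/t_min) for a calibration split of known Ks and age
window (default 54-90 MYA, the Brassicales stem). The calibration Ks is a
required input; the default 1.475 is obtained by inverting the published
radish β-WGD interval (12.8-21.4 MYA at Ks 0.35), and reproduces that
interval to within the peak-location uncertainty. Inverting the published
α interval (5.1-8.4 MYA at Ks 0.13) implies a slightly different rate —
the two published intervals are not perfectly consistent with a single
calibration — so α dates computed here come out near 4.8-8.0 MYA.

## Neighbor joining and bootstrap

Distances are p-distances over SNP alleles (gap = fifth state; mismatches
all count 1). The triangle inequality is not guaranteed for p-distances
and is not asserted. A Jukes-Cantor-corrected alternative is not currently
wired in because the published analysis does not state its distance model
and topology at these divergences is unaffected.

NJ is the standard Saitou-Nei agglomeration: join the pair minimizing
Q(i,j) = (n-2)d(i,j) - r_i - r_j, branch lengths from the usual formulas,
ties broken toward the lexicographically smallest cluster labels, negative
branch lengths clamped to zero with the remainder moved to the sister
edge, final three clusters joined at a trifurcating root by the
three-point formulas. On additive matrices this recovers the generating
topology and branch lengths exactly (property-tested up to 12 taxa).
Bootstrap resamples SNP columns with replacement; support is the integer
percentage of replicates containing each internal bipartition of the
point-estimate tree. Newick output (branch lengths %.6g, supports as
internal-node labels) round-trips byte-identically through the package's
own reader.

## Synthetic data

The generator emulates the study conditions so that each stage is testable
with known truth:

* **Duplicated families.** Per Ks target (defaults 0.13 and 0.35 — the two
  radish WGD peaks), `n_families` (default 300) ancestors of 300 uniform
  sense codons each. The duplicate receives a Poisson(target x S) number
  of mutation events, S being the ancestor's NG86 synonymous site count;
  each event is drawn uniformly over the synonymous single-base changes
  available in the current sequence, so multiple hits occur and the
  JC correction is exercised. The event count is therefore unbiased for
  target x S (tested within 3 SE over 500 replicates). Because two-fold
  degenerate sites follow a 2-state rather than 4-state process, the NG86
  estimate carries a small upward bias (~+0.01 at Ks 0.35), well inside
  the ±0.05 recovery tolerance.
* **Accession alignments.** Eight accessions (four cultivated Rs_*, four
  wild Rr_*) on a fixed tree with a 4|4 cultivated/wild split. Each SNP
  column is one mutation on one branch (chosen proportional to branch
  length), so all sites are perfectly tree-compatible and NJ recovery is
  exact by construction. Indel SNPs (10% of sites by default) are planted
  directly as single-base gap columns at interior, non-adjacent positions.
  Reads are uniform substrings (length ~ N(500, 50), 4 per accession per
  unigene by default) with independent per-base N noise (default 1%).
* **SSRs.** Planted runs are verified at insertion time: a local rescan
  must report exactly the planted span (or nothing, for below-threshold
  plants). Backgrounds are uniform ACGT, so spontaneous repeats can occur;
  truth-based precision/recall tests use `screened_background`, which
  redraws any span the scanner flags, and the test suite additionally
  pre-screens with an independent brute-force enumerator.

What the generator does **not** emulate: real EST error profiles
(chromatogram-quality-correlated errors, indel sequencing error),
expression-dependent coverage, paralog cross-mapping into the wrong
unigene, rate heterogeneity or selection on synonymous sites, indel
evolution along the tree, and transition-biased mutation. Passing tests
therefore demonstrate correctness of the algorithms under clean,
tree-compatible, unbiased-mutation conditions — not robustness to the
artifacts of real dbEST data.

## Problem sizes and numerics

The bundled demo and validation runs use 300 families per Ks target
(600 paralog pairs), 8 accessions with ~1,000-2,000 complete SNP sites,
and 200-1,000 bootstrap replicates; these sizes give stable peak locations
and saturated supports while keeping a full run in seconds. Degenerate
inputs are handled explicitly: empty Ks samples and sub-30-value samples
(error / warning), ps >= 3/4 (flagged undefined, excluded), all-N columns
(skipped with a warning), empty genotype matrices (allowed), matrices with
missing entries (rejected by the distance step). Determinism: every
stochastic component takes a seed; all pipeline randomness derives from
one top-level seed through named child streams.
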