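"""NG86 distance machinery, ORF translation, pairing and dating."""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from estvolve.codon import SENSE_CODONS, codon_sites, ng86_counts
from estvolve.ks import (
    CalibratedRate,
    PairStats,
    TranslatedGene,
    align_protein_pair,
    calibrate_rate,
    codon_align,
    compute_ks,
    date_event,
    filter_ks,
    ks_density_peaks,
    reciprocal_best_pairs,
    remove_redundant_cds,
    translate_longest_orf,
)
from oracles import brute_force_rbh, gotoh_score, oracle_ng86


class TestNG86:
    def test_identical_sequences_have_zero_ks(self):
        cds = "ATGGCTAAA" * 20
        res = compute_ks(cds, cds, min_codons=30)
        assert res.ks == 0.0
        assert res.sd == 0.0

    def test_site_counts_sum_to_three_per_codon(self):
        for codon in SENSE_CODONS:
            s, n = codon_sites(codon)
            assert s + n == pytest.approx(3.0)

    def test_single_synonymous_difference_frozen_value(self):
        # TTT|GCA^40 vs TTC|GCA^40: S = (1/3 + 40)+avg, one synonymous
        # difference; frozen from the all-paths oracle
        a = "TTT" + "GCA" * 40
        b = "TTC" + "GCA" * 40
        res = compute_ks(a, b, min_codons=30)
        assert res.S == pytest.approx(40 + 1 / 3)
        assert res.sd == pytest.approx(1.0)
        assert res.ks == pytest.approx(0.0252124580992, abs=1e-10)

    def test_undefined_correction_is_flagged(self):
        # a lone two-fold-degenerate difference saturates ps
        res = compute_ks("TTT", "TTC", min_codons=1)
        assert res.ks is None
        assert filter_ks([res.ks]).size == 0

    def test_matches_all_paths_oracle_on_random_alignments(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 11))
            a = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, size=n))
            b = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, size=n))
            got = ng86_counts(a, b)
            want = oracle_ng86(a, b)
            assert got == pytest.approx(want, abs=1e-9)

    def test_site_conservation_invariant(self, rng):
        for _ in range(50):
            n = int(rng.integers(30, 80))
            a = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, size=n))
            b = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, size=n))
            S, N, _, _ = ng86_counts(a, b)
            assert S + N == pytest.approx(3 * n)

    def test_short_alignment_rejected(self):
        with pytest.raises(ValueError, match="codons"):
            compute_ks("ATG" * 10, "ATG" * 10, min_codons=30)


class TestTranslateLongestORF:
    def test_finds_planted_orf(self, rng):
        orf = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, size=150))
        seq = "TAATAA" + orf + "TGA" + "AC" * 30
        gene = translate_longest_orf(seq, "g1")
        assert gene is not None
        assert gene.cds == orf
        assert len(gene.protein) == 150

    def test_short_orf_returns_none(self, rng):
        orf = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, size=99))
        seq = "TAA" + orf + "TAA"
        assert translate_longest_orf(seq) is None

    def test_matches_exhaustive_six_frame_scan(self, rng):
        from estvolve.codon import STOP_CODONS, reverse_complement

        def oracle_longest(seq):
            best = 0
            for s in (seq, reverse_complement(seq)):
                for off in range(3):
                    run = 0
                    for i in range(off, len(s) - 2, 3):
                        c = s[i : i + 3]
                        if c in STOP_CODONS or any(x not in "ACGT" for x in c):
                            run = 0
                        else:
                            run += 1
                            best = max(best, run)
            return best

        for _ in range(50):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=600))
            gene = translate_longest_orf(seq, min_aa=1)
            assert gene is not None
            assert len(gene.protein) == oracle_longest(seq)


class TestProteinAlignment:
    def test_identical_proteins_full_identity(self):
        aln = align_protein_pair("MKTAYIAKQR" * 5, "MKTAYIAKQR" * 5)
        assert aln.identity_pct == 100.0
        assert "-" not in aln.a_aligned

    def test_internal_deletion_gives_single_gap_run(self):
        p = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        q = p[:15] + p[25:]
        aln = align_protein_pair(p, q)
        assert aln.b_aligned.count("-") == 10
        assert list(_gap_runs(aln.b_aligned)) == [10]

    def test_score_matches_affine_dp_oracle(self, rng):
        mat = substitution_matrices.load("BLOSUM62")
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(25):
            a = "".join(rng.choice(aas, size=int(rng.integers(5, 61))))
            b = "".join(rng.choice(aas, size=int(rng.integers(5, 61))))
            assert align_protein_pair(a, b).score == pytest.approx(
                gotoh_score(a, b, mat)
            )


def _gap_runs(s):
    run = 0
    for c in s:
        if c == "-":
            run += 1
        elif run:
            yield run
            run = 0
    if run:
        yield run


class TestCodonAlign:
    def test_gap_free_alignment_back_translates_fully(self, rng):
        cds = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, size=40))
        gene = TranslatedGene("g", cds, _protein(cds))
        aln = align_protein_pair(gene.protein, gene.protein)
        ca, cb = codon_align(aln, cds, cds)
        assert ca == cds and cb == cds

    def test_gap_columns_dropped(self, rng):
        cds = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, size=60))
        short = cds[:60] + cds[90:]  # internal 10-codon deletion
        aln = align_protein_pair(_protein(cds), _protein(short))
        ca, cb = codon_align(aln, cds, short)
        assert len(ca) == len(cb)
        assert len(ca) % 3 == 0
        assert len(ca) == 3 * aln.n_aligned_residues
        # per-residue recheck: each retained codon translates to the residue
        # shown in its alignment column
        cols = [
            (x, y)
            for x, y in zip(aln.a_aligned, aln.b_aligned)
            if x != "-" and y != "-"
        ]
        for i, (x, y) in enumerate(cols):
            assert _protein(ca[3 * i : 3 * i + 3]) == x
            assert _protein(cb[3 * i : 3 * i + 3]) == y

    def test_translation_mismatch_rejected(self):
        cds = "ATGGCT" * 20
        aln = align_protein_pair(_protein(cds), _protein(cds))
        with pytest.raises(ValueError, match="translate"):
            codon_align(aln, cds, "GCT" * 40)


def _protein(cds):
    from estvolve.codon import translate_cds

    return translate_cds(cds)


class TestRedundancyRemoval:
    def _genes(self, la, lb):
        cds_a = "GCT" * (la // 3)
        cds_b = "GCT" * (lb // 3)
        return [
            TranslatedGene("a", cds_a, _protein(cds_a)),
            TranslatedGene("b", cds_b, _protein(cds_b)),
        ]

    def test_long_alignment_high_identity_removes_shorter(self):
        genes = self._genes(900, 700)
        kept = remove_redundant_cds(
            genes, [PairStats("a", "b", 700, 96.0, 0.7, 0.9)]
        )
        assert [g.gene_id for g in kept] == ["a"]

    def test_both_short_rule(self):
        genes = self._genes(550, 540)
        kept = remove_redundant_cds(
            genes, [PairStats("a", "b", 350, 96.0, 0.6, 0.6)]
        )
        assert [g.gene_id for g in kept] == ["a"]

    def test_low_identity_keeps_both(self):
        genes = self._genes(900, 700)
        kept = remove_redundant_cds(
            genes, [PairStats("a", "b", 700, 90.0, 0.7, 0.9)]
        )
        assert len(kept) == 2

    def test_coverage_rule_uses_95_inclusive(self):
        genes = self._genes(600, 450)
        kept = remove_redundant_cds(
            genes, [PairStats("a", "b", 420, 95.0, 0.7, 0.95)]
        )
        assert [g.gene_id for g in kept] == ["a"]

    def test_never_removes_longer_and_idempotent(self):
        genes = self._genes(900, 600)
        stats = [PairStats("a", "b", 650, 97.0, 0.72, 0.99)]
        kept = remove_redundant_cds(genes, stats)
        assert [g.gene_id for g in kept] == ["a"]
        assert remove_redundant_cds(kept, stats) == kept


class TestReciprocalBest:
    def test_mutual_best_hit_pair(self):
        assert reciprocal_best_pairs(["a", "b"], {("a", "b"): 5.0}) == [("a", "b")]

    def test_non_reciprocal_chain(self):
        scores = {("a", "b"): 3.0, ("b", "c"): 9.0, ("a", "c"): 1.0}
        assert reciprocal_best_pairs(["a", "b", "c"], scores) == [("b", "c")]

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 21))
            ids = [f"g{i:02d}" for i in range(n)]
            scores = {}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.7:
                        scores[(ids[i], ids[j])] = float(rng.integers(0, 50))
            got = set(reciprocal_best_pairs(ids, scores))
            assert got == brute_force_rbh(ids, scores)
            flat = [g for p in got for g in p]
            assert len(flat) == len(set(flat))  # each gene in <= 1 pair


class TestDensityPeaks:
    def test_unimodal_sample_single_peak(self, rng):
        vals = rng.normal(0.35, 0.05, size=2000)
        vals = vals[(vals > 0) & (vals < 3)]
        dist = ks_density_peaks(vals, bandwidth=0.03)
        assert len(dist.peaks) >= 1
        main = max(dist.peaks, key=lambda p: p[1])
        assert main[0] == pytest.approx(0.35, abs=0.03)

    def test_bimodal_sample_two_peaks(self, rng):
        vals = np.concatenate(
            [rng.normal(0.13, 0.02, 400), rng.normal(0.35, 0.04, 400)]
        )
        vals = vals[(vals > 0) & (vals < 3)]
        dist = ks_density_peaks(vals, bandwidth=0.03)
        locs = sorted(p[0] for p in dist.peaks)
        assert len(locs) == 2
        assert locs[0] == pytest.approx(0.13, abs=0.05)
        assert locs[1] == pytest.approx(0.35, abs=0.05)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ks_density_peaks([])

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError, match="strictly inside"):
            ks_density_peaks([0.0, 0.5])


class TestCalibrationAndDating:
    def test_rate_interval_arithmetic(self):
        rate = calibrate_rate(1.5, 54.0, 90.0)
        assert rate.r_interval == pytest.approx((1.5 / 90, 1.5 / 54))
        assert rate.r_interval == pytest.approx((0.016667, 0.027778), abs=1e-5)

    def test_zero_calibration_rejected(self):
        with pytest.raises(ValueError):
            calibrate_rate(0.0, 54.0, 90.0)

    def test_rate_linear_in_calibration_ks(self):
        r1 = calibrate_rate(0.7, 54.0, 90.0).r_interval
        r2 = calibrate_rate(1.4, 54.0, 90.0).r_interval
        assert r2 == pytest.approx((2 * r1[0], 2 * r1[1]))

    def test_dating_matches_published_interval_shape(self):
        # inverting a 12.8-21.4 MYA window at Ks 0.35 implies
        # r in (0.01636, 0.02734); dating 0.35 must return the window
        rate = CalibratedRate(1.475, (54.0, 90.0))
        ev = date_event(0.35, rate, "beta")
        assert ev.t_interval[0] == pytest.approx(12.8, abs=0.1)
        assert ev.t_interval[1] == pytest.approx(21.4, abs=0.1)

    def test_dating_linearity(self):
        rate = calibrate_rate(1.0, 54.0, 90.0)
        e1 = date_event(0.2, rate)
        e2 = date_event(0.4, rate)
        assert e2.t_interval == pytest.approx(
            (2 * e1.t_interval[0], 2 * e1.t_interval[1])
        )

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(ValueError):
            date_event(0.0, calibrate_rate(1.0, 54.0, 90.0))
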