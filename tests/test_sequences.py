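"""Read filtering, dereplication, pooling and pooled Z_C functions."""

from collections import Counter

import numpy as np
import pytest

from zcmeta.chem import zc
from zcmeta.sequences import (
    ReadSet,
    SamplePool,
    dereplicate,
    gc_content,
    length_filter,
    orient_cds,
    pool_dsdna,
    read_fasta,
    rna_counts_from_cds,
    strand_from_fgs_header,
    taxon_pools,
    taxon_read_sets,
    zc_dsdna,
    zc_dsdna_gc,
    zc_protein,
    zc_rna,
)
from zcmeta.simulate import gen_reads


def make_reads(seqs, label="test"):
    return ReadSet([f"r{i}" for i in range(len(seqs))], list(seqs), label)


class TestLengthFilter:
    def test_outlier_removed(self):
        # 100 reads of length 100 plus one of length 1000: the long read is
        # far beyond mean + 2 sd of the 101 lengths and must go.
        lengths = [100] * 100 + [1000]
        mean = np.mean(lengths)
        sd = np.std(lengths)
        assert 1000 > mean + 2 * sd
        reads = make_reads(["A" * n for n in lengths])
        kept = length_filter(reads)
        assert len(kept) == 100
        assert all(len(s) == 100 for s in kept.seqs)

    def test_ambiguous_base_limit(self):
        reads = make_reads(["ACGT" * 25, "N" * 6 + "ACGT" * 25, "N" * 5 + "ACGT" * 25])
        kept = length_filter(reads)
        # exactly 6 N removed, 5 N kept ("more than 5 ambiguous bases")
        assert len(kept) == 2
        assert all(s.count("N") <= 5 for s in kept.seqs)

    def test_uniform_lengths_unchanged_and_idempotent(self):
        reads = make_reads(["ACGT" * 10] * 20)
        once = length_filter(reads)
        assert once.seqs == reads.seqs
        assert length_filter(once).seqs == once.seqs

    def test_boundary_read_is_kept(self):
        # lengths 100,100,100,100,110: mean 102, population sd 4, so the
        # length-110 read sits exactly on mean + 2 sd and is retained.
        reads = make_reads(["A" * 100] * 4 + ["A" * 110])
        assert len(length_filter(reads)) == 5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            length_filter(make_reads([]))

    def test_never_increases_read_count(self):
        reads, _ = gen_reads(0.5, 500, 120, 30, seed=4)
        assert len(length_filter(reads)) <= len(reads)


class TestDereplicate:
    def test_exact_duplicates_collapse(self):
        reads = make_reads(["ACGT" * 20, "ACGT" * 20, "TTTT" * 20])
        assert len(dereplicate(reads)) == 2

    def test_unique_prefixes_unchanged(self):
        reads, _ = gen_reads(0.5, 100, 150, 10, seed=1)
        assert dereplicate(reads).seqs == reads.seqs

    def test_prefix_duplicates_with_different_tails_collapse(self):
        prefix = "AC" * 25  # 50 bases
        reads = make_reads([prefix + "G" * 30, prefix + "T" * 30, "TG" * 40])
        kept = dereplicate(reads, prefix_len=50)
        assert kept.seqs == [prefix + "G" * 30, "TG" * 40]  # first wins

    def test_injected_duplicates_all_removed(self):
        reads, truth = gen_reads(0.4, 1000, 150, 15, dup_rate=0.1, seed=2)
        kept = dereplicate(reads)
        assert len(reads) - len(kept) == truth["n_duplicates"]

    def test_idempotent(self):
        reads, _ = gen_reads(0.5, 300, 100, 10, dup_rate=0.2, seed=3)
        once = dereplicate(reads)
        assert dereplicate(once).seqs == once.seqs

    def test_invalid_prefix_len(self):
        with pytest.raises(ValueError):
            dereplicate(make_reads(["ACGT"]), prefix_len=0)


class TestPoolDsdna:
    def test_polya_counts(self):
        pool = pool_dsdna(make_reads(["AAAA"]))
        assert pool.pair_counts == Counter({"AT": 4, "GC": 0})
        assert gc_content(pool) == 0.0

    def test_pairing_identity(self):
        pool = pool_dsdna(make_reads(["ACGTTGCA", "GGCC"]))
        assert pool.pair_counts["AT"] == pool.base_counts["A"] + pool.base_counts["T"]
        assert pool.pair_counts["GC"] == pool.base_counts["G"] + pool.base_counts["C"]

    def test_reverse_complement_invariance(self):
        seq = "ACCGTTGATCGGCTA"
        rc = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
        p1 = pool_dsdna(make_reads([seq]))
        p2 = pool_dsdna(make_reads([rc]))
        assert p1.pair_counts == p2.pair_counts
        assert zc_dsdna(p1) == zc_dsdna(p2)

    def test_ambiguity_codes_excluded(self):
        pool = pool_dsdna(make_reads(["AANRYA"]))
        assert sum(pool.base_counts.values()) == 3

    def test_no_countable_bases_rejected(self):
        with pytest.raises(ValueError):
            pool_dsdna(make_reads(["NNNN"]))

    def test_generator_gc_within_binomial_bound(self):
        gc = 0.42
        reads, _ = gen_reads(gc, 1000, 100, 0, seed=5)  # 1e5 bases
        f = gc_content(pool_dsdna(reads))
        bound = 3 * np.sqrt(gc * (1 - gc) / reads.total_bases)
        assert abs(f - gc) < bound


class TestZcDsdna:
    def test_base_pair_endpoints(self):
        assert round(zc_dsdna_gc(0.0), 2) == 0.50
        assert round(zc_dsdna_gc(1.0), 2) == 0.74

    def test_bulk_dna_range(self):
        assert round(zc_dsdna_gc(0.25), 2) == 0.56
        assert round(zc_dsdna_gc(0.75), 2) == 0.68

    @pytest.mark.parametrize("f", np.linspace(0, 1, 21).tolist())
    def test_closed_form_matches_composition_oracle(self, f):
        # the composition route (summed nucleosides) against (10+4f)/(20-f)
        assert zc_dsdna_gc(f) == pytest.approx((10 + 4 * f) / (20 - f), rel=1e-12)

    def test_strictly_increasing_in_gc(self):
        grid = np.linspace(0, 1, 50)
        values = [zc_dsdna_gc(f) for f in grid]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert values[0] == pytest.approx(0.5)
        assert values[-1] == pytest.approx(14 / 19)

    def test_pool_route_depends_only_on_gc_fraction(self):
        p1 = pool_dsdna(make_reads(["ACGT" * 10]))
        p2 = pool_dsdna(make_reads(["AAGG" * 25, "TTCC" * 15]))
        assert gc_content(p1) == gc_content(p2) == 0.5
        assert zc_dsdna(p1) == pytest.approx(zc_dsdna(p2))

    def test_gc_skew_invariance(self):
        # same GC fraction, strongly skewed G-vs-C on the emitted strand:
        # double-strand pairing must erase the skew
        r1, _ = gen_reads(0.5, 200, 100, 0, gc_skew=0.0, seed=6)
        r2, _ = gen_reads(0.5, 200, 100, 0, gc_skew=0.8, seed=6)
        z1, z2 = zc_dsdna(pool_dsdna(r1)), zc_dsdna(pool_dsdna(r2))
        f1, f2 = gc_content(pool_dsdna(r1)), gc_content(pool_dsdna(r2))
        assert zc_dsdna_gc(f1) == pytest.approx(z1)
        assert abs(f1 - f2) < 0.02 and abs(z1 - z2) < 0.002


class TestZcRnaProtein:
    def test_poly_rg(self):
        # guanosine C10H13N5O5 by hand: (-13 + 15 + 10)/10 = 1.2
        assert zc_rna({"G": 100}) == pytest.approx(1.2)

    def test_ribose_displacement_is_exactly_point_two(self):
        # T-containing ssRNA at the A-T composition vs dsDNA at GC=0:
        # the only difference is ribose for deoxyribose
        rna_t = zc_rna({"A": 1, "U": 1}, thymine_variant=True)
        assert rna_t - zc_dsdna_gc(0.0) == pytest.approx(0.2)

    def test_rna_above_dna_at_full_gc(self):
        assert zc_rna({"G": 1, "C": 1}) > zc_dsdna_gc(1.0)

    def test_t_counts_read_as_u(self):
        assert zc_rna({"A": 2, "T": 3}) == zc_rna({"A": 2, "U": 3})

    def test_protein_worked_examples(self):
        assert zc_protein({"A": 50, "G": 50}) == pytest.approx(0.4)
        assert round(zc_protein({"A": 50, "L": 50}), 2) == -0.67
        assert zc_protein({"G": 10}) == pytest.approx(1.0)
        assert zc_protein({"Gly": 5, "Ala": 0}) == pytest.approx(1.0)

    def test_empty_or_unknown_rejected(self):
        with pytest.raises(ValueError):
            zc_protein({})
        with pytest.raises(ValueError):
            zc_protein({"X": 3})
        with pytest.raises(ValueError):
            zc_rna({"Q": 1})


class TestOrientCds:
    def test_positive_unchanged_negative_complemented(self):
        reads = make_reads(["ATGGCC"])
        assert orient_cds(reads, ["+"]).seqs == ["ATGGCC"]
        assert orient_cds(reads, ["-"]).seqs == ["GGCCAT"]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            orient_cds(make_reads(["ATG"]), ["?"])
        with pytest.raises(ValueError):
            orient_cds(make_reads(["ATG", "CCC"]), ["+"])

    def test_mixed_set_matches_hand_computed_counts(self):
        # r0 positive ATGC; r1 negative AACCG -> revcomp CGGTT;
        # r2 positive GGG.  Positive-sense totals by hand:
        # A: 1+0+0=1 ... T: 1+2+0=3, G: 1+2+3=6, C: 1+1+0=2
        reads = make_reads(["ATGC", "AACCG", "GGG"])
        oriented = orient_cds(reads, ["+", "-", "+"])
        counts = rna_counts_from_cds(oriented)
        assert counts == Counter({"A": 1, "U": 3, "G": 6, "C": 2})

    def test_fgs_header_convention(self):
        assert strand_from_fgs_header("readA_1_300_+") == "+"
        assert strand_from_fgs_header("readA_1_300_-") == "-"
        with pytest.raises(ValueError):
            strand_from_fgs_header("readA")


class TestTaxonPools:
    @pytest.fixture()
    def classified(self):
        # 1000 classified reads of 100 bases: taxon A 900 reads, taxon B 5
        # reads (0.5%), taxon C 95 reads but only 9500 bases total
        a, _ = gen_reads(0.35, 900, 100, 0, seed=7, label="A")
        b, _ = gen_reads(0.5, 5, 100, 0, seed=8, label="B")
        c, _ = gen_reads(0.65, 95, 100, 0, seed=9, label="C")
        ids = [f"A{i}" for i in range(900)] + [f"B{i}" for i in range(5)] + [
            f"C{i}" for i in range(95)]
        seqs = a.seqs + b.seqs + c.seqs
        assignments = {rid: rid[0] for rid in ids}
        return ReadSet(ids, seqs), assignments

    def test_fraction_threshold(self, classified):
        reads, assignments = classified
        pools = taxon_pools(reads, assignments, min_bases=0)
        assert "B" not in pools  # 0.5% < 1% of classified reads
        assert "A" in pools and "C" in pools

    def test_base_threshold(self, classified):
        reads, assignments = classified
        pools = taxon_pools(reads, assignments, min_bases=20000)
        assert "C" not in pools  # 9.5 kb < 20 kb despite >1% of reads
        assert "A" in pools

    def test_per_taxon_zc_matches_closed_form(self, classified):
        reads, assignments = classified
        pools = taxon_pools(reads, assignments, min_bases=0)
        for taxon in ("A", "C"):
            f = gc_content(pools[taxon])
            assert zc_dsdna(pools[taxon]) == pytest.approx(zc_dsdna_gc(f))
        # GC 0.35 vs 0.65 orders the taxa as the closed form predicts
        assert zc_dsdna(pools["A"]) < zc_dsdna(pools["C"])

    def test_unassigned_reads_ignored(self, classified):
        reads, assignments = classified
        partial = {k: v for k, v in assignments.items() if not k.startswith("C")}
        pools = taxon_read_sets(reads, partial, min_bases=0)
        assert set(pools) == {"A"}


class TestFastaIO:
    def test_roundtrip_and_max_bases(self, tmp_path):
        reads = make_reads(["ACGTACGT", "GGGG", "TTTT"])
        path = tmp_path / "x.fasta"
        reads.to_fasta(path)
        back = read_fasta(path)
        assert back.seqs == reads.seqs and back.ids == reads.ids
        capped = read_fasta(path, max_bases=9)
        assert len(capped) == 2  # stops once the cap is reached

    def test_fastq_accepted_qualities_ignored(self, tmp_path):
        path = tmp_path / "x.fastq"
        path.write_text("@r0\nACGT\n+\nIIII\n@r1\nGGTT\n+\nIIII\n")
        reads = read_fasta(path)
        assert reads.seqs == ["ACGT", "GGTT"]
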