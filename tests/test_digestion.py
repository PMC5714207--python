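"""IUPAC scanning, digestion, pre-computed files and index merging.

The scanner is checked two independent ways: against a naive
all-start-positions oracle written directly from the IUPAC degeneracy
tables, and against Biopython's Restriction package for a stock enzyme.
"""

import numpy as np
import pytest

from rrbsdesign.catalog import EnzymeSpec, IsoschizomerFamily
from rrbsdesign.digestion import (
    CutSiteIndex,
    PrecomputedFormatError,
    digest_genome,
    is_palindromic,
    iupac_match,
    iupac_reverse_complement,
    merge_cut_indices,
    read_precomputed,
    scan_cut_sites,
    write_precomputed,
)
from rrbsdesign.genome import GenomeSequence

# Independent degeneracy tables for the oracle (deliberately not imported
# from the package).
ORACLE_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
ORACLE_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def oracle_match(pattern, window):
    for p, w in zip(pattern, window):
        if p == "N":
            continue
        if w == "N" or w not in ORACLE_SETS[p]:
            return False
    return True


def oracle_cuts(seq, motif, offset):
    """Every start position, both strands, straight from the definitions."""
    seq = seq.upper()
    rc = motif.translate(ORACLE_COMPLEMENT)[::-1]
    n, m = len(seq), len(motif)
    cuts = set()
    for i in range(n - m + 1):
        window = seq[i : i + m]
        if oracle_match(motif, window):
            cuts.add(i + offset)
        if rc != motif and oracle_match(rc, window):
            cuts.add(i + m - offset)
    return sorted(cuts)


class TestIupacMatch:
    @pytest.mark.parametrize(
        "pattern,window,expected",
        [
            ("CCGG", "CCGG", True),
            ("WCCGGW", "TCCGGA", True),
            ("WCCGGW", "GCCGGA", False),
            ("CCGG", "CCGN", False),   # genome N never satisfies a base
            ("CNGG", "CNGG", True),    # pattern N accepts genome N
            ("RYSW", "AGCT", False),
            ("RYSW", "ATCA", True),
            ("RYSW", "GTGT", True),
        ],
    )
    def test_examples(self, pattern, window, expected):
        assert iupac_match(pattern, window) is expected

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            iupac_match("CCGG", "CCG")


class TestPalindromy:
    @pytest.mark.parametrize("motif", ["CCGG", "TCGA", "CCCGGG", "WCCGGW", "RGATCY"])
    def test_palindromic(self, motif):
        assert is_palindromic(motif)

    @pytest.mark.parametrize("motif", ["GACGC", "CCTC", "GGTCTC"])
    def test_non_palindromic(self, motif):
        assert not is_palindromic(motif)

    def test_reverse_complement_involution(self):
        for motif in ["CCGG", "GACGC", "WCCGGW", "NRYSWKM"]:
            assert iupac_reverse_complement(iupac_reverse_complement(motif)) == motif


class TestScanCutSites:
    def test_single_palindromic_match(self, mspi):
        assert scan_cut_sites("ATCCGGAT", mspi) == [3]

    def test_two_matches(self, mspi):
        assert scan_cut_sites("CCGGAACCGG", mspi) == [1, 7]

    def test_adjacent_matches(self, mspi):
        assert scan_cut_sites("CCGGCCGG", mspi) == [1, 5]

    def test_overlapping_matches_all_reported(self):
        enz = EnzymeSpec("FauxI", "CGCG", 1)
        # CGCGCG: matches start at 0 and 2.
        assert scan_cut_sites("CGCGCG", enz) == [1, 3]

    def test_empty_sequence(self, mspi):
        assert scan_cut_sites("", mspi) == []

    def test_n_run_produces_no_cuts(self, mspi):
        assert scan_cut_sites("CCNGGCCGN", mspi) == []

    def test_soft_masked_lowercase_scanned(self, mspi):
        assert scan_cut_sites("atccggat", mspi) == [3]

    def test_non_palindromic_both_strands(self):
        enz = EnzymeSpec("HgaIish", "GACGC", 2)
        # Top strand at 1 -> cut 3; bottom strand motif GCGTC at 8 -> cut 8+5-2.
        seq = "TGACGCTTGCGTCT"
        assert scan_cut_sites(seq, enz) == [3, 11]

    @pytest.mark.parametrize(
        "motif,offset",
        [("CCGG", 1), ("CGCG", 2), ("WCCGGW", 2), ("GACGC", 2),
         ("GWGCAC", 1), ("CCCGGG", 1), ("NCATGN", 3)],
    )
    def test_matches_naive_oracle_on_random_sequences(self, motif, offset):
        rng = np.random.default_rng(42)
        enz = EnzymeSpec(f"T_{motif}", motif, offset)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=2000))
            # splice in an N gap and a planted motif-rich patch
            seq = seq[:500] + "N" * 17 + seq[517:1500] + "CCGGGACGCTCGA" + seq[1513:]
            assert scan_cut_sites(seq, enz) == oracle_cuts(seq, motif, offset)

    def test_agrees_with_biopython_restriction(self):
        """Cross-check MspI coordinates against Bio.Restriction.

        Bio.Restriction reports 1-based positions of the first base of
        the downstream fragment, i.e. our 0-based cut coordinate + 1.
        """
        from Bio.Restriction import MspI
        from Bio.Seq import Seq

        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        ours = scan_cut_sites(seq, EnzymeSpec("MspI", "CCGG", 1))
        theirs = sorted(p - 1 for p in MspI.search(Seq(seq)))
        assert ours == theirs


class TestDigestGenome:
    def test_toy_genome(self, toy_genome, fam_mspi):
        index = digest_genome(toy_genome, fam_mspi)
        assert index.cuts == {"chr1": [1, 7]}
        assert index.genome_id == "toy"
        assert index.family_id == "fam_MspI"

    def test_absent_motif_gives_empty_list(self, toy_genome):
        fam = IsoschizomerFamily("fam_XmaI", (EnzymeSpec("XmaI", "CCCGGG", 1),))
        assert digest_genome(toy_genome, fam).cuts == {"chr1": []}

    def test_any_family_member_gives_identical_index(self, toy_genome):
        mspi = EnzymeSpec("MspI", "CCGG", 1)
        hpaii = EnzymeSpec("HpaII", "CCGG", 1, sensitive_cpg=True)
        fam_a = IsoschizomerFamily("f", (mspi, hpaii), representative=mspi)
        fam_b = IsoschizomerFamily("f", (mspi, hpaii), representative=hpaii)
        assert digest_genome(toy_genome, fam_a).cuts == digest_genome(toy_genome, fam_b).cuts

    def test_planted_fixture_ground_truth(self, scene):
        for fam, motif in [("fam_MspI", "CCGG"), ("fam_TaqI", "TCGA")]:
            family = next(f for f in scene.catalog if f.family_id == fam)
            index = digest_genome(scene.genome, family)
            if motif == "CCGG":
                # CCCGGG plants nest a CCGG: expect the union of both truths.
                expected = {
                    chrom: sorted(
                        {p + 1 for p in scene.truth["CCGG"][chrom]}
                        | {p + 2 for p in scene.truth["CCCGGG"][chrom]}
                    )
                    for chrom in scene.genome.chrom_names
                }
            else:
                expected = {
                    chrom: [p + 1 for p in scene.truth[motif][chrom]]
                    for chrom in scene.genome.chrom_names
                }
            assert index.cuts == expected


class TestPrecomputedFiles:
    def roundtrip(self, index, tmp_path, **kwargs):
        path = tmp_path / "cuts.txt.gz"
        write_precomputed(index, path)
        return read_precomputed(path, **kwargs)

    def test_round_trip(self, tmp_path):
        index = CutSiteIndex("toyA", "fam_MspI", {"chr1": [1, 7], "chr2": [3]})
        back = self.roundtrip(index, tmp_path)
        assert back.genome_id == "toyA"
        assert back.family_id == "fam_MspI"
        assert back.cuts == index.cuts

    def test_empty_index_round_trip(self, tmp_path):
        back = self.roundtrip(CutSiteIndex("toyA", "f", {}), tmp_path)
        assert back.cuts == {}

    def test_genome_mismatch_refused(self, tmp_path):
        index = CutSiteIndex("toyA", "f", {"chr1": [1]})
        with pytest.raises(PrecomputedFormatError, match="toyB"):
            self.roundtrip(index, tmp_path, expect_genome_id="toyB")

    def test_unsorted_file_rejected(self, tmp_path):
        import gzip

        path = tmp_path / "bad.txt.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("#genome_id=g\n#family_id=f\nchr1\t7\nchr1\t1\n")
        with pytest.raises(PrecomputedFormatError, match="increasing"):
            read_precomputed(path)


class TestMerge:
    def test_union(self):
        a = CutSiteIndex("g", "A", {"chr1": [1, 7]})
        b = CutSiteIndex("g", "B", {"chr1": [4]})
        merged = merge_cut_indices(a, b)
        assert merged.cuts == {"chr1": [1, 4, 7]}
        assert merged.family_id == "A+B"

    def test_idempotent_dedup(self):
        a = CutSiteIndex("g", "A", {"chr1": [3]})
        assert merge_cut_indices(a, a).cuts == {"chr1": [3]}

    def test_commutative(self):
        a = CutSiteIndex("g", "A", {"chr1": [1, 9], "chr2": [2]})
        b = CutSiteIndex("g", "B", {"chr1": [5]})
        assert merge_cut_indices(a, b).cuts == merge_cut_indices(b, a).cuts

    def test_associative(self):
        a = CutSiteIndex("g", "A", {"chr1": [1]})
        b = CutSiteIndex("g", "B", {"chr1": [5]})
        c = CutSiteIndex("g", "C", {"chr1": [3, 5]})
        left = merge_cut_indices(merge_cut_indices(a, b), c)
        right = merge_cut_indices(a, merge_cut_indices(b, c))
        assert left.cuts == right.cuts

    def test_genome_mismatch_rejected(self):
        a = CutSiteIndex("g1", "A", {})
        b = CutSiteIndex("g2", "B", {})
        with pytest.raises(ValueError, match="different genomes"):
            merge_cut_indices(a, b)

    def test_union_equals_joint_scan(self):
        """Merging two single-enzyme digests == one pass with both motifs."""
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=8000))
        genome = GenomeSequence.from_dict("g", {"chr1": seq})
        mspi = IsoschizomerFamily("M", (EnzymeSpec("MspI", "CCGG", 1),))
        taqi = IsoschizomerFamily("T", (EnzymeSpec("TaqI", "TCGA", 1),))
        merged = merge_cut_indices(
            digest_genome(genome, mspi), digest_genome(genome, taqi)
        )
        joint = sorted(
            set(oracle_cuts(seq, "CCGG", 1)) | set(oracle_cuts(seq, "TCGA", 1))
        )
        assert merged.cuts["chr1"] == joint
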