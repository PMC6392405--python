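"""Validation-design filters: expression allowlist, distal-mismatch
selection, restriction-site cleavage assays, shared-flank deletion guides,
and transversion guide variants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cascensus.design import (
    builtin_enzymes,
    design_pair,
    filter_expressed,
    filter_first3,
    restriction_assay_candidates,
    shared_flank_guides,
    transversion_variant,
)
from cascensus.genome import GenomeSequence
from cascensus.offtargets import classify_pair
from cascensus.profiles import cut_position, get_profile
from cascensus.scan import TargetSite

SPCAS9 = get_profile("SpCas9")


def mk(spacer, start=0, chrom="chr1", strand="+", pam="TGG", genes=()):
    return TargetSite("SpCas9", chrom, start, start + 23, strand, spacer, pam, tuple(genes))


def mk_pair(t_genes, o_genes, mismatch_pos=None):
    spacer = "ATAT" * 5
    other = spacer if mismatch_pos is None else transversion_variant(spacer, mismatch_pos)
    return classify_pair(mk(spacer, 0, genes=t_genes), mk(other, 100, genes=o_genes))


class TestExpressionAndDistalFilters:
    def test_both_genes_listed_kept(self):
        pair = mk_pair(("g1",), ("g2",))
        assert filter_expressed([pair], {"g1", "g2"}) == [pair]

    def test_one_end_unlisted_dropped(self):
        pair = mk_pair(("g1",), ("g2",))
        assert filter_expressed([pair], {"g1"}) == []

    def test_full_allowlist_is_identity(self):
        pairs = [mk_pair(("g1",), ("g2",)), mk_pair(("g3",), ("g4",), 2)]
        assert filter_expressed(pairs, {"g1", "g2", "g3", "g4"}) == pairs

    def test_empty_allowlist_warns_and_empties(self):
        with pytest.warns(UserWarning, match="empty"):
            assert filter_expressed([mk_pair(("g1",), ("g2",))], set()) == []

    def test_first3_keeps_only_distal_1_to_3_mismatches(self):
        identical = mk_pair(("g1",), ("g2",))
        pos1 = mk_pair(("g1",), ("g2",), 1)
        pos7 = mk_pair(("g1",), ("g2",), 7)
        assert filter_first3([identical, pos1, pos7]) == [pos1]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([None, 1, 2, 3, 7, 15]), min_size=0, max_size=6))
    def test_filters_commute(self, positions):
        pairs = [
            mk_pair(("g1",) if i % 2 else ("gX",), ("g2",), pos)
            for i, pos in enumerate(positions)
        ]
        allow = {"g1", "g2"}
        assert filter_first3(filter_expressed(pairs, allow)) == filter_expressed(filter_first3(pairs), allow)


class TestRestrictionAssay:
    # spacer whose positions 15-20 spell GAATTC, so the EcoRI site spans the
    # expected cut (between spacer positions 17 and 18)
    SPACER = "C" * 14 + "GAATTC"
    GENOME = GenomeSequence({"chr1": "A" * 10 + SPACER + "TGG" + "A" * 10})
    SITE = mk(SPACER, 10)

    def test_recognition_interval_containing_cut_is_hit(self):
        hits = restriction_assay_candidates(self.SITE, [("EcoRI", "GAATTC")], self.GENOME)
        assert [h.enzyme for h in hits] == ["EcoRI"]
        cut = cut_position(self.SITE, SPCAS9)
        assert all(h.start < cut < h.end for h in hits)

    def test_recognition_interval_touching_cut_boundary_is_not_hit(self):
        # an interval that merely ends (or starts) at the between-base cut
        # survives a clean cut-and-rejoin, so strict containment excludes it
        boundary_seq = self.GENOME["chr1"][27:33]
        hits = restriction_assay_candidates(self.SITE, [("Edge", boundary_seq)], self.GENOME)
        assert hits == []

    def test_minus_strand_recognition_detected(self):
        hits = restriction_assay_candidates(self.SITE, [("RevEco", "CTGCAG")], self.GENOME)
        assert hits == []  # absent entirely
        # non-palindromic recognition present only as reverse complement
        spacer = "C" * 14 + "GGTCTC"  # BsaI top strand at spacer 15-20
        genome = GenomeSequence({"chr1": "A" * 10 + spacer + "TGG" + "A" * 10})
        site = mk(spacer, 10)
        hits = restriction_assay_candidates(site, [("BsaI-rc", "GAGACC")], genome)
        assert [h.strand for h in hits] == ["-"]

    def test_empty_enzyme_table(self):
        assert restriction_assay_candidates(self.SITE, [], self.GENOME) == []

    def test_builtin_table_is_iupac_clean(self):
        enzymes = builtin_enzymes()
        assert ("EcoRI", "GAATTC") in enzymes
        assert all(set(seq) <= set("ACGTRYSWKMBDHVN") for _, seq in enzymes)


def _deletion_fixture():
    """Two loci with an identical extra guide site planted 50 nt downstream
    of both; a second guide appears only near the target locus."""
    t_spacer = "ATAT" * 5
    o_spacer = transversion_variant(t_spacer, 2)
    shared_guide = "ACACACACACACACACACAT" + "AGG"
    lone_guide = "TATATATATATATATATACT" + "CGG"
    chrom1 = "A" * 100 + t_spacer + "TGG" + "A" * 50 + shared_guide + "A" * 30 + lone_guide + "A" * 300
    chrom2 = "A" * 200 + o_spacer + "TGG" + "A" * 50 + shared_guide + "A" * 500
    genome = GenomeSequence({"chr1": chrom1, "chr2": chrom2})
    target = mk(t_spacer, 100, "chr1", genes=("g1",))
    offtarget = mk(o_spacer, 200, "chr2", genes=("g2",))
    pair = classify_pair(target, offtarget)
    return genome, pair, shared_guide, lone_guide


class TestSharedFlankGuides:
    def test_guide_planted_near_both_loci_is_returned_with_offsets(self):
        genome, pair, shared_guide, _ = _deletion_fixture()
        guides = shared_flank_guides(pair, genome, window=1000)
        sequences = {g.sequence for g in guides}
        assert shared_guide in sequences
        hit = next(g for g in guides if g.sequence == shared_guide)
        assert hit.target_offset == 50 and hit.offtarget_offset == 50

    def test_guide_near_only_one_locus_not_returned(self):
        genome, pair, _, lone_guide = _deletion_fixture()
        guides = shared_flank_guides(pair, genome, window=1000)
        assert lone_guide not in {g.sequence for g in guides}

    def test_symmetric_in_the_two_sites(self):
        genome, pair, _, _ = _deletion_fixture()
        swapped = classify_pair(pair.offtarget, pair.target)
        fwd = {g.sequence for g in shared_flank_guides(pair, genome, window=1000)}
        rev = {g.sequence for g in shared_flank_guides(swapped, genome, window=1000)}
        assert fwd == rev

    def test_zero_window_empty(self):
        genome, pair, _, _ = _deletion_fixture()
        assert shared_flank_guides(pair, genome, window=0) == []

    def test_design_pair_prefers_restriction_then_deletion(self):
        genome, pair, _, _ = _deletion_fixture()
        design = design_pair(pair, genome)
        assert design.assay == "paired_deletion"
        assert design.shared_guides


class TestTransversionVariant:
    def test_distal_position_one_substitutes_the_five_prime_base(self):
        assert transversion_variant("TGGCAAAGGAACAAAGCCAT", 1) == "AGGCAAAGGAACAAAGCCAT"

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError, match="out of range"):
            transversion_variant("ACGT", 5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=23), st.data())
    def test_involution_and_single_transversion(self, spacer, data):
        pos = data.draw(st.integers(1, len(spacer)))
        variant = transversion_variant(spacer, pos)
        assert transversion_variant(variant, pos) == spacer
        diffs = [i for i, (a, b) in enumerate(zip(spacer, variant)) if a != b]
        assert len(diffs) == 1
        purines = set("AG")
        assert (spacer[diffs[0]] in purines) != (variant[diffs[0]] in purines)
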