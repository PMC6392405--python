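"""Target enumeration: completeness, containment filtering, dedup, I/O."""

import pytest

from cascensus.genome import CodingAnnotation, CodingInterval, GenomeSequence, reverse_complement
from cascensus.profiles import IUPAC_SETS, NucleaseProfile, builtin_profiles, get_profile
from cascensus.scan import (
    TargetSite,
    count_targets,
    read_sites_tsv,
    scan_targets,
    write_sites_bed,
    write_sites_tsv,
)
from cascensus.simulate import (
    PlantEntry,
    SyntheticGenomeSpec,
    demo_spec,
    generate_genome,
)

TOY = NucleaseProfile("Toy", 2, "GG", "3_prime")


def naive_enumerate(seq, profile):
    """Independent all-windows matcher used as the small-scale reference."""
    w = profile.spacer_length + len(profile.pam_pattern)
    out = set()
    for start in range(len(seq) - w + 1):
        for strand in "+-":
            window = seq[start:start + w] if strand == "+" else reverse_complement(seq[start:start + w])
            if profile.pam_side == "3_prime":
                spacer, pam = window[:profile.spacer_length], window[profile.spacer_length:]
            else:
                pam, spacer = window[:len(profile.pam_pattern)], window[len(profile.pam_pattern):]
            if any(c not in "ACGT" for c in spacer):
                continue
            if all(c in IUPAC_SETS[p] for c, p in zip(pam, profile.pam_pattern)):
                out.add((start, strand, spacer, pam))
    return out


def as_tuples(sites):
    return {(s.start, s.strand, s.spacer, s.pam) for s in sites}


class TestScanTargets:
    def test_nine_mer_hand_enumeration(self):
        genome = GenomeSequence({"chr1": "AAAAGGAAA"})
        sites = scan_targets(genome, TOY)
        assert as_tuples(sites) == naive_enumerate("AAAAGGAAA", TOY)
        # spot-check one known forward site: spacer "AA" at [2,4) + PAM "GG"
        assert (2, "+", "AA", "GG") in as_tuples(sites)

    @pytest.mark.parametrize("profile", builtin_profiles(), ids=lambda p: p.name)
    def test_matches_naive_enumeration_on_random_sequence(self, profile):
        genome, _, _ = generate_genome(
            SyntheticGenomeSpec(chromosome_lengths=(3000,), n_genes=4, seed=7)
        )
        sites = scan_targets(genome, profile)
        assert as_tuples(sites) == naive_enumerate(genome["chr1"], profile)

    def test_windows_containing_n_are_excluded(self):
        genome = GenomeSequence({"chr1": "AANAGGAAA"})
        assert all("N" not in s.spacer and "N" not in s.pam for s in scan_targets(genome, TOY))
        assert (2, "+", "NA", "GG") not in as_tuples(scan_targets(genome, TOY))

    def test_annotation_filter_only_removes(self, demo):
        genome, annotation, _ = demo
        prof = get_profile("SpCas9")
        unrestricted = {s.key for s in scan_targets(genome, prof)}
        restricted = {s.key for s in scan_targets(genome, prof, annotation)}
        assert restricted <= unrestricted
        assert len(restricted) < len(unrestricted)

    def test_full_containment_excludes_border_straddlers(self):
        seq = "A" * 30 + "T" * 2 + "GG" + "A" * 30
        genome = GenomeSequence({"chr1": seq})
        # toy site occupies [30, 34); an exon covering only part of it fails
        partial = CodingAnnotation([CodingInterval("chr1", 0, 32, "+", "g1")])
        full = CodingAnnotation([CodingInterval("chr1", 28, 36, "+", "g1")])
        assert (30, "+", "TT", "GG") not in as_tuples(scan_targets(genome, TOY, partial))
        assert (30, "+", "TT", "GG") in as_tuples(scan_targets(genome, TOY, full))

    def test_planted_validated_spacer_recovered(self):
        spec = SyntheticGenomeSpec(
            chromosome_lengths=(20000,),
            n_genes=10,
            plants=(PlantEntry("SpCas9", "TGGCAAAGGAACAAAGCCAT", 1, (None,), (True,), ("-",)),),
            seed=11,
        )
        genome, annotation, truth = generate_genome(spec)
        sites = scan_targets(genome, get_profile("SpCas9"), annotation)
        hits = [s for s in sites if s.spacer == "TGGCAAAGGAACAAAGCCAT"]
        assert len(hits) == 1
        assert hits[0].key == truth.planted[0].site.key
        assert hits[0].strand == "-"
        assert hits[0].genes  # attributed to the containing gene

    def test_window_longer_than_chromosome_yields_no_sites(self):
        genome = GenomeSequence({"chr1": "ACGTACGT"})
        assert scan_targets(genome, get_profile("SpCas9")) == []

    def test_strand_completeness_under_reverse_complement(self):
        genome, annotation, _ = generate_genome(
            SyntheticGenomeSpec(chromosome_lengths=(5000,), n_genes=6, seed=3)
        )
        prof = get_profile("SpCas9")
        L = len(genome["chr1"])
        mirror = GenomeSequence({"chr1": reverse_complement(genome["chr1"])})
        mirror_ann = CodingAnnotation(
            [CodingInterval(r.chrom, L - r.end, L - r.start, "+" if r.strand == "-" else "-", r.gene_id)
             for r in annotation.records]
        )
        orig = {(L - s.end, "-" if s.strand == "+" else "+", s.spacer, s.pam)
                for s in scan_targets(genome, prof, annotation)}
        mirrored = as_tuples(scan_targets(mirror, prof, mirror_ann))
        assert orig == mirrored


class TestCountTargets:
    def test_empty(self):
        assert count_targets([]) == 0

    def test_site_in_two_isoform_records_counts_once(self):
        a = TargetSite("SpCas9", "chr1", 5, 28, "+", "A" * 20, "AGG", ("g1",))
        b = TargetSite("SpCas9", "chr1", 5, 28, "+", "A" * 20, "AGG", ("g1", "g2"))
        assert count_targets([a, b]) == 1

    def test_planted_in_exon_count(self, demo, demo_spcas9):
        _, _, truth = demo
        targets, _ = demo_spcas9
        keys = {s.key for s in targets}
        for planted in truth.planted:
            assert (planted.site.key in keys) == planted.in_exon


class TestSiteIO:
    def test_tsv_round_trip(self, tmp_path, demo_spcas9):
        targets, _ = demo_spcas9
        path = tmp_path / "sites.tsv"
        write_sites_tsv(targets[:50], path)
        assert read_sites_tsv(path) == list(targets[:50])

    def test_bed_columns(self, tmp_path, demo_spcas9):
        targets, _ = demo_spcas9
        path = tmp_path / "sites.bed"
        write_sites_bed(targets[:5], path)
        line = path.read_text().splitlines()[0].split("\t")
        assert len(line) == 6
        assert line[3] == f"{targets[0].profile}:{targets[0].spacer}"
        assert line[5] in "+-"
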