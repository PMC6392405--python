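"""Enumeration of protospacer+PAM target sites on both strands.

Every window of spacer+PAM length whose PAM portion matches the profile's
IUPAC pattern is a candidate target; windows containing N are excluded.
With an annotation supplied, only sites whose *full* interval (spacer plus
PAM) is contained within a single merged coding interval are kept, so a
site straddling an exon border does not count and isoform duplication
cannot double-count.  Overlapping and nested windows are all emitted; sites
are genomic occurrences, so two loci carrying the same spacer are two
targets (and each other's potential off-targets).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from cascensus.genome import CodingAnnotation, GenomeSequence, reverse_complement
from cascensus.profiles import (
    THREE_PRIME,
    NucleaseProfile,
    pattern_to_regex,
    reverse_complement_pattern,
)

__all__ = ["TargetSite", "scan_targets", "count_targets", "write_sites_tsv", "read_sites_tsv", "write_sites_bed"]


@dataclass(frozen=True)
class TargetSite:
    """One genomic protospacer+PAM occurrence.

    ``start``/``end`` span the full site (spacer plus PAM) in forward-strand
    0-based half-open coordinates; ``spacer`` and ``pam`` are written 5'->3'
    on the site's own strand.
    """

    profile: str
    chrom: str
    start: int
    end: int
    strand: str
    spacer: str
    pam: str
    genes: tuple[str, ...] = ()

    @property
    def key(self) -> tuple[str, int, str]:
        """Genomic identity: (chromosome, start, strand)."""
        return (self.chrom, self.start, self.strand)


def full_site_sequence(site: TargetSite, profile: NucleaseProfile) -> str:
    """Spacer and PAM concatenated 5'->3' on the site's strand."""
    if profile.pam_side == THREE_PRIME:
        return site.spacer + site.pam
    return site.pam + site.spacer


def scan_string(seq: str, profile: NucleaseProfile) -> Iterator[tuple[int, str, str, str]]:
    """Yield (offset, strand, spacer, pam) for every site in ``seq``.

    Offsets index the full spacer+PAM window within ``seq`` (forward
    orientation); overlapping windows are all reported via zero-width
    lookahead matching.
    """
    L = profile.spacer_length
    pam_re = pattern_to_regex(profile.pam_pattern)
    rc_pam_re = pattern_to_regex(reverse_complement_pattern(profile.pam_pattern))
    spacer_re = "[ACGT]{%d}" % L
    if profile.pam_side == THREE_PRIME:
        fwd = re.compile(f"(?=({spacer_re})({pam_re}))")
        rev = re.compile(f"(?=({rc_pam_re})({spacer_re}))")
        for m in fwd.finditer(seq):
            yield m.start(), "+", m.group(1), m.group(2)
        for m in rev.finditer(seq):
            yield m.start(), "-", reverse_complement(m.group(2)), reverse_complement(m.group(1))
    else:
        fwd = re.compile(f"(?=({pam_re})({spacer_re}))")
        rev = re.compile(f"(?=({spacer_re})({rc_pam_re}))")
        for m in fwd.finditer(seq):
            yield m.start(), "+", m.group(2), m.group(1)
        for m in rev.finditer(seq):
            yield m.start(), "-", reverse_complement(m.group(1)), reverse_complement(m.group(2))


def scan_targets(
    genome: GenomeSequence,
    profile: NucleaseProfile,
    annotation: CodingAnnotation | None = None,
) -> list[TargetSite]:
    """Enumerate all target sites of ``profile`` in ``genome``.

    With ``annotation`` given, keep only sites fully contained in a merged
    coding interval and attribute overlapping gene ids.  Output is sorted by
    (chromosome, start, strand), one record per distinct genomic site.
    """
    if annotation is not None:
        missing = {r.chrom for r in annotation.records} - set(genome)
        if missing:
            raise ValueError(f"annotation chromosomes absent from genome: {sorted(missing)}")
    w = profile.site_length
    sites = []
    for chrom in genome:
        seq = genome[chrom]
        if len(seq) < w:
            continue
        for off, strand, spacer, pam in scan_string(seq, profile):
            start, end = off, off + w
            if annotation is not None:
                if not annotation.contains(chrom, start, end):
                    continue
                genes = annotation.genes_overlapping(chrom, start, end)
            else:
                genes = ()
            sites.append(TargetSite(profile.name, chrom, start, end, strand, spacer, pam, genes))
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return sites


def count_targets(sites: Iterable[TargetSite]) -> int:
    """Number of distinct genomic sites (chromosome, start, strand)."""
    return len({s.key for s in sites})


_TSV_COLUMNS = ["profile", "chrom", "start", "end", "strand", "spacer", "pam", "genes"]


def write_sites_tsv(sites: Iterable[TargetSite], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for s in sites:
            writer.writerow([s.profile, s.chrom, s.start, s.end, s.strand, s.spacer, s.pam, ",".join(s.genes)])


def read_sites_tsv(path: str | Path) -> list[TargetSite]:
    sites = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            genes = tuple(g for g in row["genes"].split(",") if g)
            sites.append(
                TargetSite(
                    row["profile"], row["chrom"], int(row["start"]), int(row["end"]),
                    row["strand"], row["spacer"], row["pam"], genes,
                )
            )
    return sites


def write_sites_bed(sites: Iterable[TargetSite], path: str | Path) -> None:
    """BED6: full-site interval, name = profile:spacer, strand column."""
    with open(path, "w", newline="") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.profile}:{s.spacer}\t0\t{s.strand}\n")
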