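"""Guide-validation design filters for target/off-target pairs.

These reproduce the experimental-design funnel used to pick pairs for
protoplast validation: restrict to genes on an expression allowlist
(standing in for a leaf-expression atlas query), keep pairs whose single
mismatch lies in the first three PAM-distal spacer positions (where
wild-type Cas9 tolerates mismatches, so off-target cleavage is expected),
and then find a readout: either a Type II restriction site overlapping the
expected cut (lost upon indel formation, enabling a cleavage-resistance
assay) or an additional guide site present identically within 1000 bp of
both loci (enabling a detectable paired deletion).

A transversion-variant constructor for mismatched-guide panels is included:
substituting a spacer base with its complement is always a
purine<->pyrimidine change, giving a deterministic transversion rule.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from cascensus.genome import GenomeSequence, reverse_complement
from cascensus.offtargets import POS_1_3, OffTargetPair
from cascensus.profiles import FIVE_PRIME, NucleaseProfile, cut_position, get_profile, iupac_match
from cascensus.scan import TargetSite, full_site_sequence, scan_string

__all__ = [
    "RestrictionHit",
    "SharedGuide",
    "GuidePairDesign",
    "filter_expressed",
    "filter_first3",
    "load_enzymes",
    "builtin_enzymes",
    "restriction_assay_candidates",
    "shared_flank_guides",
    "transversion_variant",
    "design_pair",
]


@dataclass(frozen=True)
class RestrictionHit:
    """A restriction recognition interval containing the expected cut."""

    enzyme: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class SharedGuide:
    """A full guide site (spacer+PAM) present near both loci of a pair."""

    sequence: str
    target_offset: int
    offtarget_offset: int


@dataclass
class GuidePairDesign:
    """Assay decision and evidence for one candidate pair."""

    pair: OffTargetPair
    assay: str = "none"  # restriction_site | paired_deletion | none
    restriction_hits: list[RestrictionHit] = field(default_factory=list)
    shared_guides: list[SharedGuide] = field(default_factory=list)


def filter_expressed(pairs: Iterable[OffTargetPair], allowlist: set[str]) -> list[OffTargetPair]:
    """Keep pairs whose target *and* off-target genes intersect the allowlist."""
    if not allowlist:
        warnings.warn("empty expression allowlist: all pairs filtered out", stacklevel=2)
        return []
    return [
        p for p in pairs
        if set(p.target.genes) & allowlist and set(p.offtarget.genes) & allowlist
    ]


def filter_first3(pairs: Iterable[OffTargetPair]) -> list[OffTargetPair]:
    """Keep pairs differing at a single base in PAM-distal positions 1-3."""
    return [p for p in pairs if p.mismatch_class == POS_1_3]


def load_enzymes(path: str | Path) -> list[tuple[str, str]]:
    """Read an enzyme table TSV: name <tab> IUPAC recognition sequence."""
    enzymes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, seq = line.split("\t")[:2]
            if name == "name":
                continue
            enzymes.append((name, seq.upper()))
    return enzymes


def builtin_enzymes() -> list[tuple[str, str]]:
    """Small bundled table of common Type II six-cutters."""
    ref = resources.files("cascensus").joinpath("data/enzymes.tsv")
    with resources.as_file(ref) as path:
        return load_enzymes(path)


def restriction_assay_candidates(
    site: TargetSite,
    enzymes: Sequence[tuple[str, str]],
    genome: GenomeSequence,
    profile: NucleaseProfile | None = None,
) -> list[RestrictionHit]:
    """Enzymes whose recognition interval strictly contains the cut point.

    Strict containment (the between-base cut point in the recognition
    interval's interior) guarantees an indel at the cut destroys the site;
    a recognition site merely touching the cut at its boundary survives a
    clean cut-and-rejoin, so it does not qualify.
    """
    if profile is None:
        profile = get_profile(site.profile)
    cut = cut_position(site, profile)
    seq = genome[site.chrom]
    hits: list[RestrictionHit] = []
    for name, recog in enzymes:
        k = len(recog)
        rc = None
        for start in range(max(0, cut - k + 1), min(len(seq) - k, cut - 1) + 1):
            # strict: start < cut < start + k
            if not (start < cut < start + k):
                continue
            window = seq[start:start + k]
            if "N" in window:
                continue
            if iupac_match(window, recog):
                hits.append(RestrictionHit(name, site.chrom, start, start + k, "+"))
                continue
            if rc is None:
                rc = reverse_complement(recog)
            # an enzyme site is double-stranded; report minus-strand-pattern
            # occurrences for non-palindromic recognition sequences
            if iupac_match(window, rc):
                hits.append(RestrictionHit(name, site.chrom, start, start + k, "-"))
    return hits


def _flank_guides(
    genome: GenomeSequence,
    site: TargetSite,
    profile: NucleaseProfile,
    window: int,
) -> dict[str, list[int]]:
    """Full-site sequences found in the two flanks of ``site``.

    Offsets are signed positions of the guide window start relative to the
    site's start (upstream flank, negative) or end (downstream, positive);
    guides overlapping the site itself are excluded because the flanks do.
    """
    seq = genome[site.chrom]
    found: dict[str, list[int]] = {}
    up_lo = max(0, site.start - window)
    if site.start - window < 0 or site.end + window > len(seq):
        warnings.warn(
            f"flank window truncated at chromosome end for site {site.chrom}:{site.start}",
            stacklevel=3,
        )
    for flank_seq, base in (
        (seq[up_lo:site.start], up_lo - site.start),
        (seq[site.end:min(len(seq), site.end + window)], 0),
    ):
        for off, strand, spacer, pam in scan_string(flank_seq, profile):
            guide = TargetSite(profile.name, site.chrom, 0, 0, strand, spacer, pam)
            full = full_site_sequence(guide, profile)
            found.setdefault(full, []).append(base + off)
    return found


def shared_flank_guides(
    pair: OffTargetPair,
    genome: GenomeSequence,
    profile: NucleaseProfile | None = None,
    window: int = 1000,
) -> list[SharedGuide]:
    """Guide sites present identically in flanks of both loci of a pair.

    Scans ``window`` nt on each side of the target and of the off-target
    for valid sites of the profile and returns the full spacer+PAM
    sequences occurring (on either strand, either side) near both loci —
    the second guide needed to create a detectable deletion at each locus.
    """
    if window <= 0:
        return []
    if profile is None:
        profile = get_profile(pair.target.profile)
    near_t = _flank_guides(genome, pair.target, profile, window)
    near_o = _flank_guides(genome, pair.offtarget, profile, window)
    shared = []
    for full in sorted(set(near_t) & set(near_o)):
        shared.append(SharedGuide(full, near_t[full][0], near_o[full][0]))
    return shared


def transversion_variant(spacer: str, position: int, pam_side: str = "3_prime") -> str:
    """Substitute the base at a PAM-distal 1-based position with its
    complement — always a transversion — leaving all other bases unchanged.
    """
    L = len(spacer)
    if not 1 <= position <= L:
        raise ValueError(f"position {position} out of range 1..{L}")
    idx = (L - position) if pam_side == FIVE_PRIME else (position - 1)
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}[spacer[idx]]
    return spacer[:idx] + comp + spacer[idx + 1:]


def design_pair(
    pair: OffTargetPair,
    genome: GenomeSequence,
    enzymes: Sequence[tuple[str, str]] | None = None,
    window: int = 1000,
    profile: NucleaseProfile | None = None,
) -> GuidePairDesign:
    """Pick a validation assay for one pair.

    Prefers a restriction-site cleavage assay (a hit at both loci), falling
    back to a shared-flank paired-deletion design, else ``none``.
    """
    if profile is None:
        profile = get_profile(pair.target.profile)
    if enzymes is None:
        enzymes = builtin_enzymes()
    design = GuidePairDesign(pair=pair)
    hits_t = restriction_assay_candidates(pair.target, enzymes, genome, profile)
    hits_o = restriction_assay_candidates(pair.offtarget, enzymes, genome, profile)
    design.restriction_hits = hits_t + hits_o
    common = {h.enzyme for h in hits_t} & {h.enzyme for h in hits_o}
    if common:
        design.assay = "restriction_site"
        return design
    design.shared_guides = shared_flank_guides(pair, genome, profile, window)
    if design.shared_guides:
        design.assay = "paired_deletion"
    return design


def write_designs_tsv(designs: Iterable[GuidePairDesign], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([
            "target_chrom", "target_start", "target_spacer",
            "offtarget_chrom", "offtarget_start", "offtarget_spacer",
            "mismatch_position", "assay", "restriction_enzymes", "shared_guides",
        ])
        for d in designs:
            p = d.pair
            writer.writerow([
                p.target.chrom, p.target.start, p.target.spacer,
                p.offtarget.chrom, p.offtarget.start, p.offtarget.spacer,
                "" if p.mismatch_position is None else p.mismatch_position,
                d.assay,
                ",".join(sorted({h.enzyme for h in d.restriction_hits})),
                ",".join(g.sequence for g in d.shared_guides),
            ])
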