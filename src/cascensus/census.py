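"""End-to-end coding-exon census: scan, pair search, summary table.

`run_census` ties the pipeline together for any genome + annotation pair;
`reproduce_census` is the file-level entry point for running the full
census on a real genome release (e.g. the Arabidopsis TAIR10
whole-chromosome FASTA plus its GFF3 gene annotation) — expect tens of
minutes and a few GB of memory at plant-genome scale.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from cascensus.genome import read_coding_exons, read_genome
from cascensus.offtargets import OffTargetSummary, find_offtargets, summarize_offtargets
from cascensus.profiles import NucleaseProfile, builtin_profiles
from cascensus.scan import scan_targets

__all__ = ["run_census", "reproduce_census"]


def run_census(
    genome,
    annotation,
    profiles: Sequence[NucleaseProfile] | None = None,
    max_mismatch: int = 1,
    convention: str = "targets_with_class",
) -> dict[str, OffTargetSummary]:
    """Per-profile coding-exon target and off-target summary."""
    if profiles is None:
        profiles = builtin_profiles()
    summaries = {}
    for prof in profiles:
        targets = scan_targets(genome, prof, annotation)
        pairs = find_offtargets(targets, max_mismatch=max_mismatch, profile=prof)
        summaries[prof.name] = summarize_offtargets(targets, pairs, convention=convention)
    return summaries


def reproduce_census(
    fasta_path: str | Path,
    gff_path: str | Path,
    profiles: Sequence[NucleaseProfile] | None = None,
    feature_type: str = "CDS",
    convention: str = "targets_with_class",
) -> dict[str, OffTargetSummary]:
    """Run the full coding-exon census from genome + annotation files."""
    genome = read_genome(fasta_path)
    annotation = read_coding_exons(gff_path, feature_type=feature_type, genome=genome)
    return run_census(genome, annotation, profiles=profiles, convention=convention)
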