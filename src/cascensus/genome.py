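"""Genome and coding-annotation model.

Whole genomes load into memory as plain upper-case strings (the organisms
this census targets are small enough that indexed access buys nothing), and
all internal coordinates are 0-based half-open on the forward strand.
Conversion from GFF3's 1-based inclusive convention happens exactly once,
at the file boundary.

"Coding exons" are GFF3 features of a configurable type, ``CDS`` by
default, which is how coding portions of exons are annotated in standard
plant genome releases.  Per-gene records are preserved for attribution, and
a merged (isoform-deduplicated) interval set per chromosome backs the
containment queries used by the target scan.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeSequence",
    "CodingInterval",
    "CodingAnnotation",
    "read_genome",
    "read_coding_exons",
    "fetch_sequence",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence(Mapping):
    """Chromosome id -> upper-case nucleotide string (A/C/G/T/N only)."""

    def __init__(self, sequences: Mapping[str, str]):
        seqs = {}
        for name, seq in sequences.items():
            if not name:
                raise ValueError("chromosome identifier must be non-empty")
            if name in seqs:
                raise ValueError(f"duplicate chromosome identifier {name!r}")
            seq = seq.upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise ValueError(
                    f"chromosome {name!r} contains non-A/C/G/T/N character "
                    f"{seq[pos]!r} at position {pos}"
                )
            seqs[name] = seq
        self._seqs = seqs

    def __getitem__(self, key: str) -> str:
        return self._seqs[key]

    def __iter__(self):
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}


@dataclass(frozen=True)
class CodingInterval:
    """One gene-attributed coding feature, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str


class CodingAnnotation:
    """Gene-attributed coding intervals plus merged containment indexes."""

    def __init__(self, records: Iterable[CodingInterval], chrom_lengths: Mapping[str, int] | None = None):
        self.records: list[CodingInterval] = sorted(
            records, key=lambda r: (r.chrom, r.start, r.end, r.gene_id)
        )
        for r in self.records:
            if not (0 <= r.start < r.end):
                raise ValueError(f"invalid interval {r}")
            if chrom_lengths is not None and r.end > chrom_lengths.get(r.chrom, r.end):
                raise ValueError(f"interval {r} exceeds chromosome length")
            if r.strand not in "+-":
                raise ValueError(f"invalid strand in {r}")
        self._merged: dict[str, list[tuple[int, int]]] | None = None
        self._trees: dict[str, IntervalTree] | None = None
        self._gene_trees: dict[str, IntervalTree] | None = None

    def merged_intervals(self) -> dict[str, list[tuple[int, int]]]:
        """Per-chromosome genomic intervals merged across genes/isoforms."""
        if self._merged is None:
            merged: dict[str, list[tuple[int, int]]] = {}
            for r in self.records:
                ivs = merged.setdefault(r.chrom, [])
                if ivs and r.start <= ivs[-1][1]:
                    ivs[-1] = (ivs[-1][0], max(ivs[-1][1], r.end))
                else:
                    ivs.append((r.start, r.end))
            self._merged = merged
        return self._merged

    def _merged_trees(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            self._trees = {
                chrom: IntervalTree.from_tuples(ivs)
                for chrom, ivs in self.merged_intervals().items()
            }
        return self._trees

    def contains(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) is fully inside one merged coding interval."""
        tree = self._merged_trees().get(chrom)
        if tree is None:
            return False
        return any(iv.begin <= start and end <= iv.end for iv in tree.overlap(start, end))

    def genes_overlapping(self, chrom: str, start: int, end: int) -> tuple[str, ...]:
        """Sorted ids of genes whose coding records overlap [start, end)."""
        if self._gene_trees is None:
            trees: dict[str, IntervalTree] = {}
            for r in self.records:
                trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r.gene_id)
            self._gene_trees = trees
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return ()
        return tuple(sorted({iv.data for iv in tree.overlap(start, end)}))

    def __len__(self) -> int:
        return len(self.records)


def read_genome(path: str | Path) -> GenomeSequence:
    """Load a (multi-)FASTA genome, upper-casing sequences.

    Raises on empty files, duplicate or empty record ids, and any character
    outside A/C/G/T/N (ambiguity codes other than N are rejected at load so
    downstream matching semantics stay simple).
    """
    path = Path(path)
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if rec.id in records:
            raise ValueError(f"{path}: duplicate FASTA record id {rec.id!r}")
        records[rec.id] = seq
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    try:
        return GenomeSequence(records)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def _resolve_gene_id(db: gffutils.FeatureDB, feature) -> str:
    """Gene id for a coding feature: nearest 'gene' ancestor, else the
    Parent attribute, else the feature's own id."""
    try:
        for anc in db.parents(feature, featuretype="gene"):
            return anc.id
    except Exception:  # pragma: no cover - malformed hierarchies
        pass
    parent = feature.attributes.get("Parent")
    if parent:
        return parent[0]
    return feature.id


def read_coding_exons(
    path: str | Path,
    feature_type: str = "CDS",
    genome: GenomeSequence | None = None,
) -> CodingAnnotation:
    """Extract coding intervals of ``feature_type`` from a GFF3 file.

    Coordinates convert from GFF3 1-based inclusive to 0-based half-open
    (start-1, end).  Features on chromosomes absent from ``genome`` (when
    supplied) are skipped with a logged warning and count.
    """
    path = Path(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    records = []
    skipped = 0
    for feat in db.features_of_type(feature_type):
        if feat.end < feat.start:
            raise ValueError(f"{path}: feature at {feat.seqid}:{feat.start}-{feat.end} has end < start")
        if genome is not None and feat.seqid not in genome:
            skipped += 1
            continue
        strand = feat.strand if feat.strand in "+-" else "+"
        records.append(
            CodingInterval(feat.seqid, feat.start - 1, feat.end, strand, _resolve_gene_id(db, feat))
        )
    if skipped:
        warnings.warn(
            f"{path}: skipped {skipped} {feature_type} feature(s) on chromosomes absent from the genome",
            stacklevel=2,
        )
    if not records:
        warnings.warn(f"{path}: no {feature_type} features found", stacklevel=2)
    lengths = genome.lengths if genome is not None else None
    return CodingAnnotation(records, chrom_lengths=lengths)


def fetch_sequence(genome: GenomeSequence, chrom: str, start: int, end: int, strand: str = "+") -> str:
    """5'->3' sequence of [start, end) on the requested strand."""
    seq = genome[chrom]
    if not (0 <= start <= end <= len(seq)):
        raise ValueError(
            f"interval [{start}, {end}) out of bounds for chromosome {chrom!r} (length {len(seq)})"
        )
    if strand not in "+-":
        raise ValueError(f"invalid strand {strand!r}")
    sub = seq[start:end]
    return sub if strand == "+" else reverse_complement(sub)
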