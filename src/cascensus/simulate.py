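"""Synthetic genomes with planted target/off-target structure, plus the
brute-force search oracle.

The generator emulates only what the census depends on: a multi-chromosome
genome of i.i.d. background bases at a configurable GC fraction, a simple
gene/CDS annotation, and planted spacer+PAM sites — identical copies and
single-mismatch copies at controlled PAM-distal positions, inside and
outside coding exons, on either strand.  No repeat structure or codon
realism is attempted; exact-match combinatorics are all that matter here.

Background sequence is collision-checked against the plants: after
generation the whole genome is rescanned and the attempt is rejected (and
regenerated deterministically) if any non-planted site's spacer lies within
Hamming distance 1 of a planted spacer.  Planted truth tables are therefore
exact for every pair involving a planted site; accidental pairs between
background sites are allowed and are covered by the oracle, not the truth
table.

:func:`brute_force_offtargets` is the independent reference: it enumerates
every window on both strands by direct slicing, filters by IUPAC PAM match
and exon containment, and compares every spacer pair, with no shared search
machinery beyond base-level primitives.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from cascensus.genome import CodingAnnotation, CodingInterval, GenomeSequence, reverse_complement
from cascensus.offtargets import IDENTICAL, OTHER, POS_1_3, OffTargetPair
from cascensus.profiles import (
    FIVE_PRIME,
    THREE_PRIME,
    IUPAC_SETS,
    NucleaseProfile,
    get_profile,
)
from cascensus.scan import TargetSite, scan_targets

__all__ = [
    "PlantEntry",
    "SyntheticGenomeSpec",
    "PlantedSite",
    "TruthTable",
    "generate_genome",
    "write_genome_files",
    "demo_spec",
    "equivalence_spec",
    "brute_force_offtargets",
    "ORACLE_TARGET_GUARD",
]

ORACLE_TARGET_GUARD = 10_000
_COMPLEMENT_BASE = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class PlantEntry:
    """One family of planted sites sharing a base spacer.

    ``mismatch_positions``, ``in_exon`` and ``strands`` are per-copy; a
    mismatch position of ``None`` plants the base spacer unchanged, an
    integer p substitutes the base at PAM-distal position p with its
    complement (guaranteeing a difference).
    """

    profile: str
    spacer: str = "random"
    copies: int = 1
    mismatch_positions: tuple[int | None, ...] = ()
    in_exon: tuple[bool, ...] = ()
    strands: tuple[str, ...] = ()

    def normalized(self) -> "PlantEntry":
        def pad(values, default):
            vals = tuple(values) if values else ()
            return vals + (default,) * (self.copies - len(vals))

        return replace(
            self,
            mismatch_positions=pad(self.mismatch_positions, None),
            in_exon=pad(self.in_exon, True),
            strands=pad(self.strands, "+"),
        )


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    chromosome_lengths: tuple[int, ...] = (50_000, 50_000, 50_000)
    gc: float = 0.36
    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (80, 200)
    intergenic: tuple[int, int] = (200, 600)
    plants: tuple[PlantEntry, ...] = ()
    seed: int = 1


@dataclass(frozen=True)
class PlantedSite:
    site: TargetSite
    in_exon: bool


class TruthTable:
    """Planted sites and the off-target pairs they imply.

    Expected pairs are computed by direct pairwise comparison of the
    planted spacers (in-exon sites only — out-of-exon plants exist to prove
    the containment filter excludes them), independent of the search
    engine.
    """

    def __init__(self, planted: Sequence[PlantedSite]):
        self.planted = list(planted)
        self.expected_pairs: list[OffTargetPair] = []
        in_exon = [p.site for p in self.planted if p.in_exon]
        for i, t in enumerate(in_exon):
            for j, o in enumerate(in_exon):
                if i == j or t.profile != o.profile or t.key == o.key:
                    continue
                diffs = [k for k, (x, y) in enumerate(zip(t.spacer, o.spacer)) if x != y]
                if len(diffs) > 1:
                    continue
                prof = get_profile(t.profile)
                if diffs:
                    idx = diffs[0]
                    pos = (prof.spacer_length - idx) if prof.pam_side == FIVE_PRIME else idx + 1
                    cls = POS_1_3 if pos in (1, 2, 3) else OTHER
                    self.expected_pairs.append(OffTargetPair(t, o, 1, pos, cls))
                else:
                    self.expected_pairs.append(OffTargetPair(t, o, 0, None, IDENTICAL))

    def planted_keys(self, profile: str) -> set[tuple[str, int, str]]:
        return {p.site.key for p in self.planted if p.site.profile == profile}

    def in_exon_sites(self, profile: str) -> list[TargetSite]:
        return [p.site for p in self.planted if p.in_exon and p.site.profile == profile]

    def expected_class_counts(self, profile: str, convention: str = "targets_with_class") -> dict[str, int]:
        pairs = [p for p in self.expected_pairs if p.target.profile == profile]
        if convention == "pair_count":
            counts = {c: 0 for c in (IDENTICAL, POS_1_3, OTHER)}
            for p in pairs:
                counts[p.mismatch_class] += 1
            return counts
        per_class: dict[str, set] = {c: set() for c in (IDENTICAL, POS_1_3, OTHER)}
        for p in pairs:
            per_class[p.mismatch_class].add(p.target.key)
        return {c: len(v) for c, v in per_class.items()}


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)


def _realize_pam(rng: np.random.Generator, pattern: str) -> str:
    return "".join(sorted(IUPAC_SETS[c])[rng.integers(len(IUPAC_SETS[c]))] for c in pattern)


def _apply_mismatch(spacer: str, position: int | None, pam_side: str) -> str:
    if position is None:
        return spacer
    L = len(spacer)
    idx = (L - position) if pam_side == FIVE_PRIME else (position - 1)
    return spacer[:idx] + _COMPLEMENT_BASE[spacer[idx]] + spacer[idx + 1:]


def _overlaps(start: int, end: int, intervals: list[tuple[int, int]]) -> bool:
    return any(start < e and s < end for s, e in intervals)


def _place(
    rng: np.random.Generator,
    site_len: int,
    chrom_names: list[str],
    cds_by_chrom: dict[str, list[CodingInterval]],
    lengths: dict[str, int],
    planted_windows: dict[str, list[tuple[int, int]]],
    in_exon: bool,
    merged: dict[str, list[tuple[int, int]]],
) -> tuple[str, int, str]:
    """Choose (chrom, start, gene_id) for a planted window; raises after
    bounded retries."""
    for _ in range(200):
        if in_exon:
            candidates = [
                (chrom, iv) for chrom in chrom_names
                for iv in cds_by_chrom.get(chrom, [])
                if iv.end - iv.start >= site_len
            ]
            if not candidates:
                raise ValueError("no CDS interval long enough for planting")
            chrom, iv = candidates[rng.integers(len(candidates))]
            start = int(iv.start + rng.integers(iv.end - iv.start - site_len + 1))
            gene = iv.gene_id
        else:
            chrom = chrom_names[rng.integers(len(chrom_names))]
            start = int(rng.integers(lengths[chrom] - site_len + 1))
            gene = ""
            if _overlaps(start, start + site_len, merged.get(chrom, [])):
                continue
        if _overlaps(start, start + site_len, planted_windows.setdefault(chrom, [])):
            continue
        planted_windows[chrom].append((start, start + site_len))
        return chrom, start, gene
    raise ValueError("could not place a planted site after bounded retries (spec unsatisfiable?)")


def _build_annotation(
    rng: np.random.Generator, spec: SyntheticGenomeSpec, chrom_names: list[str]
) -> list[CodingInterval]:
    records = []
    gene_no = 0
    per_chrom = -(-spec.n_genes // len(chrom_names))  # ceil split
    for ci, chrom in enumerate(chrom_names):
        cursor = int(rng.integers(*spec.intergenic))
        length = spec.chromosome_lengths[ci]
        for _ in range(per_chrom):
            if gene_no >= spec.n_genes:
                break
            n_exons = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
            strand = "+" if rng.integers(2) == 0 else "-"
            gene_id = f"SYNG{gene_no + 1:04d}"
            exons = []
            pos = cursor
            for k in range(n_exons):
                elen = int(rng.integers(spec.exon_length[0], spec.exon_length[1] + 1))
                if pos + elen > length - 100:
                    break
                exons.append((pos, pos + elen))
                pos = pos + elen + int(rng.integers(spec.intron_length[0], spec.intron_length[1] + 1))
            if not exons:
                break
            for s, e in exons:
                records.append(CodingInterval(chrom, s, e, strand, gene_id))
            gene_no += 1
            cursor = exons[-1][1] + int(rng.integers(*spec.intergenic))
            if cursor > length - 1000:
                break
    return records


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def generate_genome(spec: SyntheticGenomeSpec, max_attempts: int = 50):
    """Generate (GenomeSequence, CodingAnnotation, TruthTable) from a spec.

    Deterministic for a fixed spec (including its seed).  Attempts are
    rejected and regenerated if any background (non-planted) site of a
    planted profile falls within Hamming distance 1 of a planted spacer,
    so the truth table stays exact.
    """
    chrom_names = [f"chr{i + 1}" for i in range(len(spec.chromosome_lengths))]
    plants = [e.normalized() for e in spec.plants]
    for entry in plants:
        if entry.copies < 1:
            raise ValueError("plant entry must have copies >= 1")
    for attempt in range(max_attempts):
        rng = np.random.default_rng([spec.seed, attempt])
        arrays = {
            name: _random_seq(rng, spec.chromosome_lengths[i], spec.gc)
            for i, name in enumerate(chrom_names)
        }
        lengths = {n: len(a) for n, a in arrays.items()}
        records = _build_annotation(rng, spec, chrom_names)
        annotation = CodingAnnotation(records, chrom_lengths=lengths)
        cds_by_chrom: dict[str, list[CodingInterval]] = {}
        for r in records:
            cds_by_chrom.setdefault(r.chrom, []).append(r)
        merged = annotation.merged_intervals()

        planted: list[PlantedSite] = []
        planted_windows: dict[str, list[tuple[int, int]]] = {}
        try:
            for entry in plants:
                prof = get_profile(entry.profile)
                base = entry.spacer
                if base == "random":
                    base = "".join("ACGT"[rng.integers(4)] for _ in range(prof.spacer_length))
                base = base.upper()
                if len(base) != prof.spacer_length:
                    raise ValueError(
                        f"plant spacer length {len(base)} != profile spacer_length {prof.spacer_length}"
                    )
                for c in range(entry.copies):
                    spacer = _apply_mismatch(base, entry.mismatch_positions[c], prof.pam_side)
                    pam = _realize_pam(rng, prof.pam_pattern)
                    full = spacer + pam if prof.pam_side == THREE_PRIME else pam + spacer
                    strand = entry.strands[c]
                    chrom, start, gene = _place(
                        rng, prof.site_length, chrom_names, cds_by_chrom, lengths,
                        planted_windows, entry.in_exon[c], merged,
                    )
                    placed = full if strand == "+" else reverse_complement(full)
                    arrays[chrom][start:start + prof.site_length] = np.frombuffer(
                        placed.encode(), dtype=np.uint8
                    )
                    genes = (gene,) if gene else ()
                    planted.append(
                        PlantedSite(
                            TargetSite(prof.name, chrom, start, start + prof.site_length,
                                       strand, spacer, pam, genes),
                            entry.in_exon[c],
                        )
                    )
        except ValueError:
            if attempt == max_attempts - 1:
                raise
            continue

        genome = GenomeSequence({n: a.tobytes().decode() for n, a in arrays.items()})
        if _background_collision(genome, planted):
            continue
        return genome, annotation, TruthTable(planted)
    raise ValueError(f"spec unsatisfiable after {max_attempts} attempts")


def _background_collision(genome: GenomeSequence, planted: Sequence[PlantedSite]) -> bool:
    """True if any non-planted site lies within distance 1 of a planted
    spacer of the same profile (anywhere in the genome, either strand)."""
    by_profile: dict[str, list[PlantedSite]] = {}
    for p in planted:
        by_profile.setdefault(p.site.profile, []).append(p)
    for name, plist in by_profile.items():
        prof = get_profile(name)
        keys = {p.site.key for p in plist}
        spacers = [p.site.spacer for p in plist]
        for site in scan_targets(genome, prof, annotation=None):
            if site.key in keys:
                continue
            for sp in spacers:
                if _hamming(site.spacer, sp) <= 1:
                    return True
    return False


def write_genome_files(
    genome: GenomeSequence, annotation: CodingAnnotation, out_prefix: str | Path
) -> tuple[Path, Path]:
    """Write FASTA and GFF3 (gene/mRNA/CDS hierarchy); returns the paths."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    fasta = out_prefix.with_suffix(".fasta")
    gff = out_prefix.with_suffix(".gff3")
    with open(fasta, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    by_gene: dict[str, list[CodingInterval]] = {}
    for r in annotation.records:
        by_gene.setdefault(r.gene_id, []).append(r)
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id in sorted(by_gene):
            ivs = by_gene[gene_id]
            chrom, strand = ivs[0].chrom, ivs[0].strand
            lo = min(r.start for r in ivs) + 1
            hi = max(r.end for r in ivs)
            fh.write(f"{chrom}\tcascensus\tgene\t{lo}\t{hi}\t.\t{strand}\t.\tID={gene_id}\n")
            fh.write(f"{chrom}\tcascensus\tmRNA\t{lo}\t{hi}\t.\t{strand}\t.\tID={gene_id}.1;Parent={gene_id}\n")
            for r in ivs:
                fh.write(
                    f"{chrom}\tcascensus\tCDS\t{r.start + 1}\t{r.end}\t.\t{strand}\t0\t"
                    f"ID=CDS:{gene_id};Parent={gene_id}.1\n"
                )
    return fasta, gff


def demo_spec(seed: int = 1) -> SyntheticGenomeSpec:
    """The canonical demo fixture: 3 x 50 kb, 60 genes, 12 planted sites
    covering every off-target class, both strands, and out-of-exon
    exclusion."""
    plants = (
        PlantEntry("SpCas9", "random", 2, (None, None), (True, True), ("+", "-")),
        PlantEntry("SpCas9", "random", 2, (None, 1), (True, True), ("+", "+")),
        PlantEntry("SpCas9", "random", 2, (None, 2), (True, True), ("+", "-")),
        PlantEntry("SpCas9", "random", 2, (None, 3), (True, True), ("+", "+")),
        PlantEntry("SpCas9", "random", 2, (None, 7), (True, True), ("+", "-")),
        PlantEntry("SpCas9", "random", 2, (None, None), (True, False), ("+", "+")),
    )
    return SyntheticGenomeSpec(plants=plants, seed=seed)


def equivalence_spec(seed: int) -> SyntheticGenomeSpec:
    """A 3 x 50 kb genome planting pairs for all five profiles, used for
    engine-vs-oracle equivalence runs."""
    mismatch_cycle = (None, 1, 2, 3, 7)
    plants = []
    for i, name in enumerate(("SpCas9", "SaCas9", "SpCas9-VQR", "SpCas9-VRER", "Lb/AsCas12a")):
        pos = mismatch_cycle[(seed + i) % len(mismatch_cycle)]
        plants.append(PlantEntry(name, "random", 2, (None, pos), (True, True), ("+", "-")))
    plants.append(PlantEntry("SpCas9", "random", 3, (None, None, None), (True, True, True), ("+", "-", "+")))
    return SyntheticGenomeSpec(plants=tuple(plants), seed=seed)


def _oracle_sites(
    genome: GenomeSequence,
    annotation: CodingAnnotation | None,
    profile: NucleaseProfile,
) -> list[TargetSite]:
    """Naive all-windows enumeration by direct slicing, both strands."""
    L, plen, w = profile.spacer_length, profile.pam_length, profile.site_length
    pam_sets = [IUPAC_SETS[c] for c in profile.pam_pattern]
    sites = []
    for chrom in genome:
        seq = genome[chrom]
        for start in range(len(seq) - w + 1):
            window = seq[start:start + w]
            for strand in "+-":
                oriented = window if strand == "+" else reverse_complement(window)
                if profile.pam_side == THREE_PRIME:
                    spacer, pam = oriented[:L], oriented[L:]
                else:
                    pam, spacer = oriented[:plen], oriented[plen:]
                if any(c not in "ACGT" for c in spacer):
                    continue
                if not all(c in s for c, s in zip(pam, pam_sets)):
                    continue
                if annotation is not None:
                    if not annotation.contains(chrom, start, start + w):
                        continue
                    genes = annotation.genes_overlapping(chrom, start, start + w)
                else:
                    genes = ()
                sites.append(TargetSite(profile.name, chrom, start, start + w, strand, spacer, pam, genes))
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return sites


def brute_force_offtargets(
    genome: GenomeSequence,
    annotation: CodingAnnotation | None,
    profile: NucleaseProfile,
    max_mismatch: int = 1,
) -> tuple[list[TargetSite], list[OffTargetPair]]:
    """Reference search: naive window enumeration plus all-pairs spacer
    comparison.  Guarded to small inputs; the indexed engine must agree
    with this exactly on every synthetic genome."""
    sites = _oracle_sites(genome, annotation, profile)
    n = len(sites)
    if n > ORACLE_TARGET_GUARD:
        raise ValueError(
            f"{n} targets exceeds the oracle guard of {ORACLE_TARGET_GUARD}; use find_offtargets"
        )
    pairs: list[OffTargetPair] = []
    if n:
        arr = np.frombuffer("".join(s.spacer for s in sites).encode(), dtype=np.uint8).reshape(n, -1)
        chunk = max(1, (1 << 24) // max(1, arr.shape[1] * n))
        for lo in range(0, n, chunk):
            hi = min(n, lo + chunk)
            d = (arr[lo:hi, None, :] != arr[None, :, :]).sum(axis=2)
            ii, jj = np.nonzero(d <= max_mismatch)
            for i, j in zip(ii + lo, jj):
                i, j = int(i), int(j)
                if i == j:
                    continue
                t, o = sites[i], sites[j]
                diffs = [k for k, (x, y) in enumerate(zip(t.spacer, o.spacer)) if x != y]
                if len(diffs) == 0:
                    pairs.append(OffTargetPair(t, o, 0, None, IDENTICAL))
                elif len(diffs) == 1:
                    idx = diffs[0]
                    pos = (profile.spacer_length - idx) if profile.pam_side == FIVE_PRIME else idx + 1
                    cls = POS_1_3 if pos in (1, 2, 3) else OTHER
                    pairs.append(OffTargetPair(t, o, 1, pos, cls))
                else:
                    # beyond a single mismatch there is no single distal
                    # position; class falls through to "other"
                    pairs.append(OffTargetPair(t, o, len(diffs), None, OTHER))
    pairs.sort(key=lambda p: (p.target.key, p.offtarget.key))
    return sites, pairs
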