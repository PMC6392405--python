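# Methods

## Coordinate and sequence conventions

All internal coordinates are 0-based, half-open, on the forward strand.
GFF3 input is converted at the file boundary (`start-1, end`). Spacer and PAM
strings are always written 5'→3' on the site's own strand; a site's
`start`/`end` span the full spacer+PAM window regardless of strand.

Genomes must contain only `A C G T N` (case-insensitive; normalised to upper
case). `N` in the genome matches **nothing**, including the pattern letter
`N`: a window overlapping an assembly gap is never a target. IUPAC ambiguity
codes other than `N` are rejected at load time so that every reported site is
a concrete sequence.

## Targets

A target is an occurrence of `spacer + PAM` (3'-PAM profiles) or
`PAM + spacer` (5'-PAM profiles) on either strand. Minus-strand sites are
found by scanning the forward strand for the reverse-complemented pattern, so
one pass covers both strands; overlapping occurrences are all reported.

"Coding exon" means the union of GFF3 `CDS` features, merged across isoforms
per chromosome — counting each isoform separately would double-count sites in
constitutive exons. A target is in a coding exon only if the **full**
spacer+PAM window is contained in one merged interval; a PAM hanging over the
exon boundary would not be faithfully represented in a transcript-derived
screen, and partial-overlap counting is not reproducible across annotation
versions. Gene attribution uses any CDS-bearing gene overlapping the window.

## Nuclease profiles

Five built-in profiles: SpCas9 (20, `NGG`), SaCas9 (21, `NNGGGT`),
SpCas9-VQR (20, `NGAG`), SpCas9-VRER (20, `NGCG`), Lb/AsCas12a (23, `TTTV`).
SaCas9 is modelled with the stricter `NNGGGT` PAM (the variant used for the
validated 21-nt guides) rather than the looser `NNGRRT`; users can supply any
profile table via `load_profiles`. Cas9 profiles carry `cut_offset = 3`: a
blunt cut 3 nt 5' of the PAM, i.e. after spacer base 17 (SpCas9) or 18
(SaCas9). Cas12a cuts distal to the PAM with staggered, variable geometry, so
its cut offset is left undefined by default (`with_cut_offset` opts in).

## Off-target pairs

Pairs are ordered, same-profile, and exclude self-pairs by genomic key
(chromosome, start, strand) — two distinct loci with identical spacers *do*
form a pair in both directions. Spacer mismatch positions are numbered 1 from
the PAM-distal end (index+1 for 3'-PAM, length−index for 5'-PAM). Classes:
`identical` (0 mismatches), `pos_1_3` (1 mismatch at distal positions 1–3),
`other` (1 mismatch elsewhere; or, when `max_mismatch > 1`, >1 mismatches
with `mismatch_position = None`).

For `max_mismatch ≤ 1` the search uses an exact-key index plus L
position-masked keys per spacer; for larger radii it falls back to a chunked
vectorised all-pairs comparison. Both are exhaustive; the index is just fast.

Summaries support two counting conventions because a published per-class
tabulation can be read either way: `targets_with_class` (default) counts
targets having at least one pair of a class; `pair_count` counts ordered
pairs. The default was chosen on internal-consistency grounds: ordered
identical pairs necessarily come in even totals, while per-target counts need
not, and per-target class counts can sum to more than the number of targets
with any off-target (a target can have pairs in several classes).
`percent_with_any` is reported to two decimals (61,739 / 2,695,798 → 2.29).

## Validation-design filters

- `filter_expressed(pairs, allowlist)` keeps pairs whose target **and**
  off-target each overlap at least one allow-listed (e.g. leaf-expressed)
  gene.
- `filter_first3` keeps single-mismatch pairs at distal positions 1–3, where
  Cas9 tolerance is highest, making them informative specificity probes.
- `restriction_assay_candidates` reports enzyme recognition sites that
  **strictly contain** the between-base cut point on either strand: only then
  does imperfect repair destroy the site, enabling a digest-based mutation
  readout. A site merely touching the cut boundary survives clean re-ligation
  and is excluded. A small table of common 6-cutters ships as package data.
- `shared_flank_guides` finds guide sites (any strand, either side, within a
  1000 bp window excluding the site itself) whose full site sequence occurs
  near **both** loci of a pair, enabling paired deletions that give a
  PCR-sized readout when no restriction site spans the cut.
- `transversion_variant` substitutes the complement base at a chosen distal
  position, producing a purine↔pyrimidine change; it is an involution, so a
  guide and its variant differ at exactly that position.

## Spacer statistics

`gc_percent` is exact (G+C count × 100 / length). `seed_sequence` returns the
6 bases adjacent to the PAM (PAM-proximal), the region where mismatch
sensitivity is highest. `compare_gc` is a one-tailed two-sample t-test
(active > inactive) with pooled variance by default (`equal_var=True`,
recorded in the result; Welch available). `normalize_mutation_rate` divides
an observed mutation rate by a delivery/transformation efficiency, warning if
the normalised rate exceeds 1.

## Synthetic genomes and the oracle

`generate_genome(spec)` builds an i.i.d. background at a configurable GC
fraction (default 0.36, a typical plant genome-wide value), lays out
gene/mRNA/CDS hierarchies, and plants spacer+PAM copies with per-copy
mismatch position, strand and exon membership. Determinism: all randomness
flows from `numpy.random.default_rng([seed, attempt])`. If the background
accidentally contains a window within Hamming distance 1 of a planted spacer,
the whole genome is regenerated with the next attempt index (rejection
sampling keeps the background distribution unbiased near the planted sites);
accidental background–background pairs are allowed — the truth table is
defined only over planted sites, and background pairs are covered by the
oracle comparison instead.

`brute_force_offtargets` is the independent oracle: it enumerates every
window on both strands by naive slicing (no index) and compares all spacer
pairs. The pair stage is vectorised in chunks for speed but remains
semantically all-pairs. A guard (10,000 targets) rejects inputs where the
quadratic comparison would be unreasonable.

The t-test was frozen against an independent reference implementation
(R `t.test`, `var.equal=TRUE`, `alternative="greater"`) on a fixed example;
the expected statistic and p-value are asserted to 8–9 significant digits in
the test suite.

## External-data analyses

Two analyses need inputs that cannot be shipped: the genome-wide census
requires the TAIR10 whole-chromosome FASTA and gene GFF3 (place under
`data/tair10/`), and the tested-spacer GC comparison requires the table of
tested spacers with activity labels (`data/tested_spacers.tsv`). The code
paths (`cascensus.census.reproduce_census`, `cascensus.stats
.load_spacer_table` + `compare_gc`) are complete and tested on synthetic
data; the corresponding acceptance tests fail with instructions until the
files are provided.
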