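# cascensus

Genome-wide census of CRISPR-Cas nuclease target sites in coding exons,
near-identical off-target pairs, guide-validation design filters, and spacer
composition statistics — with a synthetic-genome generator and a brute-force
oracle for testing the pipeline end to end.

## The problem

Cas nucleases cut genomic DNA wherever a protospacer (the sequence matched by
the guide RNA's spacer) sits next to the nuclease's protospacer-adjacent motif
(PAM). When a genome contains a second site identical, or nearly identical, to
a chosen target, the nuclease may cut there too. Quantifying how often such
near-identical site pairs occur in coding sequence — and selecting pairs whose
single mismatch falls in the PAM-distal positions where nucleases are most
tolerant — is the groundwork for measuring nuclease specificity in plants.

`cascensus` implements that census for five nuclease profiles:

| profile      | spacer | PAM      | PAM side |
|--------------|--------|----------|----------|
| SpCas9       | 20 nt  | `NGG`    | 3'       |
| SaCas9       | 21 nt  | `NNGGGT` | 3'       |
| SpCas9-VQR   | 20 nt  | `NGAG`   | 3'       |
| SpCas9-VRER  | 20 nt  | `NGCG`   | 3'       |
| Lb/AsCas12a  | 23 nt  | `TTTV`   | 5'       |

A *target* is a spacer+PAM occurrence, on either strand, fully contained in a
coding exon (GFF3 `CDS` features, merged across isoforms). An *off-target
pair* is an ordered pair of same-profile targets whose spacers differ by at
most one substitution; pairs are classed as `identical`, `pos_1_3` (single
mismatch at PAM-distal positions 1–3), or `other`. Mismatch positions are
numbered 1 from the PAM-distal end of the spacer.

## Quick start

Generate a small synthetic genome with planted target/off-target structure,
scan it, and tabulate the pairs:

```bash
cascensus simulate --seed 1 --out-prefix demo
cascensus scan --genome demo.fasta --gff demo.gff3 --profile SpCas9 --out sites.tsv
cascensus offtargets --targets sites.tsv --out-pairs pairs.tsv --out-summary summary.tsv
cascensus design-pairs --targets sites.tsv --genome demo.fasta --out designs.tsv
```

Or from Python:

```python
from cascensus import (
    generate_genome, demo_spec, get_profile,
    scan_targets, find_offtargets, summarize_offtargets,
)

genome, annotation, truth = generate_genome(demo_spec(seed=1))
profile = get_profile("SpCas9")
targets = scan_targets(genome, profile, annotation)
pairs = find_offtargets(targets, profile=profile)
print(summarize_offtargets(targets, pairs))
```

On the seed-1 demo genome this finds 2,981 exonic SpCas9 targets, of which 12
have an off-target within one mismatch (0.40%); the planted pairs cover the
`identical`, `pos_1_3` (positions 1, 2 and 3) and `other` classes.

Worked sequence example: the spacer `TGGCAAAGGAACAAAGCCAT` (GC 45.0%) next to
PAM `GGG` and the spacer `CGGCAAAGGAACAAAGCCAT` form a single-mismatch pair at
PAM-distal position 1 (class `pos_1_3`); the blunt cut falls 3 nt 5' of the
PAM, i.e. after spacer base 17 for SpCas9 and base 18 for SaCas9.

## Modules

- `cascensus.profiles` — nuclease profiles, IUPAC matching, cut positions.
- `cascensus.genome` — FASTA/GFF3 loading, merged coding-exon intervals.
- `cascensus.scan` — strand-aware target scanning with containment filtering.
- `cascensus.offtargets` — Hamming-≤1 pair search, mismatch classification,
  census summaries (two counting conventions: `targets_with_class` and
  `pair_count`).
- `cascensus.design` — validation-design filters: expression allowlists,
  PAM-distal-1–3 selection, restriction sites spanning the cut point, shared
  flanking guides for paired deletions, transversion guide variants.
- `cascensus.stats` — spacer GC content, seed sequences, one-tailed
  active-vs-inactive GC comparison, mutation-rate normalisation.
- `cascensus.simulate` — deterministic synthetic genomes with planted truth
  tables, plus a brute-force all-windows/all-pairs oracle.
- `cascensus.census` — per-profile census over a whole genome
  (`reproduce_census(fasta, gff)` is the full-genome entry point).

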