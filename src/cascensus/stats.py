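"""Spacer nucleotide-composition statistics and activity comparison.

GC content of a spacer correlates with mutagenesis efficiency in plant
protoplasts; this module computes full-spacer and seed-region (the six
bases adjacent to the PAM) GC percentages and runs the one-tailed
two-sample t-test of active-vs-inactive spacers.  The variance assumption
is a recorded parameter: the default is the classical pooled-variance test,
with Welch's unequal-variance test available, and the choice is carried in
the result so reports are unambiguous.

Mutation quantities measured in transient-transfection experiments are
normalised to transfection efficiency (fraction mutated / fraction
transfected); normalised values above 1 are possible with noisy estimates
and are flagged, not clamped.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from scipy import stats as sp_stats

from cascensus.profiles import FIVE_PRIME, NucleaseProfile, get_profile

__all__ = [
    "SpacerRecord",
    "make_spacer_record",
    "gc_percent",
    "seed_sequence",
    "GCComparison",
    "compare_gc",
    "normalize_mutation_rate",
    "load_spacer_table",
]

DEFAULT_SEED_LENGTH = 6
# Reported minimum GC for efficient spacers; a guidance value, not a filter.
GC_GUIDANCE_THRESHOLD = 40.0


def gc_percent(sequence: str) -> float:
    """100 x (#G + #C) / length, over the A/C/G/T alphabet."""
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - set("ACGT")
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)} in sequence")
    return 100.0 * (sequence.count("G") + sequence.count("C")) / len(sequence)


def seed_sequence(spacer: str, profile: NucleaseProfile, seed_length: int = DEFAULT_SEED_LENGTH) -> str:
    """The ``seed_length`` spacer bases adjacent to the PAM."""
    if seed_length > len(spacer):
        raise ValueError(f"seed_length {seed_length} exceeds spacer length {len(spacer)}")
    if profile.pam_side == FIVE_PRIME:
        return spacer[:seed_length]
    return spacer[-seed_length:]


@dataclass(frozen=True)
class SpacerRecord:
    """One tested spacer with its activity label and GC features."""

    spacer: str
    active: bool
    profile: str
    gc_full: float
    gc_seed: float


def make_spacer_record(
    spacer: str,
    active: bool,
    profile: str | NucleaseProfile = "SpCas9",
    seed_length: int = DEFAULT_SEED_LENGTH,
) -> SpacerRecord:
    prof = profile if isinstance(profile, NucleaseProfile) else get_profile(profile)
    return SpacerRecord(
        spacer=spacer,
        active=active,
        profile=prof.name,
        gc_full=gc_percent(spacer),
        gc_seed=gc_percent(seed_sequence(spacer, prof, seed_length)),
    )


@dataclass(frozen=True)
class GCComparison:
    """One-tailed t-test result, active-GC-greater alternative."""

    statistic: float
    pvalue: float
    mean_active: float
    mean_inactive: float
    n_active: int
    n_inactive: int
    equal_var: bool
    feature: str


def compare_gc(
    records: Sequence[SpacerRecord],
    feature: str = "gc_full",
    equal_var: bool = True,
) -> GCComparison:
    """One-tailed two-sample t-test that active spacers have higher GC.

    ``feature`` selects ``gc_full`` or ``gc_seed``; ``equal_var`` chooses
    the pooled-variance test (default) or Welch's test.
    """
    if feature not in ("gc_full", "gc_seed"):
        raise ValueError(f"unknown feature {feature!r}")
    active = [getattr(r, feature) for r in records if r.active]
    inactive = [getattr(r, feature) for r in records if not r.active]
    for name, group in (("active", active), ("inactive", inactive)):
        if len(group) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 records ({len(group)})")
    res = sp_stats.ttest_ind(active, inactive, equal_var=equal_var, alternative="greater")
    return GCComparison(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        mean_active=float(sum(active) / len(active)),
        mean_inactive=float(sum(inactive) / len(inactive)),
        n_active=len(active),
        n_inactive=len(inactive),
        equal_var=equal_var,
        feature=feature,
    )


def normalize_mutation_rate(mutated_fraction: float, transfection_efficiency: float) -> float:
    """Mutated fraction divided by transfection efficiency.

    Values above 1 are returned but flagged with a warning, since they
    indicate the efficiency estimate undershot the truly transfected
    fraction.
    """
    if not 0 <= mutated_fraction <= 1:
        raise ValueError(f"mutated_fraction {mutated_fraction} outside [0, 1]")
    if not 0 < transfection_efficiency <= 1:
        raise ValueError(f"transfection_efficiency {transfection_efficiency} outside (0, 1]")
    rate = mutated_fraction / transfection_efficiency
    if rate > 1:
        warnings.warn(
            f"normalised mutation rate {rate:.3f} exceeds 1; transfection efficiency likely underestimated",
            stacklevel=2,
        )
    return rate


def load_spacer_table(path: str | Path, profile: str = "SpCas9", seed_length: int = DEFAULT_SEED_LENGTH) -> list[SpacerRecord]:
    """Read a TSV of tested spacers: columns spacer, active (0/1 or
    true/false), and optionally profile."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "spacer" not in reader.fieldnames:
            raise ValueError(f"{path}: expected a header with at least 'spacer' and 'active' columns")
        for row in reader:
            active = str(row["active"]).strip().lower() in ("1", "true", "yes", "y")
            records.append(
                make_spacer_record(row["spacer"].upper(), active, row.get("profile") or profile, seed_length)
            )
    return records
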