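"""Nuclease target-site profiles: PAM patterns, IUPAC matching, cut-site model.

A :class:`NucleaseProfile` describes how one Cas nuclease recognises a
target: the programmable spacer length, the PAM pattern as an IUPAC string,
which side of the protospacer the PAM sits on, and (where configured) the
blunt-cut offset measured from the PAM-proximal end of the spacer.

Five profiles ship built in:

========  ======  =======  ========  ==========
name      spacer  PAM      PAM side  cut offset
========  ======  =======  ========  ==========
SpCas9        20  NGG      3'                 3
SaCas9        21  NNGGGT   3'                 3
SpCas9-VQR    20  NGAG     3'                 3
SpCas9-VRER   20  NGCG     3'                 3
Lb/AsCas12a   23  TTTV     5'        undefined
========  ======  =======  ========  ==========

SaCas9 is deliberately fixed to the NNGGGT pattern used for the coding-exon
census (not the broader NNGRRT preference reported for the enzyme); a user
who wants NNGRRT can register a custom profile or load one from a TSV.

An ``N`` base in the *genome* is an unknown base and matches no pattern
position, including ``N`` positions of the pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

__all__ = [
    "IUPAC_SETS",
    "NucleaseProfile",
    "builtin_profiles",
    "get_profile",
    "load_profiles",
    "iupac_match",
    "pattern_to_regex",
    "reverse_complement_pattern",
    "cut_position",
]

# Degeneracy sets. Values deliberately exclude N on the sequence side:
# a genome N is unknown, never a wildcard.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

FIVE_PRIME = "5_prime"
THREE_PRIME = "3_prime"


@dataclass(frozen=True)
class NucleaseProfile:
    """Target-recognition geometry of one Cas nuclease.

    Parameters
    ----------
    name
        Profile label, e.g. ``"SpCas9"``.
    spacer_length
        Length of the programmable spacer / genomic protospacer in nt.
    pam_pattern
        PAM as an IUPAC string, written 5'->3' on the protospacer strand.
    pam_side
        ``"3_prime"`` (Cas9-type) or ``"5_prime"`` (Cas12a-type), relative
        to the protospacer.
    cut_offset
        Blunt-cut distance in nt from the PAM-proximal end of the spacer,
        or ``None`` when no cut model is configured (Cas12a default; its
        staggered cut is not modelled here).
    """

    name: str
    spacer_length: int
    pam_pattern: str
    pam_side: str
    cut_offset: int | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("profile name must be non-empty")
        if self.spacer_length <= 0:
            raise ValueError(f"spacer_length must be positive, got {self.spacer_length}")
        bad = [c for c in self.pam_pattern if c not in IUPAC_SETS]
        if bad or not self.pam_pattern:
            raise ValueError(f"pam_pattern {self.pam_pattern!r} contains non-IUPAC codes {bad}")
        if self.pam_side not in (FIVE_PRIME, THREE_PRIME):
            raise ValueError(f"pam_side must be {FIVE_PRIME!r} or {THREE_PRIME!r}, got {self.pam_side!r}")

    @property
    def pam_length(self) -> int:
        return len(self.pam_pattern)

    @property
    def site_length(self) -> int:
        """Full site length: spacer plus PAM."""
        return self.spacer_length + self.pam_length

    def with_cut_offset(self, offset: int) -> "NucleaseProfile":
        return replace(self, cut_offset=offset)


_BUILTINS: tuple[NucleaseProfile, ...] = (
    NucleaseProfile("SpCas9", 20, "NGG", THREE_PRIME, cut_offset=3),
    NucleaseProfile("SaCas9", 21, "NNGGGT", THREE_PRIME, cut_offset=3),
    NucleaseProfile("SpCas9-VQR", 20, "NGAG", THREE_PRIME, cut_offset=3),
    NucleaseProfile("SpCas9-VRER", 20, "NGCG", THREE_PRIME, cut_offset=3),
    NucleaseProfile("Lb/AsCas12a", 23, "TTTV", FIVE_PRIME, cut_offset=None),
)


def builtin_profiles() -> list[NucleaseProfile]:
    """Return the five built-in nuclease profiles."""
    return list(_BUILTINS)


def get_profile(name: str) -> NucleaseProfile:
    """Look up a built-in profile by name (case-sensitive)."""
    for p in _BUILTINS:
        if p.name == name:
            return p
    known = ", ".join(p.name for p in _BUILTINS)
    raise KeyError(f"unknown nuclease profile {name!r}; built-ins: {known}")


def load_profiles(path: str | Path) -> list[NucleaseProfile]:
    """Load profiles from a TSV with columns
    name, spacer_length, pam_pattern, pam_side, cut_offset.

    ``cut_offset`` may be empty or ``"undefined"`` to leave the cut model
    unconfigured.
    """
    profiles = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "name":  # header
                continue
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 tab-separated fields")
            name, spacer_length, pam_pattern, pam_side = fields[:4]
            cut: int | None = None
            if len(fields) > 4 and fields[4] not in ("", "undefined", "NA"):
                cut = int(fields[4])
            profiles.append(NucleaseProfile(name, int(spacer_length), pam_pattern, pam_side, cut))
    return profiles


def iupac_match(sequence: str, pattern: str) -> bool:
    """True iff every base of ``sequence`` lies in the degeneracy set of the
    pattern code at that position.

    ``sequence`` must be over A/C/G/T/N; an N base matches nothing.  Raises
    on length mismatch or invalid codes.
    """
    if len(sequence) != len(pattern):
        raise ValueError(f"length mismatch: sequence {len(sequence)} vs pattern {len(pattern)}")
    for i, (s, p) in enumerate(zip(sequence, pattern)):
        try:
            allowed = IUPAC_SETS[p]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {p!r} at pattern position {i}") from None
        if s not in "ACGTN":
            raise ValueError(f"invalid sequence base {s!r} at position {i}")
        if s not in allowed:
            return False
    return True


def pattern_to_regex(pattern: str) -> str:
    """Translate an IUPAC pattern to a regex over A/C/G/T character classes.

    The classes contain only unambiguous bases, so genomic N never matches.
    """
    parts = []
    for c in pattern:
        try:
            s = IUPAC_SETS[c]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {c!r}") from None
        parts.append(f"[{''.join(sorted(s))}]")
    return "".join(parts)


def reverse_complement_pattern(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (e.g. NNGGGT -> ACCCNN)."""
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(pattern))


def cut_position(site, profile: NucleaseProfile) -> int:
    """Forward-strand between-base coordinate of the expected blunt cut.

    The cut sits ``profile.cut_offset`` nt from the PAM-proximal end of the
    spacer (for Cas9-type enzymes, 3 nt 5' of the PAM), inside the spacer.
    ``site`` needs ``start``, ``end`` and ``strand`` attributes giving the
    full spacer+PAM interval in forward-strand 0-based half-open
    coordinates.
    """
    if profile.cut_offset is None:
        raise ValueError(f"cut model not configured for profile {profile.name!r}")
    plen = profile.pam_length
    # Locate the PAM-proximal spacer end in forward coordinates, then step
    # cut_offset nt into the spacer (away from the PAM).
    pam_at_high = (profile.pam_side == THREE_PRIME) == (site.strand == "+")
    if pam_at_high:
        return site.end - plen - profile.cut_offset
    return site.start + plen + profile.cut_offset
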